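"""Deterministic synthetic reference database and panel fixtures.

Everything here is *synthetic*: locus backbones are random sequences and the
allele names are borrowed from HLA nomenclature purely so that the engineered
variants mirror the clinically interesting situations the pipeline must
handle:

* ``A*01:01:01:02N`` — null allele differing from ``A*01:01:01:01`` only at an
  intron 2 position inside the retained exon flank (excludable from flanks);
  ``A*24:02:01:02L`` is the low-expression analogue.
* ``A*74:12N`` — 6 bp deletion in exon 3 (exonic null, callable directly).
* ``A*68:11N`` — differs from ``A*68:01:01:01`` only in exon 1, which no A
  amplicon covers: not excludable, must be reported with a warning.
* ``B*15:01/02/03/04`` — quartet differing at two exon 2 positions such that
  the two cis/trans genotypes share one unphased (Sanger) superposition.
* ``B*40:01/02/03/04`` — quartet with one exon 2 and one exon 3 site: the
  shuffled pair is indistinguishable across amplicons (inter-exon phase).
* ``C*07:01/02`` — exon 4 starts with a 5 bp C homopolymer (the classic
  pyrosequencing trouble spot).
* ``DRB1*03:68N`` — differs from ``DRB1*03:01:01`` only under the generic DRB
  reverse primer (masked): undetectable by design.
* ``DRB3/4/5`` — co-amplified paralogues with locus signature variants;
  ``DRBP`` — pseudo-locus standing in for the DRB2/6/7/9 pseudogenes
  (>8 differences from every functional allele).
* ``DPB1*04:01:01`` — intron 2 left unannotated (ABSENT) to model the
  widespread lack of intronic reference sequence.

The builder is fully deterministic; the packaged ``data/`` files are written
verbatim from it.
"""

from __future__ import annotations

import numpy as np

from .allele_db import Allele, AlleleDatabase, parse_allele_name

__all__ = [
    "CLASS_I_MODEL",
    "CLASS_II_MODEL",
    "PANEL_ROWS",
    "build_mock_database",
    "build_mids",
    "panel_tsv_text",
    "mids_tsv_text",
    "write_fixtures",
]

_SEED = 454

CLASS_I_MODEL = (
    ("5NCR", 60), ("exon1", 73), ("intron1", 120), ("exon2", 270),
    ("intron2", 120), ("exon3", 276), ("intron3", 100), ("exon4", 276),
    ("intron4", 100), ("exon5", 117), ("intron5", 60), ("exon6", 33),
    ("intron6", 80), ("exon7", 48), ("intron7", 40), ("exon8", 40),
    ("3NCR", 40),
)

CLASS_II_MODEL = (
    ("5NCR", 40), ("exon1", 60), ("intron1", 200), ("exon2", 270),
    ("intron2", 150), ("exon3", 282), ("intron3", 100), ("exon4", 111),
    ("3NCR", 30),
)

#: Panel rows (tab-separated cell values) consistent with the mock gene models.
PANEL_ROWS = [
    ("A", 2, "A*01:01:01:01", "exon1", "51-67", "intron2", "66-83", 496, "long", "1"),
    ("A", 3, "A*01:01:01:01", "intron2", "95-116", "intron3", "65-83", 385, "long", "1"),
    ("A", 4, "A*01:01:01:01", "intron3", "75-95", "intron4", "76-91", 393, "long", "1"),
    ("B", 1, "B*07:02:01:01", "5NCR", "35-55", "intron1", "45-59", 158, "short", "0.5"),
    ("B", 2, "B*07:02:01:01", "intron1", "45-59", "intron2", "25-43", 389, "long", "1"),
    ("B", 3, "B*07:02:01:01", "intron2", "95-109", "intron3", "36-52", 354, "long", "1"),
    ("B", 4, "B*07:02:01:01", "intron3", "70-88", "exon5", "27-45", 452, "long", "1"),
    ("C", 1, "C*01:02:01:01", "5NCR", "30-50", "intron1", "42-62", 166, "short", "0.5"),
    ("C", 2, "C*01:02:01:01", "intron1", "42-62", "intron2", "42-58", 407, "long", "1"),
    ("C", 3, "C*01:02:01:01", "intron2", "85-105", "intron3", "65-83", 395, "long", "1"),
    ("C", 4, "C*01:02:01:01", "intron3", "70-87", "intron4", "76-94", 401, "long", "1"),
    ("C", 7, "C*01:02:01:01", "intron6", "62-80", "exon8", "14-33", 140, "short", "0.5"),
    ("DRB", 2, "DRB1*01:01:01", "intron1", "168-189", "exon2", "250-270", 303, "long", "6"),
    ("DRB", 3, "DRB1*01:01:01", "intron2", "120-140", "intron3", "1-20", 333, "long", "1"),
    ("DQB1", 2, "DQB1*02:01:01", "intron1|exon2", "191-200|1-9", "exon2|intron2", "268-270|1-16", 296, "short", "0.5"),
    ("DQB1", 3, "DQB1*02:01:01", "exon3", "43-62", "intron3", "1-27", 267, "short", "0.5"),
    ("DPB1", 2, "DPB1*03:01:01", "intron1", "168-195", "intron2", "3-27", 330, "long", "1"),
]

_BASES = "ACGT"
_ROT = {"A": "C", "C": "G", "G": "T", "T": "A"}


def _random_backbone(rng, model) -> dict[str, str]:
    return {
        feat: "".join(rng.choice(list(_BASES), size=n))
        for feat, n in model
    }


def _sub(seq: str, pos0: int) -> str:
    """Substitute position *pos0* with the next base in a fixed rotation."""
    return seq[:pos0] + _ROT[seq[pos0]] + seq[pos0 + 1 :]


def _apply(backbone: dict[str, str], edits) -> dict[str, str]:
    feats = dict(backbone)
    for edit in edits:
        if edit[0] == "sub":
            _, feat, pos0 = edit
            feats[feat] = _sub(feats[feat], pos0)
        elif edit[0] == "del":
            _, feat, pos0, length = edit
            feats[feat] = feats[feat][:pos0] + feats[feat][pos0 + length :]
        elif edit[0] == "set":
            _, feat, pos0, bases = edit
            s = feats[feat]
            feats[feat] = s[:pos0] + bases + s[pos0 + len(bases) :]
        elif edit[0] == "drop":
            _, feat = edit
            feats.pop(feat)
        else:  # pragma: no cover - builder misuse
            raise ValueError(edit)
    return feats


def _sig(feat: str, positions) -> list:
    return [("sub", feat, p) for p in positions]


# name -> list of edits relative to the locus backbone
_CLASS_I_LOCI: dict[str, dict[str, list]] = {
    "A": {
        "A*01:01:01:01": [],
        "A*01:01:01:02N": _sig("intron2", [4]),
        "A*01:02": _sig("exon2", [50, 120]),
        "A*02:01:01:01": _sig("exon2", [30, 90, 150]) + _sig("exon3", [40, 100]) + _sig("exon4", [60]),
        "A*03:01:01:01": _sig("exon2", [45, 135]) + _sig("exon3", [70, 160]) + _sig("exon4", [90, 170]),
        "A*24:02:01:01": _sig("exon2", [20, 80, 140, 200]) + _sig("exon3", [25, 85, 145]) + _sig("exon4", [35, 95]),
        "A*24:02:01:02L": _sig("exon2", [20, 80, 140, 200]) + _sig("exon3", [25, 85, 145]) + _sig("exon4", [35, 95]) + _sig("intron2", [7]),
        "A*68:01:01:01": _sig("exon2", [60, 180]) + _sig("exon3", [55, 130]) + _sig("exon4", [75]),
        "A*68:11N": _sig("exon2", [60, 180]) + _sig("exon3", [55, 130]) + _sig("exon4", [75]) + _sig("exon1", [30]),
        "A*74:01:01:01": _sig("exon2", [10, 110, 210]) + _sig("exon3", [90, 200]),
        "A*74:12N": _sig("exon2", [10, 110, 210]) + _sig("exon3", [90, 200]) + [("del", "exon3", 100, 6)],
    },
    "B": {
        "B*07:02:01:01": [],
        "B*08:01:01:01": _sig("exon1", [20]) + _sig("exon2", [40, 100, 160]) + _sig("exon3", [50, 110]) + _sig("exon4", [45]),
        # cis/trans quartet: two exon 2 sites on a shared backbone
        "B*15:01:01:01": _sig("exon2", [230, 70, 190]),
        "B*15:02:01:01": _sig("exon2", [230]),
        "B*15:03:01:01": _sig("exon2", [230, 70]),
        "B*15:04:01:01": _sig("exon2", [230, 190]),
        # inter-exon quartet: one exon 2 and one exon 3 site
        "B*40:01:01:01": _sig("exon4", [130]) + _sig("exon2", [120]) + _sig("exon3", [80]),
        "B*40:02:01:01": _sig("exon4", [130]),
        "B*40:03:01:01": _sig("exon4", [130]) + _sig("exon2", [120]),
        "B*40:04:01:01": _sig("exon4", [130]) + _sig("exon3", [80]),
    },
    "C": {
        "C*01:02:01:01": [],
        "C*03:03:01:01": _sig("exon2", [55, 140]) + _sig("exon3", [65]),
        "C*03:04:01:01": _sig("exon2", [55, 140, 220]) + _sig("exon3", [65]),
        "C*04:01:01:01": _sig("exon1", [25]) + _sig("exon2", [35, 95, 155]) + _sig("exon4", [50]),
        "C*05:01:01:01": _sig("exon2", [75, 165]) + _sig("exon3", [105]) + _sig("exon7", [20]),
        "C*06:02:01:01": _sig("exon2", [85, 175, 245]) + _sig("exon3", [125]),
        "C*07:01:01:01": [("set", "exon4", 0, "CCCCC")] + _sig("exon2", [15, 125]),
        "C*07:02:01:01": [("set", "exon4", 0, "CCCCC")] + _sig("exon2", [15, 125, 205]),
    },
}

_DRB_SIG = {
    "DRB3": _sig("exon2", [12, 52, 92, 132, 172, 212]) + _sig("exon3", [40]),
    "DRB4": _sig("exon2", [16, 56, 96, 136, 176, 216]) + _sig("exon3", [80]),
    "DRB5": _sig("exon2", [24, 64, 104, 144, 184, 224]) + _sig("exon3", [120]),
}

_CLASS_II_LOCI: dict[str, dict[str, list]] = {
    "DRB": {  # shared backbone for the whole DRB group
        "DRB1*01:01:01": [],
        "DRB1*03:01:01": _sig("exon2", [30, 90, 150, 210]) + _sig("exon3", [60, 130]),
        # variant only under the masked generic reverse primer footprint
        "DRB1*03:68N": _sig("exon2", [30, 90, 150, 210, 254]) + _sig("exon3", [60, 130]),
        "DRB1*04:01:01": _sig("exon2", [45, 105, 165, 225]) + _sig("exon3", [75, 145]),
        "DRB1*15:01:01": _sig("exon2", [20, 80, 140, 200]) + _sig("exon3", [95, 175]),
        "DRB3*01:01:01": _DRB_SIG["DRB3"],
        "DRB3*02:02:01": _DRB_SIG["DRB3"] + _sig("exon2", [240]),
        "DRB4*01:01:01": _DRB_SIG["DRB4"],
        "DRB4*01:03:01": _DRB_SIG["DRB4"] + _sig("exon2", [235]),
        "DRB5*01:01:01": _DRB_SIG["DRB5"],
        "DRB5*02:02:01": _DRB_SIG["DRB5"] + _sig("exon2", [245]),
        # pseudogene stand-ins, far from every functional allele
        "DRBP*01:01:01": _sig("exon2", [8, 28, 48, 68, 88, 108, 128, 148, 168, 188, 208, 228]),
        "DRBP*02:01:01": _sig("exon2", [8, 28, 48, 68, 88, 108, 128, 148, 168, 188, 208, 228, 60]),
    },
    "DQB1": {
        "DQB1*02:01:01": [],
        "DQB1*03:01:01": _sig("exon2", [50, 110, 170]) + _sig("exon3", [100, 180]),
        "DQB1*05:01:01": _sig("exon2", [65, 125, 185]) + _sig("exon3", [120, 200]),
        "DQB1*06:02:01": _sig("exon2", [80, 140, 200]) + _sig("exon3", [140, 220]),
    },
    "DPB1": {
        "DPB1*01:01:01": [],
        "DPB1*02:01:01": _sig("exon2", [40, 100]),
        "DPB1*03:01:01": _sig("exon2", [55, 115, 175]),
        "DPB1*04:01:01": _sig("exon2", [70, 130]) + [("drop", "intron2")],
    },
}


def build_mock_database(version: str = "mock-3.7.0") -> AlleleDatabase:
    """Construct the synthetic reference database (always identical)."""
    rng = np.random.default_rng(_SEED)
    db = AlleleDatabase(version=version)
    for locus, table in _CLASS_I_LOCI.items():
        backbone = _random_backbone(rng, CLASS_I_MODEL)
        # keep the first exon 4 bases out of any accidental C run so the
        # engineered C*07 homopolymer is exactly 5 long
        if locus == "C" and backbone["exon4"][5] == "C":
            backbone["exon4"] = backbone["exon4"][:5] + "A" + backbone["exon4"][6:]
        for name, edits in table.items():
            db.add(Allele(parse_allele_name(name), _apply(backbone, edits)))
    for group, table in _CLASS_II_LOCI.items():
        backbone = _random_backbone(rng, CLASS_II_MODEL)
        for name, edits in table.items():
            db.add(Allele(parse_allele_name(name), _apply(backbone, edits)))
    return db


def build_mids(n: int = 24, min_distance: int = 3) -> list[str]:
    """Deterministic set of *n* decamer MIDs with pairwise Hamming >= 3."""
    rng = np.random.default_rng(_SEED + 1)
    mids: list[str] = []
    while len(mids) < n:
        cand = "".join(rng.choice(list(_BASES), size=10))
        if all(sum(a != b for a, b in zip(cand, m)) >= min_distance for m in mids):
            mids.append(cand)
    return mids


def panel_tsv_text() -> str:
    header = "Locus\tExon\tReference\tFwdRegion\tFwdPos\tRevRegion\tRevPos\tLength\tPool\tPoolingFactor"
    lines = [header]
    for row in PANEL_ROWS:
        lines.append("\t".join(str(x) for x in row))
    return "\n".join(lines) + "\n"


def mids_tsv_text() -> str:
    lines = ["MID\tSequence"]
    for i, seq in enumerate(build_mids(), 1):
        lines.append(f"MID{i:02d}\t{seq}")
    return "\n".join(lines) + "\n"


def write_fixtures(directory) -> None:
    """Write panel.tsv and mids.tsv into *directory* (the reference database
    is built in code; use :func:`gstyper.allele_db.write_database` to
    serialise it when a file is needed)."""
    import os

    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "panel.tsv"), "w") as fh:
        fh.write(panel_tsv_text())
    with open(os.path.join(directory, "mids.tsv"), "w") as fh:
        fh.write(mids_tsv_text())
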