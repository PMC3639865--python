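"""Amplicon panel model: fusion primers, MIDs, pools and trimming arithmetic.

The panel mirrors a 17-amplicon GS Junior HLA assay: each amplicon row names a
locus, a target exon, a reference allele and the forward/reverse primer
footprints as (feature, 1-based inclusive span) coordinates on that reference.
Primer footprints may be composite (e.g. an intron tail plus the first bases
of the exon) written ``intron1|exon2`` / ``191-200|1-9``.

Fusion primers have the structure ``adapter + 10 bp MID + template-specific
primer``; reads delivered by the instrument start at the MID.  Two pools are
used: a *short* pool of the 5 shortest amplicons (down-weighted 0.5x against
their higher emulsion-PCR efficiency) and a *long* pool of the remaining 12,
with the generic DRB exon 2 system up-weighted 6x because it co-amplifies
several loci.

Geometry resolved against the reference allele drives exon-boundary trimming:
the 3' cut point is the sum of MID, primer, primer-to-exon distance and exon
length plus a configurable retained-flank offset, which keeps the complete
exon in every trimmed read.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .allele_db import (
    ABSENT,
    FEATURE_ORDER,
    Allele,
    AlleleDatabase,
    AlleleName,
    load_database,
    parse_allele_name,
)

__all__ = [
    "ADAPTER",
    "DRB_GROUP",
    "DRB_PSEUDO_LOCUS",
    "PanelError",
    "PrimerFootprint",
    "AmpliconDef",
    "Panel",
    "load_panel",
    "load_packaged_panel",
    "load_packaged_database",
    "build_fusion_primer",
    "trimming_point",
    "revcomp",
]

#: Synthetic sequencing adapter (key A analogue); instrument-trimmed, so reads
#: begin at the MID, but kept for fusion-primer construction.
ADAPTER = "CGTATCGCCTCCCTCGCGCCA"

#: Loci co-amplified by the generic DRB primer system.
DRB_GROUP = ("DRB1", "DRB3", "DRB4", "DRB5")

#: Pseudo-locus holding non-functional DRB paralogues (DRB2/6/7/9 stand-ins).
DRB_PSEUDO_LOCUS = "DRBP"

_RANK = {f: i for i, f in enumerate(FEATURE_ORDER)}

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class PanelError(ValueError):
    """Schema or configuration error in a panel definition."""


@dataclass(frozen=True)
class PrimerFootprint:
    """Ordered (feature, lo, hi) segments a primer covers on the reference."""

    segments: tuple[tuple[str, int, int], ...]

    @classmethod
    def parse(cls, region_text: str, pos_text: str) -> "PrimerFootprint":
        feats = [f.strip() for f in region_text.split("|")]
        spans = [p.strip() for p in pos_text.split("|")]
        if len(feats) != len(spans):
            raise PanelError(f"region/position arity mismatch: {region_text!r} vs {pos_text!r}")
        segs = []
        for feat, span in zip(feats, spans):
            if feat not in _RANK:
                raise PanelError(f"unknown feature {feat!r}")
            try:
                lo, hi = (int(x) for x in span.split("-"))
            except ValueError:
                raise PanelError(f"bad position span {span!r}") from None
            if not 1 <= lo <= hi:
                raise PanelError(f"bad position span {span!r}")
            segs.append((feat, lo, hi))
        for (f1, _, _), (f2, _, _) in zip(segs, segs[1:]):
            if _RANK[f2] <= _RANK[f1]:
                raise PanelError(f"footprint segments out of gene order: {region_text!r}")
        return cls(tuple(segs))

    @property
    def length(self) -> int:
        return sum(hi - lo + 1 for _, lo, hi in self.segments)

    def sequence(self, allele: Allele) -> str:
        parts = []
        for feat, lo, hi in self.segments:
            seq = allele.feature(feat)
            if seq is ABSENT:
                raise PanelError(f"{allele.name}: primer feature {feat} not annotated")
            if hi > len(seq):
                raise PanelError(f"{allele.name}: primer span {feat}:{lo}-{hi} outside feature")
            parts.append(seq[lo - 1 : hi])
        return "".join(parts)


@dataclass
class AmpliconDef:
    """One panel row plus geometry resolved against the reference allele."""

    locus: str
    exon: int
    reference: AlleleName
    fwd: PrimerFootprint
    rev: PrimerFootprint
    amplicon_length: int
    pool: str
    pooling_factor: float

    # resolved against the reference allele (resolve())
    fwd_primer: str = ""
    rev_primer: str = ""  # top-strand segment; reads carry its reverse complement
    dist5: int = 0  # template bases between fwd primer end and exon coverage start
    dist3: int = 0  # template bases between exon coverage end and rev primer start
    cov_lo: int = 1  # first covered exon base (1-based, exon-local)
    cov_hi: int = 0  # last covered exon base on the reference
    ref_exon_len: int = 0
    masked_prefix: int = 0  # primer-derived exon bases at the 5' covered edge
    masked_suffix: int = 0  # primer-derived exon bases at the 3' covered edge

    @property
    def id(self) -> str:
        return f"{self.locus}-ex{self.exon}"

    @property
    def exon_feature(self) -> str:
        return f"exon{self.exon}"

    @property
    def flank5_feature(self) -> str:
        """Feature immediately preceding the target exon in gene order."""
        return FEATURE_ORDER[_RANK[self.exon_feature] - 1]

    @property
    def flank3_feature(self) -> str:
        return FEATURE_ORDER[_RANK[self.exon_feature] + 1]

    # -- geometry ----------------------------------------------------------

    def resolve(self, db: AlleleDatabase) -> None:
        ref = db.get(self.reference)
        self.fwd_primer = self.fwd.sequence(ref)
        self.rev_primer = self.rev.sequence(ref)
        exon_feat = self.exon_feature
        exon_seq = ref.feature(exon_feat)
        if exon_seq is ABSENT:
            raise PanelError(f"{self.id}: reference lacks {exon_feat}")
        self.ref_exon_len = len(exon_seq)

        seg_list = self._segments(ref)
        # absolute template offsets of each segment
        offsets = {}
        pos = 0
        for feat, lo, hi in seg_list:
            offsets[feat] = (pos, lo, hi)
            pos += hi - lo + 1
        template_len = pos
        if exon_feat not in offsets:
            raise PanelError(f"{self.id}: target exon outside amplicon")
        e_off, e_lo, e_hi = offsets[exon_feat]
        self.cov_lo, self.cov_hi = e_lo, e_hi
        t_exon_start = e_off
        t_exon_end = e_off + (e_hi - e_lo + 1)
        self.dist5 = t_exon_start - self.fwd.length
        self.dist3 = (template_len - self.rev.length) - t_exon_end
        # primer overhang into the exon masks primer-derived bases
        self.masked_prefix = sum(
            hi - lo + 1 for feat, lo, hi in self.fwd.segments if feat == exon_feat
        )
        self.masked_suffix = sum(
            hi - lo + 1 for feat, lo, hi in self.rev.segments if feat == exon_feat
        )
        # a negative distance is only legitimate when the primer overhangs
        # into the exon (the overhang is masked as primer-derived)
        if (self.dist5 < 0 and not self.masked_prefix) or (
            self.dist3 < 0 and not self.masked_suffix
        ):
            raise PanelError(f"{self.id}: inconsistent primer geometry")
        self._t_exon_start = t_exon_start
        self._t_exon_end = t_exon_end
        self._template_len = template_len
        self.dist5 = max(self.dist5, 0)
        self.dist3 = max(self.dist3, 0)
        if self.amplicon_length <= self.fwd.length + self.rev.length:
            raise PanelError(f"{self.id}: amplicon shorter than its primers")

    def _segments(self, allele: Allele) -> list[tuple[str, int, int]]:
        """Feature segments the amplicon covers on *allele*, in gene order."""
        first_feat, first_lo, _ = self.fwd.segments[0]
        last_feat, _, last_hi = self.rev.segments[-1]
        segs: list[tuple[str, int, int]] = []
        for feat in FEATURE_ORDER:
            if _RANK[feat] < _RANK[first_feat] or _RANK[feat] > _RANK[last_feat]:
                continue
            seq = allele.feature(feat)
            if seq is ABSENT:
                raise PanelError(f"{allele.name}: amplicon feature {feat} not annotated")
            lo = first_lo if feat == first_feat else 1
            hi = last_hi if feat == last_feat else len(seq)
            segs.append((feat, lo, hi))
        return segs

    def template(self, allele: Allele) -> Optional[str]:
        """Amplified top-strand sequence for *allele*, or None if a needed
        feature is not annotated (mirrors real database gaps)."""
        try:
            segs = self._segments(allele)
        except PanelError:
            return None
        return "".join(allele.features[f][lo - 1 : hi] for f, lo, hi in segs)

    def exon_window(self, mode: str, offset: int) -> tuple[int, int, int, int]:
        """(start, end, flank5, flank3) of the trim window in template coords.

        The window always contains the complete covered exon span; in
        ``exon_plus_flank`` mode up to *offset* template-derived intron bases
        are retained on each side (never primer-derived bases).
        """
        if mode not in ("exon_only", "exon_plus_flank"):
            raise ValueError(f"unknown trim mode {mode!r}")
        f5 = f3 = 0
        if mode == "exon_plus_flank":
            f5 = min(offset, self.dist5)
            f3 = min(offset, self.dist3)
        # primer-overhang bases leave with the primer, hence the max()
        start = max(self._t_exon_start - f5, self.fwd.length)
        end = self._t_exon_end + f3
        return start, end, f5, f3

    def trimming_cut(self, mode: str, offset: int) -> int:
        """3' cut point measured from the read start (MID included)."""
        _, end, _, _ = self.exon_window(mode, offset)
        return 10 + end


@dataclass
class Panel:
    """Amplicon definitions plus the MID scheme."""

    amplicons: list[AmpliconDef] = field(default_factory=list)
    mids: dict[str, str] = field(default_factory=dict)
    adapter: str = ADAPTER

    def __post_init__(self) -> None:
        seqs = list(self.mids.values())
        if any(len(m) != 10 for m in seqs):
            raise PanelError("all MIDs must be exactly 10 bp")
        if len(set(seqs)) != len(seqs):
            raise PanelError("MID sequences must be pairwise distinct")

    def by_id(self, amplicon_id: str) -> AmpliconDef:
        for amp in self.amplicons:
            if amp.id == amplicon_id:
                return amp
        raise KeyError(amplicon_id)

    def for_locus(self, locus: str) -> list[AmpliconDef]:
        """Amplicons typing *locus*; DRB-group loci share the generic DRB rows."""
        label = "DRB" if locus in DRB_GROUP or locus == DRB_PSEUDO_LOCUS else locus
        return [a for a in self.amplicons if a.locus == label]

    def pools(self) -> dict[str, list[AmpliconDef]]:
        out: dict[str, list[AmpliconDef]] = {}
        for amp in self.amplicons:
            out.setdefault(amp.pool, []).append(amp)
        return out


def build_fusion_primer(adapter: str, mid: str, primer: str) -> str:
    """adapter + MID + template-specific primer (plain concatenation)."""
    if len(mid) != 10:
        raise PanelError(f"MID must be 10 bp, got {len(mid)}")
    return adapter + mid + primer


def trimming_point(
    mid_len: int, primer_len: int, primer_to_exon_distance: int, exon_len: int, offset: int
) -> int:
    """3' trim position from read start: sum of MID, primer, primer-to-exon
    distance and exon length, plus a similarity-enhancing offset."""
    args = (mid_len, primer_len, primer_to_exon_distance, exon_len, offset)
    if any(a < 0 for a in args):
        raise ValueError("trimming_point arguments must be non-negative")
    return sum(args)


_PANEL_COLUMNS = [
    "Locus",
    "Exon",
    "Reference",
    "FwdRegion",
    "FwdPos",
    "RevRegion",
    "RevPos",
    "Length",
    "Pool",
    "PoolingFactor",
]


def load_panel(path, mids_path, db: AlleleDatabase) -> Panel:
    """Read a panel TSV plus its MID companion TSV and resolve primer
    sequences and trimming geometry against *db*."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in _PANEL_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise PanelError(f"panel TSV missing columns: {missing}")
        rows = list(reader)
    amplicons: list[AmpliconDef] = []
    seen = set()
    for row in rows:
        key = (row["Locus"], int(row["Exon"]))
        if key in seen:
            raise PanelError(f"duplicate amplicon for {key}")
        seen.add(key)
        amp = AmpliconDef(
            locus=row["Locus"],
            exon=int(row["Exon"]),
            reference=parse_allele_name(row["Reference"]),
            fwd=PrimerFootprint.parse(row["FwdRegion"], row["FwdPos"]),
            rev=PrimerFootprint.parse(row["RevRegion"], row["RevPos"]),
            amplicon_length=int(row["Length"]),
            pool=row["Pool"],
            pooling_factor=float(row["PoolingFactor"]),
        )
        if amp.pool not in ("short", "long"):
            raise PanelError(f"{amp.id}: unknown pool label {amp.pool!r}")
        amp.resolve(db)
        amplicons.append(amp)

    mids: dict[str, str] = {}
    with open(mids_path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            if "MID" not in row or "Sequence" not in row:
                raise PanelError("MID TSV needs columns MID, Sequence")
            mids[row["MID"]] = row["Sequence"].upper()
    return Panel(amplicons=amplicons, mids=mids)


def _data_path(name: str):
    return resources.files("gstyper") / "data" / name


def load_packaged_database() -> AlleleDatabase:
    """The package's synthetic reference database.

    Built deterministically in code (see :mod:`gstyper.mockdb`) rather than
    shipped as a file; :func:`gstyper.allele_db.write_database` serialises it
    to the annotated-FASTA dialect when a file is needed.
    """
    from .mockdb import build_mock_database

    return build_mock_database()


def load_packaged_panel(db: Optional[AlleleDatabase] = None) -> Panel:
    """The packaged 17-amplicon panel resolved against the packaged mock DB."""
    if db is None:
        db = load_packaged_database()
    return load_panel(_data_path("panel.tsv"), _data_path("mids.tsv"), db)
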