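"""Annotated HLA allele reference database.

The reference is a small annotated-FASTA dialect: each record header names the
allele and gives 1-based inclusive coordinate spans for every annotated gene
feature (5NCR, exon1..exon8, intron1..intron7, 3NCR) within the record
sequence.  Feature *absence* is a first-class state -- most published alleles
lack intronic annotation, and downstream matching must treat a missing feature
as a wildcard rather than an empty sequence.

Nomenclature follows the colon-delimited convention: ``LOCUS*f1:f2[:f3[:f4]]``
with an optional expression suffix (``N`` null, ``L`` low, ``S`` secreted,
``Q`` questionable).  Two-field ("4-digit") reduction keeps the suffix: a null
allele stays clinically distinct at every resolution.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "ABSENT",
    "FEATURE_ORDER",
    "AlleleName",
    "Allele",
    "AlleleDatabase",
    "AlleleNameError",
    "DatabaseLoadError",
    "parse_allele_name",
    "reduce_to_4digit",
    "load_database",
    "write_database",
    "feature_sequence",
]


class AlleleNameError(ValueError):
    """Malformed allele-name string."""


class DatabaseLoadError(ValueError):
    """Structurally invalid reference database file."""


class _Absent:
    """Sentinel for a feature that is not annotated for an allele."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "ABSENT"

    def __bool__(self) -> bool:
        return False


#: Distinguished marker returned when a feature is not annotated.
ABSENT = _Absent()

#: Gene order of all recognised feature identifiers.
FEATURE_ORDER: tuple[str, ...] = (
    ("5NCR",)
    + tuple(x for i in range(1, 8) for x in (f"exon{i}", f"intron{i}"))
    + ("exon8", "3NCR")
)

_FEATURE_RANK = {f: i for i, f in enumerate(FEATURE_ORDER)}

_SUFFIXES = frozenset("NLSQ")

_NAME_RE = re.compile(
    r"^(?P<locus>[A-Z][A-Z0-9]*)\*"
    r"(?P<fields>\d+(?::\d+){0,3})"
    r"(?: ?(?P<suffix>[A-Z]))?$"
)


@dataclass(frozen=True, order=True)
class AlleleName:
    """Structured allele designation, e.g. ``A*01:01:01:02N``."""

    locus: str
    fields: tuple[str, ...]
    suffix: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.locus:
            raise AlleleNameError("empty locus")
        if not 1 <= len(self.fields) <= 4:
            raise AlleleNameError(f"expected 1-4 name fields, got {len(self.fields)}")
        if self.suffix is not None and self.suffix not in _SUFFIXES:
            raise AlleleNameError(f"invalid expression suffix {self.suffix!r}")

    def __str__(self) -> str:
        return f"{self.locus}*{':'.join(self.fields)}{self.suffix or ''}"

    @property
    def is_null(self) -> bool:
        return self.suffix == "N"


def parse_allele_name(text: str) -> AlleleName:
    """Parse ``LOCUS*f1[:f2[:f3[:f4]]][ ][suffix]`` into an :class:`AlleleName`.

    A single optional space is tolerated before the expression suffix (both
    ``A*74:12N`` and ``A*74:12 N`` occur in the literature); the canonical
    form produced by ``str()`` has no space.
    """
    m = _NAME_RE.match(text.strip())
    if m is None:
        raise AlleleNameError(f"malformed allele name: {text!r}")
    suffix = m.group("suffix")
    if suffix is not None and suffix not in _SUFFIXES:
        raise AlleleNameError(f"invalid expression suffix {suffix!r} in {text!r}")
    return AlleleName(
        locus=m.group("locus"),
        fields=tuple(m.group("fields").split(":")),
        suffix=suffix,
    )


def reduce_to_4digit(name: AlleleName) -> AlleleName:
    """Truncate to the first two name fields (protein level), keeping the suffix.

    Idempotent; a one-field name is returned unchanged.
    """
    return AlleleName(name.locus, name.fields[:2], name.suffix)


@dataclass
class Allele:
    """One reference allele: name plus per-feature nucleotide segments."""

    name: AlleleName
    features: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for feat, seq in self.features.items():
            if feat not in _FEATURE_RANK:
                raise DatabaseLoadError(f"{self.name}: unknown feature {feat!r}")
            if not seq or set(seq) - set("ACGT"):
                raise DatabaseLoadError(f"{self.name}: non-ACGT sequence in {feat}")

    @property
    def complete_features(self) -> frozenset[str]:
        return frozenset(self.features)

    def ordered_features(self) -> list[str]:
        return sorted(self.features, key=_FEATURE_RANK.__getitem__)

    @property
    def sequence(self) -> str:
        """Full stored sequence: concatenation of present features in gene order."""
        return "".join(self.features[f] for f in self.ordered_features())

    def feature(self, feat: str):
        """Segment for *feat*, or :data:`ABSENT` when not annotated."""
        return self.features.get(feat, ABSENT)


@dataclass
class AlleleDatabase:
    """Collection of alleles keyed by full name, grouped by locus."""

    version: str
    alleles: dict[str, Allele] = field(default_factory=dict)

    @property
    def loci(self) -> set[str]:
        return {a.name.locus for a in self.alleles.values()}

    def __len__(self) -> int:
        return len(self.alleles)

    def __contains__(self, name) -> bool:
        return str(name) in self.alleles

    def get(self, name) -> Allele:
        key = str(name)
        try:
            return self.alleles[key]
        except KeyError:
            raise KeyError(f"allele {key!r} not in database") from None

    def add(self, allele: Allele) -> None:
        key = str(allele.name)
        if key in self.alleles:
            raise DatabaseLoadError(f"duplicate allele name {key!r}")
        self.alleles[key] = allele

    def by_locus(self, locus: str) -> list[Allele]:
        return [a for a in self.alleles.values() if a.name.locus == locus]


def feature_sequence(db: AlleleDatabase, name, feat: str):
    """Stored segment of *feat* for allele *name*, or :data:`ABSENT`.

    Never returns an empty string; an unknown allele raises ``KeyError``.
    """
    return db.get(name).feature(feat)


# ---------------------------------------------------------------------------
# Annotated-FASTA dialect
#
#   #version=<text>
#   >A*01:01:01:01 features=5NCR:1-60,exon1:61-133,...
#   ACGT... (wrapped at 70 columns)
# ---------------------------------------------------------------------------

_WRAP = 70


def write_database(db: AlleleDatabase, path) -> None:
    """Serialise *db* in the annotated-FASTA dialect (byte-stable)."""
    lines = [f"#version={db.version}"]
    for key in sorted(db.alleles):
        allele = db.alleles[key]
        spans = []
        pos = 1
        for feat in allele.ordered_features():
            seq = allele.features[feat]
            spans.append(f"{feat}:{pos}-{pos + len(seq) - 1}")
            pos += len(seq)
        lines.append(f">{key} features={','.join(spans)}")
        full = allele.sequence
        for i in range(0, len(full), _WRAP):
            lines.append(full[i : i + _WRAP])
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_header(line: str, lineno: int) -> tuple[AlleleName, list[tuple[str, int, int]]]:
    body = line[1:].strip()
    try:
        name_part, feat_part = body.split(" features=", 1)
    except ValueError:
        raise DatabaseLoadError(f"line {lineno}: header lacks features= block") from None
    name = parse_allele_name(name_part)
    spans = []
    for item in feat_part.split(","):
        try:
            feat, rng = item.split(":")
            lo, hi = rng.split("-")
            spans.append((feat, int(lo), int(hi)))
        except ValueError:
            raise DatabaseLoadError(f"line {lineno}: bad feature span {item!r}") from None
    return name, spans


def load_database(path) -> AlleleDatabase:
    """Parse an annotated-FASTA reference file.

    Coordinates are 1-based inclusive, must be non-overlapping, ordered along
    the gene and must exactly tile the record sequence.
    """
    with open(path) as fh:
        raw = fh.read().splitlines()
    version = "unknown"
    records: list[tuple[int, AlleleName, list, list[str]]] = []
    for lineno, line in enumerate(raw, 1):
        if not line.strip():
            continue
        if line.startswith("#"):
            if line.startswith("#version="):
                version = line[len("#version=") :].strip()
            continue
        if line.startswith(">"):
            name, spans = _parse_header(line, lineno)
            records.append((lineno, name, spans, []))
        else:
            if not records:
                raise DatabaseLoadError(f"line {lineno}: sequence before first header")
            records[-1][3].append(line.strip())

    db = AlleleDatabase(version=version)
    for lineno, name, spans, chunks in records:
        seq = "".join(chunks)
        if set(seq) - set("ACGT"):
            raise DatabaseLoadError(f"{name}: non-ACGT character in sequence")
        features: dict[str, str] = {}
        prev_hi = 0
        prev_rank = -1
        for feat, lo, hi in spans:
            rank = _FEATURE_RANK.get(feat)
            if rank is None:
                raise DatabaseLoadError(f"{name}: unknown feature {feat!r}")
            if rank <= prev_rank:
                raise DatabaseLoadError(f"{name}: features out of gene order at {feat}")
            if lo != prev_hi + 1 or hi < lo:
                raise DatabaseLoadError(f"{name}: non-contiguous span for {feat}")
            if hi > len(seq):
                raise DatabaseLoadError(
                    f"{name}: span {feat}:{lo}-{hi} exceeds sequence length {len(seq)}"
                )
            features[feat] = seq[lo - 1 : hi]
            prev_hi, prev_rank = hi, rank
        if prev_hi != len(seq):
            raise DatabaseLoadError(f"{name}: features do not tile full sequence")
        db.add(Allele(name=name, features=features))
    return db
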