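"""Raw-read preprocessing: exact-match demultiplexing, exon-boundary trimming
and run-level QC reporting.

A read is assigned iff its first 10 bases exactly equal a known MID *and* the
bases immediately following exactly equal a panel primer -- the forward
primer, or the reverse complement of the reverse primer for reads sequenced
from the other end.  Everything else lands in the unassigned pool with a
reject reason; the partition is exhaustive (assigned + unassigned = input).

Reverse reads are reverse-complemented before trimming so that all
downstream coordinates are in forward gene orientation.  Trimming keeps the
complete covered exon and, in ``exon_plus_flank`` mode, up to ``offset``
template-derived intron bases on each side.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

from .panel import AmpliconDef, Panel, revcomp

__all__ = [
    "Read",
    "DemuxResult",
    "RunReport",
    "TooShortError",
    "read_fasta",
    "demultiplex",
    "trim_read",
    "build_run_report",
    "write_association_file",
    "read_association_file",
]

DEFAULT_FLANK_OFFSET = 10


class Read(NamedTuple):
    id: str
    seq: str


class TooShortError(ValueError):
    """Read shorter than MID + primer; routed to the too-short list."""


def read_fasta(path) -> list[Read]:
    reads: list[Read] = []
    rid: Optional[str] = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith(">"):
                if rid is not None:
                    reads.append(Read(rid, "".join(chunks)))
                rid = line[1:].split()[0] if len(line) > 1 else None
                if rid is None:
                    raise IOError(f"{path}: empty FASTA header at line {lineno}")
                chunks = []
            elif line.strip():
                if rid is None:
                    raise IOError(f"{path}: sequence before first header at line {lineno}")
                chunks.append(line.strip().upper())
    if rid is not None:
        reads.append(Read(rid, "".join(chunks)))
    return reads


@dataclass
class DemuxResult:
    """Reads binned by (sample, amplicon id, direction) plus unassigned pool."""

    bins: dict[tuple[str, str, str], list[Read]] = field(default_factory=dict)
    unassigned: list[tuple[Read, str]] = field(default_factory=list)

    @property
    def assigned_count(self) -> int:
        return sum(len(v) for v in self.bins.values())

    def per_amplicon_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (_, amp, _), reads in self.bins.items():
            out[amp] = out.get(amp, 0) + len(reads)
        return out

    def per_sample_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (sample, _, _), reads in self.bins.items():
            out[sample] = out.get(sample, 0) + len(reads)
        return out


def demultiplex(
    reads: Iterable[Read],
    panel: Panel,
    association: dict[str, str],
    max_mismatches: int = 0,
) -> DemuxResult:
    """Exact MID + primer demultiplexing (the default, 0-mismatch mode).

    *association* maps sample id -> MID id.  A fuzzy mode tolerating one
    mismatch in the MID exists behind ``max_mismatches=1`` (the packaged MIDs
    are pairwise Hamming distance >= 3) but is off by default.
    """
    mid_ids = list(association.values())
    if len(set(mid_ids)) != len(mid_ids):
        raise ValueError("duplicate MID assignment in association")
    unknown = [m for m in mid_ids if m not in panel.mids]
    if unknown:
        raise ValueError(f"association references unknown MIDs: {unknown}")
    mid_to_sample = {panel.mids[mid]: sample for sample, mid in association.items()}
    primers = []  # (primer-as-seen-in-read, amplicon, direction)
    for amp in panel.amplicons:
        primers.append((amp.fwd_primer, amp, "F"))
        primers.append((revcomp(amp.rev_primer), amp, "R"))
    primers.sort(key=lambda t: -len(t[0]))  # longest match wins

    result = DemuxResult()
    for read in reads:
        mid_seen = read.seq[:10]
        sample = mid_to_sample.get(mid_seen)
        if sample is None and max_mismatches >= 1:
            close = [
                s
                for mseq, s in mid_to_sample.items()
                if sum(a != b for a, b in zip(mseq, mid_seen)) <= max_mismatches
            ]
            if len(close) == 1:
                sample = close[0]
        if sample is None:
            result.unassigned.append((read, "no-MID"))
            continue
        rest = read.seq[10:]
        hit = None
        for pseq, amp, direction in primers:
            if rest.startswith(pseq):
                hit = (amp, direction)
                break
        if hit is None:
            result.unassigned.append((read, "no-primer"))
            continue
        amp, direction = hit
        result.bins.setdefault((sample, amp.id, direction), []).append(read)
    return result


def trim_read(
    read: Read,
    amplicon: AmpliconDef,
    direction: str,
    mode: str = "exon_plus_flank",
    offset: int = DEFAULT_FLANK_OFFSET,
) -> str:
    """Strip MID and primer, orient forward, and cut at the exon boundary.

    The 3' cut point is the trimming-point sum (MID + primer + distance +
    covered exon + flank); the complete covered exon present in the raw read
    is always retained.
    """
    primer_len = amplicon.fwd.length if direction == "F" else amplicon.rev.length
    if len(read.seq) < 10 + primer_len:
        raise TooShortError(f"{read.id}: {len(read.seq)} bp < MID + primer")
    template = read.seq[10:] if direction == "F" else revcomp(read.seq[10:])
    start, end, _, _ = amplicon.exon_window(mode, offset)
    return template[start : min(end, len(template))]


@dataclass
class RunReport:
    """Run performance metrics (sequencer-level wells fields are pass-through
    placeholders with no desk-scale analogue)."""

    total_reads: int = 0
    assigned_reads: int = 0
    unassigned_reads: int = 0
    unassigned_reasons: dict = field(default_factory=dict)
    median_read_length: float = 0.0
    mean_read_length: float = 0.0
    per_amplicon: dict = field(default_factory=dict)
    per_sample: dict = field(default_factory=dict)
    mixed_wells: Optional[int] = None
    dot_wells: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "passed filter reads": self.total_reads,
            "assigned reads": self.assigned_reads,
            "unassigned reads": self.unassigned_reads,
            "unassigned reasons": dict(sorted(self.unassigned_reasons.items())),
            "median read length": self.median_read_length,
            "mean read length": self.mean_read_length,
            "per amplicon read count": dict(sorted(self.per_amplicon.items())),
            "per sample read count": dict(sorted(self.per_sample.items())),
            "mixed": self.mixed_wells,
            "dot": self.dot_wells,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    def to_text(self) -> str:
        d = self.to_dict()
        lines = [f"{k}: {v}" for k, v in d.items() if not isinstance(v, dict)]
        lines.append("per amplicon read count:")
        for amp, n in d["per amplicon read count"].items():
            lines.append(f"  {amp}\t{n}")
        return "\n".join(lines) + "\n"


def build_run_report(demux: DemuxResult, reads: list[Read]) -> RunReport:
    """Summarise a run; lengths are of the raw (untrimmed) reads."""
    lengths = [len(r.seq) for r in reads]
    reasons: dict[str, int] = {}
    for _, reason in demux.unassigned:
        reasons[reason] = reasons.get(reason, 0) + 1
    return RunReport(
        total_reads=len(reads),
        assigned_reads=demux.assigned_count,
        unassigned_reads=len(demux.unassigned),
        unassigned_reasons=reasons,
        median_read_length=float(statistics.median(lengths)) if lengths else 0.0,
        mean_read_length=float(statistics.fmean(lengths)) if lengths else 0.0,
        per_amplicon=demux.per_amplicon_counts(),
        per_sample=demux.per_sample_counts(),
    )


def write_association_file(association: dict[str, str], run_id: str, path) -> None:
    """One row per sample; the run id column ties the file to its run so a
    file from another run is caught before demultiplexing."""
    if len(set(association.values())) != len(association):
        raise ValueError("duplicate MID assignment in association")
    with open(path, "w") as fh:
        fh.write("Sample\tMID\tRunID\n")
        for sample, mid in association.items():
            fh.write(f"{sample}\t{mid}\t{run_id}\n")


def read_association_file(path, expected_run_id: Optional[str] = None):
    """Returns (association, run_id, warnings)."""
    association: dict[str, str] = {}
    run_ids: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["Sample", "MID", "RunID"]:
            raise ValueError(f"{path}: not an association file")
        for line in fh:
            if not line.strip():
                continue
            sample, mid, run_id = line.rstrip("\n").split("\t")[:3]
            association[sample] = mid
            run_ids.add(run_id)
    run_id = run_ids.pop() if len(run_ids) == 1 else "mixed"
    warnings = []
    if expected_run_id is not None and run_id != expected_run_id:
        warnings.append(
            f"association file belongs to run {run_id!r}, expected {expected_run_id!r}"
        )
    return association, run_id, warnings
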