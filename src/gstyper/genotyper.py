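"""Layered genotype calling from trimmed amplicon reads.

The calling engine mirrors the layer model of amplicon-based typing
software: reads of one amplicon are partitioned into a *master* layer (used
for assignment), a *failed* layer (pseudogene-derived or error-laden reads)
and a *deactivated* layer (rule- or user-excluded artefacts such as PCR
crossover chimeras).  Master reads are grouped into at most two haplotype
clusters per amplicon -- merging variants that differ only in homopolymer
run lengths, with a direction-aware consensus rule so that an error-free
sequencing direction corrects the error-prone one -- and every allele pair
of the locus is tested for zero-mismatch compatibility with the clusters.

Phase-layer mismatch counts (MM3/MM4) quantify the cis/trans ambiguity that
unphased sequencing would leave: they re-score the best assignment with the
exon 3 (resp. exon 4) cluster-to-allele mapping swapped while the exon 2
mapping is held fixed.  The unphased (Sanger-style) ambiguity count collapses
the two haplotypes into one IUPAC superposition per exon and counts all
allele pairs consistent with it, which by construction is never smaller than
the phased candidate count.

Null and low-expression alleles that differ from an expressed candidate only
in an intron can be excluded when trimmed reads retain intron flanks
(``exon_plus_flank`` mode); a suffixed allele whose discriminating region no
amplicon covers is retained with a warning.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib

from .allele_db import ABSENT, AlleleDatabase, parse_allele_name, reduce_to_4digit
from .panel import DRB_GROUP, AmpliconDef, Panel

__all__ = [
    "SBT_EXONS",
    "AlignmentResult",
    "HaplotypeCluster",
    "LayerPartition",
    "CandidatePair",
    "GenotypeCall",
    "AlleleMatcher",
    "align_to_reference",
    "partition_layers",
    "build_haplotype_clusters",
    "call_genotype",
    "phase_layer_mismatches",
    "exclude_null_alleles",
    "sanger_ambiguity_count",
    "ambiguity_reduction",
    "pair_to_4digit_string",
]

#: Exons a generic unphased sequencing-based-typing kit covers per locus.
SBT_EXONS = {
    "A": (2, 3, 4),
    "B": (2, 3, 4),
    "C": (2, 3),
    "DRB1": (2,),
    "DRB3": (2,),
    "DRB4": (2,),
    "DRB5": (2,),
    "DQB1": (2, 3),
    "DPB1": (2,),
}

_BIG = 10**9

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
}


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentResult:
    """Mismatch count (substitutions + gap bases), aligned reference span and
    per-position difference list of the best alignment."""

    mismatches: int
    span: tuple[int, int]
    differences: tuple[tuple[int, str], ...] = ()


def align_to_reference(query: str, reference: str) -> AlignmentResult:
    """Align *query* to *reference*, end gaps on the query's flanks free
    (the reference may overhang without penalty).  The mismatch count equals
    the minimal number of substituted plus gapped bases."""
    if not query or not reference:
        raise ValueError("alignment requires two non-empty sequences")
    res = edlib.align(query, reference, mode="HW", task="path")
    start, end = res["locations"][0]
    diffs = []
    if res["cigar"]:
        qpos, rpos = 0, start
        num = ""
        for ch in res["cigar"]:
            if ch.isdigit():
                num += ch
                continue
            n = int(num)
            num = ""
            if ch == "=":
                qpos += n
                rpos += n
            elif ch == "X":
                for k in range(n):
                    diffs.append((rpos + k, "X"))
                qpos += n
                rpos += n
            elif ch == "I":  # insertion in query relative to reference
                diffs.append((rpos, f"I{n}"))
                qpos += n
            elif ch == "D":
                for k in range(n):
                    diffs.append((rpos + k, "D"))
                rpos += n
    return AlignmentResult(
        mismatches=int(res["editDistance"]),
        span=(start, (end if end is None else end + 1) or 0),
        differences=tuple(diffs),
    )


def _hamming_capped(a: str, b: str, cap: int) -> int:
    """Hamming distance, aborting once it exceeds *cap* (returns cap + 1)."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > cap:
                return d
    return d


def _mismatches(a: str, b: str, cap: int = _BIG) -> int:
    if a == b:
        return 0
    if len(a) == len(b):
        return _hamming_capped(a, b, cap)
    if len(a) < len(b):
        return int(edlib.align(a, b, mode="HW")["editDistance"])
    return int(edlib.align(b, a, mode="HW")["editDistance"])


# ---------------------------------------------------------------------------
# per-amplicon expected-sequence model
# ---------------------------------------------------------------------------


class AlleleMatcher:
    """Precomputed expected trimmed sequences per (amplicon, allele).

    For an allele *a* and amplicon, an error-free trimmed read decomposes as
    ``flank5 + core + tail``: the core is the covered, informative exon
    portion of *a* plus any primer-derived (masked) bases -- which always
    show the reference sequence, whatever the template allele -- and the
    flanks are intron-derived.  A feature the allele does not annotate makes
    the corresponding span a wildcard.
    """

    def __init__(self, db: AlleleDatabase, panel: Panel, mode: str = "exon_plus_flank",
                 offset: int = 10):
        self.db = db
        self.panel = panel
        self.mode = mode
        self.offset = offset
        self._ctx: dict[str, dict] = {}
        self._core: dict[tuple[str, str], Optional[str]] = {}
        self._flank5: dict[tuple[str, str], Optional[str]] = {}
        self._tail_src: dict[tuple[str, str], Optional[str]] = {}
        for amp in panel.amplicons:
            start, end, f5, f3 = amp.exon_window(mode, offset)
            ref = db.get(amp.reference)
            ref_exon = ref.features[amp.exon_feature]
            self._ctx[amp.id] = {
                "amp": amp,
                "f5": f5,
                "f3": f3,
                "window_len": end - start,
                "head_skip": (amp.cov_lo - 1) + amp.masked_prefix,
                "tail_skip": (amp.ref_exon_len - amp.cov_hi) + amp.masked_suffix,
                "mask_sfx_seq": ref_exon[amp.cov_hi - amp.masked_suffix : amp.cov_hi],
            }

    def context(self, amp_id: str) -> dict:
        return self._ctx[amp_id]

    def amplicon(self, amp_id: str) -> AmpliconDef:
        return self._ctx[amp_id]["amp"]

    def group_loci(self, locus: str) -> list[str]:
        if locus == "DRB":
            return [l for l in DRB_GROUP if l in self.db.loci]
        return [locus]

    def allele_names(self, locus: str) -> list[str]:
        names: list[str] = []
        for loc in self.group_loci(locus):
            names.extend(sorted(str(a.name) for a in self.db.by_locus(loc)))
        return names

    # -- expected sequences -------------------------------------------------

    def core(self, amp_id: str, allele_name: str) -> Optional[str]:
        key = (amp_id, allele_name)
        if key not in self._core:
            ctx = self._ctx[amp_id]
            exon = self.db.get(allele_name).feature(ctx["amp"].exon_feature)
            if exon is ABSENT:
                self._core[key] = None
            else:
                self._core[key] = (
                    exon[ctx["head_skip"] : len(exon) - ctx["tail_skip"]]
                    + ctx["mask_sfx_seq"]
                )
        return self._core[key]

    def flank5(self, amp_id: str, allele_name: str) -> Optional[str]:
        """Expected 5' intron flank, or None as a wildcard."""
        key = (amp_id, allele_name)
        if key not in self._flank5:
            ctx = self._ctx[amp_id]
            f5 = ctx["f5"]
            if f5 == 0:
                self._flank5[key] = ""
            else:
                seq = self.db.get(allele_name).feature(ctx["amp"].flank5_feature)
                self._flank5[key] = None if seq is ABSENT else seq[-f5:]
        return self._flank5[key]

    def tail_source(self, amp_id: str, allele_name: str) -> Optional[str]:
        """Intron sequence following the exon (sliced to the observed tail
        length at compare time), or None as a wildcard."""
        key = (amp_id, allele_name)
        if key not in self._tail_src:
            ctx = self._ctx[amp_id]
            if ctx["f3"] == 0:
                self._tail_src[key] = ""
            else:
                seq = self.db.get(allele_name).feature(ctx["amp"].flank3_feature)
                self._tail_src[key] = None if seq is ABSENT else seq
        return self._tail_src[key]

    # -- comparisons ---------------------------------------------------------

    def core_mismatches(self, amp_id: str, observed: str, allele_name: str,
                        cap: int = _BIG) -> int:
        core = self.core(amp_id, allele_name)
        if core is None:
            return _BIG
        f5 = self._ctx[amp_id]["f5"]
        obs_core = observed[f5 : f5 + len(core)]
        return _mismatches(obs_core, core, cap)

    def flank_mismatches(self, amp_id: str, observed: str, allele_name: str) -> int:
        """Mismatches in the intron flanks only; wildcards contribute 0."""
        ctx = self._ctx[amp_id]
        f5 = ctx["f5"]
        core = self.core(amp_id, allele_name)
        if core is None:
            return _BIG
        total = 0
        if f5:
            exp5 = self.flank5(amp_id, allele_name)
            if exp5 is not None:
                obs5 = observed[:f5]
                total += _mismatches(obs5[-len(exp5):] if exp5 else "", exp5)
        tail = observed[f5 + len(core) :]
        if tail:
            src = self.tail_source(amp_id, allele_name)
            if src is not None and src != "":
                total += _mismatches(tail, src[: len(tail)])
        return total

    def total_mismatches(self, amp_id: str, observed: str, allele_name: str) -> int:
        return self.core_mismatches(amp_id, observed, allele_name) + self.flank_mismatches(
            amp_id, observed, allele_name
        )

    def best_locus(self, amp_id: str, observed: str, loci: Sequence[str]) -> tuple[str, int]:
        best = (None, _BIG)
        for locus in loci:
            for name in sorted(str(a.name) for a in self.db.by_locus(locus)):
                d = self.core_mismatches(amp_id, observed, name, cap=best[1])
                if d < best[1]:
                    best = (locus, d)
        return best  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# layer partition
# ---------------------------------------------------------------------------


@dataclass
class LayerPartition:
    """master / failed / deactivated partition of one amplicon's reads.

    Each read is a (read id, trimmed sequence, direction) triple; the three
    lists partition the input exactly.
    """

    master: list[tuple[str, str, str]] = field(default_factory=list)
    failed: list[tuple[str, str, str]] = field(default_factory=list)
    deactivated: list[tuple[str, str, str]] = field(default_factory=list)
    best_locus: dict[str, str] = field(default_factory=dict)  # read id -> locus

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.master), len(self.failed), len(self.deactivated)


def _is_drb_chimera(matcher: AlleleMatcher, amp_id: str, seq: str,
                    loci: Sequence[str], max_half_distance: int = 2) -> bool:
    """Crossover detection: the two halves of the covered exon best-match
    different loci of the generic DRB system."""
    ctx = matcher.context(amp_id)
    f5 = ctx["f5"]
    obs = seq[f5:]
    mid = len(obs) // 2
    halves = (obs[:mid], obs[mid:])
    assign = []
    for idx, half in enumerate(halves):
        best = (None, _BIG)
        for locus in loci:
            for name in sorted(str(a.name) for a in matcher.db.by_locus(locus)):
                core = matcher.core(amp_id, name)
                if core is None:
                    continue
                exp = core[:mid] if idx == 0 else core[mid : mid + len(half)]
                d = _mismatches(half, exp, cap=best[1])
                if d < best[1]:
                    best = (locus, d)
        if best[0] is None or best[1] > max_half_distance:
            return False
        assign.append(best[0])
    return assign[0] != assign[1]


def partition_layers(
    reads: Iterable[tuple[str, str, str]],
    matcher: AlleleMatcher,
    amplicon: AmpliconDef,
    locus: str,
    fail_threshold: int = 4,
    move_to_master: Optional[set[str]] = None,
    move_to_failed: Optional[set[str]] = None,
) -> LayerPartition:
    """Assign each trimmed read to the master or failed layer.

    A read enters the master layer iff its best core alignment over all
    alleles of the locus (the whole co-amplified group for DRB) has at most
    *fail_threshold* mismatches.  DRB exon 2 reads recognised as
    DRB1 x DRB3/4/5 crossover artefacts are deactivated.  Explicit override
    sets move individual reads in either direction afterwards.
    """
    loci = matcher.group_loci(locus)
    names = matcher.allele_names(locus)
    part = LayerPartition()
    move_to_master = move_to_master or set()
    move_to_failed = move_to_failed or set()
    is_drb2 = amplicon.locus == "DRB" and amplicon.exon == 2

    by_seq: dict[str, list[tuple[str, str, str]]] = {}
    for tup in reads:
        by_seq.setdefault(tup[1], []).append(tup)

    for seq, members in by_seq.items():
        best_d, best_name = _BIG, None
        for name in names:
            d = matcher.core_mismatches(amplicon.id, seq, name, cap=min(best_d, fail_threshold))
            if d < best_d:
                best_d, best_name = d, name
                if d == 0:
                    break
        chimeric = (
            is_drb2
            and len(loci) > 1
            and best_d > 0
            and _is_drb_chimera(matcher, amplicon.id, seq, loci)
        )
        for tup in members:
            if chimeric:
                part.deactivated.append(tup)
            elif best_d <= fail_threshold:
                part.master.append(tup)
                if best_name is not None:
                    part.best_locus[tup[0]] = parse_allele_name(best_name).locus
            else:
                part.failed.append(tup)

    if move_to_master or move_to_failed:
        def relocate(src: list, dst: list, ids: set[str]) -> None:
            keep = []
            for tup in src:
                (dst if tup[0] in ids else keep).append(tup)
            src[:] = keep

        relocate(part.failed, part.master, move_to_master)
        relocate(part.deactivated, part.master, move_to_master)
        relocate(part.master, part.failed, move_to_failed)
    return part


# ---------------------------------------------------------------------------
# haplotype clustering
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeCluster:
    amplicon: str
    consensus: str
    read_count: int
    fwd_count: int
    rev_count: int
    read_ids: tuple[str, ...] = ()


def _rle(seq: str) -> tuple[str, tuple[int, ...]]:
    bases, lengths = [], []
    for base, grp in itertools.groupby(seq):
        bases.append(base)
        lengths.append(sum(1 for _ in grp))
    return "".join(bases), tuple(lengths)


def _hp_compatible(a: tuple[str, tuple[int, ...]], b: tuple[str, tuple[int, ...]]) -> bool:
    """True when two sequences differ only in homopolymer run lengths."""
    if a[0] != b[0]:
        return False
    diff = [i for i, (x, y) in enumerate(zip(a[1], b[1])) if x != y]
    return bool(diff) and all(max(a[1][i], b[1][i]) >= 3 for i in diff)


def build_haplotype_clusters(
    master: Sequence[tuple[str, str, str]],
    amplicon_id: str,
    min_cluster_fraction: float = 0.10,
) -> tuple[list[HaplotypeCluster], bool]:
    """Group master reads into at most two haplotype clusters.

    Reads are grouped by exact trimmed sequence; variants differing from a
    larger cluster only in homopolymer run lengths are merged into it.  At
    disputed homopolymer runs, the sequencing direction whose reads are
    unanimous decides the consensus length (forward wins a unanimous tie,
    matching the manual-editing practice of correcting reverse-direction
    homopolymer miscalls from clean forward reads).  Clusters below
    *min_cluster_fraction* of the master reads are dropped as noise; a third
    surviving cluster raises the review flag.
    """
    if not master:
        return [], False
    variants: dict[str, list[tuple[str, str, str]]] = {}
    for tup in master:
        variants.setdefault(tup[1], []).append(tup)
    order = sorted(variants.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    clusters: list[dict] = []
    for seq, members in order:
        rle = _rle(seq)
        target = None
        for cl in clusters:
            if cl["rle"][0] == rle[0] and (seq == cl["seq"] or _hp_compatible(rle, cl["rle"])):
                target = cl
                break
        if target is None:
            clusters.append({"seq": seq, "rle": rle, "members": {seq: members}})
        else:
            target["members"][seq] = members

    total = len(master)
    built: list[HaplotypeCluster] = []
    for cl in clusters:
        reads = [t for mem in cl["members"].values() for t in mem]
        consensus = _consensus(cl)
        built.append(
            HaplotypeCluster(
                amplicon=amplicon_id,
                consensus=consensus,
                read_count=len(reads),
                fwd_count=sum(1 for t in reads if t[2] == "F"),
                rev_count=sum(1 for t in reads if t[2] == "R"),
                read_ids=tuple(sorted(t[0] for t in reads)),
            )
        )
    built.sort(key=lambda c: (-c.read_count, c.consensus))
    kept = [c for c in built if c.read_count >= min_cluster_fraction * total]
    review = len(kept) > 2
    return kept[:2], review


def _consensus(cluster: dict) -> str:
    """Direction-aware consensus over homopolymer-merged variants."""
    members = cluster["members"]
    if len(members) == 1:
        return next(iter(members))
    bases = cluster["rle"][0]
    n_runs = len(bases)
    # per run: direction -> {length: read count}
    run_votes: list[dict[str, dict[int, int]]] = [
        {"F": {}, "R": {}} for _ in range(n_runs)
    ]
    for seq, reads in members.items():
        lengths = _rle(seq)[1]
        nf = sum(1 for t in reads if t[2] == "F")
        nr = len(reads) - nf
        for i, ln in enumerate(lengths):
            if nf:
                run_votes[i]["F"][ln] = run_votes[i]["F"].get(ln, 0) + nf
            if nr:
                run_votes[i]["R"][ln] = run_votes[i]["R"].get(ln, 0) + nr
    out = []
    for i, votes in enumerate(run_votes):
        fw, rv = votes["F"], votes["R"]
        choices = set(fw) | set(rv)
        if len(choices) == 1:
            ln = choices.pop()
        elif len(fw) == 1 and len(rv) != 1:
            ln = next(iter(fw))
        elif len(rv) == 1 and len(fw) != 1:
            ln = next(iter(rv))
        elif len(fw) == 1 and len(rv) == 1:
            ln = next(iter(fw))  # both unanimous but disagreeing: forward wins
        else:
            merged: dict[int, int] = {}
            for d in (fw, rv):
                for k, v in d.items():
                    merged[k] = merged.get(k, 0) + v
            ln = max(merged, key=lambda k: (merged[k], -k))
        out.append(bases[i] * ln)
    return "".join(out)


# ---------------------------------------------------------------------------
# genotype calling
# ---------------------------------------------------------------------------


@dataclass
class CandidatePair:
    allele1: str
    allele2: str
    mm: Optional[int] = None
    mm3: Optional[int] = None
    mm4: Optional[int] = None

    @property
    def names(self) -> tuple[str, str]:
        return (self.allele1, self.allele2)


@dataclass
class GenotypeCall:
    locus: str
    status: str  # called | no_result | review
    candidates: list[CandidatePair] = field(default_factory=list)
    ambiguity_string_4digit: list[str] = field(default_factory=list)
    excluded_null_alleles: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    read_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "locus": self.locus,
            "status": self.status,
            "candidates": [
                {"pair": [c.allele1, c.allele2], "MM": c.mm, "MM3": c.mm3, "MM4": c.mm4}
                for c in self.candidates
            ],
            "ambiguity_string_4digit": list(self.ambiguity_string_4digit),
            "excluded_null_alleles": [list(x) for x in self.excluded_null_alleles],
            "warnings": list(self.warnings),
            "read_counts": self.read_counts,
        }


def pair_to_4digit_string(name1: str, name2: str) -> str:
    r1 = str(reduce_to_4digit(parse_allele_name(name1)))
    r2 = str(reduce_to_4digit(parse_allele_name(name2)))
    return "+".join(sorted((r1, r2)))


def _pair_orientation(
    matcher: AlleleMatcher,
    amp_id: str,
    clusters: Sequence[HaplotypeCluster],
    pair: tuple[str, str],
    use_flanks: bool = False,
) -> Optional[tuple[int, ...]]:
    """Zero-mismatch cluster->allele assignment for one amplicon, or None.

    Returns a tuple mapping cluster index -> pair index.  With a single
    cluster both alleles must match it (a homozygous-looking amplicon).
    """
    def fit(cluster: HaplotypeCluster, name: str) -> bool:
        if matcher.core_mismatches(amp_id, cluster.consensus, name) != 0:
            return False
        if use_flanks and matcher.flank_mismatches(amp_id, cluster.consensus, name) != 0:
            return False
        return True

    a, b = pair
    if len(clusters) == 1:
        c = clusters[0]
        return (0,) if fit(c, a) and fit(c, b) else None
    if len(clusters) == 2:
        c1, c2 = clusters
        if fit(c1, a) and fit(c2, b):
            return (0, 1)
        if fit(c1, b) and fit(c2, a):
            return (1, 0)
        return None
    return None


def phase_layer_mismatches(
    pair: tuple[str, str],
    clusters_by_amp: dict[str, list[HaplotypeCluster]],
    matcher: AlleleMatcher,
) -> tuple[Optional[int], Optional[int], Optional[int]]:
    """(MM, MM3, MM4) for *pair* against lane-ordered clusters.

    The cluster lists carry a lane order (allele 1 / allele 2); MM is the
    total core mismatch count under the better of the two globally
    consistent lane-to-allele mappings.  MM3 and MM4 re-score with the
    exon-3 (resp. exon-4) amplicon's mapping swapped relative to the best
    while all other amplicons -- in particular exon 2 -- are held fixed.
    Fewer than two amplicons with clusters: not applicable (all None).
    """
    amps = [a for a, cl in clusters_by_amp.items() if cl]
    if len(amps) < 2:
        return None, None, None

    def amp_cost(amp_id: str, swapped: bool) -> int:
        cl = clusters_by_amp[amp_id]
        a, b = pair if not swapped else (pair[1], pair[0])
        if len(cl) == 1:
            return matcher.core_mismatches(amp_id, cl[0].consensus, pair[0]) + \
                matcher.core_mismatches(amp_id, cl[0].consensus, pair[1])
        return matcher.core_mismatches(amp_id, cl[0].consensus, a) + \
            matcher.core_mismatches(amp_id, cl[1].consensus, b)

    total_id = sum(amp_cost(a, False) for a in amps)
    total_sw = sum(amp_cost(a, True) for a in amps)
    best_swapped = total_sw < total_id
    mm = min(total_id, total_sw)

    def flipped_total(exon: int) -> Optional[int]:
        target = [a for a in amps if matcher.amplicon(a).exon == exon]
        if not target:
            return None
        total = 0
        for a in amps:
            swapped = best_swapped
            if a in target:
                swapped = not swapped
            total += amp_cost(a, swapped)
        return total

    return mm, flipped_total(3), flipped_total(4)


def call_genotype(
    clusters_by_amp: dict[str, list[HaplotypeCluster]],
    locus: str,
    matcher: AlleleMatcher,
    min_reads: int = 20,
    required_amplicons: Optional[Sequence[str]] = None,
) -> GenotypeCall:
    """Enumerate all allele pairs compatible with the clusters of one locus.

    A pair is compatible iff at every amplicon there is a zero-mismatch
    assignment of clusters to the two alleles covering both clusters when
    two exist; an amplicon whose total cluster read count falls below
    *min_reads* makes the locus a no-result.  If no pair reaches zero
    mismatches the best pair is reported for review (novel-variant path).
    """
    if locus not in matcher.db.loci:
        raise ValueError(f"locus {locus!r} not in the reference database")
    required = list(required_amplicons or clusters_by_amp.keys())
    call = GenotypeCall(locus=locus, status="called")
    for amp_id in required:
        cl = clusters_by_amp.get(amp_id, [])
        call.read_counts[amp_id] = {
            "total": sum(c.read_count for c in cl),
            "forward": sum(c.fwd_count for c in cl),
            "reverse": sum(c.rev_count for c in cl),
        }
    low = [a for a, rc in call.read_counts.items() if rc["total"] < min_reads]
    if low:
        call.status = "no_result"
        call.warnings.append(f"insufficient read count on {', '.join(sorted(low))}")
        return call

    names = sorted(str(a.name) for a in matcher.db.by_locus(locus))
    active = {a: cl for a, cl in clusters_by_amp.items() if cl}
    compatible: list[tuple[str, str]] = []
    for i, a in enumerate(names):
        for b in names[i:]:
            if all(
                _pair_orientation(matcher, amp_id, cl, (a, b)) is not None
                for amp_id, cl in active.items()
            ):
                compatible.append((a, b))

    if not compatible:
        best_pair, best_cost = None, _BIG
        for i, a in enumerate(names):
            for b in names[i:]:
                cost = 0
                for amp_id, cl in active.items():
                    costs = []
                    for ordering in ((a, b), (b, a)):
                        if len(cl) == 1:
                            costs.append(
                                matcher.core_mismatches(amp_id, cl[0].consensus, a)
                                + matcher.core_mismatches(amp_id, cl[0].consensus, b)
                            )
                        else:
                            costs.append(
                                matcher.core_mismatches(amp_id, cl[0].consensus, ordering[0])
                                + matcher.core_mismatches(amp_id, cl[1].consensus, ordering[1])
                            )
                    cost += min(costs)
                if cost < best_cost:
                    best_pair, best_cost = (a, b), cost
        call.status = "review"
        call.warnings.append(
            f"no zero-mismatch pair; best pair has {best_cost} mismatches"
        )
        if best_pair:
            call.candidates = [CandidatePair(*best_pair, mm=best_cost)]
            call.ambiguity_string_4digit = [pair_to_4digit_string(*best_pair)]
        return call

    for a, b in compatible:
        lanes = _lane_consistent_clusters(matcher, active, (a, b))
        mm, mm3, mm4 = phase_layer_mismatches((a, b), lanes, matcher)
        call.candidates.append(CandidatePair(a, b, mm=0 if mm is None else mm, mm3=mm3, mm4=mm4))
    call.ambiguity_string_4digit = sorted(
        {pair_to_4digit_string(c.allele1, c.allele2) for c in call.candidates}
    )
    return call


def _lane_consistent_clusters(
    matcher: AlleleMatcher,
    active: dict[str, list[HaplotypeCluster]],
    pair: tuple[str, str],
) -> dict[str, list[HaplotypeCluster]]:
    """Reorder each amplicon's clusters so the pair's zero-mismatch
    assignment maps lane k to allele k everywhere."""
    out: dict[str, list[HaplotypeCluster]] = {}
    for amp_id, cl in active.items():
        orient = _pair_orientation(matcher, amp_id, cl, pair)
        if orient == (1, 0):
            out[amp_id] = [cl[1], cl[0]]
        else:
            out[amp_id] = list(cl)
    return out


def exclude_null_alleles(
    call: GenotypeCall,
    clusters_by_amp: dict[str, list[HaplotypeCluster]],
    matcher: AlleleMatcher,
    mode: str = "exon_plus_flank",
) -> GenotypeCall:
    """Remove candidates whose intron flank conflicts with the observed
    flank consensus (``exon_plus_flank`` mode only).

    Removed alleles are recorded with the discriminating feature; suffixed
    alleles that survive (no covered region separates them) are flagged with
    a retention warning rather than silently kept.
    """
    if call.status != "called":
        return call
    if mode == "exon_only":
        return call
    active = {a: cl for a, cl in clusters_by_amp.items() if cl}
    kept: list[CandidatePair] = []
    removed: list[CandidatePair] = []
    for cand in call.candidates:
        ok = all(
            _pair_orientation(matcher, amp_id, cl, cand.names, use_flanks=True) is not None
            for amp_id, cl in active.items()
        )
        (kept if ok else removed).append(cand)
    if kept:
        kept_names = {n for c in kept for n in c.names}
        for cand in removed:
            for name in cand.names:
                if name in kept_names:
                    continue
                feature = _discriminating_feature(matcher, active, name)
                entry = (name, feature or "intron")
                if entry not in call.excluded_null_alleles:
                    call.excluded_null_alleles.append(entry)
        call.candidates = kept
        call.ambiguity_string_4digit = sorted(
            {pair_to_4digit_string(c.allele1, c.allele2) for c in kept}
        )
    else:
        call.warnings.append("flank evidence conflicts with every candidate; none excluded")
    for cand in call.candidates:
        for name in cand.names:
            suffix = parse_allele_name(name).suffix
            if suffix:
                msg = f"suffixed allele {name} not excludable by covered regions"
                if msg not in call.warnings:
                    call.warnings.append(msg)
    return call


def _discriminating_feature(
    matcher: AlleleMatcher,
    active: dict[str, list[HaplotypeCluster]],
    allele_name: str,
) -> Optional[str]:
    for amp_id, cl in active.items():
        amp = matcher.amplicon(amp_id)
        for cluster in cl:
            if matcher.core_mismatches(amp_id, cluster.consensus, allele_name) != 0:
                continue
            if matcher.flank_mismatches(amp_id, cluster.consensus, allele_name) > 0:
                ctx = matcher.context(amp_id)
                f5 = ctx["f5"]
                exp5 = matcher.flank5(amp_id, allele_name)
                if f5 and exp5 and _mismatches(cluster.consensus[:f5], exp5) > 0:
                    return amp.flank5_feature
                return amp.flank3_feature
    return None


# ---------------------------------------------------------------------------
# ambiguity metrics
# ---------------------------------------------------------------------------


def _superpose_key(s1: str, s2: str):
    if len(s1) != len(s2):
        return ("indel", tuple(sorted((s1, s2))))
    return "".join(_IUPAC[frozenset((a, b))] for a, b in zip(s1, s2))


def sanger_ambiguity_count(
    pair: tuple[str, str],
    locus: str,
    matcher: AlleleMatcher,
) -> int:
    """Number of distinct 4-digit genotype pairs compatible with the unphased
    superposition of *pair* over the exons a generic SBT kit covers.

    The two haplotype sequences are collapsed position-wise into IUPAC codes
    per covered exon (over the same informative spans the clonal assay sees,
    since Sanger typing runs on the same PCR products); every allele pair
    reproducing that superposition is counted.  Always >= the phased
    candidate count.
    """
    exons = SBT_EXONS.get(locus)
    if exons is None:
        raise ValueError(f"no SBT kit definition for locus {locus}")
    amp_ids = [
        amp.id for amp in matcher.panel.for_locus(locus) if amp.exon in exons
    ]
    if not amp_ids:
        raise ValueError(f"no covered SBT exon for locus {locus}")

    def key(a: str, b: str):
        parts = []
        for amp_id in amp_ids:
            ca, cb = matcher.core(amp_id, a), matcher.core(amp_id, b)
            if ca is None or cb is None:
                return None
            parts.append(_superpose_key(ca, cb))
        return tuple(parts)

    observed = key(*pair)
    if observed is None:
        raise ValueError(f"pair {pair} lacks covered exon sequence")
    names = sorted(str(a.name) for a in matcher.db.by_locus(locus))
    hits = set()
    for i, a in enumerate(names):
        for b in names[i:]:
            if key(a, b) == observed:
                hits.add(pair_to_4digit_string(a, b))
    return len(hits)


def ambiguity_reduction(unphased: int, phased: int) -> float:
    """Percent reduction of genotype ambiguity by phased (clonal) typing."""
    if phased < 1 or unphased < phased:
        raise ValueError(
            f"invalid ambiguity counts: unphased={unphased}, phased={phased}"
        )
    return 100.0 * (unphased - phased) / unphased
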