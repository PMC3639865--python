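"""Synthetic sequencing-run generator standing in for the GS Junior.

Produces diploid genotypes, fusion-primer amplicon reads with pyrosequencing
style errors, and truth files for recovery testing.

The error model captures the platform's two characteristic failure modes:

* uniform per-base substitutions (default 0.1%/bp), and
* homopolymer length over/undercalls, with per-run probability
  ``base_rate x (run_length - 1)`` for runs of length >= 3, boosted 3x in
  reverse-orientation reads for runs near the 5' end of the target exon --
  so a C5 stretch at an exon start is miscalled mostly in one direction and
  the caller's direction-aware consensus rule has something to correct.

Read depth per amplicon follows a negative binomial whose mean scales with
the pooling factor; short-pool amplicons get a configurable emulsion-PCR
efficiency boost.  DRB exon 2 additionally receives pseudogene reads (from
the ``DRBP`` pseudo-locus) and DRB1 x DRB3/4/5 crossover chimeras with a
single uniform break point inside the exon.

Errors are confined to the template portion of each read (between the two
primer footprints): MID and primer bases are emitted faithfully, keeping
demultiplexing loss out of the quantities under study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .allele_db import AlleleDatabase
from .mockdb import build_mids
from .panel import DRB_GROUP, DRB_PSEUDO_LOCUS, Panel, revcomp
from .preprocess import Read

__all__ = [
    "ErrorModel",
    "SimTruth",
    "SimulatedRun",
    "simulate_genotypes",
    "simulate_reads",
    "simulate_quant_plate",
    "write_fasta",
]


@dataclass
class ErrorModel:
    """Per-read error and artefact rates (all probabilities in [0, 1])."""

    substitution_rate: float = 0.001  # per template base
    homopolymer_indel_base_rate: float = 0.005  # x (run_length - 1), runs >= 3
    reverse_homopolymer_boost: float = 3.0  # near the 5' exon end only
    chimera_rate: float = 0.02  # DRB exon 2 reads from DRB1 haplotypes
    pseudogene_fraction: float = 0.05  # of DRB exon 2 reads
    short_pool_efficiency: float = 1.4  # emPCR boost for short amplicons
    nb_dispersion: float = 10.0  # negative-binomial size parameter

    def __post_init__(self) -> None:
        for name in (
            "substitution_rate",
            "homopolymer_indel_base_rate",
            "chimera_rate",
            "pseudogene_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")

    @classmethod
    def noise_free(cls) -> "ErrorModel":
        return cls(
            substitution_rate=0.0,
            homopolymer_indel_base_rate=0.0,
            chimera_rate=0.0,
            pseudogene_fraction=0.0,
        )


@dataclass
class SimTruth:
    """Simulated diploid genotypes: the recovery oracle.

    ``genotypes[sample][locus]`` is an ordered pair of full allele names;
    ``mids[sample]`` the assigned MID identifier.
    """

    mids: dict[str, str]
    genotypes: dict[str, dict[str, tuple[str, str]]]
    seed: int

    @property
    def samples(self) -> list[str]:
        return list(self.genotypes)

    @property
    def loci(self) -> list[str]:
        first = next(iter(self.genotypes.values()), {})
        return list(first)

    def homozygote_fraction(self) -> float:
        pairs = [p for g in self.genotypes.values() for p in g.values()]
        if not pairs:
            return 0.0
        return sum(a == b for a, b in pairs) / len(pairs)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"seed": self.seed, "mids": self.mids, "genotypes": self.genotypes},
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        genotypes = {
            s: {loc: tuple(pair) for loc, pair in g.items()}
            for s, g in d["genotypes"].items()
        }
        return cls(mids=d["mids"], genotypes=genotypes, seed=d["seed"])


def simulate_genotypes(
    db: AlleleDatabase,
    n_samples: int,
    homozygote_rate: float = 0.103,
    seed: int = 0,
    loci: Optional[Sequence[str]] = None,
    mids: Optional[Sequence[str]] = None,
) -> SimTruth:
    """Draw diploid genotypes for *n_samples* samples.

    Each locus draw is homozygous with probability *homozygote_rate* (the
    validation-panel composition), otherwise two distinct alleles are drawn.
    The pseudo-locus never enters a genotype.
    """
    if mids is None:
        mids = [f"MID{i:02d}" for i in range(1, len(build_mids()) + 1)]
    if n_samples > len(mids):
        raise ValueError(f"{n_samples} samples exceed the {len(mids)} available MIDs")
    if loci is None:
        loci = sorted(db.loci - {DRB_PSEUDO_LOCUS})
    rng = np.random.default_rng(seed)
    genotypes: dict[str, dict[str, tuple[str, str]]] = {}
    assigned: dict[str, str] = {}
    for i in range(n_samples):
        sample = f"S{i + 1:02d}"
        assigned[sample] = mids[i]
        g: dict[str, tuple[str, str]] = {}
        for locus in loci:
            names = sorted(str(a.name) for a in db.by_locus(locus))
            if len(names) < 2:
                raise ValueError(f"locus {locus} needs >= 2 alleles")
            a1 = names[rng.integers(len(names))]
            if rng.random() < homozygote_rate:
                a2 = a1
            else:
                rest = [n for n in names if n != a1]
                a2 = rest[rng.integers(len(rest))]
            g[locus] = (a1, a2)
        genotypes[sample] = g
    return SimTruth(mids=assigned, genotypes=genotypes, seed=seed)


@dataclass
class SimulatedRun:
    """Reads plus per-read provenance for a simulated sequencing run."""

    run_id: str
    reads: list[Read]
    read_truth: list[dict]
    association: dict[str, str]  # sample -> MID id
    warnings: list[str] = field(default_factory=list)

    def truth_by_id(self) -> dict[str, dict]:
        return {t["read"]: t for t in self.read_truth}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "run_id": self.run_id,
                    "association": self.association,
                    "warnings": self.warnings,
                    "read_truth": self.read_truth,
                },
                fh,
                indent=1,
                sort_keys=True,
            )


def write_fasta(reads: list[Read], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f">{rid}\n{seq}\n")


def _homopolymer_runs(seq: str, lo: int, hi: int) -> list[tuple[int, int]]:
    """(start, length) of runs >= 3 fully inside [lo, hi)."""
    runs = []
    i = lo
    while i < hi:
        j = i
        while j < hi and seq[j] == seq[i]:
            j += 1
        if j - i >= 3:
            runs.append((i, j - i))
        i = j
    return runs


def _inject_errors(
    template: str,
    amp,
    direction: str,
    em: ErrorModel,
    rng: np.random.Generator,
) -> tuple[str, int, int]:
    """Apply substitutions then homopolymer indels; returns (seq, n_sub, n_hp)."""
    lo, hi = amp.fwd.length, len(template) - amp.rev.length
    seq = list(template)
    n_sub = 0
    if em.substitution_rate > 0:
        hits = np.nonzero(rng.random(hi - lo) < em.substitution_rate)[0]
        for off in hits:
            pos = lo + int(off)
            others = [b for b in "ACGT" if b != seq[pos]]
            seq[pos] = others[rng.integers(3)]
            n_sub += 1
    out = "".join(seq)
    n_hp = 0
    if em.homopolymer_indel_base_rate > 0:
        exon_start = amp._t_exon_start
        edits = []
        for start, length in _homopolymer_runs(out, lo, hi):
            p = em.homopolymer_indel_base_rate * (length - 1)
            if direction == "R" and exon_start - 2 <= start <= exon_start + 10:
                p *= em.reverse_homopolymer_boost
            if rng.random() < min(p, 1.0):
                edits.append((start, length, 1 if rng.random() < 0.5 else -1))
        for start, length, delta in sorted(edits, reverse=True):
            base = out[start]
            out = out[:start] + base * (length + delta) + out[start + length :]
            n_hp += 1
    return out, n_sub, n_hp


def simulate_reads(
    truth: SimTruth,
    panel: Panel,
    db: AlleleDatabase,
    mean_depth: float = 182.0,
    error_model: Optional[ErrorModel] = None,
    seed: int = 0,
    run_id: str = "SIMRUN",
) -> SimulatedRun:
    """Emit fusion-primer amplicon reads for every sample/amplicon.

    Each read is ``MID + primer + template-with-errors``; reverse-orientation
    reads are emitted reverse-complemented, starting at the reverse fusion
    primer.  Alleles lacking a feature the amplicon spans are skipped with a
    warning, mirroring real reference-database gaps.
    """
    if not truth.genotypes:
        raise ValueError("empty truth: no samples to simulate")
    em = error_model or ErrorModel()
    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    read_truth: list[dict] = []
    warnings: list[str] = []
    warned: set[tuple[str, str]] = set()
    pseudo_alleles = sorted(str(a.name) for a in db.by_locus(DRB_PSEUDO_LOCUS))
    counter = 0

    template_cache: dict[tuple[str, str], Optional[str]] = {}

    def template_for(amp, allele_name: str) -> Optional[str]:
        key = (amp.id, allele_name)
        if key not in template_cache:
            t = amp.template(db.get(allele_name))
            if t is not None:
                # primer footprints carry the primer's (reference) sequence:
                # template variation under a primer is erased by the PCR
                t = amp.fwd_primer + t[amp.fwd.length : len(t) - amp.rev.length] + amp.rev_primer
            template_cache[key] = t
            if t is None and (amp.id, allele_name) not in warned:
                warned.add((amp.id, allele_name))
                warnings.append(
                    f"{amp.id}: allele {allele_name} lacks an annotated feature; reads skipped"
                )
        return template_cache[key]

    for amp in panel.amplicons:
        is_drb2 = amp.locus == "DRB" and amp.exon == 2
        for sample in truth.samples:
            mid = panel.mids[truth.mids[sample]]
            geno = truth.genotypes[sample]
            if amp.locus == "DRB":
                haps = [
                    (locus, allele)
                    for locus in DRB_GROUP
                    if locus in geno
                    for allele in geno[locus]
                ]
            else:
                if amp.locus not in geno:
                    continue
                haps = [(amp.locus, a) for a in geno[amp.locus]]
            if not haps:
                continue
            drb345 = [h for h in haps if h[0] != "DRB1"]
            mu = mean_depth * amp.pooling_factor
            if amp.pool == "short":
                mu *= em.short_pool_efficiency
            r = em.nb_dispersion
            n = int(rng.negative_binomial(r, r / (r + mu)))
            for _ in range(n):
                rec = {
                    "sample": sample,
                    "amplicon": amp.id,
                    "chimera": False,
                    "pseudogene": False,
                }
                if is_drb2 and rng.random() < em.pseudogene_fraction:
                    allele = pseudo_alleles[rng.integers(len(pseudo_alleles))]
                    locus = DRB_PSEUDO_LOCUS
                    rec["pseudogene"] = True
                    template = template_for(amp, allele)
                else:
                    locus, allele = haps[rng.integers(len(haps))]
                    template = template_for(amp, allele)
                    if (
                        is_drb2
                        and locus == "DRB1"
                        and drb345
                        and template is not None
                        and rng.random() < em.chimera_rate
                    ):
                        partner = drb345[rng.integers(len(drb345))]
                        t2 = template_for(amp, partner[1])
                        if t2 is not None and len(t2) == len(template):
                            x = int(
                                rng.integers(amp._t_exon_start + 40, amp._t_exon_end - 40)
                            )
                            template = template[:x] + t2[x:]
                            rec["chimera"] = True
                            rec["chimera_partner"] = partner[1]
                            rec["crossover"] = x
                if template is None:
                    continue
                direction = "F" if rng.random() < 0.5 else "R"
                errored, n_sub, n_hp = _inject_errors(template, amp, direction, em, rng)
                seq = mid + (errored if direction == "F" else revcomp(errored))
                counter += 1
                rid = f"{run_id}_{counter:06d}"
                rec.update(
                    {"read": rid, "locus": locus, "allele": allele,
                     "direction": direction, "n_sub": n_sub, "n_hp_indel": n_hp}
                )
                reads.append(Read(rid, seq))
                read_truth.append(rec)

    return SimulatedRun(
        run_id=run_id,
        reads=reads,
        read_truth=read_truth,
        association=dict(truth.mids),
        warnings=warnings,
    )


@dataclass
class QuantPlate:
    """Fluorometric quantification plate: 8-point standards + amplicon wells."""

    standards: list[tuple[float, float]]  # (known ng/ul, signal)
    wells: list[tuple[str, str, float]]  # (well, amplicon id, signal)
    slope: float
    intercept: float

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("Well\tAmplicon\tSignal\n")
            for i, (conc, sig) in enumerate(self.standards, 1):
                fh.write(f"STD{i}\tstandard:{conc:g}\t{sig:.4f}\n")
            for well, amp, sig in self.wells:
                fh.write(f"{well}\t{amp}\t{sig:.4f}\n")


def simulate_quant_plate(
    panel: Panel,
    true_concs: Optional[dict[str, float]] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    slope: float = 20.0,
    intercept: float = 50.0,
) -> QuantPlate:
    """Simulate a PicoGreen plate read: linear signal plus Gaussian noise,
    with the standard series spanning 0-100 ng/ul in eight points."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if true_concs is None:
        true_concs = {
            amp.id: float(rng.uniform(5, 40)) for amp in panel.amplicons
        }
    std_concs = np.linspace(0.0, 100.0, 8)
    standards = [
        (float(c), float(slope * c + intercept + rng.normal(0.0, noise_sd)))
        for c in std_concs
    ]
    wells = []
    for i, amp in enumerate(panel.amplicons):
        conc = true_concs.get(amp.id, 0.0)
        sig = slope * conc + intercept + rng.normal(0.0, noise_sd)
        wells.append((f"W{i + 1:02d}", amp.id, float(sig)))
    return QuantPlate(standards=standards, wells=wells, slope=slope, intercept=intercept)
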