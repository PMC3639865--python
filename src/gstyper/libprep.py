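"""Library-preparation computations: quantification QC and equimolar pooling.

Fluorometric signals are translated to ng/ul through an eight-point standard
series fit by ordinary least squares; a run passes QC only when the
coefficient of determination exceeds a configurable bound (default
r^2 > 0.98).  Concentrations are converted to molecules/ul with the standard
average double-stranded base-pair mass of 660 g/mol/bp:

    molecules/ul = conc[ng/ul] x 1e-9 / (length[bp] x 660) x N_A

The pooling plan draws, from every amplicon, ``pooling_factor x
base_molecules`` molecules (default base 1e9) into one of two pools -- the
five shortest amplicons form the *short* pool, the remaining twelve the
*long* pool -- so the molar ratio between any amplicon and a factor-1
amplicon equals its pooling factor exactly.  Volumes are never rescaled; a
low-yield amplicon whose draw volume exceeds ``max_volume`` is flagged for
re-amplification instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .panel import Panel

__all__ = [
    "AVOGADRO",
    "BP_MASS_G_PER_MOL",
    "StandardCurve",
    "QuantResult",
    "PoolPlan",
    "fit_standard_curve",
    "signal_to_concentration",
    "concentration_to_molecules",
    "quantify_plate",
    "compute_pool_plan",
]

AVOGADRO = 6.02214076e23
#: average mass of one double-stranded base pair, g/mol/bp
BP_MASS_G_PER_MOL = 660.0


@dataclass(frozen=True)
class StandardCurve:
    slope: float  # signal per ng/ul
    intercept: float  # signal at zero concentration
    r_squared: float
    threshold: float
    passed: bool


def fit_standard_curve(
    standards: list[tuple[float, float]], threshold: float = 0.98
) -> StandardCurve:
    """OLS fit of signal on known concentration; passes iff r^2 > threshold."""
    if len(standards) < 2:
        raise ValueError("need at least two standards")
    x = np.asarray([s[0] for s in standards], dtype=float)
    y = np.asarray([s[1] for s in standards], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate standards: all concentrations identical")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    # a flat signal carries no calibration information: score it 0, not 1
    r2 = 0.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return StandardCurve(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        threshold=threshold,
        passed=r2 > threshold,
    )


def signal_to_concentration(curve: StandardCurve, signal: float) -> float:
    """Invert the standard curve; negative estimates clamp to 0 ng/ul."""
    return max((signal - curve.intercept) / curve.slope, 0.0)


def concentration_to_molecules(conc_ng_per_ul: float, length_bp: int) -> float:
    """dsDNA molecules/ul at *conc_ng_per_ul* for an amplicon of *length_bp*."""
    if length_bp <= 0:
        raise ValueError("amplicon length must be positive")
    if conc_ng_per_ul < 0:
        raise ValueError("concentration must be >= 0")
    grams_per_ul = conc_ng_per_ul * 1e-9
    mol_per_ul = grams_per_ul / (length_bp * BP_MASS_G_PER_MOL)
    return mol_per_ul * AVOGADRO


@dataclass
class QuantResult:
    amplicon: str
    concentration: float  # ng/ul
    molecules_per_ul: float


def read_quant_tsv(path):
    """Read a quantification plate TSV (Well, Amplicon, Signal).

    Standard wells are identified by an ``standard:<conc>`` amplicon label;
    returns (standards, wells) in the same shape the simulator produces.
    """
    standards: list[tuple[float, float]] = []
    wells: list[tuple[str, str, float]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["Well", "Amplicon", "Signal"]:
            raise ValueError(f"{path}: not a quantification TSV")
        for line in fh:
            if not line.strip():
                continue
            well, amp, signal = line.rstrip("\n").split("\t")[:3]
            if amp.startswith("standard:"):
                standards.append((float(amp.split(":", 1)[1]), float(signal)))
            else:
                wells.append((well, amp, float(signal)))
    return standards, wells


def quantify_plate(plate, panel: Panel, threshold: float = 0.98):
    """Fit the plate's standards and translate amplicon signals to
    concentrations and molarities.  Returns (curve, {amplicon: QuantResult})."""
    curve = fit_standard_curve(plate.standards, threshold)
    lengths = {a.id: a.amplicon_length for a in panel.amplicons}
    quants: dict[str, QuantResult] = {}
    for _, amp_id, signal in plate.wells:
        conc = signal_to_concentration(curve, signal)
        quants[amp_id] = QuantResult(
            amplicon=amp_id,
            concentration=conc,
            molecules_per_ul=concentration_to_molecules(conc, lengths[amp_id]),
        )
    return curve, quants


@dataclass
class PoolPlanEntry:
    amplicon: str
    pool: str
    pooling_factor: float
    target_molecules: float
    volume_ul: Optional[float]  # None when the amplicon failed quantification
    status: str  # ok | low_yield | failed


@dataclass
class PoolPlan:
    entries: list[PoolPlanEntry]
    base_molecules: float
    dilution_target: float
    max_volume: float
    qc: Optional[StandardCurve] = None

    def pool(self, label: str) -> list[PoolPlanEntry]:
        return [e for e in self.entries if e.pool == label]

    @property
    def failed(self) -> list[PoolPlanEntry]:
        return [e for e in self.entries if e.status == "failed"]

    def to_json(self, path) -> None:
        doc = {
            "base_molecules": self.base_molecules,
            "dilution_target": self.dilution_target,
            "max_volume_ul": self.max_volume,
            "qc": None
            if self.qc is None
            else {
                "r_squared": self.qc.r_squared,
                "threshold": self.qc.threshold,
                "passed": self.qc.passed,
            },
            "entries": [vars(e) for e in self.entries],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("Amplicon\tPool\tPoolingFactor\tTargetMolecules\tVolume_ul\tStatus\n")
            for e in self.entries:
                vol = "" if e.volume_ul is None else f"{e.volume_ul:.4f}"
                fh.write(
                    f"{e.amplicon}\t{e.pool}\t{e.pooling_factor:g}\t"
                    f"{e.target_molecules:g}\t{vol}\t{e.status}\n"
                )


def compute_pool_plan(
    quants: dict[str, QuantResult],
    panel: Panel,
    base_molecules: float = 1e9,
    max_volume: float = 20.0,
    dilution_target: float = 5e5,
    qc: Optional[StandardCurve] = None,
) -> PoolPlan:
    """Two-pool equimolar plan: volume_i = factor_i x base / (molecules/ul)_i.

    Amplicons with no usable concentration are flagged ``failed`` rather than
    silently dropped; volumes above *max_volume* are flagged ``low_yield``.
    """
    entries: list[PoolPlanEntry] = []
    for amp in panel.amplicons:
        target = amp.pooling_factor * base_molecules
        q = quants.get(amp.id)
        if q is None or q.molecules_per_ul <= 0:
            entries.append(
                PoolPlanEntry(amp.id, amp.pool, amp.pooling_factor, target, None, "failed")
            )
            continue
        vol = target / q.molecules_per_ul
        status = "low_yield" if vol > max_volume else "ok"
        entries.append(
            PoolPlanEntry(amp.id, amp.pool, amp.pooling_factor, target, vol, status)
        )
    return PoolPlan(
        entries=entries,
        base_molecules=base_molecules,
        dilution_target=dilution_target,
        max_volume=max_volume,
        qc=qc,
    )
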