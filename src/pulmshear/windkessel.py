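"""Three-element Windkessel (RCR) outlet boundary conditions: diameter-law
apportionment of total resistance and compliance, and iterative tuning
against right-heart-catheter targets.

Total pulmonary vascular resistance is split over outlets inversely to
``D**2.25`` (a Murray-law coefficient accounting for the microcirculation the
truncated tree does not resolve); total compliance proportionally to ``D**2``.
Each outlet's resistance is divided into a proximal part Rp and distal part
Rd at a fixed fraction, with the compliance between them and Rd referenced to
a distal pressure (the wedge pressure, PAWP).

Tuning is a damped fixed-point iteration: the total resistance scale is
updated by the ratio of target to simulated transpulmonary gradient
(mPAP - PAWP) and the total compliance by the ratio of simulated to target
pulse pressure (sPAP - dPAP); cardiac output is matched by construction since
root inflow is imposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .arterial_tree import ArterialTree, outlets
from .hemo0d import (
    BloodModel,
    FlowWaveform,
    HemoSolution,
    SolverConfig,
    make_inflow,
    solve,
    summarize_pressures,
)
from .units import LPM, MMHG, WOOD, mmhg_to_cgs

__all__ = [
    "RCRParams",
    "RCRSet",
    "RHCRecord",
    "TuningConfig",
    "TuningReport",
    "InvalidRecordError",
    "total_pvr",
    "distribute_resistance",
    "distribute_compliance",
    "assemble_rcr",
    "tune_rcr",
    "write_rcr",
    "read_rcr",
]


class InvalidRecordError(ValueError):
    """Inconsistent or unphysiological hemodynamic record."""


@dataclass(frozen=True)
class RCRParams:
    """One outlet's Windkessel elements (CGS): Rp, Rd in dyn*s/cm^5, C in
    cm^5/dyn."""

    Rp: float
    C: float
    Rd: float

    def __post_init__(self) -> None:
        if self.Rp < 0 or self.Rd <= 0 or self.C <= 0:
            raise ValueError(f"invalid RCR parameters Rp={self.Rp}, C={self.C}, Rd={self.Rd}")

    @property
    def R_total(self) -> float:
        return self.Rp + self.Rd


@dataclass
class RCRSet:
    """Windkessel parameters for every outlet, keyed by outlet id in the
    canonical :func:`~pulmshear.arterial_tree.outlets` order, plus the shared
    distal reference pressure (dyn/cm^2)."""

    entries: dict[str, RCRParams]
    distal_pressure: float


@dataclass(frozen=True)
class RHCRecord:
    """Right-heart-catheterization measurements (clinical units).

    Pressures in mmHg, CO in L/min, HR in beats/min, PVR in Wood units.
    sPAP/dPAP may be absent (echo-only pressure data); RAP is carried for
    completeness but unused by the solver. When PVR is present it must agree
    with (mPAP - PAWP)/CO within 25%.
    """

    mPAP: float
    PAWP: float
    CO: float
    HR: float
    sPAP: float | None = None
    dPAP: float | None = None
    RAP: float | None = None
    PVR: float | None = None

    def __post_init__(self) -> None:
        if not (self.CO > 0):
            raise InvalidRecordError(f"CO must be > 0, got {self.CO}")
        if not (self.HR > 0):
            raise InvalidRecordError(f"HR must be > 0, got {self.HR}")
        if self.sPAP is not None and self.dPAP is not None:
            if not (self.dPAP <= self.mPAP <= self.sPAP):
                raise InvalidRecordError(
                    f"require dPAP <= mPAP <= sPAP, got {self.dPAP}, {self.mPAP}, {self.sPAP}"
                )
        if self.PVR is not None:
            implied = (self.mPAP - self.PAWP) / self.CO
            if self.PVR <= 0 or abs(self.PVR - implied) / self.PVR >= 0.25:
                raise InvalidRecordError(
                    f"PVR={self.PVR} WU inconsistent with (mPAP-PAWP)/CO={implied:.3g} WU"
                )

    @property
    def pulse_pressure(self) -> float | None:
        if self.sPAP is None or self.dPAP is None:
            return None
        return self.sPAP - self.dPAP


def total_pvr(rhc: RHCRecord) -> float:
    """Total pulmonary vascular resistance (mPAP - PAWP)/CO in dyn*s/cm^5."""
    if rhc.PAWP >= rhc.mPAP:
        raise InvalidRecordError(f"PAWP ({rhc.PAWP}) must be below mPAP ({rhc.mPAP})")
    wood = (rhc.mPAP - rhc.PAWP) / rhc.CO
    return wood * WOOD


def distribute_resistance(
    outlet_diameters: np.ndarray,
    R_total: float,
    exponent: float = 2.25,
) -> np.ndarray:
    """Apportion total resistance over outlets with ``R_i inversely
    proportional to D_i**exponent``.

    ``R_i = R_total * sum_j(D_j**e) / D_i**e``, so the parallel combination of
    the returned vector equals ``R_total`` identically.
    """
    d = np.asarray(outlet_diameters, dtype=float)
    if d.size == 0:
        raise ValueError("outlet_diameters must be non-empty")
    if np.any(d <= 0) or not R_total > 0:
        raise ValueError("diameters and R_total must be > 0")
    w = d**exponent
    return R_total * w.sum() / w


def distribute_compliance(outlet_diameters: np.ndarray, C_total: float) -> np.ndarray:
    """Apportion total compliance proportionally to ``D_i**2``; the outputs
    sum to ``C_total``."""
    d = np.asarray(outlet_diameters, dtype=float)
    if d.size == 0:
        raise ValueError("outlet_diameters must be non-empty")
    if np.any(d <= 0) or not C_total > 0:
        raise ValueError("diameters and C_total must be > 0")
    w = d**2
    return C_total * w / w.sum()


def assemble_rcr(
    outlet_ids: list[str],
    R: np.ndarray,
    C: np.ndarray,
    rp_fraction: float = 0.1,
    distal_pressure_mmHg: float = 0.0,
) -> RCRSet:
    """Split each outlet resistance into Rp = f*R, Rd = (1-f)*R and bundle
    with its compliance; distal pressure stored in CGS."""
    if not (0 <= rp_fraction < 1):
        raise ValueError(f"rp_fraction must be in [0, 1), got {rp_fraction}")
    if not (len(outlet_ids) == len(R) == len(C)):
        raise ValueError("outlet_ids, R and C must be aligned")
    entries = {
        oid: RCRParams(Rp=rp_fraction * r, C=c, Rd=(1.0 - rp_fraction) * r)
        for oid, r, c in zip(outlet_ids, R, C)
    }
    return RCRSet(entries=entries, distal_pressure=mmhg_to_cgs(distal_pressure_mmHg))


@dataclass
class TuningConfig:
    """Controls for the fixed-point RCR tuning loop."""

    tolerance: float = 0.02
    max_iterations: int = 20
    rp_fraction: float = 0.1
    resistance_exponent: float = 2.25
    systolic_fraction: float = 0.35
    waveform_samples: int = 1000
    rc_fallback_s: float = 0.5  # RC time constant when pulse pressure unavailable
    solver: SolverConfig = field(default_factory=SolverConfig)


@dataclass
class TuningReport:
    iterations: int
    achieved_mPAP: float
    achieved_pulse_pressure: float
    relative_errors: dict[str, float]
    converged: bool


def _initial_compliance(rhc: RHCRecord, R_total: float, cfg: TuningConfig) -> float:
    pp = rhc.pulse_pressure
    if pp is not None and pp > 0:
        stroke_volume = rhc.CO * LPM * (60.0 / rhc.HR)  # cm^3 per beat
        return stroke_volume / (pp * MMHG)
    return cfg.rc_fallback_s / R_total


def tune_rcr(
    tree: ArterialTree,
    rhc: RHCRecord,
    blood: BloodModel | None = None,
    config: TuningConfig | None = None,
    inflow: FlowWaveform | None = None,
) -> tuple[RCRSet, TuningReport]:
    """Tune outlet RCR parameters until the simulated mPAP (and pulse
    pressure, when targets exist) match the catheter record.

    Returns the final :class:`RCRSet` and a :class:`TuningReport`;
    ``converged=False`` after ``max_iterations`` is returned, not raised.
    Solver instabilities propagate.
    """
    blood = blood or BloodModel()
    cfg = config or TuningConfig()
    outs = outlets(tree)
    out_ids = [s.id for s in outs]
    diam = np.array([s.diameter for s in outs])

    if inflow is None:
        inflow = make_inflow(
            rhc.CO, rhc.HR, systolic_fraction=cfg.systolic_fraction,
            n_samples=cfg.waveform_samples,
        )

    R_total = total_pvr(rhc)
    C_total = _initial_compliance(rhc, R_total, cfg)
    pp_target = rhc.pulse_pressure
    tune_pp = pp_target is not None and pp_target > 0

    damping = 1.0
    prev_log_fr = None
    rcr: RCRSet | None = None
    solution: HemoSolution | None = None
    errors: dict[str, float] = {}
    converged = False
    iterations = 0
    mpap_s = pp_s = math.nan

    for iterations in range(1, cfg.max_iterations + 1):
        R_i = distribute_resistance(diam, R_total, cfg.resistance_exponent)
        C_i = distribute_compliance(diam, C_total)
        rcr = assemble_rcr(out_ids, R_i, C_i, cfg.rp_fraction, distal_pressure_mmHg=rhc.PAWP)
        solution = solve(tree, rcr, inflow, blood, cfg.solver)
        spap_s, dpap_s, mpap_s = summarize_pressures(solution)
        pp_s = spap_s - dpap_s

        errors = {"mPAP": abs(mpap_s - rhc.mPAP) / rhc.mPAP}
        if tune_pp:
            errors["pulse_pressure"] = abs(pp_s - pp_target) / pp_target
        if all(e <= cfg.tolerance for e in errors.values()):
            converged = True
            break

        f_r = (rhc.mPAP - rhc.PAWP) / max(mpap_s - rhc.PAWP, 1e-9)
        log_fr = math.log(f_r)
        if prev_log_fr is not None and log_fr * prev_log_fr < 0:
            damping *= 0.5  # oscillating update: damp
        prev_log_fr = log_fr
        # per-iteration factors clamped to [1/4, 4] so a bad early estimate
        # cannot throw the state into a numerically unstable regime
        clamp = math.log(4.0)
        R_total *= math.exp(damping * min(max(log_fr, -clamp), clamp))
        if tune_pp and pp_s > 0:
            log_fc = math.log(pp_s / pp_target)
            C_total *= math.exp(damping * min(max(log_fc, -clamp), clamp))

    report = TuningReport(
        iterations=iterations,
        achieved_mPAP=mpap_s,
        achieved_pulse_pressure=pp_s if tune_pp else 0.0,
        relative_errors=errors,
        converged=converged,
    )
    return rcr, report


def write_rcr(rcr: RCRSet, report: TuningReport | None, path: str | Path) -> None:
    """Export one row per outlet (CGS) with a header recording convergence."""
    lines = []
    if report is not None:
        lines.append(
            f"# tuned: converged={report.converged} iterations={report.iterations} "
            f"achieved_mPAP_mmHg={report.achieved_mPAP:.4f} "
            f"achieved_pulse_pressure_mmHg={report.achieved_pulse_pressure:.4f}"
        )
    lines.append(f"# distal_pressure_dyn_cm2={float(rcr.distal_pressure)!r}")
    lines.append("outlet_id\tRp\tC\tRd")
    for oid, p in rcr.entries.items():
        lines.append(f"{oid}\t{float(p.Rp)!r}\t{float(p.C)!r}\t{float(p.Rd)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_rcr(path: str | Path) -> RCRSet:
    """Read an RCR export written by :func:`write_rcr`."""
    distal = None
    entries: dict[str, RCRParams] = {}
    header_seen = False
    for line in Path(path).read_text().splitlines():
        if line.startswith("# distal_pressure_dyn_cm2="):
            distal = float(line.split("=", 1)[1])
        elif line.startswith("#") or not line.strip():
            continue
        elif not header_seen:
            header_seen = True  # column header
        else:
            oid, rp, c, rd = line.split("\t")
            entries[oid] = RCRParams(Rp=float(rp), C=float(c), Rd=float(rd))
    if distal is None or not entries:
        raise ValueError(f"{path}: not a valid RCR export")
    return RCRSet(entries=entries, distal_pressure=distal)
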