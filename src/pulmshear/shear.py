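"""Wall shear stress waveforms and the TAWSS / OSI summary metrics.

A quasi-steady Poiseuille profile gives the signed wall shear stress from the
segment flow waveform, ``tau(t) = 4 mu Q(t) / (pi r^3)`` (dyn/cm^2, mu in
poise); the sign follows the flow direction and stands in for the direction
of the 3D WSS vector.

TAWSS is the cycle mean of ``|tau|``; the oscillatory shear index
``OSI = 0.5 (1 - |integral tau| / integral |tau|)`` is 0 for unidirectional
shear and 0.5 for perfectly balanced flow reversal. Patient-level values are
luminal-surface-area-weighted means over the proximal segments (MPA, LPA,
RPA by default), weight ``pi * diameter * length``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arterial_tree import ArterialTree
from .hemo0d import BloodModel, HemoSolution

__all__ = [
    "ShearRecord",
    "PatientShearSummary",
    "wss_waveform",
    "tawss",
    "osi",
    "compute_shear",
    "aggregate_proximal",
]


@dataclass
class ShearRecord:
    """Signed shear waveform and summary metrics for one segment."""

    segment_id: str
    tau: np.ndarray
    TAWSS: float
    OSI: float


@dataclass
class PatientShearSummary:
    """One patient's proximal aggregate."""

    patient_id: str
    TAWSS_proximal: float
    OSI_proximal: float


def wss_waveform(flow: np.ndarray, diameter: float, blood: BloodModel) -> np.ndarray:
    """Quasi-steady Poiseuille wall shear stress series, dyn/cm^2."""
    if not (diameter > 0):
        raise ValueError(f"diameter must be > 0, got {diameter}")
    r = diameter / 2.0
    return 4.0 * blood.viscosity_poise * np.asarray(flow, dtype=float) / (np.pi * r**3)


def _cycle_integral(x: np.ndarray, period: float) -> float:
    """Trapezoidal integral over one period of a uniformly sampled periodic
    signal (half-open grid); equals ``mean(x) * period``."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    return float(np.mean(x)) * period


def tawss(tau: np.ndarray, period: float) -> float:
    """Time-averaged magnitude of the wall shear stress over one cycle."""
    if not (period > 0):
        raise ValueError("period must be > 0")
    return _cycle_integral(np.abs(tau), period) / period


def osi(tau: np.ndarray, period: float) -> float:
    """Oscillatory shear index in [0, 0.5]; 0 for the degenerate no-flow
    case."""
    if not (period > 0):
        raise ValueError("period must be > 0")
    denom = _cycle_integral(np.abs(tau), period)
    if denom == 0.0:
        return 0.0
    num = abs(_cycle_integral(np.asarray(tau, dtype=float), period))
    # clip guards float cancellation when |mean| and mean|.| nearly coincide
    return float(np.clip(0.5 * (1.0 - num / denom), 0.0, 0.5))


def compute_shear(
    solution: HemoSolution,
    tree: ArterialTree,
    blood: BloodModel | None = None,
) -> list[ShearRecord]:
    """Per-segment shear records from a converged solution."""
    blood = blood or BloodModel()
    period = solution.period
    records = []
    for sid, flow in solution.flows.items():
        d = tree.segments[sid].diameter
        tau = wss_waveform(flow, d, blood)
        records.append(
            ShearRecord(segment_id=sid, tau=tau, TAWSS=tawss(tau, period), OSI=osi(tau, period))
        )
    return records


def aggregate_proximal(
    records: list[ShearRecord],
    tree: ArterialTree,
    scope: set[str] = frozenset({"MPA", "LPA", "RPA"}),
    patient_id: str = "",
) -> PatientShearSummary:
    """Area-weighted mean of TAWSS and OSI over the proximal scope segments.

    The weight is the luminal surface area ``pi * diameter * length`` so
    larger vessels dominate, mirroring a surface-averaged 3D field.
    """
    by_id = {r.segment_id: r for r in records}
    chosen = [
        (seg, by_id[seg.id])
        for seg in tree.segments.values()
        if seg.name in scope and seg.id in by_id
    ]
    if not chosen:
        raise ValueError(f"no segments in scope {sorted(scope)} with shear records")
    w = np.array([np.pi * seg.diameter * seg.length for seg, _ in chosen])
    tw = np.array([rec.TAWSS for _, rec in chosen])
    ow = np.array([rec.OSI for _, rec in chosen])
    return PatientShearSummary(
        patient_id=patient_id,
        TAWSS_proximal=float(np.average(tw, weights=w)),
        OSI_proximal=float(np.average(ow, weights=w)),
    )
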