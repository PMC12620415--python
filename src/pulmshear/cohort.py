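"""Synthetic three-group patient cohorts (CTEPH, CTEPD with V/Q mismatch,
control), 30 patients per group by default.

Two generation modes:

``statistical``
    Patient-level TAWSS is drawn directly from lognormal distributions
    quantile-matched to each group's published median and quartiles; this is
    the calibrated substrate for the diagnostic statistics. OSI is drawn from
    one shared narrow Beta distribution on [0, 0.5] for all groups (the
    clinical data showed no group effect in OSI).

``mechanistic``
    Each patient gets an arterial tree (MPA caliber sampled from the group's
    imaging summary, disease remodeling applied), RCR boundary conditions
    tuned to the patient's sampled catheter record, a pulsatile 0D solve, and
    proximal shear aggregation. This mode exercises the full modelling chain;
    its TAWSS values carry the correct between-group structure but not the
    absolute magnitudes of 3D near-wall gradients.

All positive skewed clinical quantities are modelled as lognormals matched to
median/Q1/Q3 (``mu = ln(median)``, ``sigma`` = mean one-sided log-quartile
distance / z_0.75). Heart rate, never published, is uniform on [60, 90] bpm.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .arterial_tree import Group, apply_disease_remodeling, generate_tree
from .hemo0d import BloodModel, SolverInstabilityError, solve
from .shear import aggregate_proximal, compute_shear
from .windkessel import RHCRecord, TuningConfig, tune_rcr

__all__ = [
    "Quartiles",
    "GroupSummary",
    "PatientRecord",
    "CohortTable",
    "CohortConfig",
    "DEFAULT_SUMMARIES",
    "fit_lognormal_quartiles",
    "sample_group_tawss",
    "sample_group_rhc",
    "classify_patient",
    "generate_cohort",
]

logger = logging.getLogger(__name__)

_Z75 = 0.6744897501960817  # standard normal 75th-percentile quantile


class Quartiles(NamedTuple):
    median: float
    q1: float
    q3: float


@dataclass(frozen=True)
class GroupSummary:
    """Published summary statistics for one study group.

    All clinical fields are (median, Q1, Q3) triplets: TAWSS in dyn/cm^2,
    pressures in mmHg, CO in L/min, PVR in Wood units, MPA diameter in mm,
    V/Q mismatch score dimensionless (absent for controls).
    """

    group: Group
    tawss: Quartiles
    sPAP: Quartiles
    dPAP: Quartiles
    mPAP: Quartiles
    PAWP: Quartiles
    RAP: Quartiles
    CO: Quartiles
    PVR: Quartiles
    mpa_diameter_mm: Quartiles
    mismatch_score: Quartiles | None = None

    def __post_init__(self) -> None:
        for name in ("tawss", "sPAP", "dPAP", "mPAP", "PAWP", "RAP", "CO", "PVR",
                     "mpa_diameter_mm", "mismatch_score"):
            q = getattr(self, name)
            if q is None:
                continue
            if not (0 < q.q1 <= q.median <= q.q3):
                raise ValueError(f"{self.group.value}.{name}: require 0 < q1 <= median <= q3, got {q}")


# Published group summaries: hemodynamics and MPA caliber from the clinical
# exploration table, TAWSS from the CFD results, mismatch scores from the
# clinical characteristics table.
DEFAULT_SUMMARIES: dict[Group, GroupSummary] = {
    Group.CTEPH: GroupSummary(
        group=Group.CTEPH,
        tawss=Quartiles(16.5, 13.31, 20.44),
        sPAP=Quartiles(63.00, 54.50, 79.25),
        dPAP=Quartiles(17.00, 15.75, 25.25),
        mPAP=Quartiles(38.00, 29.75, 41.25),
        PAWP=Quartiles(9.00, 6.00, 11.00),
        RAP=Quartiles(6.00, 4.00, 9.00),
        CO=Quartiles(5.15, 4.56, 5.46),
        PVR=Quartiles(5.50, 4.35, 7.53),
        mpa_diameter_mm=Quartiles(30.50, 26.75, 34.50),
        mismatch_score=Quartiles(0.40, 0.30, 0.40),
    ),
    Group.CTEPD: GroupSummary(
        group=Group.CTEPD,
        tawss=Quartiles(27.5, 24.00, 34.00),
        sPAP=Quartiles(25.55, 21.45, 28.35),
        dPAP=Quartiles(10.80, 7.55, 13.23),
        mPAP=Quartiles(15.57, 14.25, 16.91),
        PAWP=Quartiles(8.50, 7.00, 9.75),
        RAP=Quartiles(5.00, 2.50, 7.00),
        CO=Quartiles(5.67, 4.85, 6.55),
        PVR=Quartiles(1.38, 1.05, 1.51),
        mpa_diameter_mm=Quartiles(25.00, 24.00, 27.75),
        mismatch_score=Quartiles(0.30, 0.21, 0.35),
    ),
    Group.CONTROL: GroupSummary(
        group=Group.CONTROL,
        tawss=Quartiles(42.0, 34.00, 48.50),
        sPAP=Quartiles(28.00, 28.00, 30.50),
        dPAP=Quartiles(12.00, 12.00, 14.00),
        mPAP=Quartiles(18.00, 17.33, 18.84),
        PAWP=Quartiles(10.00, 8.50, 10.00),
        RAP=Quartiles(9.00, 7.00, 13.00),
        CO=Quartiles(5.20, 4.70, 5.50),
        PVR=Quartiles(1.82, 1.42, 1.92),
        mpa_diameter_mm=Quartiles(23.00, 21.00, 25.50),
        mismatch_score=None,
    ),
}


def fit_lognormal_quartiles(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Lognormal (mu, sigma) matched to a printed median/Q1/Q3 triplet.

    ``mu = ln(median)``; ``sigma`` averages the two one-sided log-quartile
    distances and divides by the 75th-percentile normal quantile, so
    asymmetric printed IQRs are honoured in the mean.
    """
    if not (0 < q1 <= median <= q3):
        raise ValueError(f"require 0 < q1 <= median <= q3, got ({median}, {q1}, {q3})")
    mu = math.log(median)
    sigma = 0.5 * (math.log(median / q1) + math.log(q3 / median)) / _Z75
    return mu, sigma


def _lognormal(rng: np.random.Generator, q: Quartiles, n: int) -> np.ndarray:
    mu, sigma = fit_lognormal_quartiles(*q)
    return np.exp(mu + sigma * rng.standard_normal(n))


def sample_group_tawss(
    summary: GroupSummary, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """n seeded lognormal TAWSS draws (dyn/cm^2) calibrated to the group
    summary."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _lognormal(rng, summary.tawss, n)


def sample_group_rhc(
    summary: GroupSummary, n: int, seed: int | np.random.Generator
) -> list[RHCRecord]:
    """n seeded catheter records calibrated to the group summary.

    Each pressure/flow field is an independent quantile-matched lognormal
    draw, post-adjusted for joint physiological consistency: the
    (dPAP, mPAP, sPAP) triple is sorted, PAWP is capped at 80% of mPAP so the
    transpulmonary gradient stays positive, the pulse pressure is clamped into
    1.2-3.5x the transpulmonary gradient (clinical group medians give ratios
    of 1.6-2.1; independent draws can otherwise compose impossible triples),
    and PVR is recomputed from the adjusted values. HR ~ uniform(60, 90) bpm.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spap = _lognormal(rng, summary.sPAP, n)
    dpap = _lognormal(rng, summary.dPAP, n)
    mpap = _lognormal(rng, summary.mPAP, n)
    pawp = _lognormal(rng, summary.PAWP, n)
    rap = _lognormal(rng, summary.RAP, n)
    co = _lognormal(rng, summary.CO, n)
    hr = rng.uniform(60.0, 90.0, n)

    tri = np.sort(np.stack([dpap, mpap, spap]), axis=0)
    dpap, mpap, spap = tri
    pawp = np.minimum(pawp, 0.8 * mpap)
    # pulse-pressure coherence: rescale sPAP/dPAP about mPAP when the sampled
    # pulse pressure falls outside 1.2-3.5x the transpulmonary gradient
    pp = np.maximum(spap - dpap, 1e-12)
    grad = mpap - pawp
    pp_clamped = np.clip(pp, 1.2 * grad, 3.5 * grad)
    k = pp_clamped / pp
    spap = mpap + (spap - mpap) * k
    dpap = np.maximum(mpap - (mpap - dpap) * k, 0.1 * mpap)
    pvr = (mpap - pawp) / co

    return [
        RHCRecord(
            mPAP=float(mpap[i]), PAWP=float(pawp[i]), CO=float(co[i]), HR=float(hr[i]),
            sPAP=float(spap[i]), dPAP=float(dpap[i]), RAP=float(rap[i]), PVR=float(pvr[i]),
        )
        for i in range(n)
    ]


def classify_patient(rhc: RHCRecord) -> bool:
    """True when the record is in the CTEPH hemodynamic range: mPAP > 20 mmHg,
    PVR > 2 Wood units, and PAWP < 15 mmHg (all strict)."""
    pvr = rhc.PVR if rhc.PVR is not None else (rhc.mPAP - rhc.PAWP) / rhc.CO
    return rhc.mPAP > 20.0 and pvr > 2.0 and rhc.PAWP < 15.0


@dataclass
class PatientRecord:
    patient_id: str
    group: Group
    rhc: RHCRecord
    mpa_diameter_mm: float
    TAWSS: float
    OSI: float
    mismatch_positive: bool
    mismatch_score: float | None = None


@dataclass
class CohortConfig:
    """Generation settings beyond the published summaries.

    OSI ~ 0.5 * Beta(osi_beta_a, osi_beta_b), identical across groups.
    Mechanistic-mode trees start from a 3 cm / 3-generation template with
    mild bifurcation asymmetry; diseased groups narrow a fraction of outlets
    to half diameter (more in CTEPH than CTEPD).
    """

    osi_beta_a: float = 2.0
    osi_beta_b: float = 8.0
    n_generations: int = 3
    murray_exponent: float = 2.25
    asymmetry: float = 0.2
    length_to_diameter: float = 3.0
    occlusion_fraction: dict[Group, float] = field(
        default_factory=lambda: {Group.CTEPH: 0.4, Group.CTEPD: 0.2, Group.CONTROL: 0.0}
    )
    stenosis_factor: float = 0.5
    tuning: TuningConfig = field(default_factory=TuningConfig)
    blood: BloodModel = field(default_factory=BloodModel)
    scope: frozenset[str] = frozenset({"MPA", "LPA", "RPA"})


@dataclass
class CohortTable:
    """Generated cohort plus provenance (mode, seed, excluded failures)."""

    patients: list[PatientRecord]
    seed: int
    mode: str
    failures: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "group": p.group.value,
                    "mismatch_positive": p.mismatch_positive,
                    "mismatch_score": p.mismatch_score,
                    "mPAP": p.rhc.mPAP,
                    "sPAP": p.rhc.sPAP,
                    "dPAP": p.rhc.dPAP,
                    "PAWP": p.rhc.PAWP,
                    "RAP": p.rhc.RAP,
                    "CO": p.rhc.CO,
                    "HR": p.rhc.HR,
                    "PVR": p.rhc.PVR,
                    "mpa_diameter_mm": p.mpa_diameter_mm,
                    "TAWSS": p.TAWSS,
                    "OSI": p.OSI,
                    "mode": self.mode,
                    "seed": self.seed,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


_GROUP_ORDER = (Group.CTEPH, Group.CTEPD, Group.CONTROL)


def _mechanistic_tawss(
    group: Group,
    rhc: RHCRecord,
    mpa_mm: float,
    patient_seed: int,
    cfg: CohortConfig,
) -> tuple[float, bool]:
    """Run the full modelling chain for one patient; returns (TAWSS, ok)."""
    base = generate_tree(
        root_diameter=3.0,
        n_generations=cfg.n_generations,
        murray_exponent=cfg.murray_exponent,
        asymmetry=cfg.asymmetry,
        length_to_diameter=cfg.length_to_diameter,
        seed=patient_seed,
    )
    tree = apply_disease_remodeling(
        base, group, mpa_diameter=mpa_mm / 10.0,
        occlusion_fraction=cfg.occlusion_fraction.get(group, 0.0),
        seed=patient_seed, stenosis_factor=cfg.stenosis_factor,
    )
    try:
        rcr, report = tune_rcr(tree, rhc, cfg.blood, cfg.tuning)
    except SolverInstabilityError:
        return math.nan, False
    if not report.converged:
        return math.nan, False
    sol = solve(tree, rcr, _tuned_inflow(rhc, cfg), cfg.blood, cfg.tuning.solver)
    records = compute_shear(sol, tree, cfg.blood)
    summary = aggregate_proximal(records, tree, scope=set(cfg.scope))
    return summary.TAWSS_proximal, True


def _tuned_inflow(rhc: RHCRecord, cfg: CohortConfig):
    from .hemo0d import make_inflow

    return make_inflow(
        rhc.CO, rhc.HR, systolic_fraction=cfg.tuning.systolic_fraction,
        n_samples=cfg.tuning.waveform_samples,
    )


def generate_cohort(
    mode: str = "statistical",
    sizes: tuple[int, int, int] = (30, 30, 30),
    seed: int = 0,
    summaries: dict[Group, GroupSummary] | None = None,
    config: CohortConfig | None = None,
) -> CohortTable:
    """Generate a seeded three-group cohort.

    Parameters
    ----------
    mode : {"statistical", "mechanistic"}
        See the module docstring.
    sizes : tuple of int
        (CTEPH, CTEPD, CONTROL) group sizes; default 30 each.
    summaries : dict, optional
        Per-group :class:`GroupSummary`; defaults to the published values.

    Mechanistic-mode patients whose RCR tuning fails to converge are excluded
    and recorded in ``CohortTable.failures`` with a logged count.
    """
    if mode not in ("statistical", "mechanistic"):
        raise ValueError(f"unknown mode {mode!r}")
    summaries = summaries or DEFAULT_SUMMARIES
    cfg = config or CohortConfig()

    ss = np.random.SeedSequence(seed)
    group_seeds = ss.spawn(len(_GROUP_ORDER))
    patients: list[PatientRecord] = []
    failures: list[str] = []

    for gi, group in enumerate(_GROUP_ORDER):
        n = sizes[gi]
        if n == 0:
            continue
        summary = summaries[group]
        rng = np.random.default_rng(group_seeds[gi])
        rhcs = sample_group_rhc(summary, n, rng)
        mpa_mm = _lognormal(rng, summary.mpa_diameter_mm, n)
        osi_vals = 0.5 * rng.beta(cfg.osi_beta_a, cfg.osi_beta_b, n)
        if summary.mismatch_score is not None:
            scores = _lognormal(rng, summary.mismatch_score, n)
        else:
            scores = [None] * n
        if mode == "statistical":
            tawss_vals = sample_group_tawss(summary, n, rng)
        else:
            # per-patient seeds for tree generation/remodeling, < 2**31
            tree_seeds = rng.integers(0, 2**31 - 1, size=n)
            tawss_vals = np.empty(n)
            ok = np.ones(n, dtype=bool)
            for i in range(n):
                tawss_vals[i], ok[i] = _mechanistic_tawss(
                    group, rhcs[i], float(mpa_mm[i]), int(tree_seeds[i]), cfg
                )

        for i in range(n):
            pid = f"{group.value}-{i + 1:03d}"
            if mode == "mechanistic" and not ok[i]:
                failures.append(pid)
                continue
            patients.append(
                PatientRecord(
                    patient_id=pid,
                    group=group,
                    rhc=rhcs[i],
                    mpa_diameter_mm=float(mpa_mm[i]),
                    TAWSS=float(tawss_vals[i]),
                    OSI=float(osi_vals[i]),
                    mismatch_positive=group in (Group.CTEPH, Group.CTEPD),
                    mismatch_score=None if scores[i] is None else float(scores[i]),
                )
            )

    if failures:
        logger.warning("excluded %d patients with non-converged tuning: %s",
                       len(failures), failures)
    return CohortTable(patients=patients, seed=seed, mode=mode, failures=failures)
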