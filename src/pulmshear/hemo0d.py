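"""Pulsatile 0D (lumped-parameter) hemodynamics of the arterial tree.

The tree is a network of Poiseuille segment resistances driven by an imposed
root inflow; each outlet terminates in a three-element Windkessel (proximal
resistance Rp in series with a parallel compliance C / distal resistance Rd
pair referenced to a distal pressure). Blood is Newtonian and incompressible.

At each time step the purely resistive part of the network is solved exactly
for nodal pressures and flows given the current capacitor pressures (a
Thevenin up-sweep / down-sweep over the tree, O(n) per step), after which each
Windkessel capacitor is advanced by an implicit-Euler update of
``dPc/dt = (Q_outlet - (Pc - P_distal)/Rd) / C``. Cycles are repeated until
the cycle-mean root pressure is periodic, with a floor of six cycles; metrics
are taken from the final cycle only.

Because the resistive solve is linear in ``(Q_in, Pc_1..Pc_m)``, the network
response is precomputed once as an affine map by (m+1) basis solves; the time
loop then costs one small mat-vec per step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .arterial_tree import ArterialTree, outlets
from .units import LPM, POISE_PER_PAS, cgs_to_mmhg

if TYPE_CHECKING:  # pragma: no cover
    from .windkessel import RCRSet

__all__ = [
    "BloodModel",
    "FlowWaveform",
    "SolverConfig",
    "HemoSolution",
    "SolverInstabilityError",
    "make_inflow",
    "segment_resistance",
    "solve",
    "summarize_pressures",
    "write_solution",
]


class SolverInstabilityError(RuntimeError):
    """Non-finite solver state."""


@dataclass(frozen=True)
class BloodModel:
    """Newtonian blood rheology: viscosity in Pa*s, density in kg/m^3."""

    viscosity: float = 0.0035
    density: float = 1060.0

    def __post_init__(self) -> None:
        if not (self.viscosity > 0 and self.density > 0):
            raise ValueError("viscosity and density must be > 0")

    @property
    def viscosity_poise(self) -> float:
        return self.viscosity * POISE_PER_PAS


@dataclass
class FlowWaveform:
    """One period of root inflow on a uniform half-open grid [0, T).

    ``flow`` is in cm^3/s; its mean over the period is the cardiac output.
    """

    period: float
    times: np.ndarray
    flow: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.flow.shape:
            raise ValueError("times and flow must be 1-D arrays of equal length")
        dt = np.diff(self.times)
        if len(dt) and not (np.all(dt > 0) and np.allclose(dt, dt[0], rtol=1e-9)):
            raise ValueError("times must be strictly increasing and uniform")

    @property
    def mean_flow(self) -> float:
        # uniform periodic grid: sample mean == trapezoid of periodic extension
        return float(np.mean(self.flow))

    def at(self, t: np.ndarray) -> np.ndarray:
        """Periodic linear interpolation at arbitrary times."""
        tt = np.mod(t, self.period)
        tp = np.append(self.times, self.period)
        qp = np.append(self.flow, self.flow[0])
        return np.interp(tt, tp, qp)


def make_inflow(
    CO: float,
    HR: float,
    systolic_fraction: float = 0.35,
    n_samples: int = 1000,
) -> FlowWaveform:
    """Build a pulsatile root-inflow waveform from cardiac output and heart
    rate, the two quantities a right-heart catheterization provides.

    Shape: half-sine systole ``Q(t) = Q_peak sin(pi t / Ts)`` for
    ``t < Ts = systolic_fraction * T``, zero flow in diastole, with
    ``Q_peak = Q_mean * pi * T / (2 * Ts)``. The sampled vector is
    renormalized so its mean equals the prescribed CO exactly.

    Parameters
    ----------
    CO : float
        Cardiac output, L/min; > 0.
    HR : float
        Heart rate, beats/min; > 0.
    """
    if not (CO > 0 and HR > 0):
        raise ValueError("CO and HR must be > 0")
    if not (0 < systolic_fraction < 1):
        raise ValueError(f"systolic_fraction must be in (0, 1), got {systolic_fraction}")
    if n_samples < 8:
        raise ValueError("n_samples must be >= 8")

    T = 60.0 / HR
    Ts = systolic_fraction * T
    q_mean = CO * LPM
    q_peak = q_mean * np.pi * T / (2.0 * Ts)
    t = np.arange(n_samples) * (T / n_samples)
    q = np.where(t < Ts, q_peak * np.sin(np.pi * t / Ts), 0.0)
    q *= q_mean / np.mean(q)  # exact discrete mean
    return FlowWaveform(period=T, times=t, flow=q)


def segment_resistance(blood: BloodModel, length: float, diameter: float) -> float:
    """Poiseuille resistance ``8 mu L / (pi r^4)`` in dyn*s/cm^5 (mu in poise)."""
    if not (diameter > 0):
        raise ValueError(f"diameter must be > 0, got {diameter}")
    if length < 0:
        raise ValueError(f"length must be >= 0, got {length}")
    r = diameter / 2.0
    return 8.0 * blood.viscosity_poise * length / (np.pi * r**4)


@dataclass
class SolverConfig:
    """Time-stepping controls.

    ``dt`` is nominal: the actual step is ``T / round(T/dt)`` so each cycle is
    an integer number of steps. Cycles repeat until the relative change of the
    cycle-mean root pressure drops below ``periodicity_tol`` (never fewer than
    ``min_cycles``).
    """

    dt: float = 1e-3
    min_cycles: int = 6
    max_cycles: int = 20
    periodicity_tol: float = 0.005

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise ValueError("dt must be > 0")
        if self.min_cycles < 1 or self.max_cycles < self.min_cycles:
            raise ValueError("need 1 <= min_cycles <= max_cycles")


@dataclass
class HemoSolution:
    """Final-cycle pressure/flow waveforms per segment (CGS units).

    ``pressures[seg_id]`` is the pressure at the segment inlet node;
    ``flows[seg_id]`` the volumetric flow through the segment. ``times`` is
    the final-cycle grid (half-open).
    """

    times: np.ndarray
    pressures: dict[str, np.ndarray]
    flows: dict[str, np.ndarray]
    root_id: str
    cycles_run: int
    periodicity_error: float
    converged: bool
    config: SolverConfig = field(repr=False, default_factory=SolverConfig)

    @property
    def root_pressure(self) -> np.ndarray:
        return self.pressures[self.root_id]

    @property
    def period(self) -> float:
        n = len(self.times)
        return float(self.times[1] - self.times[0]) * n if n > 1 else 0.0


def _network_maps(tree: ArterialTree, rcr: "RCRSet", blood: BloodModel):
    """Affine maps of the resistive network.

    Returns (seg_ids, out_ids, A_p, b_p, A_q, b_q) such that for root inflow
    ``q`` and capacitor pressures ``pc`` (outlet order):
    inlet pressures = ``b_p * q + A_p @ pc``; segment flows =
    ``b_q * q + A_q @ pc``.
    """
    segs = list(tree.walk())  # topological, canonical order
    seg_ids = [s.id for s in segs]
    idx = {sid: i for i, sid in enumerate(seg_ids)}
    outs = outlets(tree)
    out_ids = [s.id for s in outs]
    out_pos = {sid: j for j, sid in enumerate(out_ids)}
    missing = [sid for sid in out_ids if sid not in rcr.entries]
    if missing:
        raise ValueError(f"RCR set missing outlets {missing}")

    children = {sid: [c.id for c in tree.children(sid)] for sid in seg_ids}
    r_seg = np.array([segment_resistance(blood, s.length, s.diameter) for s in segs])
    rp = np.array([rcr.entries[sid].Rp for sid in out_ids])

    n, m = len(segs), len(outs)

    def solve_resistive(q_in: float, p_term: np.ndarray):
        # up-sweep: Thevenin equivalent (R_eq, P_eq) of each subtree
        r_eq = np.empty(n)
        p_eq = np.empty(n)
        for i in range(n - 1, -1, -1):
            sid = seg_ids[i]
            kids = children[sid]
            if not kids:
                j = out_pos[sid]
                r_eq[i] = r_seg[i] + rp[j]
                p_eq[i] = p_term[j]
            else:
                g = np.array([1.0 / r_eq[idx[k]] for k in kids])
                pk = np.array([p_eq[idx[k]] for k in kids])
                gsum = g.sum()
                r_eq[i] = r_seg[i] + 1.0 / gsum
                p_eq[i] = float(g @ pk) / gsum
        # down-sweep: flows and nodal pressures
        q = np.empty(n)
        p_in = np.empty(n)
        root_i = idx[tree.root_id]
        q[root_i] = q_in
        p_in[root_i] = p_eq[root_i] + q_in * r_eq[root_i]
        for i in range(n):
            sid = seg_ids[i]
            p_dist = p_in[i] - q[i] * r_seg[i]
            for k in children[sid]:
                ki = idx[k]
                q[ki] = (p_dist - p_eq[ki]) / r_eq[ki]
                p_in[ki] = p_dist
        return p_in, q

    b_p, b_q = solve_resistive(1.0, np.zeros(m))
    A_p = np.empty((n, m))
    A_q = np.empty((n, m))
    for j in range(m):
        e = np.zeros(m)
        e[j] = 1.0
        A_p[:, j], A_q[:, j] = solve_resistive(0.0, e)
    return seg_ids, out_ids, A_p, b_p, A_q, b_q


def solve(
    tree: ArterialTree,
    rcr: "RCRSet",
    inflow: FlowWaveform,
    blood: BloodModel | None = None,
    config: SolverConfig | None = None,
) -> HemoSolution:
    """Run the pulsatile 0D simulation to periodic convergence.

    Raises
    ------
    SolverInstabilityError
        If the state becomes non-finite (names the failing cycle).
    """
    blood = blood or BloodModel()
    config = config or SolverConfig()

    seg_ids, out_ids, A_p, b_p, A_q, b_q = _network_maps(tree, rcr, blood)
    leaf_rows = [seg_ids.index(sid) for sid in out_ids]
    A_qo = A_q[leaf_rows, :]
    b_qo = b_q[leaf_rows]

    rd = np.array([rcr.entries[sid].Rd for sid in out_ids])
    cap = np.array([rcr.entries[sid].C for sid in out_ids])
    p_d = rcr.distal_pressure
    if np.any(cap <= 0) or np.any(rd <= 0):
        raise SolverInstabilityError("RCR requires C > 0 and Rd > 0 at every outlet")

    T = inflow.period
    n_steps = max(int(round(T / config.dt)), 16)
    dt = T / n_steps
    t_grid = np.arange(n_steps) * dt
    q_in = inflow.at(t_grid)

    denom = 1.0 + dt / (rd * cap)
    pc = np.full(len(out_ids), p_d, dtype=float)
    pc_hist = np.empty((n_steps, len(out_ids)))

    prev_mean = None
    periodicity_error = np.inf
    converged = False
    cycles = 0
    root_row = seg_ids.index(tree.root_id)

    for cycle in range(1, config.max_cycles + 1):
        with np.errstate(over="ignore", invalid="ignore"):
            for k in range(n_steps):
                pc_hist[k] = pc
                q_out = b_qo * q_in[k] + A_qo @ pc
                pc = (pc + (dt / cap) * (q_out + p_d / rd)) / denom
        if not np.all(np.isfinite(pc)):
            raise SolverInstabilityError(f"non-finite capacitor pressure in cycle {cycle}")
        cycles = cycle
        root_p = b_p[root_row] * q_in + pc_hist @ A_p[root_row]
        mean_p = float(np.mean(root_p))
        if prev_mean is not None:
            periodicity_error = abs(mean_p - prev_mean) / max(abs(mean_p), 1e-30)
            if cycle >= config.min_cycles and periodicity_error <= config.periodicity_tol:
                converged = True
                break
        prev_mean = mean_p

    # reconstruct the final cycle from the recorded capacitor trajectory
    p_all = np.outer(b_p, q_in) + A_p @ pc_hist.T  # (n_seg, n_steps)
    q_all = np.outer(b_q, q_in) + A_q @ pc_hist.T
    return HemoSolution(
        times=t_grid,
        pressures={sid: p_all[i] for i, sid in enumerate(seg_ids)},
        flows={sid: q_all[i] for i, sid in enumerate(seg_ids)},
        root_id=tree.root_id,
        cycles_run=cycles,
        periodicity_error=float(periodicity_error),
        converged=converged,
        config=config,
    )


def summarize_pressures(solution: HemoSolution) -> tuple[float, float, float]:
    """(sPAP, dPAP, mPAP) in mmHg from the final-cycle root pressure.

    mPAP is the trapezoidal cycle mean (= sample mean on the uniform periodic
    grid); sPAP/dPAP are the extrema.
    """
    p = solution.root_pressure
    return (
        cgs_to_mmhg(float(np.max(p))),
        cgs_to_mmhg(float(np.min(p))),
        cgs_to_mmhg(float(np.mean(p))),
    )


def write_solution(solution: HemoSolution, path) -> None:
    """Export the final cycle in long format with a metadata header."""
    import pandas as pd

    rows = []
    for sid in solution.pressures:
        rows.append(
            pd.DataFrame(
                {
                    "segment_id": sid,
                    "time_s": solution.times,
                    "pressure_dyn_cm2": solution.pressures[sid],
                    "flow_cm3_s": solution.flows[sid],
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(
            f"# cycles_run={solution.cycles_run} "
            f"periodicity_error={solution.periodicity_error:.3e} "
            f"converged={solution.converged}\n"
            f"# dt={solution.config.dt} min_cycles={solution.config.min_cycles} "
            f"max_cycles={solution.config.max_cycles} "
            f"periodicity_tol={solution.config.periodicity_tol}\n"
        )
        df.to_csv(fh, index=False)
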