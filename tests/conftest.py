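import numpy as np
import pytest

from pulmshear.arterial_tree import ArterialSegment, ArterialTree, generate_tree
from pulmshear.hemo0d import BloodModel, FlowWaveform, SolverConfig
from pulmshear.windkessel import RCRParams, RCRSet


@pytest.fixture
def blood():
    return BloodModel()


@pytest.fixture
def symmetric_tree():
    """Symmetric 2-generation tree (4 outlets), Murray exponent 3."""
    return generate_tree(3.0, n_generations=2, murray_exponent=3.0, asymmetry=0.0, seed=0)


@pytest.fixture
def single_segment_tree():
    """Root-only tree with negligible segment resistance, for closed-form
    Windkessel checks."""
    tree = ArterialTree()
    tree.add(ArterialSegment(id="MPA", parent_id=None, name="MPA", length=1e-6, diameter=2.0))
    return tree


@pytest.fixture
def tight_solver():
    """Solver config tight enough for analytic comparisons."""
    return SolverConfig(dt=2e-4, min_cycles=6, max_cycles=80, periodicity_tol=1e-8)


def constant_inflow(Q: float, period: float = 1.0, n: int = 200) -> FlowWaveform:
    return FlowWaveform(period=period, times=np.arange(n) * period / n, flow=np.full(n, Q))


def single_rcr(Rp: float, C: float, Rd: float, distal: float = 0.0) -> RCRSet:
    return RCRSet(entries={"MPA": RCRParams(Rp=Rp, C=C, Rd=Rd)}, distal_pressure=distal)
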