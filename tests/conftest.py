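import numpy as np
import pytest

from kcnq1ca import gating as G
from kcnq1ca import pipelines as P
from kcnq1ca import synth as SY


@pytest.fixture(scope="session")
def wt_scheme():
    return G.build_default_scheme("WT", include_starved_layer=True)


@pytest.fixture(scope="session")
def wt5_scheme():
    return G.build_default_scheme("WT", include_starved_layer=False)


@pytest.fixture(scope="session")
def low_ca():
    """Intracellular Ca2+ after 5 min of wash-out with the standard ICS."""
    cond = SY.ConditionSpec()
    return float(np.asarray(SY.intracellular_ca_timecourse(cond, 300.0)))


@pytest.fixture(scope="session")
def low_ca_iv_recording(wt_scheme, low_ca):
    """Noiseless double-pulse family of the WT model in the low-Ca regime."""
    return P.model_recording(wt_scheme, "iv2s", ca=low_ca)


@pytest.fixture(scope="session")
def early_iv_recording(wt_scheme):
    return P.model_recording(wt_scheme, "iv2s", ca=P.EARLY_CA_M)


def two_state_scheme(k_plus=0.01, k_minus=0.01, z_plus=0.0, z_minus=0.0):
    """Minimal closed<->open toy scheme for closed-form checks."""
    return G.GatingScheme(
        states=(G.State("C"), G.State("O", conducting_weight=1.0)),
        transitions=(
            G.Transition("C", "O", G.RateLaw(k_plus, z_plus)),
            G.Transition("O", "C", G.RateLaw(k_minus, z_minus)),
        ),
        ca_sensor=None,
        name="toy2",
    )


def random_scheme(rng, n_states=4):
    """Random connected reversible chain with random voltage dependence."""
    states = [G.State(f"S{i}", conducting_weight=float(i == n_states - 1))
              for i in range(n_states)]
    transitions = []
    for i in range(n_states - 1):
        kf = float(rng.uniform(0.002, 0.04))
        kb = float(rng.uniform(0.002, 0.04))
        zf = float(rng.uniform(-1.0, 1.0))
        zb = float(rng.uniform(-1.0, 1.0))
        transitions.append(G.Transition(f"S{i}", f"S{i+1}", G.RateLaw(kf, zf)))
        transitions.append(G.Transition(f"S{i+1}", f"S{i}", G.RateLaw(kb, zb)))
    return G.GatingScheme(states=tuple(states), transitions=tuple(transitions),
                          ca_sensor=G.CaSensor(), name="random")
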