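import numpy as np
import pytest
from hypothesis import HealthCheck, settings as hyp_settings

from metaboloq import SolverSettings, build_canonical_network, integrate

hyp_settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
hyp_settings.load_profile("default")


@pytest.fixture(scope="session")
def canonical():
    return build_canonical_network()


@pytest.fixture(scope="session")
def wt_trajectory(canonical):
    return integrate(canonical, SolverSettings(), scenario_label="wt")


# ---------------------------------------------------------------------------
# Independent fixed-step RK4 oracle over a hand-transcribed right-hand side.
# The equations below are written out directly (k1..k5 inlined, the two
# identical monomer reactions folded into factors of 2) so that the oracle
# shares no code with the package's generalized mass-action machinery.
# ---------------------------------------------------------------------------

def oracle_rhs(x):
    x1, x2, x3, x4, x5, x6, x7, x8, x9, x10, x11, x12, x13, x14 = x
    a = 5.0 * x1 * x2 * x3            # each monomer Qo oxidation
    b = 5.0 * x3 * x4 * x7 * x8       # each monomer Qi reduction
    c = 5.0 * x3 * x9 * x12           # ETFDH(FADH2) semiquinone reduction
    d = 5.0 * x3 * x10 * x13 * x14    # ETFDH(FADH) semiquinone reduction
    e = 20.0 * x3 * x12 * x13         # CIII-autonomous disproportionation
    return (
        -2 * a + d + e,
        -2 * a,
        -2 * a - 2 * b - c - d - e,
        2 * a - 2 * b,
        2 * a,
        2 * a + 2 * b,
        d + e,
        -2 * b + c + d,
        -c,
        c - d,
        d,
        b - c - e,
        b - d - e,
        c - d,
    )


def oracle_initial_state(etfdh_level):
    return (0.6, 1.1, 4.6, 0.0, 0.0, 0.0, 0.5, 0.5, float(etfdh_level),
            0.0, 0.0, 0.0, 0.0, 0.0)


def rk4_oracle(etfdh_level, sample_times, dt=1e-4):
    """Classic fixed-step RK4 on the hand-transcribed equations.

    ``sample_times`` must be integer multiples of ``dt``; returns an array of
    the state at each sample time.
    """
    n = 14
    x = list(oracle_initial_state(etfdh_level))
    steps = [int(round(t / dt)) for t in sample_times]
    assert all(abs(s * dt - t) < 1e-12 for s, t in zip(steps, sample_times))
    out = []
    target = dict.fromkeys(steps)
    half = dt / 2.0
    sixth = dt / 6.0
    if 0 in target:
        out.append(np.array(x))
    last = max(steps)
    for step in range(1, last + 1):
        k1 = oracle_rhs(x)
        k2 = oracle_rhs([x[i] + half * k1[i] for i in range(n)])
        k3 = oracle_rhs([x[i] + half * k2[i] for i in range(n)])
        xk = [x[i] + dt * k3[i] for i in range(n)]
        k4 = oracle_rhs(xk)
        x = [x[i] + sixth * (k1[i] + 2 * k2[i] + 2 * k3[i] + k4[i]) for i in range(n)]
        if step in target:
            out.append(np.array(x))
    return np.array(out)
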