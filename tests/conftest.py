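import numpy as np
import pytest
from scipy.sparse import lil_matrix

from compsyn import PlasticityParams


def random_params(rng, lo=0.1, hi=0.9):
    a, b = rng.uniform(lo, hi, 2)
    return PlasticityParams(float(a), float(b))


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def exact_conditioned_window_mean(n, alpha, beta, sweeps, window_start):
    """Independent master-equation oracle for the chain simulator.

    Enumerates all 2^n lattice states, builds the exact single-update
    transition matrix of the random-sequential dynamics directly from the
    plasticity rules (mixed neighbours: potentiate w.p. alpha(1-beta),
    depress w.p. beta(1-alpha)), and computes the time-averaged strong
    fraction over sweeps [window_start, sweeps], conditioned on not being
    absorbed by the end — the exact analogue of averaging surviving
    simulation runs started from the uniform product state at x0 = 1/2.
    """
    nstates = 2**n
    P = lil_matrix((nstates, nstates))
    p_pot = alpha * (1.0 - beta)
    p_dep = beta * (1.0 - alpha)
    for s in range(nstates):
        for i in range(n):
            lt = (s >> ((i - 1) % n)) & 1
            rt = (s >> ((i + 1) % n)) & 1
            if lt == rt:
                P[s, s] += 1.0 / n
                continue
            P[s, s | (1 << i)] += p_pot / n
            P[s, s & ~(1 << i)] += p_dep / n
            P[s, s] += (1.0 - p_pot - p_dep) / n
    P = P.tocsr()
    keep = np.arange(1, nstates - 1)  # drop the two absorbing states
    Q = P[np.ix_(keep, keep)].tocsr()
    QT = Q.T.tocsr()
    frac = np.array([bin(int(s)).count("1") / n for s in keep])

    total_steps = sweeps * n
    d = np.full(len(keep), 1.0 / nstates)  # uniform product init, x0 = 1/2
    fwd = {}
    for t in range(total_steps + 1):
        if t % n == 0 and t // n >= window_start:
            fwd[t // n] = d.copy()
        if t < total_steps:
            d = QT @ d
    b = np.ones(len(keep))
    back = {sweeps: b.copy()}
    for t in range(total_steps - 1, -1, -1):
        b = Q @ b
        if t % n == 0 and t // n >= window_start:
            back[t // n] = b.copy()
    num = den = 0.0
    for sweep in range(window_start, sweeps + 1):
        w = fwd[sweep] * back[sweep]
        num += (w * frac).sum()
        den += w.sum()
    return num / den
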