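"""Independent brute-force oracles shared by the test suite and the
acceptance checks.  These deliberately use different algorithms from the
implementation they check."""

import numpy as np


def _column_ll(xcol: np.ndarray, v: np.ndarray, u: np.ndarray) -> np.ndarray:
    """LL of one matrix column over a u-grid for fixed row multipliers v.

    Returns an array over u; entries where any product v_i*u leaves (0,1)
    are -inf.
    """
    t = np.outer(v, u)  # (m, |u|)
    valid = (t > 0).all(axis=0) & (t < 1).all(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (xcol[:, None] * np.log(t) + (1 - xcol)[:, None] * np.log1p(-t)).sum(axis=0)
    ll[~valid] = -np.inf
    return ll


def product_grid_search(
    x: np.ndarray, candidate: np.ndarray, u_step: float = 0.001, keep_tol: float = 3e-4
):
    """Dense grid search of the Bernoulli LL over rank-1 product matrices.

    A rank-1 matrix of products t_ij = p_i q_j is parametrized as
    t_ij = v_i * u_j with v_1 = 1 (u_j = p_1 q_j, v_i = p_i / p_1), which
    respects the rank-1 constraint exactly.  For fixed row multipliers v the
    LL separates over columns, so each u_j is maximized on a dense 1-D grid.

    The optimum can be a ridge, so the oracle returns the best LL found and
    the minimum max-entry distance between `candidate` and the set of grid
    points within `keep_tol` nats of the optimum (keep_tol absorbs the LL
    discretization error of the ridge).  Supports 2x2 and 3x3 matrices.
    """
    x = np.asarray(x, dtype=float)
    candidate = np.asarray(candidate, dtype=float)
    m, n = x.shape
    if m not in (2, 3) or n > 3:
        raise ValueError("oracle supports 2- or 3-row matrices up to 3 columns")
    u = np.arange(u_step, 1.0, u_step)
    base = np.linspace(0.01, 1.0, 250)
    v_grid = np.unique(np.concatenate([base, 1.0 / base]))

    if m == 2:
        v_sets = [(v2,) for v2 in v_grid]
    else:
        v_sets = [(v2, v3) for v2 in v_grid for v3 in v_grid]

    lls = np.empty(len(v_sets))
    u_stars = np.empty((len(v_sets), n))
    for k, vs in enumerate(v_sets):
        v = np.array((1.0,) + vs)
        total = 0.0
        for j in range(n):
            ll_u = _column_ll(x[:, j], v, u)
            kk = int(np.argmax(ll_u))
            total += ll_u[kk]
            u_stars[k, j] = u[kk]
        lls[k] = total
    best = float(lls.max())
    min_dist = np.inf
    for k in np.nonzero(lls >= best - keep_tol)[0]:
        t = np.outer(np.array((1.0,) + v_sets[k]), u_stars[k])
        min_dist = min(min_dist, float(np.abs(t - candidate).max()))
    return best, min_dist
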