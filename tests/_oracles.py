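"""Independent brute-force oracles for the kinetics fits.

A vectorized grid search with local refinement over the model parameters;
shares no code with the package's optimizer path, so agreement between the
two is evidence both are finding the least-squares optimum.
"""

import numpy as np


def _rss_grid(model, t, y, grids):
    """RSS over the cartesian product of 1-D parameter grids."""
    mesh = np.meshgrid(*grids, indexing="ij")
    flat = [m.ravel() for m in mesh]
    pred = model(t[:, None], *[p[None, :] for p in flat])
    rss = ((pred - y[:, None]) ** 2).sum(axis=0)
    i = int(np.argmin(rss))
    return np.array([p[i] for p in flat]), float(rss[i])


def grid_oracle(model, t, y, lo, hi, n_grid=25, n_refine=4, log_axes=()):
    """Best least-squares parameters of ``model`` by refined grid search.

    ``model(t, *params)`` must broadcast; ``lo``/``hi`` bound each
    parameter; axes listed in ``log_axes`` are gridded geometrically.
    Each refinement re-grids a shrinking box around the incumbent.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    cur_lo, cur_hi = lo.copy(), hi.copy()
    best_p, best_rss = None, np.inf
    for _ in range(n_refine):
        grids = []
        for j, (a, b) in enumerate(zip(cur_lo, cur_hi)):
            if j in log_axes:
                grids.append(np.geomspace(max(a, 1e-9), b, n_grid))
            else:
                grids.append(np.linspace(a, b, n_grid))
        p, rss = _rss_grid(model, t, y, grids)
        if rss < best_rss:
            best_p, best_rss = p, rss
        span = (cur_hi - cur_lo) / (n_grid - 1) * 3.0
        cur_lo = np.maximum(lo, best_p - span)
        cur_hi = np.minimum(hi, best_p + span)
    return best_p, best_rss


def hyperbolic_light_oracle(t, y, **kw):
    return grid_oracle(
        lambda tt, a, k: a * tt / (k + tt),
        t, y, lo=[1e-3, 1e-2], hi=[20.0, 1e4], log_axes=(1,), **kw,
    )


def hyperbolic_dark_oracle(t, y, **kw):
    # parameters (N0, frac=A_D/N0, K_D): enforces 0 <= A_D <= N0
    return grid_oracle(
        lambda tt, n0, f, k: n0 - f * n0 * tt / (k + tt),
        t, y, lo=[1e-3, 0.0, 1e-2], hi=[20.0, 1.0, 1e4], log_axes=(2,), **kw,
    )


def exponential_light_oracle(t, y, **kw):
    return grid_oracle(
        lambda tt, a, tau: a * (1.0 - np.exp(-tt / tau)),
        t, y, lo=[1e-3, 1e-2], hi=[20.0, 1e4], log_axes=(1,), **kw,
    )
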