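"""Independent oracles used by the test suite.

Each function here recomputes a quantity by a different route from the
implementation it checks: a Newton optimizer for the IRLS fit, exhaustive
enumeration for the exact tests, and plain double loops with an
independently written spherical-distance formula for the raster engine.
"""

import itertools
import math

import numpy as np
from scipy import optimize
from scipy.special import comb


# --- maximum-likelihood oracle for the binomial GLM ------------------------

def newton_ml_fit(X, y, n, tol=1e-12):
    """Maximize the binomial log-likelihood by Newton-CG from zero.

    Same likelihood as the IRLS engine, different optimizer and code path.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = np.asarray(n, float)

    def negll(beta):
        eta = X @ beta
        # log(1+e^eta) computed stably
        return float(np.sum(n * np.logaddexp(0.0, eta) - y * eta))

    def grad(beta):
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        return X.T @ (n * p - y)

    def hess(beta):
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        w = n * p * (1.0 - p)
        return X.T @ (X * w[:, None])

    res = optimize.minimize(negll, np.zeros(X.shape[1]), jac=grad, hess=hess,
                            method="Newton-CG",
                            options={"xtol": tol, "maxiter": 500})
    return res.x


# --- exact-test oracles -----------------------------------------------------

def fisher_exact_enumeration(a, b, c, d):
    """Two-sided Fisher p by direct enumeration with exact rational-ish pmf."""
    n1, n2, m = a + b, c + d, a + c
    ks = range(max(0, m - n2), min(m, n1) + 1)
    denom = comb(n1 + n2, m, exact=True)
    pmf = {k: comb(n1, k, exact=True) * comb(n2, m - k, exact=True) / denom
           for k in ks}
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7))


def rank_sum_exact_enumeration(x, y):
    """Two-sided rank-sum p by enumerating all assignments of ranks (no ties)."""
    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires untied data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    nx = len(x)
    w_obs = sum(ranks[v] for v in x)
    mean_w = nx * (len(pooled) + 1) / 2.0
    dev_obs = abs(w_obs - mean_w)
    total = 0
    hits = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), nx):
        total += 1
        if abs(sum(combo) - mean_w) >= dev_obs - 1e-9:
            hits += 1
    return hits / total


# --- spherical distance oracle ----------------------------------------------

_R = 6371.0088


def sphere_distance_km(lat1, lon1, lat2, lon2):
    """Great-circle distance via the chord/central-angle construction
    (independent of the haversine formulation)."""
    phi1, lam1, phi2, lam2 = map(math.radians, (lat1, lon1, lat2, lon2))
    x1 = math.cos(phi1) * math.cos(lam1)
    y1 = math.cos(phi1) * math.sin(lam1)
    z1 = math.sin(phi1)
    x2 = math.cos(phi2) * math.cos(lam2)
    y2 = math.cos(phi2) * math.sin(lam2)
    z2 = math.sin(phi2)
    chord = math.sqrt((x1 - x2) ** 2 + (y1 - y2) ** 2 + (z1 - z2) ** 2)
    return 2.0 * _R * math.asin(min(1.0, chord / 2.0))


def distance_to_range_scan(grid, interval, lat, lon):
    """Minimum distance to in-range cell centers by an explicit double loop."""
    t_lo, t_hi = interval
    best = None
    on_cell = None
    try:
        row = math.floor((grid.lat_nw - lat) / grid.cell_size)
        col = math.floor((lon - grid.lon_nw) / grid.cell_size)
        if 0 <= row < grid.n_rows and 0 <= col < grid.n_cols:
            on_cell = (row, col)
    except ValueError:
        pass
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            v = grid.values[r, c]
            if v == grid.nodata:
                continue
            vc = v / 10.0
            if not (t_lo <= vc <= t_hi):
                continue
            if on_cell == (r, c):
                return 0.0
            clat = grid.lat_nw - (r + 0.5) * grid.cell_size
            clon = grid.lon_nw + (c + 0.5) * grid.cell_size
            d = sphere_distance_km(lat, lon, clat, clon)
            if best is None or d < best:
                best = d
    return best
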