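"""Validate a predicted temperature range against worldwide strain locations.

Strains collated from published genotyping studies are classified against a
Tmax raster and a predicted envelope interval: each record gets the Tmax of
its single containing pixel, an in/out-of-range flag, and — when out of
range — the great-circle distance to the nearest in-range cell.  Summaries
are stratified by genotype class (wild, human-associated, mosaic), because
human-associated strains form dispersal-maintained sink populations that are
expected far outside the climatically suitable range and must not count
against the envelope.

Two significance tests used in these comparisons are provided:
Fisher's exact test (two-sided, probability-mass definition) for 2x2
isolation-rate tables, and the Wilcoxon rank-sum test for distance
comparisons between genotype classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .raster import RasterGrid, value_at, distance_to_range, OutOfExtentError

GENOTYPE_CLASSES = ("wild", "human-associated", "mosaic", "unknown")

#: Substrings of a substrate description that mark a strain as
#: wine/vineyard-associated (excluded from envelope validation by default).
WINE_SUBSTRATE_MARKERS = ("wine", "grape")

STRAIN_COLUMNS = ["strain_id", "species", "genotype_class", "lat", "lon",
                  "substrate", "source_study"]


class ValidationError(ValueError):
    """Contract violation in classification or testing inputs."""


# ---------------------------------------------------------------------------
# classification


def filter_wine_associated(strains: pd.DataFrame,
                           markers=WINE_SUBSTRATE_MARKERS) -> pd.DataFrame:
    """Drop strains whose substrate suggests wine/vineyard origin.

    Matching is by substring on the lower-cased substrate description; the
    marker list is configurable because e.g. vineyard *soil* is a judgement
    call.
    """
    if "substrate" not in strains.columns or strains.empty:
        return strains
    sub = strains["substrate"].fillna("").astype(str).str.lower()
    keep = ~sub.apply(lambda s: any(m in s for m in markers))
    return strains[keep]


def classify_strains(
    strains: pd.DataFrame,
    grid: RasterGrid,
    interval: tuple[float, float],
) -> pd.DataFrame:
    """Attach pixel Tmax, in-range flag and distance-to-range to each strain.

    Strains on nodata cells (or off the grid) get ``tmax_c = NaN`` and
    ``in_range = NA``; they are counted separately by
    :func:`summarize_validation` rather than silently dropped.
    """
    for col in ("lat", "lon"):
        if col not in strains.columns:
            raise ValidationError(f"strain table lacks column {col!r}")
    bad = strains[(strains["lat"].abs() > 90) | (strains["lon"].abs() > 180)]
    if len(bad):
        raise ValidationError(
            f"{len(bad)} strain(s) have invalid WGS84 coordinates "
            f"(first bad row index: {bad.index[0]})"
        )
    out = strains.copy()
    tmax = np.full(len(out), np.nan)
    in_range = np.full(len(out), np.nan)
    dist = np.full(len(out), np.nan)
    t_lo, t_hi = interval
    from .raster import in_range_mask

    any_in_range = bool(in_range_mask(grid, interval).any())
    for i, (lat, lon) in enumerate(zip(out["lat"].to_numpy(),
                                       out["lon"].to_numpy())):
        try:
            v = value_at(grid, float(lat), float(lon))
        except OutOfExtentError:
            continue
        if math.isnan(v):
            continue
        tmax[i] = v
        inside = t_lo <= v <= t_hi
        in_range[i] = float(inside)
        if inside:
            dist[i] = 0.0
        elif any_in_range:
            dist[i] = distance_to_range(grid, interval, float(lat),
                                        float(lon))
    out["tmax_c"] = tmax
    out["in_range"] = pd.array(
        [bool(v) if not math.isnan(v) else pd.NA for v in in_range],
        dtype="boolean",
    )
    out["distance_km"] = dist
    return out


def summarize_validation(classified: pd.DataFrame,
                         by: str = "genotype_class") -> pd.DataFrame:
    """Per-class counts, in-range fractions, and distance quantiles.

    ``n_total = n_in + n_out + n_nodata`` per class; the in-range fraction is
    over classifiable strains only (``n_in / (n_in + n_out)``), NaN when the
    class has none.
    """
    if classified.empty:
        return pd.DataFrame(columns=[by, "n_total", "n_in", "n_out", "n_nodata",
                                     "fraction_in", "median_distance_km",
                                     "max_distance_km"])
    rows = []
    for cls, grp in classified.groupby(by, dropna=False):
        known = grp[grp["in_range"].notna()]
        n_in = int((known["in_range"] == True).sum())  # noqa: E712
        n_out = int((known["in_range"] == False).sum())  # noqa: E712
        out_d = known.loc[known["in_range"] == False, "distance_km"]  # noqa: E712
        rows.append({
            by: cls,
            "n_total": int(len(grp)),
            "n_in": n_in,
            "n_out": n_out,
            "n_nodata": int(len(grp) - len(known)),
            "fraction_in": n_in / (n_in + n_out) if (n_in + n_out) else np.nan,
            "median_distance_km": float(known["distance_km"].median())
            if len(known) else np.nan,
            "median_out_distance_km": float(out_d.median()) if len(out_d) else np.nan,
            "max_distance_km": float(known["distance_km"].max())
            if len(known) else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fisher's exact test


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b) / (c, d): successes/failures in group 1 / group 2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValidationError("contingency counts must be non-negative integers")
        if min(self.a + self.b, self.c + self.d,
               self.a + self.c, self.b + self.d) <= 0:
            raise ValidationError("every margin must be positive for testing")


def _log_hypergeom_pmf(k, m, n1, n2):
    """log P(X = k) for X ~ Hypergeometric(n1+n2, n1, m): k successes in
    group 1 given row totals n1, n2 and first-column total m."""
    return (
        gammaln(n1 + 1) - gammaln(k + 1) - gammaln(n1 - k + 1)
        + gammaln(n2 + 1) - gammaln(m - k + 1) - gammaln(n2 - (m - k) + 1)
        - (gammaln(n1 + n2 + 1) - gammaln(m + 1) - gammaln(n1 + n2 - m + 1))
    )


def fisher_exact(table, rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher's exact p-value, probability-mass definition.

    Sums the hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed that of the observed table by
    more than a relative tolerance of ``rel_tol`` (the convention used by
    R's ``fisher.test``, which these survey comparisons follow).  All
    probabilities are computed in log space.
    """
    if isinstance(table, ContingencyTable2x2):
        a, b, c, d = table.a, table.b, table.c, table.d
    else:
        (a, b), (c, d) = table
        ContingencyTable2x2(a, b, c, d)  # validate
    n1, n2, m = a + b, c + d, a + c
    k = np.arange(max(0, m - n2), min(m, n1) + 1)
    logp = _log_hypergeom_pmf(k, m, n1, n2)
    log_obs = _log_hypergeom_pmf(np.array([a]), m, n1, n2)[0]
    include = logp <= log_obs + math.log1p(rel_tol)
    # log-sum-exp over the included tables
    mx = logp[include].max()
    p = math.exp(mx) * float(np.exp(logp[include] - mx).sum())
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null enumeration when the smaller sample has at most 10 values and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = min(len(x), len(y)) <= 10
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)
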