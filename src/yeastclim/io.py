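"""Survey table I/O and aggregation.

Two table shapes are handled.  *Sample-level* tables have one row per
environmental sample (a piece of bark, or soil), listing the yeast species
found in it; *tree-level* tables have one row per oak tree with binomial
trials (bark samples) and successes (*S. paradoxus*-positive samples) — the
shape consumed by the GLM.  ``aggregate_tree`` turns the former into the
latter under the survey's default exclusions: oak bark only, no
low-temperature pilot incubations.

Missing trunk girth is encoded as an empty CSV field.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TREE_COLUMNS = [
    "site", "tree", "region", "oak_type", "girth_m", "tmax_c",
    "lat", "lon", "n_samples", "n_sp_positive", "other_yeast_freq",
]

SAMPLE_COLUMNS = [
    "sample_id", "site", "tree_id", "substrate", "collection_date",
    "incubation_c", "species_found", "lat", "lon",
]

TARGET_SPECIES = "Saccharomyces paradoxus"

#: Default sample filters reproducing the modelling dataset: bark only,
#: and no pilot samples incubated at 10 degrees C.
DEFAULT_SUBSTRATES = ("oak bark",)
PILOT_INCUBATION_C = 10.0


class SurveyFormatError(ValueError):
    """Malformed survey file (missing columns, bad rows)."""


class SurveyValidationError(ValueError):
    """Survey rows violate a domain invariant (coordinates, counts)."""


def read_survey(path) -> pd.DataFrame:
    """Read a tree-level survey CSV, validating every row.

    Raises :class:`SurveyFormatError` for missing columns and
    :class:`SurveyValidationError` (with CSV line numbers) for out-of-range
    values.  An empty girth field becomes NaN and the row is retained.
    """
    frame = pd.read_csv(path, dtype={"site": str, "tree": str})
    missing = [c for c in TREE_COLUMNS if c not in frame.columns]
    if missing:
        raise SurveyFormatError(f"{path}: missing column(s) {missing}")
    problems = []
    lineno = frame.index + 2  # header is line 1
    for cond, msg in [
        (frame["lat"].abs() > 90, "latitude outside [-90, 90]"),
        (frame["lon"].abs() > 180, "longitude outside [-180, 180]"),
        (frame["n_samples"] < 1, "n_samples < 1"),
        ((frame["n_sp_positive"] < 0)
         | (frame["n_sp_positive"] > frame["n_samples"]),
         "n_sp_positive outside [0, n_samples]"),
        (frame["girth_m"].notna() & (frame["girth_m"] <= 0),
         "non-positive girth"),
        ((frame["other_yeast_freq"] < 0) | (frame["other_yeast_freq"] > 1),
         "other_yeast_freq outside [0, 1]"),
    ]:
        for ln in lineno[cond.fillna(False)]:
            problems.append(f"line {ln}: {msg}")
    if problems:
        raise SurveyValidationError(
            f"{path}: {len(problems)} invalid row(s):\n  " + "\n  ".join(problems)
        )
    return frame


def write_survey(frame: pd.DataFrame, path) -> None:
    """Write a tree-level table as CSV (missing girth -> empty field)."""
    frame.to_csv(path, index=False, columns=[c for c in TREE_COLUMNS
                                             if c in frame.columns])


def read_samples(path) -> pd.DataFrame:
    """Read a sample-level CSV; ``species_found`` is semicolon-separated."""
    frame = pd.read_csv(path, dtype={"site": str, "tree_id": str})
    missing = [c for c in SAMPLE_COLUMNS if c not in frame.columns]
    if missing:
        raise SurveyFormatError(f"{path}: missing column(s) {missing}")
    bad = frame[(frame["lat"].abs() > 90) | (frame["lon"].abs() > 180)]
    if len(bad):
        raise SurveyValidationError(
            f"{path}: invalid coordinates on line(s) "
            f"{[int(i) + 2 for i in bad.index[:5]]}"
        )
    return frame


def species_list(cell) -> list[str]:
    """Parse a semicolon-separated species cell; empty/NaN -> no species."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return []
    text = str(cell).strip()
    if not text:
        return []
    return [s.strip() for s in text.split(";") if s.strip()]


def aggregate_tree(
    samples: pd.DataFrame,
    substrates=DEFAULT_SUBSTRATES,
    exclude_pilot: bool = True,
    tree_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Aggregate sample records to per-tree binomial observations.

    Filters are applied *before* counting: only the given substrates are
    kept (default: oak bark — soil samples at tree bases are excluded) and,
    when ``exclude_pilot``, samples incubated at 10 degrees C are dropped.
    Trials are the retained samples per tree; successes those containing
    *S. paradoxus*; ``other_yeast_freq`` the fraction of retained samples
    yielding any other yeast species.

    ``tree_meta``, if given, is merged on (site, tree_id) to supply
    girth/region/oak-type columns.
    """
    kept = samples
    if substrates is not None:
        kept = kept[kept["substrate"].isin(substrates)]
    if exclude_pilot and "incubation_c" in kept.columns:
        kept = kept[kept["incubation_c"] != PILOT_INCUBATION_C]
    if kept.empty:
        return pd.DataFrame(columns=["site", "tree", "n_samples",
                                     "n_sp_positive", "other_yeast_freq",
                                     "lat", "lon"])
    lists = kept["species_found"].apply(species_list)
    kept = kept.assign(
        _sp=lists.apply(lambda xs: TARGET_SPECIES in xs),
        _other=lists.apply(lambda xs: any(x != TARGET_SPECIES for x in xs)),
    )
    grouped = kept.groupby(["site", "tree_id"], sort=True)
    out = grouped.agg(
        n_samples=("_sp", "size"),
        n_sp_positive=("_sp", "sum"),
        n_other=("_other", "sum"),
        lat=("lat", "mean"),
        lon=("lon", "mean"),
    ).reset_index().rename(columns={"tree_id": "tree"})
    out["other_yeast_freq"] = out["n_other"] / out["n_samples"]
    out = out.drop(columns="n_other")
    if tree_meta is not None:
        meta = tree_meta.rename(columns={"tree_id": "tree"})
        out = out.merge(meta, on=[c for c in ("site", "tree") if c in meta],
                        how="left", suffixes=("", "_meta"))
    return out


def summarize_site(trees: pd.DataFrame) -> pd.DataFrame:
    """Per-site summary: weighted mean Tmax and girth, isolation frequency.

    Means are weighted by the number of bark samples per tree; the girth
    mean uses only trees with recorded girth.  ``sp_freq`` is the site's
    positive samples over its total samples, NaN when a site has none.
    """
    def _one(site_frame: pd.DataFrame) -> pd.Series:
        w = site_frame["n_samples"].to_numpy(dtype=float)
        n_samples = w.sum()
        res = {
            "n_trees": len(site_frame),
            "n_samples": int(n_samples),
            "n_sp": int(site_frame["n_sp_positive"].sum()),
        }
        res["sp_freq"] = res["n_sp"] / n_samples if n_samples > 0 else np.nan
        if "tmax_c" in site_frame:
            res["weighted_mean_tmax"] = (
                float(np.average(site_frame["tmax_c"], weights=w))
                if n_samples > 0 else np.nan
            )
        gm = site_frame["girth_m"].notna() if "girth_m" in site_frame else None
        if gm is not None and gm.any():
            res["weighted_mean_girth"] = float(
                np.average(site_frame.loc[gm, "girth_m"],
                           weights=site_frame.loc[gm, "n_samples"])
            )
        elif gm is not None:
            res["weighted_mean_girth"] = np.nan
        if "n_sc_positive" in site_frame:
            res["n_sc"] = int(site_frame["n_sc_positive"].sum())
        return pd.Series(res)

    out = trees.groupby("site", sort=True).apply(_one, include_groups=False)
    return out.reset_index()
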