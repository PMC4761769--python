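"""Weighted binomial GLM (logit link) and deviance-based model simplification.

The response is the per-tree proportion of bark samples yielding the target
yeast: ``successes`` out of ``trials`` per observation.  The model is fitted
by iteratively reweighted least squares (IRLS), the standard fixed point of
the binomial likelihood: at each step a weighted least-squares problem with
weights :math:`n_i p_i (1 - p_i)` and working response
:math:`\\eta_i + (y_i/n_i - p_i) / (p_i (1 - p_i))` is solved.

Nested models are compared by the drop in deviance, referred to a chi-square
distribution, and an initial model containing interactions is simplified
stepwise from the highest-order terms downward, respecting marginality: a
main effect is never deleted while an interaction containing it remains.

:class:`BinomialGLM` follows the scikit-learn estimator protocol (``fit`` /
``predict`` / ``get_params``), so it composes with sklearn tooling; the
module-level functions (:func:`lrt`, :func:`stepwise_simplify`, ...) are the
analysis-facing surface.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "ModelSpec",
    "BinomialGLM",
    "FitResult",
    "LrtResult",
    "GlmError",
    "RankDeficientError",
    "SeparationWarning",
    "lrt",
    "stepwise_simplify",
    "collapse_factor",
    "cooks_distance",
    "refit_without",
    "percent_deviance_explained",
]


class GlmError(ValueError):
    """Contract violation in model specification or comparison."""


class RankDeficientError(GlmError):
    """The design matrix is not of full column rank (aliased terms)."""


class SeparationWarning(UserWarning):
    """A coefficient is extreme on the logit scale, suggesting separation."""


Term = tuple[str, ...]


def _as_term(t) -> Term:
    if isinstance(t, str):
        return (t,)
    return tuple(t)


@dataclass(frozen=True)
class ModelSpec:
    """A binomial-GLM specification: response columns and model terms.

    ``terms`` is a list of tuples of variable names; ``("girth_m",)`` is a
    main effect, ``("girth_m", "region")`` a two-way interaction, and so on.
    Categorical variables are treatment-coded against their first (sorted)
    level.  The intercept is always included.
    """

    successes: str = "n_sp_positive"
    trials: str = "n_samples"
    terms: tuple[Term, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(_as_term(t) for t in self.terms))
        for t in self.terms:
            if len(set(t)) != len(t):
                raise GlmError(f"term {t} repeats a variable")
        if len(set(self.terms)) != len(self.terms):
            raise GlmError("duplicate terms in model specification")

    # -- construction helpers -------------------------------------------------
    @classmethod
    def full_factorial(cls, variables, successes="n_sp_positive", trials="n_samples"):
        """All main effects and interactions of ``variables`` (R's ``a*b*c``)."""
        variables = list(variables)
        terms = []
        for k in range(1, len(variables) + 1):
            terms.extend(itertools.combinations(variables, k))
        return cls(successes=successes, trials=trials, terms=tuple(terms))

    @classmethod
    def from_formula(cls, formula: str):
        """Parse ``"succ/trials ~ a*b + c + a:c"`` (``*`` = full factorial).

        Only ``+``, ``:`` and ``*`` are supported — enough to state every
        model used in this analysis in a config file.
        """
        lhs, _, rhs = formula.partition("~")
        if not rhs:
            raise GlmError(f"formula {formula!r} has no '~'")
        succ, _, tri = lhs.strip().partition("/")
        if not tri:
            raise GlmError("response must be written successes/trials")
        terms: list[Term] = []
        for chunk in rhs.split("+"):
            chunk = chunk.strip()
            if not chunk or chunk == "1":
                continue
            if "*" in chunk:
                vs = [v.strip() for v in chunk.split("*")]
                for k in range(1, len(vs) + 1):
                    for comb in itertools.combinations(vs, k):
                        if comb not in terms:
                            terms.append(comb)
            else:
                term = tuple(v.strip() for v in chunk.split(":"))
                if term not in terms:
                    terms.append(term)
        return cls(successes=succ.strip(), trials=tri.strip(), terms=tuple(terms))

    # -- queries --------------------------------------------------------------
    @property
    def variables(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.terms:
            for v in t:
                seen.setdefault(v)
        return tuple(seen)

    def contains(self, other: "ModelSpec") -> bool:
        return set(other.terms) <= set(self.terms)

    def removable_terms(self) -> tuple[Term, ...]:
        """Terms whose deletion respects marginality (not nested in another)."""
        out = []
        for t in self.terms:
            nested = any(set(t) < set(u) for u in self.terms if u != t)
            if not nested:
                out.append(t)
        return tuple(out)

    def drop(self, term) -> "ModelSpec":
        term = _as_term(term)
        if term not in self.terms:
            raise GlmError(f"term {term} not in specification")
        return ModelSpec(
            successes=self.successes,
            trials=self.trials,
            terms=tuple(t for t in self.terms if t != term),
        )

    def formula(self) -> str:
        rhs = " + ".join(":".join(t) for t in self.terms) or "1"
        return f"{self.successes}/{self.trials} ~ {rhs}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.formula()


# ---------------------------------------------------------------------------
# design matrix


def build_design(spec: ModelSpec, data: pd.DataFrame, levels=None):
    """Design matrix (with intercept), response, column names, row index,
    and the factor-level mapping used for encoding.

    Categorical (non-numeric) variables are treatment-coded against their
    first sorted level; interaction columns are products of the component
    columns.  Rows with missing values in any used variable are dropped;
    the returned index identifies the retained rows.  Passing the ``levels``
    mapping of a previous call re-applies that encoding (for prediction on
    new data, where some levels may be absent); unknown levels are rejected.
    """
    for col in (spec.successes, spec.trials, *spec.variables):
        if col not in data.columns:
            raise GlmError(f"column {col!r} missing from data")
    used = data[list(dict.fromkeys((spec.successes, spec.trials) + spec.variables))]
    used = used.dropna()
    y = used[spec.successes].to_numpy(dtype=float)
    n = used[spec.trials].to_numpy(dtype=float)
    if np.any(n < 1):
        raise GlmError("each observation needs at least one trial")
    if np.any((y < 0) | (y > n)):
        raise GlmError("successes must lie in [0, trials]")

    out_levels: dict[str, list[str]] = {}
    # per-variable column blocks
    blocks: dict[str, tuple[list[str], np.ndarray]] = {}
    for v in spec.variables:
        col = used[v]
        if pd.api.types.is_numeric_dtype(col):
            blocks[v] = ([v], col.to_numpy(dtype=float)[:, None])
        else:
            vals = col.astype(str)
            if levels is not None and v in levels:
                lvls = levels[v]
                unknown = sorted(set(vals.unique()) - set(lvls))
                if unknown:
                    raise GlmError(
                        f"variable {v!r} has level(s) {unknown} not present "
                        "when the model was fitted"
                    )
            else:
                lvls = sorted(vals.unique())
            out_levels[v] = list(lvls)
            rest = list(lvls)[1:]
            cols = np.column_stack(
                [(vals == lv).to_numpy(dtype=float) for lv in rest]
            ) if rest else np.empty((len(used), 0))
            blocks[v] = ([f"{v}[{lv}]" for lv in rest], cols)

    names = ["(Intercept)"]
    columns = [np.ones((len(used), 1))]
    for term in spec.terms:
        term_names = [""]
        term_cols = np.ones((len(used), 1))
        for v in term:
            vnames, vcols = blocks[v]
            term_names = [
                (a + ":" + b if a else b) for a in term_names for b in vnames
            ]
            term_cols = np.concatenate(
                [term_cols[:, [i]] * vcols for i in range(term_cols.shape[1])],
                axis=1,
            ) if vcols.shape[1] else np.empty((len(used), 0))
        names.extend(term_names[: term_cols.shape[1]])
        columns.append(term_cols)
    X = np.concatenate(columns, axis=1)
    return X, y, n, names, used.index, out_levels


# ---------------------------------------------------------------------------
# fitting


def binomial_deviance(y, n, p):
    """Deviance against the saturated model, with the 0*log(0) = 0 convention."""
    y = np.asarray(y, float)
    n = np.asarray(n, float)
    p = np.asarray(p, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / (n * p)), 0.0)
        t2 = np.where(n - y > 0, (n - y) * np.log((n - y) / (n - n * p)), 0.0)
    return float(2.0 * np.sum(t1 + t2))


@dataclass
class FitResult:
    """Outcome of a binomial GLM fit (coefficients on the logit scale)."""

    spec: ModelSpec
    beta: np.ndarray
    se: np.ndarray
    names: list[str]
    null_deviance: float
    deviance: float
    df_residual: int
    fitted_p: np.ndarray
    n_obs: int
    n_iter: int
    converged: bool
    row_index: pd.Index = field(repr=False, default=None)
    _cov: np.ndarray = field(repr=False, default=None)

    def coef(self) -> pd.Series:
        return pd.Series(self.beta, index=self.names, name="coef")

    def summary(self) -> pd.DataFrame:
        z = np.divide(self.beta, self.se, out=np.full_like(self.beta, np.nan),
                      where=self.se > 0)
        return pd.DataFrame(
            {"coef": self.beta, "se": self.se, "z": z,
             "p": 2.0 * stats.norm.sf(np.abs(z))},
            index=self.names,
        )


class BinomialGLM(BaseEstimator):
    """Binomial GLM with logit link fitted by IRLS.

    Parameters
    ----------
    spec : ModelSpec or str
        Model specification, or a formula string understood by
        :meth:`ModelSpec.from_formula`.
    max_iter : int
        IRLS iteration cap.
    tol : float
        Convergence threshold on the relative change in deviance.
    separation_threshold : float
        Emit :class:`SeparationWarning` when any fitted logit exceeds this
        in magnitude (small stratified surveys can separate).

    Attributes
    ----------
    coef_ : ndarray
        Coefficients, intercept first (order in ``feature_names_``).
    bse_ : ndarray
        Standard errors from the inverse Fisher information.
    deviance_, null_deviance_ : float
    df_residual_ : int
    fitted_p_ : ndarray
        Fitted per-observation success probabilities.
    n_iter_ : int
    converged_ : bool
    result_ : FitResult
        The same fit packaged for the testing/simplification functions.
    """

    def __init__(self, spec=None, max_iter=25, tol=1e-8, separation_threshold=15.0):
        self.spec = spec
        self.max_iter = max_iter
        self.tol = tol
        self.separation_threshold = separation_threshold

    def _resolved_spec(self) -> ModelSpec:
        if self.spec is None:
            return ModelSpec()
        if isinstance(self.spec, str):
            return ModelSpec.from_formula(self.spec)
        return self.spec

    def fit(self, X: pd.DataFrame, y=None) -> "BinomialGLM":
        """Fit to a tree-observation table (response columns named in spec)."""
        spec = self._resolved_spec()
        if not isinstance(X, pd.DataFrame):
            raise GlmError("X must be a pandas DataFrame of tree observations")
        design, yv, nv, names, idx, levels = build_design(spec, X)

        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            aliased = _aliased_columns(design, names)
            raise RankDeficientError(
                f"design is rank deficient (rank {rank} < {design.shape[1]}); "
                f"aliased column(s): {aliased}"
            )
        if design.shape[0] < design.shape[1]:
            raise GlmError("more parameters than observations")

        beta, dev, n_iter, converged, cov = _irls(
            design, yv, nv, max_iter=self.max_iter, tol=self.tol
        )
        eta = design @ beta
        # separation guard on the fitted logits: under (quasi-)separation the
        # IRLS iterates drive some eta towards +-infinity, while legitimately
        # large coefficients (e.g. a region offset against Tmax in degrees C)
        # keep every fitted logit moderate
        if np.abs(eta).max() > self.separation_threshold:
            warnings.warn(
                f"a fitted logit exceeds {self.separation_threshold} in "
                "magnitude; the data may be separated and the estimate "
                "unstable",
                SeparationWarning,
                stacklevel=2,
            )
        p = _expit(eta)
        pooled = np.clip(yv.sum() / nv.sum(), 1e-12, 1 - 1e-12)
        null_dev = binomial_deviance(yv, nv, np.full_like(p, pooled))

        self.feature_names_ = names
        self.levels_ = levels
        self.coef_ = beta
        self.bse_ = np.sqrt(np.diag(cov))
        self.deviance_ = dev
        self.null_deviance_ = null_dev
        self.df_residual_ = design.shape[0] - design.shape[1]
        self.fitted_p_ = p
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.result_ = FitResult(
            spec=spec,
            beta=beta,
            se=self.bse_,
            names=names,
            null_deviance=null_dev,
            deviance=dev,
            df_residual=self.df_residual_,
            fitted_p=p,
            n_obs=design.shape[0],
            n_iter=n_iter,
            converged=converged,
            row_index=idx,
            _cov=cov,
        )
        self._design_ = design
        self._y_ = yv
        self._n_ = nv
        self._frame_for_refit_ = X
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted success probability for new observations."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "coef_")
        spec = self._resolved_spec()
        frame = X.copy()
        # response columns are irrelevant for prediction; fill if absent
        for col, fill in ((spec.successes, 0), (spec.trials, 1)):
            if col not in frame.columns:
                frame[col] = fill
        design, _, _, names, _, _ = build_design(spec, frame,
                                                 levels=self.levels_)
        if names != self.feature_names_:  # pragma: no cover - defensive
            raise GlmError(
                "prediction design does not match the fitted design "
                f"({names} vs {self.feature_names_})"
            )
        return _expit(design @ self.coef_)


def fit(spec, data: pd.DataFrame, **kwargs) -> FitResult:
    """Functional wrapper: fit ``spec`` to ``data`` and return a FitResult."""
    if isinstance(spec, str):
        spec = ModelSpec.from_formula(spec)
    return BinomialGLM(spec=spec, **kwargs).fit(data).result_


def _expit(eta):
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))


def _aliased_columns(X, names):
    """Name columns that add no rank (greedy scan) for the error message."""
    aliased = []
    kept = np.empty((X.shape[0], 0))
    for j, name in enumerate(names):
        cand = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(cand) == kept.shape[1]:
            aliased.append(name)
        else:
            kept = cand
    return aliased or ["<undetermined>"]


def _irls(X, y, n, max_iter=25, tol=1e-8):
    nobs, nparam = X.shape
    pooled = np.clip(y.sum() / n.sum(), 1e-12, 1 - 1e-12)
    beta = np.zeros(nparam)
    beta[0] = math.log(pooled / (1.0 - pooled))
    dev = binomial_deviance(y, n, _expit(X @ beta))
    converged = False
    it = 0
    eps = 1e-10  # keep weights strictly positive at fitted 0/1
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = np.clip(_expit(eta), eps, 1.0 - eps)
        w = n * p * (1.0 - p)
        z = eta + (y / n - p) / (p * (1.0 - p))
        wx = X * w[:, None]
        xtwx = X.T @ wx
        xtwz = wx.T @ z
        try:
            beta_new = np.linalg.solve(xtwx, xtwz)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise RankDeficientError(f"weighted normal equations singular: {exc}")
        dev_new = binomial_deviance(y, n, _expit(X @ beta_new))
        # step-halving keeps the deviance monotone on hard data
        step = 1.0
        while dev_new > dev + 1e-8 and step > 1e-4:
            step /= 2.0
            beta_new = beta + step * (beta_new - beta)
            dev_new = binomial_deviance(y, n, _expit(X @ beta_new))
        beta, dev_prev, dev = beta_new, dev, dev_new
        if abs(dev_prev - dev) < tol * (abs(dev) + 0.1):
            converged = True
            break
    eta = X @ beta
    p = np.clip(_expit(eta), eps, 1.0 - eps)
    w = n * p * (1.0 - p)
    xtwx = X.T @ (X * w[:, None])
    cov = np.linalg.inv(xtwx)
    return beta, dev, it, converged, cov


# ---------------------------------------------------------------------------
# nested-model comparison


@dataclass(frozen=True)
class LrtResult:
    """Likelihood-ratio (deviance) comparison of two nested binomial GLMs."""

    term: str
    delta_deviance: float
    delta_df: int
    p_value: float
    percent_null_deviance: float


def lrt(fit_reduced: FitResult, fit_full: FitResult, term: str = "",
        check_nested: bool = True) -> LrtResult:
    """Chi-square test of a nested reduction, from the drop in deviance.

    ``check_nested=False`` skips the term-subset check for reductions that
    are nested by construction but not by term names (factor collapsing
    recodes a variable, so the reduced spec mentions a different column).
    """
    if check_nested and not fit_full.spec.contains(fit_reduced.spec):
        raise GlmError("reduced model is not nested in the full model")
    if fit_reduced.n_obs != fit_full.n_obs or not fit_reduced.row_index.equals(
        fit_full.row_index
    ):
        raise GlmError(
            "nested comparison requires both models fitted to the same rows "
            f"({fit_reduced.n_obs} vs {fit_full.n_obs} observations)"
        )
    dd = fit_reduced.deviance - fit_full.deviance
    ddf = fit_reduced.df_residual - fit_full.df_residual
    if ddf == 0:
        p = 1.0
    else:
        p = float(stats.chi2.sf(max(dd, 0.0), ddf))
    pct = 100.0 * dd / fit_full.null_deviance if fit_full.null_deviance > 0 else 0.0
    return LrtResult(
        term=term, delta_deviance=float(dd), delta_df=int(ddf), p_value=p,
        percent_null_deviance=float(pct),
    )


def stepwise_simplify(
    initial: ModelSpec,
    data: pd.DataFrame,
    alpha: float = 0.05,
    **fit_kwargs,
):
    """Backward deviance-based simplification from the highest-order terms.

    At each round every currently removable term (one whose deletion respects
    marginality) is tested by a chi-square likelihood-ratio test; among the
    deletions with p >= ``alpha`` the highest-order term is removed, breaking
    ties by largest p.  The search stops when every candidate deletion
    significantly worsens the model.

    All comparisons are made on the complete cases of the *initial*
    specification, so every nested test in the log shares the same rows (and
    the same null deviance).

    Returns
    -------
    final : ModelSpec
    log : pd.DataFrame
        One row per tested deletion: round, term, delta_deviance, delta_df,
        percent_null_deviance, p_value, deleted flag.
    """
    frame = data.dropna(
        subset=[c for c in (initial.successes, initial.trials) + initial.variables]
    )
    current = initial
    current_fit = fit(current, frame, **fit_kwargs)
    rows = []
    round_no = 0
    while current.terms:
        round_no += 1
        tests = []
        for term in current.removable_terms():
            reduced_fit = fit(current.drop(term), frame, **fit_kwargs)
            tests.append((term, lrt(reduced_fit, current_fit, ":".join(term)),
                          reduced_fit))
        # a term is retained only when its deletion is significant at level
        # alpha (p < alpha); at alpha >= 1 nothing can be significant, so
        # every deletion is accepted and the model collapses to the intercept
        candidates = [t for t in tests if not t[1].p_value < alpha or alpha >= 1.0]
        chosen = None
        if candidates:
            chosen = max(candidates, key=lambda t: (len(t[0]), t[1].p_value))
        for term, res, _ in tests:
            rows.append(
                {"round": round_no, "term": ":".join(term),
                 "delta_deviance": res.delta_deviance, "delta_df": res.delta_df,
                 "percent_null_deviance": res.percent_null_deviance,
                 "p_value": res.p_value,
                 "deleted": chosen is not None and term == chosen[0]}
            )
        if chosen is None:
            break
        current = current.drop(chosen[0])
        current_fit = chosen[2]
    log = pd.DataFrame(
        rows, columns=["round", "term", "delta_deviance", "delta_df",
                       "percent_null_deviance", "p_value", "deleted"]
    )
    return current, log


def collapse_factor(
    spec: ModelSpec,
    data: pd.DataFrame,
    factor: str,
    grouping: dict,
    collapsed_name: str | None = None,
    **fit_kwargs,
) -> tuple[LrtResult, ModelSpec, pd.DataFrame]:
    """Test whether collapsing factor levels (e.g. 3 oak types -> 2 regions)
    worsens the model.

    ``grouping`` maps every level of ``factor`` onto a (smaller) set of new
    levels; the collapsed model replaces ``factor`` by the recoded variable in
    every term.  Returns the LRT of collapsed-vs-full (the reported delta-df
    is the one actually induced by the collapse in the supplied spec), the
    collapsed specification, and the recoded data.
    """
    if factor not in spec.variables:
        raise GlmError(f"{factor!r} is not a variable of the specification")
    levels = set(pd.unique(data[factor].dropna().astype(str)))
    missing = levels - set(map(str, grouping))
    if missing:
        raise GlmError(f"grouping does not cover level(s) {sorted(missing)}")
    new_name = collapsed_name or f"{factor}_collapsed"
    frame = data.dropna(
        subset=[c for c in (spec.successes, spec.trials) + spec.variables]
    ).copy()
    frame[new_name] = frame[factor].astype(str).map({str(k): v for k, v in grouping.items()})
    new_terms = tuple(
        tuple(new_name if v == factor else v for v in t) for t in spec.terms
    )
    collapsed = ModelSpec(successes=spec.successes, trials=spec.trials,
                          terms=new_terms)
    full_fit = fit(spec, frame, **fit_kwargs)
    red_fit = fit(collapsed, frame, **fit_kwargs)
    res = lrt(red_fit, full_fit, term=f"{factor}->{new_name}",
              check_nested=False)
    return res, collapsed, frame


# ---------------------------------------------------------------------------
# influence


def cooks_distance(model: BinomialGLM) -> np.ndarray:
    """One-step Cook's distance per observation.

    Computed from the GLM hat matrix and standardized Pearson residuals:
    ``D_i = r_i^2 h_i / (k (1 - h_i))`` with ``k`` parameters — the usual
    one-step approximation to the coefficient shift from deleting row i.
    """
    X, y, n = model._design_, model._y_, model._n_
    p = np.clip(model.fitted_p_, 1e-10, 1 - 1e-10)
    w = n * p * (1.0 - p)
    wx = X * np.sqrt(w)[:, None]
    xtwx_inv = model.result_._cov
    h = np.einsum("ij,jk,ik->i", wx, xtwx_inv, wx)
    h = np.clip(h, 0.0, 1.0 - 1e-10)
    r_pearson = (y - n * p) / np.sqrt(w)
    r_std2 = r_pearson**2 / (1.0 - h)
    k = X.shape[1]
    return r_std2 * h / (k * (1.0 - h))


def refit_without(model: BinomialGLM, position: int) -> FitResult:
    """Exact leave-one-out refit, dropping the observation at ``position``
    (positional index into the rows the model was fitted on)."""
    spec = model._resolved_spec()
    idx = model.result_.row_index
    keep = idx.delete(position)
    # rebuild from the original frame rows the estimator retained
    frame = model._frame_for_refit_
    return fit(spec, frame.loc[keep])


def percent_deviance_explained(fit_result: FitResult) -> float:
    """(null - residual) / null deviance, as a percentage."""
    nd = fit_result.null_deviance
    if nd <= 0:
        return 0.0
    return 100.0 * (nd - fit_result.deviance) / nd
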