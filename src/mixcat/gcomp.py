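"""G-computation on categorized exposures.

Categorized exposures enter a generalized linear model either as ordinal
scores (one column per exposure, values ``0..k-1``) or as dummy indicators
(``k - 1`` columns per exposure, lowest category as reference).  The joint
mixture effect ``psi`` is the sum of all exposure-term coefficients —
the expected outcome change (or log-odds change) from moving every exposure
up one category simultaneously.  Per-term weights are the coefficients
normalized within their effect direction, so positive weights sum to one and
negative weights sum to minus one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr as _qr
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from . import categorize as cat
from .errors import (
    BootstrapError,
    CollinearityError,
    ConfigurationError,
    ConvergenceError,
    MixcatError,
)

__all__ = [
    "Term",
    "CodedDesign",
    "GcompFit",
    "BootstrapResult",
    "build_design",
    "direction_weights",
    "fit_gcomp",
    "bootstrap_ci",
    "odds_ratio",
    "categorize_and_fit",
]


@dataclass(frozen=True)
class Term:
    """One design-matrix column: an exposure term or a covariate."""

    name: str
    exposure: Optional[str]  # None for covariates
    level: object  # int level for dummy terms, "ordinal", or None
    is_covariate: bool = False


@dataclass(frozen=True, eq=False)
class CodedDesign:
    """An ``n x p`` coded design: exposure terms followed by covariates."""

    matrix: np.ndarray
    terms: tuple[Term, ...]
    coding: str  # "ordinal" | "dummy"

    @property
    def exposure_index(self) -> np.ndarray:
        return np.array([not t.is_covariate for t in self.terms], dtype=bool)


def build_design(
    labels: Union[pd.DataFrame, Mapping[str, np.ndarray]],
    coding: str = "ordinal",
    covariates: Optional[pd.DataFrame] = None,
) -> CodedDesign:
    """Code category labels into a regression design.

    Parameters
    ----------
    labels : DataFrame or mapping of column -> integer label array
        Category labels ``0..k_j - 1`` per exposure.
    coding : {"ordinal", "dummy"}
        Ordinal enters labels as integer scores; dummy expands each exposure
        into one indicator per non-reference level (level 0 is reference).
    covariates : DataFrame, optional
        Numeric columns enter as-is; non-numeric columns are dummy-coded
        with the first observed level as reference.
    """
    if coding not in ("ordinal", "dummy"):
        raise ConfigurationError(f"unknown coding {coding!r}")
    if not isinstance(labels, pd.DataFrame):
        labels = pd.DataFrame(dict(labels))
    cols: list[np.ndarray] = []
    terms: list[Term] = []
    for c in labels.columns:
        lab = np.asarray(labels[c], dtype=np.int64)
        if coding == "ordinal":
            cols.append(lab.astype(float))
            terms.append(Term(str(c), str(c), "ordinal"))
        else:
            for lvl in range(1, int(lab.max()) + 1):
                cols.append((lab == lvl).astype(float))
                terms.append(Term(f"{c}:{lvl}", str(c), lvl))
    if covariates is not None:
        for c in covariates.columns:
            col = covariates[c]
            if pd.api.types.is_numeric_dtype(col) and not isinstance(
                col.dtype, pd.CategoricalDtype
            ):
                cols.append(col.to_numpy(dtype=float))
                terms.append(Term(str(c), None, None, is_covariate=True))
            else:
                dummies = pd.get_dummies(col, prefix=str(c), drop_first=True)
                for dc in dummies.columns:
                    cols.append(dummies[dc].to_numpy(dtype=float))
                    terms.append(Term(str(dc), None, None, is_covariate=True))
    if not cols:
        raise ConfigurationError("design has no columns")
    matrix = np.column_stack(cols)
    return CodedDesign(matrix=matrix, terms=tuple(terms), coding=coding)


def direction_weights(coefficients: Sequence[float]) -> np.ndarray:
    """Signed weights: each coefficient divided by the absolute sum of the
    same-direction coefficients.  Positive weights sum to 1, negative
    weights sum to -1, zero coefficients get weight 0."""
    c = np.asarray(coefficients, dtype=float)
    w = np.zeros_like(c)
    pos = c > 0
    neg = c < 0
    if pos.any():
        w[pos] = c[pos] / c[pos].sum()
    if neg.any():
        w[neg] = c[neg] / (-c[neg].sum())
    return w


@dataclass(eq=False)
class GcompFit:
    """Fitted g-computation model.

    ``terms``/``coefficients``/``weights`` cover the exposure terms only;
    intercept and covariate coefficients live in ``covariate_coefficients``.
    """

    terms: tuple[Term, ...]
    coefficients: np.ndarray
    covariate_coefficients: dict[str, float]
    psi: float
    weights: np.ndarray
    family: str
    coding: str
    ci: Optional[dict[str, tuple[float, float]]] = None
    n_boot: int = 0
    seed: Optional[int] = None

    def weight_items(self) -> list[tuple[Term, float]]:
        return list(zip(self.terms, self.weights.tolist()))

    def quantities(self) -> dict[str, float]:
        """psi plus one signed weight per exposure term, keyed by name."""
        out = {"psi": float(self.psi)}
        for t, w in zip(self.terms, self.weights):
            out[t.name] = float(w)
        return out

    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "coding": self.coding,
            "psi": float(self.psi),
            "coefficients": {t.name: float(c) for t, c in zip(self.terms, self.coefficients)},
            "weights": {t.name: float(w) for t, w in zip(self.terms, self.weights)},
            "covariate_coefficients": dict(self.covariate_coefficients),
        }
        if self.family == "logistic":
            d["odds_ratio"] = odds_ratio(self.psi)
        if self.ci is not None:
            d["ci"] = {k: [float(v[0]), float(v[1])] for k, v in self.ci.items()}
            if self.family == "logistic" and "psi" in self.ci:
                lo, hi = self.ci["psi"]
                d["odds_ratio_ci"] = [odds_ratio(lo), odds_ratio(hi)]
        d["n_boot"] = self.n_boot
        d["seed"] = self.seed
        return d


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    _, r, piv = _qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(r))
    if d.size == 0 or d[0] == 0.0:
        raise CollinearityError("design matrix is all zeros", list(names))
    tol = d[0] * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(d > tol))
    if rank < X.shape[1]:
        bad = [names[i] for i in piv[rank:]]
        raise CollinearityError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"offending columns: {bad}",
            bad,
        )


def fit_gcomp(
    design: CodedDesign, outcome: Sequence[float], family: str = "linear"
) -> GcompFit:
    """Fit the g-computation GLM and derive ``psi`` and the signed weights.

    ``family`` is ``"linear"`` (Gaussian, identity link) or ``"logistic"``
    (binary outcome).  Covariates contribute to the fit but are excluded
    from ``psi`` and the weights.
    """
    if family not in ("linear", "logistic"):
        raise ConfigurationError(f"unknown family {family!r}")
    y = np.asarray(outcome, dtype=float)
    n, p = design.matrix.shape
    if y.size != n:
        raise ConfigurationError("outcome length does not match design")
    if n <= p + 1:
        raise ConfigurationError(f"need n > p (n={n}, p={p + 1} incl. intercept)")
    X = np.column_stack([np.ones(n), design.matrix])
    names = ["(intercept)"] + [t.name for t in design.terms]
    _check_full_rank(X, names)
    if family == "logistic":
        uniq = np.unique(y)
        if not np.all(np.isin(uniq, (0.0, 1.0))):
            raise ConfigurationError("logistic family requires a 0/1 outcome")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        except (
            PerfectSeparationError,
            PerfectSeparationWarning,
            np.linalg.LinAlgError,
        ) as exc:
            raise ConvergenceError(f"logistic fit failed: {exc}") from exc
        if not res.mle_retvals.get("converged", False):
            raise ConvergenceError(
                "logistic fit did not converge", diagnostics=res.mle_retvals
            )
        params = np.asarray(res.params, dtype=float)
    else:
        params, *_ = np.linalg.lstsq(X, y, rcond=None)
    coef_all = params[1:]
    is_exp = design.exposure_index
    exp_terms = tuple(t for t in design.terms if not t.is_covariate)
    exp_coefs = coef_all[is_exp]
    cov_coefs = {"(intercept)": float(params[0])}
    for t, c in zip(design.terms, coef_all):
        if t.is_covariate:
            cov_coefs[t.name] = float(c)
    return GcompFit(
        terms=exp_terms,
        coefficients=exp_coefs,
        covariate_coefficients=cov_coefs,
        psi=float(exp_coefs.sum()),
        weights=direction_weights(exp_coefs),
        family=family,
        coding=design.coding,
    )


def odds_ratio(psi: float) -> float:
    """exp(psi): the odds ratio of the joint effect under a logistic model."""
    return float(np.exp(psi))


@dataclass(eq=False)
class BootstrapResult:
    """Percentile bootstrap intervals keyed by quantity name."""

    ci: dict[str, tuple[float, float]]
    n_boot: int
    n_failed: int
    seed: int


PipelineResult = Union[GcompFit, Mapping[str, float]]


def bootstrap_ci(
    table: pd.DataFrame,
    pipeline: Callable[[pd.DataFrame], PipelineResult],
    n_boot: int,
    seed: int,
    alpha: float = 0.05,
    max_failure_fraction: float = 0.10,
) -> BootstrapResult:
    """Percentile bootstrap over individuals (rows).

    Each resample re-runs the full ``pipeline`` (so categorization
    thresholds are re-estimated per resample unless the pipeline freezes
    them).  Resamples where the pipeline raises a :class:`MixcatError` are
    recorded and skipped; more than ``max_failure_fraction`` failures is an
    error.  Reproducible under a fixed seed.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    n = len(table)
    draws: list[dict[str, float]] = []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = table.iloc[idx].reset_index(drop=True)
        try:
            out = pipeline(sample)
        except MixcatError:
            n_failed += 1
            continue
        draws.append(out.quantities() if isinstance(out, GcompFit) else dict(out))
    if n_failed > max_failure_fraction * n_boot:
        raise BootstrapError(
            f"{n_failed}/{n_boot} bootstrap resamples failed "
            f"(> {max_failure_fraction:.0%} allowed)"
        )
    keys: list[str] = []
    for d in draws:
        for k in d:
            if k not in keys:
                keys.append(k)
    ci: dict[str, tuple[float, float]] = {}
    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
    for k in keys:
        vals = np.array([d[k] for d in draws if k in d], dtype=float)
        ci[k] = (float(np.percentile(vals, lo_q)), float(np.percentile(vals, hi_q)))
    return BootstrapResult(ci=ci, n_boot=n_boot, n_failed=n_failed, seed=seed)


def categorize_and_fit(
    table: pd.DataFrame,
    outcome: str,
    exposures: Sequence[str],
    covariates: Sequence[str] = (),
    coding: str = "ordinal",
    family: str = "linear",
    method: str = "adaptive",
    search: Optional[cat.SearchConfig] = None,
    q: int = 4,
    thresholds: Optional[Mapping[str, Sequence[float]]] = None,
) -> tuple[GcompFit, dict[str, cat.Categorization]]:
    """Categorize every exposure column, code, and fit in one call.

    ``method`` selects :func:`mixcat.categorize.adaptive_categorize`
    (``"adaptive"``) or :func:`mixcat.categorize.quantile_categorize`
    (``"quantile"``, with ``q`` groups).  Pre-computed ``thresholds``
    override the search (used to freeze a categorization across bootstrap
    resamples or score new data).
    """
    if method not in ("adaptive", "quantile"):
        raise ConfigurationError(f"unknown method {method!r}")
    labels: dict[str, np.ndarray] = {}
    cats: dict[str, cat.Categorization] = {}
    for c in exposures:
        vals = np.asarray(table[c], dtype=float)
        if thresholds is not None:
            labels[c] = cat.apply_thresholds(vals, thresholds[c])
            continue
        fit_c = (
            cat.adaptive_categorize(vals, search)
            if method == "adaptive"
            else cat.quantile_categorize(vals, q)
        )
        cats[c] = fit_c
        labels[c] = fit_c.labels
    cov_df = table[list(covariates)] if covariates else None
    design = build_design(pd.DataFrame(labels), coding=coding, covariates=cov_df)
    fit = fit_gcomp(design, np.asarray(table[outcome], dtype=float), family=family)
    return fit, cats
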