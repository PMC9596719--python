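"""Latent-state mixture data generator and the two simulation studies.

Each exposure ``X_j`` arises from a hidden 4-level state ``Z_j`` drawn from a
multinomial with probabilities ``alpha``; given the state, ``X_j`` is normal
with the state's component mean and a common sd.  Outcomes are linear in the
latent states (or in their dummy expansion), plus standard normal noise:

* ``two-exposure-bias``:   Y = b1*Z_1 + b2*Z_2 + eps
* ``monotonic-ordinal``:   Y = sum_{i<=10} b_i*Z_i + eps
* ``dummy-nonmonotonic``:  Y = sum_{j<=5} beta[Z_j] + eps with beta = (0, 1, -1, 0)

The bias study measures ``psi_estimate - psi_true`` of ordinal-coded linear
g-computation; the selection study ranks signed weights and counts how many
truly causal terms land in the direction-specific top/bottom rank sets.

In both studies the adaptive-categorization arm fixes ``k = 4`` by default
(``DEFAULT_SIM_SEARCH``).  On this generative model the exact F-test p-value
keeps decreasing all the way to ``k_max``, so a literally adaptive ``k``
over-splits the four latent states: the joint effect attenuates badly and
the per-level dummy terms stop matching the causal levels.  Fixing ``k`` at
the number of latent components restores both; pass ``search=None``
explicitly via ``SearchConfig()`` to study the adaptive behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Optional, Sequence

import numpy as np
import pandas as pd

from . import categorize as cat
from .errors import ConfigurationError, MixcatError
from .gcomp import GcompFit, categorize_and_fit

__all__ = [
    "SimScenario",
    "MetricsReport",
    "SelectionTruth",
    "bias_scenario",
    "monotonic_scenario",
    "nonmonotonic_scenario",
    "generate_dataset",
    "run_bias_study",
    "run_tpr_study",
    "compute_tpr",
    "compute_fpr",
    "monotonic_truth",
    "nonmonotonic_truth",
]

COMPONENT_MEANS = (1.0, 2.0, 3.0, 4.0)
COMPONENT_SD = 0.33
EQUAL_ALPHA = (0.25, 0.25, 0.25, 0.25)
SKEWED_ALPHA = (0.4, 0.3, 0.2, 0.1)

EFFECT_MODELS = ("two-exposure-bias", "monotonic-ordinal", "dummy-nonmonotonic")

#: categorization used by the adaptive-search arm inside the studies:
#: the linear search with the category count pinned at the number of
#: latent mixture components
DEFAULT_SIM_SEARCH = cat.SearchConfig(k_fixed=4)


@dataclass(frozen=True)
class SimScenario:
    """A complete generative configuration for one simulation arm."""

    n: int
    m: int
    alpha: tuple[float, float, float, float]
    effect_model: str
    betas: tuple[float, ...]
    psi_true: float
    seed: int = 0
    component_means: tuple[float, ...] = COMPONENT_MEANS
    component_sd: float = COMPONENT_SD
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        # zeros allowed (degenerate single-component configs are useful in
        # tests); negatives and bad sums are not
        if a.size != 4 or np.any(a < 0) or abs(a.sum() - 1) > 1e-12:
            raise ConfigurationError("alpha must be 4 probabilities summing to 1")
        if self.component_sd <= 0:
            raise ConfigurationError("component_sd must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if len(self.component_means) != 4:
            raise ConfigurationError("need 4 component means")
        if self.effect_model not in EFFECT_MODELS:
            raise ConfigurationError(f"unknown effect model {self.effect_model!r}")
        need = {"two-exposure-bias": 2, "monotonic-ordinal": 10, "dummy-nonmonotonic": 4}
        if len(self.betas) != need[self.effect_model]:
            raise ConfigurationError(
                f"{self.effect_model} needs {need[self.effect_model]} betas, "
                f"got {len(self.betas)}"
            )
        causal = {"two-exposure-bias": 2, "monotonic-ordinal": 10, "dummy-nonmonotonic": 5}
        if self.m < causal[self.effect_model]:
            raise ConfigurationError(
                f"m={self.m} too small for {self.effect_model} "
                f"({causal[self.effect_model]} causal exposures)"
            )
        if self.n < 2:
            raise ConfigurationError("n must be >= 2")


def bias_scenario(scenario: int, n: int = 200, m: int = 5, seed: int = 0) -> SimScenario:
    """The four bias-study scenarios.

    1: equal state proportions, betas (0.5, 0.5);
    2: equal proportions, betas (1.5, -0.5);
    3: proportions (0.4, 0.3, 0.2, 0.1), betas (0.5, 0.5);
    4: proportions (0.4, 0.3, 0.2, 0.1), betas (1.5, -0.5).
    psi_true = 1 in all four.
    """
    if scenario not in (1, 2, 3, 4):
        raise ConfigurationError("scenario must be 1..4")
    alpha = EQUAL_ALPHA if scenario in (1, 2) else SKEWED_ALPHA
    betas = (0.5, 0.5) if scenario in (1, 3) else (1.5, -0.5)
    return SimScenario(
        n=n,
        m=m,
        alpha=alpha,
        effect_model="two-exposure-bias",
        betas=betas,
        psi_true=float(sum(betas)),
        seed=seed,
    )


def monotonic_scenario(n: int, m: int, seed: int = 0) -> SimScenario:
    """Monotonic selection study: betas 0.1 x7 then -0.1 x3; psi_true = 0.4."""
    betas = (0.1,) * 7 + (-0.1,) * 3
    return SimScenario(
        n=n,
        m=m,
        alpha=SKEWED_ALPHA,
        effect_model="monotonic-ordinal",
        betas=betas,
        psi_true=float(sum(betas)),
        seed=seed,
    )


def nonmonotonic_scenario(n: int, m: int, seed: int = 0) -> SimScenario:
    """Non-monotonic selection study: per-level effects (0, 1, -1, 0) on the
    first five exposures."""
    return SimScenario(
        n=n,
        m=m,
        alpha=SKEWED_ALPHA,
        effect_model="dummy-nonmonotonic",
        betas=(0.0, 1.0, -1.0, 0.0),
        psi_true=0.0,
        seed=seed,
    )


def generate_dataset(
    scenario: SimScenario, rng: Optional[np.random.Generator] = None
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Draw one dataset: ``(exposures, latent states, outcome)``.

    Exposure columns are named ``X1..Xm``; the latent frame shares the names.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    n, m = scenario.n, scenario.m
    z = rng.choice(4, size=(n, m), p=np.asarray(scenario.alpha, dtype=float))
    means = np.asarray(scenario.component_means, dtype=float)
    x = means[z] + scenario.component_sd * rng.standard_normal((n, m))
    eps = scenario.noise_sd * rng.standard_normal(n)
    b = np.asarray(scenario.betas, dtype=float)
    if scenario.effect_model == "two-exposure-bias":
        y = b[0] * z[:, 0] + b[1] * z[:, 1] + eps
    elif scenario.effect_model == "monotonic-ordinal":
        y = z[:, :10] @ b + eps
    else:  # dummy-nonmonotonic: level lookup equals the dummy inner product
        y = b[z[:, :5]].sum(axis=1) + eps
    names = [f"X{j + 1}" for j in range(m)]
    return (
        pd.DataFrame(x, columns=names),
        pd.DataFrame(z, columns=names),
        y,
    )


@dataclass(frozen=True)
class MetricsReport:
    """Replicate-averaged study metrics for one method arm."""

    method: str
    reps: int
    n_failed: int
    n: int
    m: int
    seed: int
    bias_mean: Optional[float] = None
    tpr_mean: Optional[float] = None
    fpr_mean: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "reps": self.reps,
            "n_failed": self.n_failed,
            "n": self.n,
            "m": self.m,
            "seed": self.seed,
            "bias": self.bias_mean,
            "tpr": self.tpr_mean,
            "fpr": self.fpr_mean,
        }


def _fit_replicate(
    X: pd.DataFrame,
    y: np.ndarray,
    method: str,
    coding: str,
    search: Optional[cat.SearchConfig],
    q: int,
) -> GcompFit:
    table = X.copy()
    table["__y__"] = y
    fit, _ = categorize_and_fit(
        table,
        outcome="__y__",
        exposures=list(X.columns),
        coding=coding,
        family="linear",
        method=method,
        search=search,
        q=q,
    )
    return fit


def run_bias_study(
    scenario: SimScenario,
    method: str = "adaptive",
    reps: int = 1000,
    search: Optional[cat.SearchConfig] = None,
    q: int = 4,
) -> MetricsReport:
    """Mean bias ``psi_estimate - psi_true`` of ordinal-coded linear
    g-computation over ``reps`` fresh datasets.

    ``search=None`` uses :data:`DEFAULT_SIM_SEARCH` (k fixed at 4) for the
    ``"adaptive"`` method arm.
    """
    if scenario.effect_model != "two-exposure-bias":
        raise ConfigurationError("bias study needs a two-exposure-bias scenario")
    if search is None:
        search = DEFAULT_SIM_SEARCH
    rng = np.random.default_rng(scenario.seed)
    biases: list[float] = []
    n_failed = 0
    for _ in range(reps):
        X, _z, y = generate_dataset(scenario, rng)
        try:
            fit = _fit_replicate(X, y, method, "ordinal", search, q)
        except MixcatError:
            n_failed += 1
            continue
        biases.append(fit.psi - scenario.psi_true)
    return MetricsReport(
        method=method,
        reps=reps,
        n_failed=n_failed,
        n=scenario.n,
        m=scenario.m,
        seed=scenario.seed,
        bias_mean=float(np.mean(biases)) if biases else float("nan"),
    )


@dataclass(frozen=True)
class SelectionTruth:
    """Keys of truly causal terms: ``positive`` are expected among the
    largest weights, ``negative`` among the smallest."""

    positive: tuple[Hashable, ...]
    negative: tuple[Hashable, ...]


def monotonic_truth() -> SelectionTruth:
    """X1..X7 carry positive effects, X8..X10 negative."""
    return SelectionTruth(
        positive=tuple(f"X{j}" for j in range(1, 8)),
        negative=tuple(f"X{j}" for j in range(8, 11)),
    )


def nonmonotonic_truth() -> SelectionTruth:
    """Level-1 terms of X1..X5 are positive, level-2 terms negative."""
    return SelectionTruth(
        positive=tuple((f"X{j}", 1) for j in range(1, 6)),
        negative=tuple((f"X{j}", 2) for j in range(1, 6)),
    )


def _rank_sets(
    weights: Sequence[tuple[Hashable, float]], truth: SelectionTruth
) -> tuple[list[Hashable], list[Hashable]]:
    keys = [k for k, _ in weights]
    w = np.array([v for _, v in weights], dtype=float)
    n_top, n_bottom = len(truth.positive), len(truth.negative)
    if len(keys) < n_top + n_bottom:
        raise ConfigurationError(
            f"need at least {n_top + n_bottom} weighted terms, got {len(keys)}"
        )
    order = np.argsort(-w, kind="stable")  # descending, ties by original order
    top = [keys[i] for i in order[:n_top]]
    bottom = [keys[i] for i in order[len(keys) - n_bottom:]]
    return top, bottom


def compute_tpr(
    weights: Sequence[tuple[Hashable, float]], truth: SelectionTruth
) -> float:
    """Fraction of causal terms recovered in the direction-specific rank
    sets: positives among the top ``|positive|`` weights, negatives among
    the bottom ``|negative|``."""
    top, bottom = _rank_sets(weights, truth)
    tp = len(set(top) & set(truth.positive)) + len(set(bottom) & set(truth.negative))
    return tp / (len(truth.positive) + len(truth.negative))


def compute_fpr(
    weights: Sequence[tuple[Hashable, float]], truth: SelectionTruth
) -> float:
    """Fraction of non-causal terms that intrude into the counted rank
    sets; 0 when every present term is causal."""
    top, bottom = _rank_sets(weights, truth)
    causal = set(truth.positive) | set(truth.negative)
    fp = sum(1 for k in top + bottom if k not in causal)
    n_noncausal = sum(1 for k, _ in weights if k not in causal)
    if n_noncausal == 0:
        return 0.0
    return fp / n_noncausal


def _weight_items(fit: GcompFit, mode: str) -> list[tuple[Hashable, float]]:
    if mode == "monotonic-ordinal":
        return [(t.exposure, float(w)) for t, w in fit.weight_items()]
    return [((t.exposure, t.level), float(w)) for t, w in fit.weight_items()]


def run_tpr_study(
    scenario: SimScenario,
    method: str = "adaptive",
    reps: int = 1000,
    search: Optional[cat.SearchConfig] = None,
    q: int = 4,
) -> MetricsReport:
    """Mean TPR/FPR of weight-ranked variable selection over ``reps``
    replicates.  The monotonic study uses ordinal coding (one signed weight
    per exposure); the non-monotonic study uses dummy coding (one signed
    weight per exposure level).  ``search=None`` uses
    :data:`DEFAULT_SIM_SEARCH` (k fixed at 4) for the ``"adaptive"`` arm."""
    if search is None:
        search = DEFAULT_SIM_SEARCH
    if scenario.effect_model == "monotonic-ordinal":
        coding, truth = "ordinal", monotonic_truth()
    elif scenario.effect_model == "dummy-nonmonotonic":
        coding, truth = "dummy", nonmonotonic_truth()
    else:
        raise ConfigurationError("TPR study needs a selection scenario")
    rng = np.random.default_rng(scenario.seed)
    tprs: list[float] = []
    fprs: list[float] = []
    n_failed = 0
    for _ in range(reps):
        X, _z, y = generate_dataset(scenario, rng)
        try:
            fit = _fit_replicate(X, y, method, coding, search, q)
            items = _weight_items(fit, scenario.effect_model)
            tprs.append(compute_tpr(items, truth))
            fprs.append(compute_fpr(items, truth))
        except MixcatError:
            n_failed += 1
            continue
    return MetricsReport(
        method=method,
        reps=reps,
        n_failed=n_failed,
        n=scenario.n,
        m=scenario.m,
        seed=scenario.seed,
        tpr_mean=float(np.mean(tprs)) if tprs else float("nan"),
        fpr_mean=float(np.mean(fprs)) if fprs else float("nan"),
    )
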