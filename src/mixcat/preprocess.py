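"""Preparation of concentration tables and a synthetic application fixture.

The application workflow on a table of trace-element concentrations is:
impute below-detection values as LOD/2, natural-log transform, categorize
each element into a fixed number of levels with a minimum-category-size
floor, dummy-code against the lowest level, fit a covariate-adjusted
logistic g-computation model, and bootstrap the whole pipeline for 95%
confidence intervals.  Category thresholds are searched on the log scale but
reported back on the original concentration scale.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import categorize as cat
from .errors import ConfigurationError
from .gcomp import bootstrap_ci, categorize_and_fit, odds_ratio

__all__ = [
    "ELEMENTS",
    "impute_lod",
    "log_transform",
    "default_lods",
    "make_application_fixture",
    "run_application",
]

#: the 12 trace elements of the application fixture
ELEMENTS = (
    "arsenic",
    "selenium",
    "zinc",
    "aluminum",
    "vanadium",
    "chromium",
    "manganese",
    "iron",
    "nickel",
    "copper",
    "cadmium",
    "lead",
)

COVARIATES = ("age", "gender", "smoking", "education", "occupation")

# log-scale location/spread of each element's background distribution;
# values are arbitrary but give right-skewed, positive concentrations
_ELEMENT_LOGNORM = {
    "arsenic": (-2.4, 0.7),
    "selenium": (-0.1, 0.25),
    "aluminum": (3.2, 0.8),
    "vanadium": (-3.0, 0.6),
    "chromium": (-0.4, 0.7),
    "manganese": (0.1, 0.8),
    "iron": (3.6, 0.7),
    "nickel": (-0.7, 0.8),
    "copper": (1.4, 0.4),
    "cadmium": (-3.5, 0.9),
    "lead": (-0.3, 0.9),
}

# zinc: three-component mixture on the log scale so a 3-level categorization
# has well-defined low/medium/high groups, each holding >= 10% of samples
_ZINC_WEIGHTS = (0.45, 0.30, 0.25)
_ZINC_LOG_MEANS = (4.55, 4.87, 5.15)
_ZINC_LOG_SDS = (0.15, 0.05, 0.10)


def impute_lod(column: Sequence[float], lod: float) -> np.ndarray:
    """Replace values below the limit of detection by ``lod / 2``.

    Idempotent: ``lod / 2`` is itself below ``lod`` and maps to ``lod / 2``.
    """
    if lod <= 0:
        raise ConfigurationError("LOD must be positive")
    x = np.asarray(column, dtype=float)
    return np.where(x < lod, lod / 2.0, x)


def log_transform(column: Sequence[float]) -> np.ndarray:
    """Natural log, elementwise; nonpositive entries are a domain error."""
    x = np.asarray(column, dtype=float)
    bad = np.flatnonzero(~(x > 0))
    if bad.size:
        raise ValueError(
            f"log transform needs positive values; row {int(bad[0])} "
            f"has {x[bad[0]]!r}"
        )
    return np.log(x)


def default_lods() -> dict[str, float]:
    """Small per-element detection limits for the synthetic fixture
    (real instrument LODs are not modelled)."""
    return {e: float(np.exp(mu - 2.5 * sd)) for e, (mu, sd) in _ELEMENT_LOGNORM.items()}


def make_application_fixture(
    n_cases: int = 265,
    n_controls: int = 353,
    seed: int = 0,
    medium_effect: float = 0.8,
    high_effect: float = -0.3,
) -> pd.DataFrame:
    """Synthetic case-control table emulating a trace-element study.

    Twelve right-skewed (log-normal) element concentrations; zinc follows a
    three-component log-normal mixture with a planted inverted-U outcome
    effect (``medium_effect`` log-odds for the middle component,
    ``high_effect`` for the top one, both vs. the lowest).  Covariates: age,
    gender, smoking (3 levels), education (3 levels), occupation (2 levels).
    Outcomes are drawn from a logistic model on a large pool, then exactly
    ``n_cases`` cases and ``n_controls`` controls are sampled.
    """
    if n_cases < 50 or n_controls < 50:
        raise ValueError("need at least 50 cases and 50 controls")
    rng = np.random.default_rng(seed)
    pool = 10 * (n_cases + n_controls)
    age = rng.normal(65.0, 10.0, pool)
    gender = rng.choice(["male", "female"], size=pool, p=[0.7, 0.3])
    smoking = rng.choice(
        ["never", "former", "current"], size=pool, p=[0.30, 0.48, 0.22]
    )
    education = rng.choice(
        ["high_school", "college", "postgraduate"], size=pool, p=[0.42, 0.41, 0.17]
    )
    occupation = rng.choice(["low_risk", "high_risk"], size=pool, p=[0.60, 0.40])
    frame = pd.DataFrame(
        {
            "age": age,
            "gender": gender,
            "smoking": smoking,
            "education": education,
            "occupation": occupation,
        }
    )
    for e, (mu, sd) in _ELEMENT_LOGNORM.items():
        frame[e] = np.exp(rng.normal(mu, sd, pool))
    zstate = rng.choice(3, size=pool, p=_ZINC_WEIGHTS)
    zmu = np.asarray(_ZINC_LOG_MEANS)[zstate]
    zsd = np.asarray(_ZINC_LOG_SDS)[zstate]
    frame["zinc"] = np.exp(rng.normal(zmu, zsd))
    frame = frame[["age", "gender", "smoking", "education", "occupation", *ELEMENTS]]

    lp = (
        -1.2
        + medium_effect * (zstate == 1)
        + high_effect * (zstate == 2)
        + 0.20 * (smoking == "former")
        + 0.55 * (smoking == "current")
        + 0.35 * (occupation == "high_risk")
        - 0.15 * (education == "postgraduate")
        + 0.10 * (gender == "male")
        + 0.010 * (age - 65.0)
    )
    case = (rng.random(pool) < 1.0 / (1.0 + np.exp(-lp))).astype(int)
    case_idx = np.flatnonzero(case == 1)
    ctrl_idx = np.flatnonzero(case == 0)
    if case_idx.size < n_cases or ctrl_idx.size < n_controls:  # pragma: no cover
        raise RuntimeError("fixture pool too small; increase the pool factor")
    keep = np.concatenate(
        [
            rng.choice(case_idx, size=n_cases, replace=False),
            rng.choice(ctrl_idx, size=n_controls, replace=False),
        ]
    )
    out = frame.iloc[keep].reset_index(drop=True)
    out.insert(0, "case", case[keep])
    return out


def run_application(
    table: pd.DataFrame,
    elements: Sequence[str] = ELEMENTS,
    outcome: str = "case",
    covariates: Sequence[str] = COVARIATES,
    lods: Optional[Mapping[str, float]] = None,
    k: int = 3,
    min_category_fraction: float = 0.10,
    n_boot: int = 1000,
    seed: int = 0,
    freeze_thresholds: bool = False,
) -> dict:
    """End-to-end application workflow; returns a JSON-serializable report.

    Bootstrap resamples individuals and, by default, re-estimates the
    category thresholds inside each resample; ``freeze_thresholds`` reuses
    the point-estimate thresholds instead.
    """
    work = table.copy()
    for e in elements:
        if lods and e in lods:
            work[e] = impute_lod(work[e], lods[e])
        work[e] = log_transform(work[e])
    search = cat.SearchConfig(
        k_max=max(10, k), k_fixed=k, min_category_fraction=min_category_fraction
    )
    fit, cats = categorize_and_fit(
        work,
        outcome=outcome,
        exposures=list(elements),
        covariates=list(covariates),
        coding="dummy",
        family="logistic",
        search=search,
    )
    frozen = (
        {e: list(cats[e].thresholds) for e in elements} if freeze_thresholds else None
    )

    def pipeline(sample: pd.DataFrame):
        f, _ = categorize_and_fit(
            sample,
            outcome=outcome,
            exposures=list(elements),
            covariates=list(covariates),
            coding="dummy",
            family="logistic",
            search=search,
            thresholds=frozen,
        )
        return f

    boot = bootstrap_ci(work, pipeline, n_boot=n_boot, seed=seed)
    fit.ci = boot.ci
    fit.n_boot = n_boot
    fit.seed = seed
    report = fit.to_dict()
    report["bootstrap_failures"] = boot.n_failed
    report["thresholds"] = {
        e: {
            "log_scale": [float(t) for t in cats[e].thresholds],
            "original_scale": [float(math.exp(t)) for t in cats[e].thresholds],
            "counts": [int(c) for c in cats[e].counts],
            "k": cats[e].k,
        }
        for e in elements
    }
    return report
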