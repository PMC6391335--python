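"""Gestational-age prediction and statistical assessment.

Includes the fixed-coefficient linear predictor (shipped as a versioned
coefficients file), a random-intercept Gaussian mixed model fit by profile
maximum likelihood for repeated-measures cohorts, variance-inflation
screening, Hittner grade lookups, and Bland--Altman agreement statistics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "GAModel",
    "MixedFit",
    "AgreementStats",
    "load_model",
    "predict_ga",
    "fit_mixed_model",
    "variance_inflation",
    "bland_altman",
    "hittner_grade_range",
    "classify_hittner_grade",
    "bland_altman_plot",
    "identity_plot",
]

VALID_FEATURE_NAMES = frozenset(
    {
        "n_branches",
        "branch_length_max",
        "branch_length_min",
        "branch_width_max",
        "branch_width_min",
        "tortuosity_max",
        "tortuosity_min",
        "density",
        "branch_thickness_max",
        "branch_thickness_min",
    }
)

# grade -> published gestational-age range (weeks)
_HITTNER_RANGES = {"I": (33, 34), "II": (31, 32), "III": (29, 30), "IV": (27, 28)}
# contiguous half-open inverse bins covering [27, 35)
_HITTNER_BINS = [("IV", 27.0, 29.0), ("III", 29.0, 31.0), ("II", 31.0, 33.0), ("I", 33.0, 35.0)]


@dataclass(frozen=True)
class GAModel:
    intercept: float
    coefficients: dict[str, float]
    mapping: dict[str, str]
    feature_units: str = "pixels"
    version: str = "unversioned"

    def __post_init__(self):
        vals = [self.intercept, *self.coefficients.values()]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("model intercept and coefficients must be finite")
        missing = set(self.coefficients) - set(self.mapping)
        if missing:
            raise ValueError(f"mapping lacks entries for coefficient terms: {sorted(missing)}")
        bad = set(self.mapping.values()) - VALID_FEATURE_NAMES
        if bad:
            raise ValueError(f"mapping targets unknown feature names: {sorted(bad)}")


def load_model(path: str | Path | None = None) -> GAModel:
    """Load a coefficients file; defaults to the shipped published model."""
    if path is None:
        payload = json.loads(
            resources.files("alcv").joinpath("data/ga_coefficients.json").read_text()
        )
    else:
        payload = json.loads(Path(path).read_text())
    return GAModel(
        intercept=float(payload["intercept"]),
        coefficients={k: float(v) for k, v in payload["coefficients"].items()},
        mapping=dict(payload["mapping"]),
        feature_units=payload.get("feature_units", "pixels"),
        version=payload.get("version", "unversioned"),
    )


def predict_ga(model: GAModel, features) -> float:
    """Population-level prediction: intercept + sum(coef_j * feature_j).

    ``features`` may be an :class:`~alcv.vessel_morphometry.ALCVFeatures`
    or a mapping; a missing or non-finite feature raises, naming it.  No
    clamping is applied.
    """
    if hasattr(features, "to_dict") and not isinstance(features, Mapping):
        features = features.to_dict()
    total = model.intercept
    for term, coef in model.coefficients.items():
        name = model.mapping[term]
        if name not in features:
            raise KeyError(f"feature '{name}' (model term '{term}') is missing")
        value = float(features[name])
        if not math.isfinite(value):
            raise ValueError(f"feature '{name}' is not finite: {value}")
        total += coef * value
    return float(total)


@dataclass
class MixedFit:
    fixed_effects: dict[str, float]
    standard_errors: dict[str, float]
    sigma_subject: float
    sigma_resid: float
    loglik: float
    aic: float
    bic: float
    n_obs: int
    n_subjects: int
    reml: bool = False


def _profile_negll(log_lam, groups_Xy, n_obs, p, reml):
    """Negative profile log-likelihood over the variance ratio lambda."""
    lam = math.exp(log_lam)
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    logdet = 0.0
    for X, y in groups_Xy:
        ni = len(y)
        w = lam / (1.0 + lam * ni)
        Xs, ys = X.sum(axis=0), y.sum()
        XtVX += X.T @ X - w * np.outer(Xs, Xs)
        XtVy += X.T @ y - w * Xs * ys
        logdet += math.log1p(lam * ni)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = 0.0
    for X, y in groups_Xy:
        r = y - X @ beta
        w = lam / (1.0 + lam * len(y))
        rss += r @ r - w * r.sum() ** 2
    dof = n_obs - p if reml else n_obs
    sigma2 = max(rss / dof, 1e-12)
    ll = -0.5 * (n_obs * math.log(2 * math.pi * sigma2) + logdet + rss / sigma2)
    if reml:
        sign, ld = np.linalg.slogdet(XtVX / sigma2)
        ll -= 0.5 * ld
    return -ll, beta, sigma2, XtVX


def fit_mixed_model(
    data: pd.DataFrame,
    formula_terms: Sequence[str],
    response: str = "ultrasound_ga",
    group: str = "subject_id",
    reml: bool = False,
) -> MixedFit:
    """Random-intercept-per-subject Gaussian mixed model.

    Fit by maximum likelihood: the likelihood is profiled over the
    variance ratio lambda = sigma_subject^2 / sigma_resid^2, with
    closed-form generalized-least-squares fixed effects at each lambda
    (the per-group covariance ``I + lambda * 11'`` is inverted via the
    Sherman--Morrison identity).  ``reml=True`` switches to restricted ML.
    """
    terms = list(formula_terms)
    if group not in data.columns or response not in data.columns:
        raise ValueError(f"data must contain '{group}' and '{response}' columns")
    subjects = data[group].to_numpy()
    uniq = pd.unique(subjects)
    if len(uniq) < 2:
        raise ValueError("need at least 2 subjects")
    counts = data.groupby(group).size()
    if not (counts >= 2).any():
        raise ValueError("need at least one subject with >= 2 sessions")

    X = np.column_stack([np.ones(len(data))] + [data[t].to_numpy(float) for t in terms])
    y = data[response].to_numpy(float)
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        collinear = [t for t in terms if _r2_on_others(data, t, [u for u in terms if u != t]) > 1 - 1e-10]
        raise ValueError(f"design matrix is rank deficient; collinear terms: {collinear or terms}")

    groups_Xy = [
        (X[subjects == s], y[subjects == s]) for s in uniq
    ]
    n_obs = len(y)

    def objective(log_lam):
        return _profile_negll(log_lam, groups_Xy, n_obs, p, reml)[0]

    # coarse grid then bounded refinement; include the lambda -> 0 boundary
    grid = np.linspace(-12.0, 8.0, 41)
    vals = [objective(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(0, i - 1)]
    hi = grid[min(len(grid) - 1, i + 1)]
    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8})
    best_log_lam = float(res.x) if res.fun <= vals[i] else float(grid[i])

    negll, beta, sigma2, XtVX = _profile_negll(best_log_lam, groups_Xy, n_obs, p, reml)
    lam = math.exp(best_log_lam)
    # treat a boundary solution as sigma_subject = 0
    sigma_subject = math.sqrt(lam * sigma2) if lam > 1e-8 else 0.0
    sigma_resid = math.sqrt(sigma2)
    cov_beta = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov_beta))
    names = ["intercept"] + terms
    loglik = -negll
    k = p + 2  # fixed effects + two variance components
    return MixedFit(
        fixed_effects=dict(zip(names, map(float, beta))),
        standard_errors=dict(zip(names, map(float, se))),
        sigma_subject=float(sigma_subject),
        sigma_resid=float(sigma_resid),
        loglik=float(loglik),
        aic=float(-2 * loglik + 2 * k),
        bic=float(-2 * loglik + k * math.log(n_obs)),
        n_obs=int(n_obs),
        n_subjects=int(len(uniq)),
        reml=reml,
    )


def _r2_on_others(data: pd.DataFrame, term: str, others: Sequence[str]) -> float:
    y = data[term].to_numpy(float)
    X = np.column_stack([np.ones(len(y))] + [data[t].to_numpy(float) for t in others])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = np.sum((y - y.mean()) ** 2)
    if tss < 1e-300:
        return 1.0
    return float(1.0 - resid @ resid / tss)


def variance_inflation(data: pd.DataFrame, terms: Sequence[str]) -> dict[str, float]:
    """VIF_j = 1 / (1 - R^2_j) from regressing term j on the other terms.

    Perfect collinearity is reported as ``inf`` rather than raising.
    """
    terms = list(terms)
    if len(data) < len(terms) + 2:
        raise ValueError("need at least len(terms) + 2 rows for VIF")
    out = {}
    for t in terms:
        r2 = _r2_on_others(data, t, [u for u in terms if u != t])
        out[t] = float("inf") if r2 >= 1 - 1e-12 else float(1.0 / (1.0 - r2))
    return out


@dataclass
class AgreementStats:
    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pearson_r: float
    pct_within_1wk: float
    pct_within_2wk: float
    n_outside_loa: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def bland_altman(predicted: Sequence[float], reference: Sequence[float]) -> AgreementStats:
    """Bland--Altman agreement of predicted vs reference values.

    differences = predicted - reference; bias is their mean, limits of
    agreement are bias +/- 1.96 * SD (sample SD, ddof=1).
    """
    pred = np.asarray(predicted, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {ref.shape}")
    if pred.ndim != 1 or len(pred) < 2:
        raise ValueError("need at least 2 paired values")
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(ref))):
        raise ValueError("inputs must be finite")
    diff = pred - ref
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    if pred.std() > 0 and ref.std() > 0:
        r = float(np.corrcoef(pred, ref)[0, 1])
    else:
        r = float("nan")  # undefined for a constant series
    return AgreementStats(
        n=len(pred),
        bias=bias,
        sd_diff=sd,
        loa_low=float(loa_low),
        loa_high=float(loa_high),
        pearson_r=r,
        pct_within_1wk=float(100.0 * np.mean(np.abs(diff) <= 1.0)),
        pct_within_2wk=float(100.0 * np.mean(np.abs(diff) <= 2.0)),
        n_outside_loa=int(np.sum((diff < loa_low) | (diff > loa_high))),
    )


def hittner_grade_range(grade: str) -> tuple[int, int]:
    """Published gestational-age range (weeks) for a Hittner grade I--IV."""
    g = str(grade).strip().upper()
    if g not in _HITTNER_RANGES:
        raise ValueError(f"unknown Hittner grade {grade!r}; expected I, II, III or IV")
    return _HITTNER_RANGES[g]


def classify_hittner_grade(ga_weeks: float) -> str:
    """Inverse lookup over contiguous half-open bins covering [27, 35)."""
    for grade, lo, hi in _HITTNER_BINS:
        if lo <= ga_weeks < hi:
            return grade
    raise ValueError(f"gestational age {ga_weeks} weeks is outside the gradable range [27, 35)")


def bland_altman_plot(predicted, reference, path: str | Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stats = bland_altman(predicted, reference)
    pred = np.asarray(predicted, float)
    ref = np.asarray(reference, float)
    mean = (pred + ref) / 2
    diff = pred - ref
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(mean, diff, s=18, alpha=0.8)
    for yv, style in ((stats.bias, "-"), (stats.loa_low, "--"), (stats.loa_high, "--")):
        ax.axhline(yv, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("Mean of methods (weeks)")
    ax.set_ylabel("Difference, predicted - reference (weeks)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def identity_plot(predicted, reference, path: str | Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pred = np.asarray(predicted, float)
    ref = np.asarray(reference, float)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(ref, pred, s=18, alpha=0.8)
    lo = min(ref.min(), pred.min()) - 0.5
    hi = max(ref.max(), pred.max()) + 0.5
    ax.plot([lo, hi], [lo, hi], "k--", linewidth=1)
    ax.set_xlabel("Reference GA (weeks)")
    ax.set_ylabel("Predicted GA (weeks)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
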