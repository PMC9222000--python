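"""Linear discriminant scoring of Gleason <=3 vs >=4 from nuclear morphometry.

This module implements the multivariate stage of the pipeline:

* the published 7-variable discriminant score (:data:`PAPER_MODEL`) with its
  decision cutoff of -1.1134 — higher scores indicate the high-grade class
  (evaluating the printed formula at the published per-grade feature means
  puts grades 4 and 5 above the cutoff and grades 1-3 below it, which fixes
  the otherwise unstated orientation);
* forward stepwise linear discriminant fitting with the Wilks-lambda
  partial-F entry/removal criterion (a logistic-regression Wald variant is
  available behind a flag for sensitivity analysis);
* ROC analysis with Youden-optimal cutoff selection.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

LOW_GRADE = "low_grade_G13"
HIGH_GRADE = "high_grade_G45"

#: The seven descriptors entering the published discriminant.
PAPER_FEATURES = (
    "radius_min",
    "fractal_dimension",
    "gray_min",
    "gray_max",
    "margination",
    "gray_green",
    "gray_blue",
)


@dataclass
class DiscriminantModel:
    """A linear discriminant: score = intercept + sum(coefficient * feature).

    ``orientation`` records which side of ``cutoff`` is called high grade;
    with the default ``"higher_score_is_high_grade"``, scores at or above the
    cutoff classify as Gleason >= 4 (ties deliberately go to the clinically
    risky class).
    """

    intercept: float
    coefficients: dict[str, float]
    cutoff: float = 0.0
    orientation: str = "higher_score_is_high_grade"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.orientation not in (
            "higher_score_is_high_grade",
            "lower_score_is_high_grade",
        ):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        for name, c in self.coefficients.items():
            if not np.isfinite(c):
                raise ValueError(f"non-finite coefficient for {name!r}")
        if not np.isfinite(self.intercept) or not np.isfinite(self.cutoff):
            raise ValueError("intercept and cutoff must be finite")

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "intercept": self.intercept,
                    "coefficients": self.coefficients,
                    "cutoff": self.cutoff,
                    "orientation": self.orientation,
                    "provenance": self.provenance,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "DiscriminantModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)


def _load_paper_model() -> DiscriminantModel:
    payload = json.loads(
        resources.files("nucleomorph.data").joinpath("paper_model.json").read_text()
    )
    return DiscriminantModel(**payload)


#: The published model, shipped as a packaged JSON asset.
PAPER_MODEL: DiscriminantModel = _load_paper_model()


def score(features: Mapping[str, float] | pd.Series, model: DiscriminantModel) -> float:
    """Evaluate the discriminant score for one feature vector.

    Every model feature must be present and finite; missing features raise
    ``KeyError`` naming the feature (no imputation).
    """
    total = model.intercept
    for name, coef in model.coefficients.items():
        try:
            value = features[name]
        except (KeyError, IndexError):
            raise KeyError(f"feature {name!r} missing from input") from None
        if value is None or not np.isfinite(value):
            raise ValueError(f"feature {name!r} is not finite: {value!r}")
        total += coef * float(value)
    return float(total)


def score_table(records: pd.DataFrame, model: DiscriminantModel) -> pd.Series:
    """Vectorised :func:`score` over a record table (one row per sample)."""
    missing = [f for f in model.features if f not in records.columns]
    if missing:
        raise KeyError(f"features missing from input: {missing}")
    X = records[list(model.features)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        bad = records.index[~np.isfinite(X).all(axis=1)].tolist()
        raise ValueError(f"non-finite feature values in rows {bad}")
    w = np.array([model.coefficients[f] for f in model.features])
    return pd.Series(model.intercept + X @ w, index=records.index, name="score")


def classify(ds: float, model: DiscriminantModel) -> str:
    """Binary call from a discriminant score; ties at the cutoff go to the
    high-grade class."""
    if not np.isfinite(ds):
        raise ValueError("score must be finite")
    high = ds >= model.cutoff
    if model.orientation == "lower_score_is_high_grade":
        high = ds <= model.cutoff
    return HIGH_GRADE if high else LOW_GRADE


# ---------------------------------------------------------------------------
# Stepwise fitting


def _wilks_lambda(X: np.ndarray, y: np.ndarray) -> float:
    """Wilks' lambda det(W)/det(T) for a two-class design."""
    n, p = X.shape
    overall = X.mean(axis=0)
    T = (X - overall).T @ (X - overall)
    W = np.zeros((p, p))
    for cls in (0, 1):
        sub = X[y == cls]
        W += (sub - sub.mean(axis=0)).T @ (sub - sub.mean(axis=0))
    det_T = np.linalg.det(T)
    if det_T <= 0:
        return 1.0
    return float(np.linalg.det(W) / det_T)


def fit_stepwise(
    records: pd.DataFrame,
    candidates: Sequence[str],
    enter_p: float = 0.05,
    remove_p: float = 0.10,
    low_grades: tuple[str, ...] = ("G13",),
    method: str = "wilks",
) -> DiscriminantModel:
    """Forward stepwise two-class linear discriminant fit.

    The low class pools the grade groups in ``low_grades`` (default G13);
    everything else is the high class.  With ``method="wilks"`` (the
    standard stepwise discriminant criterion) each step adds the candidate
    minimising Wilks' lambda provided its partial-F p-value is at most
    ``enter_p``, then removes any included variable whose partial-F p-value
    exceeds ``remove_p``; the procedure is deterministic.  The returned
    weights are scaled so the pooled within-class variance of the score is
    1, with the intercept centring the class midpoint at 0 and orientation
    such that higher scores mean high grade.

    ``method="logistic_wald"`` swaps the criterion for the Wald p-value of
    each candidate's coefficient in a logistic regression (sensitivity
    analysis variant).

    Raises ``ValueError`` when no candidate passes entry.
    """
    candidates = list(dict.fromkeys(candidates))  # dedupe, keep order
    y = (~records["grade_group"].isin(low_grades)).to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("need samples from both classes")
    data = records[candidates].to_numpy(dtype=float)
    keep_rows = np.isfinite(data).all(axis=1)
    data, y = data[keep_rows], y[keep_rows]
    n = len(y)
    g = 2

    if method == "logistic_wald":
        selected = _logistic_forward(data, y, candidates, enter_p, remove_p)
    elif method == "wilks":
        selected: list[int] = []
        lambda_cur = 1.0
        while True:
            changed = False
            # Entry scan.
            best_j, best_lambda = None, None
            for j in range(len(candidates)):
                if j in selected:
                    continue
                X_try = data[:, selected + [j]]
                # Collinearity guard: skip candidates adding no information.
                if np.linalg.matrix_rank(X_try - X_try.mean(axis=0)) < len(selected) + 1:
                    log.warning(
                        "candidate %s collinear with current model, skipped",
                        candidates[j],
                    )
                    continue
                lam = _wilks_lambda(X_try, y)
                if best_lambda is None or lam < best_lambda:
                    best_j, best_lambda = j, lam
            if best_j is not None:
                p_in = len(selected)
                df2 = n - g - p_in
                if df2 > 0 and best_lambda > 0:
                    F = (df2 / (g - 1.0)) * (lambda_cur / best_lambda - 1.0)
                    p_val = stats.f.sf(F, g - 1, df2)
                    if p_val <= enter_p:
                        selected.append(best_j)
                        lambda_cur = best_lambda
                        changed = True
            # Removal scan.
            if len(selected) > 1:
                worst_j, worst_p = None, -1.0
                for j in list(selected):
                    rest = [k for k in selected if k != j]
                    lam_without = _wilks_lambda(data[:, rest], y)
                    df2 = n - g - len(rest)
                    if df2 <= 0 or lambda_cur <= 0:
                        continue
                    F = (df2 / (g - 1.0)) * (lam_without / lambda_cur - 1.0)
                    p_val = stats.f.sf(F, g - 1, df2)
                    if p_val > worst_p:
                        worst_j, worst_p = j, p_val
                if worst_j is not None and worst_p > remove_p:
                    selected.remove(worst_j)
                    lambda_cur = _wilks_lambda(data[:, selected], y)
                    changed = True
            if not changed:
                break
    else:
        raise ValueError(f"unknown method {method!r}")

    if not selected:
        raise ValueError("no discriminative features: nothing passed entry")

    X = data[:, selected]
    names = [candidates[j] for j in selected]
    mu0 = X[y == 0].mean(axis=0)
    mu1 = X[y == 1].mean(axis=0)
    W = np.zeros((X.shape[1], X.shape[1]))
    for cls in (0, 1):
        sub = X[y == cls]
        W += (sub - sub.mean(axis=0)).T @ (sub - sub.mean(axis=0))
    S_pooled = W / (n - 2)
    w = np.linalg.solve(S_pooled, mu1 - mu0)
    # Scale: pooled within-class variance of the score equals 1.
    var_within = float(w @ S_pooled @ w)
    if var_within > 0:
        w = w / np.sqrt(var_within)
    if w @ (mu1 - mu0) < 0:  # orient: high class scores higher
        w = -w
    intercept = -float(w @ ((mu0 + mu1) / 2.0))
    return DiscriminantModel(
        intercept=intercept,
        coefficients={nm: float(c) for nm, c in zip(names, w)},
        cutoff=0.0,
        provenance=f"stepwise-{method} fit on {n} samples",
    )


def _logistic_forward(
    data: np.ndarray,
    y: np.ndarray,
    candidates: Sequence[str],
    enter_p: float,
    remove_p: float,
) -> list[int]:
    """Forward selection by logistic-regression Wald p-values."""
    import statsmodels.api as sm

    def wald_p(cols: list[int]) -> np.ndarray:
        X = sm.add_constant(data[:, cols], has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            except Exception:  # separation / singularity
                return np.full(len(cols), np.nan)
        return fit.pvalues[1:]

    selected: list[int] = []
    while True:
        changed = False
        best_j, best_p = None, None
        for j in range(len(candidates)):
            if j in selected:
                continue
            pvals = wald_p(selected + [j])
            p_j = pvals[-1]
            if np.isfinite(p_j) and (best_p is None or p_j < best_p):
                best_j, best_p = j, p_j
        if best_j is not None and best_p is not None and best_p <= enter_p:
            selected.append(best_j)
            changed = True
        if len(selected) > 1:
            pvals = wald_p(selected)
            worst = int(np.nanargmax(pvals))
            if np.isfinite(pvals[worst]) and pvals[worst] > remove_p:
                selected.pop(worst)
                changed = True
        if not changed:
            break
    return selected


# ---------------------------------------------------------------------------
# ROC


@dataclass
class RocResult:
    """ROC curve for a score with higher-is-positive orientation.

    ``thresholds`` are candidate cutoffs (midpoints between adjacent
    distinct scores plus the two infinities); a sample is called positive
    when its score is at or above the threshold.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    cutoff: float = field(default=float("nan"))
    sensitivity_at_cutoff: float = field(default=float("nan"))
    specificity_at_cutoff: float = field(default=float("nan"))


def roc(scores: Sequence[float], labels: Sequence[int] | Sequence[bool]) -> RocResult:
    """ROC analysis of scores against binary labels (1 = high grade).

    Thresholds sit at midpoints between adjacent distinct scores, flanked by
    -inf and +inf; the AUC is the trapezoidal area under the (FPR, TPR)
    curve, which for a step curve equals the concordance probability with
    ties counted half.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(labels).astype(bool)
    if t.all() or not t.any():
        raise ValueError("both classes must be present")
    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    n_pos = int(t.sum())
    n_neg = int((~t).sum())
    sens = np.array([np.count_nonzero(s[t] >= th) / n_pos for th in thresholds])
    spec = np.array([np.count_nonzero(s[~t] < th) / n_neg for th in thresholds])
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))  # ascending fpr, then tpr: step envelope
    auc = float(np.trapezoid(sens[order], fpr[order]))
    return RocResult(thresholds=thresholds, sensitivity=sens, specificity=spec, auc=auc)


def pick_cutoff(result: RocResult) -> float:
    """Youden-optimal threshold (max sensitivity + specificity - 1); ties
    break toward higher specificity, then toward the larger threshold.
    Fills the cutoff fields of ``result`` in place and returns the cutoff."""
    j = result.sensitivity + result.specificity - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    specs = result.specificity[best]
    best = best[specs >= specs.max() - 1e-12]
    idx = int(best[np.argmax(result.thresholds[best])])
    cutoff = float(result.thresholds[idx])
    if not np.isfinite(cutoff):
        # Degenerate: all-one-side decision; fall back to an extreme finite mid.
        finite = result.thresholds[np.isfinite(result.thresholds)]
        cutoff = float(finite[0]) if len(finite) else 0.0
    result.cutoff = cutoff
    result.sensitivity_at_cutoff = float(result.sensitivity[idx])
    result.specificity_at_cutoff = float(result.specificity[idx])
    return cutoff
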