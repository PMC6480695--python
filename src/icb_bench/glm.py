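"""Binomial GLM (logit link) over the merged binary marker matrix.

One model is fitted on all merged patients for coefficient inference, and
discrimination is estimated by repeated holdout: at each iteration a random
80% trains the model, the remaining 20% is scored, and the test ROC yields
an AUC plus the Youden-optimal ("best") sensitivity/specificity. Means over
the valid iterations summarize the ensemble, matching the repeated 80/20
protocol with 10,000 iterations.

Fitting is plain maximum likelihood (statsmodels GLM, binomial family):
no penalization, with complete separation detected and flagged rather than
silently regularized away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateLabelsError, ReliabilityError, SchemaError
from .performance import _as_bool_labels, auc as roc_auc, roc_curve, youden_threshold

__all__ = [
    "GlmFit",
    "CvSummary",
    "fit_glm",
    "predict_glm",
    "repeated_holdout",
    "coefficient_table",
]

#: Coefficient magnitude beyond which a logit fit is treated as separated.
_SEPARATION_COEF = 15.0


@dataclass
class GlmFit:
    """A fitted logistic model: one intercept term plus one term per marker."""

    coefficients: pd.DataFrame  # term, estimate, std_error, t_value, p_value
    converged: bool
    separation: bool
    n_train: int
    terms: list[str]
    dropped: list[str] = field(default_factory=list)

    @property
    def params(self) -> pd.Series:
        return self.coefficients.set_index("term")["estimate"]


def _design(features: pd.DataFrame) -> pd.DataFrame:
    X = features.astype(float).copy()
    X.insert(0, "Intercept", 1.0)
    return X


def fit_glm(features: pd.DataFrame, labels) -> GlmFit:
    """Maximum-likelihood logistic fit with Wald inference.

    Constant feature columns are dropped with a warning (they are collinear
    with the intercept). Complete separation is reported through the
    ``separation`` flag and ``converged=False`` instead of quietly returning
    enormous coefficients.
    """
    y = _as_bool_labels(labels).astype(float)
    if y.all() or not y.any():
        raise DegenerateLabelsError("training labels contain a single class")
    dropped = [c for c in features.columns if features[c].nunique() < 2]
    if dropped:
        warnings.warn(f"dropping constant feature columns: {dropped}", stacklevel=2)
    kept = features.drop(columns=dropped)
    X = _design(kept)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # IRLS emits its own convergence chatter
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=100)
    params = np.asarray(res.params, dtype=float)
    separated = bool(np.max(np.abs(params)) > _SEPARATION_COEF) or not np.all(
        np.isfinite(res.bse)
    )
    converged = bool(getattr(res, "converged", True)) and not separated
    table = pd.DataFrame(
        {
            "term": list(X.columns),
            "estimate": params,
            "std_error": np.asarray(res.bse, dtype=float),
            "t_value": np.asarray(res.tvalues, dtype=float),
            "p_value": np.asarray(res.pvalues, dtype=float),
        }
    )
    return GlmFit(
        coefficients=table,
        converged=converged,
        separation=separated,
        n_train=len(y),
        terms=list(kept.columns),
        dropped=dropped,
    )


def predict_glm(fit: GlmFit, features: pd.DataFrame) -> pd.Series:
    """Response probability per patient via the inverse logit."""
    if list(features.columns) != fit.terms:
        missing = set(fit.terms) - set(features.columns)
        extra = set(features.columns) - set(fit.terms)
        if missing or extra:
            raise SchemaError(
                f"feature columns do not match fit terms (missing {sorted(missing)}, "
                f"extra {sorted(extra)})"
            )
        features = features[fit.terms]
    X = _design(features)
    eta = X.to_numpy(dtype=float) @ fit.params.to_numpy()
    return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=features.index, name="probability")


@dataclass
class CvSummary:
    """Repeated-holdout discrimination summary."""

    iterations: int
    valid_iterations: int
    skipped_iterations: int
    mean_auc: float
    mean_best_sensitivity: float
    mean_best_specificity: float
    auc_distribution: np.ndarray
    seed: int
    test_fraction: float


def repeated_holdout(
    features: pd.DataFrame,
    labels,
    test_fraction: float = 0.2,
    iterations: int = 10_000,
    seed: int = 0,
    stratified: bool = False,
) -> CvSummary:
    """Random 80/20 train/test splits, refitting the GLM each time.

    Splits are simple random by default ("randomly selected", with no
    stratification implied); iterations whose train or test set lacks a
    class are skipped and counted. Each valid iteration contributes the test
    ROC's AUC and its Youden-optimal sensitivity/specificity. Deterministic
    given ``seed``; raises :class:`ReliabilityError` when more than half the
    iterations are degenerate.
    """
    rng = np.random.default_rng(seed)
    y = _as_bool_labels(labels)
    n = len(y)
    n_test = max(1, int(round(n * test_fraction)))
    X = features.astype(float)
    idx_all = np.arange(n)
    pos_idx = idx_all[y]
    neg_idx = idx_all[~y]

    aucs, sens_list, spec_list = [], [], []
    skipped = 0
    for _ in range(iterations):
        if stratified:
            n_test_pos = max(1, int(round(len(pos_idx) * test_fraction)))
            n_test_neg = max(1, int(round(len(neg_idx) * test_fraction)))
            test = np.concatenate(
                [
                    rng.choice(pos_idx, size=n_test_pos, replace=False),
                    rng.choice(neg_idx, size=n_test_neg, replace=False),
                ]
            )
        else:
            test = rng.choice(idx_all, size=n_test, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[test] = True
        y_train, y_test = y[~mask], y[mask]
        if y_train.all() or not y_train.any() or y_test.all() or not y_test.any():
            skipped += 1
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # per-split constant-column / flat-ROC chatter
            fit = fit_glm(X.loc[~mask], y_train)
            prob = predict_glm(fit, X.loc[mask][fit.terms])
            # probabilities already point toward response: no orientation flip,
            # which would bias a null model's mean AUC above chance
            curve = roc_curve(prob.to_numpy(), y_test, orient=False)
        aucs.append(roc_auc(curve))
        _, sens, spec = youden_threshold(curve)
        sens_list.append(sens)
        spec_list.append(spec)

    if skipped > iterations / 2:
        raise ReliabilityError(
            f"{skipped}/{iterations} holdout iterations had single-class splits"
        )
    return CvSummary(
        iterations=iterations,
        valid_iterations=len(aucs),
        skipped_iterations=skipped,
        mean_auc=float(np.mean(aucs)),
        mean_best_sensitivity=float(np.mean(sens_list)),
        mean_best_specificity=float(np.mean(spec_list)),
        auc_distribution=np.asarray(aucs),
        seed=seed,
        test_fraction=test_fraction,
    )


def coefficient_table(fit: GlmFit) -> pd.DataFrame:
    """Terms sorted by p-value with significance flags at 1% and 5%.

    A non-converged (e.g. separated) fit keeps its estimates but masks the
    Wald p-values, so unreliable inference is never reported silently.
    """
    table = fit.coefficients.copy()
    table["converged"] = fit.converged
    if not fit.converged:
        warnings.warn(
            "fit did not converge (possible separation): p-values masked", stacklevel=2
        )
        table[["std_error", "t_value", "p_value"]] = np.nan
        table["significant_1pct"] = False
        table["significant_5pct"] = False
        return table
    table["significant_1pct"] = table["p_value"] < 0.01
    table["significant_5pct"] = table["p_value"] < 0.05
    return table.sort_values("p_value", kind="stable").reset_index(drop=True)
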