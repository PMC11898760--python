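"""Microbiota-for-age modelling.

A random forest regresses chronological age (months) on species
relative abundances.  Because forest predictions saturate at late ages,
a cubic saturation spline of predicted age on true age is fitted to the
cross-validated predictions, and the *relative microbiota age* of a
sample is the difference between its forest prediction and the spline
expectation at its true age.  Negative values indicate maturation
delay.

Model evaluation uses subject-grouped k-fold cross-validation — all
longitudinal samples of an individual stay in one fold — so repeated
measures cannot leak age signal between training and held-out sets.
Model performance is the Spearman correlation between pooled held-out
predictions and true ages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GroupKFold

from miage.profiles import Cohort

__all__ = [
    "MicrobiotaAgeModel",
    "MicrobiotaAgeResults",
    "SaturationSpline",
    "PanelSelection",
    "fit_saturation_spline",
    "train_age_model",
    "predict_ages",
    "rank_importance",
    "select_min_panel",
    "relative_age",
    "segmented_slope",
]


# ---------------------------------------------------------------------------
# Saturation spline

class SaturationSpline:
    """Penalized cubic regression spline of predicted age on true age.

    Internal knots sit at the deciles of the training ages; the
    roughness penalty (second differences of the B-spline coefficients)
    is chosen by generalized cross-validation.  Queries outside the
    training-age domain are clamped to the nearest endpoint with a
    warning.
    """

    degree = 3

    def __init__(self, knots: np.ndarray, coef: np.ndarray, domain: tuple[float, float]):
        self._bspline = BSpline(knots, coef, self.degree, extrapolate=False)
        self.knots = knots
        self.coef = coef
        self.domain = domain

    @classmethod
    def fit(cls, true_ages, predicted_ages) -> "SaturationSpline":
        return fit_saturation_spline(true_ages, predicted_ages)

    def __call__(self, ages) -> np.ndarray:
        a = np.asarray(ages, dtype=float)
        lo, hi = self.domain
        if np.any(a < lo) or np.any(a > hi):
            warnings.warn("query outside spline domain; clamping to domain endpoints",
                          stacklevel=2)
        clamped = np.clip(a, lo, hi)
        out = self._bspline(clamped)
        return out if out.ndim else float(out)


def _spline_design(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    n_basis = len(knots) - degree - 1
    return BSpline.design_matrix(x, knots, degree).toarray()[:, :n_basis]


def fit_saturation_spline(true_ages, predicted_ages) -> SaturationSpline:
    """Fit the saturation spline on (true age, predicted age) pairs."""
    x = np.asarray(true_ages, dtype=float)
    y = np.asarray(predicted_ages, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 (true, predicted) pairs")
    if np.ptp(x) <= 0:
        raise ValueError("true ages are constant; spline is degenerate")
    lo, hi = float(x.min()), float(x.max())
    deg = SaturationSpline.degree
    internal = np.unique(np.quantile(x, np.linspace(0.1, 0.9, 9)))
    internal = internal[(internal > lo) & (internal < hi)]
    knots = np.concatenate([[lo] * (deg + 1), internal, [hi] * (deg + 1)])
    B = _spline_design(x, knots, deg)
    k = B.shape[1]
    # second-difference roughness penalty on coefficients
    D = np.diff(np.eye(k), n=2, axis=0)
    P = D.T @ D
    BtB = B.T @ B
    Bty = B.T @ y
    n = x.size
    best = None
    for lam in np.logspace(-4, 5, 28):
        A = BtB + lam * P
        try:
            coef = np.linalg.solve(A, Bty)
            # effective dof = tr(B (BtB + lam P)^-1 B^T) = tr((BtB+lamP)^-1 BtB)
            edof = float(np.trace(np.linalg.solve(A, BtB)))
        except np.linalg.LinAlgError:  # pragma: no cover - P is PSD, rare
            continue
        resid = y - B @ coef
        denom = max(n - edof, 1e-8)
        gcv = n * float(resid @ resid) / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, coef)
    assert best is not None
    return SaturationSpline(knots, best[1], (lo, hi))


# ---------------------------------------------------------------------------
# Model / Results

@dataclass
class PanelSelection:
    """Minimal species panel reaching a fraction of full-model performance."""

    panel: list[str]
    performance_fraction: float
    achieved_spearman: float
    max_spearman: float

    def __len__(self) -> int:
        return len(self.panel)


class MicrobiotaAgeModel:
    """Random-forest regression of age on species relative abundances.

    Parameters
    ----------
    abundances : DataFrame
        Samples × species percent abundances.
    ages : Series
        Chronological age in months per sample.
    subjects : Series
        Subject identifier per sample; used to group cross-validation
        folds so no individual spans train and test.
    n_folds : int
        Cross-validation folds (reduced with a warning when there are
        fewer subjects than folds).
    n_estimators : int
        Trees in the forest.
    seed : int
        Seeds the forest; identical seed and data give identical
        importances and performance.
    """

    def __init__(self, abundances: pd.DataFrame, ages: pd.Series, subjects: pd.Series,
                 n_folds: int = 10, n_estimators: int = 500, seed: int = 0):
        self.abundances = abundances
        self.ages = ages.loc[abundances.index].astype(float)
        self.subjects = subjects.loc[abundances.index].astype(str)
        if np.ptp(self.ages.values) <= 0:
            raise ValueError("ages are constant; age regression is undefined")
        n_subjects = self.subjects.nunique()
        if n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if n_subjects < n_folds:
            warnings.warn(f"only {n_subjects} subjects; reducing folds from {n_folds}",
                          stacklevel=2)
            n_folds = n_subjects
        self.n_folds = n_folds
        self.n_estimators = n_estimators
        self.seed = seed

    @classmethod
    def from_cohort(cls, cohort: Cohort, species: list[str] | None = None,
                    **kwargs) -> "MicrobiotaAgeModel":
        X = cohort.abundance_matrix(species)
        ages = cohort.ages()
        subjects = pd.Series({sid: cohort.metadata[sid].subject_id for sid in cohort.sample_ids})
        return cls(X, ages, subjects, **kwargs)

    # -- internals ----------------------------------------------------------

    def _make_forest(self) -> RandomForestRegressor:
        return RandomForestRegressor(
            n_estimators=self.n_estimators, random_state=self.seed,
            max_features=1.0 / 3.0, n_jobs=1)

    def _fold_indices(self) -> list[tuple[np.ndarray, np.ndarray]]:
        gkf = GroupKFold(n_splits=self.n_folds)
        return list(gkf.split(self.abundances.values, groups=self.subjects.values))

    def _cv_predict(self, X: np.ndarray, folds) -> np.ndarray:
        y = self.ages.values
        preds = np.empty_like(y)
        for train_idx, test_idx in folds:
            forest = self._make_forest()
            forest.fit(X[train_idx], y[train_idx])
            preds[test_idx] = forest.predict(X[test_idx])
        return preds

    @staticmethod
    def _rss_importances(forest: RandomForestRegressor, n_samples: int) -> np.ndarray:
        """Decrease in residual sum of squares per feature, averaged over trees."""
        imps = [tree.tree_.compute_feature_importances(normalize=False) * n_samples
                for tree in forest.estimators_]
        return np.mean(imps, axis=0)

    # -- public -------------------------------------------------------------

    def fit(self) -> "MicrobiotaAgeResults":
        X = self.abundances.values
        y = self.ages.values
        folds = self._fold_indices()
        cv_pred = self._cv_predict(X, folds)
        cv_spearman = float(stats.spearmanr(cv_pred, y).statistic)
        forest = self._make_forest()
        forest.fit(X, y)
        importances = pd.Series(self._rss_importances(forest, len(y)),
                                index=self.abundances.columns)
        spline = fit_saturation_spline(y, cv_pred)
        return MicrobiotaAgeResults(
            model=self, forest=forest, importances=importances,
            cv_spearman=cv_spearman,
            cv_predictions=pd.Series(cv_pred, index=self.abundances.index),
            spline=spline)


@dataclass
class MicrobiotaAgeResults:
    """Fitted microbiota-age model: forest, importances, CV performance, spline."""

    model: MicrobiotaAgeModel
    forest: RandomForestRegressor
    importances: pd.Series
    cv_spearman: float
    cv_predictions: pd.Series
    spline: SaturationSpline

    @property
    def feature_names(self) -> list[str]:
        return list(self.model.abundances.columns)

    @property
    def seed(self) -> int:
        return self.model.seed

    @property
    def n_folds(self) -> int:
        return self.model.n_folds

    def rank_importance(self) -> pd.Series:
        """Species sorted by decreasing importance, ties broken lexicographically."""
        df = self.importances.rename("importance").rename_axis("species").reset_index()
        df = df.sort_values(["importance", "species"], ascending=[False, True])
        return df.set_index("species")["importance"]

    def predict(self, data: Cohort | pd.DataFrame) -> pd.Series:
        """Predict ages for new samples.

        Features map by species name: species unseen at training time
        are dropped, trained species missing from the input are imputed
        at zero abundance.
        """
        if isinstance(data, Cohort):
            X = data.abundance_matrix(None)
        else:
            X = data
        overlap = [s for s in self.feature_names if s in X.columns]
        if not overlap:
            raise ValueError("no species shared between the trained model and the input cohort")
        aligned = X.reindex(columns=self.feature_names).fillna(0.0)
        return pd.Series(self.forest.predict(aligned.values), index=X.index)

    def relative_age(self, data: Cohort | pd.DataFrame,
                     true_ages: pd.Series | None = None) -> pd.DataFrame:
        """Per-sample relative microbiota age.

        Returns a DataFrame with ``true_age_months``,
        ``predicted_age_months``, ``expected_predicted_age`` (spline at
        true age), and ``relative_age_months`` = predicted − expected.
        """
        if isinstance(data, Cohort):
            ages = data.ages()
        else:
            if true_ages is None:
                raise ValueError("true_ages required with a DataFrame input")
            ages = true_ages.loc[data.index].astype(float)
        if (ages < 0).any():
            raise ValueError("true ages must be non-negative")
        predicted = self.predict(data)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # clamping outside domain is expected here
            expected = np.asarray(self.spline(ages.values))
        out = pd.DataFrame({
            "true_age_months": ages,
            "predicted_age_months": predicted,
            "expected_predicted_age": expected,
        })
        out["relative_age_months"] = out["predicted_age_months"] - out["expected_predicted_age"]
        return out

    def select_min_panel(self, performance_fraction: float = 0.95) -> PanelSelection:
        """Smallest importance-ranked species prefix reaching the performance cutoff.

        Species are added in order of decreasing importance; at each
        panel size the forest is retrained and re-evaluated with the
        same subject-grouped folds and seed, stopping once the
        cross-validated Spearman reaches ``performance_fraction`` times
        the full-model Spearman.
        """
        if not 0 < performance_fraction <= 1:
            raise ValueError("performance_fraction must be in (0, 1]")
        ranked = list(self.rank_importance().index)
        folds = self.model._fold_indices()
        target = performance_fraction * self.cv_spearman
        y = self.model.ages.values
        achieved = np.nan
        panel: list[str] = []
        for size in range(1, len(ranked) + 1):
            panel = ranked[:size]
            X = self.model.abundances[panel].values
            preds = self.model._cv_predict(X, folds)
            achieved = float(stats.spearmanr(preds, y).statistic)
            if achieved >= target:
                break
        return PanelSelection(panel=panel, performance_fraction=performance_fraction,
                              achieved_spearman=achieved, max_spearman=self.cv_spearman)

    def summary(self) -> str:
        lines = [
            "Microbiota-for-age model",
            "=" * 40,
            f"Samples:               {len(self.model.abundances)}",
            f"Subjects:              {self.model.subjects.nunique()}",
            f"Species features:      {len(self.feature_names)}",
            f"Trees:                 {self.model.n_estimators}",
            f"CV folds (by subject): {self.n_folds}",
            f"Seed:                  {self.seed}",
            f"CV Spearman:           {self.cv_spearman:.4f}",
            "",
            "Top 10 species by RSS-decrease importance:",
        ]
        for sp, imp in self.rank_importance().head(10).items():
            lines.append(f"  {imp:12.3f}  {sp}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Functional wrappers

def train_age_model(cohort: Cohort, n_folds: int = 10, seed: int = 0,
                    n_estimators: int = 500,
                    species: list[str] | None = None) -> MicrobiotaAgeResults:
    """Train the microbiota-age model on a cohort (subject-grouped CV)."""
    model = MicrobiotaAgeModel.from_cohort(cohort, species=species, n_folds=n_folds,
                                           n_estimators=n_estimators, seed=seed)
    return model.fit()


def predict_ages(results: MicrobiotaAgeResults, cohort: Cohort) -> pd.Series:
    return results.predict(cohort)


def rank_importance(results: MicrobiotaAgeResults) -> pd.Series:
    return results.rank_importance()


def select_min_panel(results: MicrobiotaAgeResults,
                     performance_fraction: float = 0.95) -> PanelSelection:
    return results.select_min_panel(performance_fraction)


def relative_age(results: MicrobiotaAgeResults, cohort: Cohort) -> pd.DataFrame:
    return results.relative_age(cohort)


def segmented_slope(relative_age_results: pd.DataFrame,
                    breakpoint: float = 18.0) -> dict[str, tuple[float, float]]:
    """Ordinary least-squares slopes of relative age on true age, split at a breakpoint.

    Fits relative age against true age separately for samples at or
    before the breakpoint and after it, returning
    ``{"pre": (slope, p), "post": (slope, p)}``.  A side with fewer than
    3 points is reported as ``(nan, nan)``.
    """
    t = relative_age_results["true_age_months"].values.astype(float)
    r = relative_age_results["relative_age_months"].values.astype(float)
    out: dict[str, tuple[float, float]] = {}
    for label, mask in (("pre", t <= breakpoint), ("post", t > breakpoint)):
        if mask.sum() < 3:
            out[label] = (float("nan"), float("nan"))
            continue
        out[label] = _ols_slope(t[mask], r[mask])
    return out


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = x.size
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        return (float("nan"), float("nan"))
    slope = float(xc @ (y - y.mean())) / sxx
    resid = (y - y.mean()) - slope * xc
    dof = n - 2
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    se = np.sqrt(s2 / sxx)
    if se == 0:
        # perfect fit: the slope is exact; p is 0 unless the slope itself is 0
        return (slope, 1.0 if slope == 0 else 0.0)
    tstat = slope / se
    p = 2 * stats.t.sf(abs(tstat), dof)
    return (slope, float(p))
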