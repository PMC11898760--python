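"""Dirichlet-multinomial mixture (DMM) community typing.

Each mixture component is a Dirichlet-multinomial over read counts of a
species panel (typically the species giving 99% of microbiota-age-model
performance).  Fitting is by expectation-maximization with Minka's
digamma fixed-point update for the Dirichlet parameters; because the
fixed point is a minorize-maximize step, the observed-data
log-likelihood is non-decreasing at every iteration, which the fitter
asserts.

Model size is selected by the Bayesian information criterion
BIC = −2·logL + p·ln(n) with p = K·(S+1) − 1 free parameters (K alpha
vectors over S species plus K−1 free mixture weights).  BIC optima are
known to wobble across replicate EM runs on real data, so
:func:`select_k` reports every replicate's optimum alongside the best.

Samples — including samples from another cohort — are assigned to the
component with the highest posterior probability under the fixed model,
and community progression is summarized as cluster occupancy per
3-month age bin, with clusters ordered by the bin where they peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp
from sklearn.cluster import KMeans

from miage.profiles import Cohort, SampleMetadata

__all__ = [
    "DirichletMultinomialMixture",
    "DMMResults",
    "OccupancyTable",
    "dirichlet_multinomial_logpmf",
    "fit_dmm",
    "select_k",
    "assign_clusters",
    "order_clusters_by_age",
    "phase_occupancy",
]

_ALPHA_FLOOR = 1e-10


def dirichlet_multinomial_logpmf(counts: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Log pmf of the Dirichlet-multinomial for each row of ``counts``.

    Includes the multinomial coefficient, so values are proper log
    probabilities.
    """
    X = np.atleast_2d(np.asarray(counts, dtype=float))
    a = np.asarray(alpha, dtype=float)
    n = X.sum(axis=1)
    a0 = a.sum()
    coef = gammaln(n + 1) - gammaln(X + 1).sum(axis=1)
    return (coef + gammaln(a0) - gammaln(n + a0)
            + (gammaln(X + a) - gammaln(a)).sum(axis=1))


def _weighted_alpha_update(X: np.ndarray, r: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """One Minka fixed-point step for a responsibility-weighted DM component."""
    n = X.sum(axis=1)
    a0 = alpha.sum()
    num = (r[:, None] * (digamma(X + alpha) - digamma(alpha))).sum(axis=0)
    den = float((r * (digamma(n + a0) - digamma(a0))).sum())
    if den <= 0:
        return alpha
    return np.maximum(alpha * num / den, _ALPHA_FLOOR)


class DirichletMultinomialMixture:
    """EM fitter for a K-component Dirichlet-multinomial mixture.

    Parameters
    ----------
    counts : DataFrame or array
        Samples × species non-negative integer counts over the panel.
    K : int
        Number of mixture components (≥ 1).
    seed : int
        Seeds the k-means initialisation; identical seed and data give
        an identical fit.
    max_iter, tol :
        EM stops when the log-likelihood gain drops below ``tol`` or
        after ``max_iter`` iterations.
    """

    def __init__(self, counts, K: int, seed: int = 0, max_iter: int = 500,
                 tol: float = 1e-6, n_inner: int = 3):
        if K < 1:
            raise ValueError("K must be >= 1")
        if isinstance(counts, pd.DataFrame):
            self.species = list(counts.columns)
            self.sample_ids = list(counts.index.astype(str))
            X = counts.values
        else:
            X = np.asarray(counts)
            self.species = [f"sp{j}" for j in range(X.shape[1])]
            self.sample_ids = [str(i) for i in range(X.shape[0])]
        X = np.asarray(X, dtype=float)
        if (X < 0).any():
            raise ValueError("counts must be non-negative")
        zero_rows = np.where(X.sum(axis=1) == 0)[0]
        if zero_rows.size:
            raise ValueError(f"all-zero count row for sample {self.sample_ids[zero_rows[0]]!r}")
        self.X = X
        self.K = K
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol
        self.n_inner = n_inner

    def _init_params(self) -> tuple[np.ndarray, np.ndarray]:
        X = self.X
        props = X / X.sum(axis=1, keepdims=True)
        if self.K == 1:
            labels = np.zeros(len(X), dtype=int)
        else:
            km = KMeans(n_clusters=self.K, random_state=self.seed, n_init=10)
            labels = km.fit_predict(props)
        alphas = np.empty((self.K, X.shape[1]))
        weights = np.empty(self.K)
        for k in range(self.K):
            mask = labels == k
            if not mask.any():  # pragma: no cover - kmeans rarely leaves empties
                mask = np.ones(len(X), dtype=bool)
            mean_p = props[mask].mean(axis=0)
            alphas[k] = np.maximum(mean_p, 1e-6) * 10.0
            weights[k] = max(mask.sum(), 1) / len(X)
        weights /= weights.sum()
        return alphas, weights

    def fit(self) -> "DMMResults":
        X = self.X
        alphas, weights = self._init_params()
        ll_trace: list[float] = []
        prev_ll = -np.inf
        n_iter = 0
        for it in range(1, self.max_iter + 1):
            n_iter = it
            # E-step
            log_r = np.log(weights)[None, :] + np.column_stack(
                [dirichlet_multinomial_logpmf(X, alphas[k]) for k in range(self.K)])
            ll = float(logsumexp(log_r, axis=1).sum())
            if ll < prev_ll - 1e-8 * max(1.0, abs(prev_ll)):
                raise AssertionError(
                    f"EM log-likelihood decreased at iteration {it}: {prev_ll} -> {ll}")
            ll_trace.append(ll)
            converged = ll - prev_ll < self.tol and it > 1
            prev_ll = ll
            if converged:
                break
            r = np.exp(log_r - logsumexp(log_r, axis=1, keepdims=True))
            # M-step
            weights = np.maximum(r.mean(axis=0), 1e-12)
            weights /= weights.sum()
            for k in range(self.K):
                for _ in range(self.n_inner):
                    alphas[k] = _weighted_alpha_update(X, r[:, k], alphas[k])
        bic = -2.0 * prev_ll + (self.K * (X.shape[1] + 1) - 1) * math.log(len(X))
        return DMMResults(model=self, alphas=alphas, weights=weights,
                          log_likelihood=prev_ll, bic=bic, n_iter=n_iter,
                          ll_trace=ll_trace)


@dataclass
class DMMResults:
    """Fitted DMM: K Dirichlet parameter vectors, mixture weights, BIC."""

    model: DirichletMultinomialMixture
    alphas: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    bic: float
    n_iter: int
    ll_trace: list[float] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.model.K

    @property
    def species(self) -> list[str]:
        return list(self.model.species)

    @property
    def seed(self) -> int:
        return self.model.seed

    def assign(self, counts) -> pd.DataFrame:
        """Posterior responsibilities and hard assignment under the fixed model.

        ``counts`` may be a DataFrame over any species set: species
        missing from the model's panel are zero-filled, extra species
        are dropped.  Hard assignment is the argmax posterior, ties
        breaking to the lowest cluster index.
        """
        if isinstance(counts, pd.DataFrame):
            overlap = [s for s in self.species if s in counts.columns]
            if not overlap:
                raise ValueError("no species shared with the model panel")
            X = counts.reindex(columns=self.species).fillna(0).values.astype(float)
            index = counts.index
        else:
            X = np.asarray(counts, dtype=float)
            index = pd.RangeIndex(len(X))
        log_r = np.log(self.weights)[None, :] + np.column_stack(
            [dirichlet_multinomial_logpmf(X, self.alphas[k]) for k in range(self.K)])
        post = np.exp(log_r - logsumexp(log_r, axis=1, keepdims=True))
        out = pd.DataFrame(post, index=index,
                           columns=[f"posterior_{k}" for k in range(self.K)])
        out["hard_cluster"] = post.argmax(axis=1)
        return out

    def summary(self) -> str:
        lines = [
            "Dirichlet-multinomial mixture",
            "=" * 40,
            f"Components (K):   {self.K}",
            f"Panel species:    {len(self.species)}",
            f"Samples:          {len(self.model.X)}",
            f"Log-likelihood:   {self.log_likelihood:.3f}",
            f"BIC:              {self.bic:.3f}",
            f"EM iterations:    {self.n_iter}",
            f"Weights:          {np.array2string(self.weights, precision=3)}",
        ]
        return "\n".join(lines)


@dataclass
class OccupancyTable:
    """Cluster occupancy per age bin, clusters ordered by their peak bin."""

    table: pd.DataFrame            # ordered clusters × retained bins, fractions
    bin_counts: pd.Series          # samples per retained bin
    cluster_order: list[int]       # original cluster indices, in display order
    dominant_bin: dict[int, float]  # cluster -> lower edge of its peak bin
    bin_width: float

    def display_table(self, min_fraction: float = 0.04) -> pd.DataFrame:
        """Occupancy with fractions below ``min_fraction`` suppressed (display only)."""
        return self.table.where(self.table >= min_fraction)


# ---------------------------------------------------------------------------
# Functional wrappers

def fit_dmm(counts, K: int, seed: int = 0, max_iter: int = 500,
            tol: float = 1e-6) -> DMMResults:
    """Fit a K-component Dirichlet-multinomial mixture by EM."""
    return DirichletMultinomialMixture(counts, K, seed=seed, max_iter=max_iter,
                                       tol=tol).fit()


def select_k(counts, k_range=range(1, 13), replicates: int = 5, seed: int = 0,
             max_iter: int = 500, tol: float = 1e-6) -> tuple[int, list[int]]:
    """Choose K by BIC over replicate EM runs.

    Each replicate refits every K with its own seed and records its own
    BIC-optimal K; the returned best K comes from the replicate whose
    optimum achieved the lowest BIC overall.  The per-replicate list is
    returned even when all replicates agree, because BIC optima are
    unstable on weakly separated data.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be non-empty")
    per_replicate: list[int] = []
    best_overall: tuple[float, int] | None = None
    for rep in range(replicates):
        rep_seed = seed + 1000 * rep
        best_rep: tuple[float, int] | None = None
        for K in k_range:
            res = fit_dmm(counts, K, seed=rep_seed, max_iter=max_iter, tol=tol)
            if best_rep is None or res.bic < best_rep[0]:
                best_rep = (res.bic, K)
        assert best_rep is not None
        per_replicate.append(best_rep[1])
        if best_overall is None or best_rep[0] < best_overall[0]:
            best_overall = best_rep
    assert best_overall is not None
    return best_overall[1], per_replicate


def assign_clusters(results: DMMResults, counts) -> pd.DataFrame:
    return results.assign(counts)


def order_clusters_by_age(assignments: pd.DataFrame,
                          metadata: dict[str, SampleMetadata] | pd.Series,
                          bin_width: float = 3.0, min_bin: int = 15) -> OccupancyTable:
    """Cluster occupancy fractions per age bin.

    Bins with fewer than ``min_bin`` samples are dropped.  Clusters are
    ordered by the bin where their occupancy fraction peaks (earlier
    peak first; ties break to the earlier bin, then the lower cluster
    index).
    """
    if isinstance(metadata, dict):
        ages = pd.Series({sid: m.age_months for sid, m in metadata.items()})
    else:
        ages = metadata.astype(float)
    ages = ages.loc[assignments.index]
    bin_idx = np.floor(ages.values / bin_width).astype(int)
    clusters = assignments["hard_cluster"].values
    df = pd.DataFrame({"bin": bin_idx, "cluster": clusters})
    counts = df.groupby(["bin", "cluster"]).size().unstack(fill_value=0)
    bin_sizes = counts.sum(axis=1)
    retained = bin_sizes[bin_sizes >= min_bin].index
    if len(retained) == 0:
        raise ValueError(f"every age bin has fewer than {min_bin} samples")
    counts = counts.loc[retained]
    frac = counts.div(counts.sum(axis=1), axis=0).T  # clusters × bins
    # order clusters by peak bin; ties -> earlier bin, then lower index
    order = sorted(frac.index, key=lambda c: (int(frac.loc[c].idxmax()), c))
    frac = frac.loc[order]
    dominant = {int(c): float(frac.loc[c].idxmax() * bin_width) for c in order}
    frac.index = pd.Index([int(c) for c in order], name="cluster")
    frac.columns = pd.Index([float(b * bin_width) for b in frac.columns], name="bin_lower")
    return OccupancyTable(table=frac,
                          bin_counts=pd.Series(bin_sizes.loc[retained].values,
                                               index=frac.columns),
                          cluster_order=[int(c) for c in order],
                          dominant_bin=dominant, bin_width=bin_width)


def phase_occupancy(occupancy: OccupancyTable,
                    phases: list[tuple[str, float, float]] | None = None) -> pd.DataFrame:
    """Fraction of each phase's samples in clusters dominant in each phase.

    Rows are sample phases, columns are the phases in which the
    occupied cluster's peak bin falls.  Each row sums to 1.  The cell
    (stable, transitional), for example, is the fraction of
    stable-phase samples still occupying transitional-dominant
    clusters — the stalled-progression readout.
    """
    if phases is None:
        from miage.phases import PHASES
        phases = PHASES
    labels = [p[0] for p in phases]

    def phase_of(age: float) -> str:
        for label, lo, hi in phases:
            if lo <= age < hi:
                return label
        return labels[-1]

    cluster_phase = {c: phase_of(b) for c, b in occupancy.dominant_bin.items()}
    counts = occupancy.table.mul(occupancy.bin_counts, axis=1)  # clusters × bins, sample counts
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for b in counts.columns:
        bp = phase_of(float(b))
        for c in counts.index:
            out.loc[bp, cluster_phase[int(c)]] += counts.loc[c, b]
    row_sums = out.sum(axis=1)
    nonzero = row_sums > 0
    out.loc[nonzero] = out.loc[nonzero].div(row_sums[nonzero], axis=0)
    out.index.name = "sample_phase"
    out.columns.name = "cluster_dominant_phase"
    return out
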