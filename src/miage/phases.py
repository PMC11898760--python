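"""Developmental-phase statistics for longitudinal gut metagenome cohorts.

Infant gut community progression is summarized in three phases:
developmental (0–12 months), transitional (12–18 months), and stable
(18–36 months).  This module assigns phases and implements the
phase-level comparisons between cohorts: compositional differential
abundance with volcano thresholds (p < 0.05 and |log2FC| > 1),
oral-bacteria fraction with the 3.4% low-density flag, per-individual
fungal genus prevalence, and the correlation between cumulative
antibiotic exposures and final relative microbiota age.

Because longitudinal samples from one individual are not independent,
significance defaults to subject-level permutation tests: cohort labels
are permuted across subjects, with all of a subject's samples moving
together.  This is calibrated by construction and mirrors the role of
mixed-effects models with individual as the grouping unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from miage.profiles import Cohort, TaxonProfile, lineage_name_at, parse_lineage

__all__ = [
    "PHASES",
    "ORAL_GENERA",
    "ORAL_GENUS_SYNONYMS",
    "OralFractionResult",
    "ExposureSummary",
    "assign_phase",
    "differential_abundance",
    "oral_fraction",
    "fungal_prevalence",
    "fungal_prevalence_compare",
    "exposure_age_correlation",
    "bh_adjust",
]

#: (label, lower inclusive, upper exclusive) in months.
PHASES: list[tuple[str, float, float]] = [
    ("developmental", 0.0, 12.0),
    ("transitional", 12.0, 18.0),
    ("stable", 18.0, 36.0),
]

#: Oral-associated bacterial genera whose summed stool abundance defines
#: the oral fraction.
ORAL_GENERA = (
    "Actinomyces", "Leptotrichia", "Campylobacter", "Fusobacterium",
    "Neisseria", "Corynebacterium", "Rothia", "Treponema", "Veillonella",
    "Prevotella", "Streptococcus", "Capnocytophaga", "Haemophilus",
)

#: Common misspellings mapped to canonical genus names.
ORAL_GENUS_SYNONYMS = {
    "Camplyobacter": "Campylobacter",
    "Capnocytophage": "Capnocytophaga",
}

ORAL_THRESHOLD_PERCENT = 3.4


def assign_phase(age_months: float) -> str:
    """Map an age in months to its developmental phase (half-open intervals)."""
    if age_months < 0:
        raise ValueError(f"age must be non-negative, got {age_months}")
    for label, lo, hi in PHASES:
        if lo <= age_months < hi:
            return label
    if age_months > PHASES[-1][2]:
        warnings.warn(f"age {age_months} months beyond the stable-phase upper bound; "
                      "assigning stable", stacklevel=2)
    return PHASES[-1][0]


def _phase_interval(phase: str | tuple[float, float]) -> tuple[float, float]:
    if isinstance(phase, tuple):
        return phase
    for label, lo, hi in PHASES:
        if label == phase:
            return (lo, hi)
    raise ValueError(f"unknown phase {phase!r}")


def _phase_samples(cohort: Cohort, phase) -> list[str]:
    lo, hi = _phase_interval(phase)
    return [sid for sid in cohort.sample_ids if lo <= cohort.metadata[sid].age_months < hi]


# ---------------------------------------------------------------------------
# Differential abundance

def _subject_means(cohort: Cohort, sample_ids: list[str],
                   species: list[str]) -> pd.DataFrame:
    """Per-subject mean abundance over the given samples (subjects × species)."""
    X = cohort.subset(sample_ids).abundance_matrix(species)
    subj = pd.Series({sid: cohort.metadata[sid].subject_id for sid in sample_ids})
    return X.groupby(subj).mean()


def differential_abundance(cohort_a: Cohort, cohort_b: Cohort, phase,
                           label_a: str = "A", label_b: str = "B",
                           min_mean_abundance: float = 0.01,
                           pseudo_count: float = 0.001,
                           alpha: float = 0.05, lfc_threshold: float = 1.0,
                           n_permutations: int = 999, seed: int = 0) -> pd.DataFrame:
    """Per-species differential abundance between cohorts within a phase.

    log2FC compares cohort mean abundances with a pseudo-count
    (``log2((meanA + ε)/(meanB + ε))``, ε = 0.001%); species under
    0.01% mean abundance in both cohorts are excluded.  P-values come
    from a subject-level permutation test on the difference of
    group means of per-subject mean abundances; q-values are
    Benjamini–Hochberg.  A species is significant when p < 0.05 and
    |log2FC| > 1 (the volcano rule).
    """
    ids_a = _phase_samples(cohort_a, phase)
    ids_b = _phase_samples(cohort_b, phase)
    if not ids_a or not ids_b:
        raise ValueError("a cohort has no samples in the requested phase")
    subj_a = {cohort_a.metadata[s].subject_id for s in ids_a}
    subj_b = {cohort_b.metadata[s].subject_id for s in ids_b}
    if len(subj_a) < 3 or len(subj_b) < 3:
        raise ValueError("need >= 3 subjects with phase samples in each cohort")

    species = sorted(set(cohort_a.species_index) | set(cohort_b.species_index))
    mean_a = cohort_a.subset(ids_a).abundance_matrix(species).mean(axis=0)
    mean_b = cohort_b.subset(ids_b).abundance_matrix(species).mean(axis=0)
    keep = (mean_a >= min_mean_abundance) | (mean_b >= min_mean_abundance)
    species = [s for s in species if keep[s]]
    mean_a, mean_b = mean_a[species], mean_b[species]

    log2fc = np.log2((mean_a + pseudo_count) / (mean_b + pseudo_count))

    sm_a = _subject_means(cohort_a, ids_a, species)
    sm_b = _subject_means(cohort_b, ids_b, species)
    pooled = np.vstack([sm_a.values, sm_b.values])
    n_a = len(sm_a)
    n_tot = pooled.shape[0]
    obs = sm_a.values.mean(axis=0) - sm_b.values.mean(axis=0)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(species))
    for _ in range(n_permutations):
        perm = rng.permutation(n_tot)
        stat = pooled[perm[:n_a]].mean(axis=0) - pooled[perm[n_a:]].mean(axis=0)
        exceed += np.abs(stat) >= np.abs(obs) - 1e-12
    pvals = (1.0 + exceed) / (n_permutations + 1.0)
    qvals = bh_adjust(pvals)

    out = pd.DataFrame({
        "species": species,
        "log2_fold_change": log2fc.values,
        "p_value": pvals,
        "q_value": qvals,
        "enriched_in": np.where(log2fc.values > 0, label_a, label_b),
    })
    out["significant"] = (out["p_value"] < alpha) & (out["log2_fold_change"].abs() > lfc_threshold)
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Oral fraction

@dataclass
class OralFractionResult:
    sample_id: str
    oral_percent: float
    above_threshold: bool


def oral_fraction(profile: TaxonProfile,
                  oral_genera: tuple[str, ...] = ORAL_GENERA,
                  threshold: float = ORAL_THRESHOLD_PERCENT) -> OralFractionResult:
    """Summed abundance of oral-associated genera in a stool profile.

    Genus names are matched after mapping known synonyms/misspellings
    to their canonical form; genera absent from the profile contribute
    zero.  The flag marks samples above the 3.4% low-density threshold.
    """
    wanted = {ORAL_GENUS_SYNONYMS.get(g, g) for g in oral_genera}
    total = 0.0
    for lin, ab in profile.species().items():
        genus = lineage_name_at(lin, "genus")
        if genus is not None and ORAL_GENUS_SYNONYMS.get(genus, genus) in wanted:
            total += ab
    return OralFractionResult(sample_id=profile.sample_id, oral_percent=total,
                              above_threshold=total > threshold)


# ---------------------------------------------------------------------------
# Fungal prevalence

def _fungal_genus(lineage: str, kingdoms: tuple[str, ...]) -> str | None:
    parts = dict(parse_lineage(lineage))
    if parts.get("kingdom") not in kingdoms:
        return None
    return parts.get("genus")


def fungal_prevalence(cohort: Cohort, phase,
                      kingdoms: tuple[str, ...] = ("Fungi", "Eukaryota")) -> pd.Series:
    """Per-genus fungal prevalence across individuals within a phase.

    Abundance is first collapsed by genus; a genus counts as present
    for an individual if it is detected (> 0) in at least one of that
    individual's samples in the phase.  Prevalence is the fraction of
    individuals (with any phase sample) carrying the genus.
    """
    ids = _phase_samples(cohort, phase)
    subjects = sorted({cohort.metadata[s].subject_id for s in ids})
    genus_carriers: dict[str, set[str]] = {}
    any_fungal = False
    for sid in ids:
        prof = next(p for p in cohort.profiles if p.sample_id == sid)
        subj = cohort.metadata[sid].subject_id
        for lin, ab in prof.species().items():
            genus = _fungal_genus(lin, kingdoms)
            if genus is None:
                continue
            any_fungal = True
            if ab > 0:
                genus_carriers.setdefault(genus, set()).add(subj)
    if not any_fungal:
        warnings.warn("no fungal lineages found in the cohort", stacklevel=2)
        return pd.Series(dtype=float)
    n = max(len(subjects), 1)
    return pd.Series({g: len(c) / n for g, c in sorted(genus_carriers.items())},
                     dtype=float)


def fungal_prevalence_compare(cohort_a: Cohort, cohort_b: Cohort, phase, genus: str,
                              kingdoms: tuple[str, ...] = ("Fungi", "Eukaryota"),
                              n_permutations: int = 999, seed: int = 0
                              ) -> tuple[float, float, float]:
    """Compare one genus's per-individual prevalence between cohorts.

    Returns (prevalence_a, prevalence_b, p) with p from a permutation
    test on the individual-level presence indicator — the permutation
    analog of a binomial-response model grouped by individual.
    """
    pres = []
    groups = []
    for g, cohort in ((0, cohort_a), (1, cohort_b)):
        ids = _phase_samples(cohort, phase)
        per_subj: dict[str, int] = {}
        for sid in ids:
            subj = cohort.metadata[sid].subject_id
            prof = next(p for p in cohort.profiles if p.sample_id == sid)
            hit = any(_fungal_genus(lin, kingdoms) == genus and ab > 0
                      for lin, ab in prof.species().items())
            per_subj[subj] = max(per_subj.get(subj, 0), int(hit))
        pres.extend(per_subj.values())
        groups.extend([g] * len(per_subj))
    pres_arr = np.array(pres, dtype=float)
    groups_arr = np.array(groups)
    prev_a = pres_arr[groups_arr == 0].mean()
    prev_b = pres_arr[groups_arr == 1].mean()
    obs = abs(prev_a - prev_b)
    rng = np.random.default_rng(seed)
    n_a = int((groups_arr == 0).sum())
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(pres_arr))
        stat = abs(pres_arr[perm[:n_a]].mean() - pres_arr[perm[n_a:]].mean())
        exceed += stat >= obs - 1e-12
    p = (1.0 + exceed) / (n_permutations + 1.0)
    return float(prev_a), float(prev_b), float(p)


# ---------------------------------------------------------------------------
# Antibiotic exposure correlation

@dataclass
class ExposureSummary:
    subject_id: str
    cumulative_exposures: int
    final_relative_age: float


def exposure_age_correlation(cohort: Cohort, relative_age_results: pd.DataFrame
                             ) -> tuple[float, float, list[ExposureSummary]]:
    """Spearman correlation of cumulative antibiotic exposures with final relative age.

    For each subject, the final relative age is the relative microbiota
    age at the last sequenced sample, and cumulative exposures counts
    antibiotic events at or before that sample's age.  The correlation
    is across subjects.
    """
    by_subject: dict[str, tuple[float, str]] = {}
    for sid in relative_age_results.index:
        md = cohort.metadata[sid]
        cur = by_subject.get(md.subject_id)
        if cur is None or md.age_months > cur[0]:
            by_subject[md.subject_id] = (md.age_months, sid)
    summaries = []
    for subj in sorted(by_subject):
        final_age, sid = by_subject[subj]
        md = cohort.metadata[sid]
        n_exp = sum(1 for age, _cls in md.exposures if age <= final_age)
        summaries.append(ExposureSummary(
            subject_id=subj, cumulative_exposures=n_exp,
            final_relative_age=float(relative_age_results.loc[sid, "relative_age_months"])))
    if len(summaries) < 5:
        raise ValueError("need >= 5 subjects with relative age and exposure history")
    x = np.array([s.cumulative_exposures for s in summaries], dtype=float)
    y = np.array([s.final_relative_age for s in summaries])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in exposures or relative ages; correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), summaries


# ---------------------------------------------------------------------------
# Multiplicity

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
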