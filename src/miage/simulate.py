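"""Synthetic longitudinal infant-microbiome cohorts with known ground truth.

The generator emulates the structure the analysis pipeline is built to
detect, so every stage has a parameter-recovery test without external
data:

* species follow age-dependent prevalence (logistic in age) and
  abundance trajectories — adult-like taxa rise through the first
  three years, milk-adapted taxa decline, others are stable or pure
  noise;
* per-sample compositions are Dirichlet draws around the age-dependent
  mean, with multinomial read counts at a configurable depth, so the
  Dirichlet-multinomial community-typing model can recover planted
  structure exactly in distribution;
* a disease arm develops on a *stalled effective-age clock*: between 6
  and 18 months the microbiota's effective age falls progressively
  behind chronological age and then stays behind, and each antibiotic
  exposure deflects the clock further — which mechanically produces a
  negative relative microbiota age, a negative pre-18-month slope with
  a flat post-18 slope, and a negative exposure/relative-age
  correlation, plus planted oral contamination and fungal carriage;
* marker-gene alignment simulation plants clades at a chosen coverage
  and substitution error rate, with decoy records violating each
  alignment filter.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from miage.markers import ALIGNMENT_COLUMNS, CladeScheme
from miage.profiles import Cohort, SampleMetadata, TaxonProfile

__all__ = [
    "TrajectoryParams",
    "ArmEffects",
    "SyntheticTruth",
    "default_trajectories",
    "default_arm_effects",
    "simulate_cohort",
    "simulate_dmm_counts",
    "well_separated_alphas",
    "simulate_marker_alignments",
]


@dataclass
class TrajectoryParams:
    """Age trajectory of one species.

    Prevalence is logistic in age with the given midpoint and slope
    (slope < 0 for declining taxa); log mean intensity moves linearly
    from ``log_ab_start`` to ``log_ab_end`` across 0–36 months.
    ``role`` tags the species for ground-truth bookkeeping.
    """

    lineage: str
    role: str  # age_discriminatory | stable | noise | oral | fungal
    prev_midpoint: float = 0.0
    prev_slope: float = 0.0
    prev_max: float = 1.0
    log_ab_start: float = 0.0
    log_ab_end: float = 0.0

    def prevalence(self, age: float) -> float:
        if self.prev_slope == 0.0:
            return self.prev_max
        return self.prev_max / (1.0 + np.exp(-self.prev_slope * (age - self.prev_midpoint)))

    def mean_intensity(self, age: float) -> float:
        frac = np.clip(age / 36.0, 0.0, 1.0)
        return float(np.exp(self.log_ab_start + frac * (self.log_ab_end - self.log_ab_start)))


@dataclass
class ArmEffects:
    """Disease-arm perturbations; the neutral setting reproduces the healthy arm.

    ``stall_rate`` is the months of effective-age delay accrued per
    chronological month between ``stall_onset`` and ``stall_end``;
    ``exposure_deflection`` (≤ 0) is the additional months of delay per
    antibiotic exposure; ``suppression_factor`` multiplies
    age-discriminatory species intensities; exposures additionally
    knock those species down by ``knockdown_factor`` for
    ``knockdown_months`` after each event.
    """

    stall_rate: float = 0.0
    stall_onset: float = 6.0
    stall_end: float = 18.0
    suppression_factor: float = 1.0
    oral_contamination_percent: float = 0.0
    fungal_carriage_prob: float = 0.15
    exposure_rate: float = 0.0
    exposure_deflection: float = 0.0
    knockdown_months: float = 3.0
    knockdown_factor: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.suppression_factor <= 1:
            raise ValueError("suppression_factor must be in [0, 1]")
        if self.exposure_deflection > 0:
            raise ValueError("exposure_deflection must be <= 0")
        if self.stall_rate < 0 or self.exposure_rate < 0:
            raise ValueError("rates must be non-negative")

    def effective_age(self, age: float, exposure_ages: list[float]) -> float:
        stall = self.stall_rate * max(0.0, min(age, self.stall_end) - self.stall_onset)
        n_prior = sum(1 for e in exposure_ages if e <= age)
        return max(0.0, age - stall + self.exposure_deflection * n_prior)


def default_arm_effects(arm: str) -> ArmEffects:
    """Study-condition defaults: neutral for healthy, CF-like for disease."""
    if arm == "healthy":
        return ArmEffects()
    if arm == "disease":
        return ArmEffects(stall_rate=0.5, suppression_factor=0.85,
                          oral_contamination_percent=5.0, fungal_carriage_prob=0.5,
                          exposure_rate=2.0, exposure_deflection=-0.8,
                          knockdown_months=3.0, knockdown_factor=0.3)
    raise ValueError(f"arm must be 'healthy' or 'disease', got {arm!r}")


def _lin(phylum: str, genus: str, species: str,
         kingdom: str = "Bacteria") -> str:
    return (f"k__{kingdom}|p__{phylum}|c__C_{phylum}|o__O_{phylum}"
            f"|f__F_{genus}|g__{genus}|s__{species}")


def default_trajectories() -> list[TrajectoryParams]:
    """Default species set: 10 age-discriminatory, 8 stable, 15 noise, 4 oral, 2 fungal.

    Adult-like taxa (butyrate producers, *Bacteroides*/*Alistipes*,
    *Akkermansia*) rise with logistic midpoints spread over 6–24
    months; milk-adapted *Bifidobacterium* and early *E. coli* decline.
    """
    t: list[TrajectoryParams] = []
    # Logistic midpoints are spread across the whole 0-36-month window so
    # the composition keeps gaining age information into the third year;
    # clustered early midpoints would leave late ages indistinguishable.
    rising = [
        ("Bacillota", "Faecalibacterium", "Faecalibacterium_prausnitzii", 6.0, 2.2),
        ("Bacteroidota", "Bacteroides", "Bacteroides_uniformis", 9.0, 2.0),
        ("Bacillota", "Eubacterium", "Eubacterium_rectale", 13.0, 2.6),
        ("Bacillota", "Ruminococcus", "Ruminococcus_bromii", 17.0, 2.0),
        ("Bacteroidota", "Alistipes", "Alistipes_putredinis", 21.0, 2.2),
        ("Bacillota", "Roseburia", "Roseburia_intestinalis", 25.0, 2.4),
        ("Verrucomicrobiota", "Akkermansia", "Akkermansia_muciniphila", 29.0, 2.5),
    ]
    for phylum, genus, sp, mid, end_ab in rising:
        t.append(TrajectoryParams(
            lineage=_lin(phylum, genus, sp), role="age_discriminatory",
            prev_midpoint=mid, prev_slope=0.3, prev_max=0.95,
            log_ab_start=-1.0, log_ab_end=end_ab))
    falling = [
        ("Actinomycetota", "Bifidobacterium", "Bifidobacterium_longum", 18.0, 3.0, 0.2),
        ("Actinomycetota", "Bifidobacterium", "Bifidobacterium_breve", 12.0, 2.4, -0.6),
        ("Pseudomonadota", "Escherichia", "Escherichia_coli", 10.0, 2.0, -0.8),
    ]
    for phylum, genus, sp, mid, start_ab, end_ab in falling:
        t.append(TrajectoryParams(
            lineage=_lin(phylum, genus, sp), role="age_discriminatory",
            prev_midpoint=mid, prev_slope=-0.35, prev_max=0.98,
            log_ab_start=start_ab, log_ab_end=end_ab))
    stable = [
        ("Bacteroidota", "Phocaeicola", "Phocaeicola_vulgatus", 2.2),
        ("Bacteroidota", "Bacteroides", "Bacteroides_fragilis", 1.4),
        ("Bacillota", "Blautia", "Blautia_wexlerae", 1.6),
        ("Bacillota", "Anaerostipes", "Anaerostipes_hadrus", 0.8),
        ("Bacillota", "Dorea", "Dorea_longicatena", 0.6),
        ("Actinomycetota", "Collinsella", "Collinsella_aerofaciens", 1.0),
        ("Bacteroidota", "Parabacteroides", "Parabacteroides_distasonis", 1.2),
        ("Bacillota", "Enterocloster", "Enterocloster_bolteae", 0.4),
    ]
    for phylum, genus, sp, ab in stable:
        t.append(TrajectoryParams(lineage=_lin(phylum, genus, sp), role="stable",
                                  prev_max=0.9, log_ab_start=ab, log_ab_end=ab))
    for i in range(15):
        phylum = ["Bacillota", "Bacteroidota", "Actinomycetota"][i % 3]
        t.append(TrajectoryParams(
            lineage=_lin(phylum, f"Noisegenus{i}", f"Noise_species_{i}"),
            role="noise", prev_max=0.6, log_ab_start=-0.5, log_ab_end=-0.5))
    oral = [
        ("Bacillota", "Streptococcus", "Streptococcus_salivarius"),
        ("Bacillota", "Veillonella", "Veillonella_parvula"),
        ("Actinomycetota", "Rothia", "Rothia_mucilaginosa"),
        ("Pseudomonadota", "Haemophilus", "Haemophilus_parainfluenzae"),
    ]
    for phylum, genus, sp in oral:
        t.append(TrajectoryParams(lineage=_lin(phylum, genus, sp), role="oral",
                                  prev_max=0.7, log_ab_start=-1.6, log_ab_end=-1.6))
    fungal = [
        ("Ascomycota", "Candida", "Candida_albicans"),
        ("Ascomycota", "Saccharomyces", "Saccharomyces_cerevisiae"),
    ]
    for phylum, genus, sp in fungal:
        t.append(TrajectoryParams(lineage=_lin(phylum, genus, sp, kingdom="Fungi"),
                                  role="fungal", prev_max=1.0,
                                  log_ab_start=-2.0, log_ab_end=-2.0))
    return t


@dataclass
class SyntheticTruth:
    """Ground truth serialized alongside every generated dataset."""

    seed: int
    arm: str
    arm_effects: ArmEffects
    trajectories: list[TrajectoryParams]
    effective_ages: dict[str, float] = field(default_factory=dict)
    age_scores: dict[str, float] = field(default_factory=dict)
    community_stage: dict[str, int] = field(default_factory=dict)
    exposures: dict[str, list[float]] = field(default_factory=dict)
    phylum_totals: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_clades: list[str] = field(default_factory=list)
    marker_sequences: dict[str, str] = field(default_factory=dict)
    dmm_labels: list[int] = field(default_factory=list)

    def species_by_role(self, role: str) -> list[str]:
        return [t.lineage for t in self.trajectories if t.role == role]

    def to_json(self, path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=list)


def simulate_cohort(n_subjects: int = 200, samples_per_subject: int = 6,
                    age_range: tuple[float, float] = (0.5, 36.0),
                    arm: str = "healthy",
                    trajectories: list[TrajectoryParams] | None = None,
                    effects: ArmEffects | None = None,
                    depth: int = 50_000, concentration: float = 150.0,
                    cohort_name: str | None = None,
                    seed: int = 1) -> tuple[Cohort, SyntheticTruth]:
    """Generate a longitudinal cohort with serialized ground truth.

    Each subject contributes ``samples_per_subject`` samples at sorted
    ages drawn uniformly within ``age_range``.  Species presence is
    Bernoulli in the age-dependent prevalence, compositions are
    Dirichlet draws (precision ``concentration``) around the
    age-dependent mean evaluated at the subject's *effective* age, and
    read counts are multinomial at ``depth``.  The disease arm applies
    the :class:`ArmEffects` perturbations; identical seed → identical
    output.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if samples_per_subject < 1 or depth <= 0:
        raise ValueError("invalid sampling parameters")
    trajectories = trajectories if trajectories is not None else default_trajectories()
    effects = effects if effects is not None else default_arm_effects(arm)
    rng = np.random.default_rng(seed)
    lineages = [t.lineage for t in trajectories]
    roles = np.array([t.role for t in trajectories])
    age_disc = roles == "age_discriminatory"
    oral_mask = roles == "oral"
    fungal_mask = roles == "fungal"
    rising_mask = np.array([t.role == "age_discriminatory" and t.prev_slope > 0
                            for t in trajectories])
    status = "CF" if arm == "disease" else "nonCF"
    name = cohort_name or f"synthetic_{arm}"

    profiles: list[TaxonProfile] = []
    metadata: dict[str, SampleMetadata] = {}
    truth = SyntheticTruth(seed=seed, arm=arm, arm_effects=effects,
                           trajectories=trajectories)
    stage_edges = np.array([3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 24.0, 30.0])

    for s in range(n_subjects):
        subject_id = f"{name}_subj{s:03d}"
        ages = np.sort(rng.uniform(age_range[0], age_range[1], size=samples_per_subject))
        n_exp = rng.poisson(effects.exposure_rate)
        exposure_ages = np.sort(rng.uniform(0.0, 18.0, size=n_exp)).tolist()
        classes = rng.choice(["penicillin", "cephalosporin", "macrolide"], size=n_exp)
        exposures = list(zip(exposure_ages, classes.tolist()))
        truth.exposures[subject_id] = exposure_ages
        carries_fungus = rng.random(fungal_mask.sum()) < effects.fungal_carriage_prob
        for k, age in enumerate(ages):
            sample_id = f"{subject_id}_t{k}"
            eff_age = effects.effective_age(float(age), exposure_ages)
            intensity = np.array([t.mean_intensity(eff_age) for t in trajectories])
            prev = np.array([t.prevalence(eff_age) for t in trajectories])
            present = rng.random(len(trajectories)) < prev
            intensity = np.where(present, intensity, 0.0)
            intensity[age_disc] *= effects.suppression_factor
            recent = any(e <= age < e + effects.knockdown_months for e in exposure_ages)
            if recent:
                intensity[age_disc] *= effects.knockdown_factor
            if effects.oral_contamination_percent > 0:
                others = intensity[~oral_mask].sum()
                f = effects.oral_contamination_percent / 100.0
                target = others * f / (1.0 - f)
                base_oral = intensity[oral_mask]
                if base_oral.sum() > 0:
                    intensity[oral_mask] = base_oral / base_oral.sum() * target
            fvals = intensity[fungal_mask]
            intensity[fungal_mask] = np.where(carries_fungus, fvals, 0.0)
            if intensity.sum() <= 0:  # pragma: no cover - all-absent draw
                intensity[:] = 1e-3
            mean_p = intensity / intensity.sum()
            alpha = np.where(mean_p > 0, mean_p * concentration, 0.0)
            props = np.zeros_like(mean_p)
            nz = alpha > 0
            props[nz] = rng.dirichlet(alpha[nz])
            counts_vec = rng.multinomial(depth, props)
            abund = {lin: float(100.0 * p) for lin, p in zip(lineages, props) if p > 0}
            counts = {lin: int(c) for lin, c in zip(lineages, counts_vec) if c > 0}
            counts = {lin: c for lin, c in counts.items() if lin in abund}
            profiles.append(TaxonProfile(sample_id=sample_id, abundances=abund,
                                         counts=counts, total_reads=depth))
            metadata[sample_id] = SampleMetadata(
                sample_id=sample_id, subject_id=subject_id, age_months=float(age),
                cohort=name, disease_status=status, exposures=exposures)
            truth.effective_ages[sample_id] = eff_age
            truth.age_scores[sample_id] = float(mean_p[rising_mask].sum())
            truth.community_stage[sample_id] = int(np.digitize(eff_age, stage_edges))
            phyla: dict[str, float] = {}
            for lin, p in zip(lineages, props):
                phylum = lin.split("|")[1][3:]
                phyla[phylum] = phyla.get(phylum, 0.0) + float(100.0 * p)
            truth.phylum_totals[sample_id] = phyla
    return Cohort(profiles, metadata), truth


# ---------------------------------------------------------------------------
# DMM test harness

def well_separated_alphas(K: int, n_species: int, precision: float = 30.0,
                          dominance: float = 0.8) -> np.ndarray:
    """K Dirichlet parameter vectors, each dominated by a disjoint species block."""
    if n_species < K:
        raise ValueError("need at least one species per component")
    alphas = np.full((K, n_species), (1.0 - dominance) / max(n_species - 1, 1))
    block = n_species // K
    for k in range(K):
        idx = slice(k * block, (k + 1) * block if k < K - 1 else n_species)
        width = idx.stop - idx.start if isinstance(idx, slice) else block
        alphas[k, idx] = dominance / max(width, 1)
    return alphas * precision


def simulate_dmm_counts(n_samples: int, K: int, alphas=None, weights=None,
                        depth: int = 5_000, n_species: int = 8,
                        seed: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw Dirichlet-multinomial mixture counts with component labels."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    if alphas is None:
        alphas = well_separated_alphas(K, n_species)
    alphas = np.asarray(alphas, dtype=float)
    if (alphas <= 0).any():
        raise ValueError("alphas must be positive")
    if weights is None:
        weights = np.full(K, 1.0 / K)
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(K, size=n_samples, p=weights)
    counts = np.empty((n_samples, alphas.shape[1]), dtype=int)
    for i, lab in enumerate(labels):
        p = rng.dirichlet(alphas[lab])
        counts[i] = rng.multinomial(depth, p)
    df = pd.DataFrame(counts, index=[f"dmm{i}" for i in range(n_samples)],
                      columns=[f"sp{j}" for j in range(alphas.shape[1])])
    return df, labels


# ---------------------------------------------------------------------------
# Marker alignment harness

def simulate_marker_alignments(scheme: CladeScheme, planted_clades: list[str],
                               coverage: float = 30.0, error_rate: float = 0.0,
                               read_length: int = 100, decoy_fraction: float = 0.1,
                               seed: int = 3
                               ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], SyntheticTruth]:
    """Simulate alignment records and pileups for planted clades.

    Every marker of a planted clade receives reads at the requested
    fold coverage with identities degraded by the substitution error
    rate, plus ``decoy_fraction`` of that many records violating each
    alignment-filter predicate (low identity, short alignment, low
    MAPQ, multimapping).  Pileups match the per-position depth with
    errors scattered over non-reference bases.
    """
    if coverage < 0:
        raise ValueError("coverage must be non-negative")
    unknown = set(planted_clades) - set(scheme.clades)
    if unknown:
        raise ValueError(f"planted clades not in scheme: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    records: list[dict] = []
    pileups: dict[str, pd.DataFrame] = {}
    truth = SyntheticTruth(seed=seed, arm="markers", arm_effects=ArmEffects(),
                           trajectories=[], planted_clades=sorted(planted_clades))
    read_counter = 0
    for clade in sorted(planted_clades):
        for marker in sorted(scheme.clades[clade]):
            length = scheme.marker_lengths.get(marker, 1000)
            seq = "".join(rng.choice(bases, size=length))
            truth.marker_sequences[marker] = seq
            n_reads = int(np.ceil(coverage * length / read_length)) if coverage > 0 else 0
            for _ in range(n_reads):
                errs = rng.binomial(read_length, error_rate)
                records.append({
                    "read_id": f"r{read_counter}", "marker_id": marker,
                    "percent_identity": 100.0 * (1 - errs / read_length),
                    "aligned_fraction": 1.0, "mapq": 42, "multimapping": False})
                read_counter += 1
            n_decoy = int(np.floor(decoy_fraction * n_reads))
            for kind in range(4):
                for _ in range(n_decoy):
                    rec = {"read_id": f"r{read_counter}", "marker_id": marker,
                           "percent_identity": 99.0, "aligned_fraction": 1.0,
                           "mapq": 42, "multimapping": False}
                    if kind == 0:
                        rec["percent_identity"] = float(rng.uniform(80.0, 94.9))
                    elif kind == 1:
                        rec["aligned_fraction"] = float(rng.uniform(0.1, 0.49))
                    elif kind == 2:
                        rec["mapq"] = int(rng.integers(0, 20))
                    else:
                        rec["multimapping"] = True
                    records.append(rec)
                    read_counter += 1
            if n_reads > 0:
                depth = max(1, int(round(coverage)))
                counts = np.zeros((length, 4), dtype=int)
                ref_idx = np.searchsorted(bases, list(seq))
                err_counts = rng.binomial(depth, error_rate, size=length)
                counts[np.arange(length), ref_idx] = depth - err_counts
                for pos in np.nonzero(err_counts)[0]:
                    others = [b for b in range(4) if b != ref_idx[pos]]
                    spread = rng.multinomial(err_counts[pos], [1 / 3] * 3)
                    for b, c in zip(others, spread):
                        counts[pos, b] += c
                pileups[marker] = pd.DataFrame(
                    {"position": np.arange(length), "A": counts[:, 0],
                     "C": counts[:, 1], "G": counts[:, 2], "T": counts[:, 3]})
    df = pd.DataFrame(records, columns=ALIGNMENT_COLUMNS)
    return df, pileups, truth
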