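"""Taxonomic profile containers and I/O for longitudinal metagenome cohorts.

Profiles follow the MetaPhlAn merged-table dialect: rows are full
taxonomic lineages with rank prefixes (``k__ ... s__``) joined by ``|``,
columns are samples, and values are relative abundances on a 0–100
percent scale.  A cohort couples the profiles with per-sample
longitudinal metadata (subject, age in months, cohort label, disease
status, antibiotic exposures).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Taxonomic ranks from shallowest to deepest, keyed by lineage prefix.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = {"k": "kingdom", "p": "phylum", "c": "class", "o": "order",
                 "f": "family", "g": "genus", "s": "species"}
PREFIX_OF_RANK = {v: k for k, v in RANK_PREFIXES.items()}

#: Reserved lineage for the unclassified read fraction; excluded from
#: species-level operations but retained so per-sample totals stay
#: interpretable.
UNCLASSIFIED = "UNCLASSIFIED"

_ABUND_TOL = 1e-6


class LineageParseError(ValueError):
    """Raised when a lineage string does not follow the rank-prefix dialect."""


def parse_lineage(lineage: str) -> list[tuple[str, str]]:
    """Split a ``k__A|p__B|...`` lineage into ``[(rank, name), ...]``.

    Raises
    ------
    LineageParseError
        If a component lacks a recognised rank prefix or ranks appear
        out of order.
    """
    parts = lineage.split("|")
    out: list[tuple[str, str]] = []
    last_idx = -1
    for part in parts:
        if len(part) < 3 or part[1:3] != "__" or part[0] not in RANK_PREFIXES:
            raise LineageParseError(f"malformed lineage component {part!r} in {lineage!r}")
        rank = RANK_PREFIXES[part[0]]
        idx = RANKS.index(rank)
        if idx <= last_idx:
            raise LineageParseError(f"ranks out of order in {lineage!r}")
        last_idx = idx
        out.append((rank, part[3:]))
    return out


def lineage_rank(lineage: str) -> str:
    """Deepest rank of a lineage string."""
    return parse_lineage(lineage)[-1][0]


def lineage_name_at(lineage: str, rank: str) -> str | None:
    """Name of the ancestor taxon at ``rank``, or None if not recorded."""
    for r, name in parse_lineage(lineage):
        if r == rank:
            return name
    return None


def strip_prefixes(lineage: str) -> str:
    """``k__A|...|s__X`` -> ``X`` (deepest taxon name, prefix removed)."""
    return parse_lineage(lineage)[-1][1]


@dataclass
class TaxonProfile:
    """Relative-abundance profile of one sample.

    Parameters
    ----------
    sample_id : str
    abundances : dict
        Full lineage string -> relative abundance in percent (0–100).
    counts : dict, optional
        Lineage -> estimated read count.  Every counted lineage must
        also carry an abundance entry.
    total_reads : int, optional
    """

    sample_id: str
    abundances: dict[str, float]
    counts: dict[str, int] | None = None
    total_reads: int | None = None

    def __post_init__(self) -> None:
        for lin, ab in self.abundances.items():
            if ab < 0:
                raise ValueError(f"negative abundance {ab} for {lin} in sample {self.sample_id}")
        species_total = sum(ab for lin, ab in self.abundances.items()
                            if lin != UNCLASSIFIED and lineage_rank(lin) == "species")
        if species_total > 100 + _ABUND_TOL:
            raise ValueError(
                f"species abundances sum to {species_total:.6f} > 100 in sample {self.sample_id}")
        if self.counts is not None:
            missing = set(self.counts) - set(self.abundances)
            if missing:
                raise ValueError(
                    f"counts without abundance entries in sample {self.sample_id}: {sorted(missing)[:3]}")
            for lin, c in self.counts.items():
                if c < 0 or c != int(c):
                    raise ValueError(f"count for {lin} must be a non-negative integer")

    def species(self) -> dict[str, float]:
        """Species-level abundances, excluding the unclassified fraction."""
        return {lin: ab for lin, ab in self.abundances.items()
                if lin != UNCLASSIFIED and lineage_rank(lin) == "species"}


@dataclass
class SampleMetadata:
    sample_id: str
    subject_id: str
    age_months: float
    cohort: str = ""
    disease_status: str = "nonCF"
    exposures: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.age_months < 0:
            raise ValueError(f"age_months must be >= 0, got {self.age_months}")
        if self.disease_status not in ("CF", "nonCF"):
            raise ValueError(f"disease_status must be 'CF' or 'nonCF', got {self.disease_status!r}")
        for age, _cls in self.exposures:
            if age < 0:
                raise ValueError("exposure ages must be >= 0")


@dataclass
class AgeBin:
    """Half-open age bin [lower, upper) in months."""

    lower: float
    upper: float
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.upper <= self.lower:
            raise ValueError("AgeBin upper must exceed lower")


class Cohort:
    """Profiles plus metadata for a (longitudinal) sample collection.

    ``species_index`` is the sorted union of species lineages observed
    across profiles; it defines a stable column order for matrix views.
    """

    def __init__(self, profiles: list[TaxonProfile],
                 metadata: dict[str, SampleMetadata] | None = None) -> None:
        self.profiles = list(profiles)
        self.metadata = dict(metadata) if metadata else {}
        seen: set[str] = set()
        for p in self.profiles:
            if p.sample_id in seen:
                raise ValueError(f"duplicate sample {p.sample_id!r} in cohort")
            seen.add(p.sample_id)
        if self.metadata:
            missing = [p.sample_id for p in self.profiles if p.sample_id not in self.metadata]
            if missing:
                raise ValueError(f"profiles without metadata: {missing[:5]}")
            pairs: set[tuple[str, float]] = set()
            for sid in seen:
                md = self.metadata[sid]
                key = (md.subject_id, md.age_months)
                if key in pairs:
                    logger.warning("duplicate (subject, age) pair %s", key)
                pairs.add(key)
        species = set()
        for p in self.profiles:
            species.update(p.species())
        self.species_index: list[str] = sorted(species)

    def __len__(self) -> int:
        return len(self.profiles)

    @property
    def sample_ids(self) -> list[str]:
        return [p.sample_id for p in self.profiles]

    def subjects(self) -> list[str]:
        return sorted({m.subject_id for m in self.metadata.values()})

    def ages(self) -> pd.Series:
        return pd.Series({sid: self.metadata[sid].age_months for sid in self.sample_ids})

    def abundance_matrix(self, species: list[str] | None = None) -> pd.DataFrame:
        """Samples × species matrix of percent abundances (missing -> 0)."""
        cols = list(species) if species is not None else self.species_index
        mat = np.zeros((len(self.profiles), len(cols)))
        col_idx = {s: j for j, s in enumerate(cols)}
        for i, p in enumerate(self.profiles):
            for lin, ab in p.species().items():
                j = col_idx.get(lin)
                if j is not None:
                    mat[i, j] = ab
        return pd.DataFrame(mat, index=self.sample_ids, columns=cols)

    def count_matrix(self, species: list[str], total_reads: int | None = None) -> pd.DataFrame:
        """Samples × species integer count matrix.

        Uses stored counts where available, otherwise estimates them
        from abundances via :func:`estimate_counts` (requires
        ``total_reads`` on the profile or as an argument).
        """
        rows = []
        for p in self.profiles:
            if p.counts is not None:
                row = {lin: p.counts.get(lin, 0) for lin in species}
            else:
                tr = p.total_reads if p.total_reads is not None else total_reads
                counts = estimate_counts(p, tr)
                row = {lin: counts.get(lin, 0) for lin in species}
            rows.append(row)
        return pd.DataFrame(rows, index=self.sample_ids, columns=species).astype(int)

    def subset(self, sample_ids: list[str]) -> "Cohort":
        keep = set(sample_ids)
        profiles = [p for p in self.profiles if p.sample_id in keep]
        meta = {sid: m for sid, m in self.metadata.items() if sid in keep}
        return Cohort(profiles, meta)


# ---------------------------------------------------------------------------
# I/O

def read_merged_profile_table(path, rank: str = "species",
                              metadata: dict[str, SampleMetadata] | None = None) -> Cohort:
    """Read a MetaPhlAn-style merged abundance table.

    Only rows whose deepest rank equals ``rank`` are retained (plus the
    reserved ``UNCLASSIFIED`` row, if present).  Values are kept on the
    percent scale as given.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    with open(path) as fh:  # pandas mangles duplicate headers, so check them raw
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dups = sorted({c for c in header if header.count(c) > 1})
    if dups:
        raise ValueError(f"duplicate sample columns: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.duplicated().any():
        raise ValueError("duplicate lineage rows in table")
    keep: list[str] = []
    for line_no, lin in enumerate(df.index, start=2):
        if lin == UNCLASSIFIED:
            keep.append(lin)
            continue
        try:
            deepest = lineage_rank(lin)
        except LineageParseError as exc:
            raise LineageParseError(f"line {line_no}: {exc}") from exc
        if deepest == rank:
            keep.append(lin)
    if not [k for k in keep if k != UNCLASSIFIED]:
        warnings.warn(f"no rows at rank {rank!r} in {path}", stacklevel=2)
    sub = df.loc[keep]
    if (sub.values < 0).any():
        bad = sub.index[(sub.values < 0).any(axis=1)][0]
        raise ValueError(f"negative abundance in row {bad!r}")
    profiles = []
    for sample in sub.columns:
        col = sub[sample]
        abund = {lin: float(v) for lin, v in col.items() if v > 0 or lin == UNCLASSIFIED}
        profiles.append(TaxonProfile(sample_id=str(sample), abundances=abund))
    return Cohort(profiles, metadata)


def write_merged_profile_table(cohort: Cohort, path) -> None:
    """Write the cohort's species profiles as a merged table (inverse of the reader)."""
    lineages: list[str] = sorted({lin for p in cohort.profiles for lin in p.abundances})
    data = {p.sample_id: [p.abundances.get(lin, 0.0) for lin in lineages]
            for p in cohort.profiles}
    df = pd.DataFrame(data, index=pd.Index(lineages, name="clade_name"))
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_metadata_table(meta_path, exposures_path=None) -> dict[str, SampleMetadata]:
    """Read sample metadata (and optionally an exposures table) from TSV.

    Columns: ``sample_id, subject_id, age_months, cohort, status``;
    exposures: ``subject_id, age_months, antibiotic_class``.
    """
    mdf = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str, "subject_id": str},
                      float_precision="round_trip")
    exposures_by_subject: dict[str, list[tuple[float, str]]] = {}
    if exposures_path is not None:
        edf = pd.read_csv(exposures_path, sep="\t", dtype={"subject_id": str},
                          float_precision="round_trip")
        for _, row in edf.iterrows():
            exposures_by_subject.setdefault(row["subject_id"], []).append(
                (float(row["age_months"]), str(row["antibiotic_class"])))
    out: dict[str, SampleMetadata] = {}
    for _, row in mdf.iterrows():
        sid = str(row["sample_id"])
        out[sid] = SampleMetadata(
            sample_id=sid,
            subject_id=str(row["subject_id"]),
            age_months=float(row["age_months"]),
            cohort=str(row.get("cohort", "")),
            disease_status=str(row.get("status", "nonCF")),
            exposures=sorted(exposures_by_subject.get(str(row["subject_id"]), [])),
        )
    return out


def write_metadata_table(cohort: Cohort, meta_path, exposures_path=None) -> None:
    rows = []
    for sid in cohort.sample_ids:
        m = cohort.metadata[sid]
        rows.append({"sample_id": sid, "subject_id": m.subject_id,
                     "age_months": m.age_months, "cohort": m.cohort, "status": m.disease_status})
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False, float_format="%.17g")
    if exposures_path is not None:
        erows = []
        seen_subjects = set()
        for sid in cohort.sample_ids:
            m = cohort.metadata[sid]
            if m.subject_id in seen_subjects:
                continue
            seen_subjects.add(m.subject_id)
            for age, cls in m.exposures:
                erows.append({"subject_id": m.subject_id, "age_months": age,
                              "antibiotic_class": cls})
        pd.DataFrame(erows, columns=["subject_id", "age_months", "antibiotic_class"]).to_csv(
            exposures_path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Operations

def collapse_rank(cohort: Cohort, rank: str) -> pd.DataFrame:
    """Sum species abundances within each ancestor taxon at ``rank``.

    Returns a taxa × samples DataFrame.  Per-sample totals are
    preserved: taxa whose lineage does not record the requested rank are
    grouped under ``"unassigned"``.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    if RANKS.index(rank) > RANKS.index("species"):  # pragma: no cover - species is deepest
        raise ValueError("rank deeper than stored depth")
    acc: dict[str, dict[str, float]] = {}
    for p in cohort.profiles:
        for lin, ab in p.species().items():
            name = lineage_name_at(lin, rank)
            if name is None:
                name = "unassigned"
            acc.setdefault(name, {})[p.sample_id] = acc.setdefault(name, {}).get(p.sample_id, 0.0) + ab
    df = pd.DataFrame(acc).T.reindex(columns=cohort.sample_ids).fillna(0.0)
    return df.sort_index()


def shannon_diversity(profile: TaxonProfile) -> float:
    """Shannon diversity H = −Σ p_i ln p_i over species, renormalized to sum 1."""
    vals = np.array([ab for ab in profile.species().values() if ab > 0], dtype=float)
    if vals.size == 0 or vals.sum() <= 0:
        raise ValueError(f"all-zero profile {profile.sample_id}")
    p = vals / vals.sum()
    return float(-(p * np.log(p)).sum())


def bin_by_age(cohort: Cohort, width_months: float = 3.0) -> list[AgeBin]:
    """Partition samples into half-open age bins [k·w, (k+1)·w).

    Bins tile [0, max age); every sample lands in exactly one bin.
    Empty leading/intermediate bins are included so that the tiling is
    contiguous.
    """
    if width_months <= 0:
        raise ValueError("width_months must be positive")
    ages = cohort.ages()
    if ages.empty:
        return []
    n_bins = int(math.floor(ages.max() / width_months)) + 1
    bins = [AgeBin(lower=k * width_months, upper=(k + 1) * width_months) for k in range(n_bins)]
    for sid in cohort.sample_ids:
        k = int(math.floor(cohort.metadata[sid].age_months / width_months))
        bins[k].sample_ids.append(sid)
    return bins


def estimate_counts(profile: TaxonProfile, total_reads: int | None = None) -> dict[str, int]:
    """Estimate per-lineage read counts from percent abundances.

    ``count_i = round(abundance_i / 100 × total_reads)``; the
    unclassified remainder absorbs the rest, so Σ counts ≤ total_reads
    up to rounding.
    """
    if profile.counts is not None:
        return dict(profile.counts)
    tr = total_reads if total_reads is not None else profile.total_reads
    if tr is None:
        raise ValueError(f"sample {profile.sample_id}: counts requested but no total_reads available")
    if tr <= 0:
        raise ValueError("total_reads must be positive")
    return {lin: int(round(ab / 100.0 * tr)) for lin, ab in profile.species().items()}
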