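"""Count-based clade-specific marker-gene detection.

Intra-species clades (the motivating case is *Faecalibacterium
prausnitzii* clades A–L) are defined by disjoint sets of clade-specific
marker genes.  Metagenomic reads aligned to the markers provide the
evidence: alignments are filtered (no multimapping, ≥ 95% identity,
≥ 50% of the read aligned, MAPQ ≥ 20), a marker is present when it
retains at least 25 reads, and a clade is called present when at least
10% of its markers are present.  Consensus sequences are built from
per-position pileups with the major allele, masking low-coverage and
ambiguous positions and the first/last 10 bases of each gene.

Alignment records arrive as tabular data (``read_id, marker_id,
percent_identity, aligned_fraction, mapq, multimapping``) exported from
any aligner; pileups as ``marker_id, position, A, C, G, T`` tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from miage.phases import assign_phase
from miage.profiles import SampleMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerAlignmentRecord",
    "CladeScheme",
    "CladeCall",
    "filter_alignments",
    "marker_presence",
    "call_clades",
    "consensus_from_pileup",
    "clade_richness",
    "clade_richness_compare",
    "clade_prevalence_test",
    "read_alignments_tsv",
    "read_pileups_tsv",
    "write_consensus_fasta",
]

ALIGNMENT_COLUMNS = ["read_id", "marker_id", "percent_identity",
                     "aligned_fraction", "mapq", "multimapping"]

MIN_IDENTITY = 95.0
MIN_ALIGNED_FRACTION = 0.5
MIN_MAPQ = 20
MIN_READS_PER_MARKER = 25
MIN_MARKER_FRACTION = 0.10


@dataclass
class MarkerAlignmentRecord:
    read_id: str
    marker_id: str
    percent_identity: float
    aligned_fraction: float
    mapq: int
    multimapping: bool

    def __post_init__(self) -> None:
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity must be in [0, 100]")
        if not 0 <= self.aligned_fraction <= 1:
            raise ValueError("aligned_fraction must be in [0, 1]")
        if self.mapq < 0:
            raise ValueError("mapq must be non-negative")


@dataclass
class CladeScheme:
    """Clade → marker-gene map with marker lengths.

    Marker sets must be non-empty and disjoint across clades (a shared
    marker would make the per-marker read threshold ambiguous).
    """

    clades: dict[str, set[str]]
    marker_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for clade, markers in self.clades.items():
            if not markers:
                raise ValueError(f"clade {clade!r} has an empty marker set")
            for m in markers:
                if m in seen:
                    raise ValueError(f"marker {m!r} shared by clades {seen[m]!r} and {clade!r}")
                seen[m] = clade

    @property
    def markers(self) -> set[str]:
        return {m for ms in self.clades.values() for m in ms}

    @classmethod
    def from_tsv(cls, path, lengths: dict[str, int] | None = None) -> "CladeScheme":
        df = pd.read_csv(path, sep="\t", dtype=str)
        clades: dict[str, set[str]] = {}
        for _, row in df.iterrows():
            clades.setdefault(row["clade_id"], set()).add(row["marker_id"])
        return cls(clades, lengths or {})


@dataclass
class CladeCall:
    sample_id: str
    clade_id: str
    markers_detected: int
    markers_total: int
    present: bool

    @property
    def fraction(self) -> float:
        return self.markers_detected / self.markers_total


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        missing = set(ALIGNMENT_COLUMNS) - set(records.columns)
        if missing:
            raise ValueError(f"alignment table missing columns {sorted(missing)}")
        return records
    return pd.DataFrame([vars(r) for r in records], columns=ALIGNMENT_COLUMNS)


def filter_alignments(records) -> pd.DataFrame:
    """Apply the four alignment filters.

    A record is retained iff it is not multimapping, identity ≥ 95%,
    aligned fraction of the read ≥ 0.5, and MAPQ ≥ 20.  Discard counts
    per reason are logged.
    """
    df = _records_frame(records)
    multim = df["multimapping"].astype(bool)
    low_id = df["percent_identity"] < MIN_IDENTITY
    short = df["aligned_fraction"] < MIN_ALIGNED_FRACTION
    low_q = df["mapq"] < MIN_MAPQ
    keep = ~(multim | low_id | short | low_q)
    logger.info("filter_alignments: %d/%d retained (multimapping=%d, identity<95=%d, "
                "aligned<50%%=%d, mapq<20=%d)", int(keep.sum()), len(df),
                int(multim.sum()), int(low_id.sum()), int(short.sum()), int(low_q.sum()))
    return df.loc[keep].reset_index(drop=True)


def marker_presence(filtered, min_reads: int = MIN_READS_PER_MARKER) -> dict[str, int]:
    """Markers with at least ``min_reads`` filtered reads, with their counts."""
    df = _records_frame(filtered)
    if df.empty:
        return {}
    counts = df.groupby("marker_id").size()
    return {m: int(c) for m, c in counts.items() if c >= min_reads}


def call_clades(presence: dict[str, int], scheme: CladeScheme,
                sample_id: str = "", min_fraction: float = MIN_MARKER_FRACTION
                ) -> list[CladeCall]:
    """Call clade presence from marker presence.

    A clade is present when at least ``min_fraction`` (default 10%) of
    its markers are present.  Markers seen in the data but absent from
    the scheme trigger a warning and are ignored.
    """
    unknown = set(presence) - scheme.markers
    if unknown:
        warnings.warn(f"{len(unknown)} markers not in the clade scheme were ignored",
                      stacklevel=2)
    calls = []
    for clade in sorted(scheme.clades):
        markers = scheme.clades[clade]
        detected = sum(1 for m in markers if m in presence)
        frac = detected / len(markers)
        calls.append(CladeCall(sample_id=sample_id, clade_id=clade,
                               markers_detected=detected, markers_total=len(markers),
                               present=frac >= min_fraction))
    return calls


def consensus_from_pileup(pileup: pd.DataFrame, marker_length: int | None = None,
                          min_cov: int = 5, min_margin: int = 5,
                          end_mask: int = 10) -> str:
    """Masked major-allele consensus from a per-position pileup.

    ``pileup`` holds 0-based ``position`` and allele counts ``A, C, G,
    T`` for one marker.  A position gets the major allele unless its
    coverage is below ``min_cov``, the major allele exceeds the minor
    by fewer than ``min_margin`` counts (ties count as margin 0), or it
    lies within ``end_mask`` bases of either gene end — those become N.
    """
    if marker_length is None:
        if pileup.empty:
            raise ValueError("marker_length required for an empty pileup")
        marker_length = int(pileup["position"].max()) + 1
    seq = np.full(marker_length, "N", dtype="<U1")
    if pileup.empty:
        warnings.warn("empty pileup; returning all-N consensus", stacklevel=2)
        return "".join(seq)
    bases = np.array(["A", "C", "G", "T"])
    counts = pileup[["A", "C", "G", "T"]].values.astype(int)
    positions = pileup["position"].values.astype(int)
    coverage = counts.sum(axis=1)
    order = np.sort(counts, axis=1)
    major, minor = order[:, -1], order[:, -2]
    ok = (coverage >= min_cov) & (major - minor >= min_margin) & (major > minor)
    idx = counts.argmax(axis=1)
    for pos, good, b in zip(positions, ok, bases[idx]):
        if good:
            seq[pos] = b
    if end_mask > 0:
        seq[:end_mask] = "N"
        seq[marker_length - end_mask:] = "N"
    return "".join(seq)


# ---------------------------------------------------------------------------
# Cohort-level summaries

def clade_richness(calls_by_sample: dict[str, list[CladeCall]],
                   metadata: dict[str, SampleMetadata] | None = None,
                   phase: str | None = None) -> pd.DataFrame:
    """Number of clades present per sample, with phase/status annotation."""
    rows = []
    for sid, calls in calls_by_sample.items():
        richness = sum(c.present for c in calls)
        row = {"sample_id": sid, "richness": richness}
        if metadata is not None and sid in metadata:
            md = metadata[sid]
            row["subject_id"] = md.subject_id
            row["disease_status"] = md.disease_status
            row["phase"] = assign_phase(md.age_months)
        rows.append(row)
    df = pd.DataFrame(rows)
    if phase is not None and "phase" in df.columns:
        df = df[df["phase"] == phase].reset_index(drop=True)
    return df


def clade_richness_compare(richness: pd.DataFrame, group_col: str = "disease_status",
                           n_permutations: int = 999, seed: int = 0
                           ) -> tuple[float, float, float]:
    """Compare mean clade richness between two groups.

    Subject-level permutation on per-subject mean richness — the
    permutation analog of a Poisson-response model grouped by
    individual.  Returns (mean_a, mean_b, p) for the two group labels
    in sorted order.
    """
    groups = sorted(richness[group_col].unique())
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    per_subj = richness.groupby(["subject_id", group_col])["richness"].mean().reset_index()
    vals = per_subj["richness"].values.astype(float)
    labels = per_subj[group_col].values
    a_mask = labels == groups[0]
    mean_a, mean_b = vals[a_mask].mean(), vals[~a_mask].mean()
    obs = abs(mean_a - mean_b)
    rng = np.random.default_rng(seed)
    n_a = int(a_mask.sum())
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(vals))
        stat = abs(vals[perm[:n_a]].mean() - vals[perm[n_a:]].mean())
        exceed += stat >= obs - 1e-12
    return float(mean_a), float(mean_b), float((1 + exceed) / (n_permutations + 1))


def clade_prevalence_test(calls_by_sample: dict[str, list[CladeCall]],
                          groups: dict[str, str], alternative: str = "two-sided",
                          fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Per-clade prevalence comparison across sample groups.

    With two groups, Fisher's exact test on the present/absent × group
    contingency table (``alternative`` is passed through to the test);
    with three or more ordered groups (e.g. developmental stages), a
    chi-squared test.  Benjamini–Hochberg q-values and an FDR ≤ 0.05
    flag are attached.
    """
    from miage.phases import bh_adjust

    group_labels = sorted(set(groups.values()))
    samples_by_group = {g: [s for s, lbl in groups.items() if lbl == g] for g in group_labels}
    if len(group_labels) < 2 or any(len(v) == 0 for v in samples_by_group.values()):
        raise ValueError("a group has zero samples; need at least two non-empty groups")
    clade_ids = sorted({c.clade_id for calls in calls_by_sample.values() for c in calls})
    rows = []
    for clade in clade_ids:
        present = {sid: any(c.present for c in calls if c.clade_id == clade)
                   for sid, calls in calls_by_sample.items()}
        table = np.array([[sum(present.get(s, False) for s in samples_by_group[g]),
                           sum(not present.get(s, False) for s in samples_by_group[g])]
                          for g in group_labels])
        if len(group_labels) == 2:
            _, p = stats.fisher_exact(table, alternative=alternative)
        else:
            if table.sum(axis=0).min() == 0:  # degenerate margin: no association testable
                p = 1.0
            else:
                _, p, _, _ = stats.chi2_contingency(table)
        rows.append({"clade_id": clade, "p_value": float(p),
                     **{f"present_{g}": int(table[i, 0]) for i, g in enumerate(group_labels)},
                     **{f"absent_{g}": int(table[i, 1]) for i, g in enumerate(group_labels)}})
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].values)
    out["fdr_significant"] = out["q_value"] <= fdr_alpha
    return out


# ---------------------------------------------------------------------------
# I/O

def read_alignments_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(ALIGNMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"alignment TSV missing columns {sorted(missing)}")
    df["multimapping"] = df["multimapping"].astype(bool)
    return df


def read_pileups_tsv(path) -> dict[str, pd.DataFrame]:
    """Read a pileup TSV (marker_id, position, A, C, G, T) keyed by marker."""
    df = pd.read_csv(path, sep="\t")
    return {m: g.drop(columns="marker_id").reset_index(drop=True)
            for m, g in df.groupby("marker_id")}


def write_consensus_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
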