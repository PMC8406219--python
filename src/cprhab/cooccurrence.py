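"""Marker-gene species groups and host-symbiont co-occurrence analyses.

Ribosomal protein S3 (rpS3) sequences assembled from metagenomes are
clustered greedily into "species groups" at 99% global identity, a species
proxy that lets samples be profiled for which CPR symbionts (e.g.
Saccharibacteria) co-occur with which candidate host taxa (e.g.
Actinobacteria).  Downstream analyses compute per-sample richness ratios,
exclusive co-occurrence labels, scaled coverage profiles, coverage-profile
correlations, and stringent-read relative abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

UNDEFINED = "UNDEFINED"

PRESENCE_FLOOR = 0.10           # minimum covered fraction for presence calls
SUBSAMPLE_TRIGGER = 100_000_000  # read pairs above which runs are subsampled
SUBSAMPLE_TARGET = 36_000_000    # average read count across experiments


class CooccurrenceError(ValueError):
    pass


def global_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity from a global alignment with free terminal gaps.

    Scoring: match +1, mismatch -1, gap -1 (linear); terminal gaps are free.
    Identity = matches / alignment length where the length counts every
    column of the aligned (overlapping) region, internal gaps included, and
    terminal overhangs excluded.  Returns 0.0 when the optimal alignment has
    no overlap.  Symmetric in its arguments: when several alignments tie on
    score the traceback is made canonical by ordering the two sequences
    lexicographically first.
    """
    if not seq_a or not seq_b:
        raise CooccurrenceError("global_identity requires nonempty sequences")
    if seq_b < seq_a:
        seq_a, seq_b = seq_b, seq_a
    a = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode(), dtype=np.uint8)
    la, lb = len(a), len(b)
    H = np.zeros((la + 1, lb + 1), dtype=np.int32)
    js = np.arange(1, lb + 1)
    for i in range(1, la + 1):
        s = np.where(b == a[i - 1], 1, -1)
        m = np.maximum(H[i - 1, :-1] + s, H[i - 1, 1:] - 1)
        # horizontal gaps via max-plus prefix scan:
        # H[i,j] = max_{k<=j}(m[k] - (j-k)) = cummax(m[k]+k) - j
        H[i, 1:] = np.maximum.accumulate(m + js) - js
    # free terminal gaps: best score over last row and last column
    last = np.concatenate([H[la, :], H[:, lb]])
    best = int(last.max())
    # deterministic start cell: prefer larger i+j, then larger i
    cells = [(la, j) for j in range(lb + 1)] + [(i, lb) for i in range(la + 1)]
    start = max((c for c in cells if H[c] == best),
                key=lambda c: (c[0] + c[1], c[0]))
    i, j = start
    matches = length = 0
    while i > 0 and j > 0:
        diag = H[i - 1, j - 1] + (1 if a[i - 1] == b[j - 1] else -1)
        if H[i, j] == diag:
            matches += int(a[i - 1] == b[j - 1])
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] - 1:
            i -= 1
        else:
            j -= 1
        length += 1
    return matches / length if length else 0.0


@dataclass
class SpeciesGroup:
    group_id: str
    centroid_id: str
    centroid_sequence: str
    members: list[str] = field(default_factory=list)
    taxonomy: tuple[str, str] = ("unknown", "unknown")


def cluster_species_groups(sequences: dict[str, str],
                           threshold: float = 0.99) -> list[SpeciesGroup]:
    """Greedy length-sorted clustering of marker proteins at >= threshold identity.

    Sequences are visited longest-first (ties broken by id); each joins the
    FIRST existing centroid with identity >= threshold (inclusive), else
    founds a new group whose centroid it becomes.  Deterministic: permuting
    the input dict never changes the partition.
    """
    if not sequences:
        raise CooccurrenceError("no sequences to cluster")
    order = sorted(sequences, key=lambda sid: (-len(sequences[sid]), sid))
    groups: list[SpeciesGroup] = []
    for sid in order:
        seq = sequences[sid]
        for grp in groups:
            if global_identity(seq, grp.centroid_sequence) >= threshold:
                grp.members.append(sid)
                break
        else:
            groups.append(SpeciesGroup(
                group_id=f"sg{len(groups):04d}", centroid_id=sid,
                centroid_sequence=seq, members=[sid]))
    return groups


def richness_ratio(sample: pd.DataFrame, numerator_lineage: str,
                   denominator_lineage: str):
    """Distinct species groups of one lineage per group of another in a sample.

    UNDEFINED when the denominator lineage is undetected (such samples are
    excluded from ratio tables but flagged for absence analysis).
    """
    counts = sample.groupby("lineage")["group_id"].nunique()
    num = int(counts.get(numerator_lineage, 0))
    den = int(counts.get(denominator_lineage, 0))
    if den == 0:
        return UNDEFINED
    return num / den


def richness_table(samples: pd.DataFrame, numerator_lineage: str,
                   denominator_lineage: str) -> pd.DataFrame:
    rows = []
    for sid, sub in samples.groupby("sample_id"):
        r = richness_ratio(sub, numerator_lineage, denominator_lineage)
        rows.append({"sample_id": sid,
                     "richness_ratio": np.nan if r == UNDEFINED else r,
                     "denominator_absent": r == UNDEFINED})
    return pd.DataFrame(rows)


def classify_exclusive_cooccurrence(samples: pd.DataFrame, lineage_a: str,
                                    lineage_b: str
                                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label samples by exclusivity of lineage_a/lineage_b co-occurrence.

    exclusive-species: exactly one species group of each lineage in the
    sample.  exclusive-order: exactly one group of lineage_a with two or
    more groups of lineage_b that all share one (known) order-level label.
    Otherwise none.  Also returns the linkage table of all co-occurring
    (a, b) group pairs per sample.
    """
    labels = []
    pairs = []
    for sid, sub in samples.groupby("sample_id"):
        a = sub.loc[sub["lineage"] == lineage_a]
        b = sub.loc[sub["lineage"] == lineage_b]
        a_groups = sorted(a["group_id"].unique())
        b_groups = sorted(b["group_id"].unique())
        label = "none"
        if len(a_groups) == 1 and len(b_groups) == 1:
            label = "exclusive-species"
        elif len(a_groups) == 1 and len(b_groups) >= 2:
            orders = set(b.drop_duplicates("group_id")["order"])
            if len(orders) == 1 and "unknown" not in orders:
                label = "exclusive-order"
        labels.append({"sample_id": sid, "label": label,
                       "n_a": len(a_groups), "n_b": len(b_groups)})
        for ga in a_groups:
            for gb in b_groups:
                pairs.append({"sample_id": sid, "group_a": ga, "group_b": gb})
    return (pd.DataFrame(labels, columns=["sample_id", "label", "n_a", "n_b"]),
            pd.DataFrame(pairs, columns=["sample_id", "group_a", "group_b"]))


def taxon_label(row: pd.Series) -> str:
    """Order-level label with fallback to the lowest available rank."""
    order = row.get("order")
    if order and not pd.isna(order) and order != "unknown":
        return str(order)
    lineage = row.get("lineage")
    if lineage and not pd.isna(lineage) and lineage != "unknown":
        return f"{lineage} (unresolved order)"
    return "unknown"


def scaled_coverage_profile(samples: pd.DataFrame,
                            covered_fraction_floor: float = PRESENCE_FLOOR
                            ) -> pd.DataFrame:
    """Log10-scaled relative coverage per taxon (order level) and sample.

    Detections below the covered-fraction floor are dropped before
    summation.  Relative coverage per (taxon, sample) is the sum of member
    mean coverages; values are divided by the smallest positive coverage
    across the whole matrix and log10-transformed, so the minimum cell maps
    to exactly 0.  Absent cells are NaN.
    """
    kept = samples.loc[samples["covered_fraction"] >= covered_fraction_floor].copy()
    if kept.empty:
        raise CooccurrenceError("no detections at or above the covered-fraction floor")
    kept["taxon"] = kept.apply(taxon_label, axis=1)
    mat = kept.pivot_table(index="taxon", columns="sample_id",
                           values="mean_coverage", aggfunc="sum")
    vals = mat.values
    positive = vals[np.isfinite(vals) & (vals > 0)]
    if positive.size == 0:
        raise CooccurrenceError("coverage matrix has no positive entries")
    scaled = np.log10(vals / positive.min())
    return pd.DataFrame(scaled, index=mat.index, columns=mat.columns)


def correlate_coverage_profiles(matrix: pd.DataFrame,
                                focal_taxon: str) -> pd.DataFrame:
    """Pearson correlation of every taxon's coverage profile with a focal taxon.

    Absent cells (NaN) count as zero coverage.  Taxa with constant profiles
    have undefined correlation and are excluded with a flag.  Requires at
    least three samples.
    """
    if matrix.shape[1] < 3:
        raise CooccurrenceError("correlation requires >= 3 samples")
    if focal_taxon not in matrix.index:
        raise CooccurrenceError(f"focal taxon {focal_taxon!r} not in matrix")
    filled = matrix.fillna(0.0)
    focal = filled.loc[focal_taxon].values
    rows = []
    for taxon in filled.index:
        if taxon == focal_taxon:
            continue
        vec = filled.loc[taxon].values
        constant = np.ptp(vec) == 0 or np.ptp(focal) == 0
        if constant:
            rows.append({"taxon": taxon, "pearson_r": np.nan,
                         "excluded_constant": True})
        else:
            r, _ = stats.pearsonr(focal, vec)
            rows.append({"taxon": taxon, "pearson_r": float(r),
                         "excluded_constant": False})
    out = pd.DataFrame(rows, columns=["taxon", "pearson_r", "excluded_constant"])
    return out.sort_values("pearson_r", ascending=False,
                           na_position="last").reset_index(drop=True)


def relative_abundance(mapping: pd.DataFrame,
                       presence_floor: float = PRESENCE_FLOOR
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stringent-read relative abundance with presence and subsampling rules.

    Abundance = reads mapped at >= 99% identity / total quality-filtered
    reads.  A genome is called absent in a sample when less than 10% of its
    sequence length is covered, regardless of mapped counts.  Runs whose
    read-pair count exceeds 100 million are flagged for subsampling to the
    across-experiment average of 36 million reads.  The representative
    sample per genome is the one with the highest abundance among present
    samples (ties: lexicographically smallest sample id).
    """
    if (mapping["total_reads"] <= 0).any():
        raise CooccurrenceError("total_reads must be positive")
    if ((mapping["strict_mapped"] < 0)
            | (mapping["strict_mapped"] > mapping["total_reads"])).any():
        raise CooccurrenceError("strict_mapped must lie in [0, total_reads]")
    out = mapping.copy()
    out["present"] = out["covered_fraction"] >= presence_floor
    abundance = out["strict_mapped"] / out["total_reads"]
    out["relative_abundance"] = abundance.where(out["present"])
    if "read_pairs" in out.columns:
        out["subsample"] = out["read_pairs"] > SUBSAMPLE_TRIGGER
        out["subsample_target"] = np.where(out["subsample"],
                                           SUBSAMPLE_TARGET, pd.NA)
    reps = []
    for gid, sub in out.groupby("genome_id"):
        present = sub.loc[sub["present"]].sort_values(
            ["relative_abundance", "sample_id"], ascending=[False, True])
        if len(present):
            reps.append({"genome_id": gid,
                         "representative_sample": present.iloc[0]["sample_id"],
                         "representative_abundance":
                             float(present.iloc[0]["relative_abundance"])})
    return out, pd.DataFrame(
        reps, columns=["genome_id", "representative_sample",
                       "representative_abundance"])
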