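"""Genome quality control, dereplication, and proteome-size summaries.

Completeness and contamination are estimated from a 43-gene single-copy
marker inventory chosen for CPR bacteria (which have lineage-specific losses
of many universal markers): completeness = 100 * markers_present / 43 and
duplication = 100 * markers_duplicated / 43.  Genomes pass QC at >= 70%
completeness and <= 10% duplication; the passing set is then dereplicated at
99% average nucleotide identity (ANI) using a greedy, deterministic
procedure over an externally supplied ANI matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import N_MARKERS, N_RP16


class ValidationError(ValueError):
    pass


def _validate_records(records: pd.DataFrame) -> None:
    required = {"genome_id", "markers_present", "markers_duplicated"}
    missing = required - set(records.columns)
    if missing:
        raise ValidationError(f"genome table missing columns: {sorted(missing)}")
    if (records["markers_present"] > N_MARKERS).any():
        bad = records.loc[records["markers_present"] > N_MARKERS, "genome_id"]
        raise ValidationError(
            f"markers_present > {N_MARKERS} for: {list(bad)}")
    if (records["markers_duplicated"] > records["markers_present"]).any():
        raise ValidationError("markers_duplicated exceeds markers_present")
    if (records["markers_present"] < 0).any():
        raise ValidationError("negative marker count")


def marker_completeness(records: pd.DataFrame) -> pd.DataFrame:
    """Recompute completeness/duplication percentages from marker counts.

    The marker-derived estimate is authoritative even when the input table
    carries its own columns, so synthetic and real inputs behave identically.
    """
    out = records.copy()
    out["completeness"] = 100.0 * out["markers_present"] / N_MARKERS
    out["duplication"] = 100.0 * out["markers_duplicated"] / N_MARKERS
    return out


def filter_genome_set(records: pd.DataFrame, min_completeness: float = 70.0,
                      max_duplication: float = 10.0) -> pd.DataFrame:
    """Retain genomes with completeness >= min and duplication <= max.

    Both bounds are inclusive; input order is preserved.
    """
    _validate_records(records)
    recs = marker_completeness(records)
    keep = ((recs["completeness"] >= min_completeness)
            & (recs["duplication"] <= max_duplication))
    return recs.loc[keep].reset_index(drop=True)


def genome_score(record: pd.Series) -> tuple:
    """Deterministic ordering score for dereplication representatives.

    Higher completeness and lower duplication win (completeness minus five
    times duplication); ties break toward larger predicted proteomes, then
    lexicographically smaller genome id.  The published workflow delegates
    this choice to dRep's internal scoring, which is not printed; this
    explicit score keeps representative choice reproducible.
    """
    score = record["completeness"] - 5.0 * record["duplication"]
    return (-score, -record.get("orf_count", 0), record["genome_id"])


@dataclass
class DereplicationResult:
    clusters: dict[str, list[str]]  # representative -> members (incl. itself)
    retained: list[str]

    @property
    def membership(self) -> dict[str, str]:
        return {m: rep for rep, members in self.clusters.items()
                for m in members}


def dereplicate(records: pd.DataFrame, ani: pd.DataFrame,
                threshold: float = 0.99) -> DereplicationResult:
    """Greedy ANI dereplication.

    Genomes are visited in score order (best first); each genome joins the
    first already-chosen representative with ANI >= threshold, else founds a
    new cluster.  Every member therefore has ANI >= threshold to its
    representative (but members of one cluster need not all be mutually
    above threshold, as in any greedy centroid scheme).
    """
    _validate_records(records)
    recs = marker_completeness(records)
    ids = list(recs["genome_id"])
    for gid in ids:
        if gid not in ani.index or gid not in ani.columns:
            raise ValidationError(f"ANI matrix missing genome {gid}")
    order = sorted(ids, key=lambda g: genome_score(
        recs.loc[recs["genome_id"] == g].iloc[0]))
    clusters: dict[str, list[str]] = {}
    reps: list[str] = []
    for gid in order:
        placed = False
        for rep in reps:
            pair = ani.at[gid, rep]
            if pd.isna(pair):
                raise ValidationError(f"ANI matrix missing pair ({gid}, {rep})")
            if pair >= threshold:
                clusters[rep].append(gid)
                placed = True
                break
        if not placed:
            clusters[gid] = [gid]
            reps.append(gid)
    return DereplicationResult(clusters=clusters, retained=reps)


def rp16_eligible(rp16_present: int, min_markers: int = 8) -> bool:
    """Concatenated ribosomal-protein tree eligibility: >= 8 of 16 markers."""
    if not 0 <= rp16_present <= N_RP16:
        raise ValidationError(f"rp16_present={rp16_present} outside [0, {N_RP16}]")
    return rp16_present >= min_markers


def proteome_size_by_threshold(records: pd.DataFrame,
                               thresholds: list[float],
                               group_col: str = "habitat_broad") -> pd.DataFrame:
    """Predicted proteome size (ORF count) at rising completeness thresholds.

    At each threshold t, genomes with completeness >= t are grouped by
    habitat; groups that lose all genomes are reported as NaN rows rather
    than silently dropped, so downstream tables keep a fixed shape.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValidationError("thresholds must be sorted ascending")
    if records.empty:
        return pd.DataFrame(columns=["threshold", group_col, "n_genomes",
                                     "mean_orfs", "median_orfs"])
    recs = marker_completeness(records)
    groups = sorted(recs[group_col].unique())
    rows = []
    for t in thresholds:
        sub = recs.loc[recs["completeness"] >= t]
        for g in groups:
            orfs = sub.loc[sub[group_col] == g, "orf_count"]
            rows.append({
                "threshold": t, group_col: g, "n_genomes": len(orfs),
                "mean_orfs": float(orfs.mean()) if len(orfs) else np.nan,
                "median_orfs": float(orfs.median()) if len(orfs) else np.nan,
            })
    return pd.DataFrame(rows)
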