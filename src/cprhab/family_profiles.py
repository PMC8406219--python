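"""Protein-family presence/absence profiles and proteome similarity.

Families are de-novo protein clusters; a family enters the analysis when it
has at least five member sequences across the genome set.  Per-genome copy
number collapses to binary presence.  Proteome similarity between genomes is
the Jaccard distance on family presence, ordinated by classical principal
coordinates (PCoA); families themselves are hierarchically clustered by
their distribution patterns to expose co-distributed modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform


class ProfileError(ValueError):
    pass


@dataclass
class FamilyMatrix:
    """Binary genome x family matrix plus per-family metadata."""
    presence: pd.DataFrame                      # genomes x families, 0/1
    member_count: pd.Series                     # family -> total sequences
    consensus: pd.DataFrame = field(default=None)  # family -> (label, fraction)

    @property
    def genomes(self) -> list[str]:
        return list(self.presence.index)

    @property
    def families(self) -> list[str]:
        return list(self.presence.columns)


def consensus_annotation(annotations: list) -> tuple[str | None, float]:
    """Modal annotation among annotated members, fraction over ALL members.

    Unannotated members (None, NaN, or empty string) vote for no label but
    still count in the denominator, matching per-family annotation
    percentages quoted as "x% of member sequences".  Ties break to the
    lexicographically smallest label.  All-unannotated -> (None, 0.0).
    """
    if len(annotations) == 0:
        raise ProfileError("consensus_annotation of an empty member list")
    labelled = [a for a in annotations
                if a is not None and not pd.isna(a) and str(a) != ""]
    if not labelled:
        return None, 0.0
    counts = pd.Series(labelled).value_counts()
    top = counts.max()
    label = sorted(counts.index[counts == top])[0]
    return label, float(top) / len(annotations)


def build_presence_matrix(memberships: pd.DataFrame,
                          min_members: int = 5,
                          genomes: list[str] | None = None) -> FamilyMatrix:
    """Build the binary presence matrix from a family membership table.

    ``memberships`` has one row per member sequence (family_id, genome_id,
    sequence_id, annotation).  A family is retained when its total member
    SEQUENCE count (not genome count) is >= min_members; presence is binary
    regardless of per-genome copy number.
    """
    dup = memberships.duplicated(subset=["family_id", "sequence_id"])
    if dup.any():
        bad = memberships.loc[dup, ["family_id", "sequence_id"]].iloc[0]
        raise ProfileError(
            f"duplicate (family, sequence) row: {tuple(bad)}")
    if genomes is not None:
        unknown = set(memberships["genome_id"]) - set(genomes)
        if unknown:
            raise ProfileError(f"memberships reference unknown genomes: "
                               f"{sorted(unknown)[:5]}")
    counts = memberships.groupby("family_id").size()
    kept = sorted(counts.index[counts >= min_members])
    sub = memberships[memberships["family_id"].isin(kept)]
    presence = pd.crosstab(sub["genome_id"], sub["family_id"]).clip(upper=1)
    if genomes is not None:
        presence = presence.reindex(index=genomes, columns=kept,
                                    fill_value=0).astype(int)
    else:
        presence = presence.reindex(columns=kept, fill_value=0).astype(int)
    anno_col = "annotation" if "annotation" in sub.columns else None
    cons_rows = []
    for fam in kept:
        members = sub.loc[sub["family_id"] == fam]
        if anno_col:
            label, frac = consensus_annotation(list(members[anno_col]))
        else:
            label, frac = None, 0.0
        cons_rows.append({"family_id": fam, "consensus_annotation": label,
                          "consensus_fraction": frac})
    consensus = pd.DataFrame(
        cons_rows, columns=["family_id", "consensus_annotation",
                            "consensus_fraction"]).set_index("family_id")
    return FamilyMatrix(presence=presence,
                        member_count=counts.loc[kept],
                        consensus=consensus)


def incidence_fractions(matrix: FamilyMatrix,
                        grouping: dict[str, str]) -> pd.DataFrame:
    """Fraction of genomes per group encoding each family (families x groups)."""
    unknown = set(grouping) - set(matrix.genomes)
    if unknown:
        raise ProfileError(f"grouping references unknown genomes: "
                           f"{sorted(unknown)[:5]}")
    missing = set(matrix.genomes) - set(grouping)
    if missing:
        raise ProfileError(f"genomes without a group: {sorted(missing)[:5]}")
    groups = pd.Series(grouping)
    out = {}
    for g in sorted(groups.unique()):
        ids = groups.index[groups == g]
        out[g] = matrix.presence.loc[ids].mean(axis=0)
    return pd.DataFrame(out)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame        # genomes x axes
    variance_fraction: np.ndarray    # per retained (positive) axis
    eigenvalues: np.ndarray          # all eigenvalues, descending
    negative_eigenvalue_sum: float


def jaccard_distances(presence: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard distances between genomes' family presence vectors."""
    zero = presence.sum(axis=1) == 0
    if zero.any():
        raise ProfileError("genomes with zero families: "
                           f"{list(presence.index[zero])}")
    d = pdist(presence.values.astype(bool), metric="jaccard")
    return pd.DataFrame(squareform(d), index=presence.index,
                        columns=presence.index)


def pcoa(dist: pd.DataFrame, n_axes: int | None = None) -> OrdinationResult:
    """Classical metric scaling (Gower double-centering + eigendecomposition).

    Variance fractions are computed over the sum of POSITIVE eigenvalues
    only; the (non-Euclidean) negative part is reported separately rather
    than folded into the denominator, so the convention is explicit.
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ProfileError("PCoA requires >= 3 genomes")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-10 * abs(evals[0])) if evals.size else 0.0
    pos = evals > tol
    lam = evals[pos]
    coords = evecs[:, pos] * np.sqrt(lam)
    if n_axes is not None:
        coords = coords[:, :n_axes]
        lam = lam[:n_axes]
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=dist.index, columns=cols),
        variance_fraction=lam / evals[pos].sum() if pos.any() else lam,
        eigenvalues=evals,
        negative_eigenvalue_sum=float(evals[evals < -tol].sum()),
    )


def jaccard_pcoa(matrix: FamilyMatrix, n_axes: int | None = None) -> OrdinationResult:
    """PCoA of genomes' protein-content Jaccard distances."""
    return pcoa(jaccard_distances(matrix.presence), n_axes=n_axes)


@dataclass
class FamilyClustering:
    leaf_order: list[str]     # family ids in dendrogram order
    linkage: np.ndarray       # scipy linkage matrix
    families: list[str]       # input family order (linkage leaf indices)


def cluster_families(matrix: FamilyMatrix) -> FamilyClustering:
    """Average-linkage hierarchical clustering of family distribution columns.

    Distances are Jaccard over the genome axis (which genomes encode the
    family), the same metric/linkage combination used for clustered
    presence/absence heat maps.  Tie resolution follows scipy's
    deterministic nearest-neighbor-chain ordering.
    """
    fams = matrix.families
    if len(fams) < 2:
        raise ProfileError("cluster_families requires >= 2 families")
    cols = matrix.presence.values.T.astype(bool)
    d = pdist(cols, metric="jaccard")
    Z = hierarchy.linkage(d, method="average")
    order = hierarchy.leaves_list(Z)
    return FamilyClustering(leaf_order=[fams[i] for i in order],
                            linkage=Z, families=list(fams))
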