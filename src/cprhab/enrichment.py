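"""Differential distribution of protein families across habitats.

For each lineage separately, and for each (family, habitat) pair, the
in-group is the lineage's genomes from that habitat and the out-group the
lineage's genomes from all other habitats.  The fold-enrichment ratio is
(k_in/n_in) / (k_out/n_out), flagged EXCLUSIVE when no out-group genome
encodes the family.  Significance is a two-sided Fisher exact test on the
2x2 table, corrected per lineage by Benjamini-Hochberg step-up FDR.
Enriched: ratio >= 5 (or exclusive) at q <= 0.05.  Depleted: encoded by
<= 10% of in-group but >= 50% of out-group genomes at q <= 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .family_profiles import FamilyMatrix

logger = logging.getLogger(__name__)

EXCLUSIVE = "EXCLUSIVE"
UNDEFINED = "UNDEFINED"

# above this total count, exact integer enumeration yields to log-space
_EXACT_N_MAX = 10_000
_LOG_TIE_RTOL = 1e-7


class EnrichmentError(ValueError):
    pass


def enrichment_ratio(k_in: int, n_in: int, k_out: int, n_out: int):
    """Fold-enrichment ratio, or EXCLUSIVE / UNDEFINED sentinels.

    EXCLUSIVE: present in-group, absent out-group (ratio is infinite).
    UNDEFINED: absent on both sides (no information).
    """
    if n_in <= 0 or n_out <= 0:
        raise EnrichmentError("group sizes must be >= 1")
    if not (0 <= k_in <= n_in and 0 <= k_out <= n_out):
        raise EnrichmentError("encoding counts must satisfy 0 <= k <= n")
    if k_out == 0:
        return EXCLUSIVE if k_in > 0 else UNDEFINED
    return (k_in / n_in) / (k_out / n_out)


def _fisher_exact_int(k_in: int, n_in: int, k_out: int, n_out: int) -> float:
    """Two-sided Fisher p by exact integer hypergeometric enumeration.

    Table weights C(n_in, a) * C(n_out, k-a) are exact integers, so the
    "probability <= observed" comparison is free of float ties.
    """
    k = k_in + k_out
    a_min, a_max = max(0, k - n_out), min(n_in, k)
    weights = {a: math.comb(n_in, a) * math.comb(n_out, k - a)
               for a in range(a_min, a_max + 1)}
    w_obs = weights[k_in]
    total = sum(weights.values())
    tail = sum(w for w in weights.values() if w <= w_obs)
    return tail / total


def _fisher_exact_log(k_in: int, n_in: int, k_out: int, n_out: int) -> float:
    """Log-space fallback for very large tables (1e-7 relative tie tolerance)."""
    k = k_in + k_out
    a = np.arange(max(0, k - n_out), min(n_in, k) + 1)
    logw = (_lchoose(n_in, a) + _lchoose(n_out, k - a))
    log_obs = logw[a == k_in][0]
    keep = logw <= log_obs + math.log1p(_LOG_TIE_RTOL)
    m = logw.max()
    return float(np.exp(logw[keep] - m).sum() / np.exp(logw - m).sum())


def _lchoose(n, k):
    from scipy.special import gammaln
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_two_sided(k_in: int, n_in: int, k_out: int, n_out: int) -> float:
    """Two-sided Fisher exact p for the table (k_in, n_in-k_in; k_out, n_out-k_out).

    p sums the hypergeometric probabilities of every table with the same
    margins whose probability does not exceed the observed table's.  Exact
    integer arithmetic is used up to a total of 10,000 observations,
    log-space beyond.
    """
    for v in (k_in, n_in, k_out, n_out):
        if v < 0:
            raise EnrichmentError("negative count in 2x2 table")
    if k_in > n_in or k_out > n_out:
        raise EnrichmentError("encoding counts exceed group sizes")
    if n_in + n_out <= _EXACT_N_MAX:
        return _fisher_exact_int(k_in, n_in, k_out, n_out)
    return _fisher_exact_log(k_in, n_in, k_out, n_out)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, preserving input order.

    q(i) = min_{j: rank(j) >= rank(i)} m * p(j) / rank(j), capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise EnrichmentError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class EnrichmentTable:
    """Per-(family, lineage, habitat) results plus per-lineage summaries."""
    results: pd.DataFrame
    summary: pd.DataFrame


def classify_families(matrix: FamilyMatrix, genomes: pd.DataFrame,
                      ratio_min: float = 5.0, depl_in_max: float = 0.10,
                      depl_out_min: float = 0.50, q_max: float = 0.05,
                      lineage_col: str = "lineage",
                      habitat_col: str = "habitat_broad") -> EnrichmentTable:
    """Classify families as enriched/depleted per lineage and habitat.

    Each lineage is analysed independently and its tests are BH-corrected
    jointly across all its (family, habitat) comparisons, so unevenly
    sampled lineages do not distort each other's FDR.  Lineages observed in
    fewer than two habitats are skipped with a warning.  A family can be
    enriched in one habitat and depleted in another.  Families absent from a
    lineage on both sides of a comparison are uninformative and omitted.
    """
    meta = genomes.set_index("genome_id")
    missing = [g for g in matrix.genomes if g not in meta.index]
    if missing:
        raise EnrichmentError(f"genomes without metadata: {missing[:5]}")
    rows = []
    for lineage, lmeta in meta.loc[matrix.genomes].groupby(lineage_col):
        habitats = sorted(lmeta[habitat_col].unique())
        if len(habitats) < 2:
            logger.warning("lineage %s has <2 habitats; skipped", lineage)
            continue
        sub = matrix.presence.loc[lmeta.index]
        fisher_cache: dict[tuple, float] = {}
        lineage_rows = []
        for habitat in habitats:
            in_mask = (lmeta[habitat_col] == habitat).values
            n_in = int(in_mask.sum())
            n_out = int((~in_mask).sum())
            k_in_vec = sub.values[in_mask].sum(axis=0)
            k_out_vec = sub.values[~in_mask].sum(axis=0)
            for fam, k_in, k_out in zip(matrix.families, k_in_vec, k_out_vec):
                k_in, k_out = int(k_in), int(k_out)
                if k_in == 0 and k_out == 0:
                    continue
                key = (k_in, n_in, k_out, n_out)
                if key not in fisher_cache:
                    fisher_cache[key] = fisher_exact_two_sided(*key)
                ratio = enrichment_ratio(k_in, n_in, k_out, n_out)
                lineage_rows.append({
                    "family_id": fam, "lineage": lineage, "habitat": habitat,
                    "n_in": n_in, "k_in": k_in, "n_out": n_out, "k_out": k_out,
                    "ratio": np.inf if ratio == EXCLUSIVE else float(ratio),
                    "exclusive": ratio == EXCLUSIVE,
                    "p_value": fisher_cache[key],
                })
        if not lineage_rows:
            continue
        ldf = pd.DataFrame(lineage_rows)
        ldf["q_value"] = bh_fdr(ldf["p_value"].values)
        in_frac = ldf["k_in"] / ldf["n_in"]
        out_frac = ldf["k_out"] / ldf["n_out"]
        sig = ldf["q_value"] <= q_max
        enriched = sig & (ldf["exclusive"] | (ldf["ratio"] >= ratio_min))
        depleted = sig & (in_frac <= depl_in_max) & (out_frac >= depl_out_min)
        ldf["classification"] = "not-significant"
        ldf.loc[depleted, "classification"] = "depleted"
        ldf.loc[enriched & ~ldf["exclusive"], "classification"] = "enriched"
        ldf.loc[enriched & ldf["exclusive"], "classification"] = "exclusive-enriched"
        rows.append(ldf)
    if not rows:
        results = pd.DataFrame(columns=[
            "family_id", "lineage", "habitat", "n_in", "k_in", "n_out",
            "k_out", "ratio", "exclusive", "p_value", "q_value",
            "classification"])
        return EnrichmentTable(results=results,
                               summary=_summarize(results))
    results = pd.concat(rows, ignore_index=True)
    return EnrichmentTable(results=results, summary=_summarize(results))


def _summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Unique enriched/depleted family counts per lineage x habitat + overall."""
    rows = []
    enr_classes = ("enriched", "exclusive-enriched")
    if not results.empty:
        for (lineage, habitat), grp in results.groupby(["lineage", "habitat"]):
            rows.append({
                "lineage": lineage, "habitat": habitat,
                "n_enriched": grp.loc[grp["classification"].isin(enr_classes),
                                      "family_id"].nunique(),
                "n_depleted": grp.loc[grp["classification"] == "depleted",
                                      "family_id"].nunique(),
            })
    total_enr = results.loc[results["classification"].isin(enr_classes),
                            "family_id"].nunique() if not results.empty else 0
    total_dep = results.loc[results["classification"] == "depleted",
                            "family_id"].nunique() if not results.empty else 0
    total_any = (results.loc[results["classification"] != "not-significant",
                             "family_id"].nunique()
                 if not results.empty else 0)
    rows.append({"lineage": "ALL", "habitat": "ALL",
                 "n_enriched": total_enr, "n_depleted": total_dep})
    out = pd.DataFrame(rows, columns=["lineage", "habitat",
                                      "n_enriched", "n_depleted"])
    out.attrs["n_differential_unique"] = total_any
    return out
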