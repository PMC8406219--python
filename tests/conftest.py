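"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import dendropy
import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def genome_table() -> pd.DataFrame:
    """Hand-built genome records spanning the QC boundary cases."""
    rows = [
        # 31/43 present (72.09%), 2 dup (4.65%): passes both filters
        ("gA", "Saccharibacteria", "animal_associated", 31, 2, 800, 10),
        # 30/43 present (69.77%): fails completeness
        ("gB", "Saccharibacteria", "animal_associated", 30, 0, 700, 9),
        # perfect genome
        ("gC", "Saccharibacteria", "environmental", 43, 0, 950, 16),
        # 40/43 but 5/43 duplicated (11.6%): fails duplication
        ("gD", "Gracilibacteria", "environmental", 40, 5, 900, 12),
        ("gE", "Gracilibacteria", "environmental", 36, 1, 850, 8),
    ]
    return pd.DataFrame(rows, columns=[
        "genome_id", "lineage", "habitat_broad", "markers_present",
        "markers_duplicated", "orf_count", "rp16_present"])


def fisher_oracle(k_in: int, n_in: int, k_out: int, n_out: int) -> float:
    """Independent two-sided Fisher p by exhaustive integer enumeration.

    Enumerates every 2x2 table with the observed margins, weighting each by
    C(n_in, a) * C(n_out, k - a) as an exact integer, and sums the weights
    of tables no more probable than the observed one.
    """
    k = k_in + k_out
    weights = [(a, math.comb(n_in, a) * math.comb(n_out, k - a))
               for a in range(max(0, k - n_out), min(n_in, k) + 1)]
    w_obs = dict(weights)[k_in]
    total = sum(w for _, w in weights)
    return sum(w for _, w in weights if w <= w_obs) / total


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Textbook BH step-up computed naively (O(m^2)), preserving order."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [m * p[order[j - 1]] / j for j in range(rank_pos, m + 1)]
        q[idx] = min(1.0, min(candidates))
    return q


def parsimony_oracle(tree: dendropy.Tree, presence: dict[str, int],
                     gain_cost: float = 2.0, loss_cost: float = 1.0) -> float:
    """Minimum gain/loss cost by exhaustive enumeration of internal labelings.

    The root is treated as ancestrally absent, so a root-present labeling
    pays one extra gain.  Valid for small trees only.
    """
    internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    best = math.inf
    for states in itertools.product((0, 1), repeat=len(internal)):
        assign = dict(zip(internal, states))
        for lf in tree.leaf_node_iter():
            assign[lf] = presence[lf.taxon.label]
        cost = gain_cost if assign[tree.seed_node] == 1 else 0.0
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            ps, cs = assign[nd.parent_node], assign[nd]
            if ps == 0 and cs == 1:
                cost += gain_cost
            elif ps == 1 and cs == 0:
                cost += loss_cost
        best = min(best, cost)
    return best


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
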