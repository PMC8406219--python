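"""Branch-wise gene-flux summaries over a species tree.

Reconciliation event tables (expected per-branch counts of originations,
within-lineage transfers, losses, and duplications averaged over
reconciliation samples) are aggregated into per-branch totals over
nonterminal branches.  A transfer whose donor lies outside the designated
ingroup is recounted as an origination, matching the definition of
origination as lateral transfer from outside the studied lineages or de
novo evolution.

For desk-scale verification the module also provides a two-state
minimum-cost (Wagner-type) gain/loss parsimony reconstruction of ancestral
gene content, a deterministic stand-in for probabilistic gene-species tree
reconciliation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from . import io as _io

EVENT_TYPES = ("origination", "transfer", "loss", "duplication")


class FluxError(ValueError):
    pass


def check_rooted_binary(tree: dendropy.Tree) -> None:
    """Require a rooted binary tree (every internal node has two children)."""
    root = tree.seed_node
    if root is None or len(root.child_nodes()) != 2:
        raise FluxError("tree must be rooted with a bifurcating root")
    for nd in tree.preorder_node_iter():
        nch = len(nd.child_nodes())
        if nch not in (0, 2):
            raise FluxError(f"tree must be binary; node with {nch} children")


def ensure_branch_ids(tree: dendropy.Tree) -> None:
    """Assign stable ids to unlabelled internal nodes (preorder n0, n1, ...)."""
    seen = set()
    counter = 0
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            seen.add(nd.taxon.label)
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        if nd.label is None or nd.label in seen:
            while f"n{counter}" in seen:
                counter += 1
            nd.label = f"n{counter}"
        seen.add(nd.label)


def branch_ids(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    """Branch id -> node map (a node identifies the branch above it)."""
    out = {}
    for nd in tree.preorder_node_iter():
        bid = nd.taxon.label if nd.is_leaf() else nd.label
        if bid in out:
            raise FluxError(f"duplicate branch id {bid!r}")
        out[bid] = nd
    return out


@dataclass
class BranchEventSummary:
    """Per-branch totals over nonterminal branches, plus side tables."""
    summary: pd.DataFrame      # branch_id x (originations, transfers, losses)
    leaf_events: pd.DataFrame  # events on terminal branches, passed through
    duplications: pd.DataFrame  # duplication rows, reported separately


def aggregate_events(events: pd.DataFrame, tree: dendropy.Tree,
                     ingroup: set[str] | None = None) -> BranchEventSummary:
    """Sum event weights per (branch, type) across families.

    ``events`` rows are (family_id, branch_id, event_type, weight[, donor]).
    Transfers with a donor outside ``ingroup`` (an explicit leaf partition;
    donors are leaf labels) are recounted as originations.  Terminal
    branches are excluded from the summary but retained in a per-leaf side
    table; duplications are passed through separately.  Weights are expected
    counts and are never rounded.
    """
    ensure_branch_ids(tree)
    nodes = branch_ids(tree)
    ev = events.copy()
    if (ev["weight"] < 0).any():
        raise FluxError("event weights must be >= 0")
    bad_type = ~ev["event_type"].isin(EVENT_TYPES)
    if bad_type.any():
        raise FluxError(
            f"unknown event type: {ev.loc[bad_type, 'event_type'].iloc[0]!r}")
    for i, row in ev.iterrows():
        if row["branch_id"] not in nodes:
            raise FluxError(
                f"row {i}: unknown branch id {row['branch_id']!r}")
    if ingroup is not None and "donor" in ev.columns:
        donors = ev["donor"].fillna("")
        outside = (ev["event_type"] == "transfer") & (donors != "") & \
            (~donors.isin(ingroup))
        ev.loc[outside, "event_type"] = "origination"
    dups = ev.loc[ev["event_type"] == "duplication"].reset_index(drop=True)
    rest = ev.loc[ev["event_type"] != "duplication"]
    is_leaf = rest["branch_id"].map(lambda b: nodes[b].is_leaf())
    leaf_events = rest.loc[is_leaf].reset_index(drop=True)
    internal = rest.loc[~is_leaf]
    internal_ids = [bid for bid, nd in nodes.items() if not nd.is_leaf()]
    summary = (internal.pivot_table(index="branch_id", columns="event_type",
                                    values="weight", aggfunc="sum")
               .reindex(index=internal_ids, fill_value=0.0))
    for col in ("origination", "transfer", "loss"):
        if col not in summary.columns:
            summary[col] = 0.0
    summary = summary.fillna(0.0).rename(columns={
        "origination": "originations", "transfer": "transfers",
        "loss": "losses"})[["originations", "transfers", "losses"]]
    summary.index.name = "branch_id"
    return BranchEventSummary(summary=summary, leaf_events=leaf_events,
                              duplications=dups)


@dataclass
class GainLossReconstruction:
    """Minimum-cost gain/loss history of one family on the species tree."""
    gains: list[str]           # branch ids carrying a gain
    losses: list[str]          # branch ids carrying a loss
    cost: float
    states: dict[str, int] = field(default_factory=dict)  # branch id -> state


def parsimony_gain_loss(tree: dendropy.Tree, presence: dict[str, int],
                        gain_cost: float = 2.0,
                        loss_cost: float = 1.0) -> GainLossReconstruction:
    """Two-state Sankoff parsimony with asymmetric gain/loss costs.

    The root is treated as ancestrally absent: a root-present labeling
    incurs one gain on the root branch.  Among equal-cost labelings the one
    with fewer gains is preferred, remaining ties resolve deterministically
    toward the absent state in a left-to-right (preorder) sweep.  Events are
    read off parent-to-child state changes.
    """
    check_rooted_binary(tree)
    ensure_branch_ids(tree)
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = leaves - set(presence)
    if missing:
        raise FluxError(f"missing leaf labels: {sorted(missing)[:5]}")
    INF = (np.inf, np.inf)

    def trans(ps: int, cs: int) -> tuple[float, float]:
        # (cost, n_gains) pairs, compared and summed lexicographically
        if ps == cs:
            return (0.0, 0.0)
        return (gain_cost, 1.0) if cs == 1 else (loss_cost, 0.0)

    def add(a, b):
        return (a[0] + b[0], a[1] + b[1])

    cost: dict[dendropy.Node, tuple] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            s = int(presence[nd.taxon.label])
            if s not in (0, 1):
                raise FluxError(f"leaf state must be 0/1, got {s}")
            cost[nd] = ((0.0, 0.0) if s == 0 else INF,
                        (0.0, 0.0) if s == 1 else INF)
        else:
            tot0 = tot1 = (0.0, 0.0)
            for ch in nd.child_nodes():
                tot0 = add(tot0, min(add(cost[ch][0], trans(0, 0)),
                                     add(cost[ch][1], trans(0, 1))))
                tot1 = add(tot1, min(add(cost[ch][0], trans(1, 0)),
                                     add(cost[ch][1], trans(1, 1))))
            cost[nd] = (tot0, tot1)
    root = tree.seed_node
    # root-present incurs a gain on the root branch
    root_tot = (cost[root][0], add(cost[root][1], (gain_cost, 1.0)))
    state: dict[dendropy.Node, int] = {
        root: 0 if root_tot[0] <= root_tot[1] else 1}
    gains, losses = [], []
    if state[root] == 1:
        gains.append(_bid(root))
    for nd in tree.preorder_node_iter():
        if nd is root:
            continue
        ps = state[nd.parent_node]
        t0 = add(cost[nd][0], trans(ps, 0))
        t1 = add(cost[nd][1], trans(ps, 1))
        s = 0 if t0 <= t1 else 1
        state[nd] = s
        if ps == 0 and s == 1:
            gains.append(_bid(nd))
        elif ps == 1 and s == 0:
            losses.append(_bid(nd))
    return GainLossReconstruction(
        gains=gains, losses=losses, cost=float(min(root_tot)[0]),
        states={_bid(nd): s for nd, s in state.items()})


def _bid(nd: dendropy.Node) -> str:
    return nd.taxon.label if nd.is_leaf() else nd.label


def flux_summary(presence: pd.DataFrame, tree: dendropy.Tree,
                 gain_cost: float = 2.0, loss_cost: float = 1.0
                 ) -> pd.DataFrame:
    """Cumulative per-branch gains (as originations) and losses across families.

    ``presence`` is a leaf x family 0/1 matrix; each family is reconstructed
    independently by parsimony and per-branch events are summed.  In this
    parsimony stand-in every gain is reported as an origination; transfers
    cannot be distinguished without reconciliation and are reported as 0.
    """
    check_rooted_binary(tree)
    ensure_branch_ids(tree)
    all_ids = list(branch_ids(tree))
    out = pd.DataFrame(0.0, index=all_ids,
                       columns=["originations", "transfers", "losses"])
    out.index.name = "branch_id"
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = set(leaves) - set(presence.index)
    if missing:
        raise FluxError(f"presence matrix missing leaves: {sorted(missing)[:5]}")
    for fam in presence.columns:
        rec = parsimony_gain_loss(tree, presence[fam].to_dict(),
                                  gain_cost=gain_cost, loss_cost=loss_cost)
        for b in rec.gains:
            out.loc[b, "originations"] += 1.0
        for b in rec.losses:
            out.loc[b, "losses"] += 1.0
    return out


def read_ale_events(path) -> pd.DataFrame:
    """Adapter for undated-reconciliation (ALE uml_rec-style) event tables.

    Expects a TSV with columns ``family_id, branch_id, duplications,
    transfers, losses, originations`` (per-branch expected counts averaged
    over reconciliation samples; extra columns ignored) and returns the long
    (family_id, branch_id, event_type, weight) form used by
    :func:`aggregate_events`.
    """
    wide = _io.read_tsv(path)
    colmap = {"duplications": "duplication", "transfers": "transfer",
              "losses": "loss", "originations": "origination"}
    present = [c for c in colmap if c in wide.columns]
    if not present:
        raise FluxError("no event-count columns found in ALE-style table")
    long = wide.melt(id_vars=["family_id", "branch_id"], value_vars=present,
                     var_name="event_type", value_name="weight")
    long["event_type"] = long["event_type"].map(colmap)
    long = long.loc[long["weight"] > 0].reset_index(drop=True)
    return long
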