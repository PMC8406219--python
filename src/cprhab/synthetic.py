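"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate the study design of a cross-habitat comparative
genomics survey of episymbiotic CPR bacteria (Absconditabacteria,
Gracilibacteria, Saccharibacteria):

* habitat-stratified genome sets whose protein-family occupancy depends on
  habitat, observed through completeness-driven gene dropout,
* metagenome sample tables with host-symbiont presence coupling,
* ribosomal marker protein sequences with small within-species and larger
  between-species divergence, and
* gene presence/absence evolved along a species tree by gain/loss events.

All randomness flows from a single seed; each generator derives its own
independent stream from (seed, stage tag), so stages are reproducible in
isolation and in any order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

N_MARKERS = 43          # single-copy marker genes used for completeness
N_RP16 = 16             # syntenic ribosomal proteins for the species tree
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# fixed per-stage stream tags: re-running one stage never perturbs another
_STAGE_TAGS = {"genomes": 1, "communities": 2, "markers": 3, "gene_content": 4,
               "ani": 5, "mapping": 6, "tree": 7}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class PlantedSet:
    """A block of families planted as enriched in one (habitat, lineage)."""
    habitat: str
    lineage: str
    n_families: int
    p_in: float
    p_out: float


@dataclass
class SimConfig:
    """Study-design parameters for all synthetic generators.

    Defaults mirror the scale of the real survey in miniature: two broad
    habitat classes, three CPR lineages, Bernoulli family occupancy with
    habitat-dependent planted blocks, and CheckM-style completeness drawn
    uniformly on (0.7, 1.0) that thins both gene content and the 43-marker
    inventory at the same per-genome rate.
    """
    seed: int = 0
    n_genomes_per_group: int = 20
    habitats: Sequence[str] = ("animal_associated", "environmental")
    lineages: Sequence[str] = ("Absconditabacteria", "Gracilibacteria",
                               "Saccharibacteria")
    n_families: int = 400
    baseline_occupancy: float = 0.10
    planted_sets: Sequence[PlantedSet] = ()
    completeness_range: tuple[float, float] = (0.7, 1.0)
    duplication_rate: float = 0.02
    annotation_prob: float = 0.7
    # group_sizes overrides n_genomes_per_group per habitat (applies to every
    # lineage) to allow unbalanced designs such as 40 in-group vs 200 out-group
    group_sizes: Mapping[str, int] | None = None
    # community simulation
    n_samples: int = 50
    n_host_groups: int = 6
    n_symbiont_groups: int = 6
    host_prob: float = 0.5
    coupling_prob: float = 0.9
    leak_prob: float = 0.05
    covered_fraction_floor: float = 0.0
    # marker sequence simulation
    n_species_groups: int = 10
    members_per_group: int = 8
    seq_length: int = 220
    within_divergence: float = 0.005
    between_divergence: float = 0.05
    # gene content evolution
    gain_rate: float = 0.1
    loss_rate: float = 0.3

    def __post_init__(self):
        probs = {"baseline_occupancy": self.baseline_occupancy,
                 "host_prob": self.host_prob,
                 "coupling_prob": self.coupling_prob,
                 "leak_prob": self.leak_prob,
                 "duplication_rate": self.duplication_rate,
                 "annotation_prob": self.annotation_prob,
                 "covered_fraction_floor": self.covered_fraction_floor,
                 "within_divergence": self.within_divergence,
                 "between_divergence": self.between_divergence}
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        lo, hi = self.completeness_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError(
                f"completeness_range {self.completeness_range} invalid")
        self.planted_sets = tuple(PlantedSet(**p) if isinstance(p, dict) else p
                                  for p in self.planted_sets)
        for ps in self.planted_sets:
            if not (0 <= ps.p_out <= 1 and 0 <= ps.p_in <= 1):
                raise ConfigurationError(f"planted probabilities invalid: {ps}")
            if ps.p_in <= ps.p_out:
                raise ConfigurationError(
                    f"planted set requires p_in > p_out: {ps}")
            if ps.habitat not in self.habitats or ps.lineage not in self.lineages:
                raise ConfigurationError(f"planted set references unknown group: {ps}")
        if self.between_divergence <= self.within_divergence:
            raise ConfigurationError(
                "between_divergence must exceed within_divergence")
        if sum(ps.n_families for ps in self.planted_sets) > self.n_families:
            raise ConfigurationError("more planted families than n_families")
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ConfigurationError("gain/loss rates must be >= 0")

    def rng(self, stage: str) -> np.random.Generator:
        """Independent deterministic stream for one generator stage."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STAGE_TAGS[stage],)))

    def group_size(self, habitat: str) -> int:
        if self.group_sizes and habitat in self.group_sizes:
            return int(self.group_sizes[habitat])
        return self.n_genomes_per_group


@dataclass
class Truth:
    """Planted ground truth shared by the generators.

    planted_family_labels maps family id -> (habitat, lineage) for enriched
    families and is absent for null families; host_links maps symbiont group
    id -> host group id; branch_events maps branch id -> [(family, event)].
    marker_groups maps sequence id -> species-group id.
    """
    planted_family_labels: dict = field(default_factory=dict)
    host_links: dict = field(default_factory=dict)
    branch_events: dict = field(default_factory=dict)
    marker_groups: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "planted_family_labels": {k: list(v) for k, v in
                                      self.planted_family_labels.items()},
            "host_links": dict(self.host_links),
            "branch_events": {k: [list(e) for e in v]
                              for k, v in self.branch_events.items()},
            "marker_groups": dict(self.marker_groups),
        }


def _family_ids(n: int) -> list[str]:
    return [f"fam{i:05d}" for i in range(n)]


def simulate_genome_set(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, Truth]:
    """Simulate a habitat-stratified genome set and its family memberships.

    True gene content per family is Bernoulli: ``p_in`` for genomes in a
    family's planted (habitat, lineage) group, ``p_out`` for other genomes of
    that planted lineage, and the baseline occupancy for null families and
    other lineages.  Observed content (and the 43-marker inventory, and the
    rp16 inventory) is the true content thinned by a per-genome completeness
    draw, emulating missing genes in incomplete metagenome-assembled genomes.

    Returns (genome table, membership table, truth).
    """
    rng = config.rng("genomes")
    fams = _family_ids(config.n_families)
    truth = Truth()
    # assign the first sum(n_families) families to the planted blocks, in order
    cursor = 0
    fam_params: dict[str, PlantedSet | None] = {f: None for f in fams}
    for ps in config.planted_sets:
        for f in fams[cursor:cursor + ps.n_families]:
            fam_params[f] = ps
            truth.planted_family_labels[f] = (ps.habitat, ps.lineage)
        cursor += ps.n_families

    genome_rows = []
    member_rows = []
    annotations = {f: f"K{10000 + i:05d}" for i, f in enumerate(fams)}
    lo, hi = config.completeness_range
    gidx = 0
    for lineage in config.lineages:
        for habitat in config.habitats:
            # occupancy probabilities are constant within a (lineage, habitat)
            p = np.full(config.n_families, config.baseline_occupancy)
            for j, f in enumerate(fams):
                ps = fam_params[f]
                if ps is not None and ps.lineage == lineage:
                    p[j] = ps.p_in if ps.habitat == habitat else ps.p_out
            for _ in range(config.group_size(habitat)):
                gid = f"g{gidx:04d}"
                gidx += 1
                completeness = rng.uniform(lo, hi)
                true_content = rng.random(config.n_families) < p
                observed = true_content & (rng.random(config.n_families)
                                           < completeness)
                markers_present = int(rng.binomial(N_MARKERS, completeness))
                markers_dup = int(rng.binomial(markers_present,
                                               config.duplication_rate))
                rp16 = int(rng.binomial(N_RP16, completeness))
                n_obs = int(observed.sum())
                orf_count = n_obs + int(rng.poisson(40 * completeness))
                genome_rows.append({
                    "genome_id": gid, "lineage": lineage,
                    "habitat_broad": habitat,
                    "habitat_narrow": f"{habitat}/site1",
                    "markers_present": markers_present,
                    "markers_duplicated": markers_dup,
                    "completeness": 100.0 * markers_present / N_MARKERS,
                    "duplication": 100.0 * markers_dup / N_MARKERS,
                    "orf_count": orf_count, "rp16_present": rp16,
                })
                annotated = rng.random(config.n_families) < config.annotation_prob
                for j in np.flatnonzero(observed):
                    f = fams[j]
                    member_rows.append({
                        "family_id": f, "genome_id": gid,
                        "sequence_id": f"{gid}|{f}|1",
                        "annotation": annotations[f] if annotated[j] else "",
                        "annotation_score": 100.0,
                    })
    genomes = pd.DataFrame(genome_rows)
    memberships = pd.DataFrame(
        member_rows, columns=["family_id", "genome_id", "sequence_id",
                              "annotation", "annotation_score"])
    return genomes, memberships, truth


def simulate_ani_matrix(genomes: pd.DataFrame, config: SimConfig,
                        n_duplicate_pairs: int = 5) -> pd.DataFrame:
    """Synthetic symmetric ANI matrix with a few planted near-duplicate pairs.

    Background pairs sit well below any dereplication threshold
    (0.80-0.95); planted pairs within the same lineage get ANI in
    (0.992, 0.999) so they collapse at the conventional 0.99 cutoff.
    Plumbing generator: the real analysis consumes externally computed ANI.
    """
    rng = config.rng("ani")
    ids = list(genomes["genome_id"])
    n = len(ids)
    upper = rng.uniform(0.80, 0.95, size=(n, n))
    mat = np.triu(upper, 1)
    mat = mat + mat.T + np.eye(n)
    # plant duplicates between consecutive genomes of the same lineage
    lineages = list(genomes["lineage"])
    planted = 0
    for i in range(n - 1):
        if planted >= n_duplicate_pairs:
            break
        if lineages[i] == lineages[i + 1]:
            ani = rng.uniform(0.992, 0.999)
            mat[i, i + 1] = mat[i + 1, i] = ani
            planted += 1
    return pd.DataFrame(mat, index=ids, columns=ids)


def simulate_communities(config: SimConfig) -> tuple[pd.DataFrame, Truth]:
    """Simulate per-sample marker detections with host-symbiont coupling.

    Host (Actinobacteria) species groups occur independently per sample with
    ``host_prob``; each symbiont (Saccharibacteria) group is linked to one
    host group and occurs with ``coupling_prob`` when its host is present and
    ``leak_prob`` otherwise.  Coverages are log-normal, covered fractions
    uniform above the configured floor.
    """
    if config.n_samples <= 0:
        raise ConfigurationError("n_samples must be positive")
    rng = config.rng("communities")
    orders = ["Actinomycetales", "Coriobacteriales", "Micrococcales"]
    hosts = [f"act{h:02d}" for h in range(config.n_host_groups)]
    symbionts = [f"sac{s:02d}" for s in range(config.n_symbiont_groups)]
    truth = Truth()
    for s_i, sym in enumerate(symbionts):
        truth.host_links[sym] = hosts[s_i % len(hosts)]
    rows = []
    floor = config.covered_fraction_floor
    for s in range(config.n_samples):
        sid = f"sample{s:03d}"
        host_present = {h: rng.random() < config.host_prob for h in hosts}
        for h_i, h in enumerate(hosts):
            if host_present[h]:
                rows.append({
                    "sample_id": sid, "habitat": "animal_associated",
                    "group_id": h, "lineage": "Actinobacteria",
                    "order": orders[h_i % len(orders)],
                    "mean_coverage": float(rng.lognormal(1.0, 1.0)),
                    "covered_fraction": float(rng.uniform(floor, 1.0)),
                })
        for sym in symbionts:
            p = (config.coupling_prob if host_present[truth.host_links[sym]]
                 else config.leak_prob)
            if rng.random() < p:
                rows.append({
                    "sample_id": sid, "habitat": "animal_associated",
                    "group_id": sym, "lineage": "Saccharibacteria",
                    "order": "unknown",
                    "mean_coverage": float(rng.lognormal(0.5, 1.0)),
                    "covered_fraction": float(rng.uniform(floor, 1.0)),
                })
    samples = pd.DataFrame(rows, columns=["sample_id", "habitat", "group_id",
                                          "lineage", "order", "mean_coverage",
                                          "covered_fraction"])
    return samples, truth


def simulate_marker_sequences(config: SimConfig) -> tuple[list[tuple[str, str]], Truth]:
    """Simulate rpS3-scale marker proteins for planted species groups.

    Each group has a random 20-letter amino-acid centroid; centroids of
    distinct groups differ at disjoint blocks of ceil(between_divergence * L)
    positions (pairwise divergence >= between_divergence).  Members carry
    exactly round(within_divergence * L) point substitutions relative to
    their centroid, so within-group identity is deterministic.
    """
    L = config.seq_length
    if L <= 0:
        raise ConfigurationError("seq_length must be positive")
    k_between = int(np.ceil(config.between_divergence * L))
    if config.n_species_groups * k_between > L:
        raise ConfigurationError(
            "sequence too short for the requested number of divergent groups")
    rng = config.rng("markers")
    alphabet = np.array(list(AA_ALPHABET))
    base = rng.integers(0, len(alphabet), size=L)
    k_within = int(round(config.within_divergence * L))
    records: list[tuple[str, str]] = []
    truth = Truth()

    def mutate(seq: np.ndarray, positions: np.ndarray) -> np.ndarray:
        out = seq.copy()
        shift = rng.integers(1, len(alphabet), size=len(positions))
        out[positions] = (out[positions] + shift) % len(alphabet)
        return out

    for g in range(config.n_species_groups):
        block = np.arange(g * k_between, (g + 1) * k_between)
        centroid = mutate(base, block)
        for m in range(config.members_per_group):
            if k_within > 0:
                pos = rng.choice(L, size=k_within, replace=False)
                member = mutate(centroid, pos)
            else:
                member = centroid.copy()
            sid = f"grp{g:02d}_m{m:02d}"
            records.append((sid, "".join(alphabet[member])))
            truth.marker_groups[sid] = f"grp{g:02d}"
    return records, truth


def random_binary_tree(n_leaves: int, rng: np.random.Generator,
                       min_blen: float = 0.1, max_blen: float = 1.0) -> dendropy.Tree:
    """Random rooted binary tree with uniform branch lengths and stable ids.

    Leaves are labelled L0..L{n-1}; internal nodes n0.. in the order they are
    created (root gets the last id).  Branch ids are node labels.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    taxa = dendropy.TaxonNamespace([f"L{i}" for i in range(n_leaves)])
    nodes = []
    for i in range(n_leaves):
        nd = dendropy.Node()
        nd.taxon = taxa.get_taxon(f"L{i}")
        nd.edge.length = float(rng.uniform(min_blen, max_blen))
        nodes.append(nd)
    counter = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.label = f"n{counter}"
        counter += 1
        parent.edge.length = float(rng.uniform(min_blen, max_blen))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[0]
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree


def simulate_gene_content(tree: dendropy.Tree, config: SimConfig,
                          n_families: int = 50,
                          plant_single_gains: bool = False
                          ) -> tuple[pd.DataFrame, Truth]:
    """Evolve binary gene presence along a rooted tree, recording events.

    Stochastic mode: the root starts absent; on each branch a gain occurs
    with probability 1-exp(-gain_rate*t) when absent and a loss with
    probability 1-exp(-loss_rate*t) when present (at most one event per
    branch).  Planted mode (``plant_single_gains``): each family receives
    exactly one gain on a uniformly chosen internal non-root branch and no
    other events, giving homoplasy-free test cases.
    """
    from .gene_flux import ensure_branch_ids, check_rooted_binary
    check_rooted_binary(tree)
    ensure_branch_ids(tree)
    rng = config.rng("gene_content")
    fams = _family_ids(n_families)
    truth = Truth()
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    presence = pd.DataFrame(0, index=leaves, columns=fams, dtype=int)

    internal_nonroot = [nd for nd in tree.preorder_node_iter()
                        if not nd.is_leaf() and nd.parent_node is not None]
    for f in fams:
        events: list[tuple[str, str]] = []
        if plant_single_gains:
            nd = internal_nonroot[int(rng.integers(len(internal_nonroot)))]
            state = {nd: 1}
            events.append((branch_id(nd), "gain"))
            for desc in nd.preorder_iter():
                state[desc] = 1
            for leaf in tree.leaf_node_iter():
                presence.loc[leaf.taxon.label, f] = state.get(leaf, 0)
        else:
            state = {tree.seed_node: 0}
            for nd in tree.preorder_node_iter():
                if nd.parent_node is None:
                    continue
                s = state[nd.parent_node]
                t = nd.edge.length or 0.0
                if s == 0:
                    if rng.random() < 1.0 - np.exp(-config.gain_rate * t):
                        s = 1
                        events.append((branch_id(nd), "gain"))
                else:
                    if rng.random() < 1.0 - np.exp(-config.loss_rate * t):
                        s = 0
                        events.append((branch_id(nd), "loss"))
                state[nd] = s
            for leaf in tree.leaf_node_iter():
                presence.loc[leaf.taxon.label, f] = state[leaf]
        for b, ev in events:
            truth.branch_events.setdefault(b, []).append((f, ev))
    return presence, truth


def branch_id(node: dendropy.Node) -> str:
    """Stable branch identifier: leaf taxon label or internal node label."""
    return node.taxon.label if node.taxon is not None else node.label


def simulate_mapping_summary(genomes: pd.DataFrame, config: SimConfig,
                             n_samples: int = 4) -> pd.DataFrame:
    """Synthetic read-mapping summary (plumbing for the abundance stage)."""
    rng = config.rng("mapping")
    rows = []
    for gid in genomes["genome_id"]:
        for s in range(n_samples):
            total = int(rng.integers(5_000_000, 150_000_000))
            strict = int(total * rng.uniform(0, 0.01))
            rows.append({
                "genome_id": gid, "sample_id": f"run{s:02d}",
                "strict_mapped": strict, "total_reads": total,
                "covered_fraction": float(rng.uniform(0, 1)),
                "read_pairs": total // 2,
            })
    return pd.DataFrame(rows)
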