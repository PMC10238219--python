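"""Correlation networks: construction, Leiden communities, centrality.

The gene co-expression network (GCN) keeps, among all gene pairs whose
Spearman correlation survives BH adjustment at the chosen FDR, only the top
25% most positively correlated pairs.  The metabolite correlation network
(MCN) keeps every FDR-significant pair of either sign.  Phenotype variables
(pulmonary-function parameters) can be attached as extra nodes whose edges
pass the FDR filter only, so negative phenotype-gene correlations are
retained.

Communities ("subnetworks") are found with the Leiden algorithm under the
modularity objective and relabeled in descending size order, so label 0 is
always the largest subnetwork (the G-0 / M-0 convention).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .matrix import OmicsMatrix

EDGE_COLUMNS = ["source", "target", "rho", "pvalue", "padj"]


@dataclass
class CorrNetwork:
    """Weighted undirected network over features (and phenotype nodes)."""

    edges: pd.DataFrame  # columns: source, target, rho, pvalue, padj
    node_kinds: dict[str, str]
    nodes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.edges) and (self.edges["source"] == self.edges["target"]).any():
            raise ValueError("self-edges are not allowed")
        if not self.nodes:
            seen: dict[str, None] = {}
            for row in self.edges.itertuples(index=False):
                seen.setdefault(row.source)
                seen.setdefault(row.target)
            self.nodes = list(seen)
        for n in self.nodes:
            self.node_kinds.setdefault(n, "gene")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for row in self.edges.itertuples(index=False):
            deg[row.source] += 1
            deg[row.target] += 1
        return deg

    def adjacency(self) -> dict[str, dict[str, float]]:
        adj: dict[str, dict[str, float]] = {n: {} for n in self.nodes}
        for row in self.edges.itertuples(index=False):
            adj[row.source][row.target] = row.rho
            adj[row.target][row.source] = row.rho
        return adj

    def to_igraph(self) -> ig.Graph:
        index = {n: i for i, n in enumerate(self.nodes)}
        g = ig.Graph(
            n=len(self.nodes),
            edges=[(index[r.source], index[r.target]) for r in self.edges.itertuples(index=False)],
            directed=False,
        )
        g.vs["name"] = self.nodes
        g.es["rho"] = list(self.edges["rho"]) if len(self.edges) else []
        return g


@dataclass
class Partition:
    """Node -> subnetwork labels, size-ordered (label 0 = largest)."""

    labels: dict[str, int]
    avg_cc: dict[int, float] = field(default_factory=dict)

    @property
    def n_subnetworks(self) -> int:
        return len(set(self.labels.values()))

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for lab in self.labels.values():
            out[lab] = out.get(lab, 0) + 1
        return dict(sorted(out.items()))

    def members(self, label: int) -> set[str]:
        return {n for n, lab in self.labels.items() if lab == label}


# ---------------------------------------------------------------------------
# pairwise correlation
# ---------------------------------------------------------------------------


def spearman_all_pairs(matrix: OmicsMatrix) -> pd.DataFrame:
    """Spearman rho and two-sided p for every unordered feature pair.

    Ranks use average ranks for ties; p-values come from the t
    approximation.  Zero-variance features are excluded with a warning
    (their correlation is undefined).
    """
    vals = matrix.values
    n_samples = vals.shape[1]
    if n_samples < 4:
        raise ValueError("need >= 4 samples for pairwise correlation")
    if vals.isna().any().any():
        raise ValueError("matrix must be complete (impute metabolites first)")
    sd = vals.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance feature(s) excluded from correlation")
        vals = vals.loc[~flat]
    features = list(vals.index)
    if len(features) < 2:
        return pd.DataFrame(columns=["source", "target", "rho", "pvalue"])
    rho, p = stats.spearmanr(vals.to_numpy(dtype=float), axis=1)
    if np.ndim(rho) == 0:  # scipy collapses the 2-feature case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    iu, ju = np.triu_indices(len(features), k=1)
    feats = np.asarray(features)
    return pd.DataFrame(
        {
            "source": feats[iu],
            "target": feats[ju],
            "rho": rho[iu, ju],
            "pvalue": p[iu, ju],
        }
    )


def _sorted_significant(pairs: pd.DataFrame, fdr: float) -> pd.DataFrame:
    out = pairs.copy()
    if "padj" not in out.columns:  # BH over all tested pairs
        out["padj"] = bh_adjust(out["pvalue"].to_numpy()) if len(out) else []
    return out


def build_gcn(pairs: pd.DataFrame, fdr: float = 0.05, top_fraction: float = 0.25,
              node_kinds: dict[str, str] | None = None) -> CorrNetwork:
    """Gene co-expression network: FDR-significant positive pairs, then the
    top ``top_fraction`` by rho (ties broken lexicographically on the pair).

    The retained edge count is exactly ``ceil(top_fraction * m)`` where m
    is the number of significant positive pairs.
    """
    scored = _sorted_significant(pairs, fdr)
    sig = scored[(scored["padj"] <= fdr) & (scored["rho"] > 0)]
    if sig.empty:
        warnings.warn("no significant positive pairs; network is empty")
        return CorrNetwork(pd.DataFrame(columns=EDGE_COLUMNS), node_kinds or {})
    sig = sig.sort_values(["rho", "source", "target"],
                          ascending=[False, True, True], kind="mergesort")
    n_keep = math.ceil(top_fraction * len(sig))
    kept = sig.head(n_keep).reset_index(drop=True)
    return CorrNetwork(kept[EDGE_COLUMNS], dict(node_kinds or {}))


def build_mcn(pairs: pd.DataFrame, fdr: float = 0.05, positive_only: bool = False,
              node_kinds: dict[str, str] | None = None) -> CorrNetwork:
    """Metabolite correlation network: every FDR-significant pair (both
    signs unless ``positive_only``)."""
    scored = _sorted_significant(pairs, fdr)
    sig = scored[scored["padj"] <= fdr]
    if positive_only:
        sig = sig[sig["rho"] > 0]
    if sig.empty:
        warnings.warn("no significant pairs; network is empty")
        return CorrNetwork(pd.DataFrame(columns=EDGE_COLUMNS), node_kinds or {})
    sig = sig.sort_values(["rho", "source", "target"],
                          ascending=[False, True, True], kind="mergesort").reset_index(drop=True)
    kinds = {k: "metabolite" for k in set(sig["source"]) | set(sig["target"])}
    kinds.update(node_kinds or {})
    return CorrNetwork(sig[EDGE_COLUMNS], kinds)


def attach_phenotypes(matrix: OmicsMatrix, phenotypes: OmicsMatrix) -> tuple[OmicsMatrix, dict[str, str]]:
    """Append phenotype rows to an omics matrix before correlation.

    Returns the augmented matrix and a node->kind map so phenotype nodes are
    never counted as features downstream.
    """
    if list(matrix.samples) != list(phenotypes.samples):
        if set(matrix.samples) != set(phenotypes.samples):
            raise ValueError("phenotype samples do not match matrix samples")
        phenotypes = phenotypes.subset_samples(matrix.samples)
    overlap = set(matrix.features) & set(phenotypes.features)
    if overlap:
        raise ValueError(f"phenotype names collide with features: {sorted(overlap)[:5]}")
    base_kind = "gene" if matrix.value_kind in ("counts", "tpm") else "metabolite"
    kinds = {f: base_kind for f in matrix.features}
    kinds.update({f: "phenotype" for f in phenotypes.features})
    combined = pd.concat([matrix.values, phenotypes.values])
    return OmicsMatrix(combined, "phenotype"), kinds


def build_network_with_phenotypes(
    matrix: OmicsMatrix,
    phenotypes: OmicsMatrix | None,
    fdr: float = 0.05,
    top_fraction: float = 0.25,
    omics: str = "genes",
    phenotype_fdr_only: bool = True,
) -> CorrNetwork:
    """Full network construction: correlate features (plus phenotype nodes),
    BH-adjust over all tested pairs, then apply the omics-specific edge rule.

    Feature-feature edges follow the GCN rule (positive, FDR, top fraction)
    for ``omics='genes'`` or the MCN rule (FDR only) for
    ``omics='metabolites'``.  Phenotype edges pass the FDR filter only (both
    signs) when ``phenotype_fdr_only`` — they bypass the top-fraction
    quantile so negative phenotype-gene correlations are kept.
    """
    if phenotypes is None:
        combined = matrix
        kinds = {f: ("gene" if omics == "genes" else "metabolite") for f in matrix.features}
    else:
        combined, kinds = attach_phenotypes(matrix, phenotypes)
    pairs = spearman_all_pairs(combined)
    pairs["padj"] = bh_adjust(pairs["pvalue"].to_numpy()) if len(pairs) else []
    is_pheno = pairs["source"].map(lambda s: kinds.get(s) == "phenotype") | \
        pairs["target"].map(lambda s: kinds.get(s) == "phenotype")
    feature_pairs = pairs[~is_pheno]
    pheno_pairs = pairs[is_pheno]

    if omics == "genes":
        sig = feature_pairs[(feature_pairs["padj"] <= fdr) & (feature_pairs["rho"] > 0)]
        sig = sig.sort_values(["rho", "source", "target"],
                              ascending=[False, True, True], kind="mergesort")
        sig = sig.head(math.ceil(top_fraction * len(sig))) if len(sig) else sig
    elif omics == "metabolites":
        sig = feature_pairs[feature_pairs["padj"] <= fdr]
    else:
        raise ValueError("omics must be 'genes' or 'metabolites'")

    if phenotype_fdr_only:
        pheno_sig = pheno_pairs[pheno_pairs["padj"] <= fdr]
    else:
        pheno_sig = pheno_pairs[(pheno_pairs["padj"] <= fdr) & (pheno_pairs["rho"] > 0)]
    edges = pd.concat([sig, pheno_sig]).reset_index(drop=True)
    if edges.empty:
        warnings.warn("no significant pairs; network is empty")
        return CorrNetwork(pd.DataFrame(columns=EDGE_COLUMNS), kinds)
    return CorrNetwork(edges[EDGE_COLUMNS], kinds)


# ---------------------------------------------------------------------------
# community detection
# ---------------------------------------------------------------------------


def leiden_partition(network: CorrNetwork, resolution: float = 1.0, seed: int = 0,
                     weighted: bool = False) -> Partition:
    """Leiden communities under the modularity objective, relabeled by
    descending size (ties broken by the lexicographically smallest member).
    Deterministic under ``seed``."""
    if not network.nodes:
        raise ValueError("cannot partition an empty network")
    g = network.to_igraph()
    kwargs = {"weights": g.es["rho"]} if (weighted and g.ecount()) else {}
    if resolution == 1.0:
        part = leidenalg.find_partition(
            g, leidenalg.ModularityVertexPartition, seed=seed, **kwargs)
    else:
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition, seed=seed,
            resolution_parameter=resolution, **kwargs)
    raw = {network.nodes[i]: m for i, m in enumerate(part.membership)}
    groups: dict[int, list[str]] = {}
    for node, lab in raw.items():
        groups.setdefault(lab, []).append(node)
    order = sorted(groups, key=lambda lab: (-len(groups[lab]), min(groups[lab])))
    relabel = {old: new for new, old in enumerate(order)}
    labels = {node: relabel[lab] for node, lab in raw.items()}
    partition = Partition(labels=labels)
    partition.avg_cc = subnetwork_avg_cc(network, partition)
    return partition


def detect_subnetworks(network: CorrNetwork, resolution: float = 1.0,
                       seed: int = 0, weighted: bool = False) -> Partition:
    """Subnetwork detection with phenotype nodes assigned by adjacency.

    Communities are found on the feature-feature subgraph only; each
    phenotype node is then assigned to the subnetwork holding the majority
    of its feature neighbors (ties -> smaller label).  Phenotype nodes are
    deliberately kept out of the modularity optimization: they are
    correlated with a large fraction of all features, so at small network
    sizes they act as hubs that can glue otherwise disjoint feature modules
    together.  Phenotype nodes without feature neighbors get a fresh label.
    """
    pheno = {n for n in network.nodes if network.node_kinds.get(n) == "phenotype"}
    if not pheno:
        return leiden_partition(network, resolution, seed, weighted)
    feat_edges = network.edges[
        ~network.edges["source"].isin(pheno) & ~network.edges["target"].isin(pheno)
    ].reset_index(drop=True)
    feat_net = CorrNetwork(
        feat_edges,
        {n: k for n, k in network.node_kinds.items() if n not in pheno},
        [n for n in network.nodes if n not in pheno],
    )
    part = leiden_partition(feat_net, resolution, seed, weighted)
    labels = dict(part.labels)
    adj = network.adjacency()
    next_label = max(labels.values()) + 1 if labels else 0
    for p in sorted(pheno):
        votes: dict[int, int] = {}
        # only positively correlated neighbors vote: a negative edge means the
        # phenotype moves against that subnetwork, not with it
        for n, rho in adj.get(p, {}).items():
            if rho > 0 and n in labels and n not in pheno:
                votes[labels[n]] = votes.get(labels[n], 0) + 1
        if votes:
            labels[p] = min(votes, key=lambda lab: (-votes[lab], lab))
        else:
            labels[p] = next_label
            next_label += 1
    out = Partition(labels=labels)
    out.avg_cc = subnetwork_avg_cc(network, out)
    return out


# ---------------------------------------------------------------------------
# centrality and composition
# ---------------------------------------------------------------------------


def local_cc(network: CorrNetwork, node: str, _adj: dict | None = None) -> float:
    """Local clustering coefficient 2T/(d(d-1)); degree < 2 -> 0."""
    adj = _adj if _adj is not None else network.adjacency()
    if node not in adj:
        raise KeyError(f"unknown node {node!r}")
    neigh = list(adj[node])
    d = len(neigh)
    if d < 2:
        return 0.0
    triangles = 0
    for i in range(d):
        ni = adj[neigh[i]]
        for j in range(i + 1, d):
            if neigh[j] in ni:
                triangles += 1
    return 2.0 * triangles / (d * (d - 1))


def subnetwork_avg_cc(network: CorrNetwork, partition: Partition) -> dict[int, float]:
    """Average local clustering coefficient per subnetwork, computed on the
    full network's edges (not the induced subgraph)."""
    g = network.to_igraph()
    cc = g.transitivity_local_undirected(mode="zero")
    by_node = dict(zip(network.nodes, cc))
    out: dict[int, list[float]] = {}
    for node, lab in partition.labels.items():
        out.setdefault(lab, []).append(by_node.get(node, 0.0))
    return {lab: float(np.mean(v)) for lab, v in sorted(out.items())}


def phenotype_centrality(network: CorrNetwork) -> dict[str, int]:
    """Number of adjacent non-phenotype nodes per phenotype node."""
    pheno = [n for n in network.nodes if network.node_kinds.get(n) == "phenotype"]
    if not pheno:
        warnings.warn("network has no phenotype nodes")
        return {}
    adj = network.adjacency()
    return {
        p: sum(1 for n in adj[p] if network.node_kinds.get(n) != "phenotype")
        for p in pheno
    }


def top_correlates(network: CorrNetwork, phenotype: str, k: int = 10) -> pd.DataFrame:
    """Nodes adjacent to a phenotype, ranked by \\|rho\\| descending (ties
    broken lexicographically), with the signed rho reported."""
    if k <= 0:
        raise ValueError("k must be positive")
    if phenotype not in network.nodes:
        raise KeyError(f"phenotype {phenotype!r} not in network")
    adj = network.adjacency()[phenotype]
    rows = sorted(adj.items(), key=lambda kv: (-abs(kv[1]), kv[0]))[:k]
    return pd.DataFrame(rows, columns=["node", "rho"])


def composition_stats(sizes: dict[int, int] | "Partition",
                      union_labels: tuple[int, ...] = (),
                      n_phenotypes: int = 0) -> pd.DataFrame:
    """Subnetwork sizes as percentages of the network, plus the share of a
    labeled union (e.g. the two central subnetworks).

    Accepts either a Partition or a ``label -> size`` dict (so printed
    subnetwork sizes can be analyzed directly).  Percentages are reported to
    2 decimals; ``pct_excl_phenotypes`` uses the node count minus
    ``n_phenotypes`` as the denominator.
    """
    if isinstance(sizes, Partition):
        sizes = sizes.sizes()
    total = sum(sizes.values())
    if total == 0:
        raise ValueError("empty partition")
    denom_np = total - n_phenotypes
    rows = []
    for lab in sorted(sizes):
        rows.append(
            {
                "subnetwork": lab,
                "size": sizes[lab],
                "pct_of_network": round(100.0 * sizes[lab] / total, 2),
                "pct_excl_phenotypes": round(100.0 * sizes[lab] / denom_np, 2)
                if denom_np > 0 else float("nan"),
            }
        )
    out = pd.DataFrame(rows)
    if union_labels:
        union_size = sum(sizes.get(lab, 0) for lab in union_labels)
        out.attrs["union_labels"] = tuple(union_labels)
        out.attrs["union_size"] = union_size
        out.attrs["union_pct"] = round(100.0 * union_size / total, 2)
    return out
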