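"""Over-representation statistics and the two integration layers.

A single upper-tail hypergeometric test underlies everything here: pathway
over-representation of a subnetwork, the metabolic-subsystem profiles that
bridge the gene network to the metabolite network, and the association of
externally supplied temporal gene tracks with subnetworks.

Bridging rule: a gene subnetwork g and a metabolite subnetwork m are
connected through subsystem s when s is significantly over-represented (BH
<= fdr) in g on the gene side AND in m on the metabolite side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .io import GeneSetLibrary
from .network import Partition

ENRICH_COLUMNS = [
    "query", "annotation", "overlap", "query_size", "annotation_size",
    "universe_size", "pvalue", "padj", "members",
]


@dataclass(frozen=True)
class BridgeEdge:
    """A subsystem connecting a gene subnetwork to a metabolite subnetwork."""

    gcn_label: int
    mcn_label: int
    subsystem: str
    padj_gene: float
    padj_metabolite: float


def hypergeom_pvalue(overlap: int, query_size: int, annotation_size: int,
                     universe_size: int) -> float:
    """Upper-tail hypergeometric P(X >= overlap)."""
    if overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, universe_size, annotation_size,
                                    query_size))


def hypergeom_ora(query: set[str], library: GeneSetLibrary, universe: set[str],
                  fdr: float = 0.05, query_name: str = "query") -> pd.DataFrame:
    """Over-representation of each library set in a query set.

    Query and library sets are intersected with the universe first; p-values
    are BH-adjusted across the library's sets.
    """
    if not universe:
        raise ValueError("empty universe")
    q = query & universe
    lib = library.intersect_universe(universe)
    rows = []
    for name, members in lib.sets.items():
        overlap = q & members
        p = hypergeom_pvalue(len(overlap), len(q), len(members), len(universe))
        rows.append(
            {
                "query": query_name,
                "annotation": name,
                "overlap": len(overlap),
                "query_size": len(q),
                "annotation_size": len(members),
                "universe_size": len(universe),
                "pvalue": p,
                "members": ",".join(sorted(overlap)),
            }
        )
    out = pd.DataFrame(rows, columns=[c for c in ENRICH_COLUMNS if c != "padj"])
    out["padj"] = bh_adjust(out["pvalue"].to_numpy()) if len(out) else []
    return out[ENRICH_COLUMNS]


def subsystem_profiles(partition: Partition, subsystem_map: dict[str, set[str]],
                       universe: set[str], fdr: float = 0.05) -> pd.DataFrame:
    """Per-subnetwork over-representation of metabolic subsystems.

    ``universe`` is all partitioned features of the omics type; the map is
    feature -> subsystem names.  BH is applied within each subnetwork's
    profile.
    """
    mapped = set(subsystem_map) & universe
    if universe and len(mapped) < 0.01 * len(universe):
        warnings.warn("subsystem map covers <1% of the universe")
    subsystems: dict[str, set[str]] = {}
    for feat, names in subsystem_map.items():
        if feat in universe:
            for s in names:
                subsystems.setdefault(s, set()).add(feat)
    library = GeneSetLibrary(subsystems)
    frames = []
    for label in sorted(set(partition.labels.values())):
        members = partition.members(label) & universe
        res = hypergeom_ora(members, library, universe, fdr=fdr,
                            query_name=str(label))
        frames.append(res)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=ENRICH_COLUMNS)


def bridge_networks(gcn_profiles: pd.DataFrame, mcn_profiles: pd.DataFrame,
                    fdr: float = 0.05) -> list[BridgeEdge]:
    """Connect gene and metabolite subnetworks through shared significant
    subsystems (significant on both sides at the same FDR)."""
    g_vocab = set(gcn_profiles["annotation"])
    m_vocab = set(mcn_profiles["annotation"])
    if g_vocab and m_vocab and not (g_vocab & m_vocab):
        raise ValueError("gene and metabolite profiles share no subsystem vocabulary")
    g_sig = gcn_profiles[gcn_profiles["padj"] <= fdr]
    m_sig = mcn_profiles[mcn_profiles["padj"] <= fdr]
    edges = []
    for grow in g_sig.itertuples(index=False):
        for mrow in m_sig.itertuples(index=False):
            if grow.annotation == mrow.annotation:
                edges.append(
                    BridgeEdge(
                        gcn_label=int(grow.query),
                        mcn_label=int(mrow.query),
                        subsystem=grow.annotation,
                        padj_gene=float(grow.padj),
                        padj_metabolite=float(mrow.padj),
                    )
                )
    return edges


def bridges_to_frame(edges: list[BridgeEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.gcn_label, e.mcn_label, e.subsystem, e.padj_gene, e.padj_metabolite)
         for e in edges],
        columns=["gcn_label", "mcn_label", "subsystem", "padj_gene", "padj_metab"],
    )


def track_association(tracks: dict[str, set[str]], partition: Partition,
                      universe: set[str], fdr: float = 0.05) -> pd.DataFrame:
    """Hypergeometric association of gene tracks with subnetworks.

    Tracks are externally supplied temporal gene groups; one p-value per
    (track, subnetwork) cell, BH-adjusted across the whole matrix.
    """
    if not universe:
        raise ValueError("empty universe")
    rows = []
    for track, genes in tracks.items():
        g = genes & universe
        if not g:
            warnings.warn(f"track {track!r} has no genes in the universe; skipped")
            continue
        for label in sorted(set(partition.labels.values())):
            members = partition.members(label) & universe
            overlap = g & members
            p = hypergeom_pvalue(len(overlap), len(g), len(members), len(universe))
            rows.append(
                {
                    "track": track,
                    "subnetwork": label,
                    "overlap": len(overlap),
                    "track_size": len(g),
                    "subnetwork_size": len(members),
                    "universe_size": len(universe),
                    "pvalue": p,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    else:
        out["padj"] = []
    return out
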