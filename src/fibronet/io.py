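"""Readers and writers for every file the pipeline touches.

All tabular interchange is TSV (UTF-8, ``.`` decimal, missing values encoded
as empty strings).  Gene-set libraries use the GMT convention (set name,
description, then tab-separated members).  Networks are written as an edge
list plus a node table, with an optional GraphML export for graph tools.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .matrix import OmicsMatrix, StudyDesign

# ---------------------------------------------------------------------------
# matrices and designs
# ---------------------------------------------------------------------------


def read_matrix(path: str | Path, value_kind: str) -> OmicsMatrix:
    """Read a feature x sample TSV (first column = feature ID, header = samples).

    Empty cells become missing values; those are only legal for metabolite
    (``relative_peak_area``) and ``phenotype`` matrices.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col].str.strip() if df[col].dtype == object else df[col],
                                  errors="coerce")
        blank = df[col].isna() | (df[col].astype(str).str.strip() == "")
        bad = converted.isna() & ~blank
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"non-numeric cell at feature {row!r}, sample {col!r} in {path}"
            )
        numeric[col] = converted
    return OmicsMatrix(numeric, value_kind)


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.index.name = "feature"
    df.to_csv(path, sep="\t", na_rep="")


def read_design(path: str | Path, reference: str | None = None) -> StudyDesign:
    """Read a two-column TSV (sample, group).  Group order follows first
    appearance; the reference defaults to the first group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"design file {path} needs columns (sample, group)")
    sample_col, group_col = df.columns[:2]
    if df[sample_col].duplicated().any():
        raise ValueError(f"duplicate sample IDs in design {path}")
    groups = list(dict.fromkeys(df[group_col]))
    return StudyDesign(
        sample_to_group=dict(zip(df[sample_col], df[group_col])),
        groups=groups,
        reference=reference if reference is not None else groups[0],
    )


def write_design(design: StudyDesign, path: str | Path) -> None:
    pd.DataFrame(
        {"sample": list(design.sample_to_group), "group": list(design.sample_to_group.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene-set libraries and feature maps
# ---------------------------------------------------------------------------


@dataclass
class GeneSetLibrary:
    """Named sets of feature IDs with free-text descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def intersect_universe(self, universe: set[str]) -> "GeneSetLibrary":
        """Restrict every set to `universe`, dropping sets that become empty."""
        kept = {
            name: members & universe
            for name, members in self.sets.items()
            if members & universe
        }
        return GeneSetLibrary(kept, {n: self.descriptions.get(n, "") for n in kept})


def read_gmt(path: str | Path) -> GeneSetLibrary:
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has <3 fields")
            name, desc, *members = parts
            sets[name] = set(m for m in members if m)
            descriptions[name] = desc
    if not sets:
        warnings.warn(f"GMT file {path} contains no sets")
    return GeneSetLibrary(sets, descriptions)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in library.sets:
            members = sorted(library.sets[name])
            desc = library.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_feature_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column TSV mapping feature ID -> target ID (subsystem,
    ortholog or track).  A feature may map to several targets; exact
    duplicate rows are collapsed."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"feature map {path} needs two columns")
    a, b = df.columns[:2]
    out: dict[str, set[str]] = {}
    for feat, target in zip(df[a], df[b]):
        out.setdefault(str(feat), set()).add(str(target))
    return out


def write_feature_map(mapping: dict[str, set[str] | str], path: str | Path,
                      columns: tuple[str, str] = ("feature", "target")) -> None:
    rows = []
    for feat, targets in mapping.items():
        if isinstance(targets, str):
            targets = {targets}
        for t in sorted(targets):
            rows.append((feat, t))
    pd.DataFrame(rows, columns=list(columns)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# differential tables
# ---------------------------------------------------------------------------

DIFF_COLUMNS = ["feature", "log2fc", "pvalue", "padj", "contrast"]


def read_differential(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DIFF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"differential table {path} lacks columns {missing}")
    return df[DIFF_COLUMNS].assign(feature=lambda d: d["feature"].astype(str))


def write_differential(table: pd.DataFrame, path: str | Path) -> None:
    table[DIFF_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


def write_network(network, partition, path_prefix: str | Path,
                  graphml: bool = False) -> list[Path]:
    """Write a correlation network as ``<prefix>_edges.tsv`` and
    ``<prefix>_nodes.tsv`` (plus optional ``<prefix>.graphml``).

    The node table carries kind (gene/metabolite/phenotype), subnetwork
    label, degree and local clustering coefficient so the files round-trip
    the full analysis state.
    """
    from .network import CorrNetwork, Partition  # local import: avoid cycle

    prefix = Path(path_prefix)
    if partition is not None:
        stray = set(partition.labels) - set(network.nodes)
        if stray:
            raise ValueError(f"partition nodes absent from network: {sorted(stray)[:5]}")
    edges = network.edges.copy()
    edge_path = prefix.parent / (prefix.name + "_edges.tsv")
    node_path = prefix.parent / (prefix.name + "_nodes.tsv")
    edges.to_csv(edge_path, sep="\t", index=False)

    degrees = network.degrees()
    if network.nodes:
        g = network.to_igraph()
        cc_by_node = dict(zip(network.nodes,
                              g.transitivity_local_undirected(mode="zero")))
    else:
        cc_by_node = {}
    rows = []
    for node in network.nodes:
        rows.append(
            {
                "node": node,
                "kind": network.node_kinds.get(node, "gene"),
                "subnetwork": partition.labels[node] if partition is not None and node in partition.labels else "",
                "degree": degrees.get(node, 0),
                "local_cc": cc_by_node.get(node, 0.0),
            }
        )
    pd.DataFrame(rows, columns=["node", "kind", "subnetwork", "degree", "local_cc"]).to_csv(
        node_path, sep="\t", index=False
    )
    written = [edge_path, node_path]
    if graphml:
        import networkx as nx

        g = nx.Graph()
        for node in network.nodes:
            g.add_node(node, kind=network.node_kinds.get(node, "gene"))
        for row in network.edges.itertuples(index=False):
            g.add_edge(row.source, row.target, rho=row.rho, p=row.pvalue, fdr=row.padj)
        gpath = prefix.parent / (prefix.name + ".graphml")
        nx.write_graphml(g, gpath)
        written.append(gpath)
    return written


def read_network(path_prefix: str | Path):
    """Re-read a network written by :func:`write_network`."""
    from .network import CorrNetwork

    prefix = Path(path_prefix)
    edges = pd.read_csv(prefix.parent / (prefix.name + "_edges.tsv"), sep="\t")
    nodes = pd.read_csv(prefix.parent / (prefix.name + "_nodes.tsv"), sep="\t")
    kinds = dict(zip(nodes["node"].astype(str), nodes["kind"]))
    if len(edges):
        edges = edges.assign(source=edges["source"].astype(str),
                             target=edges["target"].astype(str))
    return CorrNetwork(edges=edges, node_kinds=kinds,
                       nodes=list(nodes["node"].astype(str)))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated pipeline configuration with the documented defaults."""

    fdr: float = 0.05
    alpha: float = 0.05
    top_fraction: float = 0.25
    resolution: float = 1.0
    seed: int = 0
    knn_k: int = 3
    min_present: int = 2
    tpm_min: float = 5.0
    min_timepoints: int = 2
    phenotype_fdr_only: bool = True
    weighted_leiden: bool = False
    cc_on_full_network: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise ValueError(f"top_fraction must be in (0, 1], got {self.top_fraction}")
        for name in ("fdr", "alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


def read_config(path: str | Path) -> RunConfig:
    """Read a YAML or JSON run configuration; unknown keys are an error."""
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        data = json.loads(text) or {}
    else:
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    known = {f.name for f in dc_fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    return RunConfig(**data)


def write_config(config: RunConfig, path: str | Path) -> None:
    data = {f.name: getattr(config, f.name) for f in dc_fields(RunConfig)}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")
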