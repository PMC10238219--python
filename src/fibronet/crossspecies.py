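"""Cross-species trend validation against human cohort differential tables.

The mouse time-course results are translated through a one-to-one ortholog
map and compared with independently produced human differential tables:
what fraction of a gene set is significant in the cohort, what fraction of
jointly significant genes moves in the same direction, and which genes are
validated (same direction, significant) in the mouse study and two human
cohorts at once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import Partition, composition_stats


def filter_one_to_one(raw_map: dict[str, set[str]] | list[tuple[str, str]]
                      ) -> tuple[dict[str, str], int]:
    """Drop every pair involved in a many-to-many relation.

    Returns the one-to-one mouse -> human map and the number of dropped
    pairs.
    """
    pairs: list[tuple[str, str]] = []
    if isinstance(raw_map, dict):
        for mouse, humans in raw_map.items():
            for h in sorted(humans) if not isinstance(humans, str) else [humans]:
                pairs.append((mouse, h))
    else:
        pairs = list(raw_map)
    mouse_counts: dict[str, int] = {}
    human_counts: dict[str, int] = {}
    for m, h in pairs:
        mouse_counts[m] = mouse_counts.get(m, 0) + 1
        human_counts[h] = human_counts.get(h, 0) + 1
    kept = {m: h for m, h in pairs if mouse_counts[m] == 1 and human_counts[h] == 1}
    if not kept:
        raise ValueError("no one-to-one ortholog pairs remain")
    return kept, len(pairs) - len(kept)


def _significance(table: pd.DataFrame, alpha: float) -> pd.DataFrame:
    t = table.set_index("feature")
    return pd.DataFrame(
        {"sig": t["padj"] < alpha, "sign": np.sign(t["log2fc"])}, index=t.index
    )


def overlap_with_cohort(gene_set: set[str], cohort: pd.DataFrame,
                        ortholog_map: dict[str, str], alpha: float = 0.05,
                        count_unmapped: bool = True) -> tuple[int, float]:
    """How many genes of a (mouse) set are significant in a human cohort.

    Returns (count, percentage of the set size to 2 decimals).  Unmapped
    members stay in the denominator by default.
    """
    cohort_sig = set(cohort.loc[cohort["padj"] < alpha, "feature"])
    mapped = {g: ortholog_map[g] for g in gene_set if g in ortholog_map}
    hits = sum(1 for h in mapped.values() if h in cohort_sig)
    denom = len(gene_set) if count_unmapped else len(mapped)
    pct = round(100.0 * hits / denom, 2) if denom else 0.0
    return hits, pct


def same_trend_fraction(mouse: pd.DataFrame, cohort: pd.DataFrame,
                        ortholog_map: dict[str, str], alpha: float = 0.05,
                        denominator: str = "joint"
                        ) -> tuple[float, pd.DataFrame]:
    """Fraction of genes regulated in the same direction in mouse and cohort.

    With ``denominator='joint'`` (default) the fraction is computed over
    genes significant in *both* tables; ``'mouse'`` uses all mouse-significant
    mapped genes.  Returns (percentage, per-gene table).
    """
    ms = _significance(mouse, alpha)
    cs = _significance(cohort, alpha)
    rows = []
    for gene in mouse["feature"]:
        human = ortholog_map.get(gene)
        if human is None or human not in cs.index:
            continue
        rows.append(
            {
                "mouse_gene": gene,
                "human_gene": human,
                "mouse_sig": bool(ms.loc[gene, "sig"]),
                "cohort_sig": bool(cs.loc[human, "sig"]),
                "mouse_sign": int(ms.loc[gene, "sign"]),
                "cohort_sign": int(cs.loc[human, "sign"]),
            }
        )
    per_gene = pd.DataFrame(rows)
    if per_gene.empty:
        raise ValueError("no mapped genes shared between the tables")
    per_gene["same_trend"] = per_gene["mouse_sign"] == per_gene["cohort_sign"]
    if denominator == "joint":
        pool = per_gene[per_gene["mouse_sig"] & per_gene["cohort_sig"]]
    elif denominator == "mouse":
        pool = per_gene[per_gene["mouse_sig"]]
    else:
        raise ValueError("denominator must be 'joint' or 'mouse'")
    if pool.empty:
        raise ValueError("no jointly significant genes; same-trend fraction undefined")
    pct = round(100.0 * pool["same_trend"].mean(), 2)
    return pct, per_gene


def validated_set(mouse: pd.DataFrame, cohort_a: pd.DataFrame,
                  cohort_b: pd.DataFrame, ortholog_map: dict[str, str],
                  alpha: float = 0.05,
                  partition: Partition | None = None
                  ) -> tuple[set[str], pd.DataFrame | None]:
    """Genes significant with the same sign in the mouse table and both
    human cohorts.

    Optionally reports the subnetwork composition of the validated set
    (restricted to the partition's labels over those genes).
    """
    ms = _significance(mouse, alpha)
    ca = _significance(cohort_a, alpha)
    cb = _significance(cohort_b, alpha)
    validated = set()
    for gene in mouse["feature"]:
        human = ortholog_map.get(gene)
        if human is None or human not in ca.index or human not in cb.index:
            continue
        if not (ms.loc[gene, "sig"] and ca.loc[human, "sig"] and cb.loc[human, "sig"]):
            continue
        if ms.loc[gene, "sign"] == ca.loc[human, "sign"] == cb.loc[human, "sign"]:
            validated.add(gene)
    composition = None
    if partition is not None and validated:
        sizes: dict[int, int] = {}
        for g in validated:
            if g in partition.labels:
                lab = partition.labels[g]
                sizes[lab] = sizes.get(lab, 0) + 1
        if sizes:
            composition = composition_stats(sizes)
    return validated, composition
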