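"""Perturbation-reversal scoring over network subnetworks.

Given a disease differential table (disease vs control) and a perturbation
table (perturbed-disease vs disease, e.g. a receptor knockout under the same
insult), a gene is *reversed* when it is significant in both tables with
opposite fold-change signs.  Each subnetwork is then scored by the fraction
of its disease-dysregulated members that are reversed, the hypergeometric
enrichment of perturbation-affected genes among its members, and a call:
``reversed-up`` / ``reversed-down`` when the enrichment survives BH at the
chosen FDR and the median perturbation sign among dysregulated members
opposes the disease sign, else ``unchanged``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .differential import bh_adjust
from .enrich import hypergeom_pvalue
from .network import Partition

REPORT_COLUMNS = [
    "subnetwork", "n_members", "n_dysregulated", "n_reversed",
    "reversed_fraction", "pvalue", "padj", "call",
]


def _indexed(table: pd.DataFrame, alpha: float) -> pd.DataFrame:
    t = table.set_index("feature")
    return pd.DataFrame(
        {"sig": t["padj"] < alpha, "sign": np.sign(t["log2fc"])}, index=t.index
    )


def reversed_genes(disease: pd.DataFrame, perturbation: pd.DataFrame,
                   alpha: float = 0.05, require_significance: bool = True
                   ) -> set[str]:
    """Genes significant in both tables with opposite signs (or merely with
    opposite point estimates when ``require_significance=False``)."""
    d = _indexed(disease, alpha)
    p = _indexed(perturbation, alpha)
    shared = d.index.intersection(p.index)
    d, p = d.loc[shared], p.loc[shared]
    opposite = (d["sign"] * p["sign"]) < 0
    if require_significance:
        opposite &= d["sig"] & p["sig"]
    return set(shared[opposite])


def reversal_analysis(disease: pd.DataFrame, perturbation: pd.DataFrame,
                      partition: Partition, alpha: float = 0.05,
                      fdr: float = 0.05,
                      require_significance: bool = True) -> pd.DataFrame:
    """Score each subnetwork for perturbation-driven reversal.

    Universe for the enrichment is the set of partitioned genes present in
    both tables (intersected with a warning on mismatch).
    """
    d = _indexed(disease, alpha)
    p = _indexed(perturbation, alpha)
    universe = set(partition.labels) & set(d.index) & set(p.index)
    if len(universe) < len(set(partition.labels)):
        warnings.warn(
            f"{len(set(partition.labels)) - len(universe)} partitioned gene(s) "
            "missing from a differential table; universes intersected"
        )
    if not universe:
        raise ValueError("no partitioned genes shared with the differential tables")
    rev = reversed_genes(disease, perturbation, alpha, require_significance) & universe
    affected = {g for g in universe if p.loc[g, "sig"]}

    rows = []
    for label in sorted(set(partition.labels.values())):
        members = partition.members(label) & universe
        dysregulated = {g for g in members if d.loc[g, "sig"]}
        reversed_here = rev & dysregulated
        pval = hypergeom_pvalue(len(affected & members), len(members),
                                len(affected), len(universe))
        if dysregulated:
            med_pert = float(np.median([p.loc[g, "sign"] for g in sorted(dysregulated)]))
            med_dis = float(np.median([d.loc[g, "sign"] for g in sorted(dysregulated)]))
        else:
            med_pert = med_dis = 0.0
        rows.append(
            {
                "subnetwork": label,
                "n_members": len(members),
                "n_dysregulated": len(dysregulated),
                "n_reversed": len(reversed_here),
                "reversed_fraction": len(reversed_here) / len(dysregulated)
                if dysregulated else 0.0,
                "pvalue": pval,
                "_med_pert": med_pert,
                "_med_dis": med_dis,
            }
        )
    report = pd.DataFrame(rows)
    report["padj"] = bh_adjust(report["pvalue"].to_numpy())

    def _call(row) -> str:
        if row["padj"] <= fdr and row["_med_pert"] != 0 and row["_med_pert"] * row["_med_dis"] < 0:
            return "reversed-up" if row["_med_pert"] > 0 else "reversed-down"
        return "unchanged"

    report["call"] = report.apply(_call, axis=1)
    return report[REPORT_COLUMNS]


def gene_panel_report(panel: set[str], disease: pd.DataFrame,
                      perturbation: pd.DataFrame, alpha: float = 0.05
                      ) -> pd.DataFrame:
    """Per-gene reversal table for a curated panel (e.g. validated track
    target genes).  A panel gene is *attenuated* when it is significant in
    both tables with opposite signs; genes absent from either table are
    flagged missing."""
    d = disease.set_index("feature")
    p = perturbation.set_index("feature")
    rows = []
    for gene in sorted(panel):
        present = gene in d.index and gene in p.index
        if not present:
            rows.append({"gene": gene, "missing": True, "attenuated": False,
                         "disease_log2fc": np.nan, "disease_padj": np.nan,
                         "perturbation_log2fc": np.nan, "perturbation_padj": np.nan})
            continue
        drow, prow = d.loc[gene], p.loc[gene]
        attenuated = (
            drow["padj"] < alpha and prow["padj"] < alpha
            and np.sign(drow["log2fc"]) * np.sign(prow["log2fc"]) < 0
        )
        rows.append(
            {
                "gene": gene,
                "missing": False,
                "attenuated": bool(attenuated),
                "disease_log2fc": float(drow["log2fc"]),
                "disease_padj": float(drow["padj"]),
                "perturbation_log2fc": float(prow["log2fc"]),
                "perturbation_padj": float(prow["padj"]),
            }
        )
    return pd.DataFrame(rows)
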