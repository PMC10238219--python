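"""End-to-end orchestration: simulate -> differential -> networks ->
integration -> cross-species -> reversal, with a reproducibility manifest.

Each stage writes its outputs as TSV/JSON under the output directory; the
manifest records the configuration snapshot, input hashes, seed and the
output file list so a rerun with the same inputs is bit-identical
(timings excluded).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from . import crossspecies as xs
from . import differential as diff
from . import enrich, io, network as net, reversal as rev
from . import simulate as sim
from .io import RunConfig


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def run_all(sim_config: sim.SimConfig, run_config: RunConfig, outdir: str | Path,
            reversed_modules: tuple[int, ...] = (1, 2),
            concordant_fraction: float = 0.75) -> Path:
    """Run the whole synthetic-data pipeline and write a manifest.

    Returns the output directory.  Stage failures raise :class:`StageError`
    naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    timings: dict[str, float] = {}

    def _stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, str(exc)) from exc
                return False

        return _Timer()

    with _stage("simulate"):
        counts, design, truth = sim.generate_counts(sim_config)
        mets_raw, mdesign = sim.generate_metabolites(sim_config, truth)
        phenos, _ = sim.generate_phenotypes(sim_config, truth)
        io.write_matrix(counts, outdir / "counts.tsv")
        io.write_matrix(mets_raw, outdir / "metabolites_raw.tsv")
        io.write_matrix(phenos, outdir / "phenotypes.tsv")
        io.write_design(design, outdir / "design.tsv")
        outputs += [outdir / n for n in
                    ("counts.tsv", "metabolites_raw.tsv", "phenotypes.tsv", "design.tsv")]

    with _stage("differential"):
        factors = diff.size_factors(counts)
        de_tables = {g: diff.de_test(counts, design, g, factors)
                     for g in design.non_reference_groups}
        deg = diff.consistent_deg_sets(list(de_tables.values()), alpha=run_config.alpha)
        for g, t in de_tables.items():
            io.write_differential(t, outdir / f"de_{g}.tsv")
            outputs.append(outdir / f"de_{g}.tsv")
        (outdir / "deg_sets.json").write_text(json.dumps(
            {"DEG-0": sorted(deg.up), "DEG-1": sorted(deg.down)}, indent=1))
        outputs.append(outdir / "deg_sets.json")

    with _stage("metabolomics"):
        filtered, removed = diff.metabolite_missing_filter(
            mets_raw, mdesign, min_present=run_config.min_present)
        imputed = diff.knn_impute(filtered, mdesign, k=run_config.knn_k)
        dm_tables = {g: diff.dm_test(imputed, mdesign, g)
                     for g in mdesign.non_reference_groups}
        dm = diff.recurrent_dm_sets(list(dm_tables.values()), alpha=run_config.alpha,
                                    min_timepoints=run_config.min_timepoints)
        io.write_matrix(imputed, outdir / "metabolites_imputed.tsv")
        (outdir / "dm_sets.json").write_text(json.dumps(
            {"DM-0": sorted(dm.up), "DM-1": sorted(dm.down),
             "removed_by_missingness": sorted(removed)}, indent=1))
        outputs += [outdir / "metabolites_imputed.tsv", outdir / "dm_sets.json"]

    with _stage("networks"):
        import numpy as np
        from .matrix import OmicsMatrix

        norm_counts = counts.values / factors
        gene_mat = OmicsMatrix(np.log2(norm_counts + 1.0), "tpm")
        gcn = net.build_network_with_phenotypes(
            gene_mat, phenos, fdr=run_config.fdr,
            top_fraction=run_config.top_fraction, omics="genes",
            phenotype_fdr_only=run_config.phenotype_fdr_only)
        gcn_part = net.detect_subnetworks(gcn, resolution=run_config.resolution,
                                          seed=run_config.seed,
                                          weighted=run_config.weighted_leiden)
        met_mat = OmicsMatrix(np.log2(imputed.values), "phenotype")
        mcn = net.build_network_with_phenotypes(
            met_mat, None, fdr=run_config.fdr, omics="metabolites")
        mcn_part = net.leiden_partition(mcn, resolution=run_config.resolution,
                                        seed=run_config.seed,
                                        weighted=run_config.weighted_leiden)
        outputs += io.write_network(gcn, gcn_part, outdir / "gcn")
        outputs += io.write_network(mcn, mcn_part, outdir / "mcn")
        centrality = net.phenotype_centrality(gcn)
        (outdir / "phenotype_centrality.json").write_text(
            json.dumps(centrality, indent=1, sort_keys=True))
        outputs.append(outdir / "phenotype_centrality.json")

    with _stage("integrate"):
        gene_map, met_map = sim.make_subsystem_map(
            truth, genes=counts.features, metabolites=imputed.features,
            seed=sim_config.seed)
        gene_universe = {n for n in gcn_part.labels
                        if gcn.node_kinds.get(n) == "gene"}
        met_universe = {n for n in mcn_part.labels
                       if mcn.node_kinds.get(n) == "metabolite"}
        g_prof = enrich.subsystem_profiles(gcn_part, gene_map, gene_universe,
                                           fdr=run_config.fdr)
        m_prof = enrich.subsystem_profiles(mcn_part, met_map, met_universe,
                                           fdr=run_config.fdr)
        bridges = enrich.bridge_networks(g_prof, m_prof, fdr=run_config.fdr)
        enrich.bridges_to_frame(bridges).to_csv(outdir / "bridges.tsv", sep="\t", index=False)
        tracks = sim.make_track_map(truth)
        assoc = enrich.track_association(tracks, gcn_part, gene_universe,
                                         fdr=run_config.fdr)
        assoc.to_csv(outdir / "track_association.tsv", sep="\t", index=False)
        outputs += [outdir / "bridges.tsv", outdir / "track_association.tsv"]

    with _stage("crossspecies"):
        ortho = sim.make_ortholog_map(counts.features)
        mouse_d14 = de_tables.get("d14", list(de_tables.values())[0])
        cohorts = sim.generate_cohort_tables(
            mouse_d14, ortho, concordant_fraction=concordant_fraction,
            seed=sim_config.seed)
        trends = {}
        for i, cohort in enumerate(cohorts, 1):
            pct, _table = xs.same_trend_fraction(mouse_d14, cohort, ortho,
                                                 alpha=run_config.alpha)
            trends[f"cohort{i}_same_trend_pct"] = pct
        validated, composition = xs.validated_set(
            mouse_d14, cohorts[0], cohorts[1], ortho, alpha=run_config.alpha,
            partition=gcn_part)
        summary = {"validated_n": len(validated), **trends}
        (outdir / "crossspecies.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        outputs.append(outdir / "crossspecies.json")

    with _stage("reversal"):
        ko_counts, ko_design = sim.generate_knockout_counts(
            sim_config, truth, reversed_modules=reversed_modules)
        pert = diff.de_test(ko_counts, ko_design, "ko_bleo")
        gene_part = net.Partition(labels={
            n: lab for n, lab in gcn_part.labels.items()
            if gcn.node_kinds.get(n) == "gene"})
        report = rev.reversal_analysis(mouse_d14, pert, gene_part,
                                       alpha=run_config.alpha, fdr=run_config.fdr)
        report.to_csv(outdir / "reversal.tsv", sep="\t", index=False)
        outputs.append(outdir / "reversal.tsv")

    manifest = {
        "version": __version__,
        "sim_config": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in asdict(sim_config).items()},
        "run_config": asdict(run_config),
        "seed": sim_config.seed,
        "outputs": sorted(str(p.relative_to(outdir)) for p in outputs),
        "hashes": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(outputs)},
        "timings_s": timings,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir
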