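"""Synthetic multi-omics time-course generator with planted structure.

The generator emulates the statistical shape of a bleomycin-style fibrosis
time course: five sample groups (control plus four post-treatment time
points) with a handful of replicates each, negative-binomial RNA-seq counts
in which planted gene modules follow distinct temporal trajectories,
lognormal metabolite abundances with detection-limit missingness, pulmonary
function-like phenotype variables driven by module trajectories plus noise,
and sign-concordant "human cohort" differential tables over an ortholog map.

Every planted feature is recorded in a :class:`GroundTruth` object so
downstream stages (differential testing, network community detection,
subsystem bridging, cross-species concordance, perturbation reversal) can be
tested against known structure.  A single integer seed fully determines all
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import OmicsMatrix, StudyDesign

DEFAULT_GROUPS = ("control", "d7", "d14", "d21", "d28")

# Per-module standardized effects over the group sequence (natural-log scale,
# reference group pinned at 0).  The five shapes mirror the canonical
# time-course archetypes: sustained down with a day-14 nadir; early up with
# recovery; progressive up with a plateau; late up; transient up then down.
DEFAULT_TRAJECTORIES = (
    (0.0, -1.2, -2.0, -1.5, -1.0),
    (0.0, 2.2, 1.8, 0.8, 0.3),
    (0.0, 0.6, 1.8, 1.5, 1.4),
    (0.0, -0.8, -0.3, 1.5, 1.7),
    (0.0, 1.2, -0.2, -1.0, -1.4),
)

# Phenotype couplings: lung-function-like parameters riding on module
# trajectories.  Stiffness/elastance/resistance track the progressive module;
# volume parameters track the sustained-down module.
DEFAULT_PHENOTYPE_COUPLINGS = (
    ("stiffness_index", 2, 1, 0.0),
    ("elastance", 2, 1, 0.2),
    ("airway_resistance", 2, 1, 0.3),
    ("FVC", 0, 1, 0.2),
    ("FEV", 0, 1, 0.3),
)


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    ``loading_sd`` sets the typical per-feature loading magnitude: module
    features receive loadings drawn from Normal(loading_sd, 0.1*loading_sd)
    truncated at zero, so ``loading_sd=0`` yields a pure null dataset.
    ``module_fraction`` of the features carry planted structure; the rest
    are unstructured background.
    """

    n_genes: int = 2000
    n_metabolites: int = 300
    n_modules: int = 5
    groups: tuple[str, ...] = DEFAULT_GROUPS
    replicates: int = 5
    module_trajectories: tuple[tuple[float, ...], ...] = DEFAULT_TRAJECTORIES
    loading_sd: float = 1.0
    nb_dispersion: float = 0.05
    baseline_logmean_sd: float = 1.0
    baseline_logmean: float = 4.5
    library_size_range: tuple[float, float] = (0.8, 1.2)
    metabolite_noise_sd: float = 0.25
    metabolite_baseline_sd: float = 1.0
    missing_threshold_quantile: float = 0.10
    missing_prob: float = 0.7
    module_fraction: float = 0.8
    phenotype_couplings: tuple[tuple[str, int, int, float], ...] = DEFAULT_PHENOTYPE_COUPLINGS
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.module_trajectories) < self.n_modules:
            raise ValueError(
                f"{self.n_modules} modules but only "
                f"{len(self.module_trajectories)} trajectories"
            )
        for i, traj in enumerate(self.module_trajectories[: self.n_modules]):
            if len(traj) != len(self.groups):
                raise ValueError(f"trajectory {i} has {len(traj)} entries for "
                                 f"{len(self.groups)} groups")
            if traj[0] != 0.0:
                raise ValueError(f"trajectory {i} must be 0 in the reference group")
        if not 0 <= self.module_fraction <= 1:
            raise ValueError("module_fraction must be in [0, 1]")
        if not 0 <= self.missing_threshold_quantile <= 1:
            raise ValueError("missing_threshold_quantile must be in [0, 1]")
        if not 0 <= self.missing_prob <= 1:
            raise ValueError("missing_prob must be in [0, 1]")
        n_module_genes = int(round(self.module_fraction * self.n_genes))
        if self.n_modules > 0 and n_module_genes < self.n_modules:
            raise ValueError("module sizes exceed available genes")
        for name, idx, sign, _sd in self.phenotype_couplings:
            if not 0 <= idx < self.n_modules:
                raise ValueError(f"phenotype {name!r} references unknown module {idx}")
            if sign not in (-1, 1):
                raise ValueError(f"phenotype {name!r} sign must be +1 or -1")


@dataclass
class GroundTruth:
    """Record of all planted structure for oracle-based testing."""

    gene_modules: dict[str, int]
    metabolite_modules: dict[str, int]
    trajectories: list[np.ndarray]
    phenotype_couplings: list[tuple[str, int, int, float]]
    gene_loadings: dict[str, float] = field(default_factory=dict)
    metabolite_loadings: dict[str, float] = field(default_factory=dict)

    def module_genes(self, module: int) -> list[str]:
        return [g for g, m in self.gene_modules.items() if m == module]

    def module_metabolites(self, module: int) -> list[str]:
        return [m for m, mod in self.metabolite_modules.items() if mod == module]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _sample_ids(config: SimConfig) -> tuple[list[str], StudyDesign]:
    samples, mapping = [], {}
    for g in config.groups:
        for i in range(config.replicates):
            sid = f"{g}_{i + 1}"
            samples.append(sid)
            mapping[sid] = g
    design = StudyDesign(mapping, list(config.groups), config.groups[0])
    return samples, design


def _assign_modules(ids: list[str], n_modules: int, fraction: float) -> dict[str, int]:
    n_planted = int(round(fraction * len(ids)))
    if n_modules == 0 or n_planted == 0:
        return {}
    sizes = np.full(n_modules, n_planted // n_modules, dtype=int)
    sizes[: n_planted % n_modules] += 1
    out, pos = {}, 0
    for m, size in enumerate(sizes):
        for fid in ids[pos: pos + size]:
            out[fid] = m
        pos += size
    return out


def _loadings(rng: np.random.Generator, modules: dict[str, int], scale: float) -> dict[str, float]:
    if scale == 0:
        return {fid: 0.0 for fid in modules}
    draws = rng.normal(scale, 0.1 * scale, size=len(modules))
    return {fid: float(max(d, 0.0)) for fid, d in zip(modules, draws)}


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_counts(config: SimConfig) -> tuple[OmicsMatrix, StudyDesign, GroundTruth]:
    """Simulate a negative-binomial count matrix with planted gene modules.

    Counts for gene g in sample s of group t are drawn from
    NB(mean = L_s * exp(b_g + w_g * traj_{m(g)}(t)), variance = mu + alpha*mu^2)
    where ``L_s`` is a per-sample library-size factor, ``b_g`` a baseline
    log-mean, ``w_g`` the gene's loading and ``alpha`` the dispersion.
    Background genes have loading 0.
    """
    rng = np.random.default_rng([config.seed, 1])
    samples, design = _sample_ids(config)
    genes = [f"gene_{i + 1:04d}" for i in range(config.n_genes)]

    gene_modules = _assign_modules(genes, config.n_modules, config.module_fraction)
    loadings = _loadings(rng, gene_modules, config.loading_sd)
    trajectories = [np.asarray(t, dtype=float)
                    for t in config.module_trajectories[: config.n_modules]]

    baseline = rng.normal(config.baseline_logmean, config.baseline_logmean_sd,
                          size=config.n_genes)
    lib = rng.uniform(*config.library_size_range, size=len(samples))
    group_idx = np.array([config.groups.index(design.sample_to_group[s]) for s in samples])

    log_effect = np.zeros((config.n_genes, len(config.groups)))
    for gi, g in enumerate(genes):
        if g in gene_modules:
            log_effect[gi] = loadings[g] * trajectories[gene_modules[g]]

    mu = lib[None, :] * np.exp(baseline[:, None] + log_effect[:, group_idx])
    if config.nb_dispersion <= 1e-12:
        counts = rng.poisson(mu)
    else:
        n = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(n, n / (n + mu))

    matrix = OmicsMatrix(pd.DataFrame(counts, index=genes, columns=samples), "counts")
    truth = GroundTruth(
        gene_modules=gene_modules,
        metabolite_modules={},
        trajectories=trajectories,
        phenotype_couplings=list(config.phenotype_couplings),
        gene_loadings=loadings,
    )
    return matrix, design, truth


def generate_metabolites(config: SimConfig, truth: GroundTruth
                         ) -> tuple[OmicsMatrix, StudyDesign]:
    """Simulate lognormal metabolite abundances with module structure and
    abundance-dependent (detection-limit-like) missingness.

    Metabolite module m shares the latent trajectory of gene module m, so a
    planted gene-module/metabolite-module pair exists for the integration
    stage.  Entries below the ``missing_threshold_quantile`` of the pooled
    abundance distribution are masked with probability ``missing_prob``.
    """
    rng = np.random.default_rng([config.seed, 2])
    samples, design = _sample_ids(config)
    mets = [f"met_{i + 1:03d}" for i in range(config.n_metabolites)]

    met_modules = _assign_modules(mets, config.n_modules, config.module_fraction)
    loadings = _loadings(rng, met_modules, config.loading_sd)
    truth.metabolite_modules = met_modules
    truth.metabolite_loadings = loadings

    baseline = rng.normal(2.0, config.metabolite_baseline_sd, size=config.n_metabolites)
    group_idx = np.array([config.groups.index(design.sample_to_group[s]) for s in samples])

    log_effect = np.zeros((config.n_metabolites, len(config.groups)))
    for mi, m in enumerate(mets):
        if m in met_modules:
            log_effect[mi] = loadings[m] * truth.trajectories[met_modules[m]]

    log_abund = (baseline[:, None] + log_effect[:, group_idx]
                 + rng.normal(0, config.metabolite_noise_sd,
                              size=(config.n_metabolites, len(samples))))
    abund = np.exp(log_abund)

    if config.missing_threshold_quantile > 0 and config.missing_prob > 0:
        threshold = np.quantile(abund, config.missing_threshold_quantile)
        low = abund < threshold
        mask = low & (rng.uniform(size=abund.shape) < config.missing_prob)
        abund = np.where(mask, np.nan, abund)

    matrix = OmicsMatrix(pd.DataFrame(abund, index=mets, columns=samples),
                         "relative_peak_area")
    return matrix, design


def generate_phenotypes(config: SimConfig, truth: GroundTruth
                        ) -> tuple[OmicsMatrix, StudyDesign]:
    """Phenotype value = sign * module trajectory(group) + Normal(0, noise)."""
    rng = np.random.default_rng([config.seed, 3])
    samples, design = _sample_ids(config)
    group_idx = np.array([config.groups.index(design.sample_to_group[s]) for s in samples])

    rows, names = [], []
    for name, module, sign, noise_sd in config.phenotype_couplings:
        if not 0 <= module < len(truth.trajectories):
            raise ValueError(f"phenotype {name!r} references unknown module {module}")
        base = sign * truth.trajectories[module][group_idx]
        noise = rng.normal(0, noise_sd, size=len(samples)) if noise_sd > 0 else 0.0
        rows.append(base + noise)
        names.append(name)
    matrix = OmicsMatrix(pd.DataFrame(rows, index=names, columns=samples), "phenotype")
    return matrix, design


def generate_cohort_tables(
    mouse_diff: pd.DataFrame,
    ortholog_map: dict[str, str],
    concordant_fraction: float = 0.75,
    seed: int = 0,
    alpha: float = 0.05,
    dropout: float = 0.1,
    n_cohorts: int = 2,
) -> list[pd.DataFrame]:
    """Build synthetic human-cohort differential tables from a mouse table.

    Each mouse-significant gene with an ortholog first drops to
    non-significance with probability ``dropout``; otherwise it stays
    significant in the cohort with the mouse sign (probability
    ``concordant_fraction``) or the opposite sign.  Mouse-non-significant
    genes stay non-significant.  Among genes significant in both species the
    expected same-trend fraction is therefore ``concordant_fraction``.
    """
    if not 0 <= concordant_fraction <= 1:
        raise ValueError("concordant_fraction must be in [0, 1]")
    if not ortholog_map:
        raise ValueError("empty ortholog map")
    rng = np.random.default_rng(seed)
    tables = []
    for cohort_i in range(n_cohorts):
        rows = []
        for rec in mouse_diff.itertuples(index=False):
            human = ortholog_map.get(rec.feature)
            if human is None:
                continue
            mouse_sig = rec.padj < alpha and rec.log2fc != 0
            if mouse_sig and rng.uniform() >= dropout:
                sign = np.sign(rec.log2fc)
                if rng.uniform() >= concordant_fraction:
                    sign = -sign
                lfc = sign * abs(rng.normal(1.5, 0.4))
                p = rng.uniform(1e-8, alpha * 0.5)
            else:
                lfc = rng.normal(0, 0.1)
                p = rng.uniform(max(alpha * 2, 0.2), 1.0)
            rows.append((human, lfc, p))
        table = pd.DataFrame(rows, columns=["feature", "log2fc", "pvalue"])
        # padj kept monotone with p while preserving the planted significance split
        table["padj"] = np.minimum(1.0, table["pvalue"] * 1.2)
        table["contrast"] = f"cohort{cohort_i + 1}_ipf_vs_control"
        tables.append(table)
    return tables


def generate_knockout_counts(
    config: SimConfig,
    truth: GroundTruth,
    reversed_modules: tuple[int, ...],
    timepoint: str = "d14",
) -> tuple[OmicsMatrix, StudyDesign]:
    """Simulate a knockout experiment at one time point.

    Two groups are produced: ``wt_bleo`` (genes keep their disease effect at
    ``timepoint``) and ``ko_bleo`` (genes in ``reversed_modules`` return to
    baseline, all other genes keep the disease effect).  A differential test
    of ko_bleo vs wt_bleo therefore shows effects opposite in sign to the
    disease effect exactly in the reversed modules.
    """
    if timepoint not in config.groups:
        raise ValueError(f"unknown timepoint {timepoint!r}")
    for m in reversed_modules:
        if not 0 <= m < len(truth.trajectories):
            raise ValueError(f"unknown module {m}")
    rng = np.random.default_rng([config.seed, 4])
    t_idx = config.groups.index(timepoint)
    genes = [f"gene_{i + 1:04d}" for i in range(config.n_genes)]
    groups = ["wt_bleo", "ko_bleo"]
    samples, mapping = [], {}
    for g in groups:
        for i in range(config.replicates):
            sid = f"{g}_{i + 1}"
            samples.append(sid)
            mapping[sid] = g
    design = StudyDesign(mapping, groups, "wt_bleo")

    baseline_rng = np.random.default_rng([config.seed, 1])
    baseline = baseline_rng.normal(config.baseline_logmean, config.baseline_logmean_sd,
                                   size=config.n_genes)
    lib = rng.uniform(*config.library_size_range, size=len(samples))

    effect = np.zeros((config.n_genes, 2))  # columns: wt_bleo, ko_bleo
    for gi, g in enumerate(genes):
        if g in truth.gene_modules:
            module = truth.gene_modules[g]
            disease = truth.gene_loadings[g] * truth.trajectories[module][t_idx]
            effect[gi, 0] = disease
            effect[gi, 1] = 0.0 if module in reversed_modules else disease
    col = np.array([groups.index(mapping[s]) for s in samples])
    mu = lib[None, :] * np.exp(baseline[:, None] + effect[:, col])
    if config.nb_dispersion <= 1e-12:
        counts = rng.poisson(mu)
    else:
        n = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(n, n / (n + mu))
    return OmicsMatrix(pd.DataFrame(counts, index=genes, columns=samples), "counts"), design


def make_ortholog_map(genes: list[str]) -> dict[str, str]:
    """One-to-one mouse -> human ID map (uppercased with an ``HS_`` prefix)."""
    return {g: "HS_" + g.upper() for g in genes}


def make_subsystem_map(
    truth: GroundTruth,
    genes: list[str] | None = None,
    metabolites: list[str] | None = None,
    n_background: int = 4,
    seed: int = 0,
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Gene->subsystem and metabolite->subsystem maps.

    Module m's genes and metabolites share subsystem ``subsys_m`` (the
    planted bridge); background features (from ``genes``/``metabolites``)
    are spread over ``n_background`` decoy subsystems.
    """
    rng = np.random.default_rng([seed, 5])
    gene_map: dict[str, set[str]] = {}
    met_map: dict[str, set[str]] = {}
    for g, m in truth.gene_modules.items():
        gene_map[g] = {f"subsys_{m}"}
    for mt, m in truth.metabolite_modules.items():
        met_map[mt] = {f"subsys_{m}"}
    for g in genes or []:
        if g not in gene_map:
            gene_map[g] = {f"decoy_{rng.integers(n_background)}"}
    for mt in metabolites or []:
        if mt not in met_map:
            met_map[mt] = {f"decoy_{rng.integers(n_background)}"}
    return gene_map, met_map


def make_track_map(truth: GroundTruth, modules: tuple[int, ...] | None = None
                   ) -> dict[str, set[str]]:
    """Track -> gene assignments: track T-(m+1) carries module m's genes."""
    if modules is None:
        modules = tuple(sorted(set(truth.gene_modules.values())))
    return {f"T-{m + 1}": set(truth.module_genes(m)) for m in modules}


def fixture_config(seed: int = 1) -> SimConfig:
    """The small deterministic dataset used in unit tests and docs."""
    return SimConfig(
        n_genes=30,
        n_metabolites=12,
        n_modules=3,
        replicates=3,
        loading_sd=1.0,
        nb_dispersion=0.05,
        missing_threshold_quantile=0.10,
        missing_prob=0.7,
        phenotype_couplings=(("stiffness_index", 2, 1, 0.0), ("FVC", 0, 1, 0.2)),
        seed=seed,
    )
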