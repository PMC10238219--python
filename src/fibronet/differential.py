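"""Time-course differential analysis for genes and metabolites.

Genes: library-size normalization by median-of-ratios, then a Welch t-test
on log2(normalized count + 1) for each post-treatment time point against
control, with Benjamini-Hochberg adjustment across genes per contrast.  The
differential stage is deliberately simple and pluggable — downstream stages
only consume (effect sign, adjusted p).

Metabolites: a missingness filter (every time-point group must retain at
least ``min_present`` observed values), per-group k-nearest-neighbour
imputation, then an equal-variance two-sample t-test on relative peak areas
with BH adjustment.

Consistent sets follow the standard time-course conventions: DEG-0/DEG-1
are genes significantly up/down at *every* post-treatment time point, while
DM-0/DM-1 are metabolites significantly up/down at >= 2 time points (and
never significant in the opposite direction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.impute import KNNImputer
from statsmodels.stats.multitest import multipletests

from .matrix import OmicsMatrix, StudyDesign


# ---------------------------------------------------------------------------
# normalization and multiple testing
# ---------------------------------------------------------------------------


def size_factors(counts: OmicsMatrix) -> pd.Series:
    """Median-of-ratios library-size factors.

    For each sample, the factor is the median over all-positive genes of
    count / geometric-mean-across-samples.  Genes with a zero anywhere are
    excluded from the median.
    """
    vals = counts.values.to_numpy(dtype=float)
    positive = (vals > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample")
    v = vals[positive]
    log_geo_mean = np.log(v).mean(axis=1)
    ratios = np.exp(np.log(v) - log_geo_mean[:, None])
    return pd.Series(np.median(ratios, axis=0), index=counts.samples, name="size_factor")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (order-preserving, monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# differential tests
# ---------------------------------------------------------------------------


def _two_sample_rows(a: np.ndarray, b: np.ndarray, equal_var: bool) -> np.ndarray:
    """Row-wise two-sample t-test p-values with the zero-variance convention:
    equal means and zero variance on both sides -> p = 1."""
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # degenerate (zero-variance) rows are handled by the convention below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        equal = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    return p


def de_test(counts: OmicsMatrix, design: StudyDesign, contrast: str,
            factors: pd.Series | None = None) -> pd.DataFrame:
    """Differential expression of ``contrast`` vs the design's reference.

    Per gene: y = log2(count / size_factor + 1); the effect is
    mean(y_contrast) - mean(y_reference); the p-value is a Welch t-test on
    y, BH-adjusted across all tested genes.
    """
    if contrast not in design.groups:
        raise ValueError(f"contrast group {contrast!r} not in design")
    treat = [s for s in design.samples_in(contrast) if s in counts.values.columns]
    ref = [s for s in design.samples_in(design.reference) if s in counts.values.columns]
    if len(treat) < 2 or len(ref) < 2:
        raise ValueError(f"need >= 2 samples per side for {contrast!r} vs reference")
    if factors is None:
        factors = size_factors(counts)
    y = np.log2(counts.values.to_numpy(dtype=float) / factors.reindex(counts.samples).to_numpy() + 1.0)
    y = pd.DataFrame(y, index=counts.features, columns=counts.samples)
    a = y[treat].to_numpy()
    b = y[ref].to_numpy()
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    p = _two_sample_rows(a, b, equal_var=False)
    return pd.DataFrame(
        {
            "feature": counts.features,
            "log2fc": log2fc,
            "pvalue": p,
            "padj": bh_adjust(p),
            "contrast": f"{contrast}_vs_{design.reference}",
        }
    )


def dm_test(matrix: OmicsMatrix, design: StudyDesign, contrast: str) -> pd.DataFrame:
    """Differential metabolite abundance (equal-variance Student t-test).

    Run on imputed relative peak areas; the reported effect is the log2
    ratio of group means.
    """
    if contrast not in design.groups:
        raise ValueError(f"contrast group {contrast!r} not in design")
    if matrix.values.isna().any().any():
        raise ValueError("dm_test requires an imputed (complete) matrix")
    treat = [s for s in design.samples_in(contrast) if s in matrix.values.columns]
    ref = [s for s in design.samples_in(design.reference) if s in matrix.values.columns]
    if len(treat) < 2 or len(ref) < 2:
        raise ValueError(f"need >= 2 samples per side for {contrast!r} vs reference")
    a = matrix.values[treat].to_numpy(dtype=float)
    b = matrix.values[ref].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        effect = np.log2(a.mean(axis=1) / b.mean(axis=1))
    p = _two_sample_rows(a, b, equal_var=True)
    return pd.DataFrame(
        {
            "feature": matrix.features,
            "log2fc": effect,
            "pvalue": p,
            "padj": bh_adjust(p),
            "contrast": f"{contrast}_vs_{design.reference}",
        }
    )


# ---------------------------------------------------------------------------
# consistent sets
# ---------------------------------------------------------------------------


@dataclass
class ConsistentSets:
    """Direction-consistent feature sets across time points.

    ``up`` / ``down`` are DEG-0/DEG-1-style sets for genes (significant at
    every time point) or DM-0/DM-1-style sets for metabolites (significant
    at >= ``min_timepoints`` time points, never the opposite direction).
    """

    up: set[str]
    down: set[str]

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down sets must be disjoint")


def consistent_deg_sets(tables: list[pd.DataFrame], alpha: float = 0.05) -> ConsistentSets:
    """Genes significantly up (DEG-0) / down (DEG-1) at every time point."""
    if len(tables) < 2:
        raise ValueError("need >= 2 time-point tables")
    feature_sets = [set(t["feature"]) for t in tables]
    common = set.intersection(*feature_sets)
    union = set.union(*feature_sets)
    if union - common:
        warnings.warn(f"{len(union - common)} features missing from some tables; excluded")
    up, down = common.copy(), common.copy()
    for t in tables:
        t = t.set_index("feature")
        sig = t["padj"] < alpha
        up &= set(t.index[sig & (t["log2fc"] > 0)])
        down &= set(t.index[sig & (t["log2fc"] < 0)])
    return ConsistentSets(up=up, down=down)


def recurrent_dm_sets(tables: list[pd.DataFrame], alpha: float = 0.05,
                      min_timepoints: int = 2) -> ConsistentSets:
    """Metabolites significantly up (DM-0) / down (DM-1) at >=
    ``min_timepoints`` time points and never significant in the opposite
    direction."""
    if len(tables) < 2:
        raise ValueError("need >= 2 time-point tables")
    up_counts: dict[str, int] = {}
    down_counts: dict[str, int] = {}
    for t in tables:
        sig = t["padj"] < alpha
        for f in t.loc[sig & (t["log2fc"] > 0), "feature"]:
            up_counts[f] = up_counts.get(f, 0) + 1
        for f in t.loc[sig & (t["log2fc"] < 0), "feature"]:
            down_counts[f] = down_counts.get(f, 0) + 1
    up = {f for f, c in up_counts.items() if c >= min_timepoints and f not in down_counts}
    down = {f for f, c in down_counts.items() if c >= min_timepoints and f not in up_counts}
    return ConsistentSets(up=up, down=down)


# ---------------------------------------------------------------------------
# metabolomics preprocessing
# ---------------------------------------------------------------------------


def metabolite_missing_filter(matrix: OmicsMatrix, design: StudyDesign,
                              min_present: int = 2
                              ) -> tuple[OmicsMatrix, list[str]]:
    """Keep a metabolite iff every group has >= ``min_present`` observed
    values; return the filtered matrix and the removed feature list."""
    for g in design.groups:
        n = len([s for s in design.samples_in(g) if s in matrix.values.columns])
        if n < min_present:
            raise ValueError(f"group {g!r} has {n} samples; fewer than min_present={min_present}")
    keep = pd.Series(True, index=matrix.values.index)
    for g in design.groups:
        cols = [s for s in design.samples_in(g) if s in matrix.values.columns]
        keep &= matrix.values[cols].notna().sum(axis=1) >= min_present
    removed = list(matrix.values.index[~keep])
    return OmicsMatrix(matrix.values.loc[keep].copy(), matrix.value_kind), removed


def knn_impute(matrix: OmicsMatrix, design: StudyDesign, k: int = 3) -> OmicsMatrix:
    """Impute missing metabolite values within each time-point group.

    Each group is imputed independently with a k-nearest-neighbour imputer
    over samples (Euclidean distance on co-observed metabolites, uniform
    weights); k is capped at the number of available donor samples.
    Observed values are never changed.
    """
    out = matrix.values.copy()
    for g in design.groups:
        cols = [s for s in design.samples_in(g) if s in matrix.values.columns]
        if not cols:
            continue
        block = matrix.values[cols]
        if block.isna().all(axis=1).any():
            bad = block.index[block.isna().all(axis=1)][0]
            raise ValueError(
                f"metabolite {bad!r} has no observed value in group {g!r}; "
                "apply the missingness filter first"
            )
        if not block.isna().any().any():
            continue
        imputer = KNNImputer(n_neighbors=min(k, max(len(cols) - 1, 1)), weights="uniform")
        # samples are the observations: impute on the transposed block
        imputed = imputer.fit_transform(block.to_numpy(dtype=float).T).T
        out.loc[:, cols] = imputed
    return OmicsMatrix(out, matrix.value_kind)


# ---------------------------------------------------------------------------
# mass-spectrometry arithmetic
# ---------------------------------------------------------------------------

#: m/z tolerance (ppm) per acquisition mode and time tolerance (min) per axis
PPM_TOLERANCE = {"CE": 10.0, "LC": 25.0}
TIME_TOLERANCE = {"MT": 0.5, "RT": 0.3}


def relative_peak_area(metabolite_area: float, internal_standard_area: float,
                       sample_amount: float) -> float:
    """Peak area normalized by internal-standard area and sample amount."""
    if internal_standard_area <= 0:
        raise ValueError("internal standard area must be positive")
    if sample_amount <= 0:
        raise ValueError("sample amount must be positive")
    return metabolite_area / (internal_standard_area * sample_amount)


def mass_error_ppm(measured_mz: float, theoretical_mz: float) -> float:
    """(measured - theoretical) / measured, in parts per million."""
    if measured_mz <= 0:
        raise ValueError("measured m/z must be positive")
    return (measured_mz - theoretical_mz) / measured_mz * 1e6


def within_tolerance(ppm: float, mode: str) -> bool:
    """Check a mass error against the mode's ppm window (CE: +-10, LC: +-25)."""
    if mode not in PPM_TOLERANCE:
        raise ValueError(f"mode must be one of {sorted(PPM_TOLERANCE)}")
    return abs(ppm) <= PPM_TOLERANCE[mode]


def time_within_tolerance(delta_minutes: float, axis: str) -> bool:
    """Check a migration/retention time difference (MT: +-0.5, RT: +-0.3 min)."""
    if axis not in TIME_TOLERANCE:
        raise ValueError(f"axis must be one of {sorted(TIME_TOLERANCE)}")
    return abs(delta_minutes) <= TIME_TOLERANCE[axis]


# ---------------------------------------------------------------------------
# trajectories and PCA
# ---------------------------------------------------------------------------


def zscore_features(matrix: OmicsMatrix) -> pd.DataFrame:
    """Per-feature z-score across all samples (zero-variance features -> 0)."""
    vals = matrix.values.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0) | np.isnan(sd)
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance feature(s); z-scores set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(flat, 0.0, (vals - mean) / np.where(flat, 1.0, sd))
    return pd.DataFrame(z, index=matrix.values.index, columns=matrix.values.columns)


def trajectories(matrix: OmicsMatrix, design: StudyDesign,
                 feature_sets: dict[str, set[str]] | None = None) -> pd.DataFrame:
    """Per-group median of per-feature z-scored values.

    Returns a feature x group table.  With ``feature_sets``, each set's row
    is the per-group median over its members' medians (the usual way a
    subnetwork's temporal trend is summarized).
    """
    if matrix.values.isna().any().any():
        raise ValueError("trajectories require a complete matrix")
    z = zscore_features(matrix)
    per_group = pd.DataFrame(index=z.index, columns=design.groups, dtype=float)
    for g in design.groups:
        cols = [s for s in design.samples_in(g) if s in z.columns]
        per_group[g] = z[cols].median(axis=1)
    if feature_sets is None:
        return per_group
    rows = {}
    for name, members in feature_sets.items():
        present = [f for f in members if f in per_group.index]
        rows[name] = per_group.loc[present].median(axis=0)
    return pd.DataFrame(rows).T[design.groups]


def pca_view(matrix: OmicsMatrix, design: StudyDesign, tpm_min: float = 5.0,
             n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample coordinates on the leading principal components.

    Genes whose maximum abundance exceeds ``tpm_min`` are retained, values
    are log2(x+1)-transformed and feature-centered, and the samples are
    projected onto the leading components.  Returns (coordinates,
    explained-variance fractions).
    """
    from sklearn.decomposition import PCA

    keep = matrix.values.max(axis=1) > tpm_min
    if keep.sum() < 2:
        raise ValueError(f"fewer than 2 genes exceed tpm_min={tpm_min}")
    x = np.log2(matrix.values.loc[keep].to_numpy(dtype=float) + 1.0)
    x = x - x.mean(axis=1, keepdims=True)
    n_components = min(n_components, min(x.T.shape) - 1 if min(x.T.shape) > 1 else 1)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x.T)
    out = pd.DataFrame(coords, index=matrix.samples,
                       columns=[f"PC{i + 1}" for i in range(coords.shape[1])])
    out["group"] = [design.sample_to_group.get(s, "") for s in matrix.samples]
    return out, pca.explained_variance_ratio_
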