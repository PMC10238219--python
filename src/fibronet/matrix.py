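"""Core in-memory containers: feature x sample matrices and study designs.

Everything downstream (differential testing, correlation networks,
enrichment) consumes these two objects.  An :class:`OmicsMatrix` is a thin,
validated wrapper around a pandas DataFrame whose rows are features (genes,
metabolites or phenotype parameters) and whose columns are samples.  A
:class:`StudyDesign` assigns each sample to a group (a time point and/or a
genotype) and names the reference group for contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALUE_KINDS = ("counts", "tpm", "relative_peak_area", "phenotype")

#: value kinds whose matrices may contain missing entries
_MISSING_ALLOWED = ("relative_peak_area", "phenotype")


@dataclass
class OmicsMatrix:
    """A feature x sample numeric table.

    Parameters
    ----------
    values
        DataFrame with feature IDs as the index and sample IDs as columns.
    value_kind
        One of ``counts`` (non-negative integers), ``tpm``,
        ``relative_peak_area`` (non-negative reals; NaN allowed) or
        ``phenotype`` (any reals; NaN allowed).
    """

    values: pd.DataFrame
    value_kind: str

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(
                f"unknown value_kind {self.value_kind!r}; expected one of {VALUE_KINDS}"
            )
        self.values.index = self.values.index.astype(str).rename("feature")
        self.values.columns = self.values.columns.astype(str).rename(None)
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dupes = sorted(idx[idx.duplicated()].unique())
            raise ValueError(f"duplicate feature IDs: {dupes[:5]}")
        if cols.duplicated().any():
            dupes = sorted(cols[cols.duplicated()].unique())
            raise ValueError(f"duplicate sample IDs: {dupes[:5]}")
        vals = self.values.to_numpy(dtype=float)
        has_nan = np.isnan(vals).any()
        if has_nan and self.value_kind not in _MISSING_ALLOWED:
            bad = self.values.isna().stack()
            row, col = bad[bad].index[0]
            raise ValueError(
                f"missing value not allowed in a {self.value_kind} matrix "
                f"(feature {row!r}, sample {col!r})"
            )
        if self.value_kind == "counts":
            with np.errstate(invalid="ignore"):
                if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
                    raise ValueError("counts must be non-negative integers")
        elif self.value_kind in ("tpm", "relative_peak_area"):
            with np.errstate(invalid="ignore"):
                if np.nanmin(vals) < 0 if vals.size else False:
                    raise ValueError(f"{self.value_kind} values must be non-negative")

    # -- convenience accessors -------------------------------------------------

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, samples: list[str]) -> "OmicsMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return OmicsMatrix(self.values.loc[:, samples].copy(), self.value_kind)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, m = self.shape
        return f"OmicsMatrix({n} features x {m} samples, kind={self.value_kind})"


@dataclass
class StudyDesign:
    """Sample -> group assignment with an ordered group list and a reference.

    The group order is the biological time order (e.g. ``control, d7, d14,
    d21, d28``); the reference group is the baseline for all contrasts.
    """

    sample_to_group: dict[str, str]
    groups: list[str]
    reference: str

    def __post_init__(self) -> None:
        if self.reference not in self.groups:
            raise ValueError(f"reference group {self.reference!r} not in group list")
        unknown = sorted(set(self.sample_to_group.values()) - set(self.groups))
        if unknown:
            raise ValueError(f"samples assigned to unlisted groups: {unknown}")

    def samples_in(self, group: str) -> list[str]:
        if group not in self.groups:
            raise KeyError(f"unknown group {group!r}")
        return [s for s, g in self.sample_to_group.items() if g == group]

    @property
    def non_reference_groups(self) -> list[str]:
        return [g for g in self.groups if g != self.reference]

    def validate_against(self, matrix: OmicsMatrix, min_per_group: int = 2) -> None:
        """Check every matrix sample is assigned and groups are big enough."""
        unassigned = [s for s in matrix.samples if s not in self.sample_to_group]
        if unassigned:
            raise ValueError(f"samples without a group assignment: {unassigned[:5]}")
        for g in self.groups:
            n = len([s for s in self.samples_in(g) if s in matrix.values.columns])
            if 0 < n < min_per_group:
                raise ValueError(
                    f"group {g!r} has only {n} sample(s); need >= {min_per_group}"
                )

    def group_vector(self, samples: list[str]) -> list[str]:
        return [self.sample_to_group[s] for s in samples]
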