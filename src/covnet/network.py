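"""Group-level weighted structural covariance networks.

Pipeline per group: residualize each region's volumes on [1, age, sex] by
ordinary least squares, Pearson-correlate the residuals across subjects, and
zero every negative coefficient. The result is a symmetric weighted adjacency
matrix with zero diagonal and entries in [0, 1] — one network per group, not
per subject.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .cohort import Cohort
from .regions import RegionSet

__all__ = [
    "ResidualMatrix",
    "residualize_arrays",
    "correlation_weights",
    "ConnectivityMatrix",
    "residualize",
    "build_network",
    "group_network",
    "write_matrix",
    "read_matrix",
    "write_edge_list",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResidualMatrix:
    """Subjects x regions residual volumes after removing age/sex effects."""

    values: np.ndarray
    region_set: RegionSet
    group: str

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 2 or vals.shape[1] != len(self.region_set):
            raise ValueError("values must be subjects x regions")
        col_means = vals.mean(axis=0)
        scale = np.abs(vals).max(axis=0) + 1.0
        if np.any(np.abs(col_means) / scale > 1e-8):
            raise ValueError("residual columns must have mean ~0 (intercept in design)")


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric weighted adjacency over a region set (negatives zeroed)."""

    weights: np.ndarray
    region_set: RegionSet
    group: str
    n_subjects: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        n = len(self.region_set)
        if w.shape != (n, n):
            raise ValueError(f"weights shape {w.shape} != ({n}, {n})")
        if not np.array_equal(w, w.T):
            raise ValueError("weights must be exactly symmetric")
        if np.any(np.diag(w) != 0.0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(w < 0) or np.any(w > 1) or not np.all(np.isfinite(w)):
            raise ValueError("weights must lie in [0, 1]")


def residualize_arrays(
    volumes: np.ndarray,
    ages: np.ndarray,
    sexes: np.ndarray,
    *,
    group: str = "group",
    region_labels: Sequence[str] | None = None,
) -> np.ndarray:
    """Array-level core of :func:`residualize` (shared with the permutation
    fast path so observed and permuted statistics use identical arithmetic)."""
    n = volumes.shape[0]
    if np.ptp(ages) == 0:
        raise ValueError(f"group {group!r}: age is constant; cannot adjust for age")
    columns = [np.ones(n), np.asarray(ages, dtype=float)]
    if np.ptp(sexes) == 0:
        warnings.warn(
            f"group {group!r}: sex is constant; dropping sex from the design",
            UserWarning,
            stacklevel=3,
        )
    else:
        columns.append(np.asarray(sexes, dtype=float))
    design = np.column_stack(columns)
    if n < design.shape[1] + 1:
        raise ValueError(
            f"group {group!r}: {n} subjects < {design.shape[1] + 1} required for "
            "residualization with nonzero error degrees of freedom"
        )
    constant = np.flatnonzero(volumes.std(axis=0) == 0)
    for j in constant:
        label = region_labels[j] if region_labels is not None else f"column {j}"
        warnings.warn(
            f"group {group!r}: region {label!r} has zero variance; "
            "its residuals are all zero",
            UserWarning,
            stacklevel=3,
        )
    beta, *_ = np.linalg.lstsq(design, volumes, rcond=None)
    return volumes - design @ beta


def residualize(cohort_group: Cohort) -> ResidualMatrix:
    """OLS residuals of each region's volumes on [1, age, sex].

    The group must be homogeneous (single label). A constant sex column is
    dropped from the design with a warning; constant age is an error (age is
    then collinear with the intercept). Zero-variance volume columns come out
    as all-zero residuals with a warning naming the region.
    """
    labels = cohort_group.group_labels()
    if len(labels) != 1:
        raise ValueError(f"expected a single-group cohort, got groups {labels}")
    group = labels[0]
    residuals = residualize_arrays(
        cohort_group.volumes,
        cohort_group.ages,
        cohort_group.sexes,
        group=group,
        region_labels=cohort_group.region_set.regions,
    )
    return ResidualMatrix(residuals, cohort_group.region_set, group)


def correlation_weights(
    residual_values: np.ndarray,
    *,
    group: str = "group",
    region_labels: Sequence[str] | None = None,
) -> np.ndarray:
    """Array-level core of :func:`build_network`: Pearson correlations of
    residual columns, negatives and diagonal zeroed, exact symmetry."""
    vals = residual_values
    n = vals.shape[0]
    if n < 4:
        raise ValueError(f"need >= 4 subjects to correlate, got {n}")
    degenerate = np.flatnonzero(vals.std(axis=0) == 0)
    for j in degenerate:
        label = region_labels[j] if region_labels is not None else f"column {j}"
        warnings.warn(
            f"group {group!r}: region {label!r} has zero residual variance; "
            "its edge weights are set to 0",
            UserWarning,
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    if degenerate.size:
        corr[degenerate, :] = 0.0
        corr[:, degenerate] = 0.0
    upper = np.triu(np.clip(corr, 0.0, 1.0), k=1)
    return upper + upper.T


def build_network(residuals: ResidualMatrix) -> ConnectivityMatrix:
    """Pearson-correlate residual columns; zero negatives and the diagonal.

    Correlations are computed once per unordered pair (upper triangle mirrored)
    so symmetry is exact. All-zero (or zero-variance) residual columns get
    weight 0 against every other region, with a warning.
    """
    weights = correlation_weights(
        residuals.values,
        group=residuals.group,
        region_labels=residuals.region_set.regions,
    )
    return ConnectivityMatrix(
        weights, residuals.region_set, residuals.group, residuals.values.shape[0]
    )


def group_network(cohort: Cohort, group: str) -> ConnectivityMatrix:
    """Covariance network for one group: residualize then correlate."""
    return build_network(residualize(cohort.restrict_group(group)))


# -- matrix IO ---------------------------------------------------------------


def write_matrix(matrix: ConnectivityMatrix, path: Union[str, Path]) -> None:
    """Square TSV with region labels on both axes, full double precision."""
    frame = pd.DataFrame(
        matrix.weights,
        index=matrix.region_set.regions,
        columns=matrix.region_set.regions,
    )
    frame.to_csv(path, sep="\t", float_format="%.17g", index_label="region")


def read_matrix(
    path: Union[str, Path], *, group: str = "unknown", n_subjects: int = 0,
    name: str = "custom",
) -> ConnectivityMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    labels = tuple(frame.columns)
    if tuple(frame.index) != labels:
        raise ValueError(f"matrix file {path}: row and column labels differ")
    w = frame.to_numpy(dtype=float)
    w = np.triu(w, k=1) + np.triu(w, k=1).T  # restore exact symmetry after text round-trip
    return ConnectivityMatrix(w, RegionSet(name, labels), group, n_subjects)


def write_edge_list(matrix: ConnectivityMatrix, path: Union[str, Path]) -> None:
    """Long-format edges (region_a, region_b, weight) for i < j."""
    labels = matrix.region_set.regions
    i_idx, j_idx = np.triu_indices(len(labels), k=1)
    frame = pd.DataFrame(
        {
            "region_a": [labels[i] for i in i_idx],
            "region_b": [labels[j] for j in j_idx],
            "weight": matrix.weights[i_idx, j_idx],
        }
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
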