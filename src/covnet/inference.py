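"""Permutation comparison of group-level network measures, with BH FDR.

Because the covariance network (and hence every measure) exists only at the
group level, significance comes from relabeling: subjects of both groups are
pooled and randomly split into pseudo-groups of the original sizes, and the
*entire* pipeline — residualize within pseudo-group, build the network,
compute all measures — is recomputed per permutation.

The reported confidence interval is the percentile interval of the null
permutation distribution of differences (it is NOT centered on the observed
difference, so it need not bracket it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cohort import Cohort
from .metrics import MEASURE_NAMES, all_measures
from .network import correlation_weights, residualize_arrays

__all__ = [
    "PermutationConfig",
    "ComparisonResult",
    "permutation_null",
    "permutation_pvalue",
    "permutation_ci",
    "fdr_bh",
    "compare_groups",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermutationConfig:
    n_permutations: int = 1000
    seed: int = 0
    alpha: float = 0.05
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100 for reported p-values")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class ComparisonResult:
    """One measure's between-group comparison (machine-readable table row)."""

    measure: str
    value_group_a: float
    value_group_b: float
    difference: float  # b - a
    ci_lower: float
    ci_upper: float
    p_raw: float
    p_adjusted: float
    significant: bool


def _group_arrays(cohort: Cohort) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return cohort.volumes, cohort.ages, cohort.sexes


def _measures_from_arrays(
    region_set, group: str, volumes: np.ndarray, ages: np.ndarray, sexes: np.ndarray,
    distance: str,
) -> np.ndarray:
    # same arithmetic as group_network + all_measures, minus per-call
    # container validation (this runs once per permutation)
    residuals = residualize_arrays(
        volumes, ages, sexes, group=group, region_labels=region_set.regions
    )
    weights = correlation_weights(
        residuals, group=group, region_labels=region_set.regions
    )
    return all_measures(weights, distance=distance).as_array()


def permutation_null(
    cohort_a: Cohort,
    cohort_b: Cohort,
    config: PermutationConfig,
    *,
    distance: str = "inverse-weight",
) -> np.ndarray:
    """Null distribution of per-measure differences (pseudo-B minus pseudo-A).

    Returns an ``n_permutations x len(MEASURE_NAMES)`` array. Permutations
    whose pseudo-groups violate the residualization preconditions are redrawn
    (logged), up to ``10 * n_permutations`` attempts in total.
    """
    if cohort_a.region_set.regions != cohort_b.region_set.regions:
        raise ValueError("cohorts must share the same region set")
    region_set = cohort_a.region_set
    vols = np.vstack([cohort_a.volumes, cohort_b.volumes])
    ages = np.concatenate([cohort_a.ages, cohort_b.ages])
    sexes = np.concatenate([cohort_a.sexes, cohort_b.sexes])
    n_a = cohort_a.n_subjects
    n_total = n_a + cohort_b.n_subjects

    rng = np.random.default_rng(config.seed)
    null = np.empty((config.n_permutations, len(MEASURE_NAMES)))
    attempts = 0
    max_attempts = 10 * config.n_permutations
    done = 0
    while done < config.n_permutations:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"exceeded {max_attempts} permutation attempts "
                f"({done}/{config.n_permutations} usable)"
            )
        attempts += 1
        perm = rng.permutation(n_total)
        idx_a, idx_b = perm[:n_a], perm[n_a:]
        try:
            m_a = _measures_from_arrays(
                region_set, "permA", vols[idx_a], ages[idx_a], sexes[idx_a], distance
            )
            m_b = _measures_from_arrays(
                region_set, "permB", vols[idx_b], ages[idx_b], sexes[idx_b], distance
            )
        except ValueError as exc:
            logger.info("redrawing degenerate permutation %d: %s", attempts, exc)
            continue
        null[done] = m_b - m_a
        done += 1
    if attempts > config.n_permutations:
        logger.info(
            "permutation_null: %d redraws over %d permutations",
            attempts - config.n_permutations, config.n_permutations,
        )
    return null


def permutation_pvalue(observed_diff: float, null_diffs: np.ndarray) -> float:
    """Two-sided p = (#{|null| >= |observed|} + 1) / (n + 1).

    NaN null entries (measures undefined on a pseudo-network) are dropped; a
    NaN observed difference yields a NaN p-value.
    """
    null = np.asarray(null_diffs, dtype=float)
    if null.size == 0:
        raise ValueError("null_diffs must be non-empty")
    if np.isnan(observed_diff):
        return float("nan")
    valid = null[~np.isnan(null)]
    if valid.size < null.size:
        logger.info("permutation_pvalue: dropped %d NaN null draws", null.size - valid.size)
    if valid.size == 0:
        return float("nan")
    exceed = int(np.sum(np.abs(valid) >= abs(observed_diff)))
    return (exceed + 1) / (valid.size + 1)


def permutation_ci(null_diffs: np.ndarray, ci_level: float = 0.95) -> tuple[float, float]:
    """Percentile interval of the null difference distribution."""
    null = np.asarray(null_diffs, dtype=float)
    valid = null[~np.isnan(null)]
    if valid.size < 40:
        raise ValueError(f"need >= 40 null values for a percentile CI, got {valid.size}")
    tail = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(valid, [tail, 1.0 - tail])
    return float(lo), float(hi)


def fdr_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, returned in input order.

    q_(i) = min_{j >= i} (m / j) * p_(j), capped at 1, for ascending p_(1..m).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted


def compare_groups(
    cohort_a: Cohort,
    cohort_b: Cohort,
    config: Optional[PermutationConfig] = None,
    *,
    distance: str = "inverse-weight",
    include_average_degree: bool = True,
    null_out: Optional[list] = None,
) -> list[ComparisonResult]:
    """Full permutation comparison of every network measure between two groups.

    The BH family is the measure set of this one comparison; measures with an
    undefined (NaN) raw p are excluded from the family and reported with NaN
    adjusted p. Pass a list as ``null_out`` to receive the raw null matrix.
    """
    config = config or PermutationConfig()
    label_a = cohort_a.group_labels()[0] if len(cohort_a.group_labels()) == 1 else "A"
    label_b = cohort_b.group_labels()[0] if len(cohort_b.group_labels()) == 1 else "B"

    obs_a = _measures_from_arrays(
        cohort_a.region_set, label_a, *_group_arrays(cohort_a), distance
    )
    obs_b = _measures_from_arrays(
        cohort_b.region_set, label_b, *_group_arrays(cohort_b), distance
    )
    null = permutation_null(cohort_a, cohort_b, config, distance=distance)
    if null_out is not None:
        null_out.append(null)

    keep = [
        i for i, name in enumerate(MEASURE_NAMES)
        if include_average_degree or name != "average_degree"
    ]
    diffs = obs_b - obs_a
    p_raw = np.array([permutation_pvalue(diffs[i], null[:, i]) for i in keep])
    finite = np.flatnonzero(~np.isnan(p_raw))
    p_adj = np.full(len(keep), np.nan)
    if finite.size:
        p_adj[finite] = fdr_bh(p_raw[finite])

    results = []
    for pos, i in enumerate(keep):
        valid = np.sum(~np.isnan(null[:, i]))
        if valid >= 40:
            lo, hi = permutation_ci(null[:, i], config.ci_level)
        else:
            logger.info(
                "compare_groups: %s has only %d defined null draws; CI undefined",
                MEASURE_NAMES[i], valid,
            )
            lo, hi = float("nan"), float("nan")
        adj = p_adj[pos]
        results.append(
            ComparisonResult(
                measure=MEASURE_NAMES[i],
                value_group_a=float(obs_a[i]),
                value_group_b=float(obs_b[i]),
                difference=float(diffs[i]),
                ci_lower=lo,
                ci_upper=hi,
                p_raw=float(p_raw[pos]),
                p_adjusted=float(adj),
                significant=bool(adj < config.alpha) if not np.isnan(adj) else False,
            )
        )
    return results
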