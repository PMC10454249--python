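"""Cohort container and delimited-text IO.

A cohort is a subjects x regions volume table plus per-subject covariates
(group label, age in years, sex coded 0/1). The on-disk layout is a single
delimited file (comma or tab, auto-detected) with header
``subject_id, group, age, sex, <region 1>, <region 2>, ...``.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .regions import RegionSet

__all__ = ["SubjectRecord", "Cohort", "read_cohort", "write_cohort"]

_META_COLUMNS = ("subject_id", "group", "age", "sex")

_SEX_CODES = {"0": 0, "1": 1, "f": 0, "m": 1, "female": 0, "male": 1}


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: identifier, group label, covariates, region volumes (mm^3)."""

    subject_id: str
    group: str
    age: float
    sex: int
    volumes: tuple[float, ...]

    def __post_init__(self) -> None:
        if not np.isfinite(self.age) or self.age < 0:
            raise ValueError(f"subject {self.subject_id!r}: age must be nonnegative finite")
        if self.sex not in (0, 1):
            raise ValueError(f"subject {self.subject_id!r}: sex must be 0 or 1")
        vols = np.asarray(self.volumes, dtype=float)
        if not np.all(np.isfinite(vols)) or np.any(vols <= 0):
            raise ValueError(
                f"subject {self.subject_id!r}: volumes must be strictly positive and finite"
            )


class Cohort:
    """Subjects sharing one :class:`RegionSet`.

    Stored column-major as numpy arrays for fast residualization and
    permutation; :attr:`subjects` materializes :class:`SubjectRecord` views.
    """

    def __init__(
        self,
        region_set: RegionSet,
        subject_ids: Sequence[str],
        groups: Sequence[str],
        ages: Sequence[float],
        sexes: Sequence[int],
        volumes: np.ndarray,
        *,
        min_group_size: int = 4,
    ) -> None:
        self.region_set = region_set
        self.subject_ids = np.asarray(subject_ids, dtype=object)
        self.groups = np.asarray(groups, dtype=object)
        self.ages = np.asarray(ages, dtype=float)
        self.sexes = np.asarray(sexes, dtype=int)
        self.volumes = np.asarray(volumes, dtype=float)

        n = len(self.subject_ids)
        if self.volumes.shape != (n, len(region_set)):
            raise ValueError(
                f"volumes shape {self.volumes.shape} != "
                f"(n_subjects={n}, n_regions={len(region_set)})"
            )
        if len(self.groups) != n or len(self.ages) != n or len(self.sexes) != n:
            raise ValueError("covariate arrays must all have one entry per subject")
        ids = list(self.subject_ids)
        if len(set(ids)) != n:
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise ValueError(f"duplicated subject IDs: {dupes}")
        bad = ~np.isfinite(self.volumes) | (self.volumes <= 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-positive or non-finite volume for subject "
                f"{self.subject_ids[i]!r}, region {region_set.regions[j]!r}"
            )
        if not np.all(np.isin(self.sexes, (0, 1))):
            raise ValueError("sex must be coded 0/1")
        if np.any(~np.isfinite(self.ages)) or np.any(self.ages < 0):
            raise ValueError("ages must be nonnegative and finite")
        for g, count in zip(*np.unique(self.groups, return_counts=True)):
            if count < min_group_size:
                raise ValueError(
                    f"group {g!r} has {count} subjects; at least {min_group_size} "
                    "are required for residualization on intercept+age+sex"
                )

    # -- construction ------------------------------------------------------

    @classmethod
    def from_subjects(cls, region_set: RegionSet, subjects: Iterable[SubjectRecord]) -> "Cohort":
        records = list(subjects)
        for rec in records:
            if len(rec.volumes) != len(region_set):
                raise ValueError(
                    f"subject {rec.subject_id!r}: {len(rec.volumes)} volumes for "
                    f"{len(region_set)}-region set"
                )
        return cls(
            region_set,
            [r.subject_id for r in records],
            [r.group for r in records],
            [r.age for r in records],
            [r.sex for r in records],
            np.array([r.volumes for r in records], dtype=float),
        )

    # -- views -------------------------------------------------------------

    @property
    def subjects(self) -> list[SubjectRecord]:
        return [
            SubjectRecord(sid, grp, age, int(sex), tuple(vol))
            for sid, grp, age, sex, vol in zip(
                self.subject_ids, self.groups, self.ages, self.sexes, self.volumes
            )
        ]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def group_labels(self) -> list[str]:
        """Group labels present, in order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def group_sizes(self) -> dict[str, int]:
        return {g: int(np.sum(self.groups == g)) for g in self.group_labels()}

    def restrict_group(self, group: str) -> "Cohort":
        """Subjects of one group only."""
        if group not in self.groups:
            raise KeyError(
                f"unknown group {group!r}; available groups: {self.group_labels()}"
            )
        mask = self.groups == group
        return Cohort(
            self.region_set,
            self.subject_ids[mask],
            self.groups[mask],
            self.ages[mask],
            self.sexes[mask],
            self.volumes[mask],
        )

    def restrict_regions(self, labels: Sequence[str], name: str | None = None) -> "Cohort":
        """Keep only the named region columns, in the order given."""
        sub = self.region_set.subset(labels, name=name)
        idx = [self.region_set.index(lab) for lab in labels]
        return Cohort(
            sub, self.subject_ids, self.groups, self.ages, self.sexes,
            self.volumes[:, idx],
        )

    def to_frame(self) -> pd.DataFrame:
        data = {
            "subject_id": self.subject_ids,
            "group": self.groups,
            "age": self.ages,
            "sex": self.sexes,
        }
        for j, lab in enumerate(self.region_set.regions):
            data[lab] = self.volumes[:, j]
        return pd.DataFrame(data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            self.region_set == other.region_set
            and list(self.subject_ids) == list(other.subject_ids)
            and list(self.groups) == list(other.groups)
            and np.array_equal(self.ages, other.ages)
            and np.array_equal(self.sexes, other.sexes)
            and np.array_equal(self.volumes, other.volumes)
        )


def _normalize_sex(values: pd.Series) -> np.ndarray:
    out = np.empty(len(values), dtype=int)
    for i, v in enumerate(values):
        key = str(v).strip().lower()
        if key.endswith(".0"):
            key = key[:-2]
        if key not in _SEX_CODES:
            raise ValueError(
                f"unrecognized sex code {v!r} (row {i}); accepted: 0/1, F/M, female/male"
            )
        out[i] = _SEX_CODES[key]
    return out


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def write_cohort(cohort: Cohort, path: Union[str, Path], *, delimiter: str = ",") -> None:
    """Write a cohort as delimited text (header + one row per subject)."""
    frame = cohort.to_frame()
    buf = io.StringIO()
    frame.to_csv(buf, sep=delimiter, index=False, float_format="%.12g")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_cohort(path: Union[str, Path], *, region_set_name: str = "custom") -> Cohort:
    """Read a cohort file, validating columns, codes and volume positivity.

    Region columns are every column after the four required metadata columns,
    in file order.
    """
    path = Path(path)
    delim = _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=delim, dtype={"subject_id": str, "group": str})
    missing = [c for c in _META_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing required columns: {missing}")
    region_cols = [c for c in frame.columns if c not in _META_COLUMNS]
    if len(region_cols) < 3:
        raise ValueError(
            f"cohort file {path} has {len(region_cols)} region columns; need >= 3"
        )
    vols = frame[region_cols]
    non_numeric = [c for c in region_cols if not pd.api.types.is_numeric_dtype(vols[c])]
    if non_numeric:
        raise ValueError(f"non-numeric volume columns: {non_numeric}")
    values = vols.to_numpy(dtype=float)
    bad = ~np.isfinite(values) | (values <= 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid volume for subject {frame['subject_id'].iloc[i]!r}, "
            f"region {region_cols[j]!r}: {values[i, j]!r}"
        )
    ids = frame["subject_id"].tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicated subject IDs in {path}: {dupes}")
    region_set = RegionSet(region_set_name, tuple(region_cols))
    return Cohort(
        region_set,
        ids,
        frame["group"].tolist(),
        frame["age"].to_numpy(dtype=float),
        _normalize_sex(frame["sex"]),
        values,
    )
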