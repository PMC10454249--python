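"""Run configuration: YAML parsing and validation for end-to-end pipelines."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import yaml

from .cohort import Cohort
from .inference import PermutationConfig
from .metrics import DISTANCE_CONVENTIONS
from .synthetic import SyntheticSpec, make_correlation_template

__all__ = ["RunConfig", "load_run_config", "load_synthetic_spec"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``network_specs`` maps network name -> ordered list of region columns;
    ``comparisons`` is a list of (group_a, group_b) pairs.
    """

    cohort_path: Path
    network_specs: dict[str, list[str]]
    comparisons: list[tuple[str, str]]
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    distance_convention: str = "inverse-weight"
    include_average_degree: bool = True
    dump_null: bool = False
    output_dir: Path = Path("covnet_results")

    def __post_init__(self) -> None:
        self.cohort_path = Path(self.cohort_path)
        self.output_dir = Path(self.output_dir)
        if self.distance_convention not in DISTANCE_CONVENTIONS:
            raise ValueError(
                f"distance_convention must be one of {DISTANCE_CONVENTIONS}, "
                f"got {self.distance_convention!r}"
            )
        if not self.network_specs:
            raise ValueError("at least one network_spec is required")
        if not self.comparisons:
            raise ValueError("at least one comparison is required")

    def validate_against(self, cohort: Cohort) -> None:
        """Check every region column and comparison group exists in the cohort."""
        available = set(cohort.region_set.regions)
        for name, cols in self.network_specs.items():
            missing = [c for c in cols if c not in available]
            if missing:
                raise ValueError(
                    f"network {name!r} names region columns absent from the "
                    f"cohort file: {missing}"
                )
        groups = set(cohort.group_labels())
        for a, b in self.comparisons:
            for g in (a, b):
                if g not in groups:
                    raise ValueError(
                        f"comparison group {g!r} not in cohort groups {sorted(groups)}"
                    )


def load_run_config(path: Union[str, Path], **overrides) -> RunConfig:
    """Load a RunConfig from YAML; keyword overrides win over file values."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, Mapping):
        raise ValueError(f"config file {path} must contain a mapping")
    perm = dict(raw.get("permutation", {}))
    cfg = dict(
        cohort_path=raw["cohort_path"],
        network_specs={str(k): list(v) for k, v in raw["networks"].items()},
        comparisons=[tuple(pair) for pair in raw["comparisons"]],
        permutation=PermutationConfig(**perm),
        distance_convention=raw.get("distance_convention", "inverse-weight"),
        include_average_degree=bool(raw.get("include_average_degree", True)),
        dump_null=bool(raw.get("dump_null", False)),
        output_dir=raw.get("output_dir", "covnet_results"),
    )
    cfg.update(overrides)
    return RunConfig(**cfg)


def _correlation_from_config(entry, n_regions: int) -> np.ndarray:
    """A correlation matrix either given explicitly or as a template recipe."""
    if isinstance(entry, Mapping):
        return make_correlation_template(
            n_regions,
            style=entry.get("style", "uniform"),
            strength=float(entry.get("strength", 0.5)),
            seed=int(entry.get("seed", 0)),
            block_size=int(entry.get("block_size", 3)),
            ring_neighbors=int(entry.get("ring_neighbors", 2)),
        )
    return np.asarray(entry, dtype=float)


def load_synthetic_spec(path: Union[str, Path], *, seed: Optional[int] = None) -> SyntheticSpec:
    """Load a SyntheticSpec from YAML.

    ``correlation`` entries may be explicit matrices (nested lists) or
    template recipes ``{style, strength, ...}``.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    n = int(raw["region_count"])
    groups = raw["groups"]  # name -> {size, correlation}
    group_sizes = {g: int(v["size"]) for g, v in groups.items()}
    target = {g: _correlation_from_config(v["correlation"], n) for g, v in groups.items()}
    age = raw.get("age_distribution", {})
    return SyntheticSpec(
        group_sizes=group_sizes,
        region_count=n,
        mean_volumes=np.asarray(raw.get("mean_volumes", 1000.0), dtype=float),
        age_effect=np.asarray(raw.get("age_effect", 0.0), dtype=float),
        sex_effect=np.asarray(raw.get("sex_effect", 0.0), dtype=float),
        target_correlation=target,
        noise_sd=np.asarray(raw.get("noise_sd", 50.0), dtype=float),
        age_distribution=(
            float(age.get("mean", 69.9)), float(age.get("sd", 11.9)),
        ),
        sex_balance=float(raw.get("sex_balance", 0.47)),
        seed=int(raw["seed"] if seed is None else seed),
    )
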