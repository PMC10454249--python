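"""End-to-end orchestration: cohort file -> networks -> comparisons -> tables."""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, read_cohort, write_cohort
from .config import RunConfig
from .inference import PermutationConfig, compare_groups
from .metrics import MEASURE_NAMES, all_measures
from .network import group_network, write_matrix
from .regions import RegionSet, default_global_regions, default_thalamic_regions
from .synthetic import SyntheticSpec, make_correlation_template, generate_cohort

__all__ = ["run", "demo", "demo_synthetic_spec", "results_frame"]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = (
    "measure", "group_a", "group_b", "difference",
    "ci_lower", "ci_upper", "p_value", "adjusted_p_value", "significant",
)


def results_frame(results, group_a: str, group_b: str) -> pd.DataFrame:
    rows = [
        {
            "measure": r.measure,
            "group_a": r.value_group_a,
            "group_b": r.value_group_b,
            "difference": r.difference,
            "ci_lower": r.ci_lower,
            "ci_upper": r.ci_upper,
            "p_value": r.p_raw,
            "adjusted_p_value": r.p_adjusted,
            "significant": r.significant,
        }
        for r in results
    ]
    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    frame.attrs["groups"] = (group_a, group_b)
    return frame


def _write_table(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.10g", na_rep="NA")


def run(config: RunConfig, cohort: Cohort | None = None) -> Path:
    """Execute every (network, comparison) of ``config``; return the output dir.

    Per pair this writes the two group connectivity matrices (labeled square
    TSV), a measures table, and a Tables-2/3-style comparison table, plus a
    run log recording seed, permutation count and warnings.
    """
    if cohort is None:
        cohort = read_cohort(config.cohort_path)
    config.validate_against(cohort)
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)

    log_lines = [
        f"covnet {__version__}",
        f"cohort: {config.cohort_path} ({cohort.n_subjects} subjects, "
        f"groups {cohort.group_sizes()})",
        f"seed: {config.permutation.seed}",
        f"permutations: {config.permutation.n_permutations}",
        f"alpha: {config.permutation.alpha}  ci_level: {config.permutation.ci_level}",
        f"distance_convention: {config.distance_convention}",
    ]

    for net_name, columns in config.network_specs.items():
        sub = cohort.restrict_regions(columns, name=net_name)
        measure_rows = []
        nets = {}
        for group in sub.group_labels():
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                net = group_network(sub, group)
            for warning in caught:
                log_lines.append(f"warning [{net_name}/{group}]: {warning.message}")
            nets[group] = net
            write_matrix(net, out / f"network_{net_name}_{group}.tsv")
            record = all_measures(net, distance=config.distance_convention).to_record()
            measure_rows.append({"network": net_name, "group": group, **record})
        pd.DataFrame(measure_rows).to_csv(
            out / f"measures_{net_name}.csv", index=False
        )

        for group_a, group_b in config.comparisons:
            null_sink: list = []
            results = compare_groups(
                sub.restrict_group(group_a),
                sub.restrict_group(group_b),
                config.permutation,
                distance=config.distance_convention,
                include_average_degree=config.include_average_degree,
                null_out=null_sink if config.dump_null else None,
            )
            if config.dump_null:
                pd.DataFrame(null_sink[0], columns=MEASURE_NAMES).to_csv(
                    out / f"null_{net_name}_{group_a}_vs_{group_b}.tsv",
                    sep="\t", index=False, float_format="%.10g", na_rep="NA",
                )
            frame = results_frame(results, group_a, group_b)
            path = out / f"comparison_{net_name}_{group_a}_vs_{group_b}.csv"
            _write_table(frame, path)
            log_lines.append(
                f"comparison [{net_name}] {group_a} vs {group_b}: "
                f"{int(frame['significant'].sum())}/{len(frame)} significant"
            )

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return out


def demo_synthetic_spec(seed: int = 7) -> tuple[SyntheticSpec, list[str], list[str]]:
    """Synthetic stand-in for the study cohort.

    Three groups (healthy controls n=45, disease without epilepsy n=56,
    disease with epilepsy n=25) over the default 82-region whole-brain set
    plus the 50-nucleus thalamic set, with the epilepsy group given distinct
    correlation templates (weaker whole-brain coupling, stronger thalamic
    coupling).
    """
    global_rs = default_global_regions()
    thal_rs = default_thalamic_regions()
    global_cols = list(global_rs.regions)
    thal_cols = [f"thal_{r}" for r in thal_rs.regions]
    all_cols = global_cols + thal_cols
    n_global, n_thal = len(global_cols), len(thal_cols)
    p = n_global + n_thal

    def combined(style_g, s_g, style_t, s_t):
        m = np.eye(p)
        m[:n_global, :n_global] = make_correlation_template(
            n_global, style_g, s_g, block_size=10
        )
        m[n_global:, n_global:] = make_correlation_template(
            n_thal, style_t, s_t, block_size=5
        )
        return m

    target = {
        "HC": combined("modular", 0.55, "modular", 0.35),
        "AD_no_epilepsy": combined("modular", 0.45, "modular", 0.35),
        "AD_epilepsy": combined("modular", 0.30, "modular", 0.55),
    }
    spec = SyntheticSpec(
        group_sizes={"HC": 45, "AD_no_epilepsy": 56, "AD_epilepsy": 25},
        region_count=p,
        mean_volumes=np.full(p, 3000.0),
        age_effect=np.full(p, -8.0),
        sex_effect=np.full(p, 120.0),
        target_correlation=target,
        noise_sd=np.full(p, 250.0),
        age_distribution=(69.9, 11.9),
        sex_balance=0.47,
        seed=seed,
        region_set=RegionSet("combined", tuple(all_cols)),
    )
    return spec, global_cols, thal_cols


def demo(
    seed: int = 7,
    output_dir: str | Path = "covnet_demo",
    n_permutations: int = 200,
) -> Path:
    """Generate the demo cohort and run the full pipeline on it."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec, global_cols, thal_cols = demo_synthetic_spec(seed)
    cohort = generate_cohort(spec)
    cohort_path = out / "cohort.csv"
    write_cohort(cohort, cohort_path)

    config = RunConfig(
        cohort_path=cohort_path,
        network_specs={"global": global_cols, "thalamic": thal_cols},
        comparisons=[
            ("HC", "AD_no_epilepsy"),
            ("HC", "AD_epilepsy"),
            ("AD_no_epilepsy", "AD_epilepsy"),
        ],
        permutation=PermutationConfig(n_permutations=n_permutations, seed=seed),
        output_dir=out,
    )
    return run(config, cohort=cohort)
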