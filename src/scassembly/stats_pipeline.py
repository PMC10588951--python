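"""Statistical comparisons and end-to-end pipeline orchestration.

The three tests used to compare genotypes: an unpaired t test (testis
weights; Welch by default), Fisher's exact test on tubule counts
dichotomized at >= 5 apoptotic nuclei per tubule, and the Mann-Whitney U
test (intensity quantifications). All are thin, recorded wrappers over
scipy.stats; the exactness conventions are pinned down here (enumeration-
exact Mann-Whitney for small tie-free samples, minimum-likelihood
two-sided Fisher) so that results are reproducible and auditable against
brute-force oracles. No multiple-testing correction is applied: pairwise
tests are reported unadjusted, and the run manifest says so.

``run_pipeline`` executes the requested stages (steered dissociation
assay, synthetic imaging + distance measurement, synthetic counts +
dichotomize + Fisher) from a config mapping, writes TSV/JSON outputs and
a machine-readable manifest of seeds and thresholds; re-running a
manifest reproduces all stochastic stages bit for bit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import CountTable2x2
from .cg_simulator import (
    CGModelParams,
    SteeringConfig,
    build_tetramer_model,
    genotype_scale,
    load_defaults,
    simulate,
)
from .traj_analysis import (
    DissociationResult,
    detect_dissociation,
    interdimer_distance_series,
)

__all__ = [
    "TestResult",
    "mann_whitney_u",
    "fisher_exact_2x2",
    "t_test_unpaired",
    "dichotomize_tunel",
    "compare_tunel_counts",
    "steered_assay",
    "run_pipeline",
    "TUNEL_THRESHOLD",
]

TUNEL_THRESHOLD = 5
EXACT_MW_MAX_N = 12


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    sidedness: str = "two-sided"
    method: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError("p-value outside [0, 1]")
        if any(n < 1 for n in self.n_per_group):
            raise ValueError("each group needs >= 1 observation")

    def to_dict(self) -> dict:
        return {
            "test": self.name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_per_group": list(self.n_per_group),
            "sidedness": self.sidedness,
            "method": self.method,
        }


def mann_whitney_u(
    x, y, sided: str = "two-sided"
) -> TestResult:
    """Mann-Whitney U test.

    Exact p by enumeration when n_x + n_y <= 12 with no ties, otherwise
    the normal approximation with tie correction (and continuity
    correction); the method used is recorded.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    exact = no_ties and (x.size + y.size) <= EXACT_MW_MAX_N
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=sided, method=method)
    return TestResult(
        name="mann-whitney-u",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group=(x.size, y.size),
        sidedness=sided,
        method=method,
    )


def fisher_exact_2x2(
    table: CountTable2x2 | np.ndarray, sided: str = "two-sided"
) -> TestResult:
    """Fisher's exact test on a 2x2 table.

    Two-sided p is the minimum-likelihood convention: the sum of
    hypergeometric probabilities of all tables (with the observed
    margins) no more probable than the observed one.
    """
    if isinstance(table, CountTable2x2):
        table.check_margins()
        arr = table.table
    else:
        arr = np.asarray(table, dtype=int)
        if arr.shape != (2, 2):
            raise ValueError("table must be 2x2")
        if (arr < 0).any():
            raise ValueError("table entries must be non-negative")
        if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
            raise ValueError("both margins must be positive")
    res = stats.fisher_exact(arr, alternative=sided)
    return TestResult(
        name="fisher-exact",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_per_group=(int(arr[0].sum()), int(arr[1].sum())),
        sidedness=sided,
        method="hypergeometric-sum",
    )


def t_test_unpaired(x, y, equal_variance: bool = False) -> TestResult:
    """Unpaired two-sided t test; Welch by default, pooled optional.

    Degenerate zero-variance-equal-means input returns t=0, p=1 with a
    warning (the comparison is uninformative, not an error).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 observations per group")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            warnings.warn("zero variance in both groups with equal means; p=1")
            return TestResult(
                name="t-test",
                statistic=0.0,
                p_value=1.0,
                n_per_group=(x.size, y.size),
                method="degenerate",
            )
    res = stats.ttest_ind(x, y, equal_var=equal_variance)
    return TestResult(
        name="t-test",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group=(x.size, y.size),
        method="pooled" if equal_variance else "welch",
    )


def dichotomize_tunel(counts, threshold: int = TUNEL_THRESHOLD) -> tuple[int, int]:
    """Split per-tubule counts at the threshold: (#below, #at-or-above).

    The threshold is inclusive on the high side: a tubule with exactly
    ``threshold`` labelled nuclei counts as "at or above".
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("no counts")
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.all(counts == np.round(counts)):
            raise ValueError("counts must be integers")
        counts = counts.astype(int)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    n_hi = int((counts >= threshold).sum())
    return int(counts.size - n_hi), n_hi


def compare_tunel_counts(
    counts_a,
    counts_b,
    threshold: int = TUNEL_THRESHOLD,
    labels: tuple[str, str] = ("genotype_a", "genotype_b"),
) -> tuple[CountTable2x2, TestResult]:
    """Dichotomize two genotypes' tubule counts and run Fisher's exact test."""
    row_a = dichotomize_tunel(counts_a, threshold)
    row_b = dichotomize_tunel(counts_b, threshold)
    table = CountTable2x2(
        table=np.array([row_a, row_b]),
        row_labels=labels,
        col_labels=(f"<{threshold}", f">={threshold}"),
    )
    return table, fisher_exact_2x2(table)


# ----------------------------------------------------------------------
# Steered dissociation assay (simulator + analysis in one call)
# ----------------------------------------------------------------------

def steered_assay(
    genotype: str,
    force: float = 0.05,
    seed: int = 0,
    duration: float = 100.0,
    params: CGModelParams | None = None,
) -> DissociationResult:
    """Build, steer, simulate and classify one replicate.

    ``force`` is the per-atom steering force in kJ mol^-1 nm^-1 (0 = no
    steering); returns the dissociation classification with its
    interdimer-distance series.
    """
    params = params or CGModelParams()
    model = build_tetramer_model(params)
    steering = SteeringConfig(per_particle_force=force) if force > 0 else None
    traj = simulate(
        model,
        params,
        steering,
        duration=duration,
        seed=seed,
        genotype=genotype_scale(genotype),
    )
    times, distances = interdimer_distance_series(traj)
    return detect_dissociation(times, distances)


# ----------------------------------------------------------------------
# Pipeline
# ----------------------------------------------------------------------

_STAGES = ("dissociation", "imaging", "counts")


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute the configured stages and write outputs plus a manifest.

    ``config`` maps stage names to their parameters (see the shipped demo
    config); unknown stages raise with the list of valid ones. The
    manifest echoes the fully resolved config, seeds and thresholds and
    the package version, and is itself a valid config: re-running it
    reproduces every stochastic stage bit for bit.
    """
    from . import __version__

    if not isinstance(config, dict):
        with open(config) as fh:
            import yaml

            config = yaml.safe_load(fh)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", {})
    unknown = set(stages) - set(_STAGES)
    if unknown:
        raise ValueError(
            f"unknown stage(s) {sorted(unknown)}; valid stages: {list(_STAGES)}"
        )
    base_seed = int(config.get("seed", 0))
    report: dict = {}

    if "dissociation" in stages:
        cfg = stages["dissociation"] or {}
        genotypes = cfg.get("genotypes", ["WT", "L102E", "L106E", "L102E/L106E"])
        forces = cfg.get("forces", [0.05])
        n_seeds = int(cfg.get("n_seeds", 3))
        duration = float(cfg.get("duration_ns", 100.0))
        rows = []
        for genotype in genotypes:
            for force in forces:
                for rep in range(n_seeds):
                    import zlib

                    tag = zlib.crc32(f"{genotype}:{force}".encode()) % 997
                    seed = (base_seed * 10007 + tag + rep) % (2**31)
                    res = steered_assay(
                        genotype, force=force, seed=seed, duration=duration
                    )
                    rows.append(
                        {
                            "genotype": genotype,
                            "force_kj_mol_nm": force,
                            "seed": seed,
                            "status": res.status,
                            "disruption_time_ns": res.disruption_time,
                        }
                    )
        df = pd.DataFrame(rows)
        df.to_csv(out_dir / "dissociation.tsv", sep="\t", index=False)
        report["dissociation"] = rows

    if "imaging" in stages:
        from .image_quant import measure_axis_separation
        from .synth_imaging import AxisPairGroundTruth, synthesize_axis_pair_stack

        cfg = stages["imaging"] or {}
        separations = cfg.get("separations_nm", [150.0, 350.0])
        n_seeds = int(cfg.get("n_seeds", 5))
        rows = []
        for sep in separations:
            for rep in range(n_seeds):
                seed = (base_seed * 7919 + int(sep) * 31 + rep) % (2**31)
                mid = np.column_stack(
                    [
                        np.linspace(12, 148, 20),
                        32 + 4 * np.sin(np.linspace(0, 2.5, 20)),
                    ]
                )
                truth = AxisPairGroundTruth(
                    true_separation_nm=float(sep), midline=mid, seed=seed
                )
                stack, trace = synthesize_axis_pair_stack(
                    truth, n_slices=9, shape=(64, 160)
                )
                out = measure_axis_separation(stack, trace)
                rows.append(
                    {
                        "true_separation_nm": sep,
                        "seed": seed,
                        "measured_nm": out["mean_separation_nm"],
                        "n_valid": out["n_valid"],
                        "classification": out["classification"],
                    }
                )
        pd.DataFrame(rows).to_csv(out_dir / "imaging.tsv", sep="\t", index=False)
        report["imaging"] = rows

    if "counts" in stages:
        from .synth_imaging import TubuleCountModel, synthesize_tubule_counts

        cfg = stages["counts"] or {}
        n_tubules = int(cfg.get("n_tubules", 200))
        fractions = cfg.get("burst_fractions", {"WT": 0.015, "L106E": 0.161})
        labels = list(fractions)
        counts = {}
        for i, (label, f) in enumerate(fractions.items()):
            model = TubuleCountModel(
                n_tubules=n_tubules,
                burst_fraction=float(f),
                seed=(base_seed * 104729 + i) % (2**31),
            )
            counts[label] = synthesize_tubule_counts(model)
        table, fisher = compare_tunel_counts(
            counts[labels[0]], counts[labels[1]], labels=(labels[0], labels[1])
        )
        pd.DataFrame(
            {label: c for label, c in counts.items()}
        ).to_csv(out_dir / "tubule_counts.tsv", sep="\t", index=False)
        report["counts"] = {
            "table": table.table.tolist(),
            "labels": labels,
            "fisher": fisher.to_dict(),
        }

    manifest = {
        "package_version": __version__,
        "seed": base_seed,
        "stages": stages,
        "thresholds": {
            "tunel_threshold": TUNEL_THRESHOLD,
            "synapsis_threshold_nm": 250.0,
            "intact_threshold_A": 10.0,
            "dissociated_threshold_A": 30.0,
        },
        "cg_defaults": load_defaults(),
        "multiple_testing_correction": "none (pairwise tests reported unadjusted)",
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
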