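"""Simulation studies validating the estimators against known demography.

These are the package's calibration experiments: each one simulates
populations whose true effective size, split time, or decay slope is
known, runs the full estimation path (sampling, chip ascertainment, EM
r2/phase, binning, Sved inversion), and returns the estimates next to
the truth.  The analysis drivers and the test suite both run them; the
problem sizes are chosen so a full replicate set completes in minutes on
one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ld import pairwise_ld
from .ne import ne_trajectory
from .phase import match_pairs, phase_correlation
from .simulate import (
    SimConfig,
    ascertain_and_degrade,
    evolve,
    make_crossbred,
    sample_panel,
    simulate_base_population,
    split_populations,
)

#: generation grid spanning 4Nc in [0.5, 5] for N = 100
NE_RECOVERY_GRID = (40, 63, 100, 160, 250, 400)


def ne_recovery_experiment(
    seeds,
    true_n: int = 100,
    n_chromosomes: int = 3,
    n_markers_per_chromosome: int = 350,
    chromosome_length_bp: int = 10_000_000,
    burn_in_generations: int = 300,
    generation_grid=NE_RECOVERY_GRID,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Constant-N Wright-Fisher truth vs Sved Ne estimates.

    Every individual is sampled (full sampling) and the finite-sample
    r2 correction is applied, since with n = 2N sampled chromosomes the
    sampling inflation 1/n is half as large as the drift signal itself.
    Returns one row per (seed, generation bin) with the estimate.
    """
    rows = []
    for seed in seeds:
        cfg = SimConfig(
            n_chromosomes=n_chromosomes,
            chromosome_length_bp=chromosome_length_bp,
            n_markers_per_chromosome=n_markers_per_chromosome,
            base_pop_size=true_n,
            burn_in_generations=burn_in_generations,
            split_generation=0,
            ne_schedule=(),
            sample_sizes=(true_n, 0, 0),
            seed=int(seed),
        )
        pop = simulate_base_population(cfg)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
        panel, mmap = sample_panel(pop, true_n, "pop", rng)
        panel, mmap = ascertain_and_degrade(panel, mmap, maf_min, 0.0, rng)
        rec = pairwise_ld(panel, mmap, max_distance_bp=1_500_000, min_pair_n=30)
        traj = ne_trajectory(
            rec, generation_grid, sample_n=2 * true_n, correct_sample_size=True
        )
        for g_req, (_, row) in zip(generation_grid, traj.iterrows()):
            rows.append(
                {
                    "seed": int(seed),
                    "generations_requested": g_req,
                    "generations_ago": row["generations_ago"],
                    "n_pairs": row["n_pairs"],
                    "mean_r2": row["mean_r2"],
                    "ne_estimate": row["ne"],
                    "true_n": true_n,
                }
            )
    return pd.DataFrame(rows)


def _panel_ld(pop, n_sample, label, rng, max_dist=70_000, maf_min=0.05):
    panel, mmap = sample_panel(pop, n_sample, label, rng)
    panel, mmap = ascertain_and_degrade(panel, mmap, maf_min, 0.0, rng)
    return pairwise_ld(panel, mmap, max_distance_bp=max_dist, min_pair_n=30)


def _corr_0_70kb(rec_a, rec_b, common_keys=None) -> float:
    matched = match_pairs(rec_a, rec_b)
    if common_keys is not None:
        keys = pd.MultiIndex.from_frame(matched[["id_i", "id_j"]])
        matched = matched[keys.isin(common_keys)]
    row = phase_correlation(matched, strata=((0, 70_000),)).iloc[0]
    return float(row["correlation_all"])


def split_time_phase_experiment(
    seeds,
    split_times=(10, 100, 500),
    pop_n: int = 200,
    n_sample: int = 50,
    n_chromosomes: int = 2,
    n_markers_per_chromosome: int = 600,
    chromosome_length_bp: int = 6_000_000,
    burn_in_generations: int = 200,
    f1_at: int = 100,
) -> pd.DataFrame:
    """Phase-persistence decay with divergence time, plus the F1 contrast.

    Two populations split from a common ancestor and drift apart; the
    0-70 kb correlation of signed r between them is recorded at each
    split time.  Because fixation and ascertainment change which marker
    pairs remain estimable over time, correlations at all split times
    are computed on the common set of pairs estimable at every snapshot
    (a paired design; otherwise composition drift confounds the
    comparison).  At ``f1_at`` generations an F1 cross is bred and the
    parent-F1 correlation recorded next to the parent-parent one (a
    crossbred panel should share phase with each parent at least as well
    as the parents share it with each other).
    """
    rows = []
    for seed in seeds:
        cfg = SimConfig(
            n_chromosomes=n_chromosomes,
            chromosome_length_bp=chromosome_length_bp,
            n_markers_per_chromosome=n_markers_per_chromosome,
            base_pop_size=pop_n,
            burn_in_generations=burn_in_generations,
            split_generation=0,
            ne_schedule=(),
            sample_sizes=(n_sample, n_sample, 0),
            seed=int(seed),
        )
        base = simulate_base_population(cfg)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
        pop_a, pop_b = split_populations(base, pop_n // 2, rng)
        t_done = 0
        snapshots: dict[int, tuple] = {}
        row = {"seed": int(seed)}
        for t in sorted(split_times):
            pop_a = evolve(pop_a, t - t_done, pop_n, rng)
            pop_b = evolve(pop_b, t - t_done, pop_n, rng)
            t_done = t
            rec_a = _panel_ld(pop_a, n_sample, "A", rng)
            rec_b = _panel_ld(pop_b, n_sample, "B", rng)
            snapshots[t] = (rec_a, rec_b)
            if t == f1_at:
                panel_c, map_c, _ = make_crossbred(pop_a, pop_b, "F1", n_sample, rng)
                panel_c, map_c = ascertain_and_degrade(panel_c, map_c, 0.05, 0.0, rng)
                rec_c = pairwise_ld(panel_c, map_c, max_distance_bp=70_000,
                                    min_pair_n=30)
                row["corr_parent_f1"] = _corr_0_70kb(rec_a, rec_c)
                row["corr_parent_parent"] = _corr_0_70kb(rec_a, rec_b)
        common = None
        for rec_a, rec_b in snapshots.values():
            keys = set(zip(rec_a["id_i"], rec_a["id_j"])) & set(
                zip(rec_b["id_i"], rec_b["id_j"])
            )
            common = keys if common is None else (common & keys)
        common = pd.MultiIndex.from_tuples(sorted(common), names=["id_i", "id_j"])
        for t, (rec_a, rec_b) in snapshots.items():
            row[f"corr_split_{t}"] = _corr_0_70kb(rec_a, rec_b, common_keys=common)
        rows.append(row)
    return pd.DataFrame(rows)


def planted_decay_records(
    rng: np.random.Generator,
    n_records: int = 2000,
    intercept: float = 0.3,
    slope: float = -0.5,
    noise_sd: float = 0.01,
    max_dist_morgans: float = 0.4,
) -> pd.DataFrame:
    """LD records with a known linear decay, for regression recovery.

    Distances are uniform on (0, max_dist_morgans) Morgans; r2 values are
    intercept + slope * distance + Gaussian noise.  The slope is in r2
    per Morgan, so records carry dist_bp = distance * 1e8.
    """
    d = rng.uniform(0, max_dist_morgans, size=n_records)
    r2 = intercept + slope * d + rng.normal(0, noise_sd, size=n_records)
    return pd.DataFrame(
        {
            "chrom": "1",
            "id_i": [f"m{i}a" for i in range(n_records)],
            "id_j": [f"m{i}b" for i in range(n_records)],
            "pos_i": 1,
            "pos_j": (d * 1e8).astype(int) + 1,
            "dist_bp": (d * 1e8).astype(int),
            "r2": r2,
            "r": np.sqrt(np.clip(r2, 0, 1)),
            "converged": True,
        }
    )
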