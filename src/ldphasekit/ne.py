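"""Effective population size from LD via Sved's relation.

Sved's approximation E[r2] = 1 / (1 + 4 Ne c) links the expected squared
correlation between loci at recombination distance c (Morgans) to the
effective population size.  Inverting it,

    Ne = (1 / 4c) (1 / r2 - 1),

and the LD at distance c reflects the population roughly 1/(2c)
generations ago, so sparse marker pairs at a range of distances trace an
Ne trajectory through time.  Physical distance maps to c assuming 1e8 bp
per Morgan.

Observed r2 from n sampled chromosomes is inflated by ~1/n even in
linkage equilibrium; an optional correction subtracts 1/n from the bin
mean before inversion (off by default, matching the plain formula).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phase import _pearson

BP_PER_MORGAN = 100_000_000
MIN_C_MORGANS = 1e-5


@dataclass(frozen=True)
class NeEstimate:
    generations_ago: float
    c: float
    c_window: tuple
    n_pairs: int
    mean_r2: float
    ne: float


@dataclass(frozen=True)
class DemographicNeInput:
    """Census inputs for Hill's demographic Ne: N alive, generation length L,
    variance of family size sigma2_n."""

    n_alive: float
    generation_length: float
    var_family_size: float

    def __post_init__(self) -> None:
        if min(self.n_alive, self.generation_length) <= 0 or self.var_family_size < 0:
            raise ValueError("all demographic inputs must be positive")


def bp_to_morgans(distance_bp: float) -> float:
    """c = distance / 1e8 (one Morgan per 100 Mb)."""
    if distance_bp <= 0:
        raise ValueError("distance must be positive")
    return distance_bp / BP_PER_MORGAN


def generations_for_c(c: float) -> float:
    """Age (generations ago) probed by LD at recombination distance c: 1/(2c)."""
    if c < MIN_C_MORGANS:
        raise ValueError(f"c below the minimum of {MIN_C_MORGANS} Morgans")
    return 1.0 / (2.0 * c)


def sved_ne(
    mean_r2: float,
    c: float,
    sample_n: int | None = None,
    correct_sample_size: bool = False,
) -> float:
    """Ne = (1/4c)(1/r2 - 1), optionally removing finite-sample inflation.

    ``sample_n`` is the number of sampled chromosomes (2x individuals);
    with the correction on, 1/sample_n is subtracted from mean_r2 first.
    Returns NaN when the (corrected) r2 leaves (0, 1].
    """
    if c < MIN_C_MORGANS:
        raise ValueError(f"c below the minimum of {MIN_C_MORGANS} Morgans")
    r2 = mean_r2
    if correct_sample_size:
        if not sample_n or sample_n <= 0:
            raise ValueError("sample_n required for the sample-size correction")
        r2 = mean_r2 - 1.0 / sample_n
    if not (0.0 < r2 <= 1.0):
        return float("nan")
    return (1.0 / (4.0 * c)) * (1.0 / r2 - 1.0)


def demographic_ne(inp: DemographicNeInput) -> float:
    """Hill's demographic formula Ne = 4 N L / (2 + sigma2_n)."""
    return 4.0 * inp.n_alive * inp.generation_length / (2.0 + inp.var_family_size)


def _window_for_generation(g: float, window_factor: float) -> tuple[float, float]:
    c_target = 1.0 / (2.0 * g)
    return c_target / window_factor, c_target * window_factor


def ne_trajectory(
    records: pd.DataFrame,
    generation_grid,
    sample_n: int | None = None,
    correct_sample_size: bool = False,
    window_factor: float = 1.1,
    drop_nonconverged: bool = True,
) -> pd.DataFrame:
    """One Sved Ne estimate per requested generation.

    For each g the target c is 1/(2g); pairs whose c lies within a
    multiplicative window (x/÷ ``window_factor``) contribute.  The bin's
    representative c is the mean of contributing pairs' c, and
    generations_ago is recomputed as 1/(2c) at that representative c.
    Empty windows are skipped.
    """
    df = records
    if drop_nonconverged and "converged" in df.columns:
        df = df[df["converged"]]
    c_all = df["dist_bp"].to_numpy(dtype=float) / BP_PER_MORGAN
    r2_all = df["r2"].to_numpy(dtype=float)
    rows = []
    for g in generation_grid:
        lo, hi = _window_for_generation(float(g), window_factor)
        sel = (c_all >= lo) & (c_all < hi)
        n = int(sel.sum())
        if n == 0:
            continue
        mean_r2 = float(r2_all[sel].mean())
        c_rep = float(c_all[sel].mean())
        ne = sved_ne(mean_r2, c_rep, sample_n, correct_sample_size)
        rows.append(
            {
                "generations_ago": generations_for_c(c_rep),
                "c_morgans": c_rep,
                "c_lo": lo,
                "c_hi": hi,
                "n_pairs": n,
                "mean_r2": mean_r2,
                "ne": ne,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["generations_ago", "c_morgans", "c_lo", "c_hi", "n_pairs",
                 "mean_r2", "ne"],
    )


def phase_correlation_trajectory(
    matched: pd.DataFrame,
    generation_grid,
    window_factor: float = 1.1,
) -> pd.DataFrame:
    """Correlation of signed r between two populations per generation window.

    Uses the same c-windowing as :func:`ne_trajectory`: large g means
    small c (short distances), i.e. old LD.  Windows with fewer than two
    pairs are skipped.
    """
    c_all = matched["dist_bp"].to_numpy(dtype=float) / BP_PER_MORGAN
    rows = []
    for g in generation_grid:
        lo, hi = _window_for_generation(float(g), window_factor)
        sel = (c_all >= lo) & (c_all < hi)
        if sel.sum() < 2:
            continue
        corr = _pearson(
            matched.loc[sel, "r_A"].to_numpy(), matched.loc[sel, "r_B"].to_numpy()
        )
        rows.append(
            {
                "generations_ago": generations_for_c(float(c_all[sel].mean())),
                "n_pairs": int(sel.sum()),
                "correlation": corr,
            }
        )
    return pd.DataFrame(rows, columns=["generations_ago", "n_pairs", "correlation"])
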