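"""Forward-time Wright-Fisher simulator for multi-breed SNP panels.

Generates diploid populations with known demography so every downstream
stage (QC, r2/phase estimation, decay, persistence of phase, Sved Ne)
can be validated against ground truth.  The model:

* standing variation only — founder allele frequencies are drawn from a
  stated initial distribution (Uniform(0.1, 0.9) by default) and no
  mutation occurs afterwards; at the timescales of LD decay this is
  sufficient and keeps the allele bookkeeping trivial;
* discrete generations, random union of gametes, constant or scheduled
  diploid size N per population;
* recombination with no interference: a gamete crosses over in each
  inter-marker interval independently with probability
  min(interval_bp / 1e8, 0.5) — the linear bp-to-Morgan map, capped at
  free recombination.

Two purebred populations are produced by splitting a burned-in base
population; crossbred panels (F1 or backcross) take one recombinant
gamete from a parent of each pool.  Chip-like ascertainment drops
low-MAF markers and masks genotypes at random before export.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import MISSING, GenotypePanel, MarkerMap

BP_PER_MORGAN = 100_000_000


@dataclass
class SimConfig:
    """Study-design parameters for a two-breed-plus-crossbred simulation.

    Defaults emulate a beef-cattle style design at desk scale: two
    purebred populations diverged from a common ancestor, chip markers at
    ~70 kb mean spacing, hundreds of sampled individuals per population,
    and effective size declining from 1000 to 250 over the 250
    generations since the split.
    """

    n_chromosomes: int = 3
    chromosome_length_bp: int = 35_000_000
    n_markers_per_chromosome: int = 500
    base_pop_size: int = 1000
    burn_in_generations: int = 300
    split_generation: int = 250
    # per-population post-split schedule: list of (n_generations, diploid N)
    ne_schedule: tuple = ((50, 1000), (50, 750), (50, 500), (50, 375), (50, 250))
    sample_sizes: tuple = (597, 450, 616)  # breed A, breed B, crossbred
    maf_ascertainment_min: float = 0.05
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_chromosomes,
            self.chromosome_length_bp,
            self.n_markers_per_chromosome,
            self.base_pop_size,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.base_pop_size < 2:
            raise ValueError("need a diploid population of at least 2")
        if not (0.0 <= self.maf_ascertainment_min < 0.5):
            raise ValueError("maf_ascertainment_min must be in [0, 0.5)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if sum(g for g, _ in self.ne_schedule) != self.split_generation:
            raise ValueError("ne_schedule generations must sum to split_generation")
        if any(n < 2 for _, n in self.ne_schedule):
            raise ValueError("scheduled N must be >= 2 everywhere")


@dataclass
class PopulationState:
    """Haplotypes of one population: per chromosome a (2N, L) 0/1 array."""

    haplotypes: list  # list over chromosomes of uint8 arrays (2N, L)
    positions: list  # list over chromosomes of int64 bp positions (sorted)
    generation: int = 0

    def __post_init__(self) -> None:
        if not self.haplotypes:
            raise ValueError("empty population")
        n_h = {h.shape[0] for h in self.haplotypes}
        if len(n_h) != 1 or next(iter(n_h)) % 2:
            raise ValueError("haplotype count must be even and equal across chromosomes")
        for h, p in zip(self.haplotypes, self.positions):
            if h.shape[1] != len(p):
                raise ValueError("haplotype width does not match positions")
            if np.any(np.diff(p) <= 0):
                raise ValueError("positions must be strictly increasing")

    @property
    def n_individuals(self) -> int:
        return self.haplotypes[0].shape[0] // 2

    @property
    def n_chromosomes(self) -> int:
        return len(self.haplotypes)

    def copy(self) -> "PopulationState":
        return PopulationState(
            [h.copy() for h in self.haplotypes],
            [p.copy() for p in self.positions],
            self.generation,
        )


def _marker_positions(length_bp: int, n_markers: int, rng: np.random.Generator) -> np.ndarray:
    """Strictly increasing 1-based positions, roughly uniform over the chromosome."""
    if n_markers > length_bp:
        raise ValueError("more markers than base pairs")
    pos = np.sort(rng.choice(length_bp, size=n_markers, replace=False)) + 1
    return pos.astype(np.int64)


def recombination_fractions(positions: np.ndarray) -> np.ndarray:
    """Per-interval crossover probability: min(delta_bp / 1e8, 0.5)."""
    return np.minimum(np.diff(positions) / BP_PER_MORGAN, 0.5)


def _make_gametes(
    haps: np.ndarray,
    parent_idx: np.ndarray,
    rec_frac: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete per parent index (no interference)."""
    n_g = len(parent_idx)
    n_loci = haps.shape[1]
    start = rng.integers(0, 2, size=(n_g, 1)).astype(bool)
    if n_loci > 1:
        cross = rng.random((n_g, n_loci - 1)) < rec_frac
        # parity of (start, crossover events) tells which parental strand
        sel = np.logical_xor.accumulate(
            np.concatenate([start, cross], axis=1), axis=1
        )
    else:
        sel = start
    hap_a = haps[2 * parent_idx]
    hap_b = haps[2 * parent_idx + 1]
    return np.where(sel, hap_b, hap_a).astype(np.uint8)


def simulate_base_population(config: SimConfig) -> PopulationState:
    """Found and burn in the common ancestral population.

    Per-locus founder frequencies are Uniform(0.1, 0.9); founder
    haplotypes are independent Bernoulli draws (linkage equilibrium), and
    ``burn_in_generations`` of Wright-Fisher reproduction with
    recombination then build up the LD structure drift creates.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.base_pop_size
    haplotypes, positions = [], []
    for _ in range(config.n_chromosomes):
        pos = _marker_positions(
            config.chromosome_length_bp, config.n_markers_per_chromosome, rng
        )
        freqs = rng.uniform(0.1, 0.9, size=len(pos))
        haps = (rng.random((2 * n, len(pos))) < freqs).astype(np.uint8)
        haplotypes.append(haps)
        positions.append(pos)
    pop = PopulationState(haplotypes, positions, generation=0)
    if config.burn_in_generations > 0:
        pop = evolve(pop, config.burn_in_generations, n, rng=rng)
    return pop


def evolve(
    pop: PopulationState,
    n_generations: int,
    n_diploid: int,
    rng: np.random.Generator,
) -> PopulationState:
    """Wright-Fisher reproduction: random union of recombinant gametes.

    Each offspring draws two parents uniformly at random (selfing
    allowed) and receives one recombinant gamete from each; chromosomes
    assort independently.
    """
    if n_diploid < 2:
        raise ValueError("need N >= 2")
    haps = [h for h in pop.haplotypes]
    rec = [recombination_fractions(p) for p in pop.positions]
    n_parents = pop.n_individuals
    for _ in range(n_generations):
        mothers = rng.integers(0, n_parents, size=n_diploid)
        fathers = rng.integers(0, n_parents, size=n_diploid)
        new_haps = []
        for c in range(len(haps)):
            g_m = _make_gametes(haps[c], mothers, rec[c], rng)
            g_f = _make_gametes(haps[c], fathers, rec[c], rng)
            out = np.empty((2 * n_diploid, haps[c].shape[1]), dtype=np.uint8)
            out[0::2] = g_m
            out[1::2] = g_f
            new_haps.append(out)
        haps = new_haps
        n_parents = n_diploid
    return PopulationState(haps, [p.copy() for p in pop.positions],
                           pop.generation + n_generations)


def evolve_schedule(
    pop: PopulationState, schedule, rng: np.random.Generator
) -> PopulationState:
    """Apply a piecewise-constant N schedule: iterable of (generations, N)."""
    for n_gen, n_dip in schedule:
        pop = evolve(pop, n_gen, n_dip, rng)
    return pop


def split_populations(
    pop: PopulationState, n_each: int, rng: np.random.Generator
) -> tuple[PopulationState, PopulationState]:
    """Seed two descendant populations from disjoint founder draws.

    If 2*n_each exceeds the source population, founders are resampled
    with replacement (with a warning) instead of failing.
    """
    n_src = pop.n_individuals
    if 2 * n_each <= n_src:
        perm = rng.permutation(n_src)
        idx_a, idx_b = perm[:n_each], perm[n_each : 2 * n_each]
    else:
        warnings.warn(
            "split requests more founders than available; resampling with replacement"
        )
        idx_a = rng.integers(0, n_src, size=n_each)
        idx_b = rng.integers(0, n_src, size=n_each)
    def take(idx):
        hap_rows = np.empty(2 * len(idx), dtype=np.int64)
        hap_rows[0::2] = 2 * idx
        hap_rows[1::2] = 2 * idx + 1
        return PopulationState(
            [h[hap_rows].copy() for h in pop.haplotypes],
            [p.copy() for p in pop.positions],
            pop.generation,
        )
    return take(idx_a), take(idx_b)


def sample_panel(
    pop: PopulationState,
    n_individuals: int,
    population_label: str,
    rng: np.random.Generator,
    id_prefix: str | None = None,
) -> tuple[GenotypePanel, MarkerMap]:
    """Sample diploid individuals without replacement and export dosages.

    The counted allele is the founder "1" allele at every marker, so
    orientation is consistent across all populations of a run.
    """
    if n_individuals > pop.n_individuals:
        raise ValueError("cannot sample more individuals than the population holds")
    idx = np.sort(rng.choice(pop.n_individuals, size=n_individuals, replace=False))
    dosages = np.concatenate(
        [h[2 * idx] + h[2 * idx + 1] for h in pop.haplotypes], axis=1
    ).astype(np.int8)
    prefix = id_prefix or population_label
    ids = [f"{prefix}_{i:05d}" for i in range(n_individuals)]
    panel = GenotypePanel(ids, population_label, dosages)
    return panel, _marker_map(pop)


def _marker_map(pop: PopulationState) -> MarkerMap:
    ids, chroms, pos = [], [], []
    for c, p in enumerate(pop.positions, start=1):
        ids += [f"chr{c}_snp{k:05d}" for k in range(len(p))]
        chroms += [str(c)] * len(p)
        pos.append(p)
    n = len(ids)
    return MarkerMap(
        np.array(ids, dtype=object),
        np.array(chroms, dtype=object),
        np.concatenate(pos),
        np.full(n, "A", dtype=object),
        np.full(n, "G", dtype=object),  # counted allele = founder "1"
    )


CROSS_SCHEMES = {
    "F1": (0.5, 0.5),
    "backcross_A": (0.75, 0.25),
    "backcross_B": (0.25, 0.75),
}


def make_crossbred(
    pop_a: PopulationState,
    pop_b: PopulationState,
    scheme: str,
    n_offspring: int,
    rng: np.random.Generator,
    population_label: str = "crossbred",
) -> tuple[GenotypePanel, MarkerMap, tuple[float, float]]:
    """Breed a crossbred panel: F1, or a backcross of F1 dams to purebred sires.

    Each offspring receives one recombinant gamete per parent; parents
    within a mating are distinct.  Returns the panel, its map, and the
    expected breed composition (share of A, share of B).
    """
    if scheme not in CROSS_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if pop_a.n_individuals < 1 or pop_b.n_individuals < 1:
        raise ValueError("insufficient parents")
    rec = [recombination_fractions(p) for p in pop_a.positions]

    def f1_gametes(n: int) -> tuple[list, list]:
        """n offspring as (maternal gamete list, paternal gamete list) per chrom."""
        dams = rng.integers(0, pop_a.n_individuals, size=n)
        sires = rng.integers(0, pop_b.n_individuals, size=n)
        g_a = [_make_gametes(pop_a.haplotypes[c], dams, rec[c], rng)
               for c in range(pop_a.n_chromosomes)]
        g_b = [_make_gametes(pop_b.haplotypes[c], sires, rec[c], rng)
               for c in range(pop_b.n_chromosomes)]
        return g_a, g_b

    if scheme == "F1":
        g_a, g_b = f1_gametes(n_offspring)
        dosage_chunks = [ga + gb for ga, gb in zip(g_a, g_b)]
    else:
        # build an intermediate F1 generation, then cross back
        g_a, g_b = f1_gametes(max(2, n_offspring))
        f1_haps = []
        for ga, gb in zip(g_a, g_b):
            h = np.empty((2 * ga.shape[0], ga.shape[1]), dtype=np.uint8)
            h[0::2] = ga
            h[1::2] = gb
            f1_haps.append(h)
        f1 = PopulationState(f1_haps, [p.copy() for p in pop_a.positions],
                             pop_a.generation + 1)
        pure = pop_a if scheme == "backcross_A" else pop_b
        f1_parents = rng.integers(0, f1.n_individuals, size=n_offspring)
        pure_parents = rng.integers(0, pure.n_individuals, size=n_offspring)
        dosage_chunks = [
            _make_gametes(f1.haplotypes[c], f1_parents, rec[c], rng)
            + _make_gametes(pure.haplotypes[c], pure_parents, rec[c], rng)
            for c in range(pop_a.n_chromosomes)
        ]
    dosages = np.concatenate(dosage_chunks, axis=1).astype(np.int8)
    ids = [f"{population_label}_{i:05d}" for i in range(n_offspring)]
    panel = GenotypePanel(ids, population_label, dosages)
    return panel, _marker_map(pop_a), CROSS_SCHEMES[scheme]


def ascertain_and_degrade(
    panel: GenotypePanel,
    mmap: MarkerMap,
    maf_min: float,
    missing_rate: float,
    rng: np.random.Generator,
) -> tuple[GenotypePanel, MarkerMap]:
    """Chip-style ascertainment: drop sample-MAF < maf_min, mask at random.

    Each retained genotype is set missing independently with probability
    ``missing_rate``.  Raises if no marker survives ascertainment.
    """
    if not (0.0 <= maf_min < 0.5):
        raise ValueError("maf_min must be in [0, 0.5)")
    d = panel.dosages
    typed = d != MISSING
    with np.errstate(invalid="ignore"):
        p = np.where(
            typed.sum(axis=0) > 0,
            (d * typed).sum(axis=0) / (2.0 * np.maximum(typed.sum(axis=0), 1)),
            np.nan,
        )
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= maf_min
    if not keep.any():
        raise ValueError("ascertainment removed every marker")
    new_d = d[:, keep].copy()
    if missing_rate > 0:
        mask = rng.random(new_d.shape) < missing_rate
        new_d[mask] = MISSING
    return (
        GenotypePanel(list(panel.individual_ids), panel.population_label, new_d),
        mmap.subset(keep),
    )


def expected_heterozygosity(pop: PopulationState) -> float:
    """Mean 2p(1-p) across loci — the drift-decay diagnostic."""
    vals = []
    for h in pop.haplotypes:
        p = h.mean(axis=0)
        vals.append(2 * p * (1 - p))
    return float(np.concatenate(vals).mean())


@dataclass
class StudyPanels:
    """Everything one simulated study produces."""

    panels: dict  # label -> GenotypePanel
    maps: dict  # label -> MarkerMap
    truth: pd.DataFrame
    config: SimConfig = field(repr=False, default=None)


def simulate_study(config: SimConfig) -> StudyPanels:
    """Run the full study design: burn-in, split, scheduled decline, F1 cross.

    Produces ascertained, degraded panels for breed A, breed B and the F1
    crossbred, plus a truth table of the demographic schedule.  All
    randomness flows from ``config.seed`` through deterministic
    per-population substreams.
    """
    ss = np.random.SeedSequence(config.seed)
    s_base, s_a, s_b, s_cross, s_export = [
        np.random.default_rng(child) for child in ss.spawn(5)
    ]
    base_cfg = SimConfig(**{**config.__dict__})
    base = simulate_base_population(base_cfg)
    pop_a, pop_b = split_populations(base, config.base_pop_size // 2, s_base)
    pop_a = evolve_schedule(pop_a, config.ne_schedule, s_a)
    pop_b = evolve_schedule(pop_b, config.ne_schedule, s_b)

    n_a, n_b, n_c = config.sample_sizes
    # the genotyped animals are one large cohort bred from the (smaller)
    # effective breeding population, as in a livestock census >> Ne
    if n_a > pop_a.n_individuals:
        pop_a = evolve(pop_a, 1, n_a, s_a)
    if n_b > pop_b.n_individuals:
        pop_b = evolve(pop_b, 1, n_b, s_b)
    panel_a, map_a = sample_panel(pop_a, n_a, "breedA", s_export)
    panel_b, map_b = sample_panel(pop_b, n_b, "breedB", s_export)
    panel_c, map_c, composition = make_crossbred(
        pop_a, pop_b, "F1", n_c, s_cross, population_label="crossbred"
    )
    panels, maps = {}, {}
    for label, (panel, mmap) in {
        "breedA": (panel_a, map_a),
        "breedB": (panel_b, map_b),
        "crossbred": (panel_c, map_c),
    }.items():
        panels[label], maps[label] = ascertain_and_degrade(
            panel, mmap, config.maf_ascertainment_min, config.missing_rate, s_export
        )
    truth_rows = [
        {"population": "base", "generation_range": f"0-{config.burn_in_generations}",
         "true_n": config.base_pop_size, "split_generations_ago": config.split_generation},
    ]
    g0 = 0
    for n_gen, n_dip in config.ne_schedule:
        for label in ("breedA", "breedB"):
            truth_rows.append(
                {
                    "population": label,
                    "generation_range": f"{g0}-{g0 + n_gen} post-split",
                    "true_n": n_dip,
                    "split_generations_ago": config.split_generation,
                }
            )
        g0 += n_gen
    truth_rows.append(
        {"population": "crossbred", "generation_range": "F1",
         "true_n": 0.5, "split_generations_ago": config.split_generation}
    )
    return StudyPanels(panels=panels, maps=maps, truth=pd.DataFrame(truth_rows),
                       config=copy.deepcopy(config))
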