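# ldphasekit

Linkage disequilibrium (LD), persistence of LD phase across populations,
and LD-based effective population size (Ne) from diploid SNP genotype
panels — with a Wright–Fisher forward simulator that generates
multi-breed panels with known demography so every estimator can be
validated against ground truth.

The package is aimed at quantitative and population geneticists working
with livestock-style SNP-chip data: panels of a few tens of thousands of
markers on a few hundred individuals per population, where the questions
are how fast r² decays with distance, whether marker–QTL phase transfers
between breeds and their crossbreds, and what demographic history the LD
pattern implies.

## The statistics at the core

For two biallelic loci with alleles A/a and B/b:

- **D** = f(AB) − f(A)·f(B): excess of the observed haplotype frequency
  over its linkage-equilibrium expectation.
- **r²** = D² / (f(A)·f(a)·f(B)·f(b)): the squared allelic correlation,
  in [0, 1].
- **LD phase r** = sign(D)·√r²: the signed correlation. The *persistence
  of phase* between two populations is the Pearson correlation of r over
  shared marker pairs; high values mean a marker–QTL association found in
  one population keeps its direction in the other.
- **Sved's relation** E[r²] ≈ 1/(1 + 4·Ne·c) at recombination distance c
  (Morgans; 10⁸ bp ≡ 1 Morgan), inverted as Ne = (1/4c)(1/r² − 1). The
  LD at distance c reflects the population ~1/(2c) generations ago, so
  binning marker pairs by c traces an Ne trajectory through time.

f(AB) is estimated from *unphased* genotypes by maximum likelihood under
random union of gametes: an EM algorithm splits the double-heterozygote
count between its coupling and repulsion resolutions (multi-start, since
the likelihood's score equation is cubic and can have several roots).
Before any of this, markers are filtered on call rate (< 95% removed),
an exact conditional Hardy–Weinberg test (p < 0.01 removed), and minor
allele frequency (< 5% removed).

## Worked example

```python
from ldphasekit import (SimConfig, simulate_study, apply_qc, pairwise_ld,
                        ne_trajectory, match_pairs, phase_correlation)

study = simulate_study(SimConfig(seed=1))   # two breeds + F1 cross
records = {}
for label in ("breedA", "breedB"):
    panel, mmap, report = apply_qc(study.panels[label], study.maps[label])
    records[label] = pairwise_ld(panel, mmap, max_distance_bp=6_000_000)

matched = match_pairs(records["breedA"], records["breedB"])
print(phase_correlation(matched).iloc[0][["n_pairs", "correlation_all",
                                          "correlation_highLD"]])
traj = ne_trajectory(records["breedA"], [10, 100, 250],
                     sample_n=2 * 597, correct_sample_size=True)
print(traj[["generations_ago", "mean_r2", "ne"]].round(3))
```

Output (seed 1):

```
n_pairs                    468
correlation_all       0.486176
correlation_highLD    0.803303
Name: 0, dtype: object
   generations_ago  mean_r2       ne
0            9.976    0.019  263.858
1           99.855    0.114  391.770
2          248.703    0.200  499.315
```

The two simulated breeds diverged 250 generations ago with Ne declining
from 1000 to 250: the 0–70 kb phase correlation between them is ~0.49
over all shared pairs but rises to ~0.80 when restricted to pairs with
r² ≥ 0.3 in both breeds (strong LD is old, hence shared), and the Sved
trajectory recovers an Ne near 250 in the recent past, rising toward the
larger ancestral size at older horizons.

The same pipeline is laid out as numbered drivers under `analysis/`
(simulate → QC+LD → decay → phase persistence → Ne trajectory →
validation), each writing its tables under `results/run/`, and as a CLI:

```bash
ldphase-kit pipeline --seed 1 --out-dir results/run
ldphase-kit ne --ld results/run/breedA.ld.tsv --sample-n 1194 --correct --out ne.tsv
```

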