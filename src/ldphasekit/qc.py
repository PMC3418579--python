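"""Marker quality control: call rate, exact Hardy-Weinberg test, MAF.

Markers are removed when call rate < 0.95, exact-test HWE p < 0.01, or
MAF < 0.05 (inclusion at exactly 5%).  Filters are applied in that fixed
order so each removed marker is attributed to the first filter it fails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .panel_io import MISSING, GenotypePanel, MarkerMap


@dataclass(frozen=True)
class MarkerCounts:
    """Genotype counts at one biallelic marker."""

    n_hom_other: int
    n_het: int
    n_hom_counted: int
    n_missing: int = 0

    @property
    def n_typed(self) -> int:
        return self.n_hom_other + self.n_het + self.n_hom_counted

    @property
    def n_total(self) -> int:
        return self.n_typed + self.n_missing


@dataclass
class QCReport:
    thresholds: dict
    n_input: int
    removed: dict  # filter name -> list of marker ids
    survivors: list

    @property
    def removal_counts(self) -> dict:
        return {k: len(v) for k, v in self.removed.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"filter": k, "n_removed": len(v)} for k, v in self.removed.items()
        ]
        rows.append({"filter": "survivors", "n_removed": len(self.survivors)})
        return pd.DataFrame(rows)


def counts_from_panel(panel: GenotypePanel) -> list[MarkerCounts]:
    """Per-marker genotype counts from a dosage matrix."""
    d = panel.dosages
    return [
        MarkerCounts(
            int(np.sum(d[:, m] == 0)),
            int(np.sum(d[:, m] == 1)),
            int(np.sum(d[:, m] == 2)),
            int(np.sum(d[:, m] == MISSING)),
        )
        for m in range(panel.n_markers)
    ]


def _log_config_prob(n_het: int, n_minor: int, n: int) -> float:
    """log P(het count | allele counts) under the exact conditional null.

    Multiplicity n! / (nAA! nAa! naa!) * 2^nAa out of C(2n, n_minor)
    arrangements of the alleles into genotypes.
    """
    n_hom_minor = (n_minor - n_het) // 2
    n_hom_major = n - n_het - n_hom_minor
    return (
        gammaln(n + 1)
        - gammaln(n_hom_minor + 1)
        - gammaln(n_het + 1)
        - gammaln(n_hom_major + 1)
        + n_het * np.log(2.0)
        - (gammaln(2 * n + 1) - gammaln(n_minor + 1) - gammaln(2 * n - n_minor + 1))
    )


def hwe_exact_pvalue(counts: MarkerCounts) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probability of
    every heterozygote count no more probable than the observed one.
    Monomorphic markers return 1.0 (no alternative configuration exists).
    """
    n = counts.n_typed
    if n == 0:
        raise ValueError("no non-missing genotypes")
    n_counted = 2 * counts.n_hom_counted + counts.n_het
    n_minor = min(n_counted, 2 * n - n_counted)
    if n_minor == 0:
        return 1.0
    # heterozygote counts share the parity of the minor allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    logp = np.array([_log_config_prob(int(h), n_minor, n) for h in hets])
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[hets == counts.n_het][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def hwe_chi2_pvalue(counts: MarkerCounts) -> float:
    """One-df chi-square HWE test (no continuity correction); for comparison."""
    n = counts.n_typed
    if n == 0:
        raise ValueError("no non-missing genotypes")
    p = (2 * counts.n_hom_counted + counts.n_het) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    obs = np.array([counts.n_hom_other, counts.n_het, counts.n_hom_counted])
    stat = float(np.sum((obs - exp) ** 2 / exp))
    return float(chi2.sf(stat, df=1))


def call_rate(counts: MarkerCounts) -> float:
    """Fraction of individuals with a non-missing genotype."""
    if counts.n_total == 0:
        raise ValueError("empty marker")
    return counts.n_typed / counts.n_total


def minor_allele_frequency(counts: MarkerCounts) -> float:
    """min(p, 1-p) of the counted allele among typed individuals."""
    if counts.n_typed == 0:
        raise ValueError("all genotypes missing")
    p = (2 * counts.n_hom_counted + counts.n_het) / (2 * counts.n_typed)
    return min(p, 1.0 - p)


DEFAULT_THRESHOLDS = {"hwe_p": 0.01, "call_rate": 0.95, "maf": 0.05}


def apply_qc(
    panel: GenotypePanel,
    mmap: MarkerMap,
    thresholds: dict | None = None,
    hwe_test: str = "exact",
) -> tuple[GenotypePanel, MarkerMap, QCReport]:
    """Remove markers failing call rate, then HWE, then MAF.

    Removal is strict: call rate < threshold, HWE p < threshold, MAF <
    threshold (a marker at exactly 5% MAF or 95% call rate is retained).
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    hwe_fn = hwe_exact_pvalue if hwe_test == "exact" else hwe_chi2_pvalue
    counts = counts_from_panel(panel)
    removed: dict[str, list] = {"call_rate": [], "hwe": [], "maf": []}
    keep = np.ones(panel.n_markers, dtype=bool)
    for m, c in enumerate(counts):
        mid = mmap.marker_id[m]
        if call_rate(c) < th["call_rate"]:
            removed["call_rate"].append(mid)
        elif c.n_typed > 0 and hwe_fn(c) < th["hwe_p"]:
            removed["hwe"].append(mid)
        elif c.n_typed > 0 and minor_allele_frequency(c) < th["maf"]:
            removed["maf"].append(mid)
        else:
            continue
        keep[m] = False
    if not keep.any():
        raise ValueError("no markers survive QC")
    survivors = list(mmap.marker_id[keep])
    report = QCReport(thresholds=th, n_input=panel.n_markers, removed=removed,
                      survivors=survivors)
    return panel.subset_markers(keep), mmap.subset(keep), report
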