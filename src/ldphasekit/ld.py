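"""Two-locus LD from unphased genotypes: EM haplotype frequency, D, r, r2.

For a pair of biallelic loci the only phase-ambiguous genotype is the
double heterozygote.  The EM algorithm splits that cell between the
coupling (AB/ab) and repulsion (Ab/aB) resolutions in proportion to the
current haplotype-frequency estimates, assuming random union of gametes
(Hardy-Weinberg at the haplotype level), and recounts haplotypes until
f(AB) converges.  From the fitted f(AB):

    D  = f(AB) - f(A) f(B)
    r2 = D^2 / (f(A) f(a) f(B) f(b))
    r  = sign(D) * sqrt(r2)          (the "LD phase")

Allele frequencies f(A), f(B) are fixed by the genotype counts and are
not re-estimated by EM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import MISSING, GenotypePanel, MarkerMap

EM_TOL = 1e-10
EM_MAX_ITER = 1000
DEFAULT_MIN_PAIR_N = 30
DEFAULT_MAX_DISTANCE_BP = 10_000_000


@dataclass(frozen=True)
class PairGenotypeTable:
    """3x3 joint genotype counts (dosage at locus 1 x dosage at locus 2).

    counts[g1, g2] is the number of individuals non-missing at both loci
    with dosage g1 at the first locus and g2 at the second.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (3, 3) or np.any(c < 0):
            raise ValueError("counts must be a nonnegative 3x3 table")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def n_used(self) -> int:
        return int(self.counts.sum())


def pair_table(dos_i: np.ndarray, dos_j: np.ndarray) -> PairGenotypeTable:
    """Joint genotype table over individuals non-missing at both loci."""
    ok = (dos_i != MISSING) & (dos_j != MISSING)
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (dos_i[ok], dos_j[ok]), 1)
    return PairGenotypeTable(counts)


def _known_haplotype_counts(c: np.ndarray) -> tuple[float, float, float, float]:
    """Phase-unambiguous haplotype counts (AB, Ab, aB, ab) from a 3x3 table.

    Every cell except the double heterozygote (1,1) resolves uniquely.
    Dosage counts copies of A at locus 1 and B at locus 2.
    """
    n_ab = 2 * c[2, 2] + c[2, 1] + c[1, 2]          # AB
    n_aB = 2 * c[2, 0] + c[2, 1] + c[1, 0]          # Ab
    n_bA = 2 * c[0, 2] + c[1, 2] + c[0, 1]          # aB
    n_nn = 2 * c[0, 0] + c[1, 0] + c[0, 1]          # ab
    return float(n_ab), float(n_aB), float(n_bA), float(n_nn)


def _loglik(c: np.ndarray, f_ab: float, f_a: float, f_b: float) -> float:
    """Multinomial log-likelihood of the 3x3 table at haplotype freqs."""
    h = np.array(
        [f_ab, f_a - f_ab, f_b - f_ab, 1.0 - f_a - f_b + f_ab]
    )  # AB, Ab, aB, ab
    h = np.clip(h, 1e-300, None)
    # genotype-pair probabilities under random union of gametes
    hap_dos = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
    probs = np.zeros((3, 3))
    for x in range(4):
        for y in range(4):
            g1 = hap_dos[x, 0] + hap_dos[y, 0]
            g2 = hap_dos[x, 1] + hap_dos[y, 1]
            probs[g1, g2] += h[x] * h[y]
    return float(np.sum(c * np.log(np.clip(probs, 1e-300, None))))


def haplotype_freq_em(
    table: PairGenotypeTable,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> tuple[float, float, bool]:
    """Maximum-likelihood f(AB) under random union of gametes, by EM.

    Returns (f_AB, log_likelihood, converged).  The likelihood in f(AB)
    can have several stationary points (its score equation is cubic), and
    the linkage-equilibrium start can even sit exactly on a symmetric
    saddle, so EM is run from the equilibrium start plus starts near each
    end of the admissible interval and the highest-likelihood solution is
    kept.  Raises on a monomorphic locus.
    """
    c = table.counts
    n = table.n_used
    if n == 0:
        raise ValueError("empty genotype table")
    n_hap = 2.0 * n
    f_a = (2 * c[2, :].sum() + c[1, :].sum()) / n_hap
    f_b = (2 * c[:, 2].sum() + c[:, 1].sum()) / n_hap
    if f_a in (0.0, 1.0) or f_b in (0.0, 1.0):
        raise ValueError("monomorphic locus in the used individuals")
    k_ab, _, _, _ = _known_haplotype_counts(c)
    n_dh = float(c[1, 1])
    lo, hi = max(0.0, f_a + f_b - 1.0), min(f_a, f_b)
    starts = [f_a * f_b, lo + 0.02 * (hi - lo), lo + 0.98 * (hi - lo)]
    best = (-np.inf, f_a * f_b, False)
    for f_ab in starts:
        converged = False
        for _ in range(max_iter):
            coup = f_ab * (1.0 - f_a - f_b + f_ab)
            rep = (f_a - f_ab) * (f_b - f_ab)
            w = coup / (coup + rep) if (coup + rep) > 0 else 0.5
            f_new = (k_ab + w * n_dh) / n_hap
            f_new = min(max(f_new, lo), hi)
            if abs(f_new - f_ab) < tol:
                f_ab = f_new
                converged = True
                break
            f_ab = f_new
        ll = _loglik(c, f_ab, f_a, f_b)
        if ll > best[0] + 1e-12:
            best = (ll, f_ab, converged)
    return best[1], best[0], best[2]


def ld_from_freqs(f_ab: float, f_a: float, f_b: float) -> tuple[float, float, float]:
    """(D, r, r2) from haplotype and allele frequencies.

    D = f(AB) - f(A)f(B); r2 = D^2 / (f(A)f(a)f(B)f(b)); r carries the
    sign of D.  Boundary allele frequencies are rejected.
    """
    if not (0.0 < f_a < 1.0 and 0.0 < f_b < 1.0):
        raise ValueError("allele frequencies must be interior")
    lo, hi = max(0.0, f_a + f_b - 1.0), min(f_a, f_b)
    if f_ab < lo - 1e-9 or f_ab > hi + 1e-9:
        raise ValueError("f_AB outside the admissible interval")
    d = f_ab - f_a * f_b
    r2 = d * d / (f_a * (1 - f_a) * f_b * (1 - f_b))
    r2 = min(r2, 1.0)
    r = float(np.sign(d)) * float(np.sqrt(r2))
    return d, r, r2


def ld_from_phased(hap_counts: dict[str, float]) -> tuple[float, float, float]:
    """(D, r, r2) by direct counting of known-phase haplotypes.

    ``hap_counts`` keys: "AB", "Ab", "aB", "ab".
    """
    n = sum(hap_counts.get(k, 0) for k in ("AB", "Ab", "aB", "ab"))
    if n == 0:
        raise ValueError("no haplotypes")
    f_ab = hap_counts.get("AB", 0) / n
    f_a = (hap_counts.get("AB", 0) + hap_counts.get("Ab", 0)) / n
    f_b = (hap_counts.get("AB", 0) + hap_counts.get("aB", 0)) / n
    return ld_from_freqs(f_ab, f_a, f_b)


# ---------------------------------------------------------------------------
# vectorized EM over many pairs (used by pairwise_ld)

def _loglik_batch(c: np.ndarray, f_ab, f_a, f_b) -> np.ndarray:
    """Multinomial log-likelihood per pair; c is (P, 3, 3)."""
    h0 = f_ab
    h1 = f_a - f_ab
    h2 = f_b - f_ab
    h3 = 1.0 - f_a - f_b + f_ab
    probs = np.empty((len(c), 3, 3))
    probs[:, 2, 2] = h0 * h0
    probs[:, 2, 1] = 2 * h0 * h1
    probs[:, 2, 0] = h1 * h1
    probs[:, 1, 2] = 2 * h0 * h2
    probs[:, 0, 2] = h2 * h2
    probs[:, 1, 1] = 2 * h0 * h3 + 2 * h1 * h2
    probs[:, 1, 0] = 2 * h1 * h3
    probs[:, 0, 1] = 2 * h2 * h3
    probs[:, 0, 0] = h3 * h3
    return np.sum(c * np.log(np.clip(probs, 1e-300, None)), axis=(1, 2))


def _em_batch(tables9: np.ndarray, tol: float = EM_TOL, max_iter: int = EM_MAX_ITER):
    """Multi-start EM over P pairs at once; tables9 has shape (P, 3, 3).

    Runs the same three starts as :func:`haplotype_freq_em` and keeps the
    highest-likelihood solution per pair.  Returns (f_ab, f_a, f_b,
    converged); pairs with a monomorphic locus get NaN f_ab.
    """
    c = tables9.astype(np.float64)
    n_hap = 2.0 * c.sum(axis=(1, 2))
    f_a = (2 * c[:, 2, :].sum(axis=1) + c[:, 1, :].sum(axis=1)) / n_hap
    f_b = (2 * c[:, :, 2].sum(axis=1) + c[:, :, 1].sum(axis=1)) / n_hap
    poly = (f_a > 0) & (f_a < 1) & (f_b > 0) & (f_b < 1)
    k_ab = 2 * c[:, 2, 2] + c[:, 2, 1] + c[:, 1, 2]
    n_dh = c[:, 1, 1]
    lo = np.maximum(0.0, f_a + f_b - 1.0)
    hi = np.minimum(f_a, f_b)

    def run(f0: np.ndarray):
        f_ab = f0.copy()
        converged = np.zeros(len(c), dtype=bool)
        active = poly.copy()
        for _ in range(max_iter):
            if not active.any():
                break
            h_ab = f_ab[active]
            fa, fb = f_a[active], f_b[active]
            coup = h_ab * (1.0 - fa - fb + h_ab)
            rep = (fa - h_ab) * (fb - h_ab)
            tot = coup + rep
            w = np.where(tot > 0, coup / np.where(tot > 0, tot, 1.0), 0.5)
            f_new = (k_ab[active] + w * n_dh[active]) / n_hap[active]
            f_new = np.clip(f_new, lo[active], hi[active])
            done = np.abs(f_new - h_ab) < tol
            f_ab[active] = f_new
            idx = np.flatnonzero(active)
            converged[idx[done]] = True
            active[idx[done]] = False
        return f_ab, converged

    best_f, best_conv = run(f_a * f_b)
    best_ll = _loglik_batch(c, best_f, f_a, f_b)
    # extra starts only matter for pairs with double heterozygotes
    multi = poly & (n_dh > 0)
    if multi.any():
        for frac in (0.02, 0.98):
            f0 = np.where(multi, lo + frac * (hi - lo), best_f)
            f_alt, conv_alt = run(f0)
            ll_alt = _loglik_batch(c, f_alt, f_a, f_b)
            better = multi & (ll_alt > best_ll + 1e-12)
            best_f = np.where(better, f_alt, best_f)
            best_conv = np.where(better, conv_alt, best_conv)
            best_ll = np.where(better, ll_alt, best_ll)
    f_ab = np.where(poly, best_f, np.nan)
    return f_ab, f_a, f_b, best_conv.astype(bool)


def _onehot(dosages: np.ndarray) -> np.ndarray:
    """(n, M, 3) float32 indicator of dosage 0/1/2; missing rows all-zero."""
    n, m = dosages.shape
    oh = np.zeros((n, m, 3), dtype=np.float32)
    for g in (0, 1, 2):
        oh[:, :, g] = dosages == g
    return oh


def pairwise_ld(
    panel: GenotypePanel,
    mmap: MarkerMap,
    max_distance_bp: int = DEFAULT_MAX_DISTANCE_BP,
    min_pair_n: int = DEFAULT_MIN_PAIR_N,
) -> pd.DataFrame:
    """LD records for every within-chromosome marker pair within range.

    Pairs never span chromosomes.  A pair is skipped when fewer than
    ``min_pair_n`` individuals are non-missing at both loci or when either
    locus is monomorphic among those individuals.  Output is ordered by
    (chromosome, pos_i, pos_j); columns follow the ``ld`` table layout.
    """
    if mmap.n_markers == 0:
        raise ValueError("empty marker map")
    frames: list[pd.DataFrame] = []
    for chrom in pd.unique(mmap.chromosome):
        idx = np.flatnonzero(mmap.chromosome == chrom)
        pos = mmap.position_bp[idx]
        ids = mmap.marker_id[idx]
        oh = _onehot(panel.dosages[:, idx])
        m = len(idx)
        # gather joint genotype tables for every in-range pair, then run a
        # single EM batch per chromosome (per-pair loops are too slow)
        table_chunks, ai_chunks, bi_chunks = [], [], []
        for a in range(m - 1):
            b_end = int(np.searchsorted(pos, pos[a] + max_distance_bp, side="right"))
            if b_end <= a + 1:
                continue
            tables = np.einsum("ng,nwh->wgh", oh[:, a, :], oh[:, a + 1 : b_end, :])
            table_chunks.append(np.rint(tables).astype(np.int64))
            ai_chunks.append(np.full(b_end - a - 1, a))
            bi_chunks.append(np.arange(a + 1, b_end))
        if not table_chunks:
            continue
        tables = np.concatenate(table_chunks)
        ai = np.concatenate(ai_chunks)
        bi = np.concatenate(bi_chunks)
        n_used = tables.sum(axis=(1, 2))
        ok = n_used >= min_pair_n
        if not ok.any():
            continue
        tables, ai, bi, n_used = tables[ok], ai[ok], bi[ok], n_used[ok]
        f_ab, f_a, f_b, conv = _em_batch(tables)
        keep = ~np.isnan(f_ab)  # drop pairs monomorphic within used individuals
        f_ab, f_a, f_b = f_ab[keep], f_a[keep], f_b[keep]
        ai, bi, n_used, conv = ai[keep], bi[keep], n_used[keep], conv[keep]
        d = f_ab - f_a * f_b
        r2 = np.minimum(d * d / (f_a * (1 - f_a) * f_b * (1 - f_b)), 1.0)
        r = np.sign(d) * np.sqrt(r2)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "id_i": ids[ai],
                    "id_j": ids[bi],
                    "pos_i": pos[ai],
                    "pos_j": pos[bi],
                    "dist_bp": pos[bi] - pos[ai],
                    "fA": f_a,
                    "fB": f_b,
                    "fAB": f_ab,
                    "D": d,
                    "r": r,
                    "r2": r2,
                    "n_used": n_used,
                    "converged": conv,
                }
            )
        )
    cols = [
        "chrom", "id_i", "id_j", "pos_i", "pos_j", "dist_bp",
        "fA", "fB", "fAB", "D", "r", "r2", "n_used", "converged",
    ]
    if not frames:
        return pd.DataFrame(columns=cols)
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["chrom", "pos_i", "pos_j"], kind="mergesort").reset_index(
        drop=True
    )
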