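"""Distance-binned LD decay summaries, the decay linear model, useful-LD coverage.

Two stock binning schemes are provided: ``figure2`` (a 10-kb first bin
then 5-kb bins up to 5 Mb, restricted to marker pairs lying in the first
5 Mb of each chromosome) and ``table3`` (0-30, 30-70, 70-100, 100-200,
200-1000 kb).  All intervals are half-open [lo, hi) in bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf


@dataclass(frozen=True)
class BinScheme:
    kind: str
    edges: tuple  # strictly increasing bp boundaries, len >= 2
    max_position_bp: int | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=np.int64)
        if len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("edges must be strictly increasing with >= 2 entries")
        object.__setattr__(self, "edges", tuple(int(x) for x in e))

    @property
    def labels(self) -> list[str]:
        e = self.edges
        return [f"[{e[i]},{e[i+1]})" for i in range(len(e) - 1)]


def figure2_scheme() -> BinScheme:
    """10-kb first bin then 5-kb bins to 5 Mb; pairs confined to the first 5 Mb."""
    edges = [0, 10_000] + list(range(15_000, 5_000_001, 5_000))
    return BinScheme("figure2", tuple(edges), max_position_bp=5_000_000)


def table3_scheme() -> BinScheme:
    """Distance ranges 0-30, 30-70, 70-100, 100-200, 200-1000 kb."""
    return BinScheme("table3", (0, 30_000, 70_000, 100_000, 200_000, 1_000_000))


def custom_scheme(edges, max_position_bp: int | None = None) -> BinScheme:
    return BinScheme("custom", tuple(edges), max_position_bp)


def assign_bins(records: pd.DataFrame, scheme: BinScheme) -> pd.DataFrame:
    """Tag LD records with bin labels; drop records outside the scheme.

    A record is excluded when its distance falls beyond the last edge or,
    if the scheme caps positions, when either marker lies past the cap.
    """
    if len(records) == 0:
        out = records.copy()
        out["bin"] = pd.Series(dtype=object)
        return out
    df = records.copy()
    keep = np.ones(len(df), dtype=bool)
    if scheme.max_position_bp is not None:
        keep &= (df["pos_i"].to_numpy() <= scheme.max_position_bp) & (
            df["pos_j"].to_numpy() <= scheme.max_position_bp
        )
    edges = np.asarray(scheme.edges)
    dist = df["dist_bp"].to_numpy()
    which = np.searchsorted(edges, dist, side="right") - 1
    keep &= (which >= 0) & (which < len(edges) - 1)
    df = df.loc[keep].copy()
    labels = np.asarray(scheme.labels, dtype=object)
    df["bin"] = labels[which[keep]]
    return df


def summarize(
    binned: pd.DataFrame,
    threshold: float = 0.3,
    strict: bool = True,
    population: str | None = None,
) -> pd.DataFrame:
    """Per-(population, bin) mean/SD of r2 and the share above threshold.

    The proportion uses strict ``>`` by default (configurable to ``>=``).
    Bins with one record get NaN SD; the ``population`` argument labels
    records lacking a population column.
    """
    df = binned.copy()
    if "population" not in df.columns:
        df["population"] = population if population is not None else "all"
    rows = []
    for (pop, label), grp in df.groupby(["population", "bin"], sort=True):
        r2 = grp["r2"].to_numpy(dtype=float)
        above = (r2 > threshold) if strict else (r2 >= threshold)
        n = len(r2)
        rows.append(
            {
                "population": pop,
                "bin": label,
                "n_pairs": n,
                "mean_r2": float(r2.mean()) if n else np.nan,
                "sd_r2": float(r2.std(ddof=1)) if n > 1 else np.nan,
                "n_above_threshold": int(above.sum()),
                "pct_above_threshold": 100.0 * above.sum() / n if n else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "population", "bin", "n_pairs", "mean_r2", "sd_r2",
            "n_above_threshold", "pct_above_threshold",
        ],
    )


@dataclass
class DecayModelFit:
    """OLS fit of r2 on distance with population x chromosome factors."""

    params: pd.Series
    distance_slope: float
    anova: pd.DataFrame  # sequential (type I) table
    model: object = field(repr=False, default=None)

    @property
    def slope_se(self) -> float:
        return float(self.model.bse["dist_bp"])


def fit_decay_model(records: pd.DataFrame) -> DecayModelFit:
    """Fit r2 ~ population + chromosome + distance + population:chromosome.

    Ordinary least squares on per-pair records; the ANOVA table is
    sequential (type I) in the order population, chromosome, distance,
    interaction.  Factor terms with a single level are dropped; rank
    deficiency is reported rather than silently absorbed.
    """
    df = records.copy()
    if "population" not in df.columns:
        df["population"] = "all"
    df["dist_bp"] = df["dist_bp"].astype(float)
    # factor terms only for factors that vary (a single-population,
    # single-chromosome fit degenerates to simple regression on distance)
    terms = []
    if df["population"].nunique() >= 2:
        terms.append("C(population)")
    if df["chrom"].nunique() >= 2:
        terms.append("C(chrom)")
    terms.append("dist_bp")
    if df["population"].nunique() >= 2 and df["chrom"].nunique() >= 2:
        terms.append("C(population):C(chrom)")
    formula = "r2 ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=df).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("design matrix is rank deficient")
    anova = _sequential_anova(df, terms, fit)
    return DecayModelFit(
        params=fit.params,
        distance_slope=float(fit.params["dist_bp"]),
        anova=anova,
        model=fit,
    )


def _sequential_anova(df: pd.DataFrame, terms: list, full_fit) -> pd.DataFrame:
    """Type-I ANOVA by nested model comparison in the given term order.

    Built explicitly (rather than via anova_lm) so the sequential order
    is exactly the one requested even with a continuous covariate mixed
    into categorical terms.
    """
    from scipy.stats import f as f_dist

    resid_df = full_fit.df_resid
    resid_ms = full_fit.ssr / resid_df
    rows = []
    prev = smf.ols("r2 ~ 1", data=df).fit()
    for i, term in enumerate(terms):
        cur = smf.ols("r2 ~ " + " + ".join(terms[: i + 1]), data=df).fit()
        ss = prev.ssr - cur.ssr
        dfree = prev.df_resid - cur.df_resid
        ms = ss / dfree if dfree else np.nan
        fval = ms / resid_ms
        rows.append(
            {
                "source": term,
                "df": dfree,
                "sum_sq": ss,
                "mean_sq": ms,
                "F": fval,
                "PR(>F)": float(f_dist.sf(fval, dfree, resid_df)),
            }
        )
        prev = cur
    rows.append(
        {
            "source": "Residual",
            "df": resid_df,
            "sum_sq": full_fit.ssr,
            "mean_sq": resid_ms,
            "F": np.nan,
            "PR(>F)": np.nan,
        }
    )
    return pd.DataFrame(rows).set_index("source")


def useful_ld_coverage(
    records: pd.DataFrame,
    mmap,
    max_distance_bp: int = 70_000,
    threshold: float = 0.15,
    inclusive: bool = True,
    with_n: bool = False,
):
    """Fraction of adjacent-marker pairs within range with r2 >= threshold.

    Only pairs of markers adjacent in the map count, mirroring the
    question of how much "useful" LD a chip of a given density captures.
    With ``with_n`` the qualifying pair count is returned alongside.
    """
    adjacent = set()
    for chrom in pd.unique(mmap.chromosome):
        ids = mmap.marker_id[mmap.chromosome == chrom]
        for a, b in zip(ids[:-1], ids[1:]):
            adjacent.add((a, b))
    mask = [
        (i, j) in adjacent and d <= max_distance_bp
        for i, j, d in zip(records["id_i"], records["id_j"], records["dist_bp"])
    ]
    sub = records.loc[mask]
    if len(sub) == 0:
        raise ValueError("no qualifying adjacent pairs")
    r2 = sub["r2"].to_numpy(dtype=float)
    hits = (r2 >= threshold) if inclusive else (r2 > threshold)
    if with_n:
        return float(hits.mean()), int(len(sub))
    return float(hits.mean())
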