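"""Persistence of LD phase: correlating signed r across populations.

For marker pairs shared by two populations, the Pearson correlation of
their signed r values measures how well marker-QTL association phase
transfers between the populations.  The comparison is only meaningful if
both populations count the same allele at every marker; recorded
orientation flips are corrected by negating r (one flipped marker in a
pair negates r, two flips cancel).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_STRATA = ((0, 70_000), (70_000, 100_000), (100_000, 200_000))


def match_pairs(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    orientation_a: dict[str, str] | None = None,
    orientation_b: dict[str, str] | None = None,
    drop_nonconverged: bool = True,
) -> pd.DataFrame:
    """Inner-join LD records of two populations on the marker pair.

    When orientation maps (marker_id -> counted allele) are supplied, a
    marker counted differently in B has r_B sign-corrected; a marker with
    unknown orientation in either population rejects the pair.  Without
    orientation maps, identical orientation is assumed.
    """
    a = records_a
    b = records_b
    if drop_nonconverged:
        if "converged" in a.columns:
            a = a[a["converged"]]
        if "converged" in b.columns:
            b = b[b["converged"]]
    merged = a.merge(
        b[["id_i", "id_j", "r", "r2"]],
        on=["id_i", "id_j"],
        suffixes=("_a", "_b"),
        how="inner",
    )
    if len(merged) == 0:
        raise ValueError("no shared marker pairs between the two record sets")
    merged = merged.rename(columns={"r_a": "r_A", "r_b": "r_B",
                                    "r2_a": "r2_A", "r2_b": "r2_B"})
    if orientation_a is not None or orientation_b is not None:
        if orientation_a is None or orientation_b is None:
            raise ValueError("supply orientation for both populations or neither")
        sign = np.ones(len(merged))
        keep = np.ones(len(merged), dtype=bool)
        for col in ("id_i", "id_j"):
            for k, mid in enumerate(merged[col]):
                ca, cb = orientation_a.get(mid), orientation_b.get(mid)
                if ca is None or cb is None:
                    keep[k] = False
                elif ca != cb:
                    sign[k] *= -1.0
        merged = merged.loc[keep].copy()
        if len(merged) == 0:
            raise ValueError("no orientable shared marker pairs")
        merged["r_B"] = merged["r_B"].to_numpy() * sign[keep]
    out_cols = ["id_i", "id_j", "dist_bp", "r_A", "r_B", "r2_A", "r2_B"]
    return merged[out_cols].sort_values(["id_i", "id_j"], kind="mergesort").reset_index(
        drop=True
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def phase_correlation(
    matched: pd.DataFrame,
    strata=DEFAULT_STRATA,
    min_r2: float = 0.3,
    restrict: str = "both",
    population_pair: str = "A-B",
) -> pd.DataFrame:
    """Pearson correlation of (r_A, r_B) per distance stratum.

    Each stratum is half-open [lo, hi) bp.  ``correlation_highLD``
    restricts to pairs with r2 >= min_r2 in both populations (or in A or
    B only, per ``restrict``).  Degenerate strata yield NaN.
    """
    if restrict not in ("both", "a", "b"):
        raise ValueError("restrict must be 'both', 'a' or 'b'")
    rows = []
    dist = matched["dist_bp"].to_numpy()
    for lo, hi in strata:
        sel = (dist >= lo) & (dist < hi)
        sub = matched.loc[sel]
        if restrict == "both":
            high = sub[(sub["r2_A"] >= min_r2) & (sub["r2_B"] >= min_r2)]
        elif restrict == "a":
            high = sub[sub["r2_A"] >= min_r2]
        else:
            high = sub[sub["r2_B"] >= min_r2]
        rows.append(
            {
                "population_pair": population_pair,
                "stratum": f"[{lo},{hi})",
                "n_pairs": len(sub),
                "correlation_all": _pearson(
                    sub["r_A"].to_numpy(), sub["r_B"].to_numpy()
                ),
                "n_pairs_highLD": len(high),
                "correlation_highLD": _pearson(
                    high["r_A"].to_numpy(), high["r_B"].to_numpy()
                ),
                "min_r2": min_r2,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "population_pair", "stratum", "n_pairs", "correlation_all",
            "n_pairs_highLD", "correlation_highLD", "min_r2",
        ],
    )
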