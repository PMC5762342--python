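"""Per-condition lncRNA-PCG co-expression calling.

A pair is co-expressed within one condition (normal or cancer) when the
Pearson correlation of the two genes' RPKM profiles across that
condition's samples satisfies |r| >= 0.7 (inclusive) with correlation
p < 0.001 (strict). The p-value is the usual two-sided t transform
t = r * sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom. Pairs where
either gene is constant within the condition are skipped (their
correlation is undefined), which is common for zero-inflated lncRNAs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

R_MIN = 0.7
P_MAX = 0.001

PAIR_COLUMNS = ["lnc_id", "pcg_id", "condition", "r", "p", "sign"]


def pearson_cc(x, y) -> float:
    """Sample Pearson correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of at least 3 samples")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson r at sample size n (t transform)."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1:
        return 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


def _standardize_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-standardize; returns (z, constant_row_mask)."""
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    return (values - mu) / sd, constant


def call_pairs(
    lnc_matrix: pd.DataFrame,
    pcg_matrix: pd.DataFrame,
    condition: str,
    r_min: float = R_MIN,
    p_max: float = P_MAX,
) -> pd.DataFrame:
    """All lncRNA x PCG pairs passing |r| >= r_min and p < p_max.

    Both matrices are genes x samples RPKM slices restricted to the same
    samples of one condition. Returns a DataFrame with columns
    (lnc_id, pcg_id, condition, r, p, sign), sorted by (lnc_id, pcg_id).
    """
    if list(lnc_matrix.columns) != list(pcg_matrix.columns):
        raise ValueError("lnc and pcg slices must cover the same samples")
    n = lnc_matrix.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples per condition")

    zl, const_l = _standardize_rows(lnc_matrix.to_numpy(dtype=float))
    zp, const_p = _standardize_rows(pcg_matrix.to_numpy(dtype=float))
    if const_l.any() or const_p.any():
        logger.info(
            "%s: skipping %d constant lncRNAs and %d constant PCGs",
            condition,
            int(const_l.sum()),
            int(const_p.sum()),
        )

    r = zl @ zp.T / n
    np.clip(r, -1.0, 1.0, out=r)
    r[const_l, :] = 0.0
    r[:, const_p] = 0.0

    mask = np.abs(r) >= r_min
    li, pi = np.nonzero(mask)
    rv = r[li, pi]
    with np.errstate(divide="ignore"):
        tstat = rv * np.sqrt((n - 2) / np.maximum(1 - rv * rv, 1e-300))
    pv = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    pv[np.abs(rv) >= 1] = 0.0
    keep = pv < p_max

    out = pd.DataFrame(
        {
            "lnc_id": np.asarray(lnc_matrix.index)[li[keep]],
            "pcg_id": np.asarray(pcg_matrix.index)[pi[keep]],
            "condition": condition,
            "r": rv[keep],
            "p": pv[keep],
            "sign": np.where(rv[keep] > 0, "positive", "negative"),
        }
    )
    return out.sort_values(["lnc_id", "pcg_id"], ignore_index=True)


def summarize_pairs(pairs: pd.DataFrame) -> dict:
    """Table-style counts: pairs, distinct lncRNAs/PCGs, sign split."""
    pos = pairs[pairs["sign"] == "positive"]
    neg = pairs[pairs["sign"] == "negative"]
    return {
        "pairs": len(pairs),
        "lncRNAs": pairs["lnc_id"].nunique(),
        "PCGs": pairs["pcg_id"].nunique(),
        "positive_pairs": len(pos),
        "positive_lncRNAs": pos["lnc_id"].nunique(),
        "positive_PCGs": pos["pcg_id"].nunique(),
        "negative_pairs": len(neg),
        "negative_lncRNAs": neg["lnc_id"].nunique(),
        "negative_PCGs": neg["pcg_id"].nunique(),
    }


def write_pairs(pairs: pd.DataFrame, path) -> None:
    """Write the pair edge list as TSV."""
    pairs.to_csv(path, sep="\t", index=False)
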