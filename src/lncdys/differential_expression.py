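"""Zero-inflation-aware differential expression between cancer and normal.

Low-abundance genes (lncRNAs especially) are frequently undetected
(read count = 0) in a subset of samples, which violates the assumptions of
a mean-difference test. The caller therefore switches per gene: when the
zero fraction exceeds 30% in either group the gene is tested as a binary
detected/undetected contrast with a two-sided Fisher's exact test
(FDR < 0.01); otherwise a pooled-variance Student's t test on RPKM is used
(FDR < 0.05). Benjamini-Hochberg adjustment is applied within each test
family separately, and every significant call additionally requires a
ratio fold change (higher group mean RPKM over lower) above 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression_data import ExpressionMatrix

ZERO_FRACTION_THRESHOLD = 0.30
FISHER_FDR = 0.01
TTEST_FDR = 0.05
FC_THRESHOLD = 2.0
FC_EPSILON = 0.01  # RPKM pseudocount guarding zero group means


@dataclass(frozen=True)
class DiffThresholds:
    """Cutoffs for the differential caller."""

    zero_fraction: float = ZERO_FRACTION_THRESHOLD
    fisher_fdr: float = FISHER_FDR
    ttest_fdr: float = TTEST_FDR
    fc: float = FC_THRESHOLD
    epsilon: float = FC_EPSILON


def zero_fraction(values) -> float:
    """Fraction of entries exactly equal to zero (undetected)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("zero_fraction of an empty vector is undefined")
    return float(np.mean(arr == 0))


def choose_test(
    zero_frac_cancer: float,
    zero_frac_normal: float,
    threshold: float = ZERO_FRACTION_THRESHOLD,
) -> str:
    """Pick "fisher" when either group's zero fraction strictly exceeds
    the threshold, else "ttest"."""
    if zero_frac_cancer > threshold or zero_frac_normal > threshold:
        return "fisher"
    return "ttest"


def fisher_detection_test(
    detected_cancer: int, n_cancer: int, detected_normal: int, n_normal: int
) -> float:
    """Two-sided Fisher's exact p for the detected/undetected 2x2 table."""
    if n_cancer <= 0 or n_normal <= 0:
        raise ValueError("each group must contain at least one sample")
    if not (0 <= detected_cancer <= n_cancer and 0 <= detected_normal <= n_normal):
        raise ValueError("detected count outside [0, n]")
    table = [
        [detected_cancer, n_cancer - detected_cancer],
        [detected_normal, n_normal - detected_normal],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


def two_group_t_test(x, y) -> float:
    """Two-sided pooled-variance Student's t p-value, df = n_x + n_y - 2.

    Degenerate convention: zero pooled variance yields p = 1 when the group
    means are equal and p = 0 when they differ.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two samples")
    sx = x.var(ddof=1)
    sy = y.var(ddof=1)
    if sx == 0 and sy == 0:
        return 1.0 if x.mean() == y.mean() else 0.0
    return float(stats.ttest_ind(x, y, equal_var=True).pvalue)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted values, order-preserving, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(
    mean_cancer: float, mean_normal: float, epsilon: float = FC_EPSILON
) -> tuple[float, str]:
    """Ratio fold change (>= 1) and direction of change in cancer.

    fc = (max + eps) / (min + eps) with a pseudocount guarding zero means;
    direction is "up_in_cancer", "down_in_cancer" or "none" (equal means).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    hi, lo = max(mean_cancer, mean_normal), min(mean_cancer, mean_normal)
    fc = (hi + epsilon) / (lo + epsilon)
    if mean_cancer > mean_normal:
        direction = "up_in_cancer"
    elif mean_cancer < mean_normal:
        direction = "down_in_cancer"
    else:
        direction = "none"
    return fc, direction


def call_differential(
    matrix: ExpressionMatrix,
    classes: pd.Series | None = None,
    thresholds: DiffThresholds = DiffThresholds(),
) -> pd.DataFrame:
    """Run the per-gene test switch over a whole matrix.

    Per gene: the zero fractions of read counts (RPKM when counts are
    absent) in cancer and normal decide the test; a gene is tested by
    exactly one family. BH adjustment runs within each family separately.
    Significance requires the family FDR cutoff and fc > 2.

    Returns a DataFrame indexed by gene with columns ``cls`` (if classes
    given), ``test_used``, ``p``, ``fdr``, ``fc``, ``direction`` and
    ``significant``.
    """
    cancer = matrix.condition_values("cancer")
    normal = matrix.condition_values("normal")
    if cancer.shape[1] < 2 or normal.shape[1] < 2:
        raise ValueError("need at least two samples per group")

    det_src_c = matrix.condition_counts("cancer")
    det_src_n = matrix.condition_counts("normal")
    if det_src_c is None:
        det_src_c, det_src_n = cancer, normal

    cn = det_src_c.to_numpy(dtype=float)
    nn = det_src_n.to_numpy(dtype=float)
    zf_c = np.mean(cn == 0, axis=1)
    zf_n = np.mean(nn == 0, axis=1)
    use_fisher = (zf_c > thresholds.zero_fraction) | (
        zf_n > thresholds.zero_fraction
    )

    genes = matrix.genes
    n_c, n_n = cn.shape[1], nn.shape[1]
    pvals = np.empty(len(genes))
    det_c = (cn > 0).sum(axis=1)
    det_n = (nn > 0).sum(axis=1)

    for i in np.flatnonzero(use_fisher):
        pvals[i] = fisher_detection_test(int(det_c[i]), n_c, int(det_n[i]), n_n)

    t_idx = np.flatnonzero(~use_fisher)
    if t_idx.size:
        xc = cancer.to_numpy(dtype=float)[t_idx]
        xn = normal.to_numpy(dtype=float)[t_idx]
        res = stats.ttest_ind(xc, xn, axis=1, equal_var=True)
        tp = np.asarray(res.pvalue, dtype=float)
        # degenerate rows: zero pooled variance
        degen = (xc.var(axis=1, ddof=1) == 0) & (xn.var(axis=1, ddof=1) == 0)
        tp[degen & (xc.mean(axis=1) == xn.mean(axis=1))] = 1.0
        tp[degen & (xc.mean(axis=1) != xn.mean(axis=1))] = 0.0
        pvals[t_idx] = tp

    fdr = np.ones(len(genes))
    for mask in (use_fisher, ~use_fisher):
        idx = np.flatnonzero(mask)
        if idx.size:
            fdr[idx] = benjamini_hochberg(pvals[idx])

    mean_c = cancer.to_numpy(dtype=float).mean(axis=1)
    mean_n = normal.to_numpy(dtype=float).mean(axis=1)
    eps = thresholds.epsilon
    hi = np.maximum(mean_c, mean_n)
    lo = np.minimum(mean_c, mean_n)
    fc = (hi + eps) / (lo + eps)
    direction = np.where(
        mean_c > mean_n,
        "up_in_cancer",
        np.where(mean_c < mean_n, "down_in_cancer", "none"),
    )

    cutoff = np.where(use_fisher, thresholds.fisher_fdr, thresholds.ttest_fdr)
    significant = (fdr < cutoff) & (fc > thresholds.fc)

    out = pd.DataFrame(
        {
            "test_used": np.where(use_fisher, "fisher", "ttest"),
            "p": pvals,
            "fdr": fdr,
            "fc": fc,
            "direction": direction,
            "significant": significant,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    if classes is not None:
        out.insert(0, "cls", classes.reindex(out.index))
    return out


def significant_genes(
    diff: pd.DataFrame, cls: str | None = None
) -> list[str]:
    """Gene ids called significant, optionally restricted to one class."""
    sub = diff[diff["significant"]]
    if cls is not None:
        sub = sub[sub["cls"] == cls]
    return list(sub.index)
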