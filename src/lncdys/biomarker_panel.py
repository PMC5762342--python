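"""ROC machinery, Youden cutoffs and three-zone diagnostic panels.

A marker's diagnostic value is quantified by the ROC curve of its RPKM
against a binary label (trapezoidal AUC, equal to the normalized
Mann-Whitney U statistic), an operating cutoff maximizing the Youden
index J = sensitivity + specificity - 1 (ties broken toward higher
specificity, cutoffs placed midway between adjacent observed values), and
a DeLong normal-approximation confidence interval for the AUC.

A three-zone panel assigns each marker two RPKM cutoffs: ``low_cutoff``
separates normal from disease and ``high_cutoff`` separates low-risk from
high-risk patients. For a marker higher in disease the zones run
normal < low_cutoff < low-risk < high_cutoff < high-risk; for a marker
lower in disease the order reverses. A sample is zoned per marker and the
overall call is the majority across markers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    direction: str  # higher_in_positive | lower_in_positive


@dataclass(frozen=True)
class PanelMarker:
    gene_id: str
    direction: str
    low_cutoff: float   # normal vs disease boundary
    high_cutoff: float  # low-risk vs high-risk boundary


def _check_binary(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("labels contain a single class")


def roc_curve(scores, labels):
    """ROC points and trapezoidal AUC for higher-score-positive markers.

    Returns (fpr, tpr, auc): arrays of the operating points over all
    threshold steps and the trapezoid area, which equals the pairwise
    Mann-Whitney probability (ties counted one half).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_binary(labels)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(1 - y)[distinct]
    tpr = np.r_[0.0, tps / tps[-1]]
    fpr = np.r_[0.0, fps / fps[-1]]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def auc_score(scores, labels) -> float:
    """Trapezoidal ROC AUC."""
    return roc_curve(scores, labels)[2]


def optimal_cutoff(scores, labels, direction: str = "higher_in_positive"):
    """Youden-optimal operating cutoff.

    Every midpoint between adjacent distinct score values (plus outer
    sentinels) is evaluated; positives are called by score > cutoff
    (``higher_in_positive``) or score < cutoff (``lower_in_positive``).
    Ties in J are broken toward higher specificity, then lower cutoff.

    Returns (cutoff, sensitivity, specificity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_binary(labels)
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2
    span = max(uniq[-1] - uniq[0], 1.0)
    cands = np.r_[uniq[0] - span / 2, mids, uniq[-1] + span / 2]

    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    best = None
    for c in cands:
        pred = scores > c if direction == "higher_in_positive" else scores < c
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        j = sens + spec - 1
        key = (-j, -spec, c)
        if best is None or key < best[0]:
            best = (key, float(c), float(sens), float(spec))
    return best[1], best[2], best[3]


def _delong_variance(scores, labels) -> float:
    """DeLong structural-component variance of the AUC estimate."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    # placement values via pairwise comparison (desk scale: O(m*n))
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (
        pos[:, None] == neg[None, :]
    )
    v10 = cmp.mean(axis=1)  # per-positive placements
    v01 = cmp.mean(axis=0)  # per-negative placements
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def auc_confidence_interval(scores, labels, level: float = 0.95):
    """DeLong normal-approximation CI for the AUC, truncated to [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_binary(labels)
    auc = auc_score(scores, labels)
    var = _delong_variance(scores, labels)
    if var == 0:
        warnings.warn("degenerate AUC variance; returning a point interval")
        return auc, auc
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


def marker_roc(
    scores, labels, direction: str = "higher_in_positive", level: float = 0.95
) -> RocResult:
    """Full per-marker ROC summary at the Youden-optimal cutoff."""
    scores = np.asarray(scores, dtype=float)
    oriented = scores if direction == "higher_in_positive" else -scores
    _, _, auc = roc_curve(oriented, labels)
    lo, hi = auc_confidence_interval(oriented, labels, level)
    cutoff, sens, spec = optimal_cutoff(scores, labels, direction)
    return RocResult(auc, lo, hi, cutoff, sens, spec, direction)


def build_panel(
    marker_expr,
    normal_samples,
    low_risk_samples,
    high_risk_samples,
) -> list[PanelMarker]:
    """Derive two RPKM cutoffs per marker from three sample groups.

    ``marker_expr`` is a genes x samples DataFrame of RPKM. Per marker the
    direction comes from the sign of mean(disease) - mean(normal);
    ``low_cutoff`` is the Youden cutoff of normal vs all-disease and
    ``high_cutoff`` that of low-risk vs high-risk. Markers whose cutoffs
    violate the zone order are flagged ambiguous and excluded with a
    warning.
    """
    for grp, name in (
        (normal_samples, "normal"),
        (low_risk_samples, "low-risk"),
        (high_risk_samples, "high-risk"),
    ):
        if len(grp) < 2:
            raise ValueError(f"{name} group needs at least 2 samples")

    panel = []
    for gene in marker_expr.index:
        x_norm = marker_expr.loc[gene, normal_samples].to_numpy(float)
        x_low = marker_expr.loc[gene, low_risk_samples].to_numpy(float)
        x_high = marker_expr.loc[gene, high_risk_samples].to_numpy(float)
        x_cancer = np.r_[x_low, x_high]

        direction = (
            "higher_in_positive"
            if x_cancer.mean() >= x_norm.mean()
            else "lower_in_positive"
        )
        low_cut, _, _ = optimal_cutoff(
            np.r_[x_norm, x_cancer],
            np.r_[np.zeros(x_norm.size), np.ones(x_cancer.size)],
            direction,
        )
        high_cut, _, _ = optimal_cutoff(
            np.r_[x_low, x_high],
            np.r_[np.zeros(x_low.size), np.ones(x_high.size)],
            direction,
        )
        ok = (
            low_cut < high_cut
            if direction == "higher_in_positive"
            else low_cut > high_cut
        )
        if not ok:
            logger.warning(
                "marker %s ambiguous (crossing cutoffs %.4g / %.4g); excluded",
                gene, low_cut, high_cut,
            )
            continue
        panel.append(PanelMarker(str(gene), direction, low_cut, high_cut))
    return panel


def classify_sample(panel: list[PanelMarker], rpkm: dict) -> dict:
    """Zone each marker and issue a majority overall call.

    A value exactly at a cutoff falls in the lower-risk zone. Returns
    {"zones": {gene: zone}, "call": zone-or-"indeterminate"}.
    """
    zones = {}
    for m in panel:
        if m.gene_id not in rpkm:
            raise KeyError(f"sample is missing panel gene {m.gene_id!r}")
        v = float(rpkm[m.gene_id])
        if m.direction == "higher_in_positive":
            if v <= m.low_cutoff:
                zone = "normal"
            elif v <= m.high_cutoff:
                zone = "low_risk"
            else:
                zone = "high_risk"
        else:
            if v >= m.low_cutoff:
                zone = "normal"
            elif v >= m.high_cutoff:
                zone = "low_risk"
            else:
                zone = "high_risk"
        zones[m.gene_id] = zone

    counts: dict[str, int] = {}
    for z in zones.values():
        counts[z] = counts.get(z, 0) + 1
    top = max(counts.values())
    winners = [z for z, c in counts.items() if c == top]
    call = winners[0] if len(winners) == 1 else "indeterminate"
    return {"zones": zones, "call": call}
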