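"""Risk-group stratification from sub-module expression and survival tests.

Patients are split into two groups by unsupervised Ward-linkage
hierarchical clustering (Euclidean distance) on the z-scored expression of
a sub-module's member genes; the group with the lower Kaplan-Meier
survival at the last time point common to both groups is labelled
"high" risk. Separation is assessed with the product-limit estimator and
the one-degree-of-freedom log-rank test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger(__name__)


def kaplan_meier(times, events) -> pd.Series:
    """Product-limit survival estimate S(t).

    Returns a Series indexed by time (starting at 0 with S = 1),
    right-continuous and non-increasing. Deaths precede censorings at tied
    times, the standard product-limit convention.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    surv = kmf.survival_function_["KM_estimate"]
    surv.index.name = "time"
    return surv


def survival_at(surv: pd.Series, t: float) -> float:
    """Step-function evaluation of a KM curve at time t."""
    idx = surv.index.to_numpy(dtype=float)
    pos = np.searchsorted(idx, t, side="right") - 1
    if pos < 0:
        return 1.0
    return float(surv.iloc[pos])


def log_rank_test(group_a: pd.DataFrame, group_b: pd.DataFrame):
    """Log-rank chi-square (df = 1) and p for two survival tables.

    Each table needs ``time`` and ``event`` columns; at least one event
    must be observed overall.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    if int(group_a["event"].sum()) + int(group_b["event"].sum()) == 0:
        raise ValueError("log-rank test requires at least one event")
    res = logrank_test(
        group_a["time"], group_b["time"],
        event_observed_A=group_a["event"], event_observed_B=group_b["event"],
    )
    return float(res.test_statistic), float(res.p_value)


def risk_split(
    module_expr: pd.DataFrame, survival: pd.DataFrame
) -> pd.Series:
    """Assign each patient to a high- or low-risk group.

    Parameters
    ----------
    module_expr
        Patients x module-member RPKM (rows = patient ids). Members
        constant across patients are dropped with a warning.
    survival
        Indexed by patient id with ``time`` and ``event`` columns; used
        only to decide which cluster is labelled "high".

    Returns a Series patient -> {"high", "low"}.
    """
    if module_expr.shape[1] < 2:
        raise ValueError("need at least 2 module members")
    if module_expr.shape[0] < 4:
        raise ValueError("need at least 4 patients")

    sd = module_expr.std(axis=0, ddof=0)
    constant = sd[sd == 0].index
    if len(constant):
        logger.warning("dropping %d constant module members", len(constant))
        module_expr = module_expr.drop(columns=constant)
    if module_expr.shape[1] < 2:
        raise ValueError("fewer than 2 non-constant module members")

    z = (module_expr - module_expr.mean(axis=0)) / module_expr.std(
        axis=0, ddof=0
    )
    if not np.isfinite(z.to_numpy()).all() or (
        np.allclose(z.to_numpy(), z.to_numpy()[0])
    ):
        raise ValueError("degenerate split: all patients identical")

    lk = linkage(z.to_numpy(), method="ward", metric="euclidean")
    labels = fcluster(lk, t=2, criterion="maxclust")
    assign = pd.Series(labels, index=module_expr.index)
    if assign.nunique() < 2:
        raise ValueError("degenerate split: clustering produced one group")

    surv = survival.reindex(module_expr.index)
    curves = {}
    for lab in (1, 2):
        sub = surv[assign == lab].dropna(subset=["time"])
        if len(sub):
            curves[lab] = kaplan_meier(sub["time"], sub["event"].astype(bool))
    if len(curves) == 2:
        t_common = min(
            surv[assign == lab]["time"].max() for lab in (1, 2)
        )
        s1 = survival_at(curves[1], t_common)
        s2 = survival_at(curves[2], t_common)
        high_label = 1 if s1 < s2 else 2
    else:  # no usable survival for one group: larger mean z is "high"
        high_label = int(z.groupby(assign).mean().mean(axis=1).idxmax())

    return assign.map(lambda l: "high" if l == high_label else "low")
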