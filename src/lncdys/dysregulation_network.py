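"""Dysregulation classification and network-level summaries.

Contrasting one condition's co-expressed pair set against the other's
partitions every (lncRNA, PCG) key in their union into:

* Type I   — present in normal, absent in cancer (lost co-expression);
* Type II  — absent in normal, present in cancer (gained co-expression);
* Type III — positive in normal, negative in cancer (sign flip);
* Type IV  — negative in normal, positive in cancer (sign flip);
* retained — present with the same sign in both conditions (not
  dysregulated, not emitted).

Summaries mirror the per-universe accounting of the source tables:
pair / distinct-lncRNA / distinct-PCG counts per condition and per type,
the cancer:normal pair ratio and the dysregulated fraction of the union,
plus descriptive scale-free diagnostics of the resulting network.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import networkx as nx
import numpy as np
import pandas as pd

DYS_COLUMNS = ["lnc_id", "pcg_id", "type", "normal_state", "cancer_state"]


def percent(numerator: float, denominator: float) -> float | None:
    """Percentage rounded half-up to 2 decimals; None when undefined."""
    if denominator == 0:
        return None
    pct = Decimal(numerator) / Decimal(denominator) * 100
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _state_map(pairs: pd.DataFrame) -> pd.Series:
    """(lnc, pcg) -> sign for one condition's pair set."""
    if len(pairs) == 0:
        empty = pd.MultiIndex.from_arrays([[], []], names=["lnc_id", "pcg_id"])
        return pd.Series(dtype=object, index=empty)
    return pd.Series(
        pairs["sign"].to_numpy(),
        index=pd.MultiIndex.from_frame(pairs[["lnc_id", "pcg_id"]]),
    )


def classify_dysregulation(
    normal_pairs: pd.DataFrame, cancer_pairs: pd.DataFrame
) -> pd.DataFrame:
    """Assign each dysregulated (lnc, pcg) key exactly one of Types I-IV.

    Same-sign retained pairs are excluded. Returns a DataFrame with
    columns (lnc_id, pcg_id, type, normal_state, cancer_state).
    """
    nm = _state_map(normal_pairs)
    cm = _state_map(cancer_pairs)
    keys = nm.index.union(cm.index)
    ns = nm.reindex(keys).fillna("absent")
    cs = cm.reindex(keys).fillna("absent")

    typ = pd.Series("", index=keys, dtype=object)
    typ[(ns != "absent") & (cs == "absent")] = "I"
    typ[(ns == "absent") & (cs != "absent")] = "II"
    typ[(ns == "positive") & (cs == "negative")] = "III"
    typ[(ns == "negative") & (cs == "positive")] = "IV"
    dys = typ != ""

    out = pd.DataFrame(
        {
            "lnc_id": keys.get_level_values(0)[dys],
            "pcg_id": keys.get_level_values(1)[dys],
            "type": typ[dys].to_numpy(),
            "normal_state": ns[dys].to_numpy(),
            "cancer_state": cs[dys].to_numpy(),
        }
    )
    return out.sort_values(["lnc_id", "pcg_id"], ignore_index=True)


def summarize_network(
    normal_pairs: pd.DataFrame,
    cancer_pairs: pd.DataFrame,
    dysregulated: pd.DataFrame,
    level_label: str,
) -> dict:
    """Per-universe counts plus the derived percentages.

    ``cancer_vs_normal_pct`` is the cancer pair count as a percentage of
    the normal pair count; ``dysregulated_pct`` is the dysregulated pair
    count as a percentage of the union of both conditions' pair keys.
    Undefined ratios (zero denominator) are reported as None.
    """
    n_normal = len(normal_pairs)
    n_cancer = len(cancer_pairs)
    keys_n = set(map(tuple, normal_pairs[["lnc_id", "pcg_id"]].to_numpy()))
    keys_c = set(map(tuple, cancer_pairs[["lnc_id", "pcg_id"]].to_numpy()))
    total = len(keys_n | keys_c)
    n_dys = len(dysregulated)

    by_type = {}
    for t in ("I", "II", "III", "IV"):
        sub = dysregulated[dysregulated["type"] == t]
        by_type[t] = {
            "pairs": len(sub),
            "lncRNAs": sub["lnc_id"].nunique(),
            "PCGs": sub["pcg_id"].nunique(),
        }

    return {
        "level": level_label,
        "normal_pairs": n_normal,
        "cancer_pairs": n_cancer,
        "total_pairs": total,
        "retained_pairs": total - n_dys,
        "dysregulated_pairs": n_dys,
        "dysregulated_lncRNAs": dysregulated["lnc_id"].nunique(),
        "dysregulated_PCGs": dysregulated["pcg_id"].nunique(),
        "cancer_vs_normal_pct": percent(n_cancer, n_normal),
        "dysregulated_pct": percent(n_dys, total),
        "by_type": by_type,
    }


def build_graph(pairs: pd.DataFrame) -> nx.Graph:
    """Bipartite lncRNA-PCG graph from a pair table.

    Edge attributes carry the pair type (if present) and weight = |r| of
    the defining condition when an ``r`` column exists, else 1.
    """
    g = nx.Graph()
    for row in pairs.itertuples(index=False):
        attrs = {}
        if hasattr(row, "type"):
            attrs["type"] = row.type
        attrs["weight"] = abs(getattr(row, "r", 1.0))
        g.add_node(row.lnc_id, role="lncRNA")
        g.add_node(row.pcg_id, role="PCG")
        g.add_edge(row.lnc_id, row.pcg_id, **attrs)
    return g


def degree_distribution(pairs: pd.DataFrame | nx.Graph) -> dict[int, int]:
    """Degree histogram over all nodes (lncRNA and PCG together)."""
    g = pairs if isinstance(pairs, nx.Graph) else build_graph(pairs)
    if g.number_of_edges() == 0:
        raise ValueError("empty edge set")
    hist: dict[int, int] = {}
    for _, k in g.degree():
        hist[k] = hist.get(k, 0) + 1
    return dict(sorted(hist.items()))


def fit_power_law(hist: dict[int, int]) -> tuple[float, float]:
    """OLS fit of log10 count(k) on log10 k over nonzero-degree bins.

    Returns (exponent, r_squared) where exponent is the negated slope, so
    a count(k) ~ k^-g law yields exponent ~ g.
    """
    ks = np.array([k for k, c in hist.items() if k > 0 and c > 0], dtype=float)
    cs = np.array([c for k, c in hist.items() if k > 0 and c > 0], dtype=float)
    if ks.size < 3:
        raise ValueError("need at least 3 distinct nonzero-degree bins")
    x = np.log10(ks)
    y = np.log10(cs)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum(resid**2) / ss_tot
    return float(-slope), float(r2)


def write_dysregulated(dys: pd.DataFrame, path) -> None:
    dys.to_csv(path, sep="\t", index=False)


def write_sif(pairs: pd.DataFrame, path) -> None:
    """Simple interaction format: lnc <relation> pcg per line."""
    with open(path, "w") as fh:
        for row in pairs.itertuples(index=False):
            rel = getattr(row, "type", "coexp")
            fh.write(f"{row.lnc_id}\t{rel}\t{row.pcg_id}\n")


def write_graphml(pairs: pd.DataFrame, path) -> None:
    nx.write_graphml(build_graph(pairs), path)
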