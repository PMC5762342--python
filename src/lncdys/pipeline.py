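"""End-to-end orchestration: load/simulate -> DE -> pairs -> network ->
modules -> risk groups -> panel, with a reproducible manifest.

All analysis thresholds live in :class:`PipelineConfig` (none are
hard-coded in the stages) and every random choice flows from one seed, so
re-running an identical config is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomarker_panel import PanelMarker, build_panel, marker_roc
from .coexpression import call_pairs, summarize_pairs, write_pairs
from .differential_expression import (
    DiffThresholds,
    call_differential,
    significant_genes,
)
from .dysregulation_network import (
    build_graph,
    classify_dysregulation,
    summarize_network,
    write_dysregulated,
    write_graphml,
    write_sif,
)
from .expression_data import classify_genes, load_annotation, load_expression
from .module_mining import mine_modules, module_membership
from .survival_risk import log_rank_test, risk_split
from .synthetic_cohort import CohortSpec, generate_cohort, write_truth

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    zero_ratio: float = 0.30
    fisher_fdr: float = 0.01
    t_fdr: float = 0.05
    fc: float = 2.0
    pcc: float = 0.7
    pcc_p: float = 0.001
    lambda_param: float = 1.0
    size_min: int = 3
    roc_ci: float = 0.95


@dataclass
class PipelineConfig:
    outdir: str = "lncdys_out"
    seed: int = 0
    log_level: str = "INFO"
    thresholds: Thresholds = field(default_factory=Thresholds)
    # exactly one of (paths, synthetic) must be set
    paths: dict | None = None       # matrix, annotation, groups, [survival],
                                    # [cancer_genes]
    synthetic: dict | None = None   # CohortSpec keyword overrides

    def __post_init__(self):
        if (self.paths is None) == (self.synthetic is None):
            raise ValueError(
                "config must set exactly one of 'paths' and 'synthetic'"
            )


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    thr = Thresholds(**raw.pop("thresholds", {}))
    return PipelineConfig(thresholds=thr, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk).

    Stage failures abort with a stage-named error; outputs written up to
    that point are renamed with a ``.partial`` suffix.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    stage = "input"
    try:
        survival = None
        cancer_genes = None
        truth = None
        if config.synthetic is not None:
            spec = CohortSpec(**{**config.synthetic, "seed": config.seed})
            matrix, annotation, survival, truth = generate_cohort(spec)
            write_truth(truth, outdir)
            written += [
                outdir / n
                for n in ("truth_de.tsv", "truth_pairs.tsv", "truth_risk.tsv")
            ]
        else:
            p = config.paths
            matrix = load_expression(p["matrix"], p["annotation"], p["groups"])
            annotation = load_annotation(p["annotation"])
            if p.get("survival"):
                survival = pd.read_csv(
                    p["survival"], sep="\t", index_col="patient_id"
                )
            if p.get("cancer_genes"):
                cancer_genes = set(
                    Path(p["cancer_genes"]).read_text().split()
                )

        stage = "classify_genes"
        classes = classify_genes(annotation)

        stage = "call_differential"
        diff = call_differential(
            matrix,
            classes,
            DiffThresholds(
                zero_fraction=thr.zero_ratio,
                fisher_fdr=thr.fisher_fdr,
                ttest_fdr=thr.t_fdr,
                fc=thr.fc,
            ),
        )
        emit("differential_expression.tsv", lambda p: diff.to_csv(p, sep="\t"))

        de_lnc = [g for g in significant_genes(diff, "lncRNA")]
        de_pcg = [g for g in significant_genes(diff, "PCG")]
        all_pcg = list(classes[classes == "PCG"].index)
        universes = {"AllPCG": all_pcg, "DiffPCG": de_pcg}
        if cancer_genes is not None:
            universes["CancerG"] = [g for g in de_pcg if g in cancer_genes]

        stage = "call_pairs"
        pair_sets: dict[str, dict[str, pd.DataFrame]] = {}
        for level, pcg_ids in universes.items():
            pair_sets[level] = {}
            for condition in ("normal", "cancer"):
                vals = matrix.condition_values(condition)
                pairs = call_pairs(
                    vals.loc[[g for g in de_lnc if g in vals.index]],
                    vals.loc[[g for g in pcg_ids if g in vals.index]],
                    condition,
                    r_min=thr.pcc,
                    p_max=thr.pcc_p,
                )
                pair_sets[level][condition] = pairs
                emit(
                    f"pairs_{level}_{condition}.tsv",
                    lambda p, pairs=pairs: write_pairs(pairs, p),
                )

        stage = "classify_dysregulation"
        summaries = []
        dysregulated = {}
        for level, sets in pair_sets.items():
            dys = classify_dysregulation(sets["normal"], sets["cancer"])
            dysregulated[level] = dys
            emit(
                f"dysregulated_{level}.tsv",
                lambda p, dys=dys: write_dysregulated(dys, p),
            )
            summaries.append(
                summarize_network(sets["normal"], sets["cancer"], dys, level)
            )
        emit(
            "network_summary.json",
            lambda p: p.write_text(json.dumps(summaries, indent=2)),
        )
        focus_level = "CancerG" if "CancerG" in dysregulated else "DiffPCG"
        focus = dysregulated[focus_level]
        if len(focus):
            emit("network.sif", lambda p: write_sif(focus, p))
            emit("network.graphml", lambda p: write_graphml(focus, p))

        stage = "mine_modules"
        # edge weight = |r| in the defining condition of each pair
        focus_w = focus.copy()
        if len(focus_w):
            r_lookup = {}
            for cond in ("normal", "cancer"):
                for row in pair_sets[focus_level][cond].itertuples(False):
                    r_lookup[(row.lnc_id, row.pcg_id, cond)] = abs(row.r)
            focus_w["r"] = [
                r_lookup.get(
                    (t.lnc_id, t.pcg_id,
                     "normal" if t.type in ("I",) else "cancer"),
                    r_lookup.get((t.lnc_id, t.pcg_id, "normal"), 1.0),
                )
                for t in focus_w.itertuples(False)
            ]
        graph = build_graph(focus_w) if len(focus_w) else None
        modules = (
            mine_modules(graph, thr.lambda_param, thr.size_min)
            if graph is not None
            else []
        )
        roles = dict(classes.map({"PCG": "PCG", "lncRNA": "lncRNA"}))
        rows = module_membership(modules, roles)
        emit(
            "modules.tsv",
            lambda p: pd.DataFrame(
                rows, columns=["module_id", "gene_id", "role"]
            ).to_csv(p, sep="\t", index=False),
        )

        # each sub-module is tested for survival separation; the one with
        # the strongest log-rank split carries forward to the panel stage
        risk = None
        risk_module = None
        logrank = None
        per_module = []
        if survival is not None and modules:
            stage = "risk_split"
            patients = [s for s in matrix.samples_in("cancer")
                        if s in survival.index]
            for mod in modules:
                members = sorted(mod.nodes)
                module_expr = np.log2(
                    matrix.values.loc[members, patients].T + 1.0
                )
                try:
                    assign = risk_split(module_expr, survival.loc[patients])
                    chi2, pval = log_rank_test(
                        survival.loc[assign[assign == "high"].index],
                        survival.loc[assign[assign == "low"].index],
                    )
                except ValueError as err:
                    logger.warning(
                        "module %d not risk-splittable: %s", mod.module_id, err
                    )
                    continue
                per_module.append(
                    {"module_id": mod.module_id, "chi2": chi2, "p": pval}
                )
                if logrank is None or pval < logrank["p"]:
                    risk, risk_module, logrank = assign, mod, per_module[-1]
            if risk is not None:
                emit(
                    "risk_groups.tsv",
                    lambda p: risk.rename("risk_group").to_csv(p, sep="\t"),
                )
        elif survival is None:
            logger.info("no survival data: risk and panel stages skipped")

        panel = []
        if risk is not None:
            stage = "build_panel"
            markers = sorted(risk_module.nodes)
            normal_s = matrix.samples_in("normal")
            low_s = list(risk[risk == "low"].index)
            high_s = list(risk[risk == "high"].index)
            panel = build_panel(
                matrix.values.loc[markers], normal_s, low_s, high_s
            )
            emit(
                "panel.tsv",
                lambda p: pd.DataFrame(
                    [dataclasses.asdict(m) for m in panel]
                ).to_csv(p, sep="\t", index=False),
            )

        stage = "manifest"
        manifest = {
            "lncdys_version": __version__,
            "seed": config.seed,
            "config": {
                "thresholds": dataclasses.asdict(thr),
                "synthetic": config.synthetic,
                "paths": config.paths,
            },
            "n_de_lncRNA": len(de_lnc),
            "n_de_PCG": len(de_pcg),
            "levels": {lvl: s for lvl, s in zip(pair_sets, summaries)},
            "n_modules": len(modules),
            "logrank_per_module": per_module,
            "logrank": logrank,
            "panel_size": len(panel),
            "outputs": {
                str(p.name): _sha256(p) for p in sorted(written)
            },
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except Exception as exc:
        for p in written:
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def apply_panel(panel_path: str | Path, rpkm_path: str | Path) -> pd.DataFrame:
    """Classify new samples with a saved panel TSV."""
    from .biomarker_panel import classify_sample

    panel_df = pd.read_csv(panel_path, sep="\t")
    panel = [
        PanelMarker(
            str(r.gene_id), r.direction, float(r.low_cutoff),
            float(r.high_cutoff),
        )
        for r in panel_df.itertuples(False)
    ]
    rpkm = pd.read_csv(rpkm_path, sep="\t", index_col=0)
    rows = []
    for sample in rpkm.columns:
        res = classify_sample(panel, rpkm[sample].to_dict())
        rows.append({"sample_id": sample, "call": res["call"], **res["zones"]})
    return pd.DataFrame(rows).set_index("sample_id")
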