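"""TCGA-like synthetic cohorts with planted ground truth.

The generator emulates the structure a bulk RNA-seq cancer/normal cohort
needs for every pipeline stage to be testable offline:

* two sample groups (default 505 cancer / 59 normal);
* lncRNAs expressed at much lower abundance than protein-coding genes,
  with zero-inflation from an expression-dependent dropout
  p(count -> 0) = exp(-RPKM / tau), so that lncRNA zero fractions
  straddle the 30% test-switch rule and both test branches run;
* planted differentially expressed genes with ratio fold changes;
* condition-specific latent-factor co-expression blocks: a block active
  in normal only plants Type I (lost) pairs, active in cancer only plants
  Type II (gained) pairs, and sign-flipped PCG loadings across conditions
  plant Type III/IV pairs. Member signal is z = loading * F + noise_sd * e
  on the log scale, giving an expected pair correlation of
  loading^2 / (loading^2 + noise_sd^2) (0.9 at the 0.9/0.3 defaults);
* survival times for cancer patients whose hazard is exponential in a
  bimodal risk-module score (the cancer-active block's factor), with a
  Bernoulli-controlled censoring rate.

Counts are Poisson around expression x transcript-length x library-depth;
RPKM is recomputed from the (dropout-thinned) counts so zeros agree
between the two representations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_data import ExpressionMatrix, compute_rpkm


@dataclass(frozen=True)
class FactorBlock:
    """A planted co-expression block driven by one latent factor."""

    name: str
    n_lnc: int
    n_pcg: int
    #: "normal" / "cancer" -> block active in one condition only
    #: (Type I / Type II); "flip_neg" / "flip_pos" -> active in both with
    #: PCG loadings negated in cancer / in normal (Type III / Type IV).
    kind: str
    loading: float = 0.9
    noise_sd: float = 0.3
    #: per-member log2 spread; None -> the cohort-wide default. Negative
    #: correlations attenuate on the linear RPKM scale under a lognormal
    #: model, so sign-flip blocks need a tighter spread to keep planted
    #: |r| above the calling cutoff.
    log2_sd: float | None = None

    @property
    def expected_type(self) -> str:
        return {"normal": "I", "cancer": "II", "flip_neg": "III",
                "flip_pos": "IV"}[self.kind]


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_cancer: int = 505
    n_normal: int = 59
    n_pcg: int = 1000
    n_lnc: int = 500
    n_other: int = 20  # small-RNA biotypes, exercise the exclusion rule
    lnc_abundance_ratio: float = 0.1
    log2_sd: float = 0.8          # per-gene biological spread, log2 units
    dropout_tau: float = 2.0      # RPKM scale of the dropout curve
    de_fc: float = 4.0
    n_de_pcg_up: int = 50
    n_de_pcg_down: int = 50
    n_de_lnc_up: int = 40
    n_de_lnc_down: int = 40
    blocks: tuple[FactorBlock, ...] = (
        FactorBlock("lost", n_lnc=8, n_pcg=10, kind="normal"),
        FactorBlock("gained", n_lnc=6, n_pcg=8, kind="cancer"),
        FactorBlock("flip_neg", n_lnc=3, n_pcg=3, kind="flip_neg",
                    log2_sd=0.4),
        FactorBlock("flip_pos", n_lnc=3, n_pcg=3, kind="flip_pos",
                    log2_sd=0.4),
    )
    risk_block: str = "gained"    # cancer-active block scoring the hazard
    hazard_beta: float = float(np.log(2) / 2)  # log HR per unit risk score
    baseline_hazard: float = 1.0 / 1500.0      # events per day
    censoring_rate: float = 0.6
    mean_library_size: float = 2e7
    seed: int = 0


@dataclass
class CohortTruth:
    """Planted ground truth aligned with one generated cohort."""

    de: pd.DataFrame          # gene_id-indexed: direction, fc
    pairs: pd.DataFrame       # lnc_id, pcg_id, block, expected type
    risk: pd.Series           # cancer patient -> "high" / "low"
    risk_score: pd.Series     # cancer patient -> latent module score
    block_members: dict       # block name -> (lnc ids, pcg ids)


def _gene_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(n)]


def generate_cohort(
    spec: CohortSpec,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Generate (expression, annotation, survival, truth) for one spec."""
    rng = np.random.default_rng(spec.seed)

    tot_block_lnc = sum(b.n_lnc for b in spec.blocks)
    tot_block_pcg = sum(b.n_pcg for b in spec.blocks)
    if tot_block_lnc > spec.n_lnc or tot_block_pcg > spec.n_pcg:
        raise ValueError("planted blocks larger than the gene universe")
    if spec.blocks and not any(
        b.name == spec.risk_block for b in spec.blocks
    ):
        raise ValueError(f"risk_block {spec.risk_block!r} not among blocks")

    pcgs = _gene_ids("PCG", spec.n_pcg)
    lncs = _gene_ids("LNC", spec.n_lnc)
    others = _gene_ids("SML", spec.n_other)
    genes = pcgs + lncs + others

    cancer = [f"TCGA-C{i:04d}" for i in range(spec.n_cancer)]
    normal = [f"TCGA-N{i:04d}" for i in range(spec.n_normal)]
    samples = cancer + normal
    n_samples = len(samples)

    # --- annotation -------------------------------------------------------
    lnc_biotypes = rng.choice(
        ["lincRNA", "antisense", "processed_transcript"], size=spec.n_lnc
    )
    other_biotypes = rng.choice(
        ["miRNA", "snoRNA", "rRNA", "tRNA", "snRNA"], size=spec.n_other
    )
    annotation = pd.DataFrame(
        {
            "biotype": ["protein_coding"] * spec.n_pcg
            + list(lnc_biotypes)
            + list(other_biotypes),
            "length": np.r_[
                np.round(rng.lognormal(np.log(2200), 0.5, spec.n_pcg)),
                np.round(rng.lognormal(np.log(1000), 0.6, spec.n_lnc)),
                rng.integers(60, 180, spec.n_other),
            ].astype(int).clip(min=60),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    # keep lncRNA lengths above the 200 nt rule so classing matches intent
    lnc_len = annotation.loc[lncs, "length"]
    annotation.loc[lncs, "length"] = lnc_len.clip(lower=201)

    # --- baseline abundance ----------------------------------------------
    base_log2 = pd.Series(0.0, index=genes)
    base_log2[pcgs] = rng.normal(5.0, 2.0, spec.n_pcg)
    base_log2[lncs] = rng.normal(
        5.0 + np.log2(spec.lnc_abundance_ratio), 2.0, spec.n_lnc
    )
    base_log2[others] = rng.normal(2.0, 1.5, spec.n_other)

    # --- planted block membership (block genes get dropout-safe abundance)
    block_members: dict[str, tuple[list[str], list[str]]] = {}
    li, pi = 0, 0
    for b in spec.blocks:
        bl = lncs[li : li + b.n_lnc]
        bp = pcgs[pi : pi + b.n_pcg]
        li += b.n_lnc
        pi += b.n_pcg
        block_members[b.name] = (bl, bp)
        base_log2[bl] = rng.uniform(3.0, 5.0, b.n_lnc)
        base_log2[bp] = rng.uniform(5.0, 8.0, b.n_pcg)

    # --- planted differential expression ---------------------------------
    free_pcg = pcgs[pi:]
    free_lnc = lncs[li:]
    de_rows = []
    shift = np.log2(spec.de_fc)
    de_log2 = pd.Series(0.0, index=genes)

    def plant(ids, direction):
        for g in ids:
            de_log2[g] = shift if direction == "up_in_cancer" else -shift
            de_rows.append((g, direction, spec.de_fc))

    plant(free_pcg[: spec.n_de_pcg_up], "up_in_cancer")
    plant(
        free_pcg[spec.n_de_pcg_up : spec.n_de_pcg_up + spec.n_de_pcg_down],
        "down_in_cancer",
    )
    plant(free_lnc[: spec.n_de_lnc_up], "up_in_cancer")
    plant(
        free_lnc[spec.n_de_lnc_up : spec.n_de_lnc_up + spec.n_de_lnc_down],
        "down_in_cancer",
    )
    # block members are planted up-regulated so they survive the DE
    # restrictions of the co-expression universes (DE lncRNAs x DE PCGs)
    for b in spec.blocks:
        plant(block_members[b.name][0], "up_in_cancer")
        plant(block_members[b.name][1], "up_in_cancer")
    de_truth = pd.DataFrame(
        de_rows, columns=["gene_id", "direction", "fc"]
    ).set_index("gene_id")

    # --- latent signal ----------------------------------------------------
    is_cancer = np.array([True] * spec.n_cancer + [False] * spec.n_normal)
    z = rng.normal(0.0, 1.0, size=(len(genes), n_samples))
    z_df = pd.DataFrame(z, index=genes, columns=samples)

    # bimodal risk score for cancer patients drives the risk block
    risk_label = rng.random(spec.n_cancer) < 0.5
    risk_score = np.where(risk_label, 1.0, -1.0) + rng.normal(
        0.0, 0.35, spec.n_cancer
    )

    pair_rows = []
    for b in spec.blocks:
        bl, bp = block_members[b.name]
        members = bl + bp
        norm = np.sqrt(b.loading**2 + b.noise_sd**2)
        for cond, active_mask in (("cancer", is_cancer), ("normal", ~is_cancer)):
            if b.kind in ("normal", "cancer") and cond != b.kind:
                continue  # inactive condition keeps independent noise
            n_active = int(active_mask.sum())
            if b.name == spec.risk_block and cond == "cancer":
                factor = risk_score / np.sqrt(
                    np.var(risk_score)
                )  # standardized bimodal factor
            else:
                factor = rng.normal(0.0, 1.0, n_active)
            eps = rng.normal(0.0, 1.0, size=(len(members), n_active))
            sig = (b.loading * factor[None, :] + b.noise_sd * eps) / norm
            # sign-flip blocks negate PCG loadings in one condition
            if (b.kind == "flip_neg" and cond == "cancer") or (
                b.kind == "flip_pos" and cond == "normal"
            ):
                pcg_sel = [members.index(g) for g in bp]
                sig[pcg_sel] = (
                    -b.loading * factor[None, :]
                    + b.noise_sd * eps[pcg_sel]
                ) / norm
            z_df.loc[members, np.array(samples)[active_mask]] = sig
        for l in bl:
            for p in bp:
                pair_rows.append((l, p, b.name, b.expected_type))
    pair_truth = pd.DataFrame(
        pair_rows, columns=["lnc_id", "pcg_id", "block", "type"]
    )

    # --- expression, counts, dropout -------------------------------------
    log2_scale = pd.Series(spec.log2_sd, index=genes)
    for b in spec.blocks:
        if b.log2_sd is not None:
            bl, bp = block_members[b.name]
            log2_scale[bl + bp] = b.log2_sd
    log2x = (
        base_log2.to_numpy()[:, None]
        + de_log2.to_numpy()[:, None] * is_cancer[None, :]
        + log2_scale.to_numpy()[:, None] * z_df.to_numpy()
    )
    x = np.power(2.0, log2x)  # true RPKM-scale expression

    lib = spec.mean_library_size * rng.lognormal(0.0, 0.15, n_samples)
    lengths = annotation["length"].to_numpy(dtype=float)
    lam = x * (lengths[:, None] / 1e3) * (lib[None, :] / 1e6)
    counts = rng.poisson(lam).astype(float)
    dropout = rng.random(counts.shape) < np.exp(-x / spec.dropout_tau)
    counts[dropout] = 0.0

    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    rpkm = compute_rpkm(
        counts_df,
        annotation["length"],
        pd.Series(lib, index=samples),
    )
    group = pd.Series(
        np.where(is_cancer, "cancer", "normal"), index=samples
    )
    matrix = ExpressionMatrix(values=rpkm, group=group, counts=counts_df)

    # --- survival ---------------------------------------------------------
    std_score = risk_score / np.sqrt(np.var(risk_score))
    hazard = spec.baseline_hazard * np.exp(spec.hazard_beta * risk_score)
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(spec.n_cancer) < spec.censoring_rate
    t_obs = np.where(censored, rng.uniform(0.0, t_event), t_event)
    survival = pd.DataFrame(
        {
            "time": t_obs,
            "event": ~censored,
        },
        index=pd.Index(cancer, name="patient_id"),
    )

    truth = CohortTruth(
        de=de_truth,
        pairs=pair_truth,
        risk=pd.Series(
            np.where(risk_label, "high", "low"), index=cancer
        ),
        risk_score=pd.Series(std_score, index=cancer),
        block_members=block_members,
    )
    return matrix, annotation, survival, truth


def evaluate_recovery(called, truth) -> dict:
    """Precision / recall of a called identifier set against a truth set.

    Both arguments are iterables of hashable identifiers (gene ids,
    (lnc, pcg) tuples, (patient, label) tuples ...). Precision is None
    (NA) when nothing was called; recall is None when the truth is empty.
    """
    called = set(called)
    truth = set(truth)
    tp = len(called & truth)
    return {
        "n_called": len(called),
        "n_truth": len(truth),
        "tp": tp,
        "precision": tp / len(called) if called else None,
        "recall": tp / len(truth) if truth else None,
    }


def write_truth(truth: CohortTruth, directory) -> None:
    """Dump truth tables as TSVs next to the generated cohort."""
    from pathlib import Path

    d = Path(directory)
    truth.de.to_csv(d / "truth_de.tsv", sep="\t")
    truth.pairs.to_csv(d / "truth_pairs.tsv", sep="\t", index=False)
    truth.risk.rename("risk").to_csv(d / "truth_risk.tsv", sep="\t")
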