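"""End-to-end orchestration of the ICI-score workflow.

Stage order: preprocess (batch correction) -> deconvolution -> immune/stroma
scores -> consensus clustering of the TME features (ICI subtypes) -> DEGs
between subtypes -> consensus clustering on DEG expression (gene clusters) ->
Pearson-sign signature partitioning -> Boruta reduction -> ICI score ->
survival / mutation-burden comparisons. Every stage output is persisted and a
JSON run manifest records the configuration snapshot, derived seeds, and
output hashes, so identical manifests reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as iio
from .clustering import consensus_cluster
from .deconvolution import deconvolve, select_signature_genes
from .enrichment import estimate_scores
from .io import ClinicalTable, ExpressionMatrix, GeneSetCollection, MutationTable, SignatureMatrix
from .preprocess import combat_correct
from .signatures import (
    SignatureSet,
    boruta_reduce,
    encode_cluster_signature,
    find_degs,
    ici_score,
    partition_signatures,
    significant_genes,
)
from .simulate import SyntheticCohortSpec, simulate_cohort
from .survival import (
    gene_mutation_contrast,
    kaplan_meier,
    pearson,
    rank_tests,
    response_rate_compare,
    stratified_km,
    tmb_and_split,
)

log = logging.getLogger("icipattern")

STAGES = (
    "preprocess",
    "deconvolution",
    "estimate",
    "ici_subtypes",
    "degs",
    "gene_clusters",
    "signatures",
    "boruta",
    "ici_score",
    "survival",
)


@dataclass
class PipelineConfig:
    """Flat pipeline configuration. Every published threshold is a key with
    the study's value as its default."""

    # inputs: either file paths or a synthetic spec
    expression_path: str | None = None
    clinical_path: str | None = None
    mutation_path: str | None = None
    signature_path: str | None = None
    expression_unit: str = "log2TPM1"
    synthetic: dict | None = None

    # stage parameters
    subsample_fraction: float = 0.9
    ici_cluster_reps: int = 1000
    gene_cluster_reps: int = 500
    ici_cluster_distance: str = "euclidean"
    ici_cluster_method: str = "pam"
    gene_cluster_distance: str = "spearman"
    gene_cluster_method: str = "pam"
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    delta_threshold: float = 0.1
    fc_cutoff: float = 1.65
    deg_alpha: float = 0.05
    boruta_max_iter: int = 100
    boruta_alpha: float = 0.05
    boruta_trees: int = 100
    max_signature_genes: int = 400
    ssgsea_alpha: float = 0.25
    score_normalize: bool = False
    cluster_signature_scheme: str = "ordinal"
    deconv_method: str = "svr"
    nu_grid: tuple[float, ...] = (0.25, 0.5, 0.75)
    signature_top_n: int = 150
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        if self.synthetic is None:
            if self.expression_path is None:
                raise ValueError("config needs expression_path or a synthetic section")
            if self.clinical_path is None:
                raise ValueError("config needs clinical_path (survival outcomes)")
            if self.signature_path is None:
                raise ValueError("config needs signature_path (cell-type reference)")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(STAGES, children)
    }


@dataclass
class PipelineResult:
    config: PipelineConfig
    manifest: dict
    expression: ExpressionMatrix
    fractions: pd.DataFrame
    tme_scores: pd.DataFrame
    ici_subtype: pd.Series
    degs: pd.DataFrame
    deg_genes: list[str]
    gene_cluster: pd.Series
    signature_set: SignatureSet
    score_table: pd.DataFrame
    stats: dict = field(default_factory=dict)


def _load_inputs(cfg: PipelineConfig):
    if cfg.synthetic is not None:
        spec_kwargs = dict(cfg.synthetic)
        spec_kwargs.setdefault("seed", cfg.seed)
        spec = SyntheticCohortSpec(**spec_kwargs)
        cohort = simulate_cohort(spec)
        immune_set = cohort.truth["immune_set"]
        stromal_set = cohort.truth["stromal_set"]
        return cohort.expression, cohort.clinical, cohort.mutations, cohort.signature, immune_set, stromal_set
    expr = iio.read_expression(cfg.expression_path, unit=cfg.expression_unit)
    clin = iio.read_clinical(cfg.clinical_path)
    mut = iio.read_mutations(cfg.mutation_path) if cfg.mutation_path else None
    sig = iio.read_signature_matrix(cfg.signature_path)
    # immune/stroma sets default to signature markers when not user-supplied
    arr = sig.values.to_numpy()
    cut = np.quantile(arr, 0.9)
    markers = {
        t: [sig.genes[i] for i in np.flatnonzero(arr[:, t] >= cut)] for t in range(arr.shape[1])
    }
    k = arr.shape[1]
    immune_set = [g for t in range(k - 1) for g in markers[t]] or sig.genes[: max(2, len(sig.genes) // 10)]
    stromal_set = markers[k - 1] or sig.genes[-max(2, len(sig.genes) // 10):]
    return expr, clin, mut, sig, immune_set, stromal_set


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute the full workflow; see the module docstring for the stage order."""
    cfg.validate()
    t0 = time.time()
    seeds = _stage_seeds(cfg.seed)
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": "0.1.0",
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        "stage_seeds": seeds,
        "outputs": {},
    }

    def persist(name: str, df: pd.DataFrame) -> None:
        if outdir is None:
            return
        path = outdir / name
        df.to_csv(path, sep="\t", float_format="%.10g")
        manifest["outputs"][name] = _sha256(path)

    expr, clin, mut, sig, immune_set, stromal_set = _load_inputs(cfg)
    log.info("cohort: %d genes x %d samples", *expr.shape)

    # 1. batch correction on the log scale
    batches = clin.indexed()["batch"]
    corrected, _model = combat_correct(expr, batches)
    persist("expression_corrected.tsv", corrected.values)
    log.info("preprocess done (%.1fs)", time.time() - t0)

    # 2. cell-fraction deconvolution against the discriminative signature rows
    fm = deconvolve(
        corrected,
        select_signature_genes(sig, top_n=cfg.signature_top_n),
        nu_grid=cfg.nu_grid,
        method=cfg.deconv_method,
    )
    persist("fractions.tsv", fm.fractions)

    # 3. immune / stroma scores
    est = estimate_scores(corrected, immune_set, stromal_set)
    tme_scores = est.scores.T  # samples x 2
    persist("tme_scores.tsv", tme_scores)
    log.info("TME quantification done (%.1fs)", time.time() - t0)

    # 4. ICI subtypes: consensus clustering of z-scored fractions + scores
    features = pd.concat([fm.fractions, tme_scores], axis=1).dropna()
    z = (features - features.mean()) / features.std().replace(0, 1.0)
    ici_res = consensus_cluster(
        z,
        k_range=cfg.k_range,
        reps=cfg.ici_cluster_reps,
        subsample_fraction=cfg.subsample_fraction,
        distance=cfg.ici_cluster_distance,
        base_method=cfg.ici_cluster_method,
        delta_threshold=cfg.delta_threshold,
        seed=seeds["ici_subtypes"],
    )
    ici_subtype = ici_res.labels.rename("ici_subtype")
    persist("ici_subtypes.tsv", ici_subtype.to_frame())
    if outdir is not None:
        ici_res.write(outdir / "consensus_ici")
    log.info("ICI subtyping done: k=%d (%.1fs)", ici_res.chosen_k, time.time() - t0)

    # 5. DEGs between ICI subtypes (subtypes too small to contrast are left out
    # of DEG discovery but keep their labels downstream)
    expr_sub = corrected.subset_samples(list(ici_subtype.index))
    sizes = ici_subtype.value_counts()
    big = sizes[sizes >= 3].index
    if len(big) < 2:
        raise RuntimeError("ICI subtyping produced fewer than two usable subtypes")
    deg_labels = ici_subtype[ici_subtype.isin(big)]
    degs = find_degs(
        corrected.subset_samples(list(deg_labels.index)),
        deg_labels,
        fc_cutoff=cfg.fc_cutoff,
        alpha=cfg.deg_alpha,
    )
    deg_genes = significant_genes(degs)
    if len(deg_genes) < 4:
        # fall back to the strongest contrasts so the signature stages stay exercisable
        top = degs.sort_values("adj_p").drop_duplicates("gene").head(20)
        deg_genes = top["gene"].tolist()
        log.warning("few significant DEGs; using top 20 by adjusted p")
    persist("degs.tsv", degs)
    log.info("%d DEGs (%.1fs)", len(deg_genes), time.time() - t0)

    # 6. gene clusters: consensus clustering of samples on DEG expression
    deg_expr = expr_sub.values.loc[deg_genes].T  # samples x DEGs
    gene_res = consensus_cluster(
        deg_expr,
        k_range=cfg.k_range,
        reps=cfg.gene_cluster_reps,
        subsample_fraction=cfg.subsample_fraction,
        distance=cfg.gene_cluster_distance,
        base_method=cfg.gene_cluster_method,
        delta_threshold=cfg.delta_threshold,
        seed=seeds["gene_clusters"],
    )
    gene_cluster = gene_res.labels.rename("gene_cluster")
    persist("gene_clusters.tsv", gene_cluster.to_frame())
    if outdir is not None:
        gene_res.write(outdir / "consensus_genes")
    log.info("gene clusters: k=%d (%.1fs)", gene_res.chosen_k, time.time() - t0)

    # 7. signed signatures from Pearson correlation with the cluster signature
    immune_score = tme_scores["ImmuneScore"].reindex(gene_cluster.index)
    cluster_sig = encode_cluster_signature(gene_cluster, immune_score, cfg.cluster_signature_scheme)
    sigset = partition_signatures(expr_sub, deg_genes, cluster_sig)

    # 8. Boruta reduction against the gene-cluster label; candidates balanced
    # across the two signatures by correlation strength
    half = cfg.max_signature_genes // 2
    by_r = sigset.correlations.abs().sort_values(ascending=False)
    top_a = [g for g in by_r.index if g in set(sigset.genes_a)][:half]
    top_b = [g for g in by_r.index if g in set(sigset.genes_b)][:half]
    candidates = top_a + top_b
    confirmed = boruta_reduce(
        expr_sub,
        candidates,
        gene_cluster,
        max_iter=cfg.boruta_max_iter,
        alpha=cfg.boruta_alpha,
        seed=seeds["boruta"],
        n_estimators=cfg.boruta_trees,
    )
    reduced_a = [g for g in sigset.genes_a if g in confirmed]
    reduced_b = [g for g in sigset.genes_b if g in confirmed]
    # Boruta may empty a side on weak cohorts; scoring then uses the full side
    sigset.reduced_a = reduced_a if reduced_a else None
    sigset.reduced_b = reduced_b if reduced_b else None
    a, b = sigset.active()
    if outdir is not None:
        iio.write_gmt(
            GeneSetCollection({"ICI_signature_A": a, "ICI_signature_B": b}),
            outdir / "signatures.gmt",
        )
        manifest["outputs"]["signatures.gmt"] = _sha256(outdir / "signatures.gmt")
    log.info("signatures: |A|=%d |B|=%d (%.1fs)", len(a), len(b), time.time() - t0)

    # 9. the ICI score and median split
    score = ici_score(expr_sub, sigset, alpha=cfg.ssgsea_alpha, normalize=cfg.score_normalize)
    persist("ici_score.tsv", score.table.set_index("sample_id"))

    # 10. survival + genomics comparisons
    ct = clin.indexed().loc[score.table["sample_id"]]
    groups = score.groups
    km = kaplan_meier(ct["os_time"], ct["os_event"], groups.to_numpy())
    stats_out: dict = {
        "ici_chosen_k": int(ici_res.chosen_k),
        "gene_chosen_k": int(gene_res.chosen_k),
        "n_deg_genes": len(deg_genes),
        "n_signature_a": len(a),
        "n_signature_b": len(b),
        "logrank_high_vs_low": {"statistic": km.statistic, "df": km.df, "p": km.p},
    }
    if mut is not None and len(mut.records):
        ms = tmb_and_split(mut, list(groups.index))
        common = ms.tmb.index
        r, p = pearson(score.scores.reindex(common), ms.tmb)
        stat, wp = rank_tests(ms.tmb.to_numpy(), groups.reindex(common).to_numpy())
        strat = stratified_km(
            ct.loc[common, "os_time"],
            ct.loc[common, "os_event"],
            ms.tmb_group.to_numpy(),
            groups.reindex(common).to_numpy(),
        )
        contrasts = gene_mutation_contrast(mut, groups.reindex(common))
        persist("mutation_contrasts.tsv", contrasts)
        stats_out.update(
            {
                "tmb_ici_pearson": {"r": r, "p": p},
                "tmb_by_ici_ranksum_p": wp,
                "tmb_logrank_p": kaplan_meier(
                    ct.loc[common, "os_time"], ct.loc[common, "os_event"], ms.tmb_group.to_numpy()
                ).p,
                "stratified_logrank_p": strat.overall.p,
                "within_stratum_p": {k: v.p for k, v in strat.within_stratum.items()},
            }
        )
    if "response" in ct.columns and ct["response"].notna().any():
        stats_out["response"] = response_rate_compare(
            ct["response"], groups.reindex(ct.index), score.scores.reindex(ct.index)
        )

    manifest["stats"] = stats_out
    manifest["runtime_s"] = round(time.time() - t0, 2)
    if outdir is not None:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    return PipelineResult(
        config=cfg,
        manifest=manifest,
        expression=corrected,
        fractions=fm.fractions,
        tme_scores=tme_scores,
        ici_subtype=ici_subtype,
        degs=degs,
        deg_genes=deg_genes,
        gene_cluster=gene_cluster,
        signature_set=sigset,
        score_table=score.table,
        stats=stats_out,
    )


def headline_config(
    seed: int,
    n_samples: int = 300,
    hazard_ratios: tuple[float, ...] = (1.0, 1.4, 2.0),
    equal_mutation_rates: bool = False,
) -> PipelineConfig:
    """The default simulation-study configuration: three planted immune groups
    (hot/intermediate/cold) with a 2-fold hazard contrast between hot and cold.

    The stage parameters are scaled down from the cohort-analysis defaults
    (fewer consensus repetitions, smaller Boruta budget) so that many
    replicates can be run; the construction itself is unchanged.
    """
    rates = (10.0, 10.0, 10.0) if equal_mutation_rates else (15.0, 10.0, 5.0)
    return PipelineConfig(
        synthetic={
            "n_samples": n_samples,
            "n_genes": 400,
            "n_cell_types": 5,
            "hazard_ratio_per_group": hazard_ratios,
            "mutation_rate_per_group": rates,
            "seed": seed,
        },
        ici_cluster_reps=40,
        gene_cluster_reps=40,
        boruta_max_iter=20,
        boruta_trees=40,
        max_signature_genes=60,
        signature_top_n=100,
        seed=seed,
    )


def headline_replicate(seed: int, **kwargs) -> dict:
    """Run one simulation replicate of the full pipeline and summarize the
    survival / mutation-burden endpoints."""
    res = run_pipeline(headline_config(seed, **kwargs))
    sc = res.score_table.set_index("sample_id")
    out = {
        "logrank_p": res.stats["logrank_high_vs_low"]["p"],
        "tmb_pearson_r": res.stats.get("tmb_ici_pearson", {}).get("r"),
        "tmb_logrank_p": res.stats.get("tmb_logrank_p"),
        "within_stratum_p": res.stats.get("within_stratum_p", {}),
        "n_signature_a": res.stats["n_signature_a"],
        "n_signature_b": res.stats["n_signature_b"],
    }
    # direction of the survival effect: restricted-mean survival per group
    cfg = res.config
    spec_kwargs = dict(cfg.synthetic)
    spec_kwargs.setdefault("seed", cfg.seed)
    cohort = simulate_cohort(SyntheticCohortSpec(**spec_kwargs))
    ct = cohort.clinical.indexed().loc[sc.index]
    from lifelines.utils import restricted_mean_survival_time
    from lifelines import KaplanMeierFitter

    rmst = {}
    for lv in ("high", "low"):
        mask = (sc["group"] == lv).to_numpy()
        kmf = KaplanMeierFitter().fit(ct["os_time"][mask], ct["os_event"][mask])
        rmst[lv] = float(restricted_mean_survival_time(kmf, t=float(ct["os_time"].max())))
    out["rmst_high"] = rmst["high"]
    out["rmst_low"] = rmst["low"]
    return out


def validate_external_cohort(
    new_expression: ExpressionMatrix,
    signatures: SignatureSet,
    min_overlap: float = 0.5,
    alpha: float = 0.25,
    normalize: bool = False,
):
    """Score a new cohort with frozen signatures (no re-derivation).

    Fails if the cohort shares less than ``min_overlap`` of the signature
    genes; returns the score table and the observed overlap fraction.
    """
    a, b = signatures.active()
    universe = set(new_expression.genes)
    needed = set(a) | set(b)
    overlap = len(needed & universe) / len(needed)
    if not (set(b) & universe) or not (set(a) & universe):
        raise ValueError("validation cohort is missing one signature entirely")
    if overlap < min_overlap:
        raise ValueError(
            f"validation cohort shares only {overlap:.1%} of signature genes "
            f"(minimum {min_overlap:.0%})"
        )
    frozen = SignatureSet(
        genes_a=[g for g in a if g in universe],
        genes_b=[g for g in b if g in universe],
        correlations=signatures.correlations,
    )
    score = ici_score(new_expression, frozen, alpha=alpha, normalize=normalize)
    return score, overlap
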