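"""End-to-end orchestration: classification -> genomic context ->
coexpression features -> essentiality classifier -> network -> group
comparisons, from a single config, into one structured report.

Stages write their TSV outputs before the next stage starts; optional
stages (missing input files) are skipped with a recorded reason rather
than aborting.  Reruns with the same config and seed are byte-identical
apart from timestamps.
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

from . import classify, coexpr, context, enet, groups, io, network
from .stats import TestResult

log = logging.getLogger(__name__)

EXIT_CONFIG_ERROR = 2
EXIT_STAGE_ERROR = 3


@dataclass
class RunConfig:
    """Paths and thresholds of one pipeline run.

    Optional inputs may be None: the corresponding stage is skipped.
    Threshold defaults are the canonical analysis settings (E < 1e-6,
    coverage > 0.30, 5 kb flank, MCL inflation 1.5, clusters > 30 members,
    elastic-net alpha 0.5).
    """

    hits: Path
    lineage: Path
    domains: Path
    essential: Path
    loci: Path
    out_dir: Path
    expr_levels: Path | None = None
    tracks: dict = field(default_factory=dict)  # name -> bedGraph path
    expr_manifest: Path | None = None
    gene_sets: Path | None = None
    edges: Path | None = None
    protein_features: Path | None = None
    rates: Path | None = None

    e_max: float = classify.DEFAULT_E_MAX
    min_cov: float = classify.DEFAULT_MIN_COV
    flank: int = context.DEFAULT_FLANK
    inflation: float = network.DEFAULT_INFLATION
    min_cluster_size: int = network.DEFAULT_MIN_CLUSTER_SIZE
    alpha: float = enet.DEFAULT_ALPHA
    folds: int = enet.DEFAULT_FOLDS
    min_support: int = coexpr.DEFAULT_MIN_SUPPORT
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        cfg = cls.from_dict(raw, base)
        return cfg

    @classmethod
    def from_dict(cls, raw: dict, base: Path = Path(".")) -> "RunConfig":
        def p(key, required=False):
            v = raw.get(key)
            if v is None:
                if required:
                    raise ValueError(f"config missing required path: {key}")
                return None
            return base / v

        tracks = {name: base / v for name, v in (raw.get("tracks") or {}).items()}
        kwargs = dict(
            hits=p("hits", True), lineage=p("lineage", True),
            domains=p("domains", True), essential=p("essential", True),
            loci=p("loci", True), out_dir=base / raw.get("out_dir", "out"),
            expr_levels=p("expr_levels"), tracks=tracks,
            expr_manifest=p("expr_manifest"), gene_sets=p("gene_sets"),
            edges=p("edges"), protein_features=p("protein_features"),
            rates=p("rates"))
        for key in ("e_max", "min_cov", "flank", "inflation",
                    "min_cluster_size", "alpha", "folds", "min_support",
                    "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    @classmethod
    def from_world(cls, world_dir, out_dir=None, **overrides) -> "RunConfig":
        """Point a run at a directory produced by the synthetic generator."""
        w = Path(world_dir)
        kwargs = dict(
            hits=w / "hits.tsv", lineage=w / "lineage.tsv",
            domains=w / "domains.tsv", essential=w / "essential.txt",
            loci=w / "genes.bed",
            out_dir=Path(out_dir) if out_dir else w / "out",
            expr_levels=w / "expr_levels.tsv",
            tracks={"h3k79": w / "h3k79.bedgraph",
                    "h3k27": w / "h3k27.bedgraph"},
            expr_manifest=w / "expr" / "manifest.tsv",
            gene_sets=w / "pathways.gmt", edges=w / "ppi.tsv",
            protein_features=w / "protein_features.tsv",
            rates=w / "rates.tsv")
        kwargs.update(overrides)
        return cls(**kwargs)

    def validate(self) -> None:
        for name in ("hits", "lineage", "domains", "essential", "loci"):
            path = getattr(self, name)
            if path is None or not Path(path).exists():
                raise FileNotFoundError(f"mandatory input missing: {name} "
                                        f"({path})")


def _result_dict(r: TestResult) -> dict:
    return {"statistic": r.statistic, "p_value": r.p_value,
            "method": r.method, "alternative": r.alternative,
            "n1": r.n1, "n2": r.n2, "degenerate": r.degenerate}


def _tests_dict(tests: dict[str, TestResult]) -> dict:
    return {k: _result_dict(v) for k, v in tests.items()}


def _config_hash(cfg: RunConfig) -> str:
    d = dataclasses.asdict(cfg)
    flat = json.dumps({k: str(v) for k, v in d.items()}, sort_keys=True)
    return hashlib.sha256(flat.encode()).hexdigest()[:16]


def run_all(cfg: RunConfig) -> dict:
    """Run every stage in dependency order and write ``report.json``.

    Returns the report dict.  Class counts everywhere in the report come
    from the classification stage (single source of truth).
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "provenance": {
        "config_hash": _config_hash(cfg), "seed": cfg.seed}}

    # -- classification ----------------------------------------------------
    hits = io.read_hits(cfg.hits)
    lineage = io.read_lineage(cfg.lineage)
    domains = io.read_domains(cfg.domains)
    loci = io.read_bed(cfg.loci)
    genes = loci["gene"].tolist()
    conservation = classify.classify_trg(hits, lineage, domains, genes,
                                         cfg.e_max, cfg.min_cov)
    essential = io.read_gene_list(cfg.essential)
    classes = classify.assign_four_classes(conservation, essential)
    io.write_classes(classes, out / "classes.tsv")
    counts = classify.class_counts(classes)
    report["stages"]["classify"] = {
        "status": "ok", "n_genes": len(classes), "class_counts": counts}
    log.info("classify: %d genes -> %s", len(classes), counts)
    trg_genes = classes.loc[classes["conservation"] == "TRG", "gene"].tolist()

    # -- genomic context ---------------------------------------------------
    if cfg.expr_levels and Path(cfg.expr_levels).exists():
        expr = io.read_series(cfg.expr_levels)
        ctx: dict = {"status": "ok"}
        itself_tests, itself_summary = context.context_group_tests(
            expr, classes)
        ctx["gene_itself"] = {"tests": _tests_dict(itself_tests)}
        nb = context.neighbor_expression(loci, expr)
        nb.to_csv(out / "neighbor_expression.tsv", sep="\t", index=False)
        ctx["neighbors"] = {}
        for k, sub in nb.groupby("offset"):
            vals = sub.groupby("gene")["value"].mean()
            tests, _ = context.context_group_tests(vals, classes)
            ctx["neighbors"][f"offset_{k}"] = _tests_dict(tests)
        itself_summary.to_csv(out / "expr_class_summary.tsv", sep="\t",
                              index=False)
        ctx["tracks"] = {}
        for name, path in cfg.tracks.items():
            track = io.read_bedgraph(path)
            med = context.window_median_signal(loci, track, cfg.flank)
            med.rename_axis("gene").to_csv(out / f"median_{name}.tsv",
                                           sep="\t")
            tests, _ = context.context_group_tests(med.dropna(), classes)
            ctx["tracks"][name] = _tests_dict(tests)
        report["stages"]["context"] = ctx
    else:
        report["stages"]["context"] = {"status": "skipped: no expr_levels"}

    # -- coexpression features + classifier --------------------------------
    features = None
    if (cfg.expr_manifest and Path(cfg.expr_manifest).exists()
            and cfg.gene_sets and Path(cfg.gene_sets).exists()):
        datasets = [coexpr.ExpressionDataset(ds, io.read_expression_matrix(p))
                    for ds, p in io.read_expression_manifest(cfg.expr_manifest)]
        sets = io.read_gmt(cfg.gene_sets)
        mean_z, support = coexpr.pairwise_mean_z(datasets, trg_genes)
        features = coexpr.pathway_features(mean_z, support, sets,
                                           cfg.min_support)
        coexpr.write_features(features, out / "features.tsv",
                              out / "features_support.tsv")
        report["stages"]["coexpr"] = {
            "status": "ok", "n_targets": features.values.shape[0],
            "n_pathways": features.values.shape[1]}
    else:
        report["stages"]["coexpr"] = {"status": "skipped: no expression"}

    if features is not None:
        y = (classes.set_index("gene").loc[features.values.index, "essential"]
             .astype(int).to_numpy())
        if y.min() == y.max() or y.sum() < cfg.folds:
            report["stages"]["classifier"] = {
                "status": "skipped: too few essential TRGs"}
        else:
            X, imput = enet.impute_column_means(features.values)
            cv = enet.cross_validated_auc(X, y, cfg.folds, seed=cfg.seed,
                                          alpha=cfg.alpha)
            per_feat = enet.single_feature_auc(X, y, cfg.folds, cfg.seed)
            final = enet.fit_elastic_net_logistic(X, y, cv.chosen_lambda,
                                                  cfg.alpha)
            coef = pd.DataFrame({"feature": final.feature_names,
                                 "coefficient": final.coefficients,
                                 "imputed_mean": imput.to_numpy()})
            coef.to_csv(out / "coefficients.tsv", sep="\t", index=False)
            per_feat.rename("cv_auc").rename_axis("feature").to_csv(
                out / "single_feature_auc.tsv", sep="\t")
            report["stages"]["classifier"] = {
                "status": "ok", "cv_auc": cv.cv_auc,
                "chosen_lambda": cv.chosen_lambda,
                "n_positives": int(y.sum()), "n_total": int(y.size),
                "single_feature_auc": per_feat.to_dict(),
                "intercept": final.intercept}
    elif "classifier" not in report["stages"]:
        report["stages"]["classifier"] = {"status": "skipped: no features"}

    # -- network -----------------------------------------------------------
    if cfg.edges and Path(cfg.edges).exists():
        graph = io.read_edges(cfg.edges)
        degrees, degree_tests = network.degree_compare(graph, classes)
        assign = network.mcl_cluster(graph, inflation=cfg.inflation)
        trg_set = set(trg_genes)
        enr = network.enrich_clusters(assign, trg_set,
                                      min_size=cfg.min_cluster_size)
        enr.to_csv(out / "cluster_enrichment.tsv", sep="\t", index=False)
        pd.Series(assign.labels, name="cluster_id").rename_axis("gene").to_csv(
            out / "clusters.tsv", sep="\t")
        n_sig = int((enr["p_bonferroni"] < 0.05).sum()) if len(enr) else 0
        report["stages"]["network"] = {
            "status": "ok", "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
            "n_clusters": len(assign.clusters),
            "n_tested_clusters": int(enr["m_tests"].iloc[0]) if len(enr) else 0,
            "n_enriched_clusters": n_sig,
            "degree_tests": _tests_dict(degree_tests),
            "degree_medians": {c: float(np.median(v))
                               for c, v in degrees.items()},
            "mcl_converged": assign.converged,
            "mcl_max_column_error": assign.max_column_error}
    else:
        report["stages"]["network"] = {"status": "skipped: no edges"}

    # -- protein features and rates ----------------------------------------
    if cfg.protein_features and Path(cfg.protein_features).exists():
        prot = io.read_protein_features(cfg.protein_features)
        dis_tests, dis_summary = groups.disorder_compare(prot, classes)
        cc_tests, cc_frac = groups.coiled_coil_compare(prot, classes)
        dis_summary.to_csv(out / "disorder_summary.tsv", sep="\t", index=False)
        cc_frac.to_csv(out / "coiled_coil_fractions.tsv", sep="\t", index=False)
        report["stages"]["protein"] = {
            "status": "ok", "disorder_tests": _tests_dict(dis_tests),
            "coiled_coil_tests": _tests_dict(cc_tests),
            "coiled_coil_fractions": cc_frac.set_index("four_class")
            ["fraction"].to_dict()}
    else:
        report["stages"]["protein"] = {"status": "skipped: no protein features"}

    if cfg.rates and Path(cfg.rates).exists():
        rates = io.read_rates(cfg.rates)
        rate_report = groups.class_rate_analysis(rates, classes)
        rate_report.to_csv(out / "class_rates.tsv", sep="\t", index=False)
        report["stages"]["rates"] = {
            "status": "ok",
            "classes": rate_report.set_index("functional_class")
            [["median_dnds", "trg_percent", "t_p_value"]]
            .to_dict(orient="index")}
    else:
        report["stages"]["rates"] = {"status": "skipped: no rates"}

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
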