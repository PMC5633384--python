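"""Synthetic world generator: a complete, internally consistent set of
input files for every pipeline stage, with planted effects and full
ground-truth bookkeeping.

The generator emulates the structure of the real inputs — BLAST-tabular
homology hits against a lineage of genomes, multi-dataset expression
matrices, gene loci on a handful of chromosomes, chromatin signal tracks,
a blocky protein-interaction network, per-protein disorder/coiled-coil
tables and per-gene dN/dS with functional classes — so that the whole
analysis runs with no download.  Expression follows a latent-factor model
(genes load on pathway factors; essential genes additionally load on
"essential pathway" factors with strength ``coexpr_loading``), which makes
the pathway-mean Fisher-Z features analytically predictable and the
planted effects recoverable.

With all effect parameters zeroed (:meth:`WorldConfig.null`) the world is
a calibrated negative control: no stage should find signal.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FOUR = ("TRG-E", "TRG-NE", "Shared-E", "Shared-NE")


def _default_disorder() -> dict[str, tuple[float, float]]:
    # (mean ordered fraction, beta concentration) per class: essential TRPs
    # markedly more disordered than shared essentials
    return {"TRG-E": (0.50, 20.0), "TRG-NE": (0.80, 20.0),
            "Shared-E": (0.85, 20.0), "Shared-NE": (0.78, 20.0)}


def _default_coiled_coil() -> dict[str, float]:
    return {"TRG-E": 0.85, "TRG-NE": 0.15, "Shared-E": 0.35,
            "Shared-NE": 0.15}


def _default_functional_classes() -> list[dict]:
    # name, fraction of genes, TRG fraction within class, target median dN/dS
    # (gamma shape 2: median ~ 1.678 * scale); the amino-acid biosynthesis
    # and chromosome-segregation entries mirror the proportions and medians
    # a real yeast catalog shows (7/200 = 3.5% and 36/231 = 15.6%)
    return [
        {"name": "amino_acid_biosynthesis", "size_frac": 0.100,
         "trg_frac": 7 / 200, "median_dnds": 0.057},
        {"name": "chromosome_segregation", "size_frac": 0.1155,
         "trg_frac": 36 / 231, "median_dnds": 0.113},
        {"name": "translation", "size_frac": 0.120,
         "trg_frac": 0.06, "median_dnds": 0.070},
        {"name": "transcription", "size_frac": 0.100,
         "trg_frac": 0.12, "median_dnds": 0.090},
        {"name": "membrane_transport", "size_frac": 0.120,
         "trg_frac": 0.15, "median_dnds": 0.095},
        {"name": "signaling", "size_frac": 0.120,
         "trg_frac": 0.20, "median_dnds": 0.100},
    ]


@dataclass
class WorldConfig:
    """Knobs of the synthetic world; defaults are the study conditions.

    Fractions echo the real catalogs (10-20% of genes taxonomically
    restricted; ~17% of genes essential; ~3% of TRGs essential).  Effect
    parameters are in the units of the corresponding measure: log-units of
    expression for ``neighbor_shift`` / ``expr_essential_shift``, track
    signal units for ``chromatin_shift``, a latent-factor loading for
    ``coexpr_loading``, and a per-node edge-probability multiplier for
    ``degree_bias_essential``.
    """

    n_genes: int = 2000
    frac_trg: float = 0.15
    frac_essential: float = 0.17
    frac_trg_essential: float = 0.03
    frac_domain_excluded: float = 0.02
    frac_trg_weak_hits: float = 0.25

    # genomes / lineage
    n_genomes_in: int = 5
    n_genomes_out: int = 10

    # chromosomes and loci
    n_chromosomes: int = 5
    gene_length: tuple[int, int] = (1000, 3000)
    intergenic: tuple[int, int] = (1000, 10000)

    # expression
    n_datasets: int = 4
    n_samples_per_dataset: int = 20
    n_pathways: int = 20
    n_essential_pathways: int = 3
    pathway_size: tuple[int, int] = (15, 30)
    coexpr_loading: float = 1.0
    frac_gene_missing_per_dataset: float = 0.05

    # genomic context effects
    neighbor_shift: float = 1.5
    expr_essential_shift: float = 0.5
    chromatin_shift: float = 1.0
    track_bin_size: int = 1000

    # protein-interaction network
    ppi_n_blocks: int = 8
    ppi_block_size: int = 40
    ppi_p_in: float = 0.30
    ppi_p_out: float = 0.01
    trg_rich_factor: float = 3.0
    degree_bias_essential: float = 2.0

    # protein features and rates
    disorder_params: dict = field(default_factory=_default_disorder)
    coiled_coil_probs: dict = field(default_factory=_default_coiled_coil)
    functional_classes: list = field(default_factory=_default_functional_classes)
    dnds_gamma_shape: float = 2.0

    seed: int = 0

    @classmethod
    def null(cls, **overrides) -> "WorldConfig":
        """A world with every planted effect switched off."""
        flat = {"TRG-E": (0.78, 20.0), "TRG-NE": (0.78, 20.0),
                "Shared-E": (0.78, 20.0), "Shared-NE": (0.78, 20.0)}
        cc = {c: 0.2 for c in FOUR}
        classes = [dict(c, median_dnds=0.09, trg_frac=0.15)
                   for c in _default_functional_classes()]
        base = dict(coexpr_loading=0.0, neighbor_shift=0.0,
                    expr_essential_shift=0.0, chromatin_shift=0.0,
                    degree_bias_essential=1.0, trg_rich_factor=1.0,
                    disorder_params=flat, coiled_coil_probs=cc,
                    functional_classes=classes)
        base.update(overrides)
        return cls(**base)

    def validate(self) -> None:
        for name in ("frac_trg", "frac_essential", "frac_trg_essential",
                     "frac_domain_excluded", "frac_trg_weak_hits"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        n_trg = round(self.n_genes * self.frac_trg)
        n_ess = round(self.n_genes * self.frac_essential)
        n_trg_e = round(n_trg * self.frac_trg_essential)
        if n_trg_e > n_ess:
            raise ValueError("frac_trg_essential implies more essential "
                             "TRGs than essential genes in total")
        if n_ess - n_trg_e > self.n_genes - n_trg:
            raise ValueError("essential fraction infeasible for the "
                             "shared-gene pool")
        if self.trg_rich_factor * self.frac_trg > 1:
            raise ValueError("trg_rich_factor makes the planted block's "
                             "TRG fraction exceed 1")
        if sum(c["size_frac"] for c in self.functional_classes) > 1:
            raise ValueError("functional class size fractions exceed 1")


def _assign_labels(cfg: WorldConfig, rng) -> pd.DataFrame:
    n = cfg.n_genes
    width = len(str(n))
    genes = [f"g{i + 1:0{width}d}" for i in range(n)]
    n_trg = round(n * cfg.frac_trg)
    n_ess = round(n * cfg.frac_essential)
    n_trg_e = round(n_trg * cfg.frac_trg_essential)
    n_dom = round(n * cfg.frac_domain_excluded)
    order = rng.permutation(n)
    is_trg = np.zeros(n, bool)
    is_trg[order[:n_trg]] = True
    dom_excluded = np.zeros(n, bool)
    dom_excluded[order[n_trg:n_trg + n_dom]] = True  # shared, no out-hits
    is_ess = np.zeros(n, bool)
    trg_idx = order[:n_trg]
    shared_idx = order[n_trg:]
    is_ess[rng.choice(trg_idx, n_trg_e, replace=False)] = True
    is_ess[rng.choice(shared_idx, n_ess - n_trg_e, replace=False)] = True
    four = np.where(is_trg, np.where(is_ess, "TRG-E", "TRG-NE"),
                    np.where(is_ess, "Shared-E", "Shared-NE"))
    return pd.DataFrame({"gene": genes, "is_trg": is_trg,
                         "essential": is_ess, "four_class": four,
                         "domain_excluded": dom_excluded})


def _make_lineage(cfg: WorldConfig) -> pd.DataFrame:
    rows = []
    for i in range(cfg.n_genomes_in + cfg.n_genomes_out):
        rows.append({"taxon_id": f"t{i + 1:02d}",
                     "in_lineage": int(i < cfg.n_genomes_in),
                     "genome_label": f"G{i + 1:02d}",
                     "phylo_rank": i + 1})
    return pd.DataFrame(rows)


def _make_hits(cfg: WorldConfig, labels: pd.DataFrame, lineage: pd.DataFrame,
               rng) -> tuple[pd.DataFrame, list[str]]:
    in_taxa = lineage.loc[lineage["in_lineage"] == 1, "taxon_id"].tolist()
    out_taxa = lineage.loc[lineage["in_lineage"] == 0, "taxon_id"].tolist()
    qlen = rng.integers(100, 1200, size=len(labels))
    rows = []

    def add(gene, taxon, ql, evalue, cov):
        rows.append((gene, f"{taxon}_p{rng.integers(1, 10000)}", evalue,
                     max(1, int(round(cov * ql))), ql, taxon))

    trg_genes = labels.loc[labels["is_trg"], "gene"].tolist()
    n_weak = round(len(trg_genes) * cfg.frac_trg_weak_hits)
    weak_set = list(rng.choice(trg_genes, n_weak, replace=False)) if n_weak else []
    weak = set(weak_set)
    for i, row in labels.iterrows():
        ql = int(qlen[i])
        g = row["gene"]
        if row["is_trg"] or row["domain_excluded"]:
            # strong homology inside the lineage only
            for taxon in rng.choice(in_taxa, size=rng.integers(2, 5),
                                    replace=False):
                add(g, taxon, ql, 10.0 ** -rng.uniform(8, 40),
                    rng.uniform(0.45, 0.9))
            if g in weak:
                # relaxed-cutoff bait: fails both strict rules (E >= 1e-6
                # and coverage <= 0.30) but passes 5% length / E < 1e-2
                add(g, rng.choice(out_taxa), ql, 10.0 ** -rng.uniform(3, 5),
                    rng.uniform(0.10, 0.25))
        else:
            n_out = rng.integers(4, len(out_taxa) + 1)
            for taxon in rng.choice(out_taxa, size=n_out, replace=False):
                rank = int(taxon[1:])
                decay = 1.0 - 0.04 * (rank - cfg.n_genomes_in)
                add(g, taxon, ql, 10.0 ** -(rng.uniform(12, 60) * decay),
                    rng.uniform(0.45, 0.95))
            for taxon in rng.choice(in_taxa, size=2, replace=False):
                add(g, taxon, ql, 10.0 ** -rng.uniform(20, 60),
                    rng.uniform(0.5, 0.95))
    hits = pd.DataFrame(rows, columns=["qseqid", "sseqid", "evalue",
                                       "length", "qlen", "staxid"])
    return hits, sorted(weak)


def _make_domains(cfg: WorldConfig, labels: pd.DataFrame, rng) -> dict:
    domains = {}
    for _, row in labels.iterrows():
        if row["is_trg"]:
            domains[row["gene"]] = []
        elif row["domain_excluded"]:
            domains[row["gene"]] = [f"IPR{rng.integers(1, 999999):06d}"]
        else:
            k = int(rng.random() < 0.6) + int(rng.random() < 0.2)
            domains[row["gene"]] = [f"IPR{rng.integers(1, 999999):06d}"
                                    for _ in range(k)]
    return domains


def _make_loci(cfg: WorldConfig, labels: pd.DataFrame, rng) -> pd.DataFrame:
    n = len(labels)
    order = rng.permutation(n)
    per_chrom = np.array_split(order, cfg.n_chromosomes)
    rows = []
    for c, idxs in enumerate(per_chrom):
        pos = 0
        for i in idxs:
            pos += int(rng.integers(*cfg.intergenic))
            length = int(rng.integers(*cfg.gene_length))
            rows.append({"chrom": f"chr{c + 1}", "start": pos,
                         "end": pos + length,
                         "gene": labels["gene"].iloc[i], "score": 0,
                         "strand": rng.choice(["+", "-"])})
            pos += length
    return pd.DataFrame(rows)


def _make_expr_levels(cfg: WorldConfig, labels: pd.DataFrame,
                      loci: pd.DataFrame, rng) -> pd.Series:
    base = pd.Series(rng.normal(5.0, 1.0, len(labels)),
                     index=labels["gene"].to_numpy())
    ess = labels.loc[labels["essential"], "gene"]
    base[ess] += cfg.expr_essential_shift
    # neighborhood effect: genes within 3 positions of an essential TRG sit
    # in a high-expression chromosomal domain
    trg_e = set(labels.loc[labels["four_class"] == "TRG-E", "gene"])
    for _, sub in loci.sort_values(["chrom", "start"]).groupby("chrom"):
        genes = sub["gene"].to_numpy()
        for i, g in enumerate(genes):
            if g in trg_e:
                lo, hi = max(0, i - 3), min(len(genes), i + 4)
                base[genes[lo:hi]] += cfg.neighbor_shift
    return base


def _make_tracks(cfg: WorldConfig, labels: pd.DataFrame, loci: pd.DataFrame,
                 rng) -> tuple[pd.DataFrame, pd.DataFrame]:
    trg_e = set(labels.loc[labels["four_class"] == "TRG-E", "gene"])
    windows = {}
    for _, row in loci.iterrows():
        if row["gene"] in trg_e:
            windows.setdefault(row["chrom"], []).append(
                (max(0, row["start"] - 5000), row["end"] + 5000))
    tracks = {"h3k79": [], "h3k27": []}
    for chrom, sub in loci.groupby("chrom"):
        chrom_len = int(sub["end"].max()) + 5000
        edges = np.arange(0, chrom_len + cfg.track_bin_size,
                          cfg.track_bin_size)
        for name in tracks:
            vals = rng.normal(0.0, 1.0, len(edges) - 1)
            if name == "h3k79" and cfg.chromatin_shift:
                for lo, hi in windows.get(chrom, []):
                    mask = (edges[1:] > lo) & (edges[:-1] < hi)
                    vals[mask] += cfg.chromatin_shift
            tracks[name].append(pd.DataFrame({
                "chrom": chrom, "start": edges[:-1], "end": edges[1:],
                "value": np.round(vals, 4)}))
    return (pd.concat(tracks["h3k79"], ignore_index=True),
            pd.concat(tracks["h3k27"], ignore_index=True))


def _make_pathways(cfg: WorldConfig, labels: pd.DataFrame, rng
                   ) -> tuple[dict[str, list], list[str]]:
    shared_e = labels.loc[labels["four_class"] == "Shared-E", "gene"].to_numpy()
    shared_ne = labels.loc[labels["four_class"] == "Shared-NE", "gene"].to_numpy()
    pathways, essential_ids = {}, []
    for p in range(cfg.n_pathways):
        pid = f"pw{p + 1:02d}"
        size = int(rng.integers(*cfg.pathway_size))
        if p < cfg.n_essential_pathways:
            pool = shared_e
            essential_ids.append(pid)
        else:
            pool = shared_ne
        members = rng.choice(pool, size=min(size, len(pool)), replace=False)
        pathways[pid] = sorted(members)
    return pathways, essential_ids


def _make_expression(cfg: WorldConfig, labels: pd.DataFrame,
                     pathways: dict[str, list], essential_ids: list[str],
                     rng) -> dict[str, pd.DataFrame]:
    genes = labels["gene"].to_numpy()
    n, p = len(genes), cfg.n_pathways
    gi = {g: i for i, g in enumerate(genes)}
    loadings = np.zeros((n, p))
    pids = sorted(pathways)
    for j, pid in enumerate(pids):
        for g in pathways[pid]:
            loadings[gi[g], j] = 1.0
    ess = labels["essential"].to_numpy()
    for j, pid in enumerate(pids):
        if pid in essential_ids:
            loadings[ess, j] += cfg.coexpr_loading
    datasets = {}
    for d in range(cfg.n_datasets):
        f = rng.normal(size=(p, cfg.n_samples_per_dataset))
        x = loadings @ f + rng.normal(size=(n, cfg.n_samples_per_dataset))
        # the first dataset is complete so every gene is measured somewhere
        keep = (rng.random(n) >= cfg.frac_gene_missing_per_dataset
                if d > 0 else np.ones(n, bool))
        df = pd.DataFrame(
            np.round(x[keep], 5), index=genes[keep],
            columns=[f"s{s + 1:02d}" for s in range(cfg.n_samples_per_dataset)])
        datasets[f"ds{d + 1}"] = df
    return datasets


def _make_ppi(cfg: WorldConfig, labels: pd.DataFrame, rng
              ) -> tuple[pd.DataFrame, dict]:
    """Planted-block PPI network with a TRG-rich block and an essential
    degree bias that preserves the in/out density ratio."""
    bs, nb = cfg.ppi_block_size, cfg.ppi_n_blocks
    n_nodes = bs * nb
    trg_pool = labels.loc[labels["is_trg"]].copy()
    other_pool = labels.loc[~labels["is_trg"]].copy()
    base_frac = cfg.frac_trg
    rich_trg = min(bs, round(bs * base_frac * cfg.trg_rich_factor))
    base_trg = round(bs * base_frac)
    need_trg = rich_trg + base_trg * (nb - 1)
    need_other = n_nodes - need_trg
    if need_trg > len(trg_pool) or need_other > len(other_pool):
        raise ValueError("PPI blocks need more genes than the world has")
    # essential TRGs always enter the network so degree contrasts exist
    trg_e = trg_pool.loc[trg_pool["essential"], "gene"].tolist()
    trg_rest = trg_pool.loc[~trg_pool["essential"], "gene"].to_numpy()
    trg_sel = (trg_e + list(rng.choice(trg_rest, need_trg - len(trg_e),
                                       replace=False)))[:need_trg]
    trg_sel = list(rng.permutation(trg_sel))
    other_sel = list(rng.choice(other_pool["gene"].to_numpy(), need_other,
                                replace=False))
    blocks = []
    ti = oi = 0
    for b in range(nb):
        k = rich_trg if b == 0 else base_trg
        members = trg_sel[ti:ti + k] + other_sel[oi:oi + bs - k]
        ti += k
        oi += bs - k
        blocks.append(members)
    nodes = [g for blk in blocks for g in blk]
    block_of = np.repeat(np.arange(nb), bs)
    ess_lookup = labels.set_index("gene")["essential"]
    bias = np.where(ess_lookup[nodes].to_numpy(),
                    cfg.degree_bias_essential, 1.0)
    iu, ju = np.triu_indices(n_nodes, k=1)
    base_p = np.where(block_of[iu] == block_of[ju], cfg.ppi_p_in,
                      cfg.ppi_p_out)
    # an edge is upweighted by the larger endpoint bias, so an essential
    # node's expected degree scales by the full bias factor while the
    # in-block / out-block density ratio (what MCL sees) is preserved
    prob = np.clip(base_p * np.maximum(bias[iu], bias[ju]), 0.0, 0.95)
    draw = rng.random(len(prob)) < prob
    nodes_arr = np.array(nodes)
    edges = pd.DataFrame({"gene_a": nodes_arr[iu[draw]],
                          "gene_b": nodes_arr[ju[draw]]})
    truth = {"blocks": [sorted(b) for b in blocks],
             "trg_rich_block": 0,
             "trg_rich_members": sorted(blocks[0]),
             "rich_block_trg_count": rich_trg,
             "base_block_trg_count": base_trg}
    return edges, truth


def _make_protein_features(cfg: WorldConfig, labels: pd.DataFrame,
                           rng) -> pd.DataFrame:
    rows = []
    for _, row in labels.iterrows():
        mean, conc = cfg.disorder_params[row["four_class"]]
        a, b = mean * conc, (1 - mean) * conc
        rows.append({
            "gene": row["gene"],
            "ordered_fraction": round(float(rng.beta(a, b)), 5),
            "has_coiled_coil": int(
                rng.random() < cfg.coiled_coil_probs[row["four_class"]]),
        })
    return pd.DataFrame(rows)


def _make_rates(cfg: WorldConfig, labels: pd.DataFrame,
                rng) -> pd.DataFrame:
    n = len(labels)
    trg_genes = labels.loc[labels["is_trg"], "gene"].to_numpy()
    other_genes = labels.loc[~labels["is_trg"], "gene"].to_numpy()
    trg_left = list(rng.permutation(trg_genes))
    other_left = list(rng.permutation(other_genes))
    assignment = {}
    for spec_cls in cfg.functional_classes:
        size = round(n * spec_cls["size_frac"])
        n_trg = min(round(size * spec_cls["trg_frac"]), len(trg_left))
        n_other = min(size - n_trg, len(other_left))
        for g in trg_left[:n_trg] + other_left[:n_other]:
            assignment[g] = spec_cls["name"]
        del trg_left[:n_trg], other_left[:n_other]
    for g in trg_left + other_left:
        assignment[g] = "other"
    medians = {c["name"]: c["median_dnds"] for c in cfg.functional_classes}
    medians["other"] = 0.090
    shape = cfg.dnds_gamma_shape
    # gamma(shape=2) median is ~1.678 * scale
    from scipy.stats import gamma as _gamma
    median_factor = float(_gamma.ppf(0.5, shape))
    rows = []
    for g in labels["gene"]:
        fc = assignment[g]
        scale = medians[fc] / median_factor
        rows.append({"gene": g, "dnds": round(float(rng.gamma(shape, scale)), 6),
                     "functional_class": fc})
    return pd.DataFrame(rows)


def generate_world(config: WorldConfig, out_dir) -> dict:
    """Generate every input file plus ``truth.json`` under ``out_dir``.

    Returns the ground-truth dictionary.  The same config (including seed)
    produces byte-identical files.
    """
    config.validate()
    out = Path(out_dir)
    rng = np.random.default_rng(config.seed)
    labels = _assign_labels(config, rng)
    lineage = _make_lineage(config)
    hits, weak = _make_hits(config, labels, lineage, rng)
    domains = _make_domains(config, labels, rng)
    loci = _make_loci(config, labels, rng)
    expr_levels = _make_expr_levels(config, labels, loci, rng)
    h3k79, h3k27 = _make_tracks(config, labels, loci, rng)
    pathways, essential_pids = _make_pathways(config, labels, rng)
    datasets = _make_expression(config, labels, pathways, essential_pids, rng)
    ppi_edges, ppi_truth = _make_ppi(config, labels, rng)
    prot = _make_protein_features(config, labels, rng)
    rates = _make_rates(config, labels, rng)

    out.mkdir(parents=True, exist_ok=True)
    hits.to_csv(out / "hits.tsv", sep="\t", index=False)
    lineage.to_csv(out / "lineage.tsv", sep="\t", index=False)
    with open(out / "domains.tsv", "w") as fh:
        fh.write("gene\tdomains\n")
        for g in labels["gene"]:
            fh.write(f"{g}\t{','.join(domains[g])}\n")
    with open(out / "essential.txt", "w") as fh:
        for g in labels.loc[labels["essential"], "gene"]:
            fh.write(g + "\n")
    loci.to_csv(out / "genes.bed", sep="\t", index=False, header=False)
    expr_levels.round(5).rename("value").rename_axis("gene").to_csv(
        out / "expr_levels.tsv", sep="\t")
    h3k79.to_csv(out / "h3k79.bedgraph", sep="\t", index=False, header=False)
    h3k27.to_csv(out / "h3k27.bedgraph", sep="\t", index=False, header=False)
    with open(out / "pathways.gmt", "w") as fh:
        for pid in sorted(pathways):
            fh.write("\t".join([pid, "synthetic pathway"] + pathways[pid]) + "\n")
    (out / "expr").mkdir(exist_ok=True)
    with open(out / "expr" / "manifest.tsv", "w") as fh:
        fh.write("dataset_id\tpath\n")
        for ds_id, df in datasets.items():
            df.rename_axis("gene").to_csv(out / "expr" / f"{ds_id}.tsv",
                                          sep="\t")
            fh.write(f"{ds_id}\t{ds_id}.tsv\n")
    ppi_edges.to_csv(out / "ppi.tsv", sep="\t", index=False)
    prot.to_csv(out / "protein_features.tsv", sep="\t", index=False)
    rates.to_csv(out / "rates.tsv", sep="\t", index=False)

    conservation = np.where(labels["is_trg"], "TRG", "shared")
    truth = {
        "config": _config_dict(config),
        "genes": labels["gene"].tolist(),
        "conservation": dict(zip(labels["gene"], conservation.tolist())),
        "four_class": dict(zip(labels["gene"], labels["four_class"])),
        "essential": sorted(labels.loc[labels["essential"], "gene"]),
        "domain_excluded": sorted(labels.loc[labels["domain_excluded"], "gene"]),
        "trg_weak_hit_genes": weak,
        "class_counts": {c: int((labels["four_class"] == c).sum())
                         for c in FOUR},
        "essential_pathways": essential_pids,
        "pathways": {k: list(v) for k, v in pathways.items()},
        "ppi": ppi_truth,
        "effects": {
            "coexpr_loading": config.coexpr_loading,
            "neighbor_shift": config.neighbor_shift,
            "chromatin_shift": config.chromatin_shift,
            "degree_bias_essential": config.degree_bias_essential,
            "trg_rich_factor": config.trg_rich_factor,
        },
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth


def _config_dict(cfg: WorldConfig) -> dict:
    d = dataclasses.asdict(cfg)
    for key, val in d.items():
        if isinstance(val, tuple):
            d[key] = list(val)
    return d


def load_truth(world_dir) -> dict:
    path = Path(world_dir) / "truth.json"
    if not path.exists():
        raise FileNotFoundError(f"no truth.json under {world_dir}")
    with open(path) as fh:
        return json.load(fh)


def truth_report(world_dir) -> pd.DataFrame:
    """Machine-readable ground-truth summary for assertions in tests."""
    truth = load_truth(world_dir)
    counts = truth["class_counts"]
    rich = truth["ppi"]
    n_rich = len(rich["trg_rich_members"])
    rows = [{"quantity": f"n_{c}", "value": counts[c]} for c in FOUR]
    rows += [
        {"quantity": "n_genes", "value": sum(counts.values())},
        {"quantity": "n_trg_weak_hit_genes",
         "value": len(truth["trg_weak_hit_genes"])},
        {"quantity": "rich_block_size", "value": n_rich},
        {"quantity": "rich_block_trg_fraction",
         "value": rich["rich_block_trg_count"] / n_rich},
        {"quantity": "global_trg_fraction",
         "value": (counts["TRG-E"] + counts["TRG-NE"]) / sum(counts.values())},
        {"quantity": "n_essential_pathways",
         "value": len(truth["essential_pathways"])},
    ]
    return pd.DataFrame(rows)


def planted_partition_graph(block_sizes, p_in: float, p_out: float,
                            seed: int = 0):
    """Planted-partition random graph; returns (networkx graph, labels)."""
    import networkx as nx

    rng = np.random.default_rng(seed)
    sizes = list(block_sizes)
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu, ju = np.triu_indices(n, k=1)
    p = np.where(labels[iu] == labels[ju], p_in, p_out)
    draw = rng.random(len(p)) < p
    g.add_edges_from(zip(iu[draw].tolist(), ju[draw].tolist()))
    return g, labels
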