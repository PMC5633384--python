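"""Taxonomically restricted gene (TRG) classification from homology hits.

A gene is called taxonomically restricted when it has no qualifying BLAST
hit (E-value < 1e-6 over > 30% of the query protein length) to any taxon
outside the focal lineage, and encodes no annotated protein domain.  Genes
failing only the domain rule are labelled shared but keep a
``trg_excluded_by_domain`` flag.  Hits within the lineage (self-hits,
paralogs, close relatives) never disqualify a gene.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import FOUR_CLASSES

DEFAULT_E_MAX = 1e-6
DEFAULT_MIN_COV = 0.30

#: BLAST reports E = 0 for overwhelming matches; clamp before -log10.
E_VALUE_FLOOR = 1e-180


def _qualifying_out_hits(hits: pd.DataFrame, lineage: pd.DataFrame,
                         e_max: float, min_cov: float) -> pd.Series:
    """Boolean mask over hit rows: out-of-lineage hits passing both cutoffs."""
    known = set(lineage["taxon_id"])
    unknown = set(hits["staxid"]) - known
    if unknown:
        raise ValueError(f"hit table references unmapped taxa: {sorted(unknown)}")
    cov = hits["length"] / hits["qlen"]
    if (cov > 1).any():
        bad = hits.loc[cov > 1, "qseqid"].iloc[0]
        raise ValueError(f"coverage > 1 for {bad}")
    in_lineage = hits["staxid"].map(
        lineage.set_index("taxon_id")["in_lineage"])
    return (~in_lineage) & (hits["evalue"] < e_max) & (cov > min_cov)


def classify_trg(hits: pd.DataFrame, lineage: pd.DataFrame,
                 domains: dict[str, frozenset], genes,
                 e_max: float = DEFAULT_E_MAX,
                 min_cov: float = DEFAULT_MIN_COV) -> pd.DataFrame:
    """Assign each catalog gene a conservation label (TRG or shared).

    Parameters
    ----------
    hits : BLAST-tabular hit table (see :func:`trgkit.io.read_hits`).
    lineage : taxon table flagging in-lineage taxa.
    domains : gene -> set of domain accessions (genes may be absent = none).
    genes : the gene catalog; genes with no hits are allowed and, lacking
        out-of-lineage homology and domains, are TRGs.
    e_max, min_cov : homology cutoffs, strict inequalities
        (E < e_max, coverage > min_cov on the query length).

    Returns a DataFrame (gene, conservation, trg_excluded_by_domain).
    """
    genes = list(genes)
    mask = _qualifying_out_hits(hits, lineage, e_max, min_cov)
    with_out_homology = set(hits.loc[mask, "qseqid"])
    conservation, excluded = [], []
    for g in genes:
        has_hom = g in with_out_homology
        has_dom = bool(domains.get(g))
        if not has_hom and not has_dom:
            conservation.append("TRG")
            excluded.append(False)
        else:
            conservation.append("shared")
            excluded.append(not has_hom and has_dom)
    return pd.DataFrame({"gene": genes, "conservation": conservation,
                         "trg_excluded_by_domain": excluded})


def relaxed_scan(hits: pd.DataFrame, lineage: pd.DataFrame, trg_genes,
                 coverage_grid, e_grid) -> pd.DataFrame:
    """Sensitivity scan: fraction of TRGs still without out-of-lineage
    matches as the homology cutoffs are relaxed.

    ``trg_genes`` is the TRG set called at the strict cutoffs.  Returns one
    row per (coverage cutoff, E cutoff) with the surviving fraction, which
    is non-increasing along each relaxation axis.
    """
    coverage_grid = list(coverage_grid)
    e_grid = list(e_grid)
    if not coverage_grid or not e_grid:
        raise ValueError("grids must be non-empty")
    trg_genes = list(trg_genes)
    if not trg_genes:
        raise ValueError("empty TRG set")
    sub = hits[hits["qseqid"].isin(set(trg_genes))].copy()
    in_lin = sub["staxid"].map(lineage.set_index("taxon_id")["in_lineage"])
    sub = sub[~in_lin.astype(bool)]
    cov = (sub["length"] / sub["qlen"]).to_numpy()
    ev = sub["evalue"].to_numpy()
    qs = sub["qseqid"].to_numpy()
    rows = []
    for c in coverage_grid:
        for e in e_grid:
            matched = set(qs[(ev < e) & (cov > c)])
            frac = 1.0 - len(matched & set(trg_genes)) / len(trg_genes)
            rows.append({"min_cov": c, "e_max": e, "frac_unmatched": frac})
    return pd.DataFrame(rows)


def best_hit_profile(gene: str, hits: pd.DataFrame,
                     lineage: pd.DataFrame) -> pd.Series:
    """Per-genome -log10 best E-value profile, ordered by phylogenetic rank.

    Genomes without a hit are reported as 0 (an E = 1 floor); E-values of 0
    are clamped to ``E_VALUE_FLOOR`` before the log.
    """
    sub = hits[hits["qseqid"] == gene]
    best = sub.groupby("staxid")["evalue"].min()
    lin = lineage.sort_values("phylo_rank")
    vals = []
    for taxon in lin["taxon_id"]:
        if taxon in best.index:
            e = max(float(best[taxon]), E_VALUE_FLOOR)
            vals.append(-np.log10(e))
        else:
            vals.append(0.0)
    return pd.Series(vals, index=lin["genome_label"].to_numpy(), name=gene)


def assign_four_classes(conservation: pd.DataFrame, essential) -> pd.DataFrame:
    """Cross conservation (TRG/shared) with essentiality into four classes.

    ``essential`` is the list of essential genes and must be a subset of
    the catalog.  Returns the full gene-class table.
    """
    essential = set(essential)
    catalog = set(conservation["gene"])
    missing = essential - catalog
    if missing:
        raise ValueError(
            f"essential genes absent from catalog: {sorted(missing)[:5]}")
    df = conservation.copy()
    df["essential"] = df["gene"].isin(essential)
    df["four_class"] = np.where(
        df["conservation"] == "TRG",
        np.where(df["essential"], "TRG-E", "TRG-NE"),
        np.where(df["essential"], "Shared-E", "Shared-NE"),
    )
    assert set(df["four_class"]) <= set(FOUR_CLASSES)
    return df[["gene", "conservation", "essential", "four_class",
               "trg_excluded_by_domain"]]


def class_counts(classes: pd.DataFrame) -> dict[str, int]:
    """Summary counts by four-way class (zero-filled)."""
    counts = classes["four_class"].value_counts().to_dict()
    return {c: int(counts.get(c, 0)) for c in FOUR_CLASSES}
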