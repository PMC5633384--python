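"""Readers and writers for the plain-text formats the pipeline consumes.

Homology hits are BLAST outfmt-6 style TSV (qseqid, sseqid, evalue, length,
qlen, staxid), gene loci are BED6, chromatin tracks are bedGraph, gene sets
are GMT, everything else is headered TSV.  All readers skip ``#`` comment
lines and tolerate an optional header row where noted.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

HIT_COLUMNS = ["qseqid", "sseqid", "evalue", "length", "qlen", "staxid"]

FOUR_CLASSES = ("TRG-E", "TRG-NE", "Shared-E", "Shared-NE")


def _has_header(path: Path, first_field: str) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return line.split("\t")[0].strip() == first_field
    return False


def read_hits(path) -> pd.DataFrame:
    """Read a BLAST-tabular hit table (header optional, '#' comments ok)."""
    path = Path(path)
    header = 0 if _has_header(path, "qseqid") else None
    df = pd.read_csv(path, sep="\t", comment="#", header=header,
                     names=HIT_COLUMNS, dtype={"staxid": str})
    df["evalue"] = df["evalue"].astype(float)
    df["length"] = df["length"].astype(int)
    df["qlen"] = df["qlen"].astype(int)
    if (df["evalue"] < 0).any():
        raise ValueError("negative E-value in hit table")
    if (df["length"] > df["qlen"]).any():
        bad = df.loc[df["length"] > df["qlen"], "qseqid"].iloc[0]
        raise ValueError(f"alignment longer than query for {bad}")
    return df


def read_lineage(path) -> pd.DataFrame:
    """Read the taxon lineage table: taxon_id, in_lineage (0/1), genome_label, phylo_rank."""
    path = Path(path)
    header = 0 if _has_header(path, "taxon_id") else None
    df = pd.read_csv(path, sep="\t", comment="#", header=header,
                     names=["taxon_id", "in_lineage", "genome_label", "phylo_rank"],
                     dtype={"taxon_id": str})
    df["in_lineage"] = df["in_lineage"].astype(int).astype(bool)
    df["phylo_rank"] = df["phylo_rank"].astype(int)
    return df


def read_domains(path) -> dict[str, frozenset]:
    """Read per-gene domain annotations: gene TAB comma-joined accessions (may be empty)."""
    out: dict[str, frozenset] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "gene":
                continue
            doms = parts[1].strip() if len(parts) > 1 else ""
            out[parts[0]] = frozenset(d for d in doms.split(",") if d)
    return out


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def read_classes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["essential"] = df["essential"].astype(bool)
    df["trg_excluded_by_domain"] = df["trg_excluded_by_domain"].astype(bool)
    return df


def write_classes(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["essential"] = out["essential"].astype(int)
    out["trg_excluded_by_domain"] = out["trg_excluded_by_domain"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_bed(path) -> pd.DataFrame:
    """Read BED6 gene loci (chrom, start, end, gene, score ignored, strand)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "gene", "score", "strand"])
    if (df["start"] >= df["end"]).any():
        bad = df.loc[df["start"] >= df["end"], "gene"].iloc[0]
        raise ValueError(f"locus with start >= end: {bad}")
    return df[["chrom", "start", "end", "gene", "strand"]]


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "value"])
    return df


def read_gmt(path) -> dict[str, set]:
    """Read a GMT gene-set collection: set_id, description, members..."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            members = {g for g in parts[2:] if g}
            if members:
                sets[parts[0]] = members
    if not sets:
        raise ValueError(f"no gene sets read from {path}")
    return sets


def read_series(path, value_name: str = "value") -> pd.Series:
    """Read a two-column gene/value TSV into a Series indexed by gene."""
    header = 0 if _has_header(Path(path), "gene") else None
    df = pd.read_csv(path, sep="\t", comment="#", header=header,
                     names=["gene", value_name])
    return df.set_index("gene")[value_name].astype(float)


def read_expression_manifest(path) -> list[tuple[str, Path]]:
    """Read the dataset manifest: dataset_id TAB path (relative to the manifest)."""
    base = Path(path).parent
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            ds, rel = line.rstrip("\n").split("\t")[:2]
            if ds == "dataset_id":
                continue
            out.append((ds, base / rel))
    if not out:
        raise ValueError(f"empty expression manifest: {path}")
    return out


def read_expression_matrix(path) -> pd.DataFrame:
    """Read one expression dataset (rows genes, columns samples).

    Duplicate gene rows (multiple probes) are collapsed to their per-dataset
    mean, the declared collapse rule.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 3:
        raise ValueError(f"expression dataset needs >= 3 samples: {path}")
    if df.index.duplicated().any():
        df = df.groupby(level=0).mean()
    return df.astype(float)


def read_edges(path, evidence_filter: str | None = None) -> nx.Graph:
    """Read an undirected PPI edge list (gene_a, gene_b[, weight][, evidence]).

    Duplicate and reversed pairs are merged; self-loops are dropped with a
    logged count.  ``evidence_filter`` keeps only rows whose evidence column
    equals it (e.g. restricting to AP-MS derived physical interactions).
    """
    header = 0 if _has_header(Path(path), "gene_a") else None
    df = pd.read_csv(path, sep="\t", comment="#", header=header)
    if header is None:
        names = ["gene_a", "gene_b", "weight", "evidence"][: df.shape[1]]
        df.columns = names
    if evidence_filter is not None and "evidence" in df.columns:
        df = df[df["evidence"] == evidence_filter]
    n_self = int((df["gene_a"] == df["gene_b"]).sum())
    if n_self:
        log.info("dropped %d self-loop edges from %s", n_self, path)
        df = df[df["gene_a"] != df["gene_b"]]
    g = nx.Graph()
    weights = df["weight"] if "weight" in df.columns else pd.Series(1.0, index=df.index)
    for a, b, w in zip(df["gene_a"], df["gene_b"], weights):
        g.add_edge(str(a), str(b), weight=float(w))
    return g


def read_protein_features(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if ((df["ordered_fraction"] < 0) | (df["ordered_fraction"] > 1)).any():
        raise ValueError("ordered_fraction outside [0, 1]")
    df["has_coiled_coil"] = df["has_coiled_coil"].astype(bool)
    return df


def read_rates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if (df["dnds"] < 0).any():
        raise ValueError("negative dN/dS value")
    return df
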