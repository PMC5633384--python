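"""Genomic context of genes: flanking-gene expression and chromatin signal.

Neighbors are defined positionally per chromosome (strand-agnostic, ordered
by start coordinate); chromatin activity around a gene is the
overlap-weighted median of a bedGraph track over the gene body extended by
a flank on both sides.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import TestResult, wilcoxon_rank_sum

DEFAULT_FLANK = 5000
DEFAULT_OFFSETS = (1, 2, 3)

#: the two class contrasts reported for every context measure
CONTRASTS = (("TRG-E", "TRG-NE"), ("TRG-E", "Shared-E"))


def _sorted_loci(loci: pd.DataFrame) -> pd.DataFrame:
    return loci.sort_values(["chrom", "start", "end", "gene"], kind="mergesort")


def neighbor_expression(loci: pd.DataFrame, expr: pd.Series,
                        offsets=DEFAULT_OFFSETS) -> pd.DataFrame:
    """Expression values of the genes k positions away from each gene.

    For each gene and each offset k, the genes k positions before and after
    it in genomic order contribute their expression value (chromosome ends
    simply yield fewer values).  Neighbors missing from ``expr`` are
    skipped.  Returns a long frame (gene, offset, neighbor, value).
    """
    if loci["chrom"].isna().any():
        bad = loci.loc[loci["chrom"].isna(), "gene"].tolist()
        raise ValueError(f"genes on unknown chromosome: {bad[:5]}")
    rows = []
    for _, sub in _sorted_loci(loci).groupby("chrom", sort=False):
        genes = sub["gene"].to_numpy()
        for i, g in enumerate(genes):
            for k in offsets:
                for j in (i - k, i + k):
                    if 0 <= j < len(genes):
                        nb = genes[j]
                        if nb in expr.index and pd.notna(expr[nb]):
                            rows.append((g, k, nb, float(expr[nb])))
    return pd.DataFrame(rows, columns=["gene", "offset", "neighbor", "value"])


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median; even split -> mean of the two bracketing values."""
    order = np.argsort(values, kind="mergesort")
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    cum = np.cumsum(w)
    half = cum[-1] / 2.0
    i = int(np.searchsorted(cum, half, side="left"))
    if cum[i] == half and i + 1 < len(v):
        return float((v[i] + v[i + 1]) / 2.0)
    return float(v[i])


def window_median_signal(loci: pd.DataFrame, track: pd.DataFrame,
                         flank: int = DEFAULT_FLANK) -> pd.Series:
    """Per-gene overlap-weighted median signal over gene body +/- flank.

    The window is [start - flank, end + flank) clipped at zero.  Interval
    values are weighted by the number of bases they cover inside the
    window; genes whose window overlaps no interval get NaN.
    """
    out = {}
    by_chrom = {c: sub.sort_values("start") for c, sub in track.groupby("chrom")}
    for _, row in loci.iterrows():
        sub = by_chrom.get(row["chrom"])
        if sub is None:
            out[row["gene"]] = np.nan
            continue
        w_start = max(0, int(row["start"]) - flank)
        w_end = int(row["end"]) + flank
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        lo = int(np.searchsorted(ends, w_start, side="right"))
        hi = int(np.searchsorted(starts, w_end, side="left"))
        if lo >= hi:
            out[row["gene"]] = np.nan
            continue
        ov = (np.minimum(ends[lo:hi], w_end)
              - np.maximum(starts[lo:hi], w_start))
        vals = sub["value"].to_numpy()[lo:hi]
        keep = ov > 0
        if not keep.any():
            out[row["gene"]] = np.nan
            continue
        out[row["gene"]] = weighted_median(vals[keep], ov[keep])
    return pd.Series(out, name="median_signal")


def context_group_tests(values: pd.Series, classes: pd.DataFrame,
                        contrasts=CONTRASTS
                        ) -> tuple[dict[str, TestResult], pd.DataFrame]:
    """Wilcoxon contrasts of a per-gene measure between gene classes.

    Returns the test results keyed ``"A_vs_B"`` plus a box-plot-ready
    summary (class, n, median, q1, q3).  NaN values are dropped before
    testing.
    """
    cls = classes.set_index("gene")["four_class"]
    df = pd.DataFrame({"value": values}).join(cls, how="inner").dropna()
    groups = {c: sub["value"].to_numpy()
              for c, sub in df.groupby("four_class")}
    results = {}
    for a, b in contrasts:
        for name in (a, b):
            if name not in groups or len(groups[name]) == 0:
                raise ValueError(f"class {name} is empty for this measure")
        results[f"{a}_vs_{b}"] = wilcoxon_rank_sum(groups[a], groups[b])
    summary = (df.groupby("four_class")["value"]
               .agg(n="size", median="median",
                    q1=lambda s: s.quantile(0.25),
                    q3=lambda s: s.quantile(0.75))
               .reset_index())
    return results, summary
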