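"""Coexpression features: mean Fisher-Z correlation of each TRG to pathways.

For every (target gene, other gene) pair, the Pearson correlation is
computed within each expression dataset where both genes are measured and
have variance, Fisher-Z transformed, and averaged across datasets.  The
per-pair averages are then averaged over the member genes of each pathway
(excluding the target itself) to give one feature per (target, pathway).
Averaging is per-pair-first, then per-pathway, which matters when genes are
missing from some datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: correlations of exactly +/-1 are clamped here before arctanh
R_CLAMP = 0.999999

DEFAULT_MIN_SUPPORT = 3


@dataclass
class ExpressionDataset:
    """One normalized expression matrix (rows genes, columns samples)."""

    dataset_id: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape[1] < 3:
            raise ValueError(
                f"dataset {self.dataset_id} has fewer than 3 samples")
        if self.values.index.duplicated().any():
            raise ValueError(
                f"dataset {self.dataset_id} has duplicate gene rows")


@dataclass
class FeatureMatrix:
    """TRG x pathway matrix of mean Fisher-Z coexpression.

    ``support`` counts the (dataset x member gene) observations behind each
    cell; cells with support below the builder's ``min_support`` are NaN.
    """

    values: pd.DataFrame
    support: pd.DataFrame = field(repr=False)


def _dataset_z(ds: ExpressionDataset, targets: list[str]) -> pd.DataFrame | None:
    """Fisher-Z correlations of targets vs all genes in one dataset.

    Returns a (target x gene) frame with NaN where either vector has zero
    variance; None if no target is present in the dataset.
    """
    present = [t for t in targets if t in ds.values.index]
    if not present:
        return None
    x = ds.values.to_numpy(dtype=float)
    m = x.shape[1]
    centred = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((centred**2).sum(axis=1))
    ok = norms > 0
    unit = np.zeros_like(centred)
    unit[ok] = centred[ok] / norms[ok, None]
    idx = {g: i for i, g in enumerate(ds.values.index)}
    tpos = np.array([idx[t] for t in present])
    r = unit[tpos] @ unit.T
    r = np.clip(r, -R_CLAMP, R_CLAMP)
    z = np.arctanh(r)
    z[:, ~ok] = np.nan
    bad_targets = ~ok[tpos]
    z[bad_targets, :] = np.nan
    return pd.DataFrame(z, index=present, columns=ds.values.index)


def pairwise_mean_z(datasets: list[ExpressionDataset],
                    targets) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean Fisher-Z correlation per (target, gene) pair across datasets.

    Each pair's value averages the per-dataset z over datasets where both
    genes are present with nonzero variance; pairs with no valid dataset
    are NaN.  Self-pairs are dropped.  Returns (mean_z, n_datasets_used),
    both (target x gene) frames.
    """
    targets = list(targets)
    all_ids = {g for ds in datasets for g in ds.values.index}
    absent = [t for t in targets if t not in all_ids]
    if absent:
        raise ValueError(f"targets present in no dataset: {absent[:5]}")
    genes = sorted(all_ids)
    total = pd.DataFrame(0.0, index=targets, columns=genes)
    count = pd.DataFrame(0, index=targets, columns=genes)
    for ds in datasets:
        z = _dataset_z(ds, targets)
        if z is None:
            continue
        zf = z.reindex(index=targets, columns=genes)
        valid = zf.notna()
        total += zf.fillna(0.0)
        count += valid.astype(int)
    mean = total.where(count > 0) / count.where(count > 0)
    for t in targets:
        if t in mean.columns:
            mean.loc[t, t] = np.nan
            count.loc[t, t] = 0
    return mean, count


def pathway_features(mean_z: pd.DataFrame, support: pd.DataFrame,
                     sets: dict[str, set],
                     min_support: int = DEFAULT_MIN_SUPPORT) -> FeatureMatrix:
    """Average per-pair mean-z over pathway members into features.

    The target gene is excluded from pathways containing it.  A cell is
    NaN when its total (dataset x member) support falls below
    ``min_support``.  Pathway members absent from the mean-z table are
    skipped.
    """
    if not sets:
        raise ValueError("empty gene-set collection")
    targets = mean_z.index
    vals = np.full((len(targets), len(sets)), np.nan)
    supp = np.zeros((len(targets), len(sets)), dtype=int)
    set_ids = sorted(sets)
    for j, sid in enumerate(set_ids):
        members = [g for g in sets[sid] if g in mean_z.columns]
        if not members:
            continue
        sub = mean_z[members]
        cnt = support[members]
        n_pairs = sub.notna().sum(axis=1)
        total_support = cnt.sum(axis=1).to_numpy()
        feat = sub.mean(axis=1, skipna=True).to_numpy()
        ok = (n_pairs.to_numpy() > 0) & (total_support >= min_support)
        vals[ok, j] = feat[ok]
        supp[:, j] = total_support
    values = pd.DataFrame(vals, index=targets, columns=set_ids)
    support_df = pd.DataFrame(supp, index=targets, columns=set_ids)
    return FeatureMatrix(values=values, support=support_df)


def write_features(fm: FeatureMatrix, values_path, support_path) -> None:
    fm.values.to_csv(values_path, sep="\t", index_label="gene")
    fm.support.to_csv(support_path, sep="\t", index_label="gene")


def read_features(values_path, support_path) -> FeatureMatrix:
    v = pd.read_csv(values_path, sep="\t", index_col="gene")
    s = pd.read_csv(support_path, sep="\t", index_col="gene")
    return FeatureMatrix(values=v, support=s)
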