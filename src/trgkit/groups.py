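"""Group comparisons of protein features and evolutionary rates.

Protein disorder (ordered fraction from an external predictor) is compared
between classes with Kolmogorov-Smirnov tests; coiled-coil presence with
chi-square on 2x2 tables; and dN/dS is summarized per functional class
with a Welch t-test of each class against all genes (the class included in
the background, deliberately).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stats import TestResult, chi_square_2x2, ks_two_sample, t_test_two_sample

log = logging.getLogger(__name__)

PROTEIN_CONTRASTS = (("TRG-E", "TRG-NE"), ("TRG-E", "Shared-E"))

#: minimum TRG count for a class to get a pie (essential-TRG) fraction
MIN_TRGS_FOR_PIE = 20

QUANTILES = (0.05, 0.25, 0.5, 0.75, 0.95)


def _joined(features: pd.DataFrame, classes: pd.DataFrame) -> pd.DataFrame:
    cls = classes.set_index("gene")["four_class"]
    return features.set_index("gene").join(cls, how="inner").dropna(
        subset=["four_class"])


def disorder_compare(features: pd.DataFrame, classes: pd.DataFrame,
                     contrasts=PROTEIN_CONTRASTS
                     ) -> tuple[dict[str, TestResult], pd.DataFrame]:
    """KS contrasts of the ordered fraction between protein classes.

    Returns tests keyed ``"A_vs_B"`` and violin-plot-ready per-class
    quantile summaries.
    """
    df = _joined(features, classes)
    groups = {c: sub["ordered_fraction"].to_numpy()
              for c, sub in df.groupby("four_class")}
    tests = {}
    for a, b in contrasts:
        for name in (a, b):
            if name not in groups or len(groups[name]) == 0:
                raise ValueError(f"class {name} empty after join")
        tests[f"{a}_vs_{b}"] = ks_two_sample(groups[a], groups[b])
    summary = (df.groupby("four_class")["ordered_fraction"]
               .quantile(QUANTILES).unstack()
               .rename(columns=lambda q: f"q{int(q * 100):02d}")
               .reset_index())
    summary.insert(1, "n", [len(groups[c]) for c in summary["four_class"]])
    return tests, summary


def coiled_coil_compare(features: pd.DataFrame, classes: pd.DataFrame,
                        contrasts=PROTEIN_CONTRASTS
                        ) -> tuple[dict[str, TestResult], pd.DataFrame]:
    """Chi-square contrasts of coiled-coil presence between classes.

    The 2x2 table per contrast is class x has_coiled_coil.  Also returns
    the per-class coiled-coil fractions.
    """
    df = _joined(features, classes)
    tables = {}
    for c, sub in df.groupby("four_class"):
        with_cc = int(sub["has_coiled_coil"].sum())
        tables[c] = (with_cc, len(sub) - with_cc)
    tests = {}
    for a, b in contrasts:
        for name in (a, b):
            if name not in tables:
                raise ValueError(f"class {name} empty after join")
        table = np.array([tables[a], tables[b]])
        try:
            tests[f"{a}_vs_{b}"] = chi_square_2x2(table)
        except ValueError as err:
            raise ValueError(f"{a} vs {b}: {err}") from err
    frac = pd.DataFrame(
        [{"four_class": c, "n": w + wo, "with_coiled_coil": w,
          "fraction": w / (w + wo)} for c, (w, wo) in sorted(tables.items())])
    return tests, frac


def class_rate_analysis(rates: pd.DataFrame,
                        classes: pd.DataFrame) -> pd.DataFrame:
    """Per-functional-class dN/dS and TRG-content report.

    For each functional class: median dN/dS, a Welch t-test of the class
    against ALL genes in the rate table (background includes the class),
    the TRG count and proportion (displayed to one decimal percent), and
    the essential fraction among the class's TRGs when the class has at
    least ``MIN_TRGS_FOR_PIE`` TRGs.  Genes annotated to several classes
    contribute a row to each.  Rate-table genes missing from the class
    table are dropped with a logged count.
    """
    cls = classes.set_index("gene")[["conservation", "essential"]]
    df = rates.join(cls, on="gene", how="left")
    n_unmatched = int(df["conservation"].isna().sum())
    if n_unmatched:
        log.info("dropped %d rate rows without class labels", n_unmatched)
        df = df.dropna(subset=["conservation"])
    background = df["dnds"].to_numpy(dtype=float)
    rows = []
    for fc, sub in df.groupby("functional_class"):
        vals = sub["dnds"].to_numpy(dtype=float)
        is_trg = (sub["conservation"] == "TRG").to_numpy()
        n_trg = int(is_trg.sum())
        if len(vals) >= 2:
            t = t_test_two_sample(vals, background)
            t_stat, t_p = t.statistic, t.p_value
            direction = ("higher" if t_stat > 0 else
                         "lower" if t_stat < 0 else "equal")
        else:
            log.info("class %s has < 2 genes, excluded from t-tests", fc)
            t_stat = t_p = np.nan
            direction = "untested"
        trg_frac = n_trg / len(vals)
        if n_trg >= MIN_TRGS_FOR_PIE:
            ess_frac = float(sub.loc[is_trg, "essential"].mean())
        else:
            ess_frac = np.nan
        rows.append({
            "functional_class": fc,
            "n_genes": len(vals),
            "median_dnds": float(np.median(vals)),
            "t_statistic": t_stat,
            "t_p_value": t_p,
            "direction": direction,
            "n_trg": n_trg,
            "trg_fraction": trg_frac,
            "trg_percent": round(100.0 * trg_frac, 1),
            "essential_trg_fraction": ess_frac,
        })
    return pd.DataFrame(rows).sort_values(
        "functional_class", kind="mergesort").reset_index(drop=True)
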