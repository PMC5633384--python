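"""Group comparisons: disorder, coiled coils, dN/dS by functional class."""

import numpy as np
import pandas as pd
import pytest

from trgkit.groups import (class_rate_analysis, coiled_coil_compare,
                           disorder_compare)


def features_frame(entries):
    return pd.DataFrame(entries, columns=["gene", "ordered_fraction",
                                          "has_coiled_coil"])


def test_disorder_identical_distributions(toy_classes):
    feats = features_frame([("a1", 0.5, 0), ("a2", 0.5, 0), ("a3", 0.5, 0),
                            ("b1", 0.5, 0), ("b2", 0.5, 0)])
    tests, summary = disorder_compare(feats, toy_classes)
    assert tests["TRG-E_vs_TRG-NE"].statistic == 0.0
    assert tests["TRG-E_vs_TRG-NE"].degenerate
    assert {"q05", "q25", "q50", "q75", "q95"} <= set(summary.columns)


def test_disorder_planted_shift_recovered(world):
    out, truth, cfg = world
    from trgkit.io import read_protein_features

    feats = read_protein_features(out / "protein_features.tsv")
    fc = pd.Series(truth["four_class"]).rename("four_class")
    classes = fc.rename_axis("gene").reset_index()
    classes["conservation"] = np.where(
        classes["four_class"].str.startswith("TRG"), "TRG", "shared")
    classes["essential"] = classes["four_class"].str.endswith("-E")
    tests, _ = disorder_compare(feats, classes)
    assert tests["TRG-E_vs_TRG-NE"].p_value < 0.01
    assert tests["TRG-E_vs_Shared-E"].p_value < 0.01
    # direction: essential TRPs are the more disordered group
    joined = feats.set_index("gene").join(fc)
    med = joined.groupby("four_class")["ordered_fraction"].median()
    assert med["TRG-E"] < med["TRG-NE"] < med["Shared-E"]


def test_coiled_coil_fixture_statistic(toy_classes):
    rng = np.random.default_rng(0)
    # build classes giving the [[20,5],[10,15]] table for TRG-E vs TRG-NE
    genes, rows, feats = [], [], []
    for i in range(25):
        genes.append((f"e{i}", "TRG", True, "TRG-E", False))
        feats.append((f"e{i}", 0.5, int(i < 20)))
    for i in range(25):
        genes.append((f"n{i}", "TRG", False, "TRG-NE", False))
        feats.append((f"n{i}", 0.5, int(i < 10)))
    classes = pd.DataFrame(genes, columns=toy_classes.columns)
    tests, frac = coiled_coil_compare(features_frame(feats), classes,
                                      contrasts=(("TRG-E", "TRG-NE"),))
    assert tests["TRG-E_vs_TRG-NE"].statistic == pytest.approx(25 / 3,
                                                               abs=1e-9)
    tab = frac.set_index("four_class")
    assert tab.loc["TRG-E", "fraction"] == 0.8
    assert tab.loc["TRG-NE", "fraction"] == 0.4


def test_coiled_coil_equal_fractions_zero_statistic(toy_classes):
    rows, feats = [], []
    for i in range(4):  # two classes, both with coiled-coil fraction 1/2
        rows.append((f"e{i}", "TRG", True, "TRG-E", False))
        feats.append((f"e{i}", 0.5, int(i % 2 == 0)))
        rows.append((f"s{i}", "shared", True, "Shared-E", False))
        feats.append((f"s{i}", 0.5, int(i % 2 == 0)))
    classes = pd.DataFrame(rows, columns=toy_classes.columns)
    tests, _ = coiled_coil_compare(features_frame(feats), classes,
                                   contrasts=(("TRG-E", "Shared-E"),))
    assert tests["TRG-E_vs_Shared-E"].statistic == pytest.approx(0.0)
    assert tests["TRG-E_vs_Shared-E"].p_value == pytest.approx(1.0)


def make_rates(counts):
    """counts: list of (class_name, n_trg, n_other, dnds_trg, dnds_other)."""
    rows, classes = [], []
    i = 0
    for name, n_trg, n_other, d_trg, d_other in counts:
        for _ in range(n_trg):
            rows.append((f"g{i}", d_trg, name))
            classes.append((f"g{i}", "TRG", False, "TRG-NE", False))
            i += 1
        for _ in range(n_other):
            rows.append((f"g{i}", d_other, name))
            classes.append((f"g{i}", "shared", False, "Shared-NE", False))
            i += 1
    rates = pd.DataFrame(rows, columns=["gene", "dnds", "functional_class"])
    cls = pd.DataFrame(classes, columns=["gene", "conservation", "essential",
                                         "four_class",
                                         "trg_excluded_by_domain"])
    return rates, cls


def test_printed_proportions_reproduced():
    rates, cls = make_rates([
        ("amino_acid_biosynthesis", 7, 193, 0.06, 0.06),
        ("chromosome_segregation", 36, 195, 0.11, 0.11),
    ])
    report = class_rate_analysis(rates, cls).set_index("functional_class")
    assert report.loc["amino_acid_biosynthesis", "n_genes"] == 200
    assert report.loc["amino_acid_biosynthesis", "trg_percent"] == 3.5
    assert report.loc["chromosome_segregation", "n_genes"] == 231
    assert report.loc["chromosome_segregation", "trg_percent"] == 15.6


def test_t_test_background_includes_the_class():
    rng = np.random.default_rng(1)
    rows = [("cls_a", 0, 50, 0.0, 0.0), ("cls_b", 0, 50, 0.0, 0.0)]
    rates, cls = make_rates(rows)
    rates["dnds"] = np.r_[rng.gamma(2, 0.03, 50), rng.gamma(2, 0.08, 50)]
    report = class_rate_analysis(rates, cls).set_index("functional_class")
    # recompute excluding the class from the background: statistic changes
    from trgkit.stats import t_test_two_sample

    a = rates.loc[rates["functional_class"] == "cls_a", "dnds"]
    rest = rates.loc[rates["functional_class"] != "cls_a", "dnds"]
    excl = t_test_two_sample(a.to_numpy(), rest.to_numpy()).statistic
    incl = report.loc["cls_a", "t_statistic"]
    assert incl != pytest.approx(excl)
    assert incl == pytest.approx(
        t_test_two_sample(a.to_numpy(), rates["dnds"].to_numpy()).statistic)
    assert report.loc["cls_a", "direction"] == "lower"
    assert report.loc["cls_b", "direction"] == "higher"


def test_background_identical_class_p_near_one():
    rates, cls = make_rates([("only", 5, 45, 0.1, 0.1)])
    report = class_rate_analysis(rates, cls)
    assert report.loc[0, "t_p_value"] > 0.9  # class IS the background


def test_essential_trg_fraction_gated_by_min_trgs():
    rates, cls = make_rates([("few", 5, 45, 0.1, 0.1),
                             ("many", 25, 45, 0.1, 0.1)])
    report = class_rate_analysis(rates, cls).set_index("functional_class")
    assert np.isnan(report.loc["few", "essential_trg_fraction"])
    assert report.loc["many", "essential_trg_fraction"] == 0.0


def test_planted_rate_structure(world_report):
    """Generator worlds reproduce the slow amino-acid-biosynthesis /
    fast chromosome-segregation contrast."""
    out, truth, report = world_report
    rates = report["stages"]["rates"]["classes"]
    aa = rates["amino_acid_biosynthesis"]
    cs = rates["chromosome_segregation"]
    assert aa["median_dnds"] < cs["median_dnds"]
    assert cs["trg_percent"] > aa["trg_percent"]
    assert aa["t_p_value"] < 0.01  # strongly slower than background
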