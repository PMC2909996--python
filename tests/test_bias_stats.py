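"""Bias tables, length comparisons and mismatch-share arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest

from itspcr.bias_stats import (length_comparison, mismatch_share,
                               order_breakdown, specificity_table,
                               taxonomic_bias_table)
from itspcr.pcr_engine import Amplicon
from itspcr.refdb_io import Group
from itspcr.subset_pipeline import (InternalEvaluation, SubsetSpec,
                                    build_subset, evaluate_internal)
from itspcr.synthetic_data import (Cohort, SimulationConfig,
                                   paper_scenario_config,
                                   simulate_reference_db)


def _amp(group, insert, rid="r"):
    return Amplicon(record_id=rid, taxid=1, group=Group(group), strand="+",
                    fwd_start=0, rev_end=insert + 40, insert_length=insert,
                    total_length=insert + 40, fwd_mismatches=0,
                    rev_mismatches=0)


# ------------------------------------------------------------ specificity

@pytest.fixture(scope="module")
def fungi_and_plant_dbs():
    cfg = SimulationConfig(seed=21, per_group_counts={
        "ascomycete": 10, "basidiomycete": 8, "non_dikarya": 4, "plant": 0})
    fungi, fungi_truth = simulate_reference_db(cfg)
    cfg_p = SimulationConfig(seed=22, per_group_counts={
        "ascomycete": 0, "basidiomycete": 0, "non_dikarya": 0, "plant": 12})
    plants, plant_truth = simulate_reference_db(cfg_p)
    return fungi, fungi_truth, plants, plant_truth


def test_specificity_fungal_only_pair_never_amplifies_plants(fungi_and_plant_dbs):
    """Plant records carry no ITS1-F or ITS4-B sites by construction, so
    the fungal-specific pairs give an all-zero plant row."""
    fungi, _, plants, _ = fungi_and_plant_dbs
    table = specificity_table(fungi, plants,
                              [("ITS3", "ITS4-B"), ("ITS1-F", "ITS2")])
    for ceiling in (0, 1, 2, 3):
        assert table.table.loc["ITS3-ITS4-B", f"plant_{ceiling}"] == 0
        assert table.table.loc["ITS1-F-ITS2", f"plant_{ceiling}"] == 0


def test_specificity_counts_match_truth_and_are_monotone(fungi_and_plant_dbs):
    fungi, fungi_truth, plants, plant_truth = fungi_and_plant_dbs
    pairs = [("ITS5", "ITS4"), ("ITS1", "ITS2"), ("ITS3", "ITS4-B")]
    table = specificity_table(fungi, plants, pairs).table
    for fwd, rev in pairs:
        row = table.loc[f"{fwd}-{rev}"]
        for label, truth in (("fungi", fungi_truth), ("plant", plant_truth)):
            values = [row[f"{label}_{c}"] for c in (0, 1, 2, 3)]
            assert values == sorted(values)
            for c in (0, 1, 2, 3):
                assert row[f"{label}_{c}"] == len(truth.amplified_ids(fwd, rev, c))
    assert table.loc["ITS5-ITS4", "fungi_0"] == len(fungi)


# --------------------------------------------------------- taxonomic bias

def test_taxonomic_bias_recovers_planted_group_rates():
    db, _ = simulate_reference_db(paper_scenario_config("taxonomic_bias", seed=3))
    sub = build_subset(db, SubsetSpec("subset1"))
    ev = evaluate_internal(sub, ("ITS1", "ITS2"), "ITS1")
    table = taxonomic_bias_table([ev]).table
    row = table.iloc[0]
    assert row["ascomycete"] == pytest.approx(62.0)
    assert row["basidiomycete"] == pytest.approx(86.0)
    assert row["non_dikarya"] == pytest.approx(89.0)
    assert "plant" not in table.columns  # zero denominator -> absent


def test_taxonomic_bias_full_amplification_is_100(small_db):
    db, _ = small_db
    sub = build_subset(db, SubsetSpec("subset1"))
    ev = evaluate_internal(sub, ("ITS5", "ITS2"), "ITS5")
    row = taxonomic_bias_table([ev]).table.iloc[0]
    for group in ("ascomycete", "basidiomycete", "non_dikarya"):
        assert row[group] == pytest.approx(100.0)


# -------------------------------------------------------- order breakdown

def test_order_breakdown_recovers_planted_rows():
    db, _ = simulate_reference_db(paper_scenario_config("order_breakdown", seed=4))
    sub = build_subset(db, SubsetSpec("subset3"))
    table = order_breakdown(sub, ("ITS3", "ITS4-B"),
                            ["Boletales", "Cantharellales", "Pucciniomycotina",
                             "Dacrymycetes"]).table
    bol = table.loc["Boletales"]
    assert (bol["n"], bol["amplified_3"], bol["amplified_0"]) == (18, 17, 15)
    assert bol["pct_3"] == pytest.approx(94.4, abs=0.05)
    assert bol["pct_0"] == pytest.approx(83.3, abs=0.05)
    assert table.loc["Pucciniomycotina", "amplified_3"] == 0
    assert "Dacrymycetes" not in table.index  # absent clade omitted
    assert (table["pct_3"] >= table["pct_0"]).all()


# ------------------------------------------------------ length comparison

def test_welch_t_on_four_point_toy():
    """Hand-computed Welch test: {100,110} vs {130,140} -> diff 30,
    t = 30/sqrt(50) = 4.2426, df = 2."""
    amps = [_amp("ascomycete", 100), _amp("ascomycete", 110),
            _amp("basidiomycete", 130), _amp("basidiomycete", 140)]
    res = length_comparison(amps, ["ascomycete", "basidiomycete"])
    row = res.pairwise.iloc[0]
    assert row.mean_diff_bp == pytest.approx(30.0)
    assert row.t == pytest.approx(30.0 / math.sqrt(50.0), rel=1e-12)
    assert row.df == pytest.approx(2.0)
    assert res.summary.loc["ascomycete", "mean_bp"] == pytest.approx(105.0)
    assert res.summary.loc["ascomycete", "sd_bp"] == pytest.approx(math.sqrt(50))


def test_identical_groups_give_tiny_t():
    rng = np.random.default_rng(8)
    lengths = rng.normal(500, 50, size=200)
    amps = [_amp("ascomycete", float(v)) for v in lengths] + \
           [_amp("basidiomycete", float(v)) for v in lengths]
    res = length_comparison(amps, ["ascomycete", "basidiomycete"])
    row = res.pairwise.iloc[0]
    assert row.mean_diff_bp == pytest.approx(0.0, abs=1e-9)
    assert abs(row.t) < 1e-9


def test_seeded_normal_groups_recover_known_difference():
    rng = np.random.default_rng(19)
    a = rng.normal(545, 60, size=500)
    b = rng.normal(640, 70, size=500)
    amps = [_amp("ascomycete", float(v)) for v in a] + \
           [_amp("basidiomycete", float(v)) for v in b]
    res = length_comparison(amps, ["ascomycete", "basidiomycete"])
    row = res.pairwise.iloc[0]
    se = math.sqrt(a.var(ddof=1) / 500 + b.var(ddof=1) / 500)
    assert abs(row.mean_diff_bp - 95.0) < 3 * se
    assert row.p < 0.01


def test_degenerate_variance_flagged():
    amps = [_amp("ascomycete", 100)] * 3 + [_amp("basidiomycete", 100)] * 3
    res = length_comparison(amps, ["ascomycete", "basidiomycete"])
    assert res.degenerate
    assert math.isnan(res.pairwise.iloc[0].p)


def test_pooled_option_differs_from_welch_under_unequal_n():
    rng = np.random.default_rng(6)
    amps = [_amp("ascomycete", float(v)) for v in rng.normal(500, 10, 50)] + \
           [_amp("basidiomycete", float(v)) for v in rng.normal(520, 80, 10)]
    welch = length_comparison(amps, ["ascomycete", "basidiomycete"])
    pooled = length_comparison(amps, ["ascomycete", "basidiomycete"], pooled=True)
    assert welch.pairwise.iloc[0].df != pytest.approx(pooled.pairwise.iloc[0].df)


def test_length_comparison_requires_two_per_group():
    with pytest.raises(ValueError):
        length_comparison([_amp("ascomycete", 100),
                           _amp("basidiomycete", 100),
                           _amp("basidiomycete", 110)],
                          ["ascomycete", "basidiomycete"])


# --------------------------------------------------------- mismatch share

def _eval(p0, p1):
    return InternalEvaluation(
        subset="s", pair=("A", "B"), internal="A", n_records=1000,
        amplified={0: int(1000 * p0), 1: int(1000 * p1)},
        proportions={0: p0, 1: p1})


def test_mismatch_share_arithmetic():
    assert mismatch_share(_eval(0.36, 0.916)) == pytest.approx(0.6069869)
    assert mismatch_share(_eval(0.5, 0.5)) == 0.0


def test_mismatch_share_bounds_and_errors():
    assert 0.0 <= mismatch_share(_eval(0.2, 0.9)) <= 1.0
    with pytest.raises(ValueError):
        mismatch_share(_eval(0.0, 0.0))
    with pytest.raises(ValueError):
        mismatch_share(InternalEvaluation("s", ("A", "B"), "A", 10,
                                          {1: 5}, {1: 0.5}))
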