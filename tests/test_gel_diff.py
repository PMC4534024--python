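"""Percent-volume quantification and the two differential filters."""

import itertools

import numpy as np
import pandas as pd
import pytest

from maldigel.gel_diff import (
    differential_report,
    fold_change,
    percent_volume,
    presence_matrix,
    specificity_filter,
)
from maldigel.synthetic import SpotSimSpec, simulate_spot_tables, table2_detection_matrix


def spot_table(volumes_by_gel, group_of, fraction="B"):
    rows = []
    for gel, vols in volumes_by_gel.items():
        for spot, v in vols.items():
            rows.append((gel, group_of[gel], fraction, spot, f"prot_{spot}", v))
    return pd.DataFrame(
        rows, columns=["gel_id", "group", "fraction", "spot_id", "protein", "raw_volume"]
    )


class TestPercentVolume:
    def test_simple_shares(self):
        tab = spot_table({"g1": {"s1": 2.0, "s2": 3.0, "s3": 5.0}}, {"g1": "case"})
        out = percent_volume(tab)
        assert out["percent_volume"].tolist() == [20.0, 30.0, 50.0]

    def test_single_spot_is_100(self):
        tab = spot_table({"g1": {"s1": 7.3}}, {"g1": "case"})
        assert percent_volume(tab)["percent_volume"].iloc[0] == 100.0

    def test_scale_invariance(self):
        tab = spot_table({"g1": {"s1": 2.0, "s2": 3.0}}, {"g1": "case"})
        scaled = tab.assign(raw_volume=tab["raw_volume"] * 37.5)
        assert np.allclose(
            percent_volume(tab)["percent_volume"], percent_volume(scaled)["percent_volume"]
        )

    def test_all_zero_gel_rejected(self):
        tab = spot_table({"g1": {"s1": 0.0, "s2": 0.0}}, {"g1": "case"})
        with pytest.raises(ValueError, match="zero total"):
            percent_volume(tab)

    def test_per_gel_sum_is_100_on_generated_tables(self):
        for seed in range(5):
            tab, _, _ = simulate_spot_tables(
                SpotSimSpec(seed=seed, n_spots=200, noise_sd=0.3, dropout_prob=0.05)
            )
            out = percent_volume(tab)
            sums = out.groupby("gel_id")["percent_volume"].sum()
            assert np.allclose(sums, 100.0, atol=1e-9)


class TestFoldChange:
    def test_twofold_up(self):
        fc, diff, cs, ctl = fold_change(3.0, 1.5, threshold=1.5)
        assert fc == 2.0 and diff and not cs and not ctl

    def test_equal_means_not_differential(self):
        fc, diff, *_ = fold_change(1.0, 1.0)
        assert fc == 1.0 and not diff

    def test_case_specific_when_control_absent(self):
        fc, diff, cs, ctl = fold_change(0.4, 0.0)
        assert np.isinf(fc) and cs and not diff and not ctl

    def test_control_specific_symmetric(self):
        fc, diff, cs, ctl = fold_change(0.0, 0.4)
        assert fc == 0.0 and ctl and not cs

    def test_absent_from_both_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 0.0)


class TestSpecificityFilter:
    def test_table2_fixture_yields_25(self):
        presence, design = table2_detection_matrix()
        assert len(specificity_filter(presence, design)) == 25

    def test_partial_case_presence_excluded(self):
        gels = [f"c{i}" for i in range(5)] + [f"h{i}" for i in range(5)]
        design = {g: ("case" if g.startswith("c") else "control") for g in gels}
        presence = pd.DataFrame(
            [[True] * 4 + [False] + [False] * 5], columns=gels, index=["p1"]
        )
        assert specificity_filter(presence, design) == []

    def test_exhaustive_patterns_exactly_one_passes(self):
        """Over all 2^10 presence patterns for 5+5 gels, only all-case/no-control."""
        gels = [f"c{i}" for i in range(5)] + [f"h{i}" for i in range(5)]
        design = {g: ("case" if g.startswith("c") else "control") for g in gels}
        passing = 0
        for bits in itertools.product([False, True], repeat=10):
            presence = pd.DataFrame([list(bits)], columns=gels, index=["p"])
            if specificity_filter(presence, design):
                passing += 1
                assert bits == (True,) * 5 + (False,) * 5
        assert passing == 1

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            specificity_filter(pd.DataFrame(), {})


class TestDifferentialReport:
    def test_null_table_has_no_specific_spots(self):
        tab, _, _ = simulate_spot_tables(
            SpotSimSpec(seed=3, n_spots=100, noise_sd=0.2, dropout_prob=0.0)
        )
        frame, summary = differential_report(tab)
        assert summary.n_case_specific == 0 and summary.n_control_specific == 0

    def test_planted_spots_recovered_exactly(self):
        planted = {f"spot{i:04d}": 2.0 for i in (3, 50, 77, 120, 400)}
        tab, _, truth = simulate_spot_tables(
            SpotSimSpec(seed=4, n_spots=800, noise_sd=0.0, dropout_prob=0.0, planted=planted)
        )
        frame, summary = differential_report(tab, fold_threshold=1.5)
        flagged = set(frame.loc[frame["differential"], "spot_id"])
        assert flagged == set(truth)

    def test_threshold_monotonicity(self):
        tab, _, _ = simulate_spot_tables(
            SpotSimSpec(seed=6, n_spots=300, noise_sd=0.25,
                        planted={"spot0010": 1.8, "spot0020": 3.0})
        )
        f10, _ = differential_report(tab, fold_threshold=1.0)
        f15, _ = differential_report(tab, fold_threshold=1.5)
        set10 = set(f10.loc[f10["differential"], "spot_id"])
        set15 = set(f15.loc[f15["differential"], "spot_id"])
        assert set15 <= set10

    def test_presence_threshold_monotonicity(self):
        tab, design, _ = simulate_spot_tables(
            SpotSimSpec(seed=8, n_spots=120, noise_sd=0.3, dropout_prob=0.3)
        )
        lo = specificity_filter(presence_matrix(tab, 0.0), design)
        hi = specificity_filter(presence_matrix(tab, 0.5), design)
        assert set(hi) <= set(lo)

    def test_null_exceedance_within_frozen_band(self):
        """Null simulation (no effects, sd 0.2, 5+5 gels): FC>=1.5 rate stays
        inside the band frozen from a 400-rep brute-force simulation."""
        tab, _, _ = simulate_spot_tables(SpotSimSpec(seed=99, n_spots=800, noise_sd=0.2))
        _, summary = differential_report(tab, fold_threshold=1.5)
        assert summary.n_differential / 800 <= 0.0125

    def test_missing_group_rejected(self):
        tab = spot_table({"g1": {"s1": 1.0}}, {"g1": "case"})
        with pytest.raises(ValueError, match="no control gels"):
            differential_report(tab)
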