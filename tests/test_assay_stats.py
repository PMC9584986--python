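"""Plate loading, E/E0 normalization and the ANOVA/Tukey contract."""

import math

import numpy as np
import pandas as pd
import pytest

from bbbrank.assay_stats import (
    PlateAssay,
    anova_with_posthoc,
    load_plate,
    normalize_to_control,
    plate_statistics,
)

HEADER = "experiment_id,assay,well,group,compound_id,insult,concentration_uM,signal\n"


def toy_plate(rows: str, tmp_path):
    p = tmp_path / "plate.csv"
    p.write_text(HEADER + rows)
    return p


def make_plate(groups: dict, assay: str = "MTT") -> PlateAssay:
    rows = []
    for g, values in groups.items():
        for i, v in enumerate(values):
            rows.append(("E1", f"{g}:w{i}", g, "", "LPS50", 10.0, float(v)))
    wells = pd.DataFrame(rows, columns=["experiment_id", "well", "group",
                                        "compound_id", "insult",
                                        "concentration_uM", "signal"])
    return PlateAssay(assay=assay, wells=wells)


class TestLoadPlate:
    def test_toy_csv_groups(self, tmp_path):
        p = toy_plate(
            "E1,MTT,w1,negative_control,,LPS50,,1.0\n"
            "E1,MTT,w2,negative_control,,LPS50,,1.1\n"
            "E1,MTT,w3,TP4@10,TP4,LPS50,10,2.0\n", tmp_path)
        (plate,) = load_plate(p)
        assert len(plate.wells) == 3
        assert plate.groups == ["negative_control", "TP4@10"]

    def test_blank_concentration_for_controls(self, tmp_path):
        p = toy_plate("E1,MTT,w1,positive_control,,none,,1.0\n", tmp_path)
        (plate,) = load_plate(p)
        assert math.isnan(plate.wells["concentration_uM"].iloc[0])

    def test_duplicate_well_in_experiment_rejected(self, tmp_path):
        p = toy_plate(
            "E1,MTT,w1,a,,none,,1.0\nE1,MTT,w1,a,,none,,1.1\n", tmp_path)
        with pytest.raises(ValueError, match="duplicated well"):
            load_plate(p)

    def test_missing_column_and_bad_signal(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("experiment_id,assay,well\nE1,MTT,w1\n")
        with pytest.raises(ValueError, match="missing column"):
            load_plate(p)
        p2 = toy_plate("E1,MTT,w1,a,,none,,not_a_number\n", tmp_path)
        with pytest.raises(ValueError, match="non-numeric signal at row 2"):
            load_plate(p2)

    def test_unknown_assay_rejected(self, tmp_path):
        p = toy_plate("E1,XYZ,w1,a,,none,,1.0\n", tmp_path)
        with pytest.raises(ValueError, match="unknown assay"):
            load_plate(p)


class TestNormalization:
    def test_treated_ratio_against_flat_control(self):
        plate = make_plate({"negative_control": [1, 1, 1], "t": [2, 2, 2]})
        s = normalize_to_control(plate)
        assert s.ratio("t") == pytest.approx(2.0)

    def test_reference_ratio_exactly_one(self):
        plate = make_plate({"negative_control": [0.8, 1.3, 1.1], "t": [2, 3, 4]})
        s = normalize_to_control(plate)
        assert s.ratio("negative_control") == 1.0

    def test_hand_ratio(self):
        plate = make_plate({"negative_control": [2, 4], "t": [3, 3]})
        s = normalize_to_control(plate)
        assert s.ratio("t") == pytest.approx(1.0)

    def test_negative_control_preferred_when_both_present(self):
        plate = make_plate({"positive_control": [2, 2],
                            "negative_control": [1, 1], "t": [3, 3]})
        s = normalize_to_control(plate)
        assert s.reference == "negative_control"
        assert s.ratio("t") == pytest.approx(3.0)

    def test_scaling_equivariance(self, rng):
        groups = {g: rng.lognormal(0, 0.2, size=5) for g in
                  ("negative_control", "a", "b")}
        s1 = normalize_to_control(make_plate(groups))
        s2 = normalize_to_control(
            make_plate({g: 7.3 * v for g, v in groups.items()}))
        for g in groups:
            assert s2.ratio(g) == pytest.approx(s1.ratio(g), rel=1e-12)

    def test_per_experiment_vs_pooled(self):
        rows = []
        for exp, (e0, t) in {"E1": (1.0, 2.0), "E2": (2.0, 2.0)}.items():
            for i in range(2):
                rows.append((exp, f"c:w{i}", "negative_control", "", "LPS50", None, e0))
                rows.append((exp, f"t:w{i}", "t", "", "LPS50", None, t))
        plate = PlateAssay(assay="MTT", wells=pd.DataFrame(
            rows, columns=["experiment_id", "well", "group", "compound_id",
                           "insult", "concentration_uM", "signal"]))
        per_exp = normalize_to_control(plate)                        # (2/1 + 2/2)/2
        pooled = normalize_to_control(plate, per_experiment=False)   # 2 / 1.5
        assert per_exp.ratio("t") == pytest.approx(1.5)
        assert pooled.ratio("t") == pytest.approx(2 / 1.5)

    def test_missing_or_zero_reference_errors(self):
        with pytest.raises(ValueError, match="absent"):
            normalize_to_control(make_plate({"a": [1, 2], "b": [2, 3]}),
                                 reference="negative_control")
        with pytest.raises(ValueError, match="zero"):
            normalize_to_control(
                make_plate({"negative_control": [0.0, 0.0], "t": [1, 1]}))


class TestAnova:
    def test_hand_anova(self):
        # groups {1,2,3},{2,3,4}: SSB = 1.5, MSW = 1.0 -> F = 1.5, df (1, 4)
        rep = anova_with_posthoc({"a": [1, 2, 3], "b": [2, 3, 4]})
        assert rep.f_statistic == pytest.approx(1.5, abs=1e-12)
        assert (rep.df_between, rep.df_within) == (1, 4)

    def test_identical_groups_give_zero_f(self):
        rep = anova_with_posthoc({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert rep.f_statistic == 0.0

    def test_degenerate_zero_within_variance_flagged_infinite(self):
        rep = anova_with_posthoc({"a": [0, 0, 0], "b": [1, 1, 1]})
        assert math.isinf(rep.f_statistic)
        assert rep.degenerate
        assert any("within" in w for w in rep.warnings)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n < 2"):
            anova_with_posthoc({"a": [1.0], "b": [1, 2]})

    def test_matches_two_pass_sum_of_squares_oracle(self, rng):
        """F agrees with an independent two-pass SS oracle on 200 datasets."""
        from scipy import stats as sps

        for _ in range(200):
            k = int(rng.integers(2, 5))
            groups = {f"g{i}": rng.normal(rng.normal(0, 1), 1.0,
                                          size=int(rng.integers(3, 8)))
                      for i in range(k)}
            rep = anova_with_posthoc(groups)
            # oracle: explicit two-pass between/within sums of squares
            allv = np.concatenate(list(groups.values()))
            grand = allv.mean()
            ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
            ssw = sum(float(np.sum((np.asarray(v) - np.mean(v)) ** 2))
                      for v in groups.values())
            f_oracle = (ssb / (k - 1)) / (ssw / (len(allv) - k))
            assert rep.f_statistic == pytest.approx(f_oracle, abs=1e-10)
            # and scipy agrees too
            assert rep.f_statistic == pytest.approx(
                sps.f_oneway(*groups.values()).statistic, rel=1e-9)

    def test_tukey_p_monotone_in_mean_difference(self):
        base = np.array([0.0, 0.1, -0.1, 0.05, -0.05])
        rep = anova_with_posthoc(
            {"a": base, "b": base + 0.5, "c": base + 2.0})
        p = {(r.group1, r.group2): r.p_adj for r in rep.posthoc.itertuples()}
        assert p[("a", "c")] < p[("a", "b")]
        assert p[("b", "c")] < p[("a", "c")] or p[("a", "c")] < 1e-6

    def test_assumption_warnings_do_not_change_tests(self, rng):
        heavy = {"a": rng.standard_cauchy(20), "b": rng.standard_cauchy(20) + 50}
        rep = anova_with_posthoc(heavy)
        assert rep.f_statistic >= 0 and not rep.posthoc.empty

    def test_plate_statistics_wrapper(self):
        plate = make_plate({"negative_control": [1, 1.1, 0.9],
                            "t": [2, 2.1, 1.9]})
        rep = plate_statistics(plate)
        assert rep.p_value < 0.01
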