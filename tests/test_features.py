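import numpy as np
import pandas as pd
import pytest

from netprog.features import (
    build_features,
    fit_class_statistics,
    read_features,
    standardize,
    write_features,
)
from netprog.io import ModuleSet
from netprog.modules import filter_modules


class TestClassStatistics:
    def test_hand_computed_mean_and_sample_sd(self, tiny_expr, tiny_labels):
        stats = fit_class_statistics(tiny_expr, tiny_labels,
                                     ["p1", "p2", "p4", "p5"])
        # gene g1 good-class training values {1, 3}
        assert stats.mean_good["g1"] == pytest.approx(2.0)
        assert stats.sd_good["g1"] == pytest.approx(np.sqrt(2.0))
        # bad-class values {4, 6}
        assert stats.mean_bad["g1"] == pytest.approx(5.0)
        assert stats.sd_bad["g1"] == pytest.approx(np.sqrt(2.0))

    def test_training_only(self, tiny_expr, tiny_labels):
        a = fit_class_statistics(tiny_expr, tiny_labels, ["p1", "p2", "p4", "p5"])
        b = fit_class_statistics(tiny_expr, tiny_labels,
                                 ["p1", "p2", "p3", "p4", "p5", "p6"])
        assert a.sd_good["g1"] != b.sd_good["g1"]

    def test_gene_unmeasured_in_one_class_flagged(self, tiny_labels):
        expr = pd.DataFrame({"p1": [np.nan], "p2": [np.nan], "p4": [1.0],
                             "p5": [2.0]}, index=pd.Index(["g"], name="gene"))
        stats = fit_class_statistics(expr, tiny_labels, ["p1", "p2", "p4", "p5"])
        assert "g" in stats.flagged

    def test_constant_gene_flagged(self, tiny_labels):
        expr = pd.DataFrame({"p1": [1.0], "p2": [1.0], "p4": [1.0], "p5": [2.0]},
                            index=pd.Index(["g"], name="gene"))
        stats = fit_class_statistics(expr, tiny_labels, ["p1", "p2", "p4", "p5"])
        assert "g" in stats.flagged

    def test_missing_class_errors(self, tiny_expr, tiny_labels):
        with pytest.raises(ValueError, match="both"):
            fit_class_statistics(tiny_expr, tiny_labels, ["p1", "p2"])


class TestStandardize:
    def test_direct_formula(self, tiny_expr, tiny_labels):
        stats = fit_class_statistics(tiny_expr, tiny_labels,
                                     ["p1", "p2", "p4", "p5"])
        p, q = standardize(5.0, stats, "g1")
        assert p == pytest.approx((5.0 - 2.0) / np.sqrt(2.0))
        assert q == pytest.approx(0.0)

    def test_class_mean_maps_to_zero(self, tiny_expr, tiny_labels):
        stats = fit_class_statistics(tiny_expr, tiny_labels,
                                     ["p1", "p2", "p4", "p5"])
        p, _ = standardize(float(stats.mean_good["g2"]), stats, "g2")
        assert p == pytest.approx(0.0)

    def test_flagged_gene_errors(self, tiny_labels):
        expr = pd.DataFrame({"p1": [1.0], "p2": [1.0], "p4": [1.0], "p5": [2.0]},
                            index=pd.Index(["g"], name="gene"))
        stats = fit_class_statistics(expr, tiny_labels, ["p1", "p2", "p4", "p5"])
        with pytest.raises(ValueError, match="flagged"):
            standardize(1.0, stats, "g")

    def test_good_class_training_standardization_identity(self, default_dataset):
        """P over good-class training patients has mean 0 and sample SD 1."""
        from netprog.io import derive_labels
        from netprog.features import _standardize_frame
        labels, _ = derive_labels(default_dataset.outcomes, 5.0)
        train = list(labels.index[:120])
        stats = fit_class_statistics(default_dataset.expression, labels, train)
        p, _ = _standardize_frame(default_dataset.expression, stats)
        good_train = [t for t in train if labels[t] == 0]
        sub = p[good_train]
        assert np.nanmax(np.abs(sub.mean(axis=1))) < 1e-10
        assert np.nanmax(np.abs(sub.std(axis=1, ddof=1) - 1.0)) < 1e-10


class TestBuildFeatures:
    def _stats(self, expr, labels, train):
        return fit_class_statistics(expr, labels, train)

    def test_averaged_is_mean_of_p(self, tiny_expr, tiny_labels, tiny_modules):
        train = ["p1", "p2", "p4", "p5"]
        stats = self._stats(tiny_expr, tiny_labels, train)
        fm = filter_modules(tiny_modules, tiny_expr)
        feats = build_features(tiny_expr, fm, stats, "averaged")
        p1 = (tiny_expr.loc["g1"] - stats.mean_good["g1"]) / stats.sd_good["g1"]
        p2 = (tiny_expr.loc["g2"] - stats.mean_good["g2"]) / stats.sd_good["g2"]
        expected = (p1 + p2) / 2.0
        assert feats.data["M1.G"].to_numpy() == pytest.approx(expected.to_numpy())

    def test_singleton_module_equals_pq(self, tiny_expr, tiny_labels, tiny_modules):
        train = ["p1", "p2", "p4", "p5"]
        stats = self._stats(tiny_expr, tiny_labels, train)
        fm = filter_modules(tiny_modules, tiny_expr)
        feats = build_features(tiny_expr, fm, stats, "averaged")
        p3 = (tiny_expr.loc["g3"] - stats.mean_good["g3"]) / stats.sd_good["g3"]
        q3 = (tiny_expr.loc["g3"] - stats.mean_bad["g3"]) / stats.sd_bad["g3"]
        assert feats.data["M2.G"].to_numpy() == pytest.approx(p3.to_numpy())
        assert feats.data["M2.B"].to_numpy() == pytest.approx(q3.to_numpy())

    def test_overlapping_gene_contributes_to_both_modules(
            self, tiny_expr, tiny_labels, tiny_modules):
        """g2 sits in M1 and M3; nudging it moves both modules' features."""
        train = ["p1", "p2", "p4", "p5"]
        stats = self._stats(tiny_expr, tiny_labels, train)
        fm = filter_modules(tiny_modules, tiny_expr)
        base = build_features(tiny_expr, fm, stats, "averaged")
        bumped_expr = tiny_expr.copy()
        bumped_expr.loc["g2", "p3"] += 1.0
        bumped = build_features(bumped_expr, fm, stats, "averaged")
        assert bumped.data.loc["p3", "M1.G"] != base.data.loc["p3", "M1.G"]
        assert bumped.data.loc["p3", "M3.G"] != base.data.loc["p3", "M3.G"]
        assert bumped.data.loc["p3", "M2.G"] == base.data.loc["p3", "M2.G"]

    def test_averaged_column_count(self, tiny_expr, tiny_labels, tiny_modules):
        stats = self._stats(tiny_expr, tiny_labels, ["p1", "p2", "p4", "p5"])
        fm = filter_modules(tiny_modules, tiny_expr)
        feats = build_features(tiny_expr, fm, stats, "averaged")
        assert feats.data.shape[1] == 2 * len(fm.kept)

    def test_missing_value_skipped_in_average(self, tiny_expr, tiny_labels,
                                              tiny_modules):
        """g5 is missing for p1, so M3's average for p1 uses g2 and g4 only."""
        train = ["p2", "p3", "p4", "p5"]
        stats = self._stats(tiny_expr, tiny_labels, train)
        fm = filter_modules(tiny_modules, tiny_expr)
        feats = build_features(tiny_expr, fm, stats, "averaged")
        p = {g: (tiny_expr.loc[g, "p1"] - stats.mean_good[g]) / stats.sd_good[g]
             for g in ["g2", "g4"]}
        assert feats.data.loc["p1", "M3.G"] == pytest.approx(
            (p["g2"] + p["g4"]) / 2.0)

    def test_expanded_names_and_values(self, tiny_expr, tiny_labels, tiny_modules):
        train = ["p1", "p2", "p4", "p5"]
        stats = self._stats(tiny_expr, tiny_labels, train)
        fm = filter_modules(tiny_modules, tiny_expr)
        feats = build_features(tiny_expr, fm, stats, "expanded")
        assert "M1.g1.P" in feats.data.columns and "M1.g1.Q" in feats.data.columns
        p1 = (tiny_expr.loc["g1", "p2"] - stats.mean_good["g1"]) / stats.sd_good["g1"]
        assert feats.data.loc["p2", "M1.g1.P"] == pytest.approx(p1)

    def test_affine_equivariance(self, tiny_expr, tiny_labels, tiny_modules):
        """Shifting one gene by +c shifts its P and Q by c/sigma under fixed stats."""
        train = ["p1", "p2", "p4", "p5"]
        stats = self._stats(tiny_expr, tiny_labels, train)
        fm = filter_modules(tiny_modules, tiny_expr)
        base = build_features(tiny_expr, fm, stats, "expanded")
        shifted_expr = tiny_expr.copy()
        shifted_expr.loc["g3"] += 2.5
        shifted = build_features(shifted_expr, fm, stats, "expanded")
        delta_p = shifted.data["M2.g3.P"] - base.data["M2.g3.P"]
        assert delta_p.to_numpy() == pytest.approx(
            np.full(6, 2.5 / stats.sd_good["g3"]))

    def test_no_leakage_from_test_labels(self, small_dataset):
        """Permuting labels of held-out patients leaves the features bit-identical."""
        from netprog.io import derive_labels
        labels, _ = derive_labels(small_dataset.outcomes, 5.0)
        train = list(labels.index[:60])
        test = list(labels.index[60:])
        fm = filter_modules(small_dataset.modules, small_dataset.expression)

        permuted = labels.copy()
        permuted.loc[test] = labels.loc[test].sample(frac=1.0, random_state=0).to_numpy()
        assert not permuted.equals(labels)

        f1 = build_features(small_dataset.expression,
                            fm, fit_class_statistics(
                                small_dataset.expression, labels, train), "averaged")
        f2 = build_features(small_dataset.expression,
                            fm, fit_class_statistics(
                                small_dataset.expression, permuted, train), "averaged")
        assert f1.data.equals(f2.data)
        assert f1.stats_fingerprint == f2.stats_fingerprint

    def test_round_trip_tsv(self, tiny_expr, tiny_labels, tiny_modules, tmp_path):
        stats = self._stats(tiny_expr, tiny_labels, ["p1", "p2", "p4", "p5"])
        fm = filter_modules(tiny_modules, tiny_expr)
        feats = build_features(tiny_expr, fm, stats, "averaged")
        p = tmp_path / "features.tsv"
        write_features(feats, p)
        back = read_features(p)
        assert back.mode == "averaged"
        assert back.stats_fingerprint == feats.stats_fingerprint
        pd.testing.assert_frame_equal(back.data, feats.data)
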