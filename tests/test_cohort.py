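import itertools

import numpy as np
import pytest

import fluoropk as fp
from fluoropk.cohort import Toxicity


def row(css, auc, tox, i=[0]):
    i[0] += 1
    return fp.ExposureToxicityRow(f"r{i[0]}", css, auc, Toxicity.parse(tox))


def brute_force_stump(rows, positive):
    """Independent oracle: evaluate every candidate split's Gini gain directly."""
    y = [positive(r.toxicity) for r in rows]
    n = len(y)
    n_pos = sum(y)
    if n_pos in (0, n):
        return None  # single class: no informative split exists

    def gini(pos, total):
        if total == 0:
            return 0.0
        p = pos / total
        return 1 - p * p - (1 - p) * (1 - p)

    parent = gini(n_pos, n)
    best = None  # (gain, feature_index, threshold)
    for fi, feat in enumerate(("css", "auc")):
        values = [
            r.css_mg_per_L if feat == "css" else r.auc_mg_h_per_L for r in rows
        ]
        for a, b in itertools.pairwise(sorted(set(values))):
            thr = (a + b) / 2
            left = [yy for v, yy in zip(values, y) if v <= thr]
            right = [yy for v, yy in zip(values, y) if v > thr]
            gain = parent - (
                len(left) * gini(sum(left), len(left))
                + len(right) * gini(sum(right), len(right))
            ) / n
            cand = (gain, fi, thr)
            if best is None or gain > best[0] + 1e-12:
                best = cand
    return best


class TestSimulateCohort:
    def test_empty_cohort(self):
        result = fp.simulate_cohort([])
        assert len(result) == 0
        assert result.failures == []

    def test_patient_schedules_as_cohort(self):
        records = [
            fp.CohortRecord("erroneous", 3052.0, 2.0, 49.0, Toxicity.LIFE_THREATENING),
            fp.CohortRecord("planned", 4612.0, 24.0, 49.0, Toxicity.NONE),
        ]
        result = fp.simulate_cohort(records)
        assert [r.id for r in result] == ["erroneous", "planned"]
        err, planned = result
        assert err.no_plateau  # 2-h infusion: peak reported in the css slot
        assert err.css_mg_per_L == pytest.approx(28.7, rel=0.02)
        assert err.auc_mg_h_per_L == pytest.approx(82.3, rel=0.02)
        assert not planned.no_plateau
        assert planned.css_mg_per_L == pytest.approx(4.115, rel=0.02)
        assert planned.auc_mg_h_per_L == pytest.approx(98.0, rel=0.02)

    def test_failures_collected_not_raised(self, monkeypatch):
        import fluoropk.cohort as cohort_mod

        real = cohort_mod.simulate_to_washout

        def flaky(regimen, *args, **kwargs):
            if regimen.total_dose_mg == 777.0:
                raise fp.SimulationError("boom")
            return real(regimen, *args, **kwargs)

        monkeypatch.setattr(cohort_mod, "simulate_to_washout", flaky)
        records = [
            fp.CohortRecord("ok", 100.0, 1.0),
            fp.CohortRecord("bad", 777.0, 1.0),
        ]
        with pytest.warns(UserWarning, match="bad"):
            result = fp.simulate_cohort(records)
        assert [r.id for r in result] == ["ok"]
        assert result.failures[0][0] == "bad"

    def test_record_validation(self):
        with pytest.raises(ValueError):
            fp.CohortRecord("x", 0.0, 1.0)
        with pytest.raises(ValueError, match="toxicity"):
            fp.CohortRecord("x", 1.0, 1.0, toxicity="fatal")


class TestBinnedFraction:
    def test_all_negative_rows(self):
        rows = [row(0.5, 1, "none"), row(1.5, 1, "none")]
        table = fp.binned_fraction(rows)
        assert table.n_total.tolist() == [1, 1]
        assert table.fraction_with_effect.tolist() == [0.0, 0.0]

    def test_count_ratio_in_one_bin(self):
        rows = [row(3.5, 1, "nlt"), row(3.5, 1, "nlt"), row(3.5, 1, "nlt"),
                row(3.5, 1, "none")]
        table = fp.binned_fraction(rows)
        assert table.n_total[3] == 4
        assert table.fraction_with_effect[3] == pytest.approx(0.75)

    def test_saturated_bin(self):
        rows = [row(5.2, 1, "nlt"), row(5.9, 1, "nlt")]
        table = fp.binned_fraction(rows)
        assert table.fraction_with_effect[5] == pytest.approx(1.0)

    def test_counts_conserved_and_permutation_invariant(self):
        rng = np.random.default_rng(7)
        rows = [
            row(c, 1, "nlt" if rng.random() < 0.4 else "none")
            for c in rng.uniform(0, 8, 60)
        ]
        t1 = fp.binned_fraction(rows)
        assert t1.n_total.sum() == 60
        rng.shuffle(rows)
        t2 = fp.binned_fraction(rows)
        assert np.array_equal(t1.n_total, t2.n_total)
        assert np.array_equal(t1.n_with_effect, t2.n_with_effect)

    def test_empty_bins_have_nan_fraction(self):
        rows = [row(0.5, 1, "nlt"), row(4.5, 1, "none")]
        table = fp.binned_fraction(rows)
        assert np.isnan(table.fraction_with_effect[2])
        assert table.n_total[2] == 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fp.binned_fraction([])
        with pytest.raises(ValueError):
            fp.binned_fraction([row(1, 1, "none")], bin_width_mg_per_L=0.0)


class TestFitStump:
    def test_css_split_at_midpoint(self):
        rows = [
            row(c, 50.0, "lt" if lab else "none")
            for c, lab in zip([1, 2, 5, 7, 8], [0, 0, 0, 1, 1])
        ]
        m = fp.fit_stump(rows)
        assert m.feature == "css"
        assert m.threshold == pytest.approx(6.0)
        assert m.counts_below == (3, 0)
        assert m.counts_above == (0, 2)
        assert m.leaf_probabilities == (0.0, 1.0)

    def test_single_class_degenerate(self):
        rows = [row(c, 1, "none") for c in (1, 2, 3)]
        m = fp.fit_stump(rows)
        assert m.is_degenerate
        pred = fp.predict_stump(m, css=100.0)
        assert not pred.positive
        assert pred.probability == 0.0

    def test_perfect_css_beats_overlapping_auc(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(30):
            lab = i < 15
            css = rng.uniform(7, 10) if lab else rng.uniform(1, 5)
            auc = rng.uniform(20, 100)  # overlapping, uninformative
            rows.append(row(css, auc, "lt" if lab else "none"))
        m = fp.fit_stump(rows)
        assert m.feature == "css"
        assert m.impurity_gain == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(30))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        rows = [
            row(
                float(abs(rng.choice([1.0, 2.5, 4.0, 6.0, 9.0]) + rng.normal(0, 2))),
                float(rng.uniform(5, 150)),
                "lt" if rng.random() < 0.4 else "none",
            )
            for _ in range(n)
        ]
        positive = lambda t: t is Toxicity.LIFE_THREATENING
        oracle = brute_force_stump(rows, positive)
        m = fp.fit_stump(rows, positive)
        if oracle is None:
            assert m.is_degenerate
        else:
            gain, fi, thr = oracle
            assert m.feature == ("css", "auc")[fi]
            assert m.threshold == pytest.approx(thr)
            assert m.impurity_gain == pytest.approx(gain)

    def test_agrees_with_sklearn_tree(self):
        """Cross-check feature/threshold against an independent CART fit."""
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(42)
        for _ in range(5):
            n = 40
            css = rng.uniform(0, 10, n)
            aucv = rng.uniform(0, 150, n)
            y = (css + rng.normal(0, 1.0, n)) > 5.5
            if y.all() or not y.any():
                continue
            rows = [
                row(c, a, "lt" if yy else "none")
                for c, a, yy in zip(css, aucv, y)
            ]
            m = fp.fit_stump(rows)
            X = np.column_stack([css, aucv])
            tree = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
            assert ("css", "auc")[tree.tree_.feature[0]] == m.feature
            assert tree.tree_.threshold[0] == pytest.approx(m.threshold, rel=1e-6)

    def test_invariant_under_monotone_transform_of_unselected_feature(self):
        rows = [
            row(c, a, "lt" if lab else "none")
            for c, a, lab in zip(
                [1, 2, 5, 7, 8], [30, 90, 10, 70, 50], [0, 0, 0, 1, 1]
            )
        ]
        m1 = fp.fit_stump(rows)
        assert m1.feature == "css"
        transformed = [
            fp.ExposureToxicityRow(
                r.id, r.css_mg_per_L, np.exp(r.auc_mg_h_per_L / 30.0), r.toxicity
            )
            for r in rows
        ]
        m2 = fp.fit_stump(transformed)
        assert (m2.feature, m2.threshold) == (m1.feature, m1.threshold)
        assert m2.counts_below == m1.counts_below


class TestPredictStump:
    def test_leaf_probabilities(self):
        # a near-pure split: low risk below 6 mg/L, high risk above
        m = fp.StumpModel(
            feature="css",
            threshold=6.0,
            counts_below=(97, 3),
            counts_above=(14, 86),
            impurity_gain=0.3,
            n_samples=200,
            n_positive=89,
        )
        below = fp.predict_stump(m, css=5.9)
        above = fp.predict_stump(m, css=6.1)
        assert below.probability == pytest.approx(0.03)
        assert not below.positive
        assert above.probability == pytest.approx(0.86)
        assert above.positive

    def test_row_input(self):
        m = fp.StumpModel("auc", 50.0, (5, 0), (0, 5), 0.5, 10, 5)
        r = row(3.0, 80.0, "none")
        assert fp.predict_stump(m, r).positive

    def test_missing_feature_rejected(self):
        m = fp.StumpModel("css", 6.0, (5, 0), (0, 5), 0.5, 10, 5)
        with pytest.raises(ValueError, match="missing"):
            fp.predict_stump(m, auc=10.0)


class TestCsvRoundtrip:
    def test_cohort_csv(self, tmp_path):
        records = [
            fp.CohortRecord("a", 1000.0, 24.0, 73.0, Toxicity.NONE),
            fp.CohortRecord("b", 3052.0, 2.0, 49.0, Toxicity.LIFE_THREATENING),
        ]
        path = tmp_path / "cohort.csv"
        fp.write_cohort_csv(records, path, header_lines=["test"])
        assert fp.read_cohort_csv(path) == records

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,dose_mg\nx,1\n")
        with pytest.raises(ValueError, match="missing columns"):
            fp.read_cohort_csv(path)
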