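"""Filter-stack and cutpoint-calibration tests.

ROC cutpoints are checked against an exhaustive threshold search written as
a plain loop; the CDA cutpoint against a hand-enumerated ECDF table.
"""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import proximap as pm
from proximap.errors import ValidationError
from proximap.filtering import label_recall
from proximap.io_formats import GoldStandard
from tests.conftest import make_table


def roc_bruteforce(scores, labels):
    """Exhaustive Youden-J search over observed thresholds (keep iff >= t)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    best_t, best_j = None, -np.inf
    for t in sorted(set(scores)):
        sens = ((scores >= t) & (labels == 1)).sum() / (labels == 1).sum()
        spec = ((scores < t) & (labels == 0)).sum() / (labels == 0).sum()
        j = sens + spec - 1
        if j > best_j:  # strict: first (smallest) threshold wins ties
            best_t, best_j = t, j
    return best_t, best_j


FILTER_ROWS = [
    # bait, prey, line, avg_spec, avg_p, reps
    ("B1", "KEEP_HEK", "HEK293", 5.0, 0.96, None),
    ("B1", "LOWP", "HEK293", 50.0, 0.80, None),
    ("B1", "LOWSPEC", "HEK293", 3.0, 0.99, None),
    ("B1", "KRT1", "HEK293", 50.0, 0.99, None),
    ("B1", "KEEP_HELA", "HeLa", 5.0, 0.96, None),
]


class TestApplyFilters:
    def make(self):
        return make_table(FILTER_ROWS, controls={})

    def test_conjunction_and_per_line_thresholds(self):
        res = pm.apply_filters(self.make(), pm.FilterConfig())
        kept = set(res.kept["prey"])
        # HEK293 record at AvgSpec 5 >= 4.5 kept; same counts in HeLa (min 6) dropped
        assert "KEEP_HEK" in kept
        assert "KEEP_HELA" not in kept
        assert "LOWP" not in kept and "LOWSPEC" not in kept

    def test_blocklist_attribution(self):
        res = pm.apply_filters(self.make(), pm.FilterConfig())
        assert "KRT1" not in set(res.kept["prey"])
        assert res.attrition["removed_blocklist"] == 1
        assert res.check_accounting()

    def test_monotone_in_thresholds(self):
        base = pm.apply_filters(self.make(), pm.FilterConfig())
        tighter = pm.apply_filters(
            self.make(), pm.FilterConfig(avg_p_min=0.98))
        assert set(map(tuple, tighter.kept[["bait", "prey"]].values)) <= set(
            map(tuple, base.kept[["bait", "prey"]].values))

    def test_missing_cell_line_threshold_errors(self):
        rows = [("B1", "P", "U2OS", 5.0, 0.99, None)]
        with pytest.raises(ValidationError, match="U2OS"):
            pm.apply_filters(make_table(rows, controls={}), pm.FilterConfig())

    def test_random_tables_order_free(self, rng):
        """Conjunctive filtering is order-free: survivors satisfy all predicates."""
        for _ in range(10):
            n = 50
            rows = [
                (f"B{rng.integers(3)}", f"P{i}", "HEK293",
                 float(rng.integers(0, 20)), float(rng.random()), None)
                for i in range(n)
            ]
            t = make_table(rows, controls={})
            cfg = pm.FilterConfig()
            res = pm.apply_filters(t, cfg)
            df = t.df
            expect = df[(df.avg_p >= 0.95) & (df.avg_spec >= 4.5)
                        & ~df.prey.isin(cfg.blocklist)]
            assert set(res.kept["prey"]) == set(expect["prey"])
            assert res.check_accounting()


class TestLabelRecall:
    def test_labels_and_bait_restriction(self):
        rows = [
            ("ARF1", "GBF1", "HEK293", 9.0, 0.99, None),
            ("ARF1", "XYZ", "HEK293", 5.0, 0.99, None),
            ("ARL2", "TBCD", "HEK293", 30.0, 0.99, None),
        ]
        gold = GoldStandard(edges={("ARF1", "GBF1")}, bait_subset={"ARF1"})
        out = label_recall(make_table(rows, controls={}).df, gold)
        assert set(out["bait"]) == {"ARF1"}
        got = out.set_index("prey")["label"]
        assert got["GBF1"] == 1 and got["XYZ"] == 0

    def test_no_positives_errors(self):
        rows = [("ARF1", "XYZ", "HEK293", 5.0, 0.99, None)]
        gold = GoldStandard(edges={("ARF1", "GBF1")}, bait_subset={"ARF1"})
        with pytest.raises(ValidationError, match="positive"):
            label_recall(make_table(rows, controls={}).df, gold)


class TestROC:
    def test_perfect_separation(self):
        rep = pm.roc_cutpoint([10, 12, 1, 2], [1, 1, 0, 0])
        assert rep.auc == pytest.approx(1.0)
        assert rep.roc_cutpoint == pytest.approx(10.0)

    def test_hand_enumerated_example(self):
        # positives {3, 8}, negatives {2, 5}: max J = 0.5 at t in {3, 8}; smallest wins
        rep = pm.roc_cutpoint([3, 8, 2, 5], [1, 1, 0, 0])
        assert rep.roc_cutpoint == pytest.approx(3.0)
        assert rep.roc_points["youden_j"].max() == pytest.approx(0.5)

    def test_equals_bruteforce_on_random_instances(self, rng):
        for _ in range(25):
            n = int(rng.integers(10, 1000))
            scores = rng.integers(0, 40, n).astype(float)
            labels = (rng.random(n) < 0.3).astype(int)
            if labels.sum() in (0, n):
                continue
            rep = pm.roc_cutpoint(scores, labels)
            t, j = roc_bruteforce(scores, labels)
            assert rep.roc_cutpoint == pytest.approx(t)
            assert rep.roc_points["youden_j"].max() == pytest.approx(j)
            assert rep.auc == pytest.approx(roc_auc_score(labels, scores))

    def test_null_auc_near_half(self, rng):
        scores = rng.normal(size=10000)
        labels = rng.integers(0, 2, 10000)
        rep = pm.roc_cutpoint(scores, labels)
        assert 0.45 <= rep.auc <= 0.55

    def test_single_class_errors(self):
        with pytest.raises(ValidationError):
            pm.roc_cutpoint([1, 2, 3], [1, 1, 1])


class TestCDA:
    def test_perfect_separation_gap_one(self):
        rep = pm.cda_cutpoint([10, 12, 1, 2], [1, 1, 0, 0])
        assert rep.cda_cutpoint == pytest.approx(2.0)  # largest negative score
        assert rep.cda_curve["gap"].max() == pytest.approx(1.0)

    def test_identical_distributions_warn(self):
        with pytest.warns(UserWarning, match="indistinguishable"):
            rep = pm.cda_cutpoint([1, 2, 1, 2], [1, 1, 0, 0])
        assert rep.cda_cutpoint == pytest.approx(1.0)

    def test_hand_ecdf_table(self):
        # pos {3, 8}, neg {2, 5}: gaps at s = 2,3,5,8 are .5, 0, .5, 0 -> smallest argmax 2
        rep = pm.cda_cutpoint([3, 8, 2, 5], [1, 1, 0, 0])
        assert rep.cda_cutpoint == pytest.approx(2.0)
        assert rep.cda_curve["gap"].tolist() == pytest.approx([0.5, 0.0, 0.5, 0.0])


class TestCalibrate:
    def build_screen(self):
        """Deterministic labelled screen: positives at AvgSpec >= 5, negatives below,
        except two high negatives that cap precision at low thresholds."""
        rows, edges = [], set()
        for i in range(20):
            prey = f"POS{i}"
            rows.append(("ARF1", prey, "HEK293", 5.0 + i, 0.99, None))
            edges.add(("ARF1", prey))
        for i in range(20):
            rows.append(("ARF1", f"NEG{i}", "HEK293", 1.0 + (i % 4), 0.99, None))
        rows.append(("ARF1", "NEGHI", "HEK293", 30.0, 0.99, None))
        return make_table(rows, controls={}), GoldStandard(edges=edges,
                                                           bait_subset={"ARF1"})

    def test_top_rank_recovers_separation(self):
        table, gold = self.build_screen()
        cal = pm.calibrate(table, gold, grid_avg_spec=[1, 3, 5, 7],
                           grid_caax_ratio=[0.0], precision_target=0.95)
        top = cal.ranked.iloc[0]
        # by hand: a = 5 keeps all 20 positives + NEGHI -> precision 20/21 = 0.952,
        # recall 1.0; a = 3 keeps negatives 3,4 too -> precision < 0.95
        assert top["avg_spec_min"] == 5
        assert top["recall"] == pytest.approx(1.0)
        rep = cal.reports["avg_spec"]
        assert abs(rep.roc_cutpoint - 5.0) <= 2.0

    def test_single_point_grid(self):
        table, gold = self.build_screen()
        cal = pm.calibrate(table, gold, [4.5], [1.7])
        assert len(cal.ranked) == 1 and cal.ranked.iloc[0]["rank"] == 1

    def test_empty_grid_errors(self):
        table, gold = self.build_screen()
        with pytest.raises(ValidationError, match="grid"):
            pm.calibrate(table, gold, [], [1.7])

    def test_all_positive_labels_error(self):
        rows = [("ARF1", "P", "HEK293", 9.0, 0.99, None)]
        gold = GoldStandard(edges={("ARF1", "P")}, bait_subset={"ARF1"})
        with pytest.raises(ValidationError):
            pm.calibrate(make_table(rows, controls={}), gold, [1.0], [1.0])
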