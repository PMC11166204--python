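"""Scoring tests, anchored on an independent brute-force WD oracle."""

import math

import numpy as np
import pandas as pd
import pytest

import proximap as pm
from proximap.errors import ValidationError
from tests.conftest import make_table


def wd_oracle(avg_spec: np.ndarray, n_detect: np.ndarray):
    """Plain-loop evaluation of the WD definition on a bait x prey matrix."""
    k, n_preys = avg_spec.shape
    wd = np.zeros_like(avg_spec, dtype=float)
    for p in range(n_preys):
        col = avg_spec[:, p]
        detecting = [b for b in range(k) if col[b] > 0]
        f = len(detecting)
        if f == 0:
            continue
        vals = [col[b] for b in detecting]
        mean = sum(vals) / f
        if f > 1:
            sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (f - 1))
            omega = max(1.0, sd / mean)
        else:
            omega = 1.0
        for b in detecting:
            wd[b, p] = math.sqrt(col[b] * ((k / f) * omega) ** n_detect[b, p])
    return wd


def table_from_matrix(counts, cell_line="HEK293"):
    """counts: bait x prey x replicate integer array -> InteractionTable."""
    rows = []
    n_baits, n_preys, _ = counts.shape
    for b in range(n_baits):
        for p in range(n_preys):
            reps = tuple(int(c) for c in counts[b, p])
            if sum(reps) == 0:
                continue
            rows.append(
                (f"B{b:02d}", f"P{p:02d}", cell_line, float(np.mean(reps)), 0.99, reps)
            )
    return make_table(rows, controls={})


class TestWD:
    def test_uniform_prey_identity(self):
        # prey in all K baits at equal AvgSpec 9: K/f = 1, omega = 1, wd = 3
        rows = [(f"B{i}", "P", "HEK293", 9.0, 0.99, (9, 9)) for i in range(4)]
        wd = pm.compute_wd(make_table(rows, controls={}), "HEK293")
        assert np.allclose(wd["wd"], 3.0)

    def test_unique_reproducible_prey(self):
        # K = 4, f = 1, AvgSpec 8, n = 2 -> sqrt(8 * (4*1)^2) = sqrt(128)
        rows = [("B0", "P", "HEK293", 8.0, 0.99, (7, 9))] + [
            (f"B{i}", "Q", "HEK293", 1.0, 0.9, (1, 1)) for i in range(4)
        ]
        wd = pm.compute_wd(make_table(rows, controls={}), "HEK293")
        got = wd.set_index(["bait", "prey"])["wd"]
        assert got[("B0", "P")] == pytest.approx(math.sqrt(128.0))

    def test_zero_avg_spec_gives_zero_wd(self):
        rows = [("B0", "P", "HEK293", 0.0, 0.99, (0, 0)),
                ("B1", "P", "HEK293", 5.0, 0.99, (4, 6)),
                ("B0", "Q", "HEK293", 2.0, 0.9, (2, 2))]
        wd = pm.compute_wd(make_table(rows, controls={}), "HEK293")
        assert ("B0", "P") not in set(zip(wd["bait"], wd["prey"]))

    def test_matches_bruteforce_oracle_on_random_matrices(self, rng):
        """WD equals an independent loop evaluation on 50 random 6x20 screens."""
        for _ in range(50):
            counts = rng.negative_binomial(2, 0.25, size=(6, 20, 2)) * rng.integers(
                0, 2, size=(6, 20, 2)
            )
            table = table_from_matrix(counts)
            avg = counts.mean(axis=2)
            ndet = np.maximum((counts > 0).sum(axis=2), 1)
            expect = wd_oracle(avg, ndet)
            got = pm.compute_wd(table, "HEK293")
            got_m = np.zeros_like(avg)
            bi = {f"B{i:02d}": i for i in range(6)}
            pi = {f"P{i:02d}": i for i in range(20)}
            for b, p, _, w in got.itertuples(index=False):
                got_m[bi[b], pi[p]] = w
            assert np.allclose(got_m, expect, atol=1e-9)

    def test_monotone_in_avg_spec_and_frequency(self):
        # raising a unique prey's counts raises its wd; adding a detecting bait
        # (frequency up) lowers it
        base = [("B0", "P", "HEK293", 8.0, 0.99, None),
                ("B1", "Q", "HEK293", 3.0, 0.9, None)]
        hi = [("B0", "P", "HEK293", 16.0, 0.99, None),
              ("B1", "Q", "HEK293", 3.0, 0.9, None)]
        shared = base + [("B1", "P", "HEK293", 8.0, 0.9, None)]
        wd = lambda rows: pm.compute_wd(make_table(rows, controls={}), "HEK293").set_index(
            ["bait", "prey"])["wd"][("B0", "P")]
        assert wd(hi) > wd(base)
        assert wd(shared) < wd(base)

    def test_controls_excluded_from_k_and_f(self):
        rows = [
            ("B0", "P", "HEK293", 8.0, 0.99, None),
            ("B1", "Q", "HEK293", 2.0, 0.9, None),
            ("CTRL_GFP", "P", "HEK293", 50.0, 0.0, None),
        ]
        wd = pm.compute_wd(make_table(rows), "HEK293")
        got = wd.set_index(["bait", "prey"])["wd"]
        # K = 2 (controls out), f(P) = 1 despite the control detection
        assert got[("B0", "P")] == pytest.approx(math.sqrt(8.0 * 2.0))
        assert "CTRL_GFP" not in set(wd["bait"])


class TestWDS:
    def frame(self, line, pairs):
        return pd.DataFrame(
            [{"bait": b, "prey": p, "cell_line": line, "wd": w} for b, p, w in pairs]
        )

    def test_sum_and_absence_as_zero(self):
        a = self.frame("HEK293", [("B", "P", 5.0)])
        b = self.frame("HeLa", [("B", "P", 3.0), ("B", "Q", 4.2)])
        wds = pm.sum_wds(a, b).set_index(["bait", "prey"])["wds"]
        assert wds[("B", "P")] == pytest.approx(8.0)
        assert wds[("B", "Q")] == pytest.approx(4.2)

    def test_symmetric(self):
        a = self.frame("HEK293", [("B", "P", 5.0)])
        b = self.frame("HeLa", [("B", "Q", 2.0)])
        pd.testing.assert_frame_equal(pm.sum_wds(a, b), pm.sum_wds(b, a))

    def test_same_cell_line_rejected(self):
        a = self.frame("HEK293", [("B", "P", 5.0)])
        with pytest.raises(ValidationError, match="same cell line"):
            pm.sum_wds(a, a)


class TestCaaxRatio:
    def test_boundary_and_hand_values(self, small_table):
        r = pm.caax_ratio(small_table).set_index(["bait", "prey"])["caax_ratio"]
        assert r[("ARF6", "SNX1")] == pytest.approx(1.7)  # 17 / 10
        assert r[("ARF1", "COMMON")] == pytest.approx(1.5)  # 9 / 6
        assert np.isinf(r[("ARF1", "GBF1")])  # absent from CAAX

    def test_scale_equivariance(self, small_table):
        r1 = pm.caax_ratio(small_table)
        scaled = small_table.df.copy()
        scaled["avg_spec"] *= 3
        scaled["replicate_specs"] = scaled["replicate_specs"].map(
            lambda t: tuple(3 * c for c in t)
        )
        t2 = pm.InteractionTable(df=scaled, controls=small_table.controls)
        r2 = pm.caax_ratio(t2)
        assert np.allclose(r1["caax_ratio"], r2["caax_ratio"])

    def test_missing_caax_control_errors(self, small_table):
        t = pm.InteractionTable(
            df=small_table.df[small_table.df["bait"] != "CTRL_CAAX"].copy(),
            controls=small_table.controls,
        )
        with pytest.raises(ValidationError, match="HEK293"):
            pm.caax_ratio(t)


class TestLog2FC:
    def test_hand_values(self):
        rows = [
            ("B0", "EQ", "HEK293", 7.0, 0.99, None),
            ("B0", "NEW", "HEK293", 15.0, 0.99, None),
            ("B0", "DOWN", "HEK293", 0.0, 0.5, None),
            ("CTRL_EMPTY", "EQ", "HEK293", 7.0, 0.0, None),
            ("CTRL_GFP", "EQ", "HEK293", 7.0, 0.0, None),
            ("CTRL_EMPTY", "DOWN", "HEK293", 3.0, 0.0, None),
            ("CTRL_GFP", "DOWN", "HEK293", 3.0, 0.0, None),
        ]
        fc = pm.log2fc_controls(make_table(rows)).set_index("prey")["log2fc"]
        assert fc["EQ"] == pytest.approx(0.0)
        assert fc["NEW"] == pytest.approx(4.0)  # log2(16 / 1)
        assert fc["DOWN"] == pytest.approx(-2.0)  # log2(1 / 4)


class TestCBNP:
    def test_equal_complexity_identity(self):
        rows = [(f"B{i}", f"P{i}", "HEK293", 8.0, 0.99, None) for i in range(3)]
        out = pm.cbnp(make_table(rows, controls={}))
        assert np.allclose(out["cbnp"], out.merge(
            pd.DataFrame({"prey": [f"P{i}" for i in range(3)], "x": 8.0}),
            on="prey")["x"])

    def test_complexity_rescaling(self):
        rows = [("BIG", f"P{i}", "HEK293", 8.0, 0.99, None) for i in range(200)]
        rows += [("MED", f"P{i}", "HEK293", 5.0, 0.99, None) for i in range(100)]
        rows += [("SMALL", f"P{i}", "HEK293", 5.0, 0.99, None) for i in range(50)]
        out = pm.cbnp(make_table(rows, controls={}))
        big = out[out["bait"] == "BIG"]["cbnp"]
        assert np.allclose(big, 8.0 * 100 / 200)  # median N = 100, N(BIG) = 200

    def test_locality_under_count_doubling(self):
        rows = [("A", "P1", "HEK293", 4.0, 0.99, None),
                ("B", "P2", "HEK293", 6.0, 0.99, None)]
        before = pm.cbnp(make_table(rows, controls={}))
        rows2 = [("A", "P1", "HEK293", 8.0, 0.99, None),
                 ("B", "P2", "HEK293", 6.0, 0.99, None)]
        after = pm.cbnp(make_table(rows2, controls={}))
        b_before = before[before["bait"] == "B"]["cbnp"].iloc[0]
        b_after = after[after["bait"] == "B"]["cbnp"].iloc[0]
        assert b_before == pytest.approx(b_after)


def test_score_table_single_line_wds_equals_wd(small_table):
    scores = pm.score_table(small_table)
    assert np.allclose(scores["wd"], scores["wds"])
    assert {"caax_ratio", "log2fc", "cbnp"} <= set(scores.columns)
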