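"""Genotype QC, double-recombinant cleaning, binning, and map building."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from growthqtl import linkage, simulate as sim


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------

class TestKosambi:
    def test_known_values(self):
        assert linkage.kosambi_cm(0.0) == 0.0
        assert linkage.kosambi_cm(0.25) == pytest.approx(25.0 * np.log(3.0), abs=1e-12)
        assert linkage.kosambi_r(0.0) == 0.0

    def test_domain_error(self):
        with pytest.raises(ValueError):
            linkage.kosambi_cm(0.5)
        with pytest.raises(ValueError):
            linkage.kosambi_cm(-0.01)

    @given(st.floats(0.0, 0.499))
    def test_round_trip(self, r):
        assert linkage.kosambi_r(linkage.kosambi_cm(r)) == pytest.approx(r, abs=1e-12)

    def test_strictly_increasing_and_convex(self):
        r = np.linspace(0.0, 0.49, 200)
        d = linkage.kosambi_cm(r)
        assert np.all(np.diff(d) > 0)
        assert np.all(np.diff(d, 2) > -1e-9)  # convex

    def test_ril_inversion(self):
        assert linkage.ril_r_from_R(0.0) == 0.0
        assert linkage.ril_r_from_R(1.0 / 3.0) == pytest.approx(0.25, abs=1e-12)
        # forward and back
        for r in (0.01, 0.1, 0.3):
            assert linkage.ril_r_from_R(linkage.ril_R_from_r(r)) == pytest.approx(r)


# ---------------------------------------------------------------------------
# missing-data filtering
# ---------------------------------------------------------------------------

def _toy_matrix():
    rng = np.random.default_rng(0)
    arr = rng.choice([0, 2], size=(6, 10)).astype(np.int8)
    geno = pd.DataFrame(arr, index=[f"L{i}" for i in range(6)],
                        columns=[f"m{j}" for j in range(10)])
    geno.iloc[0, :4] = -1  # line 0: 40% missing
    geno.iloc[2, 5] = -1   # marker m5: 20% missing among surviving lines
    return geno


class TestFilterMissing:
    def test_toy_counts(self):
        geno = _toy_matrix()
        out, report = linkage.filter_missing(geno)
        assert out.shape == (5, 9)
        assert report["lines_dropped"] == 1 and report["markers_dropped"] == 1
        assert "L0" in report["dropped_lines"] and "m5" in report["dropped_markers"]

    def test_complete_matrix_unchanged(self):
        geno = _toy_matrix().replace(-1, 0)
        out, report = linkage.filter_missing(geno)
        pd.testing.assert_frame_equal(out, geno)

    def test_exact_threshold_retained(self):
        # one missing call out of 10 = exactly 10% -> strict > keeps it
        geno = _toy_matrix().replace(-1, 0)
        geno.iloc[1, 3] = -1
        out, _ = linkage.filter_missing(geno)
        assert "L1" in out.index

    def test_everything_filtered_is_an_error(self):
        geno = pd.DataFrame(-np.ones((3, 3), dtype=np.int8))
        with pytest.raises(ValueError):
            linkage.filter_missing(geno)


class TestSetHetMissing:
    def test_example_row(self):
        geno = pd.DataFrame([[0, 1, 2, -1]])
        out = linkage.set_het_missing(geno)
        assert out.iloc[0].tolist() == [0, -1, 2, -1]

    def test_no_hets_identical(self):
        geno = _toy_matrix()
        pd.testing.assert_frame_equal(linkage.set_het_missing(geno), geno)

    def test_missing_increases_by_het_fraction(self):
        rng = np.random.default_rng(1)
        geno = pd.DataFrame(rng.choice([0, 1, 2], size=(50, 40)))
        h = (geno.to_numpy() == 1).mean()
        before = (geno.to_numpy() == -1).mean()
        after = (linkage.set_het_missing(geno).to_numpy() == -1).mean()
        assert after - before == pytest.approx(h, abs=1e-12)


# ---------------------------------------------------------------------------
# double-recombinant cleaning
# ---------------------------------------------------------------------------

def _dense_map(n_markers=101, length_cm=100.0):
    return sim.MapSpec([("1", length_cm, n_markers)])


def exhaustive_min_flips(calls, bp, min_region_bp):
    """Oracle: minimum number of flips so every run's crosspoint region
    satisfies the minimum-size constraint (exhaustive over 0/2 sequences)."""
    m = len(calls)
    best = None
    for cand in itertools.product((0, 2), repeat=m):
        runs = []
        for k, a in enumerate(cand):
            if runs and runs[-1][0] == a:
                runs[-1][1].append(k)
            else:
                runs.append([a, [k]])
        ok = True
        for i, (_, idx) in enumerate(runs):
            left = (0.5 * (bp[runs[i - 1][1][-1]] + bp[idx[0]])
                    if i > 0 else bp[idx[0]])
            right = (0.5 * (bp[idx[-1]] + bp[runs[i + 1][1][0]])
                     if i < len(runs) - 1 else bp[idx[-1]])
            if len(runs) > 1 and right - left < min_region_bp:
                ok = False
                break
        if ok:
            flips = sum(1 for a, b in zip(cand, calls) if a != b)
            best = flips if best is None else min(best, flips)
    return best


class TestCleanDoubleRecombinants:
    def test_single_island_flipped_no_breakpoint(self):
        ms = _dense_map(2001)  # 0.05 cM spacing: island region < 0.1% rule
        mmap = ms.marker_map()
        calls = np.full(2001, 2, dtype=np.int8)
        calls[1000] = 0  # isolated opposite call
        geno = pd.DataFrame([calls], index=["L1"], columns=mmap["marker"])
        cleaned, bkp, rep = linkage.clean_double_recombinants(geno, mmap)
        assert (cleaned.iloc[0] == 2).all()
        assert bkp.empty
        assert rep["calls_corrected"] == 1

    def test_error_free_lines_untouched(self):
        ms = _dense_map(201)
        geno, mmap, true_bkp = sim.simulate_ril_population(ms, 60, het_rate=0, seed=3)
        cleaned, bkp, rep = linkage.clean_double_recombinants(geno, mmap)
        assert rep["calls_corrected"] == 0
        pd.testing.assert_frame_equal(cleaned, geno)

    def test_true_crossover_breakpoint_within_one_interval(self):
        ms = _dense_map(101)
        geno, mmap, true_bkp = sim.simulate_ril_population(ms, 80, het_rate=0, seed=4)
        cleaned, bkp, _ = linkage.clean_double_recombinants(geno, mmap)
        # every reported breakpoint should be close to a true one
        interval_cm = 1.0
        for _, row in bkp.iterrows():
            tb = true_bkp[true_bkp["line"] == row["line"]]["pos_cm"]
            assert (tb - row["pos_cm"]).abs().min() <= interval_cm

    def test_idempotent(self):
        ms = _dense_map(201)
        geno, mmap, _ = sim.simulate_ril_population(ms, 40, het_rate=0, seed=5)
        rng = np.random.default_rng(6)
        arr = geno.to_numpy().copy()
        err = rng.random(arr.shape) < 0.01
        arr[err] = 2 - arr[err]
        noisy = pd.DataFrame(arr, index=geno.index, columns=geno.columns)
        c1, b1, _ = linkage.clean_double_recombinants(noisy, mmap)
        c2, b2, rep2 = linkage.clean_double_recombinants(c1, mmap)
        pd.testing.assert_frame_equal(c1, c2)
        assert rep2["calls_corrected"] == 0

    def test_matches_exhaustive_oracle_flip_count(self):
        ms = _dense_map(9, length_cm=0.8)  # dense: every run region tiny
        mmap = ms.marker_map()
        bp = mmap["bp"].to_numpy(dtype=float)
        min_region_bp = 0.05 * (bp[-1] - bp[0])
        rng = np.random.default_rng(7)
        for _ in range(20):
            calls = rng.choice([0, 2], size=9).astype(np.int8)
            geno = pd.DataFrame([calls], index=["L1"], columns=mmap["marker"])
            cleaned, _, rep = linkage.clean_double_recombinants(
                geno, mmap, min_region_frac=0.05)
            oracle = exhaustive_min_flips(calls, bp, min_region_bp)
            flips = int((cleaned.iloc[0].to_numpy() != calls).sum())
            assert flips >= oracle
            assert flips <= oracle + 2  # greedy absorption near-optimal

    def test_error_correction_rate_on_dense_data(self):
        """1% random errors: nearly all corrected, few spurious breakpoints."""
        ms = _dense_map(2001, length_cm=100.0)
        geno, mmap, true_bkp = sim.simulate_ril_population(ms, 50, het_rate=0, seed=8)
        rng = np.random.default_rng(9)
        arr = geno.to_numpy().copy()
        err = rng.random(arr.shape) < 0.01
        arr[err] = 2 - arr[err]
        noisy = pd.DataFrame(arr, index=geno.index, columns=geno.columns)
        cleaned, bkp, _ = linkage.clean_double_recombinants(noisy, mmap)
        fixed = ((cleaned.to_numpy() == geno.to_numpy()) & err).sum()
        assert fixed / err.sum() >= 0.95


# ---------------------------------------------------------------------------
# marker binning
# ---------------------------------------------------------------------------

class TestBinRedundantMarkers:
    def _geno(self):
        rng = np.random.default_rng(10)
        base = rng.choice([0, 2], size=(30, 4)).astype(np.int8)
        cols = {}
        cols["a1"] = base[:, 0].copy()
        dup = base[:, 0].copy()
        dup[:3] = -1  # duplicate of a1 with more missing
        cols["a2"] = dup
        cols["b1"] = base[:, 1]
        cols["c1"] = base[:, 2]
        cols["c2"] = base[:, 2].copy()
        geno = pd.DataFrame(cols)
        mmap = pd.DataFrame({
            "marker": list(cols), "chrom": "1",
            "bp": [100, 200, 300, 400, 500], "cm": [0.0, 0.1, 0.2, 0.3, 0.4],
        })
        return geno, mmap

    def test_representative_has_fewest_missing(self):
        geno, mmap = self._geno()
        binned, _, membership = linkage.bin_redundant_markers(geno, mmap)
        assert "a1" in binned.columns and "a2" not in binned.columns

    def test_all_distinct_no_binning(self):
        rng = np.random.default_rng(11)
        geno = pd.DataFrame(rng.choice([0, 2], size=(40, 6)),
                            columns=[f"m{i}" for i in range(6)])
        while geno.T.duplicated().any():  # ensure truly distinct
            geno = pd.DataFrame(rng.choice([0, 2], size=(40, 6)),
                                columns=[f"m{i}" for i in range(6)])
        mmap = pd.DataFrame({"marker": geno.columns, "chrom": "1",
                             "bp": np.arange(6) * 100 + 1,
                             "cm": np.arange(6) * 1.0})
        binned, _, _ = linkage.bin_redundant_markers(geno, mmap)
        assert list(binned.columns) == list(geno.columns)

    def test_matches_brute_force_group_count(self):
        geno, mmap = self._geno()
        _, _, membership = linkage.bin_redundant_markers(geno, mmap)
        # brute force: O(m^2) pairwise identity on shared non-missing lines
        cols = list(geno.columns)
        X = geno.to_numpy()
        same = np.zeros((5, 5), dtype=bool)
        for i in range(5):
            for j in range(5):
                both = (X[:, i] != -1) & (X[:, j] != -1)
                same[i, j] = both.any() and np.array_equal(X[both, i], X[both, j])
        expected_groups = {frozenset(np.flatnonzero(same[i]).tolist()) for i in range(5)}
        assert membership["bin"].nunique() == len(expected_groups)


# ---------------------------------------------------------------------------
# recombination estimation and map building
# ---------------------------------------------------------------------------

class TestRecombination:
    def test_perfect_linkage(self):
        geno = pd.DataFrame({"a": [0, 2, 0, 2] * 10, "b": [0, 2, 0, 2] * 10})
        R, r, n = linkage.estimate_recombination(geno, "a", "b")
        assert R == 0.0 and r == 0.0 and n == 40

    def test_algebraic_inversion(self):
        # R = 1/3 corresponds to meiotic r = 0.25
        a = [0] * 20 + [2] * 10
        b = [0] * 10 + [2] * 20
        geno = pd.DataFrame({"a": a, "b": b})
        R, r, _ = linkage.estimate_recombination(geno, "a", "b")
        assert R == pytest.approx(1.0 / 3.0)
        assert r == pytest.approx(0.25)

    def test_simulation_recovery(self):
        d = linkage.kosambi_cm(0.10)
        ms = sim.MapSpec([("1", d, 2)])
        geno, _, _ = sim.simulate_ril_population(ms, 10000, het_rate=0, seed=13)
        _, r, _ = linkage.estimate_recombination(geno, *geno.columns)
        assert r == pytest.approx(0.10, abs=0.008)

    def test_too_few_informative(self):
        geno = pd.DataFrame({"a": [0, 2, -1] * 3, "b": [0, -1, 2] * 3})
        with pytest.raises(ValueError):
            linkage.estimate_recombination(geno, "a", "b")


class TestBuildMap:
    def test_simulated_length_recovered(self, two_chrom_ril):
        geno, mmap, _ = two_chrom_ril
        gmap, intervals = linkage.build_map(geno, mmap)
        lengths = linkage.map_lengths(gmap)
        for chrom in ("1", "2"):
            assert lengths[chrom] == pytest.approx(100.0, abs=10.0)
        assert not intervals["capped"].any()

    def test_perfectly_linked_markers_zero_distance(self):
        geno = pd.DataFrame({"a": [0, 2] * 15, "b": [0, 2] * 15})
        mmap = pd.DataFrame({"marker": ["a", "b"], "chrom": "1",
                             "bp": [1, 1000], "cm": [0.0, 0.0]})
        gmap, _ = linkage.build_map(geno, mmap)
        assert gmap["cm"].tolist() == [0.0, 0.0]

    def test_unlinked_interval_capped(self):
        rng = np.random.default_rng(14)
        geno = pd.DataFrame({"a": rng.choice([0, 2], 500),
                             "b": rng.choice([0, 2], 500)})
        mmap = pd.DataFrame({"marker": ["a", "b"], "chrom": "1",
                             "bp": [1, 10_000], "cm": [0.0, 500.0]})
        gmap, intervals = linkage.build_map(geno, mmap)
        if intervals["capped"].any():
            assert np.isfinite(gmap["cm"]).all()

    def test_single_marker_chromosome_error(self):
        geno = pd.DataFrame({"a": [0, 2] * 15})
        mmap = pd.DataFrame({"marker": ["a"], "chrom": "1", "bp": [1], "cm": [0.0]})
        with pytest.raises(ValueError):
            linkage.build_map(geno, mmap)

    def test_cm_nondecreasing_in_bp_order(self, small_ril):
        geno, mmap, _ = small_ril
        gmap, _ = linkage.build_map(geno, mmap)
        assert (gmap.groupby("chrom")["cm"].diff().dropna() >= 0).all()
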