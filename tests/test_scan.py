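"""Genotype probabilities, interval mapping, ICIM background control, calls."""

import numpy as np
import pandas as pd
import pytest

from growthqtl import linkage, scan as sc, simulate as sim
from conftest import meiosis_ril, marker_score


class TestGenotypeProbabilities:
    def test_observed_marker_is_certain(self, small_ril):
        geno, mmap, _ = small_ril
        gp = sc.genotype_probabilities(geno, mmap)
        marker_pos = gp.positions["is_marker"].to_numpy()
        mcols = gp.positions.loc[marker_pos, "left_marker"]
        for j, m in zip(np.flatnonzero(marker_pos)[:5], mcols[:5]):
            calls = geno[m].to_numpy()
            obs = (calls == 0) | (calls == 2)
            expect = (calls[obs] == 2).astype(float)
            assert np.allclose(gp.pB[obs, j], expect)

    def test_rows_sum_to_one_and_bounded(self, small_ril):
        geno, mmap, _ = small_ril
        gp = sc.genotype_probabilities(geno, mmap)
        assert np.all((gp.pB >= 0) & (gp.pB <= 1))

    def test_all_missing_line_gets_priors(self, small_ril):
        geno, mmap, _ = small_ril
        blank = geno.copy()
        blank.iloc[0, :] = -1
        gp = sc.genotype_probabilities(blank, mmap)
        assert np.allclose(gp.pB[0], 0.5)

    def test_midpoint_matches_meiosis_oracle(self):
        """P(mid class | equal flanks) vs brute-force selfed meiosis."""
        r = 0.10
        d = linkage.kosambi_cm(r)
        n = 100_000
        oracle = meiosis_ril(np.array([r, r]), n, generations=12, seed=21)
        hom = np.all(oracle != 1, axis=1)
        o = oracle[hom]
        both0 = (o[:, 0] == 0) & (o[:, 2] == 0)
        p_mid0 = (o[both0, 1] == 0).mean()
        mmap = pd.DataFrame({"marker": ["a", "b", "c"], "chrom": "1",
                             "bp": [1, 2, 3], "cm": [0.0, d, 2 * d]})
        geno = pd.DataFrame([[0, -1, 0]], index=["L1"], columns=["a", "b", "c"])
        gp = sc.genotype_probabilities(geno, mmap, step_cm=d)
        mid = gp.positions["cm"].sub(d).abs().idxmin()
        p_model = 1.0 - gp.pB[0, mid]
        assert p_model == pytest.approx(p_mid0, abs=0.01)

    def test_symmetric_flanks_give_half_between_opposite_calls(self):
        mmap = pd.DataFrame({"marker": ["a", "b"], "chrom": "1",
                             "bp": [1, 2], "cm": [0.0, 20.0]})
        geno = pd.DataFrame([[0, 2]], index=["L1"], columns=["a", "b"])
        gp = sc.genotype_probabilities(geno, mmap, step_cm=10.0)
        mid = gp.positions["cm"].sub(10.0).abs().idxmin()
        assert gp.pB[0, mid] == pytest.approx(0.5)


def _qtl_phenotype(geno, marker, pve, rng):
    score = marker_score(geno[marker])
    a = 1.0
    sig = np.sqrt(a ** 2 * (1 - pve) / pve)
    return pd.Series(a * score + rng.normal(0, sig, len(score)),
                     index=geno.index)


class TestIntervalMapping:
    def test_constant_phenotype_zero_profile(self, small_ril):
        geno, mmap, _ = small_ril
        gp = sc.genotype_probabilities(geno, mmap)
        prof = sc.interval_mapping_scan(
            pd.Series(1.0, index=geno.index), gp)
        assert prof.attrs["zero_variance"]
        assert (prof["lod"] == 0).all()

    def test_marker_lod_equals_single_marker_regression(self, small_ril):
        """At fully informative markers the scan equals the two-class fit."""
        geno, mmap, _ = small_ril
        gp = sc.genotype_probabilities(geno, mmap)
        rng = np.random.default_rng(22)
        y = _qtl_phenotype(geno, geno.columns[10], 0.15, rng)
        prof = sc.interval_mapping_scan(y, gp)
        n = len(y)
        yc = y.to_numpy() - y.to_numpy().mean()
        tss = yc @ yc
        for m in geno.columns[::4]:
            x = marker_score(geno[m])
            xc = x - x.mean()
            slope = (yc @ xc) / (xc @ xc)
            rss1 = tss - slope * (yc @ xc)
            lod_oracle = 0.5 * n * np.log10(tss / rss1)
            i = prof.index[(prof["left_marker"] == m) & prof["is_marker"]][0]
            assert prof.loc[i, "lod"] == pytest.approx(lod_oracle, abs=1e-8)
            assert prof.loc[i, "additive"] == pytest.approx(slope, abs=1e-10)

    def test_lod_invariant_to_affine_phenotype(self, small_ril):
        geno, mmap, _ = small_ril
        gp = sc.genotype_probabilities(geno, mmap)
        rng = np.random.default_rng(23)
        y = _qtl_phenotype(geno, geno.columns[5], 0.2, rng)
        p1 = sc.interval_mapping_scan(y, gp)
        p2 = sc.interval_mapping_scan(3.0 * y + 7.0, gp)
        assert np.allclose(p1["lod"], p2["lod"], atol=1e-9)

    def test_positive_additive_means_parent_b_increases(self, small_ril):
        geno, mmap, _ = small_ril
        gp = sc.genotype_probabilities(geno, mmap)
        rng = np.random.default_rng(24)
        y = _qtl_phenotype(geno, geno.columns[10], 0.3, rng)  # B allele up
        prof = sc.interval_mapping_scan(y, gp)
        assert prof.loc[prof["lod"].idxmax(), "additive"] > 0

    def test_too_few_lines_rejected(self, small_ril):
        geno, mmap, _ = small_ril
        gp = sc.genotype_probabilities(geno, mmap)
        y = pd.Series(np.arange(5.0), index=geno.index[:5])
        with pytest.raises(ValueError):
            sc.interval_mapping_scan(y, gp)


class TestIcim:
    def test_no_selection_reduces_to_plain_im(self, small_ril):
        geno, mmap, _ = small_ril
        gp = sc.genotype_probabilities(geno, mmap)
        rng = np.random.default_rng(25)
        y = pd.Series(rng.normal(0, 1, geno.shape[0]), index=geno.index)
        icim = sc.icim_scan(y, gp, geno, pin=1e-12)  # nothing can enter
        plain = sc.interval_mapping_scan(y, gp)
        assert icim.attrs["selected_markers"] == []
        assert np.allclose(icim["lod"], plain["lod"], atol=1e-9)

    def test_own_interval_redetects_selected_qtl(self, small_ril):
        geno, mmap, _ = small_ril
        gp = sc.genotype_probabilities(geno, mmap)
        rng = np.random.default_rng(26)
        y = _qtl_phenotype(geno, geno.columns[10], 0.25, rng)
        icim = sc.icim_scan(y, gp, geno)
        plain = sc.interval_mapping_scan(y, gp)
        peak = plain["lod"].idxmax()
        assert icim.loc[peak, "lod"] == pytest.approx(
            plain.loc[peak, "lod"], rel=0.10)

    def test_background_adjustment_raises_power(self):
        """Second unlinked QTL adjusted away -> LOD at the first increases."""
        ms = sim.MapSpec([("1", 100.0, 11), ("2", 100.0, 11)])
        wins = 0
        n_runs = 100
        for s in range(n_runs):
            geno, mmap, _ = sim.simulate_ril_population(ms, 200, het_rate=0,
                                                        seed=1000 + s)
            gp = sc.genotype_probabilities(geno, mmap, step_cm=5.0)
            rng = np.random.default_rng(2000 + s)
            s1 = marker_score(geno["m1_006"])
            s2 = marker_score(geno["m2_006"])
            y = pd.Series(0.7 * s1 + 0.7 * s2 + rng.normal(0, 1, 200),
                          index=geno.index)
            chr1 = gp.positions["chrom"] == "1"
            icim = sc.icim_scan(y, gp, geno)
            plain = sc.interval_mapping_scan(y, gp)
            wins += icim.loc[chr1.to_numpy(), "lod"].max() >= \
                plain.loc[chr1.to_numpy(), "lod"].max()
        assert wins / n_runs >= 0.90

    def test_oversaturated_selection_aborts(self, small_ril):
        geno, mmap, _ = small_ril
        gp = sc.genotype_probabilities(geno.iloc[:30], mmap)
        rng = np.random.default_rng(27)
        y = pd.Series(rng.normal(0, 1, 30), index=geno.index[:30])
        with pytest.raises(RuntimeError):
            sc.icim_scan(y, gp, geno.iloc[:30], pin=1.0, pout=1.0)


def _profile(chrom, cms, lods, pves=None, adds=None):
    n = len(cms)
    return pd.DataFrame({
        "chrom": chrom, "cm": cms, "is_marker": False,
        "left_marker": "mL", "right_marker": "mR",
        "lod": lods, "additive": adds if adds is not None else np.ones(n),
        "pve": pves if pves is not None else np.full(n, 0.1), "n": 200,
    })


class TestCallQtl:
    def test_subthreshold_profile_yields_nothing(self):
        prof = _profile("1", np.arange(0, 100.0), np.full(100, 1.5))
        assert sc.call_qtl(prof).empty

    def test_single_peak_naming(self):
        cms = np.arange(0, 131.0)
        lods = 4.0 * np.exp(-0.5 * ((cms - 119) / 5.0) ** 2)
        prof = _profile("5", cms, lods)
        calls = sc.call_qtl(prof)
        assert len(calls) == 1
        assert calls.iloc[0]["name"] == "q5_119"
        assert calls.iloc[0]["ci_lo_cm"] <= 119 <= calls.iloc[0]["ci_hi_cm"]

    def test_two_separated_peaks(self):
        cms = np.arange(0, 101.0)
        lods = (4.0 * np.exp(-0.5 * ((cms - 20) / 4.0) ** 2)
                + 4.0 * np.exp(-0.5 * ((cms - 80) / 4.0) ** 2) + 0.5)
        prof = _profile("1", cms, lods)
        calls = sc.call_qtl(prof)
        assert len(calls) == 2
        assert sorted(round(c) for c in calls["peak_cm"]) == [20, 80]

    def test_pve_threshold_filters(self):
        cms = np.arange(0, 50.0)
        lods = 4.0 * np.exp(-0.5 * ((cms - 25) / 4.0) ** 2)
        prof = _profile("1", cms, lods, pves=np.full(50, 0.02))
        assert sc.call_qtl(prof).empty

    def test_peak_inside_support_interval(self):
        rng = np.random.default_rng(28)
        cms = np.arange(0, 100.0)
        lods = np.abs(rng.normal(0, 2, 100))
        prof = _profile("1", cms, lods)
        for _, c in sc.call_qtl(prof).iterrows():
            assert c["ci_lo_cm"] <= c["peak_cm"] <= c["ci_hi_cm"]
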