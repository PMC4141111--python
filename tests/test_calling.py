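"""Empirical-null genotype calling: p-values, q-values, thresholds, QC."""

import numpy as np
import pandas as pd
import pytest

from rhmap.calling import (CallingConfig, IntensityMatrix, call_genotypes,
                           call_panel, compute_imax, empirical_pvalues,
                           estimate_pi0, estimate_qvalues,
                           identify_negative_snps, merge_panels, qc_filter,
                           retention_profile)
from rhmap.panel import MISSING, RETAINED, UNRETAINED, RHPanel
from rhmap.simulate import (IntensityParams, example_genome,
                            simulate_fragments, simulate_intensities,
                            simulate_observations)


class TestImax:
    @pytest.mark.parametrize("a,b,expected", [
        (0.2, 0.8, 0.8),
        (0.5, 0.5, 0.5),   # tie
        (0.0, 0.0, 0.0),
    ])
    def test_values(self, a, b, expected):
        assert compute_imax(a, b) == expected

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            compute_imax(-0.1, 0.5)
        with pytest.raises(ValueError):
            compute_imax(np.nan, 0.5)


class TestEmpiricalPvalues:
    NEG = np.array([0.10, 0.20, 0.30, 0.40])

    def test_hand_counted_exceedances(self):
        # two of four negatives exceed 0.25
        assert empirical_pvalues([0.25], self.NEG)[0] == pytest.approx(0.5)

    def test_floor_at_one_over_nneg(self):
        assert empirical_pvalues([0.45], self.NEG)[0] == pytest.approx(0.25)

    def test_below_all_negatives_is_one(self):
        assert empirical_pvalues([0.05], self.NEG)[0] == pytest.approx(1.0)

    def test_tie_counts_as_non_exceeding(self):
        # "exceeds" is strict: a negative equal to the observation does not count
        assert empirical_pvalues([0.40], self.NEG)[0] == pytest.approx(0.25)

    def test_empty_null_is_an_error(self):
        with pytest.raises(ValueError, match="null"):
            empirical_pvalues([0.5], np.array([]))


class TestQvalues:
    def test_all_p_one(self):
        q, pi0 = estimate_qvalues(np.ones(10), lam=0.5)
        assert pi0 == pytest.approx(1.0)
        assert np.all(q == 1.0)

    def test_hand_evaluated_estimator(self):
        p = np.array([0.01, 0.02, 0.03, 0.90, 0.91, 0.95])
        q, pi0 = estimate_qvalues(p, lam=0.5)
        # pi0 = #{p > 0.5} / (6 * 0.5) = 3/3 = 1.0; q(0.01) = 1.0*6*0.01/1
        assert pi0 == pytest.approx(1.0)
        assert q[0] == pytest.approx(0.06)

    def test_monotone_in_p_and_bounded(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.001, 1, 500)
        q, _ = estimate_qvalues(p, lam=0.5)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all((q > 0) & (q <= 1))

    def test_pi0_clamped_with_warning(self):
        p = np.full(20, 0.99)
        with pytest.warns(UserWarning, match="clamped"):
            pi0 = estimate_pi0(p, lam=0.5)
        assert pi0 == 1.0

    def test_smoother_mode_close_to_fixed_lambda_on_uniform_nulls(self):
        rng = np.random.default_rng(1)
        p = np.concatenate([rng.uniform(0, 1, 4000), np.full(2000, 1e-4)])
        pi0_smooth = estimate_pi0(p)
        assert pi0_smooth == pytest.approx(4000 / 6000, abs=0.05)


class TestCallGenotypes:
    def test_retained_threshold(self):
        assert call_genotypes(np.array([0.005]), "ovine")[0] == RETAINED

    def test_array_specific_missing_band(self):
        # q = 0.07 is ambiguous on the sheep array, unretained on the bovine
        assert call_genotypes(np.array([0.07]), "ovine")[0] == MISSING
        assert call_genotypes(np.array([0.07]), "bovine")[0] == UNRETAINED

    def test_large_q_unretained(self):
        assert call_genotypes(np.array([0.50]), "ovine")[0] == UNRETAINED

    def test_unknown_array_rejected(self):
        with pytest.raises(ValueError, match="unknown array"):
            call_genotypes(np.array([0.5]), "porcine")


class TestQcFilter:
    def _calls(self, marker_retentions, n_clones=20):
        rng = np.random.default_rng(3)
        cols = []
        for ret in marker_retentions:
            n_ret = int(round(ret * n_clones))
            col = np.array([RETAINED] * n_ret + [UNRETAINED] * (n_clones - n_ret))
            cols.append(rng.permutation(col))
        return np.column_stack(cols).astype(np.int8)

    def test_high_retention_snp_dropped(self):
        # enough well-behaved markers that clone QC stays out of the way
        calls = self._calls([0.60] + [0.35] * 10)
        ids = ["hot"] + [f"ok{i}" for i in range(10)]
        panel, report = qc_filter(calls, [f"c{i}" for i in range(20)], ids)
        assert "hot" not in panel.marker_ids and "ok0" in panel.marker_ids
        row = report[report["id"] == "hot"].iloc[0]
        assert "retention>0.50" in row["reason"]

    def test_low_retention_snp_dropped(self):
        calls = self._calls([0.05] + [0.35] * 10)
        ids = ["dead"] + [f"ok{i}" for i in range(10)]
        panel, _ = qc_filter(calls, [f"c{i}" for i in range(20)], ids)
        assert "dead" not in panel.marker_ids and "ok0" in panel.marker_ids

    def test_hot_clone_dropped(self):
        calls = np.full((3, 10), UNRETAINED, dtype=np.int8)
        calls[0, :] = RETAINED          # 100% retention clone
        calls[1, :3] = RETAINED
        calls[2, :4] = RETAINED
        panel, report = qc_filter(calls, ["hot", "a", "b"],
                                  [f"m{i}" for i in range(10)])
        assert "hot" not in panel.clone_ids
        assert (report["entity"] == "clone").sum() == 1

    def test_all_clones_dropped_is_fatal(self):
        calls = np.full((2, 10), RETAINED, dtype=np.int8)
        with pytest.raises(ValueError, match="every clone"):
            qc_filter(calls, ["a", "b"], [f"m{i}" for i in range(10)])


class TestNegativeDetection:
    def test_two_mode_control_recovers_background_fraction(self):
        rng = np.random.default_rng(5)
        n = 5000
        is_neg = rng.random(n) < 0.2
        imax = np.where(is_neg, np.exp(rng.normal(-1.5, 0.4, n)),
                        np.exp(rng.normal(1.0, 0.4, n)))
        ids = [f"s{i}" for i in range(n)]
        neg = identify_negative_snps(imax, ids)
        assert len(neg) / n == pytest.approx(0.2, abs=0.02)

    def test_unimodal_control_falls_back_with_warning(self):
        rng = np.random.default_rng(6)
        imax = np.exp(rng.normal(1.0, 0.1, 2000))
        with pytest.warns(UserWarning, match="unimodal"):
            neg = identify_negative_snps(imax, [f"s{i}" for i in range(2000)])
        assert len(neg) == pytest.approx(100, abs=10)   # 5% quantile fallback


def test_calling_invariant_under_monotone_intensity_rescaling():
    """Only the rank of Imax against the negatives matters."""
    rng = np.random.default_rng(7)
    neg = np.exp(rng.normal(-1.5, 0.4, 300))
    obs = np.exp(rng.normal(0.0, 1.0, 200))
    p1 = empirical_pvalues(obs, neg)
    p2 = empirical_pvalues(np.exp(obs * 2), np.exp(neg * 2))
    assert np.allclose(p1, p2)


def test_retention_profile_flat_for_all_retained():
    calls = np.full((5, 4), RETAINED, dtype=np.int8)
    panel = RHPanel(calls, [f"c{i}" for i in range(5)], list("abcd"))
    prof = retention_profile(panel)
    assert np.all(prof.to_numpy() == 1.0)


def test_selection_locus_peaks_in_retention_profile():
    """A TK1-like selection locus pulls local retention toward 1."""
    # chromosome much longer than the ~3.3 Mb mean fragment, so selection of
    # the fragment carrying the locus does not lift distal markers
    from rhmap.simulate import GenomeSpec, SelectionLocus
    length = 30_000_000
    pos = np.unique(np.concatenate([
        np.linspace(1, length, 80).astype(np.int64), [length // 2]]))
    spec = GenomeSpec(chromosomes=[("chr1", length)], markers={"chr1": pos},
                      selection_loci=[SelectionLocus("chr1", length // 2,
                                                     peak=1.0, decay_bp=6e5)])
    truth = simulate_fragments(spec, n_clones=200, r=0.22, seed=32)
    panel = simulate_observations(truth, fnr=0, fpr=0, missing_rate=0, seed=33)
    prof = retention_profile(panel)
    locus_bp = spec.selection_loci[0].bp
    meta = panel.marker_meta
    near = (meta["bp"] - locus_bp).abs() < 2e5
    far = (meta["bp"] - locus_bp).abs() > 10e6
    assert prof[near.to_numpy()].mean() > 0.9
    # baseline approaches the diploid closed form 1 - (1-r)^2
    baseline = 1 - (1 - 0.22) ** 2
    sd = np.sqrt(baseline * (1 - baseline) / 200)
    assert abs(prof[far.to_numpy()].mean() - baseline) < 4 * sd


def test_merge_panels_suffixes_duplicates():
    calls = np.zeros((2, 1), dtype=np.int8)
    a = RHPanel(calls, ["c1", "c2"], ["snp1"])
    b = RHPanel(calls, ["c1", "c2"], ["snp1"])
    with pytest.warns(UserWarning, match="duplicate"):
        merged = merge_panels({"ovine": a, "bovine": b})
    assert merged.marker_ids == ["snp1", "snp1_bovine"]


def test_end_to_end_calling_recovers_truth_with_separated_classes():
    """Well-separated intensity classes give >=99% correct non-missing calls."""
    spec = example_genome(n_chromosomes=1, n_markers=800, length_bp=26_000_000,
                          seed=41)
    truth_panel = simulate_fragments(spec, n_clones=60, r=0.194, seed=42)
    obs = simulate_observations(truth_panel, fnr=0, fpr=0, missing_rate=0, seed=43)
    long, samples, _neg, truth = simulate_intensities(
        obs, IntensityParams(background_mean=-1.5, retained_mean=1.5,
                             background_sd=0.35, retained_sd=0.35,
                             negative_snp_fraction=0.3), seed=44)
    matrix = IntensityMatrix.from_long(long, samples)
    result = call_panel(matrix, "bovine", CallingConfig(pi0_lambda=0.5),
                        truth=truth)
    tested = [s for s in matrix.snp_ids if s not in set(result.negative_snps)]
    tr = (truth.reindex(index=matrix.clone_ids)
          .reindex(columns=tested, fill_value=False).to_numpy(bool))
    non_missing = result.calls_raw != MISSING
    correct = (result.calls_raw == RETAINED) == tr
    assert correct[non_missing].mean() >= 0.99
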