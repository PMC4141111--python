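"""Linkage grouping, TSP ordering, comparative scoring, error flagging."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from rhmap.likelihood import RHModelParams, cr_to_theta
from rhmap.mapping import (LinkageGroup, MapBuilderConfig, assign_chromosome,
                           breakpoint_count, build_linkage_groups,
                           build_lkh_map, comparative_score,
                           fragment_length_diagnostic, flag_errors,
                           order_markers, two_point_matrix, _path_length)
from rhmap.panel import MISSING, RETAINED, UNRETAINED, RHPanel
from rhmap.simulate import (example_genome, simulate_fragments,
                            simulate_observations)
from tests.conftest import simulate_chain_vectors


class TestBreakpointCount:
    def test_identity_is_zero(self):
        assert breakpoint_count("ABCDE", "ABCDE") == 0

    def test_full_reversal_is_zero(self):
        assert breakpoint_count("EDCBA", "ABCDE") == 0

    def test_hand_counted_adjacency_breaks(self):
        # pairs B-D and C-E are novel
        assert breakpoint_count("ABDCE", "ABCDE") == 2

    def test_symmetric_and_reversal_invariant(self):
        rng = np.random.default_rng(1)
        letters = list("ABCDEFGH")
        for _ in range(20):
            a = list(rng.permutation(letters))
            b = list(rng.permutation(letters))
            n = breakpoint_count(a, b)
            assert n == breakpoint_count(b, a)
            assert n == breakpoint_count(a[::-1], b)
            assert n == breakpoint_count(a, b[::-1])

    def test_uses_marker_intersection(self):
        assert breakpoint_count("ABXC", "ABC") == 0


class TestComparativeScore:
    def _setup(self):
        rng = np.random.default_rng(2)
        vec = simulate_chain_vectors(rng, [0.2, 0.2, 0.2], 0.35, 50)
        params = RHModelParams(r=0.35, thetas=[0.2, 0.2, 0.2],
                               model="diploid_equal")
        return vec, params

    def test_lambda_zero_is_pure_likelihood(self):
        from rhmap.likelihood import loglik
        vec, params = self._setup()
        order = list("ABCD")
        s = comparative_score(order, vec, params, reference_order=list("DCAB"),
                              lam=0.0)
        assert s == pytest.approx(loglik(None, vec, params))

    def test_fewer_breakpoints_wins_at_equal_likelihood(self):
        vec, params = self._setup()
        ref = list("ABCD")
        s_ref = comparative_score(ref, vec, params, ref, lam=3.0)
        s_shuffled = comparative_score(ref, vec, params, ref, lam=3.0,
                                       marker_ids=list("ACBD"))
        assert s_ref > s_shuffled


class TestLinkageGroups:
    def test_two_chromosomes_two_groups(self, two_chromosome_panel):
        _spec, _truth, panel = two_chromosome_panel
        groups, unlinked = build_linkage_groups(panel)
        assert len(groups) == 2
        assert unlinked == []
        sizes = sorted(len(g.marker_ids) for g in groups)
        assert sizes == [50, 50]
        # groups are chromosome-pure
        for g in groups:
            chroms = {m.split("_")[0] for m in g.marker_ids}
            assert len(chroms) == 1

    def test_random_marker_reported_unlinked(self, clean_panel):
        _spec, _truth, panel = clean_panel
        rng = np.random.default_rng(3)
        random_vec = rng.choice([1, 0], size=(panel.n_clones, 1),
                                p=[0.35, 0.65]).astype(np.int8)
        calls = np.hstack([panel.calls, random_vec])
        noisy = RHPanel(calls, panel.clone_ids,
                        panel.marker_ids + ["random_marker"])
        groups, unlinked = build_linkage_groups(noisy)
        assert "random_marker" in unlinked

    def test_empty_panel_no_groups(self):
        panel = RHPanel(np.empty((0, 0), dtype=np.int8), [], [])
        groups, unlinked = build_linkage_groups(panel)
        assert groups == [] and unlinked == []


class TestAssignChromosome:
    def test_majority(self):
        meta = pd.DataFrame({"chromosome": ["chr5"] * 48 + ["chr2"] * 2},
                            index=[f"m{i}" for i in range(50)])
        group = LinkageGroup(marker_ids=[f"m{i}" for i in range(50)])
        assert assign_chromosome(group, meta) == "chr5"

    def test_tie_breaks_lexicographically(self):
        meta = pd.DataFrame({"chromosome": ["chr2"] * 5 + ["chr1"] * 5},
                            index=[f"m{i}" for i in range(10)])
        group = LinkageGroup(marker_ids=[f"m{i}" for i in range(10)])
        assert assign_chromosome(group, meta) == "chr1"

    def test_no_metadata_unassigned(self):
        group = LinkageGroup(marker_ids=["a", "b"])
        assert assign_chromosome(group, None) == "unassigned"


class TestOrdering:
    def test_two_markers_canonical(self, clean_panel):
        _spec, _truth, panel = clean_panel
        group = LinkageGroup(marker_ids=panel.marker_ids[:2])
        assert order_markers(group, panel) == sorted(panel.marker_ids[:2])

    def test_additive_line_metric_recovered_exactly(self):
        """A perfectly additive distance matrix must give the line order."""
        m = 9
        positions = np.sort(np.random.default_rng(4).uniform(0, 100, m))
        dist = np.abs(positions[:, None] - positions[None, :])
        ids = [f"m{i}" for i in range(m)]
        calls = np.zeros((12, m), dtype=np.int8)   # panel content unused here
        panel = RHPanel(calls, [f"c{i}" for i in range(12)], ids)
        group = LinkageGroup(marker_ids=ids)
        cfg = MapBuilderConfig(comparative_lambda=0.0)
        order = order_markers(group, panel, config=cfg, dist=dist)
        idx = [ids.index(o) for o in order]
        assert idx == list(range(m)) or idx == list(range(m))[::-1]

    def test_heuristic_matches_exhaustive_on_seven_markers(self):
        """Heuristic path length equals the brute-force optimum over 7!/2 orders."""
        rng = np.random.default_rng(5)
        thetas = cr_to_theta(rng.uniform(20, 30, 6))
        vec = simulate_chain_vectors(rng, thetas, 0.35, 150)
        ids = [f"m{i}" for i in range(7)]
        panel = RHPanel(vec, [f"c{i}" for i in range(150)], ids)
        _lod, dist = two_point_matrix(panel)
        group = LinkageGroup(marker_ids=ids)
        cfg = MapBuilderConfig(comparative_lambda=0.0)
        order = order_markers(group, panel, config=cfg, dist=dist)
        best = min(_path_length(np.array((0,) + p), dist)
                   for p in itertools.permutations(range(1, 7)))
        got = _path_length(np.array([ids.index(o) for o in order]), dist)
        assert got == pytest.approx(best, abs=1e-9)
        assert order == ids or order == ids[::-1]


class TestFlagErrors:
    def _tight_map_panel(self, with_error=False):
        rng = np.random.default_rng(6)
        thetas = np.full(9, 0.01)
        vec = simulate_chain_vectors(rng, thetas, 0.35, 80)
        if with_error:
            # isolated present call inside a fully absent clone run
            clone = np.flatnonzero((vec == 0).all(axis=1))[0]
            vec[clone, 4] = 1
        ids = [f"m{i}" for i in range(10)]
        panel = RHPanel(vec, [f"c{i}" for i in range(80)], ids)
        params = RHModelParams(r=0.35, thetas=thetas, eps_fn=0.02,
                               eps_fp=0.002, model="diploid_equal")
        return panel, ids, params, (None if not with_error else clone)

    def test_clean_data_zero_flags(self):
        panel, ids, params, _ = self._tight_map_panel()
        _flagged, report = flag_errors(ids, panel, params)
        assert len(report) == 0

    def test_isolated_discordant_call_flagged(self):
        panel, ids, params, clone = self._tight_map_panel(with_error=True)
        flagged, report = flag_errors(ids, panel, params)
        hits = report[(report["clone"] == f"c{clone}") & (report["marker"] == "m4")]
        assert len(hits) == 1
        assert hits.iloc[0]["log10_ratio"] >= 3

    def test_flagging_is_idempotent(self):
        panel, ids, params, _clone = self._tight_map_panel(with_error=True)
        flagged, report1 = flag_errors(ids, panel, params)
        _again, report2 = flag_errors(ids, flagged, params)
        assert len(report2) == 0

    def test_never_overflags_noisy_data(self):
        rng = np.random.default_rng(7)
        vec = simulate_chain_vectors(rng, np.full(19, 0.1), 0.35, 90, eps_fn=0.07)
        ids = [f"m{i}" for i in range(20)]
        panel = RHPanel(vec, [f"c{i}" for i in range(90)], ids)
        params = RHModelParams(r=0.35, thetas=np.full(19, 0.1), eps_fn=0.05,
                               eps_fp=0.005, model="diploid_equal")
        _flagged, report = flag_errors(ids, panel, params)
        assert len(report) / vec.size <= 0.05


class TestBuildMap:
    def test_clean_simulation_recovers_order_and_length(self, clean_panel):
        spec, _truth, panel = clean_panel
        groups, _ = build_linkage_groups(panel)
        group = groups[0]
        assign_chromosome(group, panel.marker_meta)
        ref = [m for m in panel.marker_meta.sort_values("bp").index
               if m in set(group.marker_ids)]
        rh_map = build_lkh_map(group, panel, reference_order=ref)
        true_pos = panel.marker_meta.loc[rh_map.order, "cr"].to_numpy()
        rho = spearmanr(rh_map.positions_cr, true_pos).statistic
        assert abs(rho) == pytest.approx(1.0)
        # at 90 clones a single replicate has ~12% length noise; the tighter
        # replicate-averaged recovery check lives in the acceptance suite
        true_span = true_pos.max() - true_pos.min()
        assert rh_map.length_cr == pytest.approx(true_span, rel=0.30)

    def test_random_vector_marker_removed(self, clean_panel):
        _spec, _truth, panel = clean_panel
        rng = np.random.default_rng(8)
        random_vec = rng.choice([1, 0], size=(panel.n_clones, 1),
                                p=[0.35, 0.65]).astype(np.int8)
        calls = np.hstack([panel.calls, random_vec])
        noisy = RHPanel(calls, panel.clone_ids, panel.marker_ids + ["bad"],
                        marker_meta=panel.marker_meta)
        group = LinkageGroup(marker_ids=noisy.marker_ids)
        ref = list(panel.marker_meta.sort_values("bp").index)
        rh_map = build_lkh_map(group, noisy, reference_order=ref)
        assert "bad" not in rh_map.order


class TestFragmentDiagnostic:
    def test_simulated_panel_passes_ks(self, clean_panel):
        spec, _truth, panel = clean_panel
        groups, _ = build_linkage_groups(panel)
        group = groups[0]
        ref = [m for m in panel.marker_meta.sort_values("bp").index
               if m in set(group.marker_ids)]
        rh_map = build_lkh_map(group, panel, reference_order=ref)
        diag = fragment_length_diagnostic(rh_map, panel)
        assert diag["ks_pvalue"] > 0.01

    def test_zero_retention_clone_contributes_nothing(self):
        ids = [f"m{i}" for i in range(5)]
        calls = np.zeros((1, 5), dtype=np.int8)
        panel = RHPanel(calls, ["c0"], ids)
        params = RHModelParams(r=0.3, thetas=np.full(4, 0.2))
        from rhmap.mapping import RHMap
        rh_map = RHMap(group=LinkageGroup(marker_ids=ids), order=ids,
                       positions_cr=np.arange(5) * 10.0, params=params,
                       loglik=0.0, dropped=pd.DataFrame(),
                       flag_report=pd.DataFrame())
        diag = fragment_length_diagnostic(rh_map, panel)
        assert len(diag["spans"]) == 0
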