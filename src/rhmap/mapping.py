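"""Per-chromosome map construction from a QC'ed RH panel.

Stages: two-point linkage at LOD >= 10 defines linkage groups (connected
components, minor groups dissolved); each group is assigned a chromosome by
majority over marker metadata; markers are ordered by casting the group as a
travelling-salesman path over two-point distances (greedy nearest-neighbour
multi-start, 2-opt, reinsertion) and polished against a comparative score
that penalises breakpoints with the reference (assembly) order — assembly
errors create rare spurious breakpoints, modelled as Poisson events; single
calls that are overwhelmingly (1000:1) better explained as laboratory error
are blanked; markers hanging at the ends across long (>25 cR) intervals are
dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .likelihood import (DIPLOID, HAPLOID, EMResult, RHModelParams, _forward,
                         _forward_backward, cr_to_theta, em_fit,
                         pair_log_cell_probs, theta_to_cr, two_point_estimate)
from .panel import MISSING, RETAINED, UNRETAINED, RHPanel

UNLINKED_CAP_CR = 300.0     # distance assigned to pairs beyond panel resolution


@dataclass
class MapBuilderConfig:
    lod_link: float = 10.0
    min_group_size: int = 5
    long_interval_cr: float = 25.0
    error_log10: float = 3.0
    comparative_lambda: float = 3.0     # natural-log penalty per breakpoint
    # light emission-error channel: absorbs genotyping errors so they do not
    # mint spurious breakpoints and inflate distances, while keeping enough
    # geometry to order close markers; set to 0 for the textbook chain
    eps_fn: float = 0.01
    eps_fp: float = 0.001
    max_rounds: int = 3
    n_starts: int = 8
    polish_window: int = 8

    def __post_init__(self) -> None:
        if min(self.lod_link, self.min_group_size, self.long_interval_cr,
               self.error_log10) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class LinkageGroup:
    marker_ids: list[str]
    chromosome: str = "unassigned"
    edges: list[tuple[str, str, float]] = field(default_factory=list)


@dataclass
class RHMap:
    """An ordered marker map with centiRay positions."""

    group: LinkageGroup
    order: list[str]
    positions_cr: np.ndarray
    params: RHModelParams
    loglik: float
    dropped: pd.DataFrame
    flag_report: pd.DataFrame

    @property
    def length_cr(self) -> float:
        return float(self.positions_cr[-1]) if len(self.positions_cr) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker": self.order,
            "chromosome": self.group.chromosome,
            "position_cr": self.positions_cr,
            "theta_next": np.append(self.params.thetas, np.nan),
            "retention_r": self.params.r,
            "model": self.params.model,
        })


# ----------------------------------------------------------------------
# fast all-pairs two-point scan
# ----------------------------------------------------------------------
class _TwoPointGrid:
    """Precomputed 9-cell log-probability tables over a (theta, r) grid."""

    def __init__(self, eps_fn: float = 0.0, eps_fp: float = 0.0):
        self.theta_grid = np.linspace(0.0, 0.99, 100)
        self.r_grid = np.linspace(0.02, 0.98, 49)
        self.logp = pair_log_cell_probs(self.theta_grid[:, None],
                                        self.r_grid[None, :], eps_fn, eps_fp)
        self.logp_ind = pair_log_cell_probs(1.0, self.r_grid, eps_fn, eps_fp)

    def scan(self, counts9: np.ndarray) -> tuple[float, float, float]:
        """(theta_hat, r_hat, lod) from a flat 9-cell count vector."""
        ll = np.einsum("trc,c->tr", self.logp.reshape(100, 49, 9), counts9)
        it, ir = np.unravel_index(np.argmax(ll), ll.shape)
        ll_ind = np.einsum("rc,c->r", self.logp_ind.reshape(49, 9), counts9)
        lod = max((ll[it, ir] - ll_ind.max()) / np.log(10.0), 0.0)
        return float(self.theta_grid[it]), float(self.r_grid[ir]), float(lod)


def _pairwise_counts(calls: np.ndarray) -> np.ndarray:
    """All-pairs 9-cell joint observation counts via indicator products.

    Returns (m, m, 9) with cells ordered (1,1),(1,0),(1,-),(0,1),(0,0),
    (0,-),(-,1),(-,0),(-,-), matching pair_log_cell_probs' table layout."""
    ind = np.stack([(calls == RETAINED), (calls == UNRETAINED),
                    (calls == MISSING)]).astype(np.float64)   # (3, n, m)
    counts = np.einsum("ani,bnj->ijab", ind, ind)              # (m, m, 3, 3)
    return counts.reshape(calls.shape[1], calls.shape[1], 9)


def two_point_matrix(panel: RHPanel, config: MapBuilderConfig | None = None):
    """LOD and centiRay distance matrices over all marker pairs."""
    config = config or MapBuilderConfig()
    grid = _TwoPointGrid(config.eps_fn, config.eps_fp)
    counts = _pairwise_counts(panel.calls)
    m = panel.n_markers
    lod = np.zeros((m, m))
    dist = np.full((m, m), UNLINKED_CAP_CR)
    np.fill_diagonal(dist, 0.0)
    for i, j in combinations(range(m), 2):
        c9 = counts[i, j]
        informative = c9[[0, 1, 3, 4]].sum()
        if informative < 10:
            continue
        theta, _r, pair_lod = grid.scan(c9)
        lod[i, j] = lod[j, i] = pair_lod
        d = theta_to_cr(min(theta, 1 - 1e-12))
        dist[i, j] = dist[j, i] = min(d, UNLINKED_CAP_CR)
    return lod, dist


# ----------------------------------------------------------------------
# linkage groups and chromosome assignment
# ----------------------------------------------------------------------
def build_linkage_groups(panel: RHPanel, config: MapBuilderConfig | None = None,
                         lod: np.ndarray | None = None):
    """Single-linkage components at LOD >= lod_link; dissolve minor groups.

    Components below ``min_group_size`` markers are dissolved and their
    markers reported as unlinked, automating the manual raising of the LOD
    threshold used to clear minor groups."""
    config = config or MapBuilderConfig()
    if panel.n_markers == 0:
        return [], []
    if lod is None:
        lod, _ = two_point_matrix(panel, config)
    graph = nx.Graph()
    graph.add_nodes_from(range(panel.n_markers))
    for i, j in zip(*np.nonzero(np.triu(lod >= config.lod_link, k=1))):
        graph.add_edge(int(i), int(j))
    groups, unlinked = [], []
    for component in nx.connected_components(graph):
        members = sorted(component)
        ids = [panel.marker_ids[i] for i in members]
        if len(members) < config.min_group_size:
            unlinked.extend(ids)
            continue
        edges = [(panel.marker_ids[i], panel.marker_ids[j], float(lod[i, j]))
                 for i, j in graph.edges(members) if lod[i, j] >= config.lod_link]
        groups.append(LinkageGroup(marker_ids=ids, edges=edges))
    groups.sort(key=lambda g: g.marker_ids[0])
    return groups, sorted(unlinked)


def assign_chromosome(group: LinkageGroup,
                      marker_meta: pd.DataFrame | None) -> str:
    """Majority vote over members' reference chromosomes; lexicographic ties."""
    if marker_meta is None or "chromosome" not in getattr(marker_meta, "columns", ()):
        group.chromosome = "unassigned"
        return group.chromosome
    chroms = marker_meta.reindex(group.marker_ids)["chromosome"].dropna()
    if chroms.empty:
        group.chromosome = "unassigned"
        return group.chromosome
    counts = chroms.value_counts()
    best = counts.max()
    winner = sorted(counts.index[counts == best])[0]
    group.chromosome = str(winner)
    return group.chromosome


# ----------------------------------------------------------------------
# comparative model
# ----------------------------------------------------------------------
def breakpoint_count(order, reference_order) -> int:
    """Adjacencies of ``order`` absent (in either orientation) from the reference.

    Computed on the common marker subset; symmetric and reversal-invariant."""
    common = set(order) & set(reference_order)
    seq = [m for m in order if m in common]
    ref = [m for m in reference_order if m in common]
    ref_adj = {frozenset(p) for p in zip(ref[:-1], ref[1:])}
    return sum(1 for p in zip(seq[:-1], seq[1:]) if frozenset(p) not in ref_adj)


def comparative_score(order, vectors, params: RHModelParams, reference_order,
                      lam: float = 3.0, marker_ids: list[str] | None = None) -> float:
    """Multipoint log-likelihood minus lam per breakpoint with the reference.

    The penalty is the log prior odds against each extra breakpoint under a
    Poisson model of rare rearrangement/assembly-error events."""
    from .likelihood import loglik
    marker_ids = list(order) if marker_ids is None else marker_ids
    ll = loglik(None, vectors, params)
    if reference_order is None or lam == 0:
        return ll
    return ll - lam * breakpoint_count(marker_ids, reference_order)


# ----------------------------------------------------------------------
# ordering
# ----------------------------------------------------------------------
def _path_length(order_idx: np.ndarray, dist: np.ndarray) -> float:
    return float(dist[order_idx[:-1], order_idx[1:]].sum())


def _nearest_neighbor(dist: np.ndarray, start: int) -> np.ndarray:
    m = dist.shape[0]
    visited = np.zeros(m, dtype=bool)
    order = [start]
    visited[start] = True
    for _ in range(m - 1):
        d = dist[order[-1]].copy()
        d[visited] = np.inf
        nxt = int(np.argmin(d))
        order.append(nxt)
        visited[nxt] = True
    return np.asarray(order)


def _two_opt(order: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """2-opt for a Hamiltonian path (segment reversals), to local optimum."""
    order = order.copy()
    m = len(order)
    improved = True
    while improved:
        improved = False
        for i in range(m - 1):
            a = order[i - 1] if i > 0 else -1
            for j in range(i + 1, m):
                b = order[j + 1] if j + 1 < m else -1
                before = (dist[order[i - 1], order[i]] if a >= 0 else 0.0) + \
                         (dist[order[j], order[j + 1]] if b >= 0 else 0.0)
                after = (dist[order[i - 1], order[j]] if a >= 0 else 0.0) + \
                        (dist[order[i], order[j + 1]] if b >= 0 else 0.0)
                if after < before - 1e-12:
                    order[i:j + 1] = order[i:j + 1][::-1]
                    improved = True
    return order


def _reinsertion(order: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Single-marker relocation moves, to local optimum."""
    order = list(order)
    m = len(order)
    improved = True
    while improved:
        improved = False
        best_len = _path_length(np.asarray(order), dist)
        for i in range(m):
            marker = order[i]
            rest = order[:i] + order[i + 1:]
            for k in range(m):
                if k == i:
                    continue
                cand = rest[:k] + [marker] + rest[k:]
                cand_len = _path_length(np.asarray(cand), dist)
                if cand_len < best_len - 1e-12:
                    order = cand
                    best_len = cand_len
                    improved = True
                    break
            if improved:
                break
    return np.asarray(order)


def order_markers(group: LinkageGroup, panel: RHPanel,
                  reference_order: list[str] | None = None,
                  config: MapBuilderConfig | None = None,
                  dist: np.ndarray | None = None) -> list[str]:
    """TSP-path heuristic order of a linkage group.

    Greedy nearest-neighbour tours from multiple starts, improved by 2-opt
    and single-marker reinsertion on the two-point distance matrix, then a
    hill-climb on the comparative score with window-reversal moves. Never
    returns an order scoring worse than the reference/metadata order."""
    config = config or MapBuilderConfig()
    ids = sorted(group.marker_ids)
    if len(ids) <= 2:
        return ids
    sub = panel.subset(markers=np.array([panel.marker_ids.index(m) for m in ids]))
    if dist is None:
        _, dist = two_point_matrix(sub, config)

    m = len(ids)
    starts = list(np.linspace(0, m - 1, min(config.n_starts, m)).astype(int))
    best, best_len = None, np.inf
    for s in starts:
        cand = _two_opt(_nearest_neighbor(dist, int(s)), dist)
        cand = _reinsertion(cand, dist)
        length = _path_length(cand, dist)
        if length < best_len - 1e-12:
            best, best_len = cand, length

    # seed candidates from the reference order too: the output must never be
    # worse than its starting points
    candidates = [best]
    if reference_order is not None:
        ref_idx = [ids.index(x) for x in reference_order if x in set(ids)]
        if len(ref_idx) == m:
            candidates.append(_reinsertion(_two_opt(np.asarray(ref_idx), dist), dist))
    best = min(candidates, key=lambda o: _path_length(o, dist))

    order = _polish_comparative(best, sub, dist, ids, reference_order, config)
    return [ids[i] for i in order]


def _order_params(order: np.ndarray, dist: np.ndarray, r: float,
                  eps_fn: float, eps_fp: float) -> RHModelParams:
    thetas = cr_to_theta(np.minimum(dist[order[:-1], order[1:]], UNLINKED_CAP_CR))
    return RHModelParams(r=r, thetas=np.atleast_1d(thetas), eps_fn=eps_fn,
                         eps_fp=eps_fp, model=HAPLOID)


def _polish_comparative(order: np.ndarray, sub: RHPanel, dist: np.ndarray,
                        ids: list[str], reference_order, config) -> np.ndarray:
    """Hill-climb on comparative score with window reversals (window <= 8)."""
    r = float(np.nanmean(sub.marker_retention()))
    r = min(max(r, 0.01), 0.99)

    def score(o: np.ndarray) -> float:
        params = _order_params(o, dist, r, config.eps_fn, config.eps_fp)
        names = [ids[i] for i in o]
        return comparative_score(o, sub.calls[:, o], params, reference_order,
                                 lam=config.comparative_lambda, marker_ids=names)

    current = order.copy()
    current_score = score(current)
    m = len(current)
    improved = True
    while improved:
        improved = False
        for w in range(2, min(config.polish_window, m) + 1):
            for i in range(m - w + 1):
                cand = current.copy()
                cand[i:i + w] = cand[i:i + w][::-1]
                s = score(cand)
                if s > current_score + 1e-9:
                    current, current_score = cand, s
                    improved = True
    return current


# ----------------------------------------------------------------------
# error flagging
# ----------------------------------------------------------------------
def flag_errors(order: list[str], panel: RHPanel, params: RHModelParams,
                config: MapBuilderConfig | None = None):
    """Blank single calls that are >= 1000:1 better explained as errors.

    For every non-missing cell, the log10 ratio of the full-data likelihood
    with that single call flipped against as-observed is computed from one
    forward-backward pass. The ratio is taken under the pure retention chain
    (no emission-error channel — an error channel would cap the ratio at
    (1-eps)/eps); thetas are floored away from 0 so a flip makes the data
    unlikely, never impossible. Cells at or above ``error_log10`` are set to
    missing."""
    from dataclasses import replace
    from .likelihood import _emission_table
    config = config or MapBuilderConfig()
    vectors = panel.vectors_for(list(order))
    n, m = vectors.shape
    chain = replace(params, eps_fn=0.0, eps_fp=0.0,
                    thetas=np.clip(params.thetas, 1e-6, 1 - 1e-6))
    alpha, beta, emis, trans, scales, ll_clone = _forward_backward(vectors, chain)
    n_states = emis.shape[2]
    emit = _emission_table(chain, n_states)
    init = np.array([1 - chain.r, chain.r]) if n_states == 2 else None
    if n_states == 4:
        pi = np.array([1 - chain.r, chain.r])
        init = np.kron(pi, pi)
    flags = []
    new_calls = panel.calls.copy()
    col_of = {mk: panel.marker_ids.index(mk) for mk in order}
    for k in range(m):
        # forward mass at k excluding the emission at k (scaled consistently)
        if k == 0:
            alpha_excl = np.broadcast_to(init, (n, n_states))
        else:
            alpha_excl = alpha[k - 1] @ trans[k - 1]
        for obs_sym, flip_sym in ((RETAINED, UNRETAINED), (UNRETAINED, RETAINED)):
            rows = np.flatnonzero(vectors[:, k] == obs_sym)
            if rows.size == 0:
                continue
            base = alpha_excl[rows] * beta[k][rows]
            denom = (base * emit[obs_sym][None, :]).sum(axis=1)
            num = (base * emit[flip_sym][None, :]).sum(axis=1)
            log10_ratio = np.log10(np.maximum(num, 1e-300)) - \
                np.log10(np.maximum(denom, 1e-300))
            for row, lr in zip(rows, log10_ratio):
                if lr >= config.error_log10:
                    flags.append((panel.clone_ids[row], order[k], float(lr), "set_missing"))
                    new_calls[row, col_of[order[k]]] = MISSING
    report = pd.DataFrame(flags, columns=["clone", "marker", "log10_ratio", "action"])
    flagged = RHPanel(calls=new_calls, clone_ids=panel.clone_ids,
                      marker_ids=panel.marker_ids, marker_meta=panel.marker_meta,
                      truth=panel.truth)
    return flagged, report


# ----------------------------------------------------------------------
# full map construction
# ----------------------------------------------------------------------
def build_lkh_map(group: LinkageGroup, panel: RHPanel,
                  reference_order: list[str] | None = None,
                  config: MapBuilderConfig | None = None,
                  model: str = DIPLOID) -> RHMap:
    """order -> EM fit -> error flagging -> reorder, up to 3 rounds.

    Terminal markers across intervals longer than ``long_interval_cr`` are
    dropped (they are overwhelmingly end artifacts), then distances are
    refitted. Degenerate groups (< 2 markers after drops) yield a one-bin map."""
    config = config or MapBuilderConfig()
    work = panel
    dropped_rows = []
    flag_frames = []
    order = [m for m in group.marker_ids]
    for _ in range(config.max_rounds):
        current_ids = [m for m in order if m in set(work.marker_ids)]
        g = LinkageGroup(marker_ids=current_ids, chromosome=group.chromosome)
        order = order_markers(g, work, reference_order, config)
        fit = em_fit(None, work.vectors_for(order), model=model,
                     eps_fn=config.eps_fn, eps_fp=config.eps_fp, tol=1e-9)
        work, report = flag_errors(order, work, fit.params, config)
        if not report.empty:
            flag_frames.append(report)
        if report.empty:
            break

    # drop terminal markers across long intervals, re-fitting after each trim
    while len(order) > 2:
        fit = em_fit(None, work.vectors_for(order), model=model,
                     eps_fn=config.eps_fn, eps_fp=config.eps_fp, tol=1e-9)
        gaps = theta_to_cr(np.minimum(fit.params.thetas, 1 - 1e-12))
        if gaps[0] > config.long_interval_cr:
            dropped_rows.append((order[0], float(gaps[0]), "terminal_interval>25cR"))
            order = order[1:]
        elif gaps[-1] > config.long_interval_cr:
            dropped_rows.append((order[-1], float(gaps[-1]), "terminal_interval>25cR"))
            order = order[:-1]
        else:
            break

    if len(order) < 2:
        warnings.warn("group collapsed below 2 markers; degenerate map")
        params = RHModelParams(r=0.5, thetas=np.empty(0), model=model)
        return RHMap(group=group, order=order, positions_cr=np.zeros(len(order)),
                     params=params, loglik=0.0,
                     dropped=pd.DataFrame(dropped_rows,
                                          columns=["marker", "gap_cr", "reason"]),
                     flag_report=pd.concat(flag_frames, ignore_index=True)
                     if flag_frames else pd.DataFrame())

    fit = em_fit(None, work.vectors_for(order), model=model,
                 eps_fn=config.eps_fn, eps_fp=config.eps_fp, tol=1e-9)
    return RHMap(group=group, order=order, positions_cr=fit.positions_cr,
                 params=fit.params, loglik=fit.loglik,
                 dropped=pd.DataFrame(dropped_rows,
                                      columns=["marker", "gap_cr", "reason"]),
                 flag_report=pd.concat(flag_frames, ignore_index=True)
                 if flag_frames else pd.DataFrame())


# ----------------------------------------------------------------------
# diagnostics
# ----------------------------------------------------------------------
def fragment_length_diagnostic(rh_map: RHMap, panel: RHPanel,
                               min_cr: float = 2.0) -> dict:
    """Retained-segment cR spans vs the exponential expectation.

    Runs of consecutive retained calls along the map are converted to
    centiRay spans; under the Poisson breakage model these are exponential.
    Segments shorter than ``min_cr`` are excluded from the test (maps cannot
    order markers closer than their resolution, so that class is depleted).
    Returns observed spans, the fitted exponential scale and a KS test."""
    vectors = panel.vectors_for(rh_map.order)
    pos = rh_map.positions_cr
    spans = []
    for clone in vectors:
        run_start = None
        for k, call in enumerate(clone):
            if call == RETAINED and run_start is None:
                run_start = k
            elif call != RETAINED and run_start is not None:
                if k - 1 > run_start:
                    spans.append(pos[k - 1] - pos[run_start])
                run_start = None
        if run_start is not None and len(clone) - 1 > run_start:
            spans.append(pos[-1] - pos[run_start])
    spans = np.asarray(spans, dtype=float)
    kept = spans[spans >= min_cr]
    if kept.size < 5:
        return dict(spans=spans, ks_stat=np.nan, ks_pvalue=np.nan, scale=np.nan)
    # left-truncated exponential: memorylessness makes (x - min_cr) exponential
    shifted = kept - min_cr
    scale = float(shifted.mean())
    ks = stats.kstest(shifted, "expon", args=(0, scale))
    return dict(spans=spans, ks_stat=float(ks.statistic),
                ks_pvalue=float(ks.pvalue), scale=scale)
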