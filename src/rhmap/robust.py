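"""Robust maps: MCMC over marker orders and extraction of the >=95% core.

A point-estimate order (the LKH map) says nothing about which order relations
the data actually support. A Metropolis-Hastings chain over marker orders,
with the comparative posterior exp(loglik - lambda * breakpoints) as target,
gives a posterior over orders; markers that jump between positions across
high-probability orders are removed until the relative order of everything
that remains carries at least the configured posterior mass (default 95%).
Orders are identified with their reversals throughout — RH data cannot
orient a chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .likelihood import DIPLOID, RHModelParams, cr_to_theta, em_fit, loglik
from .mapping import (UNLINKED_CAP_CR, MapBuilderConfig, RHMap,
                      breakpoint_count, two_point_matrix)
from .panel import MISSING, RETAINED, RHPanel


@dataclass
class McmcConfig:
    iterations: int = 5000
    burnin: int = 1000
    # proposal mix: segment reversal / single reinsertion / short translocation
    proposal_weights: tuple[float, float, float] = (0.5, 0.3, 0.2)
    seed: int = 0
    comparative_lambda: float = 3.0
    # light error channel: keeps the order posterior sharp, so order
    # uncertainty from genotyping error surfaces as robust-map removals
    # instead of being absorbed, while final distances stay uninflated
    eps_fn: float = 0.01
    eps_fp: float = 0.001

    def __post_init__(self) -> None:
        if not self.burnin < self.iterations:
            raise ValueError("burnin must be smaller than iterations")
        if abs(sum(self.proposal_weights) - 1.0) > 1e-9:
            raise ValueError("proposal weights must sum to 1")


@dataclass
class OrderPosterior:
    """Post-burn-in sample of bin orders (orders identified with reversals)."""

    counts: dict[tuple[int, ...], int]
    n_samples: int
    bin_ids: list[str]
    adjacency_freq: np.ndarray
    acceptance_rate: float

    def masses(self) -> list[tuple[tuple[int, ...], float]]:
        items = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return [(order, c / self.n_samples) for order, c in items]

    def best_mass(self) -> float:
        return self.masses()[0][1]


@dataclass
class RobustMap:
    bins: list[list[str]]            # ordered position bins (co-mapped markers)
    positions_cr: np.ndarray
    support: float
    removed: pd.DataFrame
    params: RHModelParams | None = None
    map_lod: float = float("nan")

    @property
    def markers(self) -> list[str]:
        return [m for b in self.bins for m in b]


# ----------------------------------------------------------------------
# cohort collapsing
# ----------------------------------------------------------------------
def collapse_cohorts(panel: RHPanel, group_markers: list[str]) -> list[list[str]]:
    """Merge markers with zero obligate breakpoints into position bins.

    Two markers whose call vectors agree on every clone where both are
    non-missing imply no required fragment boundary between them, so the data
    cannot separate them. Compatibility is closed transitively (connected
    components); each bin is sorted with its lexicographically first id as
    representative."""
    vectors = panel.vectors_for(group_markers)
    m = len(group_markers)
    parent = list(range(m))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(m):
        vi = vectors[:, i]
        for j in range(i + 1, m):
            vj = vectors[:, j]
            shared = (vi != MISSING) & (vj != MISSING)
            if np.all(vi[shared] == vj[shared]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[str]] = {}
    for i in range(m):
        groups.setdefault(find(i), []).append(group_markers[i])
    bins = [sorted(v) for v in groups.values()]
    bins.sort(key=lambda b: b[0])
    return bins


# ----------------------------------------------------------------------
# MCMC over orders
# ----------------------------------------------------------------------
def _canonical(order: tuple[int, ...]) -> tuple[int, ...]:
    """Identify an order with its reversal: keep the lexicographically smaller."""
    rev = order[::-1]
    return order if order <= rev else rev


def _proposal(order: np.ndarray, rng: np.random.Generator,
              weights: tuple[float, float, float]) -> np.ndarray:
    m = len(order)
    kind = rng.choice(3, p=weights)
    cand = order.copy()
    if kind == 0 or m < 3:                     # segment reversal
        i, j = sorted(rng.choice(m, size=2, replace=False))
        cand[i:j + 1] = cand[i:j + 1][::-1]
    elif kind == 1:                            # single reinsertion
        i = int(rng.integers(m))
        x = cand[i]
        rest = np.delete(cand, i)
        k = int(rng.integers(m))
        cand = np.insert(rest, k, x)
    else:                                      # short-segment translocation
        w = int(rng.integers(1, min(3, m - 1) + 1))
        i = int(rng.integers(m - w + 1))
        seg = cand[i:i + w].copy()
        rest = np.concatenate([cand[:i], cand[i + w:]])
        k = int(rng.integers(len(rest) + 1))
        cand = np.concatenate([rest[:k], seg, rest[k:]])
    return cand


def mcmc_orders(rh_map: RHMap | None, panel: RHPanel,
                reference_order: list[str] | None = None,
                config: McmcConfig | None = None,
                bins: list[list[str]] | None = None,
                dist: np.ndarray | None = None) -> OrderPosterior:
    """Metropolis-Hastings over bin orders starting from the LKH map.

    The target is exp(comparative score): the multipoint log-likelihood of
    the bin-representative vectors (with per-interval thetas read off the
    two-point distance matrix) minus lambda per breakpoint against the
    reference order. All proposals are symmetric."""
    config = config or McmcConfig()
    if bins is None:
        if rh_map is None:
            raise ValueError("need an LKH map or explicit bins")
        bins = collapse_cohorts(panel, rh_map.order)
    reps = [b[0] for b in bins]
    n_bins = len(bins)
    vectors = panel.vectors_for(reps)
    sub = panel.subset(markers=np.array([panel.marker_ids.index(m) for m in reps]))
    if dist is None:
        # distance matrix from the pure chain: pairwise theta MLEs stay sharp
        # so that genuine order signal is not absorbed as emission error; the
        # scoring likelihood below keeps a light error channel to avoid
        # impossible (-inf) orders
        _, dist = two_point_matrix(sub, MapBuilderConfig(eps_fn=0.0, eps_fp=0.0))
    r = float(np.clip(np.nanmean(sub.marker_retention()), 0.01, 0.99))

    ref_adj = None
    if reference_order is not None:
        rep_of = {m: i for i, b in enumerate(bins) for m in b}
        ref_bins = []
        for mk in reference_order:
            i = rep_of.get(mk)
            if i is not None and (not ref_bins or ref_bins[-1] != i):
                ref_bins.append(i)
        ref_adj = {frozenset(p) for p in zip(ref_bins[:-1], ref_bins[1:])}

    def score(order: np.ndarray) -> float:
        thetas = cr_to_theta(np.minimum(dist[order[:-1], order[1:]],
                                        UNLINKED_CAP_CR))
        params = RHModelParams(r=r, thetas=np.atleast_1d(thetas),
                               eps_fn=config.eps_fn, eps_fp=config.eps_fp)
        ll = loglik(None, vectors[:, order], params)
        if ref_adj is None:
            return ll
        bp = sum(1 for p in zip(order[:-1], order[1:])
                 if frozenset((int(p[0]), int(p[1]))) not in ref_adj)
        return ll - config.comparative_lambda * bp

    rng = np.random.default_rng(config.seed)
    if rh_map is not None:
        start_rep = {b[0]: i for i, b in enumerate(bins)}
        start = [start_rep[m] for m in rh_map.order if m in start_rep]
        current = np.asarray(start + [i for i in range(n_bins) if i not in set(start)])
    else:
        current = np.arange(n_bins)
    current_score = score(current)

    counts: dict[tuple[int, ...], int] = {}
    adjacency = np.zeros((n_bins, n_bins))
    accepted = 0
    for it in range(config.iterations):
        cand = _proposal(current, rng, config.proposal_weights)
        cand_score = score(cand)
        if np.log(rng.random()) < cand_score - current_score:
            current, current_score = cand, cand_score
            accepted += 1
        if it >= config.burnin:
            key = _canonical(tuple(int(x) for x in current))
            counts[key] = counts.get(key, 0) + 1
            adjacency[current[:-1], current[1:]] += 1
            adjacency[current[1:], current[:-1]] += 1
    n_samples = config.iterations - config.burnin
    rate = accepted / config.iterations
    if rate < 0.01:
        warnings.warn(f"MCMC acceptance rate {rate:.3f} < 1%: poor mixing")
    return OrderPosterior(counts=counts, n_samples=n_samples, bin_ids=reps,
                          adjacency_freq=adjacency / n_samples,
                          acceptance_rate=rate)


# ----------------------------------------------------------------------
# robust-map extraction
# ----------------------------------------------------------------------
def _projected_masses(counts: dict[tuple[int, ...], int],
                      keep: tuple[int, ...]) -> dict[tuple[int, ...], int]:
    keep_set = set(keep)
    out: dict[tuple[int, ...], int] = {}
    for order, c in counts.items():
        proj = _canonical(tuple(i for i in order if i in keep_set))
        out[proj] = out.get(proj, 0) + c
    return out


def extract_robust(posterior: OrderPosterior, threshold: float = 0.95,
                   bins: list[list[str]] | None = None) -> RobustMap:
    """Greedy bin deletion until the best remaining order reaches ``threshold``.

    At each step the bin whose removal most increases the best projected
    order's posterior mass is removed; ties go to the bin with the lowest
    mean adjacency stability. Removals are reported with reasons."""
    n_bins = len(posterior.bin_ids)
    if bins is None:
        bins = [[b] for b in posterior.bin_ids]
    keep = list(range(n_bins))
    removed = []
    total = sum(posterior.counts.values())

    def best_mass(indices: list[int]) -> tuple[float, tuple[int, ...]]:
        proj = _projected_masses(posterior.counts, tuple(indices))
        order, c = max(proj.items(), key=lambda kv: (kv[1], kv[0]))
        return c / total, order

    mass, order = best_mass(keep)
    while mass < threshold and len(keep) > 2:
        gains = []
        for i in keep:
            rest = [k for k in keep if k != i]
            m, _ = best_mass(rest)
            stability = float(np.mean(posterior.adjacency_freq[i][rest]))
            gains.append((m, -stability, i))
        gains.sort(key=lambda t: (-t[0], t[1], t[2]))
        m_best, neg_stab, victim = gains[0]
        removed.append((posterior.bin_ids[victim], m_best,
                        "order_instability"))
        keep = [k for k in keep if k != victim]
        mass, order = best_mass(keep)
    if len(keep) < 2:
        warnings.warn("robust map degenerate: fewer than 2 bins remain")

    ordered_bins = [bins[i] for i in order]
    removed_frame = pd.DataFrame(removed, columns=["bin", "mass_after", "reason"])
    return RobustMap(bins=ordered_bins, positions_cr=np.zeros(len(ordered_bins)),
                     support=mass, removed=removed_frame)


def map_lod(posterior: OrderPosterior) -> float:
    """log10 ratio of best to second-best posterior order mass.

    Saturated (single sampled order) posteriors report +inf."""
    masses = posterior.masses()
    if len(masses) < 2:
        return float("inf")
    return float(np.log10(masses[0][1] / masses[1][1]))


def finalize_distances(robust: RobustMap, panel: RHPanel,
                       reference_order: list[str] | None = None,
                       tol: float = 1e-9, eps_fn: float = 0.0,
                       eps_fp: float = 0.0) -> RobustMap:
    """Fit the diploid equal-retention model on the robust order.

    Co-positioned markers in one bin share the bin position; the map is
    anchored to chromosome orientation by the reference order when provided
    (the orientation correlating better with the reference wins)."""
    reps = [b[0] for b in robust.bins]
    if len(reps) < 2:
        return robust
    fit = em_fit(None, panel.vectors_for(reps), model=DIPLOID, tol=tol,
                 eps_fn=eps_fn, eps_fp=eps_fp)
    positions = fit.positions_cr
    if reference_order is not None:
        rank = {m: i for i, m in enumerate(reference_order)}
        ranks = np.array([min(rank.get(m, np.inf) for m in b) for b in robust.bins])
        ok = np.isfinite(ranks)
        if ok.sum() >= 2:
            forward = np.corrcoef(positions[ok], ranks[ok])[0, 1]
            if forward < 0:
                robust.bins = robust.bins[::-1]
                positions = positions[-1] - positions[::-1]
                fit.params.thetas = fit.params.thetas[::-1]
    robust.positions_cr = positions
    robust.params = fit.params
    return robust


def build_robust_map(rh_map: RHMap, panel: RHPanel,
                     reference_order: list[str] | None = None,
                     mcmc_config: McmcConfig | None = None,
                     threshold: float = 0.95) -> tuple[RobustMap, OrderPosterior]:
    """LKH map -> bin collapse -> MCMC -> >=threshold extraction -> distances."""
    mcmc_config = mcmc_config or McmcConfig()
    bins = collapse_cohorts(panel, rh_map.order)
    posterior = mcmc_orders(rh_map, panel, reference_order, mcmc_config, bins=bins)
    robust = extract_robust(posterior, threshold=threshold, bins=bins)
    robust.map_lod = map_lod(posterior)
    robust = finalize_distances(robust, panel, reference_order,
                                eps_fn=mcmc_config.eps_fn,
                                eps_fp=mcmc_config.eps_fp)
    return robust, posterior
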