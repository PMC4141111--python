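"""Markov retention models for radiation-hybrid vectors.

A hybrid clone retains random irradiation-induced fragments of the donor
genome. Along an ordered set of markers, retention forms a two-state Markov
chain: a marker starts a new fragment with breakage probability theta in each
inter-marker interval, and every fragment is retained independently with
probability r. The haploid chain has

    P(S_1 = 1) = r
    P(S_{k+1} = 1 | S_k = 1) = (1 - theta_k) + theta_k * r
    P(S_{k+1} = 1 | S_k = 0) = theta_k * r

The diploid equal-retention model runs two independent copies of this chain
with shared (r, theta) and emits the OR of the two states: donor cells are
diploid, so a marker is observed as present when either copy retains it.

Observation errors are an explicit emission layer: a retained marker is
observed absent with probability ``eps_fn`` and an absent one observed present
with probability ``eps_fp``; missing observations are marginalised. Distances
are in centiRays, d = -100 * ln(1 - theta), so 1 cR is a 1% breakage chance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .panel import MISSING, RETAINED, UNRETAINED

HAPLOID = "haploid"
DIPLOID = "diploid_equal"

_TINY = 1e-300


# ----------------------------------------------------------------------
# distance conversion
# ----------------------------------------------------------------------
def theta_to_cr(theta: float | np.ndarray) -> float | np.ndarray:
    """Breakage probability -> centiRay distance, d = -100 ln(1 - theta).

    theta = 1 maps to +inf (unlinked)."""
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta > 1)):
        raise ValueError("theta must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        d = -100.0 * np.log1p(-theta)
    return float(d) if d.ndim == 0 else d


def cr_to_theta(d: float | np.ndarray) -> float | np.ndarray:
    """centiRay distance -> breakage probability, theta = 1 - exp(-d/100)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    theta = -np.expm1(-d / 100.0)
    return float(theta) if theta.ndim == 0 else theta


# ----------------------------------------------------------------------
# parameters
# ----------------------------------------------------------------------
@dataclass
class RHModelParams:
    """Parameters of the retention chain.

    r : per-fragment retention probability.
    thetas : breakage probability per adjacent interval (length = markers - 1).
    eps_fn, eps_fp : emission error probabilities (false negative / positive).
    model : "haploid" or "diploid_equal".
    """

    r: float
    thetas: np.ndarray
    # genotyping-error emission extension; set both to 0 for the exact
    # textbook retention chain
    eps_fn: float = 0.05
    eps_fp: float = 0.005
    model: str = HAPLOID

    def __post_init__(self) -> None:
        self.thetas = np.atleast_1d(np.asarray(self.thetas, dtype=float))
        probs = np.concatenate([[self.r, self.eps_fn, self.eps_fp], self.thetas])
        if not np.all(np.isfinite(probs)) or np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("all parameters must be probabilities in [0, 1]")
        if self.model not in (HAPLOID, DIPLOID):
            raise ValueError(f"unknown model {self.model!r}")

    def positions_cr(self) -> np.ndarray:
        """Cumulative centiRay positions (0 at the first marker)."""
        return np.concatenate([[0.0], np.cumsum(theta_to_cr(self.thetas))])


# ----------------------------------------------------------------------
# building blocks
# ----------------------------------------------------------------------
def _haploid_transition(theta: float, r: float) -> np.ndarray:
    """2x2 transition matrix over states (0=absent, 1=retained)."""
    return np.array([
        [1.0 - theta * r, theta * r],
        [theta * (1.0 - r), (1.0 - theta) + theta * r],
    ])


def _diploid_transition(theta: float, r: float) -> np.ndarray:
    """4x4 joint transition for two independent copies; states (s1, s2)."""
    t = _haploid_transition(theta, r)
    return np.kron(t, t)


def _haploid_init(r: float) -> np.ndarray:
    return np.array([1.0 - r, r])


def _diploid_init(r: float) -> np.ndarray:
    pi = _haploid_init(r)
    return np.kron(pi, pi)


def _emission_table(params: RHModelParams, n_states: int) -> dict[int, np.ndarray]:
    """Map observation symbol -> per-state emission probability vector.

    For the diploid joint states (0,0),(0,1),(1,0),(1,1) the emitted presence
    follows the OR of the two copies."""
    if n_states == 2:
        present = np.array([params.eps_fp, 1.0 - params.eps_fn])
    else:
        any_ret = np.array([0.0, 1.0, 1.0, 1.0])
        present = np.where(any_ret > 0, 1.0 - params.eps_fn, params.eps_fp)
    return {
        RETAINED: present,
        UNRETAINED: 1.0 - present,
        MISSING: np.ones(n_states),
    }


def _ordered(vectors: np.ndarray, order: np.ndarray | list | None) -> np.ndarray:
    vectors = np.asarray(vectors)
    if vectors.ndim != 2:
        raise ValueError("vectors must be clones x markers")
    if order is None:
        return vectors
    order = np.asarray(order, dtype=int)
    return vectors[:, order]


def _forward(vectors: np.ndarray, params: RHModelParams) -> np.ndarray:
    """Scaled forward algorithm; returns per-clone log-likelihoods.

    Vectorised over clones; the marker loop builds transition matrices from
    the per-interval thetas."""
    n_clones, m = vectors.shape
    if len(params.thetas) != max(m - 1, 0):
        raise ValueError("thetas length must equal markers - 1")
    n_states = 2 if params.model == HAPLOID else 4
    init = _haploid_init(params.r) if n_states == 2 else _diploid_init(params.r)
    emit = _emission_table(params, n_states)

    emis0 = np.empty((n_clones, n_states))
    for sym, e in emit.items():
        emis0[vectors[:, 0] == sym] = e
    alpha = init[None, :] * emis0
    scale = alpha.sum(axis=1)
    loglik = np.log(np.maximum(scale, _TINY))
    alpha = alpha / np.maximum(scale, _TINY)[:, None]

    for k in range(1, m):
        trans = (_haploid_transition(params.thetas[k - 1], params.r) if n_states == 2
                 else _diploid_transition(params.thetas[k - 1], params.r))
        emis = np.empty((n_clones, n_states))
        for sym, e in emit.items():
            emis[vectors[:, k] == sym] = e
        alpha = (alpha @ trans) * emis
        scale = alpha.sum(axis=1)
        loglik += np.log(np.maximum(scale, _TINY))
        alpha = alpha / np.maximum(scale, _TINY)[:, None]
    return loglik


def haploid_loglik(order, vectors, params: RHModelParams) -> float:
    """Total log-likelihood of the panel under the haploid retention chain."""
    params = replace(params, model=HAPLOID)
    return float(_forward(_ordered(vectors, order), params).sum())


def diploid_loglik(order, vectors, params: RHModelParams) -> float:
    """Total log-likelihood under the diploid equal-retention model."""
    params = replace(params, model=DIPLOID)
    return float(_forward(_ordered(vectors, order), params).sum())


def loglik(order, vectors, params: RHModelParams) -> float:
    if params.model == DIPLOID:
        return diploid_loglik(order, vectors, params)
    return haploid_loglik(order, vectors, params)


# ----------------------------------------------------------------------
# enumeration oracle
# ----------------------------------------------------------------------
def enumerate_loglik(order, vectors, params: RHModelParams) -> float:
    """Exact log-likelihood by brute-force summation over hidden state paths.

    Verification oracle for the forward algorithm; rejects instances whose
    path space is too large (> 12 markers haploid, > 6 diploid)."""
    vectors = _ordered(vectors, order)
    m = vectors.shape[1]
    limit = 12 if params.model == HAPLOID else 6
    if m > limit:
        raise ValueError(f"enumeration limited to {limit} markers for {params.model}")

    init = _haploid_init(params.r)
    transitions = [_haploid_transition(t, params.r) for t in params.thetas]

    def path_prob(path: tuple[int, ...]) -> float:
        p = init[path[0]]
        for k in range(1, m):
            p *= transitions[k - 1][path[k - 1], path[k]]
        return p

    emit = _emission_table(params, 2)
    total = 0.0
    paths = list(itertools.product((0, 1), repeat=m))
    for clone in vectors:
        clone_p = 0.0
        if params.model == HAPLOID:
            for path in paths:
                pe = path_prob(path)
                for k in range(m):
                    pe *= emit[int(clone[k])][path[k]]
                clone_p += pe
        else:
            for p1 in paths:
                pp1 = path_prob(p1)
                for p2 in paths:
                    pe = pp1 * path_prob(p2)
                    for k in range(m):
                        state = 1 if (p1[k] or p2[k]) else 0
                        pe *= emit[int(clone[k])][state]
                    clone_p += pe
        total += np.log(max(clone_p, _TINY))
    return float(total)


# ----------------------------------------------------------------------
# two-point estimation
# ----------------------------------------------------------------------
@dataclass
class TwoPointResult:
    """MLE of a marker pair under the haploid chain, with linkage LOD."""

    theta_hat: float
    r_hat: float
    lod: float
    d_cr: float
    n_informative: int
    unlinked: bool = False


def _pair_counts(vec_i: np.ndarray, vec_j: np.ndarray) -> np.ndarray:
    """3x3 table of joint observation counts, axes over (1, 0, missing)."""
    symbols = (RETAINED, UNRETAINED, MISSING)
    counts = np.zeros((3, 3))
    for a, sa in enumerate(symbols):
        mask_a = vec_i == sa
        for b, sb in enumerate(symbols):
            counts[a, b] = np.count_nonzero(mask_a & (vec_j == sb))
    return counts


def pair_log_cell_probs(theta, r, eps_fn: float = 0.0, eps_fp: float = 0.0) -> np.ndarray:
    """Log probabilities of the 9 observable cells for a marker pair.

    Broadcasts over array-valued theta/r; last two axes index the cell table
    over (present, absent, missing) x (present, absent, missing)."""
    theta = np.asarray(theta, dtype=float)
    r = np.asarray(r, dtype=float)
    shape = np.broadcast_shapes(theta.shape, r.shape)
    theta = np.broadcast_to(theta, shape)
    r = np.broadcast_to(r, shape)

    # hidden joint P(s1, s2)
    p1 = np.stack([1 - r, r])                         # (2, ...)
    t11 = (1 - theta) + theta * r
    t01 = theta * r
    trans = np.stack([np.stack([1 - t01, t01]), np.stack([1 - t11, t11])])  # (s1, s2, ...)
    joint = p1[:, None, ...] * trans                  # (s1, s2, ...)

    e_present = np.array([eps_fp, 1 - eps_fn])        # per hidden state
    e_absent = 1 - e_present
    obs_emit = np.stack([e_present, e_absent, np.ones(2)])   # (obs, state)

    # P(o1, o2) = sum_{s1,s2} joint * e(o1|s1) e(o2|s2)
    cells = np.einsum("ab...,xa,yb->...xy", joint, obs_emit, obs_emit)
    return np.log(np.maximum(cells, _TINY))


def _pair_loglik(counts: np.ndarray, theta, r, eps_fn=0.0, eps_fp=0.0):
    logp = pair_log_cell_probs(theta, r, eps_fn, eps_fp)
    return np.einsum("...xy,xy->...", logp, counts)


def _golden_max(fun, lo: float, hi: float, tol: float = 1e-6) -> float:
    """Golden-section maximisation of a unimodal scalar function."""
    invphi = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = fun(c), fun(d)
    while b - a > tol:
        if fc >= fd:     # ties toward smaller argument
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fun(d)
    return c if fc >= fd else d


def two_point_estimate(vec_i, vec_j, eps_fn: float = 0.0, eps_fp: float = 0.0,
                       min_informative: int = 10) -> TwoPointResult:
    """Maximum-likelihood (theta, r) for a marker pair and the linkage LOD.

    LOD compares the fitted linked model against independence (theta = 1 with
    its own retention MLE), in log10 units. Pairs with fewer than
    ``min_informative`` doubly non-missing clones are reported unlinked."""
    vec_i = np.asarray(vec_i)
    vec_j = np.asarray(vec_j)
    counts = _pair_counts(vec_i, vec_j)
    n_informative = int(counts[:2, :2].sum())
    if n_informative < min_informative:
        warnings.warn(f"only {n_informative} informative clones; pair treated as unlinked")
        return TwoPointResult(1.0, float("nan"), 0.0, float("inf"),
                              n_informative, unlinked=True)

    theta_grid = np.linspace(0.0, 0.99, 100)
    r_grid = np.linspace(0.02, 0.98, 49)
    ll = _pair_loglik(counts, theta_grid[:, None], r_grid[None, :], eps_fn, eps_fp)
    it, ir = np.unravel_index(np.argmax(ll), ll.shape)
    theta0, r0 = float(theta_grid[it]), float(r_grid[ir])

    # alternate 1-D golden-section refinements
    theta_hat, r_hat = theta0, r0
    for _ in range(3):
        theta_hat = _golden_max(
            lambda t: _pair_loglik(counts, t, r_hat, eps_fn, eps_fp),
            max(theta_hat - 0.02, 0.0), min(theta_hat + 0.02, 1.0))
        r_hat = _golden_max(
            lambda r: _pair_loglik(counts, theta_hat, r, eps_fn, eps_fp),
            max(r_hat - 0.03, 1e-6), min(r_hat + 0.03, 1 - 1e-6))
    ll_hat = float(_pair_loglik(counts, theta_hat, r_hat, eps_fn, eps_fp))

    r_ind = _golden_max(
        lambda r: _pair_loglik(counts, 1.0, r, eps_fn, eps_fp), 1e-6, 1 - 1e-6)
    ll_ind = float(_pair_loglik(counts, 1.0, r_ind, eps_fn, eps_fp))

    lod = max((ll_hat - ll_ind) / np.log(10.0), 0.0)
    return TwoPointResult(theta_hat=theta_hat, r_hat=r_hat, lod=lod,
                          d_cr=theta_to_cr(min(theta_hat, 1.0 - 1e-12)),
                          n_informative=n_informative)


# ----------------------------------------------------------------------
# EM multipoint fit
# ----------------------------------------------------------------------
@dataclass
class EMResult:
    params: RHModelParams
    loglik: float
    positions_cr: np.ndarray
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


def _forward_backward(vectors: np.ndarray, params: RHModelParams):
    """Scaled forward-backward; returns (alpha, beta, emissions, loglik/clone).

    alpha[k] is scaled so rows sum to 1; beta is scaled compatibly so that
    posterior gamma = alpha * beta / sum."""
    n_clones, m = vectors.shape
    n_states = 2 if params.model == HAPLOID else 4
    init = _haploid_init(params.r) if n_states == 2 else _diploid_init(params.r)
    emit = _emission_table(params, n_states)

    emis = np.empty((m, n_clones, n_states))
    for k in range(m):
        for sym, e in emit.items():
            emis[k][vectors[:, k] == sym] = e

    trans = np.empty((max(m - 1, 0), n_states, n_states))
    for k in range(m - 1):
        trans[k] = (_haploid_transition(params.thetas[k], params.r) if n_states == 2
                    else _diploid_transition(params.thetas[k], params.r))

    alpha = np.empty((m, n_clones, n_states))
    scales = np.empty((m, n_clones))
    a = init[None, :] * emis[0]
    scales[0] = np.maximum(a.sum(axis=1), _TINY)
    alpha[0] = a / scales[0][:, None]
    for k in range(1, m):
        a = (alpha[k - 1] @ trans[k - 1]) * emis[k]
        scales[k] = np.maximum(a.sum(axis=1), _TINY)
        alpha[k] = a / scales[k][:, None]

    beta = np.empty((m, n_clones, n_states))
    beta[m - 1] = 1.0
    for k in range(m - 2, -1, -1):
        b = (beta[k + 1] * emis[k + 1]) @ trans[k].T
        beta[k] = b / scales[k + 1][:, None]

    loglik = np.log(scales).sum(axis=0)
    return alpha, beta, emis, trans, scales, loglik


def em_fit(order, vectors, model: str = DIPLOID, r_init: float = 0.3,
           eps_fn: float = 0.0, eps_fp: float = 0.0, tol: float = 1e-9,
           max_iter: int = 2000) -> EMResult:
    """Fit per-interval breakage probabilities and shared retention by EM.

    The complete data augment the chain with per-interval breakpoint
    indicators and per-fragment retention draws, which gives closed-form
    M-steps: theta_k is the mean posterior breakpoint probability in interval
    k, and r is the posterior fraction of fragment starts that were retained
    (initial fragments plus one new fragment per breakpoint, per copy).
    Iterates until the log-likelihood improves by less than ``tol``.
    """
    vectors = _ordered(vectors, order)
    n_clones, m = vectors.shape
    if m < 2:
        params = RHModelParams(r=r_init, thetas=np.empty(0), eps_fn=eps_fn,
                               eps_fp=eps_fp, model=model)
        ll = loglik(None, vectors, params) if m == 1 else 0.0
        return EMResult(params, ll, np.zeros(m), 0, True)

    n_copies = 1 if model == HAPLOID else 2
    params = RHModelParams(r=r_init, thetas=np.full(m - 1, 0.1),
                           eps_fn=eps_fn, eps_fp=eps_fp, model=model)
    prev_ll = -np.inf
    trace = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        alpha, beta, emis, trans, scales, ll_clone = _forward_backward(vectors, params)
        ll = float(ll_clone.sum())
        trace.append(ll)

        # posterior transition probabilities xi[k] per clone: (n_clones, S, S)
        r = params.r
        exp_breaks = np.empty(m - 1)
        exp_ret_new = np.empty(m - 1)
        if model == HAPLOID:
            q = np.array([1.0 - r, r])          # fragment state probability
        for k in range(m - 1):
            theta = params.thetas[k]
            num = (alpha[k][:, :, None] * trans[k][None, :, :]
                   * (emis[k + 1] * beta[k + 1])[:, None, :])
            xi = num / scales[k + 1][:, None, None]
            if model == HAPLOID:
                # P(break | s -> s') = theta * q(s') / T(s, s')
                with np.errstate(divide="ignore", invalid="ignore"):
                    pb = np.where(trans[k] > 0, theta * q[None, :] / np.maximum(trans[k], _TINY), 0.0)
                    pr = np.where(trans[k] > 0, theta * r / np.maximum(trans[k], _TINY), 0.0)
                pr = pr * np.array([0.0, 1.0])[None, :]   # only s' = retained
                exp_breaks[k] = float((xi * pb[None, :, :]).sum()) / n_clones
                exp_ret_new[k] = float((xi * pr[None, :, :]).sum())
            else:
                t1 = _haploid_transition(theta, r)
                with np.errstate(divide="ignore", invalid="ignore"):
                    pb1 = np.where(t1 > 0, theta * np.array([1 - r, r])[None, :] / np.maximum(t1, _TINY), 0.0)
                    pr1 = np.where(t1 > 0, theta * r / np.maximum(t1, _TINY), 0.0)
                pr1 = pr1 * np.array([0.0, 1.0])[None, :]
                # joint state index = s1 * 2 + s2; expected per-copy sums
                pb = np.empty((4, 4))
                pr = np.empty((4, 4))
                for s1 in range(2):
                    for s2 in range(2):
                        for u1 in range(2):
                            for u2 in range(2):
                                pb[s1 * 2 + s2, u1 * 2 + u2] = pb1[s1, u1] + pb1[s2, u2]
                                pr[s1 * 2 + s2, u1 * 2 + u2] = pr1[s1, u1] + pr1[s2, u2]
                exp_breaks[k] = float((xi * pb[None, :, :]).sum()) / (n_clones * 2)
                exp_ret_new[k] = float((xi * pr[None, :, :]).sum())

        gamma0 = alpha[0] * beta[0]
        gamma0 = gamma0 / np.maximum(gamma0.sum(axis=1, keepdims=True), _TINY)
        if model == HAPLOID:
            exp_ret_start = float(gamma0[:, 1].sum())
        else:
            copies = np.array([0.0, 1.0, 1.0, 2.0])
            exp_ret_start = float((gamma0 * copies[None, :]).sum())

        total_starts = n_clones * n_copies + exp_breaks.sum() * n_clones * n_copies
        total_retained = exp_ret_start + exp_ret_new.sum()
        new_r = float(np.clip(total_retained / max(total_starts, _TINY), 1e-9, 1 - 1e-9))
        new_thetas = np.clip(exp_breaks, 0.0, 1.0 - 1e-12)

        if ll - prev_ll < tol and n_iter > 1:
            converged = True
            params = RHModelParams(r=new_r, thetas=new_thetas, eps_fn=eps_fn,
                                   eps_fp=eps_fp, model=model)
            break
        prev_ll = ll
        params = RHModelParams(r=new_r, thetas=new_thetas, eps_fn=eps_fn,
                               eps_fp=eps_fp, model=model)
    else:
        warnings.warn(f"EM did not converge after {max_iter} iterations")

    final_ll = loglik(None, vectors, params)
    trace.append(final_ll)
    return EMResult(params=params, loglik=final_ll,
                    positions_cr=params.positions_cr(), n_iter=n_iter,
                    converged=converged, loglik_trace=np.asarray(trace))
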