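"""Genotype calling of RH clones from raw two-allele SNP-array intensities.

Cross-species arrays give a built-in empirical null: a subset of array SNPs
("negative SNPs") has no conserved target in the donor genome and shows
background intensity in every sample, including the whole-genome positive
control. Within each clone, those negative SNPs describe the intensity
distribution of a non-retained SNP, so the p-value that a SNP is not retained
is simply the fraction of negative-SNP Imax values exceeding the observed
Imax (floored at 1/Nneg when none exceeds). Storey q-values then control the
FDR for "retained" calls, and 1 - pi0 estimates the panel retention fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .panel import MISSING, RETAINED, UNRETAINED, RHPanel

CLONE = "clone"
POSITIVE_CONTROL = "positive_control"
NEGATIVE_CONTROL = "negative_control"

# per-array q-value thresholds below which an ambiguous point is "missing"
ARRAY_MISSING_Q = {"ovine": 0.10, "bovine": 0.05}


@dataclass
class CallingConfig:
    """Thresholds of the calling and QC procedure.

    fdr_retained : q-value at or below which a point is called retained.
    q_missing : per-array upper q-value bound for the "missing" call band.
    snp_retention_min/max : per-SNP retention window outside which a SNP is
        dropped (cross-hybridising or dead probes).
    clone_retention_max : clones retaining more than this are dropped.
    negative_quantile : fallback quantile when the control Imax distribution
        has no detectable antimode.
    pi0_lambda : fixed censoring point for the pi0 estimator, or None for the
        smoother over the 0.05..0.90 grid.
    """

    fdr_retained: float = 0.01
    q_missing: dict = field(default_factory=lambda: dict(ARRAY_MISSING_Q))
    snp_retention_min: float = 0.10
    snp_retention_max: float = 0.50
    clone_retention_max: float = 0.90
    negative_quantile: float = 0.05
    pi0_lambda: float | None = None

    def __post_init__(self) -> None:
        for thr in self.q_missing.values():
            if not (0 < self.fdr_retained < thr <= 1):
                raise ValueError("need 0 < fdr_retained < q_missing <= 1")
        if not (0 <= self.snp_retention_min < self.snp_retention_max <= 1):
            raise ValueError("invalid SNP retention window")


@dataclass
class IntensityMatrix:
    """Imax per (sample, SNP), with sample roles.

    imax : (n_samples, n_snps) array of per-cell max allele intensities.
    roles : per-sample role in {clone, positive_control, negative_control}.
    """

    imax: np.ndarray
    sample_ids: list[str]
    snp_ids: list[str]
    roles: dict[str, str]
    n_rejected: int = 0

    @property
    def clone_ids(self) -> list[str]:
        return [s for s in self.sample_ids if self.roles.get(s, CLONE) == CLONE]

    def row(self, sample_id: str) -> np.ndarray:
        return self.imax[self.sample_ids.index(sample_id)]

    def positive_control_row(self) -> np.ndarray:
        for s in self.sample_ids:
            if self.roles.get(s) == POSITIVE_CONTROL:
                return self.row(s)
        raise ValueError("no positive-control sample present")

    @classmethod
    def from_long(cls, intensities: pd.DataFrame,
                  samples: pd.DataFrame | None = None) -> "IntensityMatrix":
        """Build from a long table (sample_id, snp_id, intensity_A, intensity_B).

        Rows with negative or non-finite intensities are rejected and counted.
        ``samples`` maps sample_id -> role; absent samples default to clones.
        """
        need = {"sample_id", "snp_id", "intensity_A", "intensity_B"}
        if not need.issubset(intensities.columns):
            raise ValueError(f"intensity table must have columns {sorted(need)}")
        a = intensities["intensity_A"].to_numpy(float)
        b = intensities["intensity_B"].to_numpy(float)
        ok = np.isfinite(a) & np.isfinite(b) & (a >= 0) & (b >= 0)
        n_rejected = int((~ok).sum())
        if n_rejected:
            warnings.warn(f"rejected {n_rejected} records with invalid intensities")
        sub = intensities.loc[ok].copy()
        sub["imax"] = compute_imax(sub["intensity_A"].to_numpy(float),
                                   sub["intensity_B"].to_numpy(float))
        wide = sub.pivot_table(index="sample_id", columns="snp_id", values="imax",
                               aggfunc="first")
        roles = {}
        if samples is not None:
            roles = dict(zip(samples["sample_id"].astype(str), samples["role"]))
        sample_ids = [str(s) for s in wide.index]
        return cls(imax=wide.to_numpy(float), sample_ids=sample_ids,
                   snp_ids=[str(s) for s in wide.columns], roles=roles,
                   n_rejected=n_rejected)


@dataclass
class CallingResult:
    """Full output of the calling stage, before and after QC."""

    panel: RHPanel                     # QC-filtered panel
    calls_raw: np.ndarray              # pre-QC calls, clones x snps
    pvalues: np.ndarray
    qvalues: np.ndarray
    pi0_hat: float
    negative_snps: list[str]
    qc_report: pd.DataFrame

    @property
    def retention_estimate(self) -> float:
        """Panel retention fraction, 1 - pi0."""
        return 1.0 - self.pi0_hat

    @property
    def n_neg(self) -> int:
        return len(self.negative_snps)


# ----------------------------------------------------------------------
# elementary operations
# ----------------------------------------------------------------------
def compute_imax(intensity_a, intensity_b):
    """Per-cell calling statistic: max of the two allele intensities."""
    a = np.asarray(intensity_a, dtype=float)
    b = np.asarray(intensity_b, dtype=float)
    if np.any(~np.isfinite(a) | ~np.isfinite(b)) or np.any(a < 0) or np.any(b < 0):
        raise ValueError("intensities must be finite and non-negative")
    return np.maximum(a, b)


def identify_negative_snps(control_imax: np.ndarray, snp_ids: list[str],
                           config: CallingConfig | None = None) -> list[str]:
    """Split the positive-control Imax mixture at its antimode.

    The control sample is a whole-genome donor DNA: SNPs conserved enough to
    hybridise sit in a high mode, non-conserved ("negative") SNPs in a low
    background mode. A kernel-density antimode between the two largest modes
    defines the cut; if the density is unimodal a low-quantile fallback is
    used with a warning."""
    config = config or CallingConfig()
    x = np.log(np.maximum(np.asarray(control_imax, float), 1e-12))
    grid = np.linspace(x.min(), x.max(), 512)
    dens = gaussian_kde(x)(grid)
    # local maxima / minima of the smoothed density
    up = dens[1:-1] > dens[:-2]
    down = dens[1:-1] > dens[2:]
    peaks = np.flatnonzero(up & down) + 1
    if len(peaks) < 2:
        warnings.warn("control Imax distribution looks unimodal; "
                      f"falling back to the {config.negative_quantile:.0%} quantile rule")
        cut = np.quantile(x, config.negative_quantile)
        neg = [s for s, v in zip(snp_ids, x) if v <= cut]
        if not neg:
            warnings.warn("no negative SNPs detected")
        return neg
    top2 = peaks[np.argsort(dens[peaks])][-2:]
    lo, hi = sorted(top2)
    valley = lo + int(np.argmin(dens[lo:hi + 1]))
    cut = grid[valley]
    neg = [s for s, v in zip(snp_ids, x) if v <= cut]
    if not neg:
        warnings.warn("no negative SNPs detected")
    return neg


def empirical_pvalues(clone_imax: np.ndarray, negative_imax: np.ndarray) -> np.ndarray:
    """P(not retained) per SNP: exceedance fraction in the clone's own null.

    p = #{negative Imax strictly greater than observed} / Nneg, floored at
    1/Nneg when no negative value exceeds the observation."""
    negative_imax = np.asarray(negative_imax, float)
    n_neg = negative_imax.size
    if n_neg == 0:
        raise ValueError("empty negative-SNP set: no empirical null available")
    neg_sorted = np.sort(negative_imax)
    exceed = n_neg - np.searchsorted(neg_sorted, np.asarray(clone_imax, float),
                                     side="right")
    p = exceed / n_neg
    return np.where(exceed == 0, 1.0 / n_neg, p)


def estimate_pi0(pvalues: np.ndarray, lam: float | None = None) -> float:
    """Proportion of true nulls by the censoring estimator.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)). With ``lam`` fixed the
    single-point estimate is returned (deterministic test mode); otherwise
    pi0(lambda) is evaluated on the 0.05..0.90 grid and a cubic fit is read
    off at the terminal lambda, following the reference q-value procedure."""
    p = np.asarray(pvalues, float).ravel()
    p = p[np.isfinite(p)]
    m = p.size
    if m == 0:
        raise ValueError("no p-values")

    def point(l):
        return (p > l).sum() / (m * (1.0 - l))

    if lam is not None:
        pi0 = point(lam)
    else:
        grid = np.arange(0.05, 0.9001, 0.05)
        vals = np.array([point(l) for l in grid])
        coef = np.polyfit(grid, vals, 3)
        pi0 = float(np.polyval(coef, grid[-1]))
    if pi0 > 1.0:
        warnings.warn(f"pi0 estimate {pi0:.3f} > 1, clamped to 1")
        pi0 = 1.0
    return float(max(pi0, 0.0))


def estimate_qvalues(pvalues: np.ndarray,
                     lam: float | None = None) -> tuple[np.ndarray, float]:
    """Storey q-values: q_i = min_{t >= p_i} pi0 * m * t / rank(t).

    Returns (qvalues, pi0_hat); q-values are monotone in p and capped at 1."""
    p = np.asarray(pvalues, float)
    shape = p.shape
    flat = p.ravel()
    finite = np.isfinite(flat)
    pi0 = estimate_pi0(flat[finite], lam=lam)
    m = int(finite.sum())
    order = np.argsort(flat[finite], kind="stable")
    sorted_p = flat[finite][order]
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * sorted_p / ranks
    # enforce monotonicity from the largest p down
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.full(flat.shape, np.nan)
    idx = np.flatnonzero(finite)[order]
    q[idx] = q_sorted
    return q.reshape(shape), pi0


def call_genotypes(qvalues: np.ndarray, array_source: str,
                   config: CallingConfig | None = None) -> np.ndarray:
    """Three-way call from q-values.

    q <= fdr_retained -> retained; fdr_retained < q < per-array missing
    threshold -> missing (ambiguous band); q >= threshold -> unretained."""
    config = config or CallingConfig()
    if array_source not in config.q_missing:
        raise ValueError(f"unknown array source {array_source!r}; "
                         f"known: {sorted(config.q_missing)}")
    q_miss = config.q_missing[array_source]
    q = np.asarray(qvalues, float)
    calls = np.full(q.shape, UNRETAINED, dtype=np.int8)
    calls[q <= config.fdr_retained] = RETAINED
    calls[(q > config.fdr_retained) & (q < q_miss)] = MISSING
    calls[~np.isfinite(q)] = MISSING
    return calls


def qc_filter(calls: np.ndarray, clone_ids: list[str], marker_ids: list[str],
              config: CallingConfig | None = None,
              marker_meta: pd.DataFrame | None = None,
              truth: np.ndarray | None = None) -> tuple[RHPanel, pd.DataFrame]:
    """Drop implausible SNPs and clones.

    SNPs whose retention over non-missing calls falls outside the
    (retention_min, retention_max) window are removed (a panel at ~35%
    retention cannot legitimately show 60% marker retention), as are clones
    retaining more than clone_retention_max of their markers."""
    config = config or CallingConfig()
    if calls.size == 0:
        raise ValueError("empty call matrix")
    panel = RHPanel(calls=calls, clone_ids=list(clone_ids),
                    marker_ids=list(marker_ids), marker_meta=marker_meta,
                    truth=truth)
    rows = []
    clone_ret = panel.clone_retention()
    keep_clones = np.ones(panel.n_clones, dtype=bool)
    for i, (cid, ret) in enumerate(zip(panel.clone_ids, clone_ret)):
        if np.isfinite(ret) and ret > config.clone_retention_max:
            keep_clones[i] = False
            rows.append(("clone", cid, ret, f"retention>{config.clone_retention_max:.2f}"))
    if not keep_clones.any():
        raise ValueError("QC removed every clone")
    panel = panel.subset(clones=keep_clones)
    marker_ret = panel.marker_retention()
    keep_markers = np.ones(panel.n_markers, dtype=bool)
    for j, (mid, ret) in enumerate(zip(panel.marker_ids, marker_ret)):
        if not np.isfinite(ret):
            keep_markers[j] = False
            rows.append(("snp", mid, ret, "all calls missing"))
        elif ret > config.snp_retention_max:
            keep_markers[j] = False
            rows.append(("snp", mid, ret, f"retention>{config.snp_retention_max:.2f}"))
        elif ret < config.snp_retention_min:
            keep_markers[j] = False
            rows.append(("snp", mid, ret, f"retention<{config.snp_retention_min:.2f}"))
    panel = panel.subset(markers=keep_markers)
    report = pd.DataFrame(rows, columns=["entity", "id", "retention", "reason"])
    return panel, report


def retention_profile(panel: RHPanel, order: list[str] | None = None) -> pd.Series:
    """Per-marker retention frequency in map (or given) order."""
    ret = pd.Series(panel.marker_retention(), index=panel.marker_ids, name="retention")
    if order is not None:
        ret = ret.loc[list(order)]
    return ret


# ----------------------------------------------------------------------
# orchestration
# ----------------------------------------------------------------------
def call_panel(intensities: IntensityMatrix, array_source: str,
               config: CallingConfig | None = None,
               truth: pd.DataFrame | None = None) -> CallingResult:
    """Run the full calling procedure on one array's intensity matrix.

    Identifies negative SNPs on the positive control, computes per-clone
    empirical p-values against the clone's own negative-SNP null, converts to
    q-values, applies the three-way thresholds and the retention QC."""
    config = config or CallingConfig()
    control = intensities.positive_control_row()
    negatives = identify_negative_snps(control, intensities.snp_ids, config)
    neg_set = set(negatives)
    neg_idx = np.array([j for j, s in enumerate(intensities.snp_ids) if s in neg_set],
                       dtype=int)
    test_idx = np.array([j for j, s in enumerate(intensities.snp_ids) if s not in neg_set],
                        dtype=int)
    if neg_idx.size == 0:
        raise ValueError("no negative SNPs: empirical null unavailable")

    clone_ids = intensities.clone_ids
    clone_rows = [intensities.sample_ids.index(c) for c in clone_ids]
    n_clones, n_test = len(clone_rows), test_idx.size
    pvals = np.empty((n_clones, n_test))
    for i, row in enumerate(clone_rows):
        imax = intensities.imax[row]
        pvals[i] = empirical_pvalues(imax[test_idx], imax[neg_idx])

    qvals, pi0 = estimate_qvalues(pvals, lam=config.pi0_lambda)
    calls = call_genotypes(qvals, array_source, config)
    snp_ids = [intensities.snp_ids[j] for j in test_idx]
    truth_sub = None
    if truth is not None:
        # truth is a clone x SNP-id boolean frame; align to the tested SNPs
        # (SNPs absent from the frame are truly never retained)
        truth_sub = (truth.reindex(index=clone_ids)
                     .reindex(columns=snp_ids, fill_value=False)
                     .fillna(False).to_numpy(bool))
    panel, report = qc_filter(calls, clone_ids, snp_ids, config, truth=truth_sub)
    return CallingResult(panel=panel, calls_raw=calls, pvalues=pvals,
                         qvalues=qvals, pi0_hat=pi0, negative_snps=negatives,
                         qc_report=report)


def merge_panels(panels: dict[str, RHPanel]) -> RHPanel:
    """Merge per-array panels after calling, keyed by SNP id.

    Duplicate SNP ids across arrays are suffixed with their source name."""
    if not panels:
        raise ValueError("nothing to merge")
    clone_ids = None
    for source, panel in panels.items():
        if clone_ids is None:
            clone_ids = panel.clone_ids
        elif panel.clone_ids != clone_ids:
            raise ValueError("panels must share the same clones to merge")
    seen: set[str] = set()
    columns, names, truths = [], [], []
    has_truth = all(p.truth is not None for p in panels.values())
    for source, panel in panels.items():
        for j, mid in enumerate(panel.marker_ids):
            name = mid if mid not in seen else f"{mid}_{source}"
            if mid in seen:
                warnings.warn(f"duplicate SNP id {mid!r}; suffixed as {name!r}")
            seen.add(name)
            names.append(name)
            columns.append(panel.calls[:, j])
            if has_truth:
                truths.append(panel.truth[:, j])
    calls = np.column_stack(columns)
    truth = np.column_stack(truths) if has_truth else None
    return RHPanel(calls=calls, clone_ids=list(clone_ids), marker_ids=names,
                   truth=truth)
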