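"""Truth-tagged synthetic RH panels, intensities, scaffolds and comparators.

The generator mirrors a 5000-rad whole-genome RH panel typed on cross-species
SNP arrays: chromosomes fragment at Poisson breakpoints (1 cR per ~32.6 kb at
the panel's resolution), each fragment of each of the two haploid copies is
retained independently with a base probability around 0.35 of diploid marker
retention (per-fragment r around 0.2), a selection locus (the TK1 analogue)
pulls local retention toward 1, and calls are corrupted by 5-7% false
negatives and ~5% missingness. Intensities per (clone, SNP) are a two-class
log-normal mixture with a background class shared by "negative" SNPs that
have no conserved target in the donor genome.

Every output carries its ground truth so downstream stages can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MISSING, RETAINED, UNRETAINED, RHPanel

# 1 cR5000 corresponds to ~32.6 kb in the panel this emulates
DEFAULT_CR_PER_BP = 1.0 / 32_600.0


@dataclass
class SelectionLocus:
    """A locus whose retention is forced up by culture selection (TK1-like)."""

    chromosome: str
    bp: int
    peak: float = 1.0
    decay_bp: float = 2_000_000.0

    def __post_init__(self) -> None:
        if not (0 < self.peak <= 1):
            raise ValueError("peak retention must be in (0, 1]")
        if self.decay_bp <= 0:
            raise ValueError("decay length must be positive")


@dataclass
class GenomeSpec:
    """Synthetic donor genome: chromosomes, marker positions, map density."""

    chromosomes: list[tuple[str, int]]
    markers: dict[str, np.ndarray]
    cr_per_bp: float = DEFAULT_CR_PER_BP
    selection_loci: list[SelectionLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cr_per_bp < 0:
            raise ValueError("cr_per_bp must be non-negative (0 = no breakage)")
        lengths = dict(self.chromosomes)
        for chrom, pos in self.markers.items():
            pos = np.asarray(pos, dtype=np.int64)
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"marker positions on {chrom} must be strictly increasing")
            if pos.size and (pos[0] < 1 or pos[-1] > lengths[chrom]):
                raise ValueError(f"marker positions on {chrom} out of chromosome bounds")
            self.markers[chrom] = pos

    @property
    def breaks_per_bp(self) -> float:
        """Poisson breakage rate per bp: cr_per_bp / 100 (1 cR = 1% breakage)."""
        return self.cr_per_bp / 100.0

    def marker_ids(self) -> list[str]:
        return [f"{chrom}_M{k:04d}" for chrom, pos in self.markers.items()
                for k in range(len(pos))]

    def marker_table(self) -> pd.DataFrame:
        """Marker metadata: id, chromosome, bp and true cR position."""
        rows = []
        for chrom, pos in self.markers.items():
            for k, bp in enumerate(pos):
                rows.append((f"{chrom}_M{k:04d}", chrom, int(bp),
                             float(bp * self.cr_per_bp)))
        return pd.DataFrame(rows, columns=["marker", "chromosome", "bp", "cr"]
                            ).set_index("marker")


def example_genome(n_chromosomes: int = 1, length_bp: int = 10_000_000,
                   n_markers: int = 60, cr_per_bp: float = DEFAULT_CR_PER_BP,
                   selection: bool = False, seed: int = 0) -> GenomeSpec:
    """A small, evenly-markered genome for tests and demonstrations."""
    rng = np.random.default_rng(seed)
    chromosomes = [(f"chr{i + 1}", length_bp) for i in range(n_chromosomes)]
    markers = {}
    for chrom, length in chromosomes:
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=n_markers,
                                 replace=False))
        markers[chrom] = pos
    loci = []
    if selection:
        loci = [SelectionLocus(chromosomes[0][0], length_bp // 2, peak=1.0,
                               decay_bp=length_bp / 10)]
    return GenomeSpec(chromosomes=chromosomes, markers=markers,
                      cr_per_bp=cr_per_bp, selection_loci=loci)


@dataclass
class TruePanel:
    """Ground-truth retained fragments per clone and haplotype copy."""

    spec: GenomeSpec
    n_clones: int
    r_true: float
    # fragments[clone][copy] = list of (chromosome, start_bp, end_bp)
    fragments: list[list[list[tuple[str, int, int]]]]

    def marker_truth(self) -> np.ndarray:
        """(n_clones, n_markers) boolean: marker covered by any retained fragment."""
        offsets = {}
        total = 0
        for chrom, pos in self.spec.markers.items():
            offsets[chrom] = (total, np.asarray(pos))
            total += len(pos)
        truth = np.zeros((self.n_clones, total), dtype=bool)
        for c, copies in enumerate(self.fragments):
            for frags in copies:
                for chrom, start, end in frags:
                    base, pos = offsets[chrom]
                    lo = np.searchsorted(pos, start, side="left")
                    hi = np.searchsorted(pos, end, side="right")
                    if hi > lo:
                        truth[c, base + lo:base + hi] = True
        return truth

    def fragment_lengths(self) -> np.ndarray:
        """Lengths (bp) of all retained fragments."""
        return np.array([end - start for copies in self.fragments
                         for frags in copies for (_, start, end) in frags])


# ----------------------------------------------------------------------
# generative stages
# ----------------------------------------------------------------------
def simulate_fragments(spec: GenomeSpec, n_clones: int, r: float,
                       seed: int) -> TruePanel:
    """Fragment each chromosome at Poisson breakpoints and retain fragments.

    Each of the two haploid copies is cut independently at rate
    ``cr_per_bp / 100`` breaks per bp; a fragment is kept with probability r,
    lifted to max(r, peak * exp(-distance / decay)) when it overlaps or lies
    near a selection locus (distance from the fragment interval to the locus).
    """
    if n_clones < 1:
        raise ValueError("need at least one clone")
    if not (np.isfinite(r) and 0 <= r <= 1):
        raise ValueError("retention probability r must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rate = spec.breaks_per_bp
    loci = {c: [] for c, _ in spec.chromosomes}
    for locus in spec.selection_loci:
        loci[locus.chromosome].append(locus)

    fragments = []
    for _ in range(n_clones):
        copies = []
        for _copy in range(2):
            kept = []
            for chrom, length in spec.chromosomes:
                n_breaks = rng.poisson(rate * length)
                cuts = np.sort(rng.integers(1, length, size=n_breaks)) if n_breaks else np.empty(0, dtype=int)
                bounds = np.concatenate([[0], cuts, [length]]).astype(np.int64)
                for start, end in zip(bounds[:-1], bounds[1:]):
                    if end <= start:
                        continue
                    keep_p = r
                    for locus in loci[chrom]:
                        if start < locus.bp <= end:
                            dist = 0.0
                        else:
                            dist = min(abs(locus.bp - start), abs(locus.bp - end))
                        keep_p = max(keep_p, locus.peak * np.exp(-dist / locus.decay_bp))
                    if rng.random() < keep_p:
                        # fragment covers bp positions start+1 .. end (1-based)
                        kept.append((chrom, int(start + 1), int(end)))
            copies.append(kept)
        fragments.append(copies)
    return TruePanel(spec=spec, n_clones=n_clones, r_true=r, fragments=fragments)


def simulate_observations(panel: TruePanel, fnr: float = 0.07,
                          fpr: float = 0.0, missing_rate: float = 0.05,
                          seed: int = 0) -> RHPanel:
    """Corrupt the true marker retention into observed calls.

    A marker is observed present iff any haplotype copy retains it, flipped
    to absent with probability ``fnr``; truly-absent cells flip to present
    with ``fpr``; finally, calls are masked to missing with ``missing_rate``.
    The truth matrix rides along on the returned panel."""
    for name, rate in (("fnr", fnr), ("fpr", fpr), ("missing_rate", missing_rate)):
        if not (0 <= rate < 1):
            raise ValueError(f"{name} must be in [0, 1)")
    rng = np.random.default_rng(seed)
    truth = panel.marker_truth()
    obs = truth.astype(np.int8)
    flips_fn = truth & (rng.random(truth.shape) < fnr)
    flips_fp = ~truth & (rng.random(truth.shape) < fpr)
    obs[flips_fn] = UNRETAINED
    obs[flips_fp] = RETAINED
    obs[rng.random(truth.shape) < missing_rate] = MISSING
    meta = panel.spec.marker_table()
    return RHPanel(calls=obs,
                   clone_ids=[f"clone{c:03d}" for c in range(panel.n_clones)],
                   marker_ids=list(meta.index), marker_meta=meta, truth=truth)


@dataclass
class IntensityParams:
    """Two-class log-normal intensity mixture parameters (log-scale)."""

    background_mean: float = -1.5
    background_sd: float = 0.4
    retained_mean: float = 1.0
    retained_sd: float = 0.4
    negative_snp_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.retained_mean <= self.background_mean:
            raise ValueError("retained class must sit above background")
        if not (0 <= self.negative_snp_fraction <= 1):
            raise ValueError("negative_snp_fraction must be in [0, 1]")


def simulate_intensities(obs: RHPanel, params: IntensityParams | None = None,
                         seed: int = 0):
    """Raw two-allele intensities consistent with the observed calls.

    A fraction of SNPs is designated "negative": background-distributed in
    every sample including the positive control. Other SNPs draw the
    retained-class intensity where observed present, background otherwise.
    Emits a long intensity table plus a samples table with a positive control
    (all non-negative SNPs on) and a negative control (all background).

    Returns (intensities, samples, negative_snp_ids, matrix-truth) where
    matrix-truth is the clone x SNP truth restricted to non-negative SNPs.
    """
    from .calling import CLONE, NEGATIVE_CONTROL, POSITIVE_CONTROL

    params = params or IntensityParams()
    rng = np.random.default_rng(seed)
    n_clones, n_markers = obs.calls.shape
    n_neg = int(round(params.negative_snp_fraction * n_markers / (1 - params.negative_snp_fraction))) \
        if params.negative_snp_fraction < 1 else 0
    neg_ids = [f"NEG{k:05d}" for k in range(n_neg)]
    snp_ids = list(obs.marker_ids) + neg_ids
    sample_ids = list(obs.clone_ids) + ["wg_control", "host_control"]
    roles = {s: CLONE for s in obs.clone_ids}
    roles["wg_control"] = POSITIVE_CONTROL
    roles["host_control"] = NEGATIVE_CONTROL

    def draw(shape, retained_mask):
        logi = rng.normal(params.background_mean, params.background_sd, size=shape)
        hi = rng.normal(params.retained_mean, params.retained_sd, size=shape)
        return np.exp(np.where(retained_mask, hi, logi))

    present = np.zeros((len(sample_ids), len(snp_ids)), dtype=bool)
    present[:n_clones, :n_markers] = obs.calls == RETAINED
    present[n_clones, :n_markers] = True            # positive control, real SNPs on
    # host (negative) control and negative SNPs stay background everywhere

    imax_target = draw(present.shape, present)
    # two allele channels whose max reproduces the target intensity
    frac = rng.uniform(0.05, 0.95, size=present.shape)
    a = imax_target
    b = imax_target * frac
    swap = rng.random(present.shape) < 0.5
    intensity_a = np.where(swap, b, a)
    intensity_b = np.where(swap, a, b)

    long = pd.DataFrame({
        "sample_id": np.repeat(sample_ids, len(snp_ids)),
        "snp_id": np.tile(snp_ids, len(sample_ids)),
        "intensity_A": intensity_a.ravel(),
        "intensity_B": intensity_b.ravel(),
    })
    samples = pd.DataFrame({"sample_id": sample_ids,
                            "role": [roles[s] for s in sample_ids]})
    truth_frame = None
    if obs.truth is not None:
        truth_frame = pd.DataFrame(obs.truth, index=obs.clone_ids,
                                   columns=obs.marker_ids)
    return long, samples, neg_ids, truth_frame


# ----------------------------------------------------------------------
# comparator genomes and scaffold drafts
# ----------------------------------------------------------------------
def simulate_rearranged_genome(spec: GenomeSpec, n_inversions: int = 0,
                               n_translocations: int = 0,
                               robertsonian: bool = False, seed: int = 0):
    """Second-genome marker coordinates after implanted rearrangements.

    Starts from a collinear copy of the marker table, then applies internal
    inversions, reciprocal translocations of chromosome tails and optionally
    a Robertsonian fusion of the first two chromosomes. Returns the
    comparative table (marker, chrB, bpB) and the list of implanted junctions
    as pairs of flanking markers in donor-genome order."""
    if n_inversions < 0 or n_translocations < 0:
        raise ValueError("rearrangement counts must be >= 0")
    rng = np.random.default_rng(seed)
    table = spec.marker_table().reset_index()
    table["chrB"] = table["chromosome"]
    table["bpB"] = table["bp"]

    per_chrom = {c: table.index[table["chromosome"] == c].to_numpy()
                 for c, _ in spec.chromosomes}
    breakpoints: list[tuple[str, str]] = []

    def record_junction(idx_left: int, idx_right: int) -> None:
        breakpoints.append((table.at[idx_left, "marker"], table.at[idx_right, "marker"]))

    # junctions are implanted with >= 3 markers on each side so the implanted
    # truth is detectable by block scanning at its default minimum block size
    feasible_inv = [c for c, idx in per_chrom.items() if len(idx) >= 9]
    if n_inversions > 0 and not feasible_inv:
        raise ValueError("no chromosome with enough markers for an inversion")
    for _ in range(n_inversions):
        chrom = feasible_inv[rng.integers(len(feasible_inv))]
        idx = per_chrom[chrom]
        i = int(rng.integers(3, len(idx) - 5))
        j = int(rng.integers(i + 2, len(idx) - 3))
        window = idx[i:j + 1]
        table.loc[window, "bpB"] = table.loc[window[::-1], "bpB"].to_numpy()
        record_junction(idx[i - 1], idx[i])
        record_junction(idx[j], idx[j + 1])

    chroms = [c for c, _ in spec.chromosomes]
    if n_translocations > 0 and len(chroms) < 2:
        raise ValueError("reciprocal translocation needs two chromosomes")
    for _ in range(n_translocations):
        ca, cb = rng.choice(len(chroms), size=2, replace=False)
        ca, cb = chroms[ca], chroms[cb]
        ia, ib = per_chrom[ca], per_chrom[cb]
        if len(ia) < 6 or len(ib) < 6:
            raise ValueError("translocation needs >= 6 markers per chromosome")
        cut_a = int(rng.integers(3, len(ia) - 2))
        cut_b = int(rng.integers(3, len(ib) - 2))
        tail_a, tail_b = ia[cut_a:], ib[cut_b:]
        # the exchanged tail is appended after the recipient head, in order:
        # its B coordinates continue from the head's end
        head_a_end = table.loc[ia[:cut_a], "bpB"].max()
        head_b_end = table.loc[ib[:cut_b], "bpB"].max()
        tail_a_bp = table.loc[tail_a, "bpB"].to_numpy()
        tail_b_bp = table.loc[tail_b, "bpB"].to_numpy()
        table.loc[tail_a, "chrB"] = cb
        table.loc[tail_a, "bpB"] = head_b_end + (tail_a_bp - tail_a_bp.min()) + 1
        table.loc[tail_b, "chrB"] = ca
        table.loc[tail_b, "bpB"] = head_a_end + (tail_b_bp - tail_b_bp.min()) + 1
        record_junction(ia[cut_a - 1], ia[cut_a])
        record_junction(ib[cut_b - 1], ib[cut_b])

    if robertsonian:
        if len(chroms) < 2:
            raise ValueError("Robertsonian fusion needs two chromosomes")
        c1, c2 = chroms[0], chroms[1]
        len1 = dict(spec.chromosomes)[c1]
        fused = f"{c1}_{c2}_fused"
        m1 = table["chrB"] == c1
        m2 = table["chrB"] == c2
        table.loc[m1, "chrB"] = fused
        table.loc[m2, "chrB"] = fused
        table.loc[m2, "bpB"] = table.loc[m2, "bpB"] + len1
        record_junction(per_chrom[c1][-1], per_chrom[c2][0])

    comparative = table[["marker", "chrB", "bpB"]].copy()
    return comparative, breakpoints


def simulate_scaffold_split(spec: GenomeSpec, n_scaffolds: int,
                            shuffle_fraction: float = 0.0,
                            invert_fraction: float = 0.0,
                            unplaced_fraction: float = 0.0, seed: int = 0):
    """Partition the genome into scaffolds and implant draft-assembly errors.

    Chromosomes are cut at random marker-free points. A fraction of scaffolds
    is then shuffled in rank, inverted, or withheld as unplaced. Returns
    (scaffolds, marker_map): ``scaffolds`` holds truth and draft placement
    per scaffold, ``marker_map`` maps each marker to its scaffold and local
    bp (in scaffold-forward coordinates)."""
    for name, f in (("shuffle", shuffle_fraction), ("invert", invert_fraction),
                    ("unplaced", unplaced_fraction)):
        if not (0 <= f <= 1):
            raise ValueError(f"{name}_fraction must be in [0, 1]")
    total_markers = sum(len(p) for p in spec.markers.values())
    if n_scaffolds > total_markers:
        raise ValueError("cannot make more scaffolds than markers")
    rng = np.random.default_rng(seed)

    scaffold_rows = []
    marker_rows = []
    sid = 0
    per_chrom = {c: max(1, int(round(n_scaffolds * len(spec.markers[c]) / total_markers)))
                 for c, _ in spec.chromosomes}
    for chrom, length in spec.chromosomes:
        pos = spec.markers[chrom]
        k = min(per_chrom[chrom], len(pos))
        # cut points in marker-free gaps: choose k-1 distinct gaps
        gaps = np.arange(len(pos) - 1)
        chosen = np.sort(rng.choice(gaps, size=min(k - 1, len(gaps)), replace=False)) \
            if k > 1 else np.empty(0, dtype=int)
        cuts = [int((pos[g] + pos[g + 1]) // 2) for g in chosen]
        bounds = [0] + cuts + [length]
        for rank, (start, end) in enumerate(zip(bounds[:-1], bounds[1:])):
            name = f"scaffold{sid:04d}"
            sid += 1
            scaffold_rows.append(dict(scaffold=name, chromosome=chrom,
                                      start=start + 1, end=end,
                                      length=end - start, true_rank=rank,
                                      true_orientation="+"))
            in_scaf = (pos > start) & (pos <= end)
            for j in np.flatnonzero(in_scaf):
                marker_rows.append(dict(marker=f"{chrom}_M{j:04d}", scaffold=name,
                                        scaffold_bp=int(pos[j] - start)))
    scaffolds = pd.DataFrame(scaffold_rows)
    marker_map = pd.DataFrame(marker_rows)

    n = len(scaffolds)
    scaffolds["draft_rank"] = scaffolds["true_rank"]
    scaffolds["draft_orientation"] = "+"
    scaffolds["status"] = "placed"

    pool = rng.permutation(n)
    n_unplaced = int(round(unplaced_fraction * n))
    unplaced = pool[:n_unplaced]
    scaffolds.loc[unplaced, "status"] = "unplaced"
    remaining = pool[n_unplaced:]

    n_invert = int(round(invert_fraction * n))
    inverted = remaining[:n_invert]
    scaffolds.loc[inverted, "draft_orientation"] = "-"

    n_shuffle = int(round(shuffle_fraction * n))
    shuffle_pool = remaining[n_invert:n_invert + n_shuffle]
    # shuffle draft ranks within each chromosome among selected scaffolds
    for chrom, _ in spec.chromosomes:
        sel = [i for i in shuffle_pool if scaffolds.at[i, "chromosome"] == chrom]
        if len(sel) >= 2:
            ranks = scaffolds.loc[sel, "draft_rank"].to_numpy()
            perm = rng.permutation(len(sel))
            while np.all(perm == np.arange(len(sel))):
                perm = rng.permutation(len(sel))
            scaffolds.loc[sel, "draft_rank"] = ranks[perm]

    # renumber draft ranks contiguously per chromosome among placed scaffolds
    for chrom, _ in spec.chromosomes:
        placed = scaffolds[(scaffolds["chromosome"] == chrom)
                           & (scaffolds["status"] == "placed")]
        order = placed.sort_values("draft_rank", kind="stable").index
        for new_rank, i in enumerate(order):
            scaffolds.at[i, "draft_rank"] = new_rank
    scaffolds.loc[scaffolds["status"] == "unplaced", "draft_rank"] = -1
    return scaffolds, marker_map
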