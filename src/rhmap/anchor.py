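"""Anchor draft-assembly scaffolds onto chromosomes using RH maps.

Scaffolds are treated as internally correct (top priority) but re-orderable:
each scaffold's markers vote on its chromosome, an IQR filter discards
suspicious markers, the median map position of the kept markers ranks the
scaffold along the chromosome, and the least-squares slope of map position
on scaffold coordinate orients it (forward/reverse, or unknown when the
slope is indistinguishable from zero). Conflicts defer to the stated
priority: scaffolds > RH map > super-scaffolds > comparator synteny.
Unplaced scaffolds enter only between two contiguous placed scaffolds, via
their strongest two-point linkage to mapped markers. The result serialises
as an AGP 2.0 assembly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .likelihood import two_point_estimate
from .panel import RHPanel
from .robust import RobustMap


@dataclass
class AnchorConfig:
    iqr_multiplier: float = 1.5
    slope_alpha: float = 0.05
    min_unplaced_len: int = 10_000
    gap_length: int = 100
    lod_place: float = 10.0

    def __post_init__(self) -> None:
        if self.iqr_multiplier <= 0 or not (0 < self.slope_alpha < 1):
            raise ValueError("invalid anchoring thresholds")


@dataclass
class ScaffoldPlacement:
    scaffold: str
    chromosome: str
    rank: int
    orientation: str            # '+', '-' or '?'
    anchor_cr: float
    markers_kept: list[str]
    markers_filtered: list[str]
    provenance: str = "rh_map"
    orientation_reason: str = ""


# ----------------------------------------------------------------------
# elementary operations
# ----------------------------------------------------------------------
def tukey_hinges(values: np.ndarray) -> tuple[float, float]:
    """Median-of-halves quartiles; for odd n the halves include the median."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    half = (n + 1) // 2
    return float(np.median(x[:half])), float(np.median(x[n - half:]))


def iqr_filter(values: np.ndarray, multiplier: float = 1.5):
    """Tukey-fence outlier filter; fewer than 4 values pass through."""
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        return np.ones(x.size, dtype=bool)
    q1, q3 = tukey_hinges(x)
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    return (x >= lo) & (x <= hi)


def orient_scaffold(scaffold_bp: np.ndarray, map_cr: np.ndarray,
                    alpha: float = 0.05) -> tuple[str, str]:
    """(orientation, reason) from the OLS slope of map cR on scaffold bp.

    Forward for a significantly positive slope, reverse for a significantly
    negative one, unknown otherwise (single marker, zero bp variance, or a
    slope statistically indistinguishable from 0)."""
    bp = np.asarray(scaffold_bp, dtype=float)
    cr = np.asarray(map_cr, dtype=float)
    if bp.size < 2:
        return "?", "single marker"
    if np.ptp(bp) == 0:
        return "?", "zero bp variance"
    if bp.size == 2:
        # no residual degrees of freedom for a slope test
        return "?", "two markers: slope untestable"
    fit = stats.linregress(bp, cr)
    if fit.pvalue >= alpha or fit.slope == 0:
        return "?", f"slope ~ 0 (p={fit.pvalue:.3g})"
    return ("+", "") if fit.slope > 0 else ("-", "")


def assign_scaffold_chromosome(marker_chroms: list[str]) -> tuple[str, bool]:
    """(majority chromosome, tie flag) for a scaffold's markers."""
    counts = pd.Series(marker_chroms).value_counts()
    best = counts.max()
    winners = sorted(counts.index[counts == best])
    return str(winners[0]), len(winners) > 1


# ----------------------------------------------------------------------
# placement
# ----------------------------------------------------------------------
def _marker_positions(robust_maps: dict[str, RobustMap]) -> pd.DataFrame:
    rows = []
    for chrom, rmap in robust_maps.items():
        for pos, bin_markers in zip(rmap.positions_cr, rmap.bins):
            for mk in bin_markers:
                rows.append((mk, chrom, float(pos)))
    return pd.DataFrame(rows, columns=["marker", "chromosome", "cr"]).set_index("marker")


def place_scaffolds(robust_maps: dict[str, RobustMap],
                    scaffold_markers: pd.DataFrame,
                    super_scaffolds: pd.DataFrame | None = None,
                    comparator_orientation: dict[str, str] | None = None,
                    draft: pd.DataFrame | None = None,
                    config: AnchorConfig | None = None):
    """Place every scaffold with mapped markers.

    scaffold_markers : columns (marker, scaffold, scaffold_bp).
    super_scaffolds : optional columns (super, scaffold, rank).
    comparator_orientation : scaffold -> '+'/'-' fallback orientation from
        conserved synteny with the comparator genome.
    draft : optional current placement (scaffold, chromosome, draft_rank,
        draft_orientation) to diff against; the change report lists every
        departure from it.

    Returns (placements, change_report, pending) where pending lists
    scaffolds whose markers were all filtered."""
    config = config or AnchorConfig()
    positions = _marker_positions(robust_maps)
    merged = scaffold_markers.merge(positions, left_on="marker", right_index=True,
                                    how="inner")
    placements: list[ScaffoldPlacement] = []
    pending = []
    super_rank = {}
    super_of = {}
    if super_scaffolds is not None:
        for row in super_scaffolds.itertuples(index=False):
            super_of[row.scaffold] = row.super
            super_rank[row.scaffold] = row.rank

    for scaffold, grp in merged.groupby("scaffold", sort=True):
        chrom, tie = assign_scaffold_chromosome(list(grp["chromosome"]))
        on_chrom = grp[grp["chromosome"] == chrom]
        keep = iqr_filter(on_chrom["cr"].to_numpy(), config.iqr_multiplier)
        kept = on_chrom.loc[keep]
        filtered = list(on_chrom.loc[~keep, "marker"]) + \
            list(grp.loc[grp["chromosome"] != chrom, "marker"])
        if kept.empty:
            pending.append(scaffold)
            continue
        orientation, reason = orient_scaffold(kept["scaffold_bp"].to_numpy(),
                                              kept["cr"].to_numpy(),
                                              config.slope_alpha)
        provenance = "rh_map"
        if orientation == "?" and comparator_orientation and \
                scaffold in comparator_orientation:
            orientation = comparator_orientation[scaffold]
            provenance = "comparator"
            reason += "; orientation from comparator synteny"
        placements.append(ScaffoldPlacement(
            scaffold=scaffold, chromosome=chrom, rank=-1,
            orientation=orientation, anchor_cr=float(kept["cr"].median()),
            markers_kept=list(kept["marker"]), markers_filtered=filtered,
            provenance=provenance,
            orientation_reason=reason + ("; chromosome tie" if tie else "")))

    # rank along each chromosome; ties/overlapping spans defer to super order
    spans = {}
    for p in placements:
        crs = merged.loc[(merged["scaffold"] == p.scaffold)
                         & (merged["chromosome"] == p.chromosome), "cr"]
        spans[p.scaffold] = (float(crs.min()), float(crs.max()))
    by_chrom: dict[str, list[ScaffoldPlacement]] = {}
    for p in placements:
        by_chrom.setdefault(p.chromosome, []).append(p)
    for chrom, plist in by_chrom.items():
        plist.sort(key=lambda p: (p.anchor_cr, p.scaffold))
        # within runs of mutually overlapping spans, preserve super-scaffold order
        i = 0
        while i < len(plist):
            j = i
            hi = spans[plist[i].scaffold][1]
            while j + 1 < len(plist) and spans[plist[j + 1].scaffold][0] <= hi:
                hi = max(hi, spans[plist[j + 1].scaffold][1])
                j += 1
            if j > i:
                run = plist[i:j + 1]
                supers = {super_of.get(p.scaffold) for p in run} - {None}
                if len(supers) == 1:
                    run.sort(key=lambda p: super_rank.get(p.scaffold, 0))
                    plist[i:j + 1] = run
            i = j + 1
        for rank, p in enumerate(plist):
            p.rank = rank

    change_report = _diff_draft(placements, draft) if draft is not None \
        else pd.DataFrame(columns=["scaffold", "field", "draft", "proposed"])
    return placements, change_report, pending


def _diff_draft(placements: list[ScaffoldPlacement],
                draft: pd.DataFrame) -> pd.DataFrame:
    rows = []
    d = draft.set_index("scaffold")
    for p in placements:
        if p.scaffold not in d.index:
            rows.append((p.scaffold, "placement", "unplaced",
                         f"{p.chromosome}:{p.rank}"))
            continue
        row = d.loc[p.scaffold]
        if str(row.get("chromosome")) != p.chromosome:
            rows.append((p.scaffold, "chromosome", str(row.get("chromosome")),
                         p.chromosome))
        elif int(row.get("draft_rank", -1)) != p.rank:
            rows.append((p.scaffold, "rank", int(row.get("draft_rank", -1)), p.rank))
        if p.orientation != "?" and str(row.get("draft_orientation", "+")) != p.orientation:
            rows.append((p.scaffold, "orientation",
                         str(row.get("draft_orientation", "+")), p.orientation))
    return pd.DataFrame(rows, columns=["scaffold", "field", "draft", "proposed"])


UNPLACED_DIST_CAP_CR = 300.0


def _best_insertion_slot(chrom, marker_dist, end_usnps, positions,
                         plist) -> int:
    """Minimum-detour scaffold gap for an unplaced scaffold.

    The unplaced scaffold enters a gap between contiguous placed scaffolds
    as an oriented segment: its two physical end uSNPs (smallest and largest
    scaffold coordinate) are matched against the gap's flanking markers (the
    last mapped marker of the left scaffold, the first of the right one),
    taking the better of the two orientations, minus the gap's own width.
    Treating the scaffold as a segment rather than a point makes gaps too
    narrow for its span expensive. Chromosome ends cost the single distance
    from the nearer scaffold end. Returns the rank to insert before."""
    pos_cr = {m: float(positions.loc[m, "cr"]) for m in positions.index
              if positions.loc[m, "chromosome"] == chrom}
    u_lo, u_hi = end_usnps

    def end_markers(p: ScaffoldPlacement):
        ms = sorted((m for m in p.markers_kept if m in pos_cr),
                    key=lambda m: (pos_cr[m], m))
        return (ms[0], ms[-1]) if ms else (None, None)

    def dist(u, mk):
        if mk is None:
            return UNPLACED_DIST_CAP_CR
        return marker_dist[u].get(mk, UNPLACED_DIST_CAP_CR)

    scores = []
    first_mk = end_markers(plist[0])[0]
    scores.append((min(dist(u_lo, first_mk), dist(u_hi, first_mk)), 0))
    for left, right in zip(plist[:-1], plist[1:]):
        a = end_markers(left)[1]
        b = end_markers(right)[0]
        gap = (pos_cr.get(b, 0.0) - pos_cr.get(a, 0.0)) if a and b else 0.0
        detour = min(dist(u_lo, a) + dist(u_hi, b),
                     dist(u_hi, a) + dist(u_lo, b)) - max(gap, 0.0)
        scores.append((detour, right.rank))
    last_mk = end_markers(plist[-1])[1]
    scores.append((min(dist(u_lo, last_mk), dist(u_hi, last_mk)),
                   plist[-1].rank + 1))
    best_score, best_rank = min(scores, key=lambda t: (t[0], t[1]))
    return int(best_rank)


def place_unplaced(panel: RHPanel, placements: list[ScaffoldPlacement],
                   robust_maps: dict[str, RobustMap],
                   unplaced_markers: pd.DataFrame,
                   scaffold_lengths: dict[str, int],
                   comparator_orientation: dict[str, str] | None = None,
                   config: AnchorConfig | None = None):
    """Insert unplaced scaffolds between contiguous placed scaffolds.

    Scaffolds shorter than ``min_unplaced_len`` are excluded up front. The
    remaining scaffolds' markers (uSNPs) are linked to mapped markers by
    two-point LOD; the chromosome of the strongest linkage (if LOD >=
    lod_place) wins. The insertion slot is chosen adjacent to the placed
    scaffold owning the best-linked marker, on the side whose end of that
    scaffold is more strongly linked — two-point LOD decays with map
    distance, so the nearer end identifies the flanking gap even when
    scaffold anchor positions tie. Returns (insertions, report)."""
    config = config or AnchorConfig()
    positions = _marker_positions(robust_maps)
    panel_markers = set(panel.marker_ids)
    report = []
    insertions = []
    by_chrom: dict[str, list[ScaffoldPlacement]] = {}
    for p in placements:
        by_chrom.setdefault(p.chromosome, []).append(p)
    for plist in by_chrom.values():
        plist.sort(key=lambda p: p.rank)
    owner = {}                       # mapped marker -> placed scaffold
    for p in placements:
        for mk in p.markers_kept:
            owner[mk] = p
    # linkage targets: only markers anchored to a placed scaffold (the map may
    # also carry uSNPs, including the query scaffold's own)
    mapped = [m for m in positions.index if m in panel_markers and m in owner]

    for scaffold, grp in unplaced_markers.groupby("scaffold", sort=True):
        length = scaffold_lengths.get(scaffold, 0)
        if length < config.min_unplaced_len:
            report.append((scaffold, "excluded",
                           f"length {length} < {config.min_unplaced_len}"))
            continue
        usnps = [m for m in grp["marker"] if m in panel_markers]
        if not usnps:
            report.append((scaffold, "unplaced", "no RH vectors"))
            continue

        # best LOD and cR distance per mapped marker over this scaffold's
        # uSNPs, and per-uSNP best-linked map position (for orientation)
        marker_lod: dict[str, float] = {}
        marker_dist: dict[str, dict[str, float]] = {}
        usnp_cr: dict[str, float] = {}
        for u in usnps:
            vu = panel.vectors_for([u])[:, 0]
            best_u = (0.0, np.nan)
            marker_dist[u] = {}
            for mk in mapped:
                tp = two_point_estimate(vu, panel.vectors_for([mk])[:, 0])
                marker_dist[u][mk] = min(tp.d_cr, UNPLACED_DIST_CAP_CR)
                if tp.lod > marker_lod.get(mk, 0.0):
                    marker_lod[mk] = tp.lod
                if tp.lod > best_u[0]:
                    best_u = (tp.lod, float(positions.loc[mk, "cr"]))
            usnp_cr[u] = best_u[1]
        if not marker_lod:
            report.append((scaffold, "unplaced", "no linkage computed"))
            continue
        anchor_marker = max(marker_lod, key=lambda m: (marker_lod[m], m))
        lod = marker_lod[anchor_marker]
        if lod < config.lod_place:
            report.append((scaffold, "unplaced",
                           f"max LOD {lod:.1f} < {config.lod_place}"))
            continue
        chrom = positions.loc[anchor_marker, "chromosome"]
        cr = float(positions.loc[anchor_marker, "cr"])
        plist = by_chrom.get(chrom, [])
        if not plist:
            report.append((scaffold, "unplaced",
                           "no placed scaffolds on chromosome"))
            continue

        bp_of = grp.set_index("marker")["scaffold_bp"]
        ranked = sorted(usnps, key=lambda u: float(bp_of[u]))
        after = _best_insertion_slot(chrom, marker_dist,
                                     (ranked[0], ranked[-1]), positions, plist)

        orientation, reason = "?", "insufficient markers to orient"
        if len(usnps) >= 2:
            bp = grp.set_index("marker").loc[usnps, "scaffold_bp"].to_numpy(float)
            crs = np.array([usnp_cr[u] for u in usnps])
            orientation, reason = orient_scaffold(bp, crs)
        if orientation == "?" and comparator_orientation and \
                scaffold in comparator_orientation:
            orientation = comparator_orientation[scaffold]
            reason += "; orientation from comparator synteny"
        insertions.append(dict(scaffold=scaffold, chromosome=chrom,
                               insert_before_rank=after, anchor_cr=cr,
                               orientation=orientation, lod=lod,
                               provenance="unplaced_insertion", reason=reason))
        report.append((scaffold, "inserted",
                       f"{chrom} before rank {after} (LOD {lod:.1f})"))
    return insertions, pd.DataFrame(report, columns=["scaffold", "action", "detail"])


def apply_insertions(placements: list[ScaffoldPlacement],
                     insertions: list[dict]) -> list[ScaffoldPlacement]:
    """Merge unplaced-scaffold insertions into the placement ranking."""
    merged = list(placements)
    for ins in sorted(insertions, key=lambda d: (d["chromosome"],
                                                 -d["insert_before_rank"])):
        chrom = ins["chromosome"]
        for p in merged:
            if p.chromosome == chrom and p.rank >= ins["insert_before_rank"]:
                p.rank += 1
        merged.append(ScaffoldPlacement(
            scaffold=ins["scaffold"], chromosome=chrom,
            rank=ins["insert_before_rank"], orientation=ins["orientation"],
            anchor_cr=ins["anchor_cr"], markers_kept=[], markers_filtered=[],
            provenance="unplaced_insertion", orientation_reason=ins["reason"]))
    return merged


# ----------------------------------------------------------------------
# AGP serialisation
# ----------------------------------------------------------------------
AGP_COLUMNS = ["object", "object_beg", "object_end", "part_number",
               "component_type", "component_id", "component_beg",
               "component_end", "orientation"]


def emit_agp(placements: list[ScaffoldPlacement],
             scaffold_lengths: dict[str, int],
             config: AnchorConfig | None = None) -> pd.DataFrame:
    """AGP 2.0 records: W component lines alternating with U scaffold gaps."""
    config = config or AnchorConfig()
    rows = []
    by_chrom: dict[str, list[ScaffoldPlacement]] = {}
    for p in placements:
        by_chrom.setdefault(p.chromosome, []).append(p)
    for chrom in sorted(by_chrom):
        plist = sorted(by_chrom[chrom], key=lambda p: p.rank)
        ranks = [p.rank for p in plist]
        if len(set(ranks)) != len(ranks):
            raise ValueError(f"rank collision on {chrom}")
        pos = 1
        part = 1
        for i, p in enumerate(plist):
            length = scaffold_lengths[p.scaffold]
            rows.append((chrom, pos, pos + length - 1, part, "W", p.scaffold,
                         1, length, p.orientation))
            pos += length
            part += 1
            if i + 1 < len(plist):
                rows.append((chrom, pos, pos + config.gap_length - 1, part, "U",
                             str(config.gap_length), "scaffold", "yes", "map"))
                pos += config.gap_length
                part += 1
    return pd.DataFrame(rows, columns=AGP_COLUMNS)


def write_agp(frame: pd.DataFrame, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.0\n")
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", header=False, index=False)


def parse_agp(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed AGP line: {line!r}")
            rows.append(parts)
    frame = pd.DataFrame(rows, columns=AGP_COLUMNS)
    for col in ("object_beg", "object_end", "part_number"):
        frame[col] = frame[col].astype(int)
    return frame


def agp_to_placements(frame: pd.DataFrame) -> list[ScaffoldPlacement]:
    """Inverse of emit_agp for round-trip checks (W lines only)."""
    placements = []
    for chrom, grp in frame[frame["component_type"] == "W"].groupby("object"):
        for rank, row in enumerate(grp.sort_values("object_beg").itertuples()):
            placements.append(ScaffoldPlacement(
                scaffold=row.component_id, chromosome=chrom, rank=rank,
                orientation=row.orientation, anchor_cr=float("nan"),
                markers_kept=[], markers_filtered=[]))
    return placements
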