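"""Synteny blocks and rearrangement breakpoints between two genome maps.

Given markers with coordinates on map A (an RH map or updated assembly) and
on a comparator genome B, maximal collinear runs (same B chromosome,
consistent +/-1 step in B rank) become synteny blocks, tolerating isolated
outlier markers up to a noise budget. Adjacent blocks on an A chromosome
define breakpoint records, classed as inversions (orientation flips),
inter-chromosomal exchanges (B chromosome changes) or intra-chromosomal
transpositions (rank jumps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SyntenyBlock:
    markers: list[str]
    chrom_a: str
    start_a: float
    end_a: float
    chrom_b: str
    start_b: float
    end_b: float
    orientation: str            # '+' or '-'

    @property
    def n_markers(self) -> int:
        return len(self.markers)


@dataclass
class BreakpointRecord:
    chrom_a: str
    left_marker: str
    right_marker: str
    left_a: float
    right_a: float
    left_b: str                 # "chrB:pos"
    right_b: str
    kind: str                   # inversion | inter_chromosomal | transposition


REQUIRED = ("marker", "chrA", "posA", "chrB", "bpB")


def _prepare(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED) - set(table.columns)
    if missing:
        raise ValueError(f"marker table lacks columns {sorted(missing)}")
    out = table.copy()
    out = out.sort_values(["chrA", "posA"], kind="stable").reset_index(drop=True)
    # B rank: position rank within each B chromosome over this marker set
    out["rankB"] = out.groupby("chrB")["bpB"].rank(method="first").astype(int)
    return out


def build_synteny_blocks(table: pd.DataFrame, min_block_markers: int = 3,
                         max_noise: int = 1):
    """Scan A-order and grow collinear runs into blocks.

    Up to ``max_noise`` isolated discordant markers inside a run are skipped
    (and listed as noise); runs shorter than ``min_block_markers`` are also
    folded into noise. Returns (blocks, noise_markers)."""
    prep = _prepare(table)
    blocks: list[SyntenyBlock] = []
    noise: list[str] = []

    for chrom_a, grp in prep.groupby("chrA", sort=True):
        rows = grp.reset_index(drop=True)
        runs = []
        current = [0]
        direction = 0
        budget = max_noise
        skipped: list[int] = []

        def flush():
            nonlocal current, direction, budget, skipped
            runs.append(list(current))
            noise.extend(rows.loc[skipped, "marker"])
            skipped = []
            budget = max_noise

        i = 1
        while i < len(rows):
            prev = rows.loc[current[-1]]
            cand = rows.loc[i]
            step = cand["rankB"] - prev["rankB"]
            same_chrom = cand["chrB"] == prev["chrB"]
            ok = same_chrom and (
                (direction == 0 and abs(step) == 1)
                or (direction != 0 and step == direction))
            if ok:
                if direction == 0:
                    direction = int(np.sign(step))
                current.append(i)
            elif budget > 0 and i + 1 < len(rows):
                # tolerate one isolated outlier if the run continues past it;
                # an outlier on the same B chromosome consumes a rank (step 2),
                # one on another chromosome does not (step 1)
                nxt = rows.loc[i + 1]
                step2 = nxt["rankB"] - prev["rankB"]
                cont = (nxt["chrB"] == prev["chrB"]) and (
                    (direction == 0 and abs(step2) in (1, 2))
                    or (direction != 0 and step2 in (direction, 2 * direction)))
                if cont:
                    budget -= 1
                    skipped.append(i)
                    if direction == 0:
                        direction = int(np.sign(step2))
                    current.append(i + 1)
                    i += 2
                    continue
                flush()
                current = [i]
                direction = 0
            else:
                flush()
                current = [i]
                direction = 0
            i += 1
        flush()

        for run in runs:
            sub = rows.loc[run]
            if len(run) < min_block_markers:
                noise.extend(sub["marker"])
                continue
            first, last = sub.iloc[0], sub.iloc[-1]
            orientation = "+" if last["rankB"] >= first["rankB"] else "-"
            blocks.append(SyntenyBlock(
                markers=list(sub["marker"]), chrom_a=str(chrom_a),
                start_a=float(first["posA"]), end_a=float(last["posA"]),
                chrom_b=str(first["chrB"]), start_b=float(first["bpB"]),
                end_b=float(last["bpB"]), orientation=orientation))
    return blocks, noise


def report_breakpoints(blocks: list[SyntenyBlock]) -> list[BreakpointRecord]:
    """One record per adjacent block pair on each A chromosome."""
    records = []
    by_a: dict[str, list[SyntenyBlock]] = {}
    for b in blocks:
        by_a.setdefault(b.chrom_a, []).append(b)
    for chrom_a, blist in sorted(by_a.items()):
        blist.sort(key=lambda b: b.start_a)
        for left, right in zip(blist[:-1], blist[1:]):
            if left.chrom_b != right.chrom_b:
                kind = "inter_chromosomal"
            elif left.orientation != right.orientation:
                kind = "inversion"
            else:
                kind = "transposition"
            records.append(BreakpointRecord(
                chrom_a=chrom_a,
                left_marker=left.markers[-1], right_marker=right.markers[0],
                left_a=left.end_a, right_a=right.start_a,
                left_b=f"{left.chrom_b}:{left.end_b / 1e6:.2f}",
                right_b=f"{right.chrom_b}:{right.start_b / 1e6:.2f}",
                kind=kind))
    return records


def breakpoints_frame(records: list[BreakpointRecord]) -> pd.DataFrame:
    """Tabular report: flanking markers with both-genome coordinates in Mb."""
    return pd.DataFrame([{
        "chromosome": r.chrom_a,
        "left_marker": r.left_marker, "right_marker": r.right_marker,
        "left_posA": round(r.left_a, 2), "right_posA": round(r.right_a, 2),
        "left_B": r.left_b, "right_B": r.right_b,
        "class": r.kind,
    } for r in records])


def blocks_frame(blocks: list[SyntenyBlock]) -> pd.DataFrame:
    """BED-like block table for each genome."""
    return pd.DataFrame([{
        "chrom_a": b.chrom_a, "start_a": b.start_a, "end_a": b.end_a,
        "chrom_b": b.chrom_b,
        "start_b": min(b.start_b, b.end_b), "end_b": max(b.start_b, b.end_b),
        "n_markers": b.n_markers, "orientation": b.orientation,
    } for b in blocks])
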