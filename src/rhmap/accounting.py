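"""Marker bookkeeping through the mapping pipeline.

Every stage of map construction removes markers for a stated reason; the
totals must reconcile exactly: mapped SNPs = total - unassigned; grouped =
mapped - unlinked; LKH-mapped = grouped - excluded; robust = LKH - unordered;
usable unassigned SNPs = unassigned - those on sub-threshold scaffolds.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class MarkerAccounting:
    """Counts of markers entering and leaving each pipeline stage."""

    total_snps: int                 # SNPs with RH vectors and a known array position
    unassigned_snps: int            # uSNPs: no chromosome position on the draft
    unlinked: int                   # dropped at linkage grouping
    excluded_lkh: int               # dropped during LKH map construction
    removed_robust: int             # dropped at robust-map extraction
    distinct_positions: int         # distinct map positions in the robust maps
    usnp_short_scaffold: int        # uSNPs on scaffolds below the length cutoff

    @property
    def mapped_snps(self) -> int:
        return self.total_snps - self.unassigned_snps

    @property
    def grouped(self) -> int:
        return self.mapped_snps - self.unlinked

    @property
    def lkh_mapped(self) -> int:
        return self.grouped - self.excluded_lkh

    @property
    def robust_mapped(self) -> int:
        return self.lkh_mapped - self.removed_robust

    @property
    def distinct_position_percent(self) -> float:
        return 100.0 * self.distinct_positions / self.robust_mapped

    @property
    def usable_usnps(self) -> int:
        return self.unassigned_snps - self.usnp_short_scaffold

    def validate(self) -> None:
        counts = [self.total_snps, self.unassigned_snps, self.unlinked,
                  self.excluded_lkh, self.removed_robust,
                  self.distinct_positions, self.usnp_short_scaffold]
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.robust_mapped <= 0:
            raise ValueError("pipeline removed every marker")
        if self.distinct_positions > self.robust_mapped:
            raise ValueError("more distinct positions than robust markers")
        if self.usnp_short_scaffold > self.unassigned_snps:
            raise ValueError("short-scaffold uSNPs exceed total uSNPs")
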