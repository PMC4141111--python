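"""Radiation-hybrid panel container.

An RH panel is a matrix of presence/absence calls: for each hybrid clone and
each SNP marker, the marker is retained (1), not retained (0) or missing (-1).
Co-retention of nearby markers is the mapping signal; everything downstream
(two-point linkage, multipoint likelihoods, robust maps) consumes this matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RETAINED = 1
UNRETAINED = 0
MISSING = -1

_SYMBOLS = {RETAINED: "1", UNRETAINED: "0", MISSING: "-"}
_FROM_SYMBOL = {"1": RETAINED, "0": UNRETAINED, "-": MISSING}


@dataclass
class RHPanel:
    """Calls in {1, 0, -1} for clones (rows) x markers (columns).

    Parameters
    ----------
    calls : (n_clones, n_markers) int8 array over {1, 0, -1}.
    clone_ids, marker_ids : row/column labels.
    marker_meta : optional per-marker metadata (reference chromosome, bp, ...),
        indexed by marker id.
    truth : optional (n_clones, n_markers) boolean array of true retention,
        carried along by the simulator for oracle tests.
    """

    calls: np.ndarray
    clone_ids: list[str]
    marker_ids: list[str]
    marker_meta: pd.DataFrame | None = None
    truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D clone x marker matrix")
        if self.calls.shape != (len(self.clone_ids), len(self.marker_ids)):
            raise ValueError("calls shape does not match clone/marker ids")
        bad = ~np.isin(self.calls, (RETAINED, UNRETAINED, MISSING))
        if bad.any():
            raise ValueError("calls must take values in {1, 0, -1}")

    @property
    def n_clones(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    # ------------------------------------------------------------------
    # retention summaries
    # ------------------------------------------------------------------
    def marker_retention(self) -> np.ndarray:
        """Fraction of non-missing calls that are retained, per marker."""
        present = (self.calls == RETAINED).sum(axis=0)
        informative = (self.calls != MISSING).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(informative > 0, present / np.maximum(informative, 1), np.nan)

    def clone_retention(self) -> np.ndarray:
        """Fraction of non-missing calls that are retained, per clone."""
        present = (self.calls == RETAINED).sum(axis=1)
        informative = (self.calls != MISSING).sum(axis=1)
        return np.where(informative > 0, present / np.maximum(informative, 1), np.nan)

    def missing_fraction(self) -> float:
        return float((self.calls == MISSING).mean())

    # ------------------------------------------------------------------
    # subsetting
    # ------------------------------------------------------------------
    def subset(self, clones: np.ndarray | None = None,
               markers: np.ndarray | None = None) -> "RHPanel":
        """Return a sub-panel by boolean masks or index arrays."""
        ci = np.arange(self.n_clones) if clones is None else np.asarray(clones)
        mi = np.arange(self.n_markers) if markers is None else np.asarray(markers)
        if ci.dtype == bool:
            ci = np.flatnonzero(ci)
        if mi.dtype == bool:
            mi = np.flatnonzero(mi)
        meta = None
        marker_ids = [self.marker_ids[i] for i in mi]
        if self.marker_meta is not None:
            meta = self.marker_meta.loc[[m for m in marker_ids if m in self.marker_meta.index]]
        truth = None
        if self.truth is not None:
            truth = self.truth[np.ix_(ci, mi)]
        return RHPanel(
            calls=self.calls[np.ix_(ci, mi)],
            clone_ids=[self.clone_ids[i] for i in ci],
            marker_ids=marker_ids,
            marker_meta=meta,
            truth=truth,
        )

    def vectors_for(self, marker_ids: list[str]) -> np.ndarray:
        """Clone x marker call matrix for the given markers, in that order."""
        index = {m: i for i, m in enumerate(self.marker_ids)}
        cols = [index[m] for m in marker_ids]
        return self.calls[:, cols]

    # ------------------------------------------------------------------
    # serialisation: RH-vector TSV (one row per SNP, one column per clone)
    # ------------------------------------------------------------------
    def to_vector_frame(self) -> pd.DataFrame:
        sym = np.empty(self.calls.shape, dtype="<U1")
        for value, s in _SYMBOLS.items():
            sym[self.calls == value] = s
        return pd.DataFrame(sym.T, index=pd.Index(self.marker_ids, name="marker"),
                            columns=self.clone_ids)

    def to_tsv(self, path) -> None:
        self.to_vector_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, marker_meta: pd.DataFrame | None = None) -> "RHPanel":
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
        marker_ids = [str(m) for m in frame.index]
        clone_ids = [str(c) for c in frame.columns]
        calls = np.empty((len(clone_ids), len(marker_ids)), dtype=np.int8)
        for j, sym_row in enumerate(frame.itertuples(index=False)):
            for i, s in enumerate(sym_row):
                try:
                    calls[i, j] = _FROM_SYMBOL[s]
                except KeyError:
                    raise ValueError(f"invalid RH-vector symbol {s!r} at marker "
                                     f"{marker_ids[j]}, clone {clone_ids[i]}") from None
        return cls(calls=calls, clone_ids=clone_ids, marker_ids=marker_ids,
                   marker_meta=marker_meta)

    def to_carthagene(self, path) -> None:
        """Export in Carthagene-style RH text: header then per-marker vectors."""
        with open(path, "w") as fh:
            fh.write(f"data type radiated hybrid\n{self.n_clones} {self.n_markers} 0 0\n")
            for j, marker in enumerate(self.marker_ids):
                vec = "".join(_SYMBOLS[v] for v in self.calls[:, j])
                fh.write(f"*{marker}\t{vec}\n")
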