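"""Genetic maps: the ordered marker scaffold shared by every pipeline stage.

A map carries, per marker, a chromosome, a 1-based physical position (bp)
and a genetic position (cM, non-decreasing within a chromosome).  Downstream
stages attach descent probabilities to marker-midpoint *intervals*; the
conversion from marker positions to 0-based half-open intervals lives here
so the convention is defined exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

REQUIRED_COLUMNS = ("marker", "chrom", "bp", "cM")


def interval_frame(
    chrom: str,
    bp: np.ndarray,
    cm: np.ndarray,
    chrom_length_cm: float,
) -> pd.DataFrame:
    """Marker-midpoint intervals for one chromosome.

    Boundaries sit halfway between adjacent markers; the first interval
    starts at bp 0 / cM 0 and the last ends at the last marker's bp and the
    chromosome's cM length, so cM widths tile the chromosome exactly.
    Coordinates are 0-based half-open.
    """
    bp = np.asarray(bp, dtype=np.int64)
    cm = np.asarray(cm, dtype=float)
    n = len(bp)
    if n == 0:
        return pd.DataFrame(
            columns=["chrom", "start_bp", "end_bp", "cm", "cm_width"]
        )
    mid_bp = (bp[:-1] + bp[1:]) // 2
    start_bp = np.concatenate(([0], mid_bp))
    end_bp = np.concatenate((mid_bp, [bp[-1]]))
    cm_bounds = np.concatenate(
        ([0.0], (cm[:-1] + cm[1:]) / 2.0, [max(chrom_length_cm, cm[-1])])
    )
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start_bp": start_bp,
            "end_bp": end_bp,
            "cm": cm,
            "cm_width": np.diff(cm_bounds),
        }
    )


@dataclass(frozen=True)
class GeneticMap:
    """Ordered markers with physical and genetic coordinates.

    Parameters
    ----------
    markers
        DataFrame with columns ``marker, chrom, bp, cM``.  Markers must be
        grouped by chromosome and sorted by position within it; cM ties are
        allowed only at identical bp.
    chrom_lengths
        Optional cM length per chromosome; defaults to the last marker's cM.
    """

    markers: pd.DataFrame
    chrom_lengths: dict[str, float] | None = None

    def __post_init__(self):
        df = self.markers
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise InvalidArgumentError(f"map is missing columns {missing}")
        df = df.reset_index(drop=True).copy()
        df["bp"] = df["bp"].astype(np.int64)
        df["cM"] = df["cM"].astype(float)
        if df["marker"].duplicated().any():
            raise InvalidArgumentError("duplicate marker IDs in map")
        chroms = list(dict.fromkeys(df["chrom"]))
        # chromosomes must form contiguous blocks
        codes = df["chrom"].map({c: i for i, c in enumerate(chroms)}).to_numpy()
        if np.any(np.diff(codes) < 0):
            raise InvalidArgumentError("markers are not grouped by chromosome")
        for c in chroms:
            sub = df[df["chrom"] == c]
            cm = sub["cM"].to_numpy()
            bp = sub["bp"].to_numpy()
            if np.any(cm < 0):
                raise InvalidArgumentError(f"negative cM on chromosome {c}")
            d = np.diff(cm)
            if np.any(d < 0):
                raise InvalidArgumentError(f"cM not sorted on chromosome {c}")
            tie = d == 0
            if np.any(tie & (np.diff(bp) != 0)):
                raise InvalidArgumentError(
                    f"cM ties at distinct bp on chromosome {c}"
                )
            if np.any(np.diff(bp) < 0):
                raise InvalidArgumentError(f"bp not sorted on chromosome {c}")
        lengths = dict(self.chrom_lengths) if self.chrom_lengths else {}
        for c in chroms:
            last = float(df.loc[df["chrom"] == c, "cM"].iloc[-1])
            lengths.setdefault(c, last)
            if lengths[c] < last:
                raise InvalidArgumentError(
                    f"chromosome {c} length {lengths[c]} cM is shorter than "
                    f"its last marker at {last} cM"
                )
        object.__setattr__(self, "markers", df)
        object.__setattr__(self, "chrom_lengths", lengths)
        object.__setattr__(self, "_chroms", tuple(chroms))

    # -- basic accessors -------------------------------------------------

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return self._chroms

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @cached_property
    def _slices(self) -> dict[str, slice]:
        out = {}
        codes = self.markers["chrom"].to_numpy()
        for c in self.chromosomes:
            idx = np.flatnonzero(codes == c)
            out[c] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def chrom_slice(self, chrom: str) -> slice:
        """Row slice of ``markers`` covering one chromosome."""
        return self._slices[chrom]

    @cached_property
    def intervals(self) -> pd.DataFrame:
        """Marker-midpoint intervals (0-based half-open bp, cM widths)."""
        frames = []
        for c in self.chromosomes:
            sub = self.markers.iloc[self.chrom_slice(c)]
            frames.append(
                interval_frame(
                    c,
                    sub["bp"].to_numpy(),
                    sub["cM"].to_numpy(),
                    self.chrom_lengths[c],
                )
            )
        if not frames:
            return interval_frame("", np.array([]), np.array([]), 0.0)
        return pd.concat(frames, ignore_index=True)

    def subset(self, indices: np.ndarray) -> "GeneticMap":
        """New map restricted to ``indices`` (kept in original order)."""
        indices = np.sort(np.asarray(indices, dtype=int))
        return GeneticMap(
            self.markers.iloc[indices].reset_index(drop=True),
            chrom_lengths=self.chrom_lengths,
        )

    def same_markers(self, other: "GeneticMap") -> bool:
        a, b = self.markers, other.markers
        return len(a) == len(b) and bool(
            (a["marker"].to_numpy() == b["marker"].to_numpy()).all()
        )
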