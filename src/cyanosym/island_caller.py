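"""Genomic-island calls from the composition and hit-frequency tracks.

A window is anomalous on a track when its value lies more than ``k_sd``
standard deviations from the track mean (two-sided, like the dotted
mean ± 2·SD lines on a genome-scan plot).  Windows anomalous on *both* the
tetranucleotide PC1 track and the hit-organism score track are island
members; runs of flagged windows whose intervals overlap or abut are merged
into one island.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .sequence_io import FeatureTable
from .tetra_windows import Window

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdParams:
    """k_sd = 2 flags values outside mean ± 2·SD (sample SD by default)."""

    k_sd: float = 2.0
    sd_mode: str = "sample"

    def __post_init__(self) -> None:
        if self.k_sd < 0:
            raise ValueError("k_sd must be >= 0")
        if self.sd_mode not in ("sample", "population"):
            raise ValueError(f"unknown sd_mode {self.sd_mode!r}")

    @property
    def ddof(self) -> int:
        return 1 if self.sd_mode == "sample" else 0


@dataclass
class IslandCall:
    """A maximal run of doubly-anomalous windows, with the genes it covers."""

    start: int
    end: int
    member_window_indices: list[int]
    genes: list[str]

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def peak_mask(
    track: np.ndarray,
    params: ThresholdParams | None = None,
    one_sided: str | None = None,
) -> np.ndarray:
    """Flag windows whose |value − mean| exceeds k_sd·SD of the track.

    Mean and SD are computed over defined (non-NaN) values only; missing
    values are never flagged.  ``one_sided`` restricts flagging to the
    "low" or "high" side.  Zero SD → nothing flagged (with a warning).
    """
    params = params or ThresholdParams()
    track = np.asarray(track, dtype=float)
    defined = ~np.isnan(track)
    if defined.sum() < 2:
        raise ValueError("need >= 2 defined window values")
    mean = track[defined].mean()
    sd = track[defined].std(ddof=params.ddof)
    if sd == 0:
        logger.warning("zero standard deviation: no windows flagged")
        return np.zeros(track.shape, dtype=bool)
    dev = track - mean
    if one_sided == "low":
        exceed = -dev > params.k_sd * sd
    elif one_sided == "high":
        exceed = dev > params.k_sd * sd
    elif one_sided is None:
        exceed = np.abs(dev) > params.k_sd * sd
    else:
        raise ValueError(f"one_sided must be 'low', 'high' or None, got {one_sided!r}")
    return np.where(defined, exceed, False)


def call_islands(
    tetra_mask: np.ndarray,
    score_mask: np.ndarray,
    windows: list[Window],
    features: FeatureTable | None = None,
    genome_id: str | None = None,
) -> list[IslandCall]:
    """AND the two masks and merge flagged windows into maximal intervals.

    Two flagged windows join the same island when their intervals overlap
    or abut.  CDS features overlapping an island interval are attached.
    """
    tetra_mask = np.asarray(tetra_mask, dtype=bool)
    score_mask = np.asarray(score_mask, dtype=bool)
    if not (len(tetra_mask) == len(score_mask) == len(windows)):
        raise ValueError(
            f"mask/window length mismatch: {len(tetra_mask)}, "
            f"{len(score_mask)}, {len(windows)}"
        )
    both = tetra_mask & score_mask
    flagged = [w for w in windows if both[w.index]]
    islands: list[IslandCall] = []
    for w in flagged:
        if islands and w.start <= islands[-1].end:
            islands[-1].end = max(islands[-1].end, w.end)
            islands[-1].member_window_indices.append(w.index)
        else:
            islands.append(
                IslandCall(
                    start=w.start, end=w.end,
                    member_window_indices=[w.index], genes=[],
                )
            )
    if features is not None:
        cds = features.of_kind("CDS")
        if genome_id is not None:
            cds = cds.for_genome(genome_id)
        for isl in islands:
            isl.genes = [
                f.feature_id for f in cds if f.overlaps(isl.start, isl.end)
            ]
    return islands


def interval_jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Jaccard index of two half-open intervals (0 when disjoint)."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union > 0 else 0.0
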