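"""Sliding-window tetranucleotide composition and its PC1 summary track.

Genome composition is summarized per window as the vector of counts of all
256 overlapping 4-mers; a principal component analysis of the window-by-
tetranucleotide count matrix (column-centered, unscaled) yields a single
per-window value (PC1) that concentrates most of the compositional variance.
Windows whose composition deviates from the genome backbone — candidate
genomic islands — sit at the extremes of this track.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

#: the 256 tetranucleotides over {A,C,G,T} in lexicographic order
TETRANUCLEOTIDES: tuple[str, ...] = tuple(
    "".join(p) for p in product("ACGT", repeat=4)
)

_BASE_CODE = np.full(256, -1, dtype=np.int16)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i

_RC_PERM = np.array(
    [
        TETRANUCLEOTIDES.index(
            t[::-1].translate(str.maketrans("ACGT", "TGCA"))
        )
        for t in TETRANUCLEOTIDES
    ],
    dtype=np.intp,
)


class WindowingError(ValueError):
    """Genome too short for the requested window width, or bad parameters."""


@dataclass(frozen=True)
class WindowingParams:
    """Sliding-window geometry: 10 kb windows overlapping by 1 kb by default.

    ``overlap`` is the number of bases shared by consecutive windows, so the
    step between window starts is ``width - overlap``.  Partial windows at
    the end of the genome are dropped.
    """

    width: int = 10_000
    overlap: int = 1_000
    tail_policy: str = "drop_partial"

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < self.width:
            raise WindowingError(
                f"need 0 <= overlap < width, got overlap={self.overlap} "
                f"width={self.width}"
            )
        if self.tail_policy != "drop_partial":
            raise WindowingError(f"unknown tail_policy {self.tail_policy!r}")

    @property
    def step(self) -> int:
        return self.width - self.overlap


@dataclass(frozen=True)
class Window:
    index: int
    start: int
    end: int

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class PcaSummary:
    """PC1 projections, the 256-element loading vector and the variance share."""

    pc1: np.ndarray
    loading_vector: np.ndarray
    explained_variance_fraction: float


def make_windows(
    genome_length: int, params: WindowingParams, genome_id: str = "genome"
) -> list[Window]:
    """Emit full-width windows at starts 0, step, 2*step, ...

    The number of windows is ``floor((L - width) / step) + 1``; any tail
    shorter than ``width`` is dropped.
    """
    if genome_length < params.width:
        raise WindowingError(
            f"{genome_id}: length {genome_length} shorter than window "
            f"width {params.width}"
        )
    n = (genome_length - params.width) // params.step + 1
    return [
        Window(index=i, start=i * params.step, end=i * params.step + params.width)
        for i in range(n)
    ]


def count_tetranucleotides(window_sequence: str) -> np.ndarray:
    """Count every overlapping 4-mer made solely of A/C/G/T on the given strand.

    4-mers containing any other symbol (N, ambiguity codes) contribute
    nothing.  Strings shorter than 4 give an all-zero vector.
    """
    codes = _BASE_CODE[np.frombuffer(window_sequence.encode("ascii"), dtype=np.uint8)]
    if codes.size < 4:
        return np.zeros(256, dtype=np.int64)
    quads = (
        codes[:-3] * 64 + codes[1:-2] * 16 + codes[2:-1] * 4 + codes[3:]
    )
    valid = (
        (codes[:-3] >= 0) & (codes[1:-2] >= 0) & (codes[2:-1] >= 0) & (codes[3:] >= 0)
    )
    return np.bincount(quads[valid].astype(np.intp), minlength=256).astype(np.int64)


def tetra_count_matrix(
    sequence: str, windows: list[Window], strand_symmetric: bool = False
) -> np.ndarray:
    """Stack per-window tetranucleotide count vectors into an (n, 256) matrix.

    With ``strand_symmetric`` each count is pooled with its reverse
    complement, removing strand asymmetry from the signature.
    """
    mat = np.stack(
        [count_tetranucleotides(sequence[w.start : w.end]) for w in windows]
    )
    if strand_symmetric:
        mat = mat + mat[:, _RC_PERM]
    return mat


def pc1_track(counts: np.ndarray) -> PcaSummary:
    """Project column-centered count rows onto the leading principal axis.

    The count matrix is centered by subtracting each tetranucleotide's mean
    across windows (no variance scaling).  The sign of the axis is fixed so
    that the loading with the largest absolute value is positive.  If all
    rows are identical (zero total variance) the track is all zeros and the
    explained-variance fraction is reported as 0.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 window rows")
    centered = counts - counts.mean(axis=0)
    if not np.any(np.abs(centered) > 1e-12):
        logger.warning("all windows identical: PC1 track is all zeros")
        return PcaSummary(
            pc1=np.zeros(counts.shape[0]),
            loading_vector=np.zeros(counts.shape[1]),
            explained_variance_fraction=0.0,
        )
    pca = PCA(n_components=1, svd_solver="full")
    scores = pca.fit_transform(centered)[:, 0]
    loadings = pca.components_[0]
    if loadings[np.argmax(np.abs(loadings))] < 0:
        loadings = -loadings
        scores = -scores
    return PcaSummary(
        pc1=scores,
        loading_vector=loadings,
        explained_variance_fraction=float(pca.explained_variance_ratio_[0]),
    )


def genome_pc1_track(
    sequence: str,
    params: WindowingParams | None = None,
    strand_symmetric: bool = False,
    genome_id: str = "genome",
) -> tuple[list[Window], PcaSummary]:
    """Convenience: windows + counts + PCA for one genome sequence."""
    params = params or WindowingParams()
    windows = make_windows(len(sequence), params, genome_id=genome_id)
    counts = tetra_count_matrix(sequence, windows, strand_symmetric=strand_symmetric)
    return windows, pc1_track(counts)
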