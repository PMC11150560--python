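"""Composed, deterministic analysis pipelines plus run manifests.

The three stages (composition track, hit-frequency track, island calling)
are deterministic functions of their inputs; all randomness in the package
lives in :mod:`cyanosym.synthetic`.  Each run can emit a JSON manifest
recording parameters, package version and input checksums so identical
configurations are verifiably identical runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .hit_frequency import (
    HitsByQuery,
    ScoreParams,
    ScoreTrack,
    score_proteins,
    window_score_track,
)
from .island_caller import IslandCall, ThresholdParams, call_islands, peak_mask
from .sequence_io import FeatureTable, GenomeRecord
from .tetra_windows import (
    PcaSummary,
    Window,
    WindowingParams,
    genome_pc1_track,
)


@dataclass
class IslandPipelineResult:
    windows: list[Window]
    pca: PcaSummary
    score_track: ScoreTrack
    tetra_mask: np.ndarray
    score_mask: np.ndarray
    islands: list[IslandCall]


def run_island_pipeline(
    genome: GenomeRecord,
    features: FeatureTable,
    hits_by_query: HitsByQuery,
    windowing: WindowingParams | None = None,
    scoring: ScoreParams | None = None,
    thresholds: ThresholdParams | None = None,
    strand_symmetric: bool = False,
    one_sided_score: bool = False,
) -> IslandPipelineResult:
    """Composition track + score track + dual-evidence island calls."""
    windowing = windowing or WindowingParams()
    scoring = scoring or ScoreParams()
    thresholds = thresholds or ThresholdParams()
    windows, pca = genome_pc1_track(
        genome.sequence,
        windowing,
        strand_symmetric=strand_symmetric,
        genome_id=genome.genome_id,
    )
    scores = score_proteins(hits_by_query, scoring)
    track = window_score_track(scores, features, windows)
    tetra_mask = peak_mask(pca.pc1, thresholds)
    score_mask = peak_mask(
        track.mean_score, thresholds, one_sided="low" if one_sided_score else None
    )
    islands = call_islands(
        tetra_mask, score_mask, windows, features, genome_id=genome.genome_id
    )
    return IslandPipelineResult(
        windows=windows,
        pca=pca,
        score_track=track,
        tetra_mask=tetra_mask,
        score_mask=score_mask,
        islands=islands,
    )


def tracks_frame(result: IslandPipelineResult, genome_id: str) -> pd.DataFrame:
    """Tab-separated-ready per-window table of both tracks and both masks."""
    return pd.DataFrame(
        {
            "genome_id": genome_id,
            "window_index": [w.index for w in result.windows],
            "start": [w.start for w in result.windows],
            "end": [w.end for w in result.windows],
            "pc1": result.pca.pc1,
            "mean_score": result.score_track.mean_score,
            "n_genes": result.score_track.n_genes,
            "tetra_flag": result.tetra_mask,
            "score_flag": result.score_mask,
        }
    )


def islands_frame(islands: Sequence[IslandCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "island_id": f"island_{i + 1:02d}",
                "start": isl.start,
                "end": isl.end,
                "n_windows": len(isl.member_window_indices),
                "genes": ",".join(isl.genes),
            }
            for i, isl in enumerate(islands)
        ],
        columns=["island_id", "start", "end", "n_windows", "genes"],
    )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (frozenset, set, tuple)):
        return sorted(str(x) for x in obj) if isinstance(obj, (set, frozenset)) else list(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_manifest(
    path: str | Path,
    params: Mapping[str, Any],
    inputs: Mapping[str, str | Path] | None = None,
) -> dict[str, Any]:
    """Record parameters, package version and input checksums as JSON."""
    manifest = {
        "package": "cyanosym",
        "version": __version__,
        "parameters": {k: _jsonable(v) for k, v in params.items()},
        "input_sha256": {
            name: _sha256(p) for name, p in (inputs or {}).items()
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
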