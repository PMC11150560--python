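"""Hit-organism frequency scores from tabular protein homology searches.

The idea: across a whole proteome, count how often each database organism
appears among each protein's top-k homology hits.  Proteins whose best
homologs belong to organisms that are rare genome-wide get low scores —
a proxy for possible foreign (horizontally transferred) origin.  Scores are
min–max normalized organism counts averaged over a protein's top hits, then
averaged again per genomic window to give a track comparable with the
tetranucleotide PC1 track.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_io import FeatureTable
from .tetra_windows import Window

logger = logging.getLogger(__name__)

#: label excluded from organism counting by default (uninformative database label)
DEFAULT_EXCLUDED = frozenset({"unidentified Synechococcus"})

BLAST6_COLUMNS = [
    "query_id", "subject_id", "pct_identity", "aln_length", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "evalue", "bitscore",
]


@dataclass(frozen=True)
class HitRecord:
    """One homology hit of a query protein, in the search tool's rank order."""

    query_id: str
    subject_organism: str
    rank: int
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError(f"{self.query_id}: rank must be >= 1")
        if not self.subject_organism:
            raise ValueError(f"{self.query_id}: empty subject organism")


@dataclass(frozen=True)
class ScoreParams:
    top_k: int = 5
    excluded_labels: frozenset[str] = DEFAULT_EXCLUDED
    resort_by_bitscore: bool = False

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass
class OrganismFrequencyTable:
    """Raw top-k hit counts per organism and their min–max normalized values."""

    raw: dict[str, int]
    normalized: dict[str, float]


@dataclass(frozen=True)
class ProteinScore:
    protein_id: str
    score: float | None
    n_hits_used: int


@dataclass
class ScoreTrack:
    """Per-window mean protein score; NaN where a window has no scored gene."""

    mean_score: np.ndarray
    n_genes: np.ndarray


HitsByQuery = dict[str, list[HitRecord]]


def _ordered_hits(hits: list[HitRecord], params: ScoreParams) -> list[HitRecord]:
    if params.resort_by_bitscore:
        return sorted(hits, key=lambda h: (-h.bitscore, h.rank))
    return sorted(hits, key=lambda h: h.rank)


def _usable_top_hits(hits: list[HitRecord], params: ScoreParams) -> list[HitRecord]:
    """First ``top_k`` hits after skipping excluded organism labels."""
    out = []
    for h in _ordered_hits(hits, params):
        if h.subject_organism in params.excluded_labels:
            continue
        out.append(h)
        if len(out) == params.top_k:
            break
    return out


def organism_frequency(
    hits_by_query: HitsByQuery, params: ScoreParams | None = None
) -> OrganismFrequencyTable:
    """Genome-wide organism hit counts over every query's top-k hits.

    Each hit increments its organism's count once; excluded labels are
    skipped (the next-ranked hit takes their slot).  Counts are min–max
    normalized over the organisms present; if all organisms are tied, every
    normalized value is 1.0.
    """
    params = params or ScoreParams()
    raw: dict[str, int] = {}
    for hits in hits_by_query.values():
        for h in _usable_top_hits(hits, params):
            raw[h.subject_organism] = raw.get(h.subject_organism, 0) + 1
    if not raw:
        logger.warning("no usable hits: empty organism frequency table")
        return OrganismFrequencyTable(raw={}, normalized={})
    lo, hi = min(raw.values()), max(raw.values())
    if hi == lo:
        normalized = {org: 1.0 for org in raw}
    else:
        normalized = {org: (c - lo) / (hi - lo) for org, c in raw.items()}
    return OrganismFrequencyTable(raw=raw, normalized=normalized)


def protein_score(
    query_id: str,
    query_hits: list[HitRecord],
    freqs: OrganismFrequencyTable,
    params: ScoreParams | None = None,
) -> ProteinScore:
    """Mean normalized organism frequency over a protein's usable top-k hits.

    Fewer than ``top_k`` usable hits → mean over those available; zero
    usable hits → missing score.  A hit organism absent from the frequency
    table (possible only when the table was built from different queries)
    is skipped and logged.
    """
    params = params or ScoreParams()
    values = []
    for h in _usable_top_hits(query_hits, params):
        if h.subject_organism not in freqs.normalized:
            logger.warning(
                "%s: organism %r absent from frequency table, skipped",
                query_id, h.subject_organism,
            )
            continue
        values.append(freqs.normalized[h.subject_organism])
    if not values:
        return ProteinScore(protein_id=query_id, score=None, n_hits_used=0)
    return ProteinScore(
        protein_id=query_id,
        score=float(np.mean(values)),
        n_hits_used=len(values),
    )


def score_proteins(
    hits_by_query: HitsByQuery,
    params: ScoreParams | None = None,
    freqs: OrganismFrequencyTable | None = None,
) -> dict[str, ProteinScore]:
    """Score every query protein against the genome-wide frequency table."""
    params = params or ScoreParams()
    if freqs is None:
        freqs = organism_frequency(hits_by_query, params)
    return {
        q: protein_score(q, hits, freqs, params)
        for q, hits in hits_by_query.items()
    }


def window_score_track(
    scores: dict[str, ProteinScore],
    cds: FeatureTable,
    windows: list[Window],
) -> ScoreTrack:
    """Unweighted mean protein score per window.

    A gene belongs to every window its interval intersects — genes that
    partially overlap a window boundary count for both windows.  Proteins
    with missing scores are omitted from the mean (never imputed as 0);
    windows with no scored gene are NaN.
    """
    mean_score = np.full(len(windows), np.nan)
    n_genes = np.zeros(len(windows), dtype=int)
    feats = {f.feature_id: f for f in cds.of_kind("CDS")}
    for w in windows:
        vals = []
        for pid, ps in scores.items():
            f = feats.get(pid)
            if f is None or not f.overlaps(w.start, w.end):
                continue
            if ps.score is not None:
                vals.append(ps.score)
        n_genes[w.index] = len(vals)
        if vals:
            mean_score[w.index] = float(np.mean(vals))
    return ScoreTrack(mean_score=mean_score, n_genes=n_genes)


def presence_track(
    hits_by_query: HitsByQuery,
    focal_organisms: set[str],
    params: ScoreParams | None = None,
) -> dict[str, bool]:
    """Per protein: does any focal organism occur among its usable top-k hits?"""
    params = params or ScoreParams()
    return {
        q: any(
            h.subject_organism in focal_organisms
            for h in _usable_top_hits(hits, params)
        )
        for q, hits in hits_by_query.items()
    }


def read_hit_table(
    path: str | Path,
    organism_map: dict[str, str] | str | Path | None = None,
) -> HitsByQuery:
    """Read a 12-column tab-separated homology table into per-query hit lists.

    The subject organism is taken from a 13th column when present, otherwise
    from ``organism_map`` (a dict or a two-column subject→organism TSV).
    Ranks follow row order within each query, preserving the search tool's
    reported ordering.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 12:
        raise ValueError(f"{path}: expected >= 12 columns, got {df.shape[1]}")
    df.columns = BLAST6_COLUMNS + [
        f"extra_{i}" for i in range(df.shape[1] - 12)
    ]
    if df.shape[1] >= 13:
        df = df.rename(columns={"extra_0": "subject_organism"})
    else:
        if organism_map is None:
            raise ValueError(
                f"{path}: no organism column and no subject→organism map supplied"
            )
        if not isinstance(organism_map, dict):
            mdf = pd.read_csv(
                organism_map, sep="\t", header=None,
                names=["subject_id", "subject_organism"],
            )
            organism_map = dict(
                zip(mdf["subject_id"].astype(str), mdf["subject_organism"])
            )
        df["subject_organism"] = df["subject_id"].astype(str).map(organism_map)
        missing = df["subject_organism"].isna()
        if missing.any():
            raise ValueError(
                f"{path}: {int(missing.sum())} subjects missing from organism map"
            )
    hits: HitsByQuery = {}
    counters: dict[str, int] = {}
    for row in df.itertuples(index=False):
        q = str(row.query_id)
        counters[q] = counters.get(q, 0) + 1
        hits.setdefault(q, []).append(
            HitRecord(
                query_id=q,
                subject_organism=str(row.subject_organism),
                rank=counters[q],
                bitscore=float(row.bitscore),
            )
        )
    return hits


def write_protein_scores(scores: dict[str, ProteinScore], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "protein_id": s.protein_id,
                "score": np.nan if s.score is None else s.score,
                "n_hits_used": s.n_hits_used,
            }
            for s in scores.values()
        ]
    ).to_csv(path, sep="\t", index=False)
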