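"""Size-fractionated metagenomic read recruitment and relative abundance.

Recruitment works on tabular nucleotide alignment results (BLAST outfmt-6
dialect): reads aligning to a genome at >= 99% identity over >= 90 bases
are "corresponding reads" for that genome, after excluding reads that
touch rRNA/tRNA regions (too conserved across lineages to be diagnostic).
Counts are summed per seawater size fraction and expressed both as a ratio
to the total reads searched per fraction and as each fraction's share of
the genome's recruited reads.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .sequence_io import FeatureTable

logger = logging.getLogger(__name__)

#: the four seawater filtration classes, in ascending size order (μm)
SIZE_FRACTIONS = ("0.8-5", "5-20", "20-180", "180-2000")

ALIGNMENT_COLUMNS = [
    "read_id", "genome_id", "pct_identity", "aln_length", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "evalue", "bitscore",
]


@dataclass(frozen=True)
class ReadFilterParams:
    min_identity: float = 99.0
    min_aln_length: int = 90

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 100:
            raise ValueError("min_identity must be in (0, 100]")
        if self.min_aln_length < 1:
            raise ValueError("min_aln_length must be >= 1")


@dataclass(frozen=True)
class SubsampleParams:
    """Skip the first 1000 reads of a run, then take the next five million."""

    skip: int = 1_000
    take: int = 5_000_000

    def __post_init__(self) -> None:
        if self.skip < 0 or self.take < 1:
            raise ValueError("need skip >= 0 and take >= 1")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    station_id: str
    size_fraction: str
    reads_searched: int

    def __post_init__(self) -> None:
        if self.size_fraction not in SIZE_FRACTIONS:
            raise ValueError(
                f"{self.sample_id}: size_fraction must be one of "
                f"{SIZE_FRACTIONS}, got {self.size_fraction!r}"
            )
        if self.reads_searched <= 0:
            raise ValueError(f"{self.sample_id}: reads_searched must be > 0")


def subsample_reads(read_stream: Iterable, params: SubsampleParams | None = None) -> Iterator:
    """Yield reads with 0-based ordinal in [skip, skip + take)."""
    params = params or SubsampleParams()
    n = 0
    for i, read in enumerate(read_stream):
        if i < params.skip:
            continue
        if i >= params.skip + params.take:
            return
        n += 1
        yield read
    if n == 0:
        logger.warning("stream exhausted before %d skipped reads", params.skip)


def read_alignment_table(path: str | Path, sample_id: str | None = None) -> pd.DataFrame:
    """Read a 12-column tab-separated alignment table.

    Column 2 is the genomic sequence the read aligned to.  An optional
    13th column (or the ``sample_id`` argument) assigns rows to a sample.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed alignment table: {exc}") from exc
    if df.shape[1] < 12:
        raise ValueError(f"{path}: expected >= 12 columns, got {df.shape[1]}")
    names = ALIGNMENT_COLUMNS + [f"extra_{i}" for i in range(df.shape[1] - 12)]
    df.columns = names
    if df.shape[1] >= 13:
        df = df.rename(columns={"extra_0": "sample_id"})
    elif sample_id is not None:
        df["sample_id"] = sample_id
    for col in ("pct_identity", "aln_length", "s_start", "s_end", "bitscore"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ValueError(f"{path}: non-numeric {col} at line {line}")
        df[col] = pd.to_numeric(df[col])
    return df


def filter_hits(alignments: pd.DataFrame, params: ReadFilterParams | None = None) -> pd.DataFrame:
    """Identity/length row filters, then best hit per read per genome.

    Keeps rows with identity >= min_identity and alignment length >=
    min_aln_length; among multiple retained alignments of one read to one
    genome, the highest-bitscore row wins (ties: first occurrence), so a
    read is counted at most once per genome.
    """
    params = params or ReadFilterParams()
    keep = (alignments["pct_identity"] >= params.min_identity) & (
        alignments["aln_length"] >= params.min_aln_length
    )
    kept = alignments[keep]
    group_cols = ["read_id", "genome_id"]
    if "sample_id" in kept.columns:
        group_cols.append("sample_id")
    best = (
        kept.sort_values("bitscore", ascending=False, kind="stable")
        .groupby(group_cols, sort=False)
        .head(1)
    )
    return best.sort_index()


def mask_features(alignments: pd.DataFrame, features: FeatureTable) -> pd.DataFrame:
    """Drop alignments whose subject interval touches an rRNA or tRNA feature.

    Subject coordinates are 1-based inclusive and may be reversed for
    minus-strand alignments; they are normalized to 0-based half-open
    before the overlap test.  Any shared base causes removal; abutting
    intervals are kept.
    """
    masked = features.of_kind("rRNA", "tRNA")
    if len(masked) == 0 or alignments.empty:
        return alignments
    lo = np.minimum(alignments["s_start"], alignments["s_end"]).to_numpy() - 1
    hi = np.maximum(alignments["s_start"], alignments["s_end"]).to_numpy()
    genome = alignments["genome_id"].astype(str).to_numpy()
    drop = np.zeros(len(alignments), dtype=bool)
    for f in masked:
        drop |= (genome == f.genome_id) & (lo < f.end) & (hi > f.start)
    return alignments[~drop]


def recruit(
    alignments: pd.DataFrame,
    features: FeatureTable | None = None,
    params: ReadFilterParams | None = None,
) -> pd.DataFrame:
    """Filter + mask + count: retained reads per (genome_id, sample_id)."""
    kept = filter_hits(alignments, params)
    if features is not None:
        kept = mask_features(kept, features)
    if "sample_id" not in kept.columns:
        kept = kept.assign(sample_id="sample")
    counts = (
        kept.groupby(["genome_id", "sample_id"], sort=True)
        .size()
        .rename("retained_reads")
        .reset_index()
    )
    return counts


def fraction_relative_abundance(
    counts: pd.DataFrame, meta: Sequence[SampleMeta]
) -> pd.DataFrame:
    """Per genome × size fraction: retained sums, search-depth ratios and shares.

    ``ratio`` is retained reads over the total reads searched in that
    fraction; ``pct_of_genome`` is the fraction's share of the genome's
    retained reads across all four fractions (NaN when the genome recruited
    nothing anywhere).
    """
    by_sample = {m.sample_id: m for m in meta}
    unknown = set(counts["sample_id"].astype(str)) - set(by_sample)
    if unknown:
        raise ValueError(f"samples without metadata: {sorted(unknown)!r}")
    searched = {f: 0 for f in SIZE_FRACTIONS}
    for m in meta:
        searched[m.size_fraction] += m.reads_searched
    rows = []
    for genome_id, sub in counts.groupby("genome_id", sort=True):
        per_fraction = {f: 0 for f in SIZE_FRACTIONS}
        for r in sub.itertuples(index=False):
            per_fraction[by_sample[str(r.sample_id)].size_fraction] += int(
                r.retained_reads
            )
        total = sum(per_fraction.values())
        for f in SIZE_FRACTIONS:
            ratio = per_fraction[f] / searched[f] if searched[f] > 0 else np.nan
            pct = 100.0 * per_fraction[f] / total if total > 0 else np.nan
            rows.append(
                {
                    "genome_id": genome_id,
                    "size_fraction": f,
                    "retained_reads": per_fraction[f],
                    "reads_searched": searched[f],
                    "ratio": ratio,
                    "pct_of_genome": pct,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id", "size_fraction", "retained_reads",
            "reads_searched", "ratio", "pct_of_genome",
        ],
    )


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """TSV with header: sample_id, station_id, size_fraction, reads_searched."""
    df = pd.read_csv(path, sep="\t")
    return [
        SampleMeta(
            sample_id=str(r.sample_id),
            station_id=str(r.station_id),
            size_fraction=str(r.size_fraction),
            reads_searched=int(r.reads_searched),
        )
        for r in df.itertuples(index=False)
    ]
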