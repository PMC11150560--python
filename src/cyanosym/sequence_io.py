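"""Reading, writing and normalizing genome sequences and feature coordinates.

All coordinates are 0-based half-open internally; conversion to and from
1-based inclusive conventions (GFF3) happens only at the I/O boundary.
Sequences are upper-cased on ingest and RNA ``U`` is normalized to ``T`` so
that downstream k-mer counting sees a single alphabet.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# IUPAC nucleotide codes accepted on ingest (after U -> T normalization).
IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN")

FEATURE_KINDS = ("CDS", "rRNA", "tRNA", "other")

#: default mapping from GFF3 ``type`` / BED ``name`` values to internal kinds
DEFAULT_KIND_MAP = {
    "CDS": "CDS",
    "cds": "CDS",
    "rRNA": "rRNA",
    "rrna": "rRNA",
    "tRNA": "tRNA",
    "trna": "tRNA",
}


class SequenceError(ValueError):
    """Malformed sequence input (bad alphabet, duplicate ids, empty file)."""


class FeatureError(ValueError):
    """Malformed feature input (inverted or out-of-range intervals)."""


@dataclass
class GenomeRecord:
    """A single replicon: id, nucleotide sequence and topology."""

    genome_id: str
    sequence: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise SequenceError("genome_id must be nonempty")
        if self.topology not in ("linear", "circular"):
            raise SequenceError(f"unknown topology {self.topology!r}")
        seq = self.sequence.upper().replace("U", "T")
        if len(seq) < 1:
            raise SequenceError(f"{self.genome_id}: empty sequence")
        bad = set(seq) - IUPAC_NUCLEOTIDES
        if bad:
            raise SequenceError(
                f"{self.genome_id}: non-IUPAC characters {sorted(bad)!r}"
            )
        self.sequence = seq

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Feature:
    """A stranded, typed interval on a genome (0-based half-open)."""

    feature_id: str
    genome_id: str
    start: int
    end: int
    strand: str = "."
    kind: str = "other"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FeatureError(
                f"{self.feature_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise FeatureError(f"{self.feature_id}: bad strand {self.strand!r}")
        if self.kind not in FEATURE_KINDS:
            raise FeatureError(f"{self.feature_id}: bad kind {self.kind!r}")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def overlaps(self, start: int, end: int) -> bool:
        """Half-open interval intersection test; abutting intervals do not overlap."""
        return self.start < end and self.end > start


class FeatureTable:
    """An indexable collection of :class:`Feature` supporting overlap queries."""

    def __init__(self, features: Iterable[Feature] = ()) -> None:
        self._features: list[Feature] = sorted(
            features, key=lambda f: (f.genome_id, f.start, f.end, f.feature_id)
        )
        seen: dict[tuple[str, str], None] = {}
        for f in self._features:
            key = (f.genome_id, f.feature_id)
            if key in seen:
                raise FeatureError(
                    f"duplicate feature_id {f.feature_id!r} on genome {f.genome_id!r}"
                )
            seen[key] = None

    def __len__(self) -> int:
        return len(self._features)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self._features)

    def for_genome(self, genome_id: str) -> "FeatureTable":
        return FeatureTable(f for f in self._features if f.genome_id == genome_id)

    def of_kind(self, *kinds: str) -> "FeatureTable":
        return FeatureTable(f for f in self._features if f.kind in kinds)

    def overlapping(self, genome_id: str, start: int, end: int) -> list[Feature]:
        """Features on ``genome_id`` whose half-open interval intersects [start, end)."""
        return [
            f
            for f in self._features
            if f.genome_id == genome_id and f.overlaps(start, end)
        ]

    def get(self, genome_id: str, feature_id: str) -> Feature:
        for f in self._features:
            if f.genome_id == genome_id and f.feature_id == feature_id:
                return f
        raise KeyError((genome_id, feature_id))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "feature_id": f.feature_id,
                    "genome_id": f.genome_id,
                    "start": f.start,
                    "end": f.end,
                    "strand": f.strand,
                    "kind": f.kind,
                }
                for f in self._features
            ],
            columns=["feature_id", "genome_id", "start", "end", "strand", "kind"],
        )

    def validate_against(self, genome_lengths: dict[str, int]) -> None:
        """Raise if any feature extends beyond its genome's length."""
        for f in self._features:
            if f.genome_id in genome_lengths and f.end > genome_lengths[f.genome_id]:
                raise FeatureError(
                    f"{f.feature_id}: end {f.end} beyond genome "
                    f"{f.genome_id} length {genome_lengths[f.genome_id]}"
                )


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Parse a (possibly line-wrapped) FASTA file into :class:`GenomeRecord` objects.

    Raises :class:`SequenceError` on an empty file, duplicate ids, or
    characters outside the IUPAC nucleotide set.
    """
    records = [
        GenomeRecord(genome_id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    ids = [r.genome_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SequenceError(f"{path}: duplicate record ids {dupes!r}")
    return records


def write_fasta(records: Sequence[GenomeRecord], path: str | Path, width: int = 70) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.genome_id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def select_analysis_sequence(records: Sequence[GenomeRecord]) -> GenomeRecord:
    """Pick the single longest record (the main chromosome / longest scaffold).

    Ties are broken by lexicographically smallest id for determinism.
    """
    if not records:
        raise SequenceError("no records to select from")
    return min(records, key=lambda r: (-len(r), r.genome_id))


def _parse_gff3(path: str | Path, kind_map: dict[str, str]) -> list[Feature]:
    rows = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=[
            "seqid", "source", "type", "start", "end",
            "score", "strand", "phase", "attributes",
        ],
        dtype={"seqid": str, "type": str, "strand": str, "attributes": str},
    )
    features = []
    auto = 0
    for row in rows.itertuples(index=False):
        start = int(row.start) - 1  # 1-based inclusive -> 0-based half-open
        end = int(row.end)
        if end <= start:
            raise FeatureError(
                f"GFF3 row {row.seqid}:{row.start}-{row.end}: end <= start"
            )
        fid = None
        for part in str(row.attributes).split(";"):
            if part.startswith("ID="):
                fid = part[3:]
                break
        if fid is None:
            auto += 1
            fid = f"feature_{auto:06d}"
        features.append(
            Feature(
                feature_id=fid,
                genome_id=str(row.seqid),
                start=start,
                end=end,
                strand=row.strand if row.strand in ("+", "-") else ".",
                kind=kind_map.get(str(row.type), "other"),
            )
        )
    return features


def _parse_bed(path: str | Path, kind_map: dict[str, str]) -> list[Feature]:
    rows = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
    )
    features = []
    for i, row in enumerate(rows.itertuples(index=False)):
        vals = list(row)
        chrom, start, end = str(vals[0]), int(vals[1]), int(vals[2])
        if end <= start:
            raise FeatureError(f"BED row {chrom}:{start}-{end}: end <= start")
        name = str(vals[3]) if len(vals) > 3 else f"feature_{i + 1:06d}"
        strand = str(vals[5]) if len(vals) > 5 and str(vals[5]) in "+-" else "."
        # BED has no type column: kind inferred from the name prefix if mapped
        kind = kind_map.get(name.split("_")[0], "other")
        features.append(
            Feature(
                feature_id=name,
                genome_id=chrom,
                start=start,
                end=end,
                strand=strand,
                kind=kind,
            )
        )
    return features


def read_features(
    path: str | Path,
    dialect: str = "gff3",
    kind_map: dict[str, str] | None = None,
    genome_lengths: dict[str, int] | None = None,
) -> FeatureTable:
    """Read a GFF3 or BED feature file into a :class:`FeatureTable`.

    GFF3 rows (1-based inclusive) are converted to the internal 0-based
    half-open convention; BED rows pass through unchanged.  ``kind_map``
    overrides the default mapping from the type/name column to internal
    feature kinds.  When ``genome_lengths`` is supplied, features running
    past the end of their genome raise :class:`FeatureError`.
    """
    kmap = dict(DEFAULT_KIND_MAP)
    if kind_map:
        kmap.update(kind_map)
    if dialect == "gff3":
        features = _parse_gff3(path, kmap)
    elif dialect == "bed":
        features = _parse_bed(path, kmap)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    table = FeatureTable(features)
    if genome_lengths is not None:
        table.validate_against(genome_lengths)
    return table


def write_features(table: FeatureTable, path: str | Path, dialect: str = "gff3") -> None:
    """Write features back out, undoing the coordinate conversion for GFF3."""
    with open(path, "w") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
            for f in table:
                gff_type = f.kind if f.kind != "other" else "region"
                fh.write(
                    f"{f.genome_id}\tcyanosym\t{gff_type}\t{f.start + 1}\t{f.end}\t."
                    f"\t{f.strand}\t.\tID={f.feature_id}\n"
                )
        elif dialect == "bed":
            for f in table:
                fh.write(
                    f"{f.genome_id}\t{f.start}\t{f.end}\t{f.feature_id}\t0\t{f.strand}\n"
                )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
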