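"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its spec (including the seed): rerun
with the same spec, it returns byte-identical output.  The generators
emulate the statistical structure the analyses assume — genomes whose
islands have genuinely tetranucleotide-level compositional shifts (an
order-3 Markov model, not just a GC offset), hit tables in which island
genes hit organisms that are rare genome-wide, ortholog matrices with a
two-clade free-living structure plus reduced symbionts, and fractionated
read sets with known per-fraction source proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fraction_abundance import ALIGNMENT_COLUMNS, SIZE_FRACTIONS, SampleMeta
from .hit_frequency import HitRecord, HitsByQuery
from .ortho_repertoire import OrthoMatrix
from .sequence_io import Feature, FeatureTable, GenomeRecord

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# composition models and genome simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompositionModel:
    """Order-0 (4 probs) or order-3 (64 x 4 transition rows) nucleotide model."""

    probs: np.ndarray  # shape (4,) or (64, 4); rows sum to 1

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape not in ((4,), (64, 4)):
            raise ValueError(f"probs must have shape (4,) or (64, 4), got {p.shape}")
        sums = p.sum(axis=-1)
        if not np.allclose(sums, 1.0):
            raise ValueError("composition probabilities must sum to 1")
        object.__setattr__(self, "probs", p)

    @property
    def order(self) -> int:
        return 0 if self.probs.ndim == 1 else 3

    @classmethod
    def from_gc(cls, gc: float) -> "CompositionModel":
        """Order-0 model with the given GC content, A/T and C/G symmetric."""
        at = (1.0 - gc) / 2.0
        return cls(np.array([at, gc / 2.0, gc / 2.0, at]))

    @classmethod
    def order3_biased(
        cls, gc: float = 0.5, tetra_bias: float = 0.0, key: int = 0
    ) -> "CompositionModel":
        """Order-3 model: GC-weighted base odds perturbed per 3-mer context.

        ``tetra_bias`` scales context-specific log-odds noise (drawn from a
        generator seeded with ``key``), so two models with different keys or
        biases differ at the tetranucleotide level even at equal GC.
        """
        base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        z = np.random.default_rng(key).normal(size=(64, 4))
        table = base[None, :] * np.exp(tetra_bias * z)
        table /= table.sum(axis=1, keepdims=True)
        return cls(table)


def sample_sequence(
    model: CompositionModel, length: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample a base-index array (0..3) of the given length from the model."""
    if model.order == 0:
        return rng.choice(4, size=length, p=model.probs)
    cum = np.cumsum(model.probs, axis=1)
    u = rng.random(length)
    out = np.empty(length, dtype=np.int8)
    ctx = 0
    for i in range(length):
        row = cum[ctx]
        ui = u[i]
        b = 0 if ui < row[0] else 1 if ui < row[1] else 2 if ui < row[2] else 3
        out[i] = b
        ctx = ((ctx << 2) | b) & 63
    return out


@dataclass
class GenomeSimSpec:
    """A background-composition genome with implanted compositional islands."""

    length: int = 500_000
    background: CompositionModel = field(
        default_factory=lambda: CompositionModel.order3_biased(
            gc=0.55, tetra_bias=0.15, key=1
        )
    )
    islands: Sequence[tuple[int, int, CompositionModel]] = ()
    gene_length_mean: int = 900
    intergenic_gap: int = 100
    genome_id: str = "simgenome"
    seed: int = 0

    def __post_init__(self) -> None:
        ivals = sorted((s, e) for s, e, _ in self.islands)
        for (s, e) in ivals:
            if not (0 <= s < e <= self.length):
                raise ValueError(f"island [{s}, {e}) outside genome [0, {self.length})")
        for (_, e1), (s2, _) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError("islands must be pairwise disjoint")


def gen_genome(
    spec: GenomeSimSpec,
) -> tuple[GenomeRecord, FeatureTable, list[tuple[int, int]]]:
    """Sample the genome, overwrite island segments, tile CDS features.

    Returns the record, a CDS feature table, and the truth island intervals
    (exactly as configured in the sim spec).
    """
    rng = np.random.default_rng(spec.seed)
    seq = sample_sequence(spec.background, spec.length, rng)
    for (s, e, model) in spec.islands:
        seq[s:e] = sample_sequence(model, e - s, rng)
    sequence = "".join(_BASES[seq])

    features = []
    pos = 0
    i = 0
    lo = max(60, int(spec.gene_length_mean * 0.7))
    hi = int(spec.gene_length_mean * 1.3) + 1
    while True:
        glen = int(rng.integers(lo, hi))
        if pos + glen > spec.length:
            break
        i += 1
        features.append(
            Feature(
                feature_id=f"gene_{i:05d}",
                genome_id=spec.genome_id,
                start=pos,
                end=pos + glen,
                strand="+" if rng.random() < 0.5 else "-",
                kind="CDS",
            )
        )
        pos += glen + spec.intergenic_gap
    record = GenomeRecord(genome_id=spec.genome_id, sequence=sequence)
    truth = [(s, e) for s, e, _ in spec.islands]
    return record, FeatureTable(features), truth


# ---------------------------------------------------------------------------
# homology hit tables
# ---------------------------------------------------------------------------

@dataclass
class HitSimSpec:
    """Organism pool for background genes; rare labels reserved for island genes."""

    organism_pool: Mapping[str, float] = field(
        default_factory=lambda: {
            "Synechococcus sp. CC9902": 50.0,
            "Synechococcus sp. BL107": 40.0,
            "Parasynechococcus marenigrum": 30.0,
            "Synechococcus sp. WH8102": 10.0,
            "Prochlorococcus marinus MED4": 5.0,
        }
    )
    island_gene_organisms: Sequence[str] = (
        "Vibrio sp. X1",
        "Alteromonas sp. X2",
        "Pseudomonas sp. X3",
    )
    top_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.organism_pool.values()):
            raise ValueError("propensities must be positive")
        if set(self.island_gene_organisms) & set(self.organism_pool):
            raise ValueError("rare labels must be disjoint from the common pool")


def _in_islands(feature: Feature, islands: Sequence[tuple[int, int]]) -> bool:
    mid = (feature.start + feature.end) // 2
    return any(s <= mid < e for s, e in islands)


def gen_hit_table(
    features: FeatureTable,
    truth_islands: Sequence[tuple[int, int]],
    spec: HitSimSpec,
) -> HitsByQuery:
    """Top-k hit lists per CDS: common organisms by propensity, rare for islands."""
    cds = list(features.of_kind("CDS"))
    if not cds:
        raise ValueError("no CDS features to generate hits for")
    common = list(spec.organism_pool)
    if not common:
        raise ValueError("empty organism pool")
    weights = np.array([spec.organism_pool[o] for o in common], dtype=float)
    weights /= weights.sum()
    rare = list(spec.island_gene_organisms)
    rng = np.random.default_rng(spec.seed)
    hits: HitsByQuery = {}
    for f in cds:
        if _in_islands(f, truth_islands):
            orgs = [rare[int(rng.integers(len(rare)))] for _ in range(spec.top_k)]
        else:
            orgs = [common[j] for j in rng.choice(len(common), size=spec.top_k, p=weights)]
        hits[f.feature_id] = [
            HitRecord(
                query_id=f.feature_id,
                subject_organism=org,
                rank=r + 1,
                bitscore=500.0 - 10.0 * r,
            )
            for r, org in enumerate(orgs)
        ]
    return hits


def write_hit_table(hits: HitsByQuery, path) -> None:
    """Emit the 12-column homology dialect plus the organism column (13th)."""
    rows = []
    for q in hits:
        for h in sorted(hits[q], key=lambda h: h.rank):
            rows.append(
                [
                    h.query_id,
                    f"{h.subject_organism}|p{h.rank}",
                    98.0,
                    200,
                    4,
                    0,
                    1,
                    200,
                    1,
                    200,
                    1e-50,
                    h.bitscore,
                    h.subject_organism,
                ]
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# ortholog matrices
# ---------------------------------------------------------------------------

@dataclass
class OrthoSimSpec:
    """Two free-living clades plus reduced symbionts, with known categories."""

    n_prochlorococcus: int = 5
    n_synechococcus_5_1: int = 5
    n_symbionts: int = 2
    n_core: int = 100
    n_ancestral_extra: int = 50
    n_accessory: int = 40
    symbiont_loss_rate: Mapping[str, float] = field(
        default_factory=lambda: {
            "core": 0.05,
            "picocyanobacterial_ancestral": 0.4,
            "accessory": 0.9,
        }
    )
    annotation_rate: Mapping[str, float] = field(
        default_factory=lambda: {
            "core": 0.8,
            "picocyanobacterial_ancestral": 0.45,
            "accessory": 0.2,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_prochlorococcus, self.n_synechococcus_5_1) < 2:
            raise ValueError("need >= 2 genomes per free-living clade")
        if any(not 0 <= r <= 1 for r in self.symbiont_loss_rate.values()):
            raise ValueError("loss rates must be in [0, 1]")


def gen_ortho_matrix(
    spec: OrthoSimSpec,
) -> tuple[OrthoMatrix, dict[str, bool], pd.Series]:
    """Build the copy-count matrix, an annotation map, and truth categories.

    Core groups are present in every free-living genome; ancestral-extra
    groups are knocked out of exactly one free-living genome (leaving both
    clades represented); accessory groups are present only within one
    free-living clade or only in symbionts.  Symbiont retention is sampled
    per category loss rate.
    """
    rng = np.random.default_rng(spec.seed)
    proc = [f"Proc_{i + 1:02d}" for i in range(spec.n_prochlorococcus)]
    syn = [f"Syn51_{i + 1:02d}" for i in range(spec.n_synechococcus_5_1)]
    sym = [f"Symbiont_{chr(ord('A') + i)}" for i in range(spec.n_symbionts)]
    free_living = proc + syn
    genomes = free_living + sym
    labels: dict[str, set[str]] = {}
    for g in proc:
        labels[g] = {"free_living", "prochlorococcus_clade"}
    for g in syn:
        labels[g] = {"free_living", "synechococcus_5_1"}
    for g in sym:
        labels[g] = {"symbiont"}

    ogs: list[str] = []
    truth: list[str] = []
    data: list[np.ndarray] = []

    def _symbiont_presence(category: str) -> np.ndarray:
        loss = spec.symbiont_loss_rate.get(category, 0.0)
        return (rng.random(len(sym)) >= loss).astype(int)

    for i in range(spec.n_core):
        row = np.zeros(len(genomes), dtype=int)
        row[: len(free_living)] = 1
        row[len(free_living):] = _symbiont_presence("core")
        ogs.append(f"OG_core_{i + 1:04d}")
        truth.append("core")
        data.append(row)

    for i in range(spec.n_ancestral_extra):
        row = np.zeros(len(genomes), dtype=int)
        row[: len(free_living)] = 1
        row[int(rng.integers(len(free_living)))] = 0  # clades have >= 2 members
        row[len(free_living):] = _symbiont_presence("picocyanobacterial_ancestral")
        ogs.append(f"OG_anc_{i + 1:04d}")
        truth.append("picocyanobacterial_ancestral")
        data.append(row)

    for i in range(spec.n_accessory):
        row = np.zeros(len(genomes), dtype=int)
        pattern = ("proc_only", "syn_only", "symbiont_only")[int(rng.integers(3))]
        if pattern == "proc_only":
            members = rng.choice(len(proc), size=int(rng.integers(1, len(proc) + 1)), replace=False)
            row[members] = 1
            row[len(free_living):] = _symbiont_presence("accessory")
        elif pattern == "syn_only":
            members = rng.choice(len(syn), size=int(rng.integers(1, len(syn) + 1)), replace=False)
            row[len(proc) + members] = 1
            row[len(free_living):] = _symbiont_presence("accessory")
        else:
            if sym:
                keep = _symbiont_presence("accessory")
                if keep.sum() == 0:
                    keep[int(rng.integers(len(sym)))] = 1
                row[len(free_living):] = keep
            else:
                row[int(rng.integers(len(proc)))] = 1
        ogs.append(f"OG_acc_{i + 1:04d}")
        truth.append("accessory")
        data.append(row)

    counts = pd.DataFrame(np.vstack(data), index=ogs, columns=genomes)
    unassigned = {g: int(rng.integers(0, 30)) for g in genomes}
    matrix = OrthoMatrix(counts=counts, labels=labels, unassigned=unassigned)
    truth_s = pd.Series(truth, index=ogs, name="category")
    annotation = {
        og: bool(rng.random() < spec.annotation_rate.get(cat, 0.3))
        for og, cat in truth_s.items()
    }
    return matrix, annotation, truth_s


def printed_retention_fixture() -> tuple[OrthoMatrix, dict[str, bool]]:
    """Compact ortho fixture encoding the published CregCyn/OmCyn retention counts.

    The ancestral proteome has 2,369 groups, of which symbiont A retains
    1,388 and symbiont B retains 1,405 with 1,259 shared; 850 of the shared
    groups, 58 of the A-only, 53 of the B-only and 196 of the lost-both
    groups carry a functional annotation (1,157 annotated in total).  All
    2,369 groups are built as picocyanobacterial-ancestral (present in one
    genome of each free-living clade, absent from a third free-living
    genome), so the ancestral set is exactly this fixture.
    """
    blocks = [  # (n_groups, in_A, in_B, n_annotated)
        (1259, 1, 1, 850),
        (129, 1, 0, 58),
        (146, 0, 1, 53),
        (835, 0, 0, 196),
    ]
    ogs, rows = [], []
    annotation: dict[str, bool] = {}
    i = 0
    for n, in_a, in_b, n_ann in blocks:
        for j in range(n):
            i += 1
            og = f"OG{i:04d}"
            ogs.append(og)
            rows.append([1, 1, 0, in_a, in_b])
            annotation[og] = j < n_ann
    counts = pd.DataFrame(
        rows, index=ogs, columns=["Proc_01", "Syn51_01", "Free_01", "CregCyn", "OmCyn"]
    )
    labels = {
        "Proc_01": {"free_living", "prochlorococcus_clade"},
        "Syn51_01": {"free_living", "synechococcus_5_1"},
        "Free_01": {"free_living"},
        "CregCyn": {"symbiont"},
        "OmCyn": {"symbiont"},
    }
    return OrthoMatrix(counts=counts, labels=labels), annotation


# ---------------------------------------------------------------------------
# fractionated read sets
# ---------------------------------------------------------------------------

@dataclass
class ReadSimSpec:
    """Per-fraction source-genome mixing proportions for recruitment tests."""

    proportions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "0.8-5": {"simgenome": 0.01},
            "5-20": {"simgenome": 0.36},
            "20-180": {"simgenome": 0.63},
            "180-2000": {"simgenome": 0.0},
        }
    )
    reads_per_fraction: int = 10_000
    read_length: int = 100
    error_rate: float = 0.001
    station_id: str = "ST1"
    seed: int = 0

    def __post_init__(self) -> None:
        for frac, mix in self.proportions.items():
            if frac not in SIZE_FRACTIONS:
                raise ValueError(f"unknown size fraction {frac!r}")
            if any(p < 0 for p in mix.values()) or sum(mix.values()) > 1 + 1e-12:
                raise ValueError(f"{frac}: proportions must be >= 0 and sum to <= 1")


@dataclass
class SimulatedReadSet:
    alignments: pd.DataFrame
    meta: list[SampleMeta]
    truth_pct: dict[str, dict[str, float]]  # genome -> fraction -> percent
    reads: list[tuple[str, str]]  # (read_id, sequence) for on-target reads


def gen_fraction_reads(
    genomes: Sequence[GenomeRecord], spec: ReadSimSpec
) -> SimulatedReadSet:
    """Sample fractionated reads and a consistent pre-computed alignment table.

    Reads are drawn uniformly from each source genome according to the
    fraction's mixing proportions (the remainder is off-target and yields
    no alignment row); per-base substitution errors reduce the reported
    identity to ``100 * (1 - mismatches / length)``.
    """
    by_id = {g.genome_id: g for g in genomes}
    for mix in spec.proportions.values():
        unknown = set(mix) - set(by_id)
        if unknown:
            raise ValueError(f"unknown source genomes {sorted(unknown)!r}")
    for g in genomes:
        if spec.read_length > len(g):
            raise ValueError(
                f"read length {spec.read_length} exceeds genome {g.genome_id}"
            )
    rng = np.random.default_rng(spec.seed)
    rows: list[list] = []
    reads: list[tuple[str, str]] = []
    meta: list[SampleMeta] = []
    for frac in SIZE_FRACTIONS:
        mix = dict(spec.proportions.get(frac, {}))
        sample_id = f"S_{frac}"
        meta.append(
            SampleMeta(
                sample_id=sample_id,
                station_id=spec.station_id,
                size_fraction=frac,
                reads_searched=spec.reads_per_fraction,
            )
        )
        sources = list(mix)
        probs = [mix[g] for g in sources] + [1.0 - sum(mix.values())]
        counts = rng.multinomial(spec.reads_per_fraction, probs)
        r = 0
        for gi, genome_id in enumerate(sources):
            genome = by_id[genome_id]
            L = spec.read_length
            for _ in range(counts[gi]):
                r += 1
                read_id = f"{sample_id}_r{r:06d}"
                start = int(rng.integers(0, len(genome) - L + 1))
                fragment = list(genome.sequence[start : start + L])
                m = int(rng.binomial(L, spec.error_rate))
                if m:
                    for pos in rng.choice(L, size=m, replace=False):
                        orig = fragment[pos]
                        alts = [b for b in "ACGT" if b != orig]
                        fragment[pos] = alts[int(rng.integers(3))]
                reads.append((read_id, "".join(fragment)))
                identity = 100.0 * (1.0 - m / L)
                rows.append(
                    [
                        read_id, genome_id, round(identity, 3), L, m, 0,
                        1, L, start + 1, start + L, 1e-40, 2.0 * L - 3.0 * m,
                        sample_id,
                    ]
                )
    alignments = pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS + ["sample_id"])
    truth_pct: dict[str, dict[str, float]] = {}
    for g in by_id:
        per_frac = {
            f: spec.proportions.get(f, {}).get(g, 0.0) for f in SIZE_FRACTIONS
        }
        total = sum(per_frac.values())
        if total > 0:
            truth_pct[g] = {f: 100.0 * p / total for f, p in per_frac.items()}
    return SimulatedReadSet(
        alignments=alignments, meta=meta, truth_pct=truth_pct, reads=reads
    )


# ---------------------------------------------------------------------------
# a ready-made island-detection scene
# ---------------------------------------------------------------------------

def default_island_scene(
    seed: int = 0,
    length: int = 500_000,
    island_length: int = 15_000,
    island_starts: Sequence[int] = (100_000, 250_000, 400_000),
) -> tuple[GenomeRecord, FeatureTable, list[tuple[int, int]], HitsByQuery]:
    """A genome with three implanted islands plus a matching hit table.

    Background: order-3 model at GC 0.55; islands: a differently keyed
    order-3 model at GC 0.40 with strong tetranucleotide bias.  Island
    genes hit only rare organisms.  This is the standard end-to-end
    recovery scenario used in tests and the worked example.
    """
    island_model = CompositionModel.order3_biased(gc=0.40, tetra_bias=1.0, key=7)
    spec = GenomeSimSpec(
        length=length,
        islands=[(s, s + island_length, island_model) for s in island_starts],
        seed=seed,
    )
    record, features, truth = gen_genome(spec)
    hits = gen_hit_table(features, truth, HitSimSpec(seed=seed + 1))
    return record, features, truth, hits
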