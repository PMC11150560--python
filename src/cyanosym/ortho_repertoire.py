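"""Orthogroup repertoire statistics for reduced symbiont genomes.

Works on an orthogroup × genome copy-count matrix (OrthoFinder-style
GeneCount table) with genome labels.  Provides: nonredundant proteome
sizes; the core / picocyanobacterial-ancestral / accessory classification;
ancestral-proteome retention and sharing statistics between two symbiont
genomes; per-set functional-annotation proportions; and single-copy marker
selection for phylogenomics.

Category definitions
--------------------
core
    orthogroups present (>= 1 copy) in every free-living genome.
picocyanobacterial_ancestral
    not core, but present in at least one *Prochlorococcus*-clade genome
    and at least one *Synechococcus* subcluster 5.1 genome — hence inferred
    present in the picocyanobacterial common ancestor.
accessory
    everything else.

Categories are tested in that order, so they partition the orthogroup
universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

GENOME_LABELS = (
    "free_living",
    "prochlorococcus_clade",
    "synechococcus_5_1",
    "symbiont",
    "other",
)

CATEGORIES = ("core", "picocyanobacterial_ancestral", "accessory")


class OrthoError(ValueError):
    pass


class OrthoMatrix:
    """Orthogroup × genome copy counts, with per-genome labels and unassigned counts."""

    def __init__(
        self,
        counts: pd.DataFrame,
        labels: Mapping[str, set[str] | frozenset[str]],
        unassigned: Mapping[str, int] | None = None,
    ) -> None:
        counts = counts.astype(int)
        if (counts.to_numpy() < 0).any():
            raise OrthoError("copy counts must be nonnegative")
        self.counts = counts
        self.labels = {g: frozenset(labels[g]) for g in counts.columns}
        for g, labs in self.labels.items():
            if not labs:
                raise OrthoError(f"genome {g!r} carries no label")
            bad = labs - set(GENOME_LABELS)
            if bad:
                raise OrthoError(f"genome {g!r}: unknown labels {sorted(bad)!r}")
        self.unassigned = {
            g: int((unassigned or {}).get(g, 0)) for g in counts.columns
        }
        if any(v < 0 for v in self.unassigned.values()):
            raise OrthoError("unassigned counts must be nonnegative")

    @property
    def genomes(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def orthogroups(self) -> list[str]:
        return list(self.counts.index)

    def with_label(self, label: str) -> list[str]:
        return [g for g in self.genomes if label in self.labels[g]]

    def presence(self) -> pd.DataFrame:
        """Boolean orthogroup × genome presence (copy count >= 1)."""
        return self.counts >= 1

    def present_in(self, genome_id: str) -> set[str]:
        if genome_id not in self.counts.columns:
            raise OrthoError(f"unknown genome {genome_id!r}")
        col = self.counts[genome_id]
        return set(col.index[col >= 1])


def repertoire_size(matrix: OrthoMatrix, genome_id: str) -> int:
    """Nonredundant proteome size: orthogroups present plus unassigned proteins.

    Extra within-genome copies of an orthogroup do not increase the size.
    """
    if genome_id not in matrix.counts.columns:
        raise OrthoError(f"unknown genome {genome_id!r}")
    return int((matrix.counts[genome_id] >= 1).sum()) + matrix.unassigned[genome_id]


def classify_groups(matrix: OrthoMatrix) -> pd.Series:
    """Assign every orthogroup exactly one of the three conservation categories."""
    free_living = matrix.with_label("free_living")
    proc = matrix.with_label("prochlorococcus_clade")
    syn = matrix.with_label("synechococcus_5_1")
    for name, members in (
        ("free_living", free_living),
        ("prochlorococcus_clade", proc),
        ("synechococcus_5_1", syn),
    ):
        if not members:
            raise OrthoError(f"no genome labelled {name!r}")
    pres = matrix.presence()
    core = pres[free_living].all(axis=1)
    ancestral = ~core & pres[proc].any(axis=1) & pres[syn].any(axis=1)
    out = pd.Series("accessory", index=matrix.counts.index, name="category")
    out[ancestral] = "picocyanobacterial_ancestral"
    out[core] = "core"
    return out


@dataclass
class RetentionReport:
    """Ancestral-proteome retention bookkeeping for two symbiont genomes."""

    symbiont_a: str
    symbiont_b: str
    ancestral_size: int
    retained_a: int
    retained_b: int
    shared: int
    lost_both: int

    def __post_init__(self) -> None:
        # inclusion–exclusion over the ancestral set must close
        assert self.lost_both == (
            self.ancestral_size - self.retained_a - self.retained_b + self.shared
        )

    @property
    def retained_pct_a(self) -> float | None:
        if self.ancestral_size == 0:
            return None
        return 100.0 * self.retained_a / self.ancestral_size

    @property
    def retained_pct_b(self) -> float | None:
        if self.ancestral_size == 0:
            return None
        return 100.0 * self.retained_b / self.ancestral_size

    @property
    def shared_pct_a(self) -> float | None:
        """Shared groups as a percentage of symbiont a's retained set."""
        if self.retained_a == 0:
            return None
        return 100.0 * self.shared / self.retained_a

    @property
    def shared_pct_b(self) -> float | None:
        if self.retained_b == 0:
            return None
        return 100.0 * self.shared / self.retained_b


def ancestral_set(
    categories: pd.Series, include_core: bool = True
) -> set[str]:
    """Orthogroups inferred present in the picocyanobacterial ancestor.

    By default the union of the core and ancestral categories; set
    ``include_core=False`` to use the ancestral category alone.
    """
    keep = {"picocyanobacterial_ancestral"}
    if include_core:
        keep.add("core")
    return set(categories.index[categories.isin(keep)])


def ancestral_retention(
    matrix: OrthoMatrix,
    categories: pd.Series,
    symbiont_a: str,
    symbiont_b: str,
    include_core: bool = True,
) -> RetentionReport:
    """How much of the ancestral proteome each symbiont retains, and the overlap."""
    A = ancestral_set(categories, include_core=include_core)
    in_a = matrix.present_in(symbiont_a) & A
    in_b = matrix.present_in(symbiont_b) & A
    shared = in_a & in_b
    return RetentionReport(
        symbiont_a=symbiont_a,
        symbiont_b=symbiont_b,
        ancestral_size=len(A),
        retained_a=len(in_a),
        retained_b=len(in_b),
        shared=len(shared),
        lost_both=len(A - in_a - in_b),
    )


def retention_sets(
    matrix: OrthoMatrix,
    categories: pd.Series,
    symbiont_a: str,
    symbiont_b: str,
    include_core: bool = True,
) -> dict[str, set[str]]:
    """The five named subsets of the ancestral proteome used in reports."""
    A = ancestral_set(categories, include_core=include_core)
    in_a = matrix.present_in(symbiont_a) & A
    in_b = matrix.present_in(symbiont_b) & A
    return {
        "ancestral": A,
        "shared": in_a & in_b,
        "a_only": in_a - in_b,
        "b_only": in_b - in_a,
        "lost_both": A - in_a - in_b,
        "retained_a": in_a,
        "retained_b": in_b,
    }


def annotation_proportions(
    sets: Mapping[str, set[str]], annotation: Mapping[str, bool]
) -> dict[str, float | None]:
    """Fraction of each orthogroup set carrying a functional (KO) annotation.

    Groups absent from the annotation map count as unannotated; empty sets
    give a missing (None) fraction.
    """
    out: dict[str, float | None] = {}
    for name, members in sets.items():
        if not members:
            out[name] = None
            continue
        annotated = sum(1 for g in members if annotation.get(g, False))
        out[name] = annotated / len(members)
    return out


def select_phylo_markers(
    matrix: OrthoMatrix,
    conservation: float = 0.99,
    scope_label: str = "free_living",
) -> list[str]:
    """Single-copy marker orthogroups for concatenated phylogenomics.

    Selected groups have exactly one copy in at least ``conservation`` of
    the scope genomes and never more than one copy in any scope genome
    (a single paralogous duplication disqualifies the group).
    """
    if not 0 < conservation <= 1:
        raise OrthoError("conservation must be in (0, 1]")
    scope = matrix.with_label(scope_label)
    if not scope:
        raise OrthoError(f"no genome labelled {scope_label!r}")
    sub = matrix.counts[scope]
    single = (sub == 1).sum(axis=1) / len(scope) >= conservation
    no_paralogs = (sub <= 1).all(axis=1)
    return list(sub.index[single & no_paralogs])


def read_ortho_counts(path: str | Path) -> pd.DataFrame:
    """Read an OrthoFinder-style GeneCount table (drops any 'Total' column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "Total" in df.columns:
        df = df.drop(columns=["Total"])
    return df.astype(int)


def read_genome_labels(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV: genome_id <tab> comma-separated labels."""
    df = pd.read_csv(path, sep="\t", header=None, names=["genome_id", "labels"])
    return {
        str(r.genome_id): {s.strip() for s in str(r.labels).split(",") if s.strip()}
        for r in df.itertuples(index=False)
    }


def read_unassigned(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["genome_id", "n"])
    return {str(r.genome_id): int(r.n) for r in df.itertuples(index=False)}


def read_annotation_map(path: str | Path) -> dict[str, bool]:
    """Two-column TSV orthogroup <tab> KO id; a nonempty KO marks the group annotated."""
    df = pd.read_csv(path, sep="\t", header=None, names=["orthogroup", "ko"])
    return {
        str(r.orthogroup): bool(str(r.ko).strip()) and str(r.ko).strip() != "-"
        for r in df.itertuples(index=False)
    }
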