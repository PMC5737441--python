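"""Core in-memory containers shared by every pipeline stage.

The pipeline operates on diploid, biallelic SNP panels.  Genotypes are
stored as alternate-allele dosages (0, 1, 2) with ``MISSING = -1`` for
uncalled genotypes, in a dense ``(n_individuals, n_loci)`` int8 array.
Locus identifiers of the form ``<tag>_<offset>`` carry RAD-tag
provenance (``24343_34`` is the SNP at offset 34 of tag 24343); an id
without an underscore-separated integer suffix is treated as a
single-SNP tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Sentinel dosage for an uncalled genotype.
MISSING: int = -1

MIGRATORY_ECOTYPES = ("anadromous", "kokanee")
REPRODUCTIVE_ECOTYPES = ("shore", "stream", "black")


def split_locus_id(locus_id: str) -> tuple[str, int]:
    """Split ``<tag>_<offset>`` into (tag, offset).

    Ids without a trailing ``_<int>`` are single-SNP tags at offset 0.
    """
    tag, sep, suffix = locus_id.rpartition("_")
    if sep and suffix.isdigit():
        return tag, int(suffix)
    return locus_id, 0


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci alternate-allele dosage matrix."""

    individual_ids: list[str]
    locus_ids: list[str]
    dosage: np.ndarray  # (n_individuals, n_loci) int8; MISSING = -1
    tag_of_locus: dict[str, str] = field(default_factory=dict)
    snp_index_in_tag: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.individual_ids = list(self.individual_ids)
        self.locus_ids = list(self.locus_ids)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.individual_ids), len(self.locus_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.locus_ids)} loci"
            )
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("duplicate locus ids")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be 0, 1, 2 or MISSING")
        if not self.tag_of_locus:
            self.tag_of_locus = {}
            self.snp_index_in_tag = {}
            for lid in self.locus_ids:
                tag, off = split_locus_id(lid)
                self.tag_of_locus[lid] = tag
                self.snp_index_in_tag[lid] = off
        # offsets must be unique within a tag
        seen: dict[tuple[str, int], str] = {}
        for lid in self.locus_ids:
            key = (self.tag_of_locus[lid], self.snp_index_in_tag[lid])
            if key in seen:
                raise ValueError(
                    f"loci {seen[key]!r} and {lid!r} share tag {key[0]!r} offset {key[1]}"
                )
            seen[key] = lid

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def called(self) -> np.ndarray:
        """Boolean mask of called genotypes, shape (n_individuals, n_loci)."""
        return self.dosage != MISSING

    # -- subsetting -----------------------------------------------------
    def locus_index(self, locus_ids: Sequence[str]) -> np.ndarray:
        pos = {lid: j for j, lid in enumerate(self.locus_ids)}
        return np.array([pos[lid] for lid in locus_ids], dtype=int)

    def individual_index(self, individual_ids: Sequence[str]) -> np.ndarray:
        pos = {iid: i for i, iid in enumerate(self.individual_ids)}
        return np.array([pos[iid] for iid in individual_ids], dtype=int)

    def subset_loci(self, keep: Sequence[str]) -> "GenotypeMatrix":
        idx = self.locus_index(keep)
        keep = list(keep)
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            locus_ids=keep,
            dosage=self.dosage[:, idx].copy(),
            tag_of_locus={lid: self.tag_of_locus[lid] for lid in keep},
            snp_index_in_tag={lid: self.snp_index_in_tag[lid] for lid in keep},
        )

    def subset_individuals(self, keep: Sequence[str]) -> "GenotypeMatrix":
        idx = self.individual_index(keep)
        return GenotypeMatrix(
            individual_ids=list(keep),
            locus_ids=list(self.locus_ids),
            dosage=self.dosage[idx, :].copy(),
            tag_of_locus=dict(self.tag_of_locus),
            snp_index_in_tag=dict(self.snp_index_in_tag),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.dosage, other.dosage)
            and self.tag_of_locus == other.tag_of_locus
            and self.snp_index_in_tag == other.snp_index_in_tag
        )


@dataclass(frozen=True)
class PopAttrs:
    """Attributes of one sampling unit (population)."""

    lake: str | None = None
    catchment: str | None = None
    migratory_ecotype: str | None = None  # anadromous | kokanee
    reproductive_ecotype: str | None = None  # shore | stream | black


@dataclass
class SampleTable:
    """Individual -> population assignment with population attributes."""

    pop_of_individual: dict[str, str]
    pop_attrs: dict[str, PopAttrs] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pop in set(self.pop_of_individual.values()):
            self.pop_attrs.setdefault(pop, PopAttrs())

    @property
    def populations(self) -> list[str]:
        """Population ids in first-seen (insertion) order."""
        seen: dict[str, None] = {}
        for pop in self.pop_of_individual.values():
            seen.setdefault(pop)
        return list(seen)

    def individuals_of(self, pop: str) -> list[str]:
        return [i for i, p in self.pop_of_individual.items() if p == pop]

    def members_mask(self, gm: GenotypeMatrix, pops: Iterable[str]) -> np.ndarray:
        """Boolean mask over ``gm.individual_ids`` for members of ``pops``."""
        pops = set(pops)
        return np.array(
            [self.pop_of_individual.get(i) in pops for i in gm.individual_ids],
            dtype=bool,
        )

    def validate_against(self, gm: GenotypeMatrix) -> None:
        missing = [i for i in gm.individual_ids if i not in self.pop_of_individual]
        if missing:
            raise ValueError(f"individuals without population assignment: {missing[:5]}")

    def restrict(self, individual_ids: Iterable[str]) -> "SampleTable":
        keep = set(individual_ids)
        return SampleTable(
            pop_of_individual={
                i: p for i, p in self.pop_of_individual.items() if i in keep
            },
            pop_attrs=dict(self.pop_attrs),
        )


@dataclass
class LinkageMap:
    """Partial genetic map: locus -> (linkage group, position in cM)."""

    position: dict[str, tuple[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lid, (lg, cm) in self.position.items():
            cm = float(cm)
            if not np.isfinite(cm) or cm < 0:
                raise ValueError(f"locus {lid!r}: cM position must be finite and >= 0")
            self.position[lid] = (str(lg), cm)

    def __len__(self) -> int:
        return len(self.position)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self.position

    def linkage_groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for lg, _ in self.position.values():
            seen.setdefault(lg)
        return list(seen)

    def loci_on(self, lg: str) -> list[tuple[str, float]]:
        """(locus_id, cM) pairs on one linkage group, sorted by position."""
        out = [(lid, cm) for lid, (g, cm) in self.position.items() if g == lg]
        out.sort(key=lambda t: (t[1], t[0]))
        return out


@dataclass(frozen=True)
class ComparisonSpec:
    """A labelled two-sided population contrast (e.g. shore vs stream)."""

    label: str
    side_a: frozenset[str]
    side_b: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "side_a", frozenset(self.side_a))
        object.__setattr__(self, "side_b", frozenset(self.side_b))
        if not self.side_a or not self.side_b:
            raise ValueError(f"comparison {self.label!r}: both sides must be non-empty")
        if self.side_a & self.side_b:
            raise ValueError(f"comparison {self.label!r}: sides overlap")


__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "PopAttrs",
    "SampleTable",
    "LinkageMap",
    "ComparisonSpec",
    "split_locus_id",
]
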