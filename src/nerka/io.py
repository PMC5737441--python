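"""Readers and writers for the formats the pipeline touches.

GENEPOP (the diploid, biallelic dialect exported by STACKS), the
tab-delimited linkage-map, sample-attribute and comparison-manifest
files, and a generic full-precision TSV serializer for result tables.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .types import MISSING, ComparisonSpec, GenotypeMatrix, LinkageMap, PopAttrs, SampleTable


class GenepopParseError(ValueError):
    """A GENEPOP file violated the expected dialect."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


_POP_RE = re.compile(r"^pop\s*$", re.IGNORECASE)
_MISSING_CODES = {"0", "00", "000", "0000"}


def _pop_name_from_label(label: str, block_index: int) -> str:
    """Population name = prefix of the first individual label before the
    last underscore; labels without an underscore fall back to pop<k>."""
    prefix, sep, _ = label.rpartition("_")
    return prefix if sep else f"pop{block_index + 1}"


def read_genepop(path: str | Path) -> tuple[GenotypeMatrix, SampleTable]:
    """Parse a diploid biallelic GENEPOP file.

    Returns the dosage matrix (alternate allele = lexicographically larger
    allele code at each locus) and a skeleton :class:`SampleTable` with one
    population per POP block and empty population attributes.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenepopParseError("empty file", line=1)

    # locus names: one per line, or comma-separated on one line
    locus_ids: list[str] = []
    i = 1
    first_pop_line = None
    while i < len(lines):
        stripped = lines[i].strip()
        if _POP_RE.match(stripped):
            first_pop_line = i
            break
        if stripped:
            if "," in stripped:
                locus_ids.extend(s.strip() for s in stripped.split(",") if s.strip())
            else:
                locus_ids.append(stripped)
        i += 1
    if first_pop_line is None:
        raise GenepopParseError("no POP block found (malformed header)", line=len(lines))
    if not locus_ids:
        # header-only file with zero loci is legal only if no genotype rows follow
        pass
    if len(set(locus_ids)) != len(locus_ids):
        dup = next(l for l in locus_ids if locus_ids.count(l) > 1)
        raise GenepopParseError(f"duplicated locus name {dup!r}", line=first_pop_line)

    n_loci = len(locus_ids)
    individual_ids: list[str] = []
    pop_of_individual: dict[str, str] = {}
    raw_genotypes: list[list[str]] = []  # per individual, allele-pair strings
    block = -1

    for lineno in range(first_pop_line, len(lines)):
        stripped = lines[lineno].strip()
        if not stripped:
            continue
        if _POP_RE.match(stripped):
            block += 1
            block_first_label: str | None = None
            continue
        if block < 0:
            raise GenepopParseError("genotype row before first POP line", line=lineno + 1)
        if "," not in stripped:
            raise GenepopParseError(
                f"genotype row without ',' separator: {stripped[:40]!r}", line=lineno + 1
            )
        label, _, rest = stripped.partition(",")
        label = label.strip()
        fields = rest.split()
        if label in pop_of_individual:
            raise GenepopParseError(f"duplicated individual label {label!r}", line=lineno + 1)
        if len(fields) != n_loci:
            raise GenepopParseError(
                f"individual {label!r} has {len(fields)} genotypes, expected {n_loci}",
                line=lineno + 1,
            )
        for f in fields:
            if len(f) not in (4, 6) or not f.isdigit():
                raise GenepopParseError(
                    f"individual {label!r}: malformed genotype field {f!r}", line=lineno + 1
                )
        if block_first_label is None:
            block_first_label = label
        individual_ids.append(label)
        pop_of_individual[label] = _pop_name_from_label(block_first_label, block)
        raw_genotypes.append(fields)

    # decode allele pairs; determine per-locus allele codes
    n_ind = len(individual_ids)
    dosage = np.full((n_ind, n_loci), MISSING, dtype=np.int8)
    for j in range(n_loci):
        pairs = []
        for i_ind in range(n_ind):
            f = raw_genotypes[i_ind][j]
            half = len(f) // 2
            pairs.append((f[:half], f[half:]))
        codes = sorted(
            {c for pair in pairs for c in pair if c not in _MISSING_CODES}
        )
        if len(codes) > 2:
            raise GenepopParseError(
                f"locus {locus_ids[j]!r} has {len(codes)} alleles ({', '.join(codes)}); "
                "only biallelic loci are supported"
            )
        # alternate = lexicographically larger code; a monomorphic locus
        # shows one code only, taken as alternate unless it is the minimal
        # code 01/001 (the canonical reference), keeping write->read lossless
        if len(codes) == 2:
            alt = codes[1]
        elif len(codes) == 1:
            alt = None if int(codes[0]) == 1 else codes[0]
        else:
            alt = None
        for i_ind, (a1, a2) in enumerate(pairs):
            if a1 in _MISSING_CODES or a2 in _MISSING_CODES:
                continue  # partially or fully missing -> MISSING
            dosage[i_ind, j] = int(a1 == alt) + int(a2 == alt)

    gm = GenotypeMatrix(individual_ids=individual_ids, locus_ids=locus_ids, dosage=dosage)
    samples = SampleTable(pop_of_individual=pop_of_individual)
    return gm, samples


def write_genepop(
    gm: GenotypeMatrix,
    samples: SampleTable,
    path: str | Path,
    title: str = "nerka genotype export",
) -> None:
    """Write a GENEPOP file: populations in first-seen order over the
    matrix's individuals, individuals and loci in matrix order, 2-digit
    allele codes (ref = "01", alt = "02"), MISSING as "0000"."""
    samples.validate_against(gm)
    by_pop: dict[str, list[int]] = {}
    for i, iid in enumerate(gm.individual_ids):
        by_pop.setdefault(samples.pop_of_individual[iid], []).append(i)

    code = {0: "0101", 1: "0102", 2: "0202", MISSING: "0000"}
    out: list[str] = [title]
    out.extend(gm.locus_ids)
    for pop, rows in by_pop.items():
        out.append("POP")
        for i in rows:
            geno = " ".join(code[int(d)] for d in gm.dosage[i])
            out.append(f"{gm.individual_ids[i]} ,  {geno}".rstrip())
    Path(path).write_text("\n".join(out) + "\n")


def read_linkage_map(path: str | Path) -> LinkageMap:
    """Read a tab-delimited linkage map: locus_id, linkage_group, cM.

    A header row is detected (and skipped) when its third column is not
    numeric.  Loci absent from the file are simply unmapped.
    """
    position: dict[str, tuple[str, float]] = {}
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"line {lineno}: expected 3 tab-delimited columns")
        lid, lg, cm_str = fields[0].strip(), fields[1].strip(), fields[2].strip()
        try:
            cm = float(cm_str)
        except ValueError:
            if lineno == 1:  # header row
                continue
            raise ValueError(f"line {lineno}: non-numeric cM value {cm_str!r}")
        if cm < 0 or not np.isfinite(cm):
            raise ValueError(f"line {lineno}: locus {lid!r} has invalid cM {cm_str}")
        if lid in position:
            raise ValueError(f"line {lineno}: duplicate locus {lid!r} in linkage map")
        position[lid] = (lg, cm)
    return LinkageMap(position=position)


def write_linkage_map(lmap: LinkageMap, path: str | Path) -> None:
    lines = ["locus_id\tlinkage_group\tcM"]
    for lid, (lg, cm) in lmap.position.items():
        lines.append(f"{lid}\t{lg}\t{cm:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_sample_attributes(path: str | Path) -> SampleTable:
    """Read individual/population attributes:
    individual, population, lake, catchment, migratory_ecotype, reproductive_ecotype."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {
        "individual",
        "population",
        "lake",
        "catchment",
        "migratory_ecotype",
        "reproductive_ecotype",
    }
    if not required.issubset(df.columns):
        raise ValueError(f"sample attribute file missing columns: {required - set(df.columns)}")
    pop_of_individual = dict(zip(df["individual"], df["population"]))
    pop_attrs: dict[str, PopAttrs] = {}
    for _, row in df.drop_duplicates("population").iterrows():
        pop_attrs[row["population"]] = PopAttrs(
            lake=row["lake"],
            catchment=row["catchment"],
            migratory_ecotype=row["migratory_ecotype"],
            reproductive_ecotype=row["reproductive_ecotype"],
        )
    return SampleTable(pop_of_individual=pop_of_individual, pop_attrs=pop_attrs)


def write_sample_attributes(samples: SampleTable, path: str | Path) -> None:
    rows = []
    for iid, pop in samples.pop_of_individual.items():
        a = samples.pop_attrs.get(pop, PopAttrs())
        rows.append(
            {
                "individual": iid,
                "population": pop,
                "lake": a.lake or "",
                "catchment": a.catchment or "",
                "migratory_ecotype": a.migratory_ecotype or "",
                "reproductive_ecotype": a.reproductive_ecotype or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_comparisons(path: str | Path) -> list[ComparisonSpec]:
    """Read a comparison manifest: label, comma-separated side A pops,
    comma-separated side B pops (tab-delimited, optional header)."""
    out: list[ComparisonSpec] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"line {lineno}: expected 3 tab-delimited columns")
        label, a, b = (f.strip() for f in fields[:3])
        if lineno == 1 and label.lower() in ("label", "comparison"):
            continue
        out.append(
            ComparisonSpec(
                label=label,
                side_a=frozenset(s.strip() for s in a.split(",") if s.strip()),
                side_b=frozenset(s.strip() for s in b.split(",") if s.strip()),
            )
        )
    return out


def write_comparisons(comparisons: Iterable[ComparisonSpec], path: str | Path) -> None:
    lines = ["label\tside_a\tside_b"]
    for c in comparisons:
        lines.append(f"{c.label}\t{','.join(sorted(c.side_a))}\t{','.join(sorted(c.side_b))}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_records(records: pd.DataFrame | list[dict], path: str | Path) -> None:
    """Serialize a result table as TSV with header, stable column order
    and full-precision numerics (%.17g round-trips doubles exactly)."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


__all__ = [
    "GenepopParseError",
    "read_genepop",
    "write_genepop",
    "read_linkage_map",
    "write_linkage_map",
    "read_sample_attributes",
    "write_sample_attributes",
    "read_comparisons",
    "write_comparisons",
    "write_records",
    "read_records",
]
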