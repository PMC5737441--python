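"""Synthetic ecotype-pair genotype panels with known truth.

Two generators live here.

``simulate_panel`` draws allele frequencies down a three-level
Balding–Nichols hierarchy (catchment -> lake -> population, each level a
beta distribution with mean equal to the parent frequency and variance
``F p (1 - p)``), superimposes ecotype-axis frequency displacements on a
chosen subset of "divergent" loci (optionally clustered into linkage-map
islands), and emits Hardy–Weinberg genotypes with missingness, RAD-tag
provenance and a partial linkage map.  The default study design mirrors a
paired-ecotype sampling of kokanee and anadromous sockeye salmon:
14 sampling units in seven lakes and two rivers across three catchments.

``simulate_wright_fisher`` is a discrete-generation random-mating
forward simulator used as the oracle for the LD-based effective
population size estimator: a finite monoecious population of ``Ne``
diploids in which each offspring draws two parents shared across loci
(the pedigree co-ancestry is what generates the drift LD the estimator
measures) and inherits one Mendelian allele per parent per locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix, LinkageMap, PopAttrs, SampleTable

CLIP_LO, CLIP_HI = 0.01, 0.99


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    lake: str
    catchment: str
    migratory_ecotype: str  # anadromous | kokanee
    reproductive_ecotype: str  # shore | stream | black
    f_pop: float = 0.02
    n_individuals: int = 36


@dataclass(frozen=True)
class DivergentGroup:
    """A block of loci displaced by +/- delta along one ecotype axis."""

    ecotype_axis: str  # shore_vs_stream | kokanee_vs_anadromous
    delta: float
    n_loci: int = 1
    shared_across: frozenset[str] | None = None  # lakes; None = all lakes

    def __post_init__(self):
        if not (0 < self.delta <= 0.5):
            raise ValueError("delta must be in (0, 0.5]")
        if self.ecotype_axis not in ("shore_vs_stream", "kokanee_vs_anadromous"):
            raise ValueError(f"unknown ecotype axis {self.ecotype_axis!r}")


@dataclass(frozen=True)
class IslandSpec:
    """A cluster of linked divergent loci on one linkage-group interval."""

    linkage_group: str
    start_cM: float
    span_cM: float
    n_member_loci: int
    delta: float
    ecotype_axis: str = "shore_vs_stream"
    shared_across: frozenset[str] | None = None


@dataclass
class SimParams:
    populations: list[PopulationSpec]
    f_catch: dict[str, float] = field(default_factory=dict)  # catchment -> F
    f_lake: dict[str, float] = field(default_factory=dict)  # lake -> F
    L_neutral: int = 2000
    divergent: list[DivergentGroup] = field(default_factory=list)
    islands: list[IslandSpec] = field(default_factory=list)
    linkage_groups: dict[str, float] = field(
        default_factory=lambda: {f"LG{i}": 100.0 for i in range(1, 5)}
    )
    map_fraction: float = 0.44
    missing_rate: float = 0.03
    multi_snp_tag_rates: tuple[float, float, float] = (0.894, 0.112, 0.0062)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, f in {**self.f_catch, **self.f_lake}.items():
            if not (0 < f < 1):
                raise ValueError(f"F parameter for {name!r} must lie in (0,1)")
        for p in self.populations:
            if not (0 < p.f_pop < 1):
                raise ValueError(f"F parameter for population {p.name!r} must lie in (0,1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0,1)")
        for isl in self.islands:
            if isl.linkage_group not in self.linkage_groups:
                raise ValueError(f"island on unknown linkage group {isl.linkage_group!r}")
            if isl.start_cM + isl.span_cM > self.linkage_groups[isl.linkage_group]:
                raise ValueError(
                    f"island span exceeds linkage group {isl.linkage_group!r} length"
                )


def _bn_draw(rng: np.random.Generator, center: np.ndarray, f: float) -> np.ndarray:
    """Balding–Nichols draw: Beta(p(1-F)/F, (1-p)(1-F)/F); mean p, var F p(1-p)."""
    center = np.clip(center, CLIP_LO, CLIP_HI)
    scale = (1.0 - f) / f
    return rng.beta(center * scale, (1.0 - center) * scale)


def study_design_params(seed: int = 0, loci_per_axis: int = 40, delta: float = 0.3,
                        **overrides) -> SimParams:
    """The default simulated study design: paired ecotypes across three
    catchments, sample sizes matching the real sampling units."""
    P = PopulationSpec
    pops = [
        P("skaha_ko_stream", "skaha", "columbia", "kokanee", "stream", 0.02, 36),
        P("okanriver_an_stream", "okan_river", "columbia", "anadromous", "stream", 0.02, 36),
        P("okanagan_ko_shore", "okanagan", "columbia", "kokanee", "shore", 0.02, 48),
        P("okanagan_ko_stream", "okanagan", "columbia", "kokanee", "stream", 0.02, 48),
        P("wood_ko_shore", "wood", "columbia", "kokanee", "shore", 0.02, 36),
        P("wood_ko_stream", "wood", "columbia", "kokanee", "stream", 0.02, 36),
        P("kootenaywest_ko_shore", "kootenay_west", "columbia", "kokanee", "shore", 0.02, 48),
        P("kootenaywest_ko_stream", "kootenay_west", "columbia", "kokanee", "stream", 0.02, 48),
        P("kootenaynorth_ko_stream", "kootenay_north", "columbia", "kokanee", "stream", 0.02, 24),
        P("tchesinkut_ko_shore", "tchesinkut", "skeena", "kokanee", "shore", 0.02, 36),
        P("tchesinkut_ko_stream", "tchesinkut", "skeena", "kokanee", "stream", 0.02, 36),
        P("anderson_ko_black", "anderson", "fraser", "kokanee", "black", 0.02, 24),
        P("seton_ko_black", "seton", "fraser", "kokanee", "black", 0.02, 23),
        P("portage_an_stream", "portage", "fraser", "anadromous", "stream", 0.02, 25),
    ]
    lakes = sorted({p.lake for p in pops})
    params = dict(
        populations=pops,
        f_catch={"columbia": 0.05, "fraser": 0.05, "skeena": 0.05},
        f_lake={lk: 0.03 for lk in lakes},
        L_neutral=2000,
        divergent=[
            DivergentGroup("shore_vs_stream", delta, n_loci=loci_per_axis),
            DivergentGroup("kokanee_vs_anadromous", delta, n_loci=loci_per_axis),
        ],
        islands=[IslandSpec("LG2", 40.0, 4.0, 8, delta)],
        seed=seed,
    )
    params.update(overrides)
    return SimParams(**params)


def _axis_side(pop: PopulationSpec, axis: str) -> int:
    """+1 / -1 / 0 displacement sign of a population on an ecotype axis."""
    if axis == "shore_vs_stream":
        if pop.reproductive_ecotype == "shore":
            return 1
        if pop.reproductive_ecotype == "stream":
            return -1
        return 0  # black kokanee sit outside the shore/stream contrast
    if pop.migratory_ecotype == "kokanee":
        return 1
    if pop.migratory_ecotype == "anadromous":
        return -1
    return 0


def simulate_panel(
    params: SimParams,
) -> tuple[GenotypeMatrix, SampleTable, LinkageMap, pd.DataFrame]:
    """Generate a genotype panel, sample table, partial linkage map and
    truth table (locus_id, is_divergent, ecotype_axis, island_id,
    ancestral_freq, delta) from a single seed."""
    rng = np.random.default_rng(params.seed)
    pops = params.populations

    # locus bookkeeping: neutral loci, free divergent loci, island members
    locus_axis: list[str | None] = [None] * params.L_neutral
    locus_delta: list[float] = [0.0] * params.L_neutral
    locus_lakes: list[frozenset[str] | None] = [None] * params.L_neutral
    locus_island: list[str | None] = [None] * params.L_neutral
    for grp in params.divergent:
        for _ in range(grp.n_loci):
            locus_axis.append(grp.ecotype_axis)
            locus_delta.append(grp.delta)
            locus_lakes.append(grp.shared_across)
            locus_island.append(None)
    island_positions: list[tuple[str, float] | None] = [None] * len(locus_axis)
    for k, isl in enumerate(params.islands):
        island_id = f"island_{k + 1}"
        offsets = np.sort(rng.uniform(0.0, isl.span_cM, size=isl.n_member_loci))
        for off in offsets:
            locus_axis.append(isl.ecotype_axis)
            locus_delta.append(isl.delta)
            locus_lakes.append(isl.shared_across)
            locus_island.append(island_id)
            island_positions.append((isl.linkage_group, isl.start_cM + float(off)))

    L = len(locus_axis)
    ancestral = rng.uniform(0.1, 0.9, size=L)

    # hierarchy: catchment -> lake -> population
    catchments = sorted({p.catchment for p in pops})
    lakes = sorted({p.lake for p in pops})
    lake_catchment = {p.lake: p.catchment for p in pops}
    p_catch = {
        c: _bn_draw(rng, ancestral, params.f_catch.get(c, 0.05)) for c in catchments
    }
    p_lake = {
        lk: _bn_draw(rng, p_catch[lake_catchment[lk]], params.f_lake.get(lk, 0.03))
        for lk in lakes
    }

    axis_arr = np.array([a if a is not None else "" for a in locus_axis])
    delta_arr = np.array(locus_delta)

    individual_ids: list[str] = []
    pop_of_individual: dict[str, str] = {}
    pop_attrs: dict[str, PopAttrs] = {}
    dosage_blocks: list[np.ndarray] = []
    for pop in pops:
        center = p_lake[pop.lake].copy()
        for axis in ("shore_vs_stream", "kokanee_vs_anadromous"):
            side = _axis_side(pop, axis)
            if side == 0:
                continue
            sel = axis_arr == axis
            # restrict the displacement to loci whose sharing set covers this lake
            covered = np.array(
                [
                    (lks is None or pop.lake in lks)
                    for lks in locus_lakes
                ]
            )
            sel &= covered
            center[sel] = center[sel] + side * delta_arr[sel]
        center = np.clip(center, CLIP_LO, CLIP_HI)
        p_pop = np.clip(_bn_draw(rng, center, pop.f_pop), CLIP_LO, CLIP_HI)
        geno = rng.binomial(2, p_pop[None, :], size=(pop.n_individuals, L)).astype(np.int8)
        if params.missing_rate > 0:
            miss = rng.random((pop.n_individuals, L)) < params.missing_rate
            geno[miss] = MISSING
        dosage_blocks.append(geno)
        for i in range(pop.n_individuals):
            iid = f"{pop.name}_{i + 1:03d}"
            individual_ids.append(iid)
            pop_of_individual[iid] = pop.name
        pop_attrs[pop.name] = PopAttrs(
            lake=pop.lake,
            catchment=pop.catchment,
            migratory_ecotype=pop.migratory_ecotype,
            reproductive_ecotype=pop.reproductive_ecotype,
        )

    # RAD-tag grouping: draw tag sizes (1/2/3 SNPs) until all loci assigned
    rates = np.asarray(params.multi_snp_tag_rates, dtype=float)
    rates = rates / rates.sum()
    locus_ids: list[str] = [""] * L
    tag_of_index: list[str] = [""] * L
    order = rng.permutation(L)
    pos = 0
    tag_no = 10000
    tag_members: dict[str, list[int]] = {}
    while pos < L:
        size = int(rng.choice((1, 2, 3), p=rates))
        size = min(size, L - pos)
        tag = str(tag_no)
        tag_no += 1
        offsets = np.sort(rng.choice(np.arange(1, 95), size=size, replace=False))
        members = []
        for s in range(size):
            j = int(order[pos + s])
            locus_ids[j] = f"{tag}_{int(offsets[s])}"
            tag_of_index[j] = tag
            members.append(j)
        tag_members[tag] = members
        pos += size

    # linkage map: island members at their planted positions; each remaining
    # tag mapped with probability map_fraction, uniform on a random LG
    lg_names = list(params.linkage_groups)
    lg_lengths = np.array([params.linkage_groups[g] for g in lg_names])
    position: dict[str, tuple[str, float]] = {}
    for j in range(L):
        if island_positions[j] is not None:
            lg, cm = island_positions[j]
            position[locus_ids[j]] = (lg, cm)
    for tag, members in tag_members.items():
        if any(island_positions[j] is not None for j in members):
            continue
        if rng.random() < params.map_fraction:
            gi = int(rng.integers(len(lg_names)))
            cm = float(rng.uniform(0.0, lg_lengths[gi]))
            for j in members:
                position[locus_ids[j]] = (lg_names[gi], cm)

    gm = GenotypeMatrix(
        individual_ids=individual_ids,
        locus_ids=locus_ids,
        dosage=np.vstack(dosage_blocks),
    )
    samples = SampleTable(pop_of_individual=pop_of_individual, pop_attrs=pop_attrs)
    lmap = LinkageMap(position=position)
    truth = pd.DataFrame(
        {
            "locus_id": locus_ids,
            "is_divergent": [a is not None for a in locus_axis],
            "ecotype_axis": [a or "" for a in locus_axis],
            "island_id": [s or "" for s in locus_island],
            "ancestral_freq": ancestral,
            "delta": delta_arr,
        }
    )
    return gm, samples, lmap, truth


def simulate_wright_fisher(
    Ne: int,
    sample_size: int,
    L: int,
    generations: int,
    seed: int,
    initial_freq_range: tuple[float, float] = (0.2, 0.8),
) -> GenotypeMatrix:
    """Forward Wright–Fisher simulation of unlinked loci in a finite
    random-mating (monoecious) population of ``Ne`` diploids.

    Parent pairs are drawn once per offspring and shared across loci, so
    unlinked loci acquire the O(1/Ne) identity-by-descent correlations
    that the LD method converts into an Ne estimate; transmission within
    a parent is independent Mendelian sampling per locus.  After
    ``generations`` generations, ``sample_size`` diploids are drawn
    without replacement.  Monomorphic loci are retained (downstream
    filters remove them).
    """
    if Ne < 10:
        raise ValueError("Ne must be >= 10")
    if sample_size > Ne:
        raise ValueError("sample_size cannot exceed Ne")
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(*initial_freq_range, size=L)
    geno = rng.binomial(2, p0[None, :], size=(Ne, L)).astype(np.int8)
    for _ in range(generations):
        mothers = rng.integers(Ne, size=Ne)
        fathers = rng.integers(Ne, size=Ne)
        # one Mendelian allele from each parent per locus
        a1 = rng.binomial(1, geno[mothers, :] / 2.0)
        a2 = rng.binomial(1, geno[fathers, :] / 2.0)
        geno = (a1 + a2).astype(np.int8)
    take = rng.choice(Ne, size=sample_size, replace=False)
    sample = geno[take, :]
    return GenotypeMatrix(
        individual_ids=[f"wf_{i + 1:04d}" for i in range(sample_size)],
        locus_ids=[f"{100000 + j}_1" for j in range(L)],
        dosage=sample,
    )


__all__ = [
    "SimParams",
    "PopulationSpec",
    "DivergentGroup",
    "IslandSpec",
    "study_design_params",
    "simulate_panel",
    "simulate_wright_fisher",
]
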