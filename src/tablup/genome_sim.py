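"""Forward-in-time simulation of genome, population history and trait.

The simulated system is the classical mutation--drift design used to
validate genomic-selection methods: a small random-mating population
(Ne = 100, 50 males x 50 females, two offspring per monogamous pair) is
run for many non-overlapping generations so that markers and QTL reach
mutation--drift equilibrium under an infinite-alleles mutation model.
Expected equilibrium heterozygosity is ``theta / (theta + 1)`` with
``theta = 4*Ne*u``. Because every pair leaves exactly two offspring,
the variance of family size is zero and the effective size of the
census-100 population is Ne = (4N - 2) / 2 = 199, so the default
per-gamete-copy mutation rate of 1.25e-3 gives theta ~ 1 and an
equilibrium heterozygosity of 0.5.

After the historical phase every locus is recoded to a biallelic SNP
(the allele with frequency closest to 0.5 becomes allele 1, everything
else collapses to allele 2) and the population is expanded into a
six-generation half-sib validation structure:

* generation 1 -- 50 x 50 monogamous matings, 20 progeny per dam
  (1,000 individuals, the training set; only these get phenotypes);
* generations 2-6 -- 50 sires sampled from the 500 males of the
  previous generation, each mated to 10 of the 500 dams, 2 progeny per
  dam (1,000 individuals per generation, the candidate sets).

The genome is a set of chromosomes with markers placed uniformly at
random and one potential QTL slot at the midpoint of every inter-marker
segment (5 chromosomes x 1 Morgan x 1,000 markers -> 5,000 markers and
4,995 slots by default). Recombination between adjacent loci follows
Haldane's mapping function with no interference; chromosomes segregate
independently.

The quantitative trait is additive: ``n_qtl`` slots are drawn among the
slots polymorphic in generation 1, allele-substitution effects are
sampled from a gamma distribution with a random sign and rescaled so
that the total additive variance ``sum_i 2 p_i (1 - p_i) a_i**2``
(allele frequencies taken in generation 1, linkage disequilibrium
ignored) equals ``sigma_A2``. Phenotypes are TBV plus normal noise with
variance ``sigma_A2 * (1 - h2) / h2`` and exist in generation 1 only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GeneticMap",
    "Population",
    "TraitArchitecture",
    "SimulationConfig",
    "SimulatedData",
    "build_genetic_map",
    "haldane_recomb_prob",
    "meiosis",
    "mutate",
    "simulate_history",
    "recode_biallelic",
    "breed_validation_generations",
    "sample_trait",
    "compute_tbv",
    "simulate_phenotypes",
    "allele2_counts",
    "simulate_dataset",
]


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------


@dataclass
class GeneticMap:
    """Marker and potential-QTL positions, in Morgans, per chromosome.

    Loci (markers and QTL slots together) are flattened into a single
    genome-wide, position-sorted axis; haplotypes are arrays over that
    axis. ``switch_prob[j]`` is the probability that a gamete switches
    its source haplotype between locus ``j-1`` and ``j`` (0.5 at the
    first locus of every chromosome, which both randomises the starting
    haplotype and makes chromosomes segregate independently).
    """

    n_chromosomes: int
    chromosome_length: float
    marker_positions: list[np.ndarray]
    qtl_slot_positions: list[np.ndarray]

    # derived, filled in __post_init__
    positions: np.ndarray = field(init=False, repr=False)
    chromosome: np.ndarray = field(init=False, repr=False)
    is_marker: np.ndarray = field(init=False, repr=False)
    switch_prob: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_chromosomes != len(self.marker_positions):
            raise ValueError("marker_positions must have one array per chromosome")
        if self.chromosome_length <= 0:
            raise ValueError("chromosome length must be positive")
        pos_parts, chrom_parts, marker_parts, switch_parts = [], [], [], []
        for c in range(self.n_chromosomes):
            m = np.asarray(self.marker_positions[c], dtype=float)
            q = np.asarray(self.qtl_slot_positions[c], dtype=float)
            if len(q) != len(m) - 1:
                raise ValueError(
                    "each chromosome must have one QTL slot per inter-marker segment"
                )
            loci = np.concatenate([m, q])
            flag = np.zeros(len(loci), dtype=bool)
            flag[: len(m)] = True
            order = np.argsort(loci, kind="stable")
            loci, flag = loci[order], flag[order]
            if np.any(loci < 0) or np.any(loci > self.chromosome_length):
                raise ValueError("positions must lie in [0, chromosome_length]")
            if np.any(np.diff(loci) <= 0):
                raise ValueError("positions must be strictly increasing")
            d = np.diff(loci)
            sp = np.empty(len(loci))
            sp[0] = 0.5
            sp[1:] = haldane_recomb_prob(d)
            pos_parts.append(loci)
            chrom_parts.append(np.full(len(loci), c, dtype=np.int32))
            marker_parts.append(flag)
            switch_parts.append(sp)
        self.positions = np.concatenate(pos_parts)
        self.chromosome = np.concatenate(chrom_parts)
        self.is_marker = np.concatenate(marker_parts)
        self.switch_prob = np.concatenate(switch_parts)

    @property
    def n_loci(self) -> int:
        return self.positions.size

    @property
    def n_markers(self) -> int:
        return int(self.is_marker.sum())

    @property
    def n_qtl_slots(self) -> int:
        return int((~self.is_marker).sum())

    @property
    def marker_loci(self) -> np.ndarray:
        """Indices of marker loci on the flattened locus axis."""
        return np.flatnonzero(self.is_marker)

    @property
    def qtl_loci(self) -> np.ndarray:
        """Indices of potential-QTL loci on the flattened locus axis."""
        return np.flatnonzero(~self.is_marker)


def build_genetic_map(
    n_chr: int,
    length: float,
    markers_per_chr: int,
    rng: np.random.Generator,
) -> GeneticMap:
    """Place ``markers_per_chr`` markers uniformly at random on each
    chromosome and one potential QTL slot at the midpoint of every
    inter-marker segment."""
    if length <= 0:
        raise ValueError("chromosome length must be positive")
    if markers_per_chr < 2:
        raise ValueError("need at least 2 markers per chromosome")
    if n_chr < 1:
        raise ValueError("need at least one chromosome")
    markers, slots = [], []
    for _ in range(n_chr):
        for _attempt in range(100):
            m = np.sort(rng.uniform(0.0, length, size=markers_per_chr))
            if np.all(np.diff(m) > 0):
                break
        else:  # pragma: no cover - probability ~0
            raise RuntimeError("could not draw distinct marker positions")
        markers.append(m)
        slots.append(0.5 * (m[:-1] + m[1:]))
    return GeneticMap(n_chr, float(length), markers, slots)


def haldane_recomb_prob(d):
    """Haldane map function: recombination probability 0.5*(1 - exp(-2d))
    for a distance ``d`` in Morgans (no interference)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    out = 0.5 * (1.0 - np.exp(-2.0 * d))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# population container
# ---------------------------------------------------------------------------


@dataclass
class Population:
    """A set of individuals with phased haplotype pairs and a pedigree.

    ``haplotypes`` has shape (n, 2, n_loci); slot 0 is the paternal
    gamete. ``sire``/``dam`` hold ids (-1 for unknown); ids double as
    row indices when populations are built by the simulator.
    Phenotypes are NaN for unphenotyped individuals.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray  # 0 male, 1 female
    generation: np.ndarray
    haplotypes: np.ndarray
    phenotypes: np.ndarray | None = None
    tbv: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[:2] != (n, 2):
            raise ValueError("haplotypes must have shape (n_individuals, 2, n_loci)")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[2]

    def rows_of(self, generation: int | Sequence[int]) -> np.ndarray:
        gens = np.atleast_1d(generation)
        return np.flatnonzero(np.isin(self.generation, gens))


def allele2_counts(pop: Population, loci: np.ndarray | None = None) -> np.ndarray:
    """Per-individual count of allele 2 (0, 1 or 2) at the given loci.

    Only meaningful after biallelic recoding. ``counts - 1`` is the
    -1/0/1 genotype coding used throughout (11 -> -1, 12 -> 0, 22 -> 1).
    """
    hap = pop.haplotypes if loci is None else pop.haplotypes[:, :, loci]
    return (hap == 2).sum(axis=1, dtype=np.int8)


# ---------------------------------------------------------------------------
# meiosis and mutation
# ---------------------------------------------------------------------------


def _meiosis_batch(
    parents: np.ndarray, switch_prob: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Gametes for a batch of parents, shape (m, 2, L) -> (m, L).

    The gamete is built by a per-interval Bernoulli source-switching
    walk: a switch occurs between adjacent loci with the Haldane
    probability, and the first locus of each chromosome draws its
    source haplotype uniformly (switch probability 0.5).
    """
    m, _, L = parents.shape
    switch = rng.random((m, L)) < switch_prob
    source = np.cumsum(switch, axis=1, dtype=np.int32) & 1
    return np.where(source == 0, parents[:, 0, :], parents[:, 1, :])


def meiosis(
    parent: np.ndarray, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """One gamete from a single parent haplotype pair (2, L)."""
    parent = np.asarray(parent)
    if parent.ndim != 2 or parent.shape[0] != 2 or parent.shape[1] != gmap.n_loci:
        raise ValueError("parent must have shape (2, n_loci) matching the map")
    return _meiosis_batch(parent[None], gmap.switch_prob, rng)[0]


def mutate(
    gametes: np.ndarray,
    rate: float,
    allele_counter: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Infinite-alleles mutation on one gamete (L,) or a batch (m, L).

    Each locus mutates independently with probability ``rate``; a
    mutated copy receives a never-before-used integer label at that
    locus, taken from (and advancing) ``allele_counter`` in place.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("mutation rate must be in [0, 1]")
    single = gametes.ndim == 1
    out = np.atleast_2d(gametes).copy()
    if rate > 0.0:
        hit = rng.random(out.shape) < rate
        rows, cols = np.nonzero(hit)
        if cols.size:
            order = np.argsort(cols, kind="stable")
            rows, cols = rows[order], cols[order]
            uniq, start, counts = np.unique(
                cols, return_index=True, return_counts=True
            )
            offsets = np.arange(cols.size) - np.repeat(start, counts)
            out[rows, cols] = allele_counter[cols] + offsets
            allele_counter[uniq] += counts.astype(allele_counter.dtype)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# historical phase
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Parameters of the full simulation design.

    The defaults are the standard scenario: 5 chromosomes x 1 Morgan x
    1,000 markers, 1,000 historical generations of size 100, 50 QTL,
    h2 = 0.5 with sigma_A2 = 1 (so sigma_e2 = 1). ``mutation_rate`` is
    per gamete copy, per locus, per generation; the default 1.25e-3
    yields equilibrium heterozygosity 0.5, since the equal-family-size
    design makes the effective population size ~2x the census of 100.
    """

    n_chromosomes: int = 5
    chromosome_length: float = 1.0
    markers_per_chromosome: int = 1000
    n_historical_generations: int = 1000
    historical_size: int = 100
    n_validation_generations: int = 6
    mutation_rate: float = 1.25e-3
    n_qtl: int = 50
    heritability: float = 0.5
    sigma_A2: float = 1.0
    gamma_shape: float = 0.4
    gamma_scale: float = 1.66

    def __post_init__(self) -> None:
        if not 0.0 < self.heritability <= 1.0:
            raise ValueError("heritability must be in (0, 1]")
        for name in (
            "n_chromosomes",
            "markers_per_chromosome",
            "historical_size",
            "n_validation_generations",
            "n_qtl",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_historical_generations < 0:
            raise ValueError("n_historical_generations must be >= 0")
        if self.historical_size % 2:
            raise ValueError("historical_size must be even (equal sex ratio)")

    @property
    def sigma_e2(self) -> float:
        return self.sigma_A2 * (1.0 - self.heritability) / self.heritability


def simulate_history(
    config: SimulationConfig, gmap: GeneticMap, rng: np.random.Generator
) -> Population:
    """Run the mutation--drift historical phase and return generation 0.

    Every historical generation keeps the census at ``historical_size``
    (default 100): 50 males are randomly paired with 50 females and
    each pair leaves exactly two offspring, one of each sex. Mutation
    is applied to every gamete in every historical generation. The base
    population carries allele 1 at every locus.
    """
    n = config.historical_size
    half = n // 2
    L = gmap.n_loci
    hap = np.ones((n, 2, L), dtype=np.int32)
    sex = np.tile(np.array([0, 1], dtype=np.int8), half)
    counter = np.full(L, 2, dtype=np.int32)  # next fresh allele label per locus
    for _ in range(config.n_historical_generations):
        males = np.flatnonzero(sex == 0)
        females = np.flatnonzero(sex == 1)
        sires = rng.permutation(males)
        dams = rng.permutation(females)
        # each monogamous pair produces one male and one female offspring
        sire_idx = np.repeat(sires, 2)
        dam_idx = np.repeat(dams, 2)
        paternal = _meiosis_batch(hap[sire_idx], gmap.switch_prob, rng)
        maternal = _meiosis_batch(hap[dam_idx], gmap.switch_prob, rng)
        paternal = mutate(paternal, config.mutation_rate, counter, rng)
        maternal = mutate(maternal, config.mutation_rate, counter, rng)
        hap = np.stack([paternal, maternal], axis=1)
        sex = np.tile(np.array([0, 1], dtype=np.int8), half)
    ids = np.arange(n, dtype=np.int64)
    unknown = np.full(n, -1, dtype=np.int64)
    return Population(
        ids=ids,
        sire=unknown,
        dam=unknown.copy(),
        sex=sex,
        generation=np.zeros(n, dtype=np.int16),
        haplotypes=hap,
    )


def recode_biallelic(pop: Population) -> Population:
    """Collapse the infinite-alleles labels of generation 0 to a SNP panel.

    At each locus the allele whose frequency is closest to 0.5 becomes
    allele 1 and every other allele becomes allele 2 (ties broken
    toward the smaller original label; a monomorphic locus becomes
    all-1 and stays in the panel).
    """
    hap = pop.haplotypes
    n, _, L = hap.shape
    out = np.empty((n, 2, L), dtype=np.int8)
    flat = hap.reshape(n * 2, L)
    for j in range(L):
        labels, counts = np.unique(flat[:, j], return_counts=True)
        freq = counts / (2.0 * n)
        keep = labels[np.argmin(np.abs(freq - 0.5))]  # ties -> smallest label
        out[:, :, j] = np.where(hap[:, :, j] == keep, 1, 2)
    return replace(pop, haplotypes=out)


# ---------------------------------------------------------------------------
# validation structure (generations 1-6)
# ---------------------------------------------------------------------------


def breed_validation_generations(
    gen0: Population,
    rng: np.random.Generator,
    n_generations: int = 6,
    gmap: GeneticMap | None = None,
    switch_prob: np.ndarray | None = None,
) -> Population:
    """Expand generation 0 into the half-sib validation structure.

    Generation 1: the 50 males and 50 females of generation 0 are
    paired at random and every dam produces 20 progeny (10 of each
    sex), giving 1,000 individuals. Generations 2..n: 50 sires are
    sampled from the 500 males of the previous generation, each is
    mated to 10 of the 500 dams and every dam leaves two progeny (one
    of each sex). No mutation occurs in these generations.

    Returns a single :class:`Population` holding generations 0..n with
    the pedigree recorded (generation-0 rows come first).
    """
    if switch_prob is None:
        if gmap is None:
            raise ValueError("either gmap or switch_prob must be given")
        switch_prob = gmap.switch_prob
    males0 = np.flatnonzero(gen0.sex == 0)
    females0 = np.flatnonzero(gen0.sex == 1)
    if len(males0) != len(females0):
        raise ValueError("generation 0 must have an equal number of males and females")

    hap_blocks = [gen0.haplotypes]
    ids_blocks = [gen0.ids]
    sire_blocks = [gen0.sire]
    dam_blocks = [gen0.dam]
    sex_blocks = [gen0.sex]
    gen_blocks = [gen0.generation]
    next_id = int(gen0.ids.max()) + 1

    def _spawn(sire_rows, dam_rows, sexes, hap_prev, id_prev, generation):
        nonlocal next_id
        paternal = _meiosis_batch(hap_prev[sire_rows], switch_prob, rng)
        maternal = _meiosis_batch(hap_prev[dam_rows], switch_prob, rng)
        m = len(sire_rows)
        ids = np.arange(next_id, next_id + m, dtype=np.int64)
        next_id += m
        hap_blocks.append(np.stack([paternal, maternal], axis=1))
        ids_blocks.append(ids)
        sire_blocks.append(id_prev[sire_rows])
        dam_blocks.append(id_prev[dam_rows])
        sex_blocks.append(np.asarray(sexes, dtype=np.int8))
        gen_blocks.append(np.full(m, generation, dtype=np.int16))

    # generation 1: monogamous pairs, 20 progeny per dam (10 male, 10 female)
    sires = rng.permutation(males0)
    dams = rng.permutation(females0)
    sire_rows = np.repeat(sires, 20)
    dam_rows = np.repeat(dams, 20)
    sexes = np.tile(np.array([0] * 10 + [1] * 10, dtype=np.int8), len(sires))
    _spawn(sire_rows, dam_rows, sexes, gen0.haplotypes, gen0.ids, 1)

    for g in range(2, n_generations + 1):
        prev_hap = hap_blocks[-1]
        prev_ids = ids_blocks[-1]
        prev_sex = sex_blocks[-1]
        males = np.flatnonzero(prev_sex == 0)
        females = np.flatnonzero(prev_sex == 1)
        n_sires = max(1, len(males) // 10)
        chosen = rng.choice(males, size=n_sires, replace=False)
        dams = rng.permutation(females)
        per_sire = len(dams) // n_sires
        sire_per_dam = np.repeat(chosen, per_sire)
        # two progeny (one male, one female) per dam
        sire_rows = np.repeat(sire_per_dam, 2)
        dam_rows = np.repeat(dams[: len(sire_per_dam)], 2)
        sexes = np.tile(np.array([0, 1], dtype=np.int8), len(sire_per_dam))
        _spawn(sire_rows, dam_rows, sexes, prev_hap, prev_ids, g)

    return Population(
        ids=np.concatenate(ids_blocks),
        sire=np.concatenate(sire_blocks),
        dam=np.concatenate(dam_blocks),
        sex=np.concatenate(sex_blocks),
        generation=np.concatenate(gen_blocks),
        haplotypes=np.concatenate(hap_blocks, axis=0),
    )


# ---------------------------------------------------------------------------
# trait architecture and phenotypes
# ---------------------------------------------------------------------------


@dataclass
class TraitArchitecture:
    """QTL slots, allele-substitution effects and the variance scaling.

    ``slot_indices`` index the QTL-slot axis (``gmap.qtl_loci`` order);
    ``freq2`` is the generation-1 frequency of allele 2 at each QTL.
    The per-QTL additive variances ``2 p (1-p) a**2`` sum to
    ``sigma_A2`` exactly after rescaling.
    """

    slot_indices: np.ndarray
    effects: np.ndarray
    sigma_A2: float
    freq2: np.ndarray

    @property
    def per_qtl_variance(self) -> np.ndarray:
        p = self.freq2
        return 2.0 * p * (1.0 - p) * self.effects**2


def sample_trait(
    gmap: GeneticMap,
    slot_freq2: np.ndarray,
    n_qtl: int,
    sigma_A2: float,
    rng: np.random.Generator,
    gamma_shape: float = 0.4,
    gamma_scale: float = 1.66,
) -> TraitArchitecture:
    """Draw a random additive architecture over polymorphic QTL slots.

    ``slot_freq2`` is the generation-1 frequency of allele 2 at every
    potential QTL slot. ``n_qtl`` slots are sampled uniformly without
    replacement among polymorphic slots; |effects| are gamma draws with
    a random sign, then rescaled so the per-QTL variances sum to
    ``sigma_A2``.
    """
    slot_freq2 = np.asarray(slot_freq2, dtype=float)
    if slot_freq2.size != gmap.n_qtl_slots:
        raise ValueError("slot_freq2 must cover every potential QTL slot")
    poly = np.flatnonzero((slot_freq2 > 0.0) & (slot_freq2 < 1.0))
    if n_qtl > poly.size:
        raise ValueError(
            f"requested {n_qtl} QTL but only {poly.size} polymorphic slots exist"
        )
    chosen = np.sort(rng.choice(poly, size=n_qtl, replace=False))
    a = rng.gamma(gamma_shape, gamma_scale, size=n_qtl)
    a *= np.where(rng.random(n_qtl) < 0.5, -1.0, 1.0)
    p = slot_freq2[chosen]
    total = np.sum(2.0 * p * (1.0 - p) * a**2)
    a *= np.sqrt(sigma_A2 / total)
    return TraitArchitecture(chosen, a, float(sigma_A2), p)


def compute_tbv(genotypes: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    """True breeding values: TBV_j = sum_i a_i * Z_ji with Z in -1/0/1."""
    Z = np.asarray(genotypes)
    if Z.ndim != 2 or Z.shape[1] != arch.effects.size:
        raise ValueError("genotypes must be (n_individuals, n_qtl)")
    if Z.size and (Z.min() < -1 or Z.max() > 1):
        raise ValueError("QTL genotypes must be coded -1/0/1")
    return Z.astype(float) @ arch.effects


def simulate_phenotypes(
    tbv: np.ndarray, sigma_e2: float, rng: np.random.Generator
) -> np.ndarray:
    """Phenotypes P = TBV + e with e ~ N(0, sigma_e2)."""
    if sigma_e2 < 0:
        raise ValueError("environmental variance must be non-negative")
    tbv = np.asarray(tbv, dtype=float)
    return tbv + rng.normal(0.0, np.sqrt(sigma_e2), size=tbv.shape)


# ---------------------------------------------------------------------------
# one-call dataset
# ---------------------------------------------------------------------------


@dataclass
class SimulatedData:
    """Everything one replicate produces, ready for the estimators.

    ``X`` counts allele 2 at every marker for every individual of
    generations 0..6 (rows follow ``pop``); ``Z = X - 1`` is the
    -1/0/1 coding. TBV and phenotypes live on ``pop``.
    """

    config: SimulationConfig
    gmap: GeneticMap
    pop: Population
    X: np.ndarray
    arch: TraitArchitecture

    @property
    def Z(self) -> np.ndarray:
        return (self.X.astype(np.int8) - 1).astype(np.int8)

    def marker_freq2(self, generation: int = 1) -> np.ndarray:
        rows = self.pop.rows_of(generation)
        return self.X[rows].mean(axis=0) / 2.0


def simulate_dataset(
    config: SimulationConfig, seed: int | np.random.SeedSequence
) -> SimulatedData:
    """Run one full replicate: map, history, recoding, expansion, trait.

    Randomness is split into independent child streams (map, history,
    breeding, trait, phenotypes) so the whole replicate is reproducible
    from a single seed.
    """
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    s_map, s_hist, s_breed, s_trait, s_phen = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )
    gmap = build_genetic_map(
        config.n_chromosomes,
        config.chromosome_length,
        config.markers_per_chromosome,
        s_map,
    )
    hist = simulate_history(config, gmap, s_hist)
    gen0 = recode_biallelic(hist)
    pop = breed_validation_generations(
        gen0, s_breed, config.n_validation_generations, gmap=gmap
    )

    X_all = allele2_counts(pop)  # all loci, int8
    Xq = X_all[:, gmap.qtl_loci]
    X = np.ascontiguousarray(X_all[:, gmap.marker_loci])

    gen1 = pop.rows_of(1)
    slot_freq2 = Xq[gen1].mean(axis=0) / 2.0
    arch = sample_trait(
        gmap,
        slot_freq2,
        config.n_qtl,
        config.sigma_A2,
        s_trait,
        config.gamma_shape,
        config.gamma_scale,
    )

    Zq = Xq[:, arch.slot_indices].astype(np.int8) - 1
    tbv = compute_tbv(Zq, arch)
    phen = np.full(pop.n_individuals, np.nan)
    phen[gen1] = simulate_phenotypes(tbv[gen1], config.sigma_e2, s_phen)
    pop.tbv = tbv
    pop.phenotypes = phen
    return SimulatedData(config=config, gmap=gmap, pop=pop, X=X, arch=arch)
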