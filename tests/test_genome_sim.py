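"""Unit and property tests for the forward-in-time simulator."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tablup as tl
from tablup.genome_sim import Population, _meiosis_batch


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "n_chr,length,markers,exp_markers,exp_slots",
    [
        (5, 1.0, 1000, 5000, 4995),  # standard genome
        (1, 1.0, 2, 2, 1),
        (2, 1.0, 3, 6, 4),
    ],
)
def test_map_counts(n_chr, length, markers, exp_markers, exp_slots, rng):
    gmap = tl.build_genetic_map(n_chr, length, markers, rng)
    assert gmap.n_markers == exp_markers
    assert gmap.n_qtl_slots == exp_slots
    assert gmap.n_loci == exp_markers + exp_slots


def test_map_positions_sorted_within_bounds(rng):
    gmap = tl.build_genetic_map(3, 1.0, 50, rng)
    for c in range(3):
        sel = gmap.chromosome == c
        pos = gmap.positions[sel]
        assert np.all(np.diff(pos) > 0)
        assert pos.min() >= 0 and pos.max() <= 1.0
        # each slot is the midpoint of its flanking markers
        m = gmap.marker_positions[c]
        np.testing.assert_allclose(gmap.qtl_slot_positions[c], 0.5 * (m[:-1] + m[1:]))


def test_map_rejects_degenerate(rng):
    with pytest.raises(ValueError):
        tl.build_genetic_map(1, 0.0, 10, rng)
    with pytest.raises(ValueError):
        tl.build_genetic_map(1, 1.0, 1, rng)


# ---------------------------------------------------------------------------
# Haldane map function
# ---------------------------------------------------------------------------


def test_haldane_closed_form():
    assert tl.haldane_recomb_prob(0.0) == 0.0
    assert tl.haldane_recomb_prob(50.0) == pytest.approx(0.5, abs=1e-12)
    assert tl.haldane_recomb_prob(0.1) == pytest.approx(0.0906346, abs=1e-6)
    with pytest.raises(ValueError):
        tl.haldane_recomb_prob(-0.01)


@given(st.floats(min_value=0.0, max_value=10.0), st.floats(min_value=0.0, max_value=10.0))
def test_haldane_monotone_bounded(d1, d2):
    r1, r2 = tl.haldane_recomb_prob(d1), tl.haldane_recomb_prob(d2)
    assert 0.0 <= r1 < 0.5 or r1 == pytest.approx(0.5)
    if d1 < d2:
        assert r1 <= r2


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


def test_meiosis_identical_parents(rng):
    gmap = tl.build_genetic_map(2, 1.0, 20, rng)
    hap = np.full((2, gmap.n_loci), 7, dtype=np.int32)
    gamete = tl.meiosis(hap, gmap, rng)
    assert np.all(gamete == 7)


def test_meiosis_no_recombination_returns_whole_haplotype(rng):
    # all loci within ~1e-9 Morgan: switch probability ~0 inside the chromosome
    m = np.array([0.5, 0.5 + 1e-9, 0.5 + 2e-9])
    gmap = tl.GeneticMap(1, 1.0, [m], [0.5 * (m[:-1] + m[1:])])
    parent = np.vstack([np.ones(gmap.n_loci, int), np.full(gmap.n_loci, 2)])
    for _ in range(20):
        gamete = tl.meiosis(parent, gmap, rng)
        assert np.all(gamete == gamete[0])  # one parental haplotype, unbroken


def test_meiosis_mendelian_mosaic(rng):
    gmap = tl.build_genetic_map(3, 1.0, 30, rng)
    parent = np.vstack(
        [np.arange(gmap.n_loci), np.arange(gmap.n_loci) + 10_000]
    ).astype(np.int32)
    gamete = tl.meiosis(parent, gmap, rng)
    assert np.all((gamete == parent[0]) | (gamete == parent[1]))


def test_empirical_recombination_matches_haldane(rng):
    """Over 10,000 meioses the recombinant fraction between loci 0.1 M
    apart matches the Haldane closed form within 3 binomial SE."""
    m = np.array([0.2, 0.3])
    gmap = tl.GeneticMap(1, 1.0, [m], [np.array([0.25])])
    parent = np.array([[1, 1, 1], [2, 2, 2]], dtype=np.int32)
    gametes = _meiosis_batch(
        np.broadcast_to(parent, (10_000, 2, 3)), gmap.switch_prob, rng
    )
    rec_frac = np.mean(gametes[:, 0] != gametes[:, -1])
    p = tl.haldane_recomb_prob(0.1)
    se = np.sqrt(p * (1 - p) / 10_000)
    assert abs(rec_frac - p) < 3 * se


# ---------------------------------------------------------------------------
# mutation
# ---------------------------------------------------------------------------


def test_mutate_rate_zero_noop(rng):
    gamete = np.array([1, 1, 1], dtype=np.int32)
    counter = np.full(3, 2, dtype=np.int32)
    out = tl.mutate(gamete, 0.0, counter, rng)
    np.testing.assert_array_equal(out, gamete)
    assert np.all(counter == 2)


def test_mutate_rate_one_all_fresh_labels(rng):
    gamete = np.array([1, 5, 9], dtype=np.int32)
    counter = np.array([2, 6, 10], dtype=np.int32)
    out = tl.mutate(gamete, 1.0, counter, rng)
    np.testing.assert_array_equal(out, [2, 6, 10])  # next unused label per locus
    np.testing.assert_array_equal(counter, [3, 7, 11])


def test_mutate_batch_unique_labels_per_locus(rng):
    gametes = np.ones((50, 4), dtype=np.int32)
    counter = np.full(4, 2, dtype=np.int32)
    out = tl.mutate(gametes, 0.5, counter, rng)
    for j in range(4):
        mutated = out[:, j][out[:, j] != 1]
        assert len(np.unique(mutated)) == len(mutated)  # never reused
    with pytest.raises(ValueError):
        tl.mutate(gametes, 1.5, counter, rng)


# ---------------------------------------------------------------------------
# history
# ---------------------------------------------------------------------------


def test_history_zero_generations_is_monomorphic_base(rng):
    cfg = tl.SimulationConfig(
        n_chromosomes=1, markers_per_chromosome=10, n_historical_generations=0
    )
    gmap = tl.build_genetic_map(1, 1.0, 10, rng)
    pop = tl.simulate_history(cfg, gmap, rng)
    assert pop.n_individuals == 100
    assert np.all(pop.haplotypes == 1)


def test_history_constant_census_and_sex_ratio(rng):
    cfg = tl.SimulationConfig(
        n_chromosomes=1, markers_per_chromosome=10, n_historical_generations=5
    )
    gmap = tl.build_genetic_map(1, 1.0, 10, rng)
    pop = tl.simulate_history(cfg, gmap, rng)
    assert pop.n_individuals == cfg.historical_size
    assert (pop.sex == 0).sum() == (pop.sex == 1).sum() == 50


# ---------------------------------------------------------------------------
# biallelic recoding
# ---------------------------------------------------------------------------


def _population_one_locus(allele_pairs):
    hap = np.array(allele_pairs, dtype=np.int32)[:, :, None]
    n = hap.shape[0]
    return Population(
        ids=np.arange(n),
        sire=np.full(n, -1),
        dam=np.full(n, -1),
        sex=np.zeros(n, dtype=np.int8),
        generation=np.zeros(n, dtype=np.int16),
        haplotypes=hap,
    )


def test_recode_keeps_allele_closest_to_half():
    # 50 individuals = 100 copies: allele 1 x48, allele 3 x30, allele 7 x22
    copies = [1] * 48 + [3] * 30 + [7] * 22
    pairs = [(copies[2 * i], copies[2 * i + 1]) for i in range(50)]
    pop = _population_one_locus(pairs)
    out = tl.recode_biallelic(pop)
    freq1 = np.mean(out.haplotypes == 1)
    assert freq1 == pytest.approx(0.48)
    assert set(np.unique(out.haplotypes)) <= {1, 2}


def test_recode_monomorphic_becomes_all_one():
    pop = _population_one_locus([(5, 5)] * 10)
    out = tl.recode_biallelic(pop)
    assert np.all(out.haplotypes == 1)


def test_recode_tie_prefers_smaller_label():
    # alleles 2 and 4 both at frequency 0.5
    pop = _population_one_locus([(2, 4)] * 10)
    out = tl.recode_biallelic(pop)
    # original allele 2 -> coded 1, original 4 -> coded 2
    assert np.all(out.haplotypes[:, 0] == 1)
    assert np.all(out.haplotypes[:, 1] == 2)


# ---------------------------------------------------------------------------
# validation-generation breeding
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def bred():
    rng = np.random.default_rng(99)
    gmap = tl.build_genetic_map(1, 1.0, 20, rng)
    hap = rng.integers(1, 3, size=(100, 2, gmap.n_loci)).astype(np.int8)
    gen0 = Population(
        ids=np.arange(100),
        sire=np.full(100, -1),
        dam=np.full(100, -1),
        sex=np.tile(np.array([0, 1], dtype=np.int8), 50),
        generation=np.zeros(100, dtype=np.int16),
        haplotypes=hap,
    )
    return tl.breed_validation_generations(gen0, rng, gmap=gmap), gen0


def test_breeding_generation_sizes(bred):
    pop, _ = bred
    sizes = {g: (pop.generation == g).sum() for g in range(7)}
    assert sizes[0] == 100
    for g in range(1, 7):
        assert sizes[g] == 1000


def test_breeding_halfsib_structure(bred):
    pop, _ = bred
    for g in range(2, 7):
        rows = pop.rows_of(g)
        sires = pop.sire[rows]
        counts = np.unique(sires, return_counts=True)[1]
        assert len(counts) == 50  # 50 selected sires
        assert np.all(counts == 20)  # 10 dams x 2 progeny each
        dams, dcounts = np.unique(pop.dam[rows], return_counts=True)
        assert len(dams) == 500 and np.all(dcounts == 2)
        assert (pop.sex[rows] == 0).sum() == 500


def test_breeding_gen1_family_sizes(bred):
    pop, _ = bred
    rows = pop.rows_of(1)
    dams, counts = np.unique(pop.dam[rows], return_counts=True)
    assert len(dams) == 50 and np.all(counts == 20)


def test_breeding_mendelian_consistency(bred):
    pop, _ = bred
    rows = pop.rows_of([1, 2, 3, 4, 5, 6])
    for i in np.random.default_rng(0).choice(rows, 200, replace=False):
        s, d = pop.sire[i], pop.dam[i]  # ids are row indices by construction
        assert np.all(
            (pop.haplotypes[i, 0] == pop.haplotypes[s, 0])
            | (pop.haplotypes[i, 0] == pop.haplotypes[s, 1])
        )
        assert np.all(
            (pop.haplotypes[i, 1] == pop.haplotypes[d, 0])
            | (pop.haplotypes[i, 1] == pop.haplotypes[d, 1])
        )


def test_breeding_rejects_sex_imbalance(rng):
    gmap = tl.build_genetic_map(1, 1.0, 5, rng)
    gen0 = Population(
        ids=np.arange(10),
        sire=np.full(10, -1),
        dam=np.full(10, -1),
        sex=np.array([0] * 7 + [1] * 3, dtype=np.int8),
        generation=np.zeros(10, dtype=np.int16),
        haplotypes=np.ones((10, 2, gmap.n_loci), dtype=np.int8),
    )
    with pytest.raises(ValueError):
        tl.breed_validation_generations(gen0, rng, gmap=gmap)


# ---------------------------------------------------------------------------
# trait architecture, TBV, phenotypes
# ---------------------------------------------------------------------------


def test_trait_variance_rescaled_exactly(tiny_data):
    arch = tiny_data.arch
    assert arch.per_qtl_variance.sum() == pytest.approx(1.0, abs=1e-10)
    assert len(arch.effects) == tiny_data.config.n_qtl


def test_trait_single_qtl_half_frequency(rng):
    gmap = tl.build_genetic_map(1, 1.0, 3, rng)  # 2 slots
    freq = np.array([0.5, 0.0])  # only slot 0 polymorphic
    arch = tl.sample_trait(gmap, freq, 1, 1.0, rng)
    assert arch.slot_indices.tolist() == [0]
    assert abs(arch.effects[0]) == pytest.approx(np.sqrt(2.0), abs=1e-12)


def test_trait_rejects_too_many_qtl(rng):
    gmap = tl.build_genetic_map(1, 1.0, 3, rng)
    with pytest.raises(ValueError):
        tl.sample_trait(gmap, np.array([0.5, 0.0]), 2, 1.0, rng)


def test_tbv_examples():
    arch = tl.TraitArchitecture(
        slot_indices=np.array([0]),
        effects=np.array([0.3]),
        sigma_A2=1.0,
        freq2=np.array([0.5]),
    )
    assert tl.compute_tbv(np.array([[0]]), arch)[0] == 0.0  # heterozygote
    assert tl.compute_tbv(np.array([[1]]), arch)[0] == pytest.approx(0.3)  # 22
    with pytest.raises(ValueError):
        tl.compute_tbv(np.array([[2]]), arch)


def test_phenotypes_zero_noise_and_variance_addition(rng):
    tbv = rng.normal(0, 1, 1000)
    np.testing.assert_array_equal(tl.simulate_phenotypes(tbv, 0.0, rng), tbv)
    phen = tl.simulate_phenotypes(tbv, np.var(tbv), rng)
    ratio = np.var(phen) / np.var(tbv)
    assert 1.7 < ratio < 2.3  # h2 = 0.5 doubles the variance
    with pytest.raises(ValueError):
        tl.simulate_phenotypes(tbv, -1.0, rng)


# ---------------------------------------------------------------------------
# full replicate
# ---------------------------------------------------------------------------


def test_dataset_structure(tiny_data):
    data = tiny_data
    pop = data.pop
    assert data.X.shape == (pop.n_individuals, data.gmap.n_markers)
    assert set(np.unique(data.X)) <= {0, 1, 2}
    # phenotypes only in generation 1
    gen1 = pop.rows_of(1)
    assert np.isfinite(pop.phenotypes[gen1]).all()
    others = pop.rows_of([0, 2, 3, 4, 5, 6])
    assert np.isnan(pop.phenotypes[others]).all()


def test_dataset_bit_reproducible():
    cfg = tl.SimulationConfig(
        n_chromosomes=1,
        markers_per_chromosome=30,
        n_historical_generations=20,
        n_qtl=5,
        n_validation_generations=2,
    )
    a = tl.simulate_dataset(cfg, 11)
    b = tl.simulate_dataset(cfg, 11)
    np.testing.assert_array_equal(a.pop.haplotypes, b.pop.haplotypes)
    np.testing.assert_array_equal(a.pop.phenotypes, b.pop.phenotypes)
    np.testing.assert_array_equal(a.arch.effects, b.arch.effects)
    c = tl.simulate_dataset(cfg, 12)
    assert not np.array_equal(a.pop.haplotypes, c.pop.haplotypes)
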