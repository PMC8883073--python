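"""Crossing-scheme simulator: meiosis, cross execution, assay emulation."""

import numpy as np
import pandas as pd
import pytest

import introtrack as it
from introtrack.simulate import _gametes_chrom


# ----------------------------------------------------------------- meiosis

def test_homozygous_parent_gametes_are_invariant(small_map):
    """Recombination cannot create novelty in a homozygote."""
    parent = {c: np.full((2, 6), 7, dtype=np.int8) for c in small_map.chroms}
    rng = np.random.default_rng(0)
    for _ in range(20):
        g = it.simulate_meiosis(parent, small_map, rng)
        for c in small_map.chroms:
            assert (g[c] == 7).all()


def test_zero_genetic_distance_never_recombines():
    """Two loci at the same cM position always co-segregate."""
    loci = pd.DataFrame({"id": ["m1", "m2"], "chrom": ["A01", "A01"],
                         "bp": [1_000_000, 2_000_000], "cM": [30.0, 30.0]})
    gmap = it.GeneticMap(loci, {"A01": 10_000_000})
    parent = {"A01": np.array([[0, 0], [1, 1]], dtype=np.int8)}
    gam = it.simulate_gametes(parent, gmap, 10_000, np.random.default_rng(1))["A01"]
    assert (gam[:, 0] == gam[:, 1]).all()


def test_haldane_recombination_fraction_at_50cm():
    """Observed recombinant fraction matches (1 - e^-1)/2 for d = 50 cM."""
    loci = pd.DataFrame({"id": ["m1", "m2"], "chrom": ["A01", "A01"],
                         "bp": [1_000_000, 9_000_000], "cM": [0.0, 50.0]})
    gmap = it.GeneticMap(loci, {"A01": 10_000_000})
    parent = {"A01": np.array([[0, 0], [1, 1]], dtype=np.int8)}
    n = 100_000
    gam = it.simulate_gametes(parent, gmap, n, np.random.default_rng(7))["A01"]
    rf_obs = (gam[:, 0] != gam[:, 1]).mean()
    rf_exp = (1 - np.exp(-2 * 50 / 100)) / 2
    se = np.sqrt(rf_exp * (1 - rf_exp) / n)
    assert abs(rf_obs - rf_exp) < 3 * se


def test_meiosis_gamete_is_parental_mosaic(small_map):
    """Every gamete allele comes from one of the two parental haplotypes."""
    rng = np.random.default_rng(3)
    parent = {c: np.stack([np.zeros(6, np.int8), np.ones(6, np.int8)])
              for c in small_map.chroms}
    g = it.simulate_meiosis(parent, small_map, rng)
    for c in small_map.chroms:
        assert set(np.unique(g[c])) <= {0, 1}


def test_meiosis_rejects_missing_chromosome(small_map):
    parent = {small_map.chroms[0]: np.zeros((2, 6), np.int8)}
    with pytest.raises(ValueError, match="no haplotypes"):
        it.simulate_meiosis(parent, small_map, np.random.default_rng(0))


# ---------------------------------------------------------------- run_cross

def test_f1_is_heterozygous_everywhere(small_map, founders):
    donor, recipient = founders
    pop = it.run_cross(it.CrossSpec(("make_f1",), n=25, seed=11), donor, recipient, small_map)
    cls = pop.genotype_classes().to_numpy()
    assert (cls == "H").all()


def test_bc1s1_unlinked_locus_segregates_1_5_2():
    """Genotype proportions at an unlinked locus approach A:B:H = 1:5:2."""
    gmap = it.demo_map(n_chrom=1, loci_per_chrom=1)
    donor = it.FounderGenome.inbred("D", gmap, 0)
    recipient = it.FounderGenome.inbred("R", gmap, 1)
    n = 40_000
    pop = it.run_cross(it.CrossSpec.bc1s1(n, seed=13), donor, recipient, gmap)
    cls = pop.genotype_classes().to_numpy()[:, 0]
    for code, p in [("A", 1 / 8), ("B", 5 / 8), ("H", 2 / 8)]:
        obs = (cls == code).mean()
        se = np.sqrt(p * (1 - p) / n)
        assert abs(obs - p) < 3.5 * se, f"{code}: {obs} vs {p}"


def test_lethal_selection_eliminates_donor_homozygote(unlinked_map):
    donor = it.FounderGenome.inbred("D", unlinked_map, 0)
    recipient = it.FounderGenome.inbred("R", unlinked_map, 1)
    locus = unlinked_map.loci["id"].iloc[0]
    sel = it.SelectionEntry(locus, {"A": 0.0, "H": 1.0, "B": 1.0})
    pop = it.run_cross(it.CrossSpec.bc1s1(2000, seed=5, selection=(sel,)),
                       donor, recipient, unlinked_map)
    cls = pop.genotype_classes()
    assert not (cls[locus] == "A").any()
    # other, unlinked loci still carry donor homozygotes
    other = unlinked_map.loci["id"].iloc[1]
    assert (cls[other] == "A").any()


def test_selection_at_untracked_locus_rejected(small_map, founders):
    donor, recipient = founders
    sel = it.SelectionEntry("nope_1", {"A": 0.5})
    with pytest.raises(KeyError, match="nope_1"):
        it.run_cross(it.CrossSpec.bc1s1(10, seed=1, selection=(sel,)),
                     donor, recipient, small_map)


def test_all_zero_fitness_rejected():
    with pytest.raises(ValueError, match="all-zero"):
        it.SelectionEntry("x", {"A": 0.0, "H": 0.0, "B": 0.0})
    with pytest.raises(ValueError, match="negative"):
        it.SelectionEntry("x", {"A": -1.0})


def test_same_spec_and_seed_reproduces_bitwise(small_map, founders):
    donor, recipient = founders
    spec = it.CrossSpec.bc1s1(50, seed=42)
    p1 = it.run_cross(spec, donor, recipient, small_map)
    p2 = it.run_cross(spec, donor, recipient, small_map)
    for c in small_map.chroms:
        assert (p1.haplotypes[c] == p2.haplotypes[c]).all()


def test_founder_origin_conservation(small_map, founders):
    """Every allele traces to a founder; per-locus counts sum to 2N."""
    donor, recipient = founders
    pop = it.run_cross(it.CrossSpec.bc1s1(200, seed=9), donor, recipient, small_map)
    for c in small_map.chroms:
        haps = pop.haplotypes[c]
        assert set(np.unique(haps)) <= {0, 1}
        for j in range(haps.shape[2]):
            counts = pop.allele_counts(c, j)
            assert sum(counts.values()) == 2 * pop.n


def test_identical_founders_rejected(small_map):
    a = it.FounderGenome.inbred("X", small_map, 0)
    b = it.FounderGenome.inbred("Y", small_map, 0)
    with pytest.raises(ValueError, match="identical"):
        it.run_cross(it.CrossSpec.bc1s1(5, seed=1), a, b, small_map)


def test_cross_spec_validation():
    with pytest.raises(ValueError, match="make_f1"):
        it.CrossSpec(("self",), n=5)
    with pytest.raises(ValueError, match="unknown step"):
        it.CrossSpec(("make_f1", "outcross"), n=5)
    with pytest.raises(ValueError, match="size"):
        it.CrossSpec(("make_f1",), n=0)


# ------------------------------------------------------- genotype_population

def test_genotyping_without_noise_equals_truth(small_map, founders):
    donor, recipient = founders
    pop = it.run_cross(it.CrossSpec.bc1s1(30, seed=2), donor, recipient, small_map)
    mat = it.genotype_population(pop, list(small_map.loci["id"]), 0.0, 0.0,
                                 np.random.default_rng(0))
    truth = pop.genotype_classes()
    assert (mat.calls.to_numpy() == truth[mat.marker_ids].to_numpy()).all()


def test_full_missingness_gives_all_D(small_map, founders):
    donor, recipient = founders
    pop = it.run_cross(it.CrossSpec.bc1s1(10, seed=2), donor, recipient, small_map)
    mat = it.genotype_population(pop, list(small_map.loci["id"]), 0.999999, 0.0,
                                 np.random.default_rng(0))
    # with missing_rate ~ 1 effectively every call is missing
    assert (mat.calls.to_numpy() == "D").mean() > 0.99


def test_missing_count_matches_binomial_expectation():
    """107 lines x 132 markers at the empirical missing rate ~ 322 missing calls."""
    gmap = it.demo_map(n_chrom=11, loci_per_chrom=12)  # 132 loci
    donor = it.FounderGenome.inbred("D", gmap, 0)
    recipient = it.FounderGenome.inbred("R", gmap, 1)
    pop = it.run_cross(it.CrossSpec.bc1s1(107, seed=21), donor, recipient, gmap)
    rate = 322 / 14_124
    mat = it.genotype_population(pop, list(gmap.loci["id"]), rate, 0.0,
                                 np.random.default_rng(22))
    assert mat.n_calls == 14_124
    n_missing = mat.counts()["D"]
    sd = np.sqrt(14_124 * rate * (1 - rate))
    assert abs(n_missing - 322) < 4 * sd


def test_error_rate_produces_wrong_codes(small_map, founders):
    donor, recipient = founders
    pop = it.run_cross(it.CrossSpec.bc1s1(200, seed=2), donor, recipient, small_map)
    mat = it.genotype_population(pop, list(small_map.loci["id"]), 0.0, 0.3,
                                 np.random.default_rng(1))
    truth = pop.genotype_classes()[mat.marker_ids].to_numpy()
    err = (mat.calls.to_numpy() != truth).mean()
    assert 0.2 < err < 0.4
    assert not (mat.calls.to_numpy() == "D").any()


def test_invalid_rates_rejected(small_map, founders):
    donor, recipient = founders
    pop = it.run_cross(it.CrossSpec.bc1s1(3, seed=2), donor, recipient, small_map)
    with pytest.raises(ValueError):
        it.genotype_population(pop, list(small_map.loci["id"]), 1.5, 0.0)


# --------------------------------------------- simulate_parental_variants

def test_zero_violation_rates_pass_everything():
    tab = it.simulate_parental_variants(50, {}, np.random.default_rng(0))
    assert tab.annotations["pass_a"].all()
    assert it.filter_a_genome_diagnostic(tab).size == 50


def test_het_rate_one_kills_all_candidates():
    tab = it.simulate_parental_variants(50, {"het_parent": 1.0}, np.random.default_rng(0))
    assert not tab.annotations["pass_a"].any()
    assert it.filter_a_genome_diagnostic(tab).size == 0


def test_unknown_violation_rate_rejected():
    with pytest.raises(ValueError, match="unknown"):
        it.simulate_parental_variants(5, {"bogus": 0.5})


def test_gamete_batch_shape():
    cm = np.array([0.0, 50.0, 90.0])
    haps = np.broadcast_to(np.array([[0, 0, 0], [1, 1, 1]], np.int8), (500, 2, 3))
    g = _gametes_chrom(haps, cm, np.random.default_rng(0))
    assert g.shape == (500, 3)
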