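"""Diagnostic-marker filtering, spacing, distribution stats and gap detection."""

import itertools

import numpy as np
import pandas as pd
import pytest

import introtrack as it
from introtrack.markerdesign import HET, HOM_ALT, HOM_REF, markers_to_frame

from conftest import make_variant_table

MIXED_RATES = {"het_parent": 0.2, "ref_mismatch": 0.15, "monomorphic": 0.25,
               "recipient_nonuniform": 0.1, "flanking_variation": 0.2,
               "nigra_hit": 0.1, "bjub_equal_a": 0.15, "bjub_nonuniform": 0.1}


# --------------------------------------------------------------- A filter

def test_heterozygous_recipient_excluded():
    tab = make_variant_table([("A01", 100), ("A01", 200)],
                             gt_R1=[HET, HOM_ALT])
    assert list(it.filter_a_genome_diagnostic(tab)) == ["A01:200"]


def test_monomorphic_locus_excluded():
    tab = make_variant_table([("A01", 100), ("A01", 200)],
                             gt_R1=[HOM_REF, HOM_ALT], gt_R2=[HOM_REF, HOM_ALT])
    assert list(it.filter_a_genome_diagnostic(tab)) == ["A01:200"]


def test_donor_reference_mismatch_excluded():
    tab = make_variant_table([("A01", 100), ("A01", 200)],
                             gt_donor=[HOM_ALT, HOM_REF],
                             gt_R1=[HOM_REF, HOM_ALT], gt_R2=[HOM_REF, HOM_ALT])
    assert list(it.filter_a_genome_diagnostic(tab)) == ["A01:200"]


def test_nonuniform_recipients_and_flags_excluded():
    tab = make_variant_table(
        [("A01", 100), ("A01", 200), ("A01", 300), ("A01", 400)],
        gt_R2=[HOM_REF, HOM_ALT, HOM_ALT, HOM_ALT],
        flag_flanking_variation=[False, True, False, False],
        flag_nigra_hit=[False, False, True, False])
    assert list(it.filter_a_genome_diagnostic(tab)) == ["A01:400"]


def test_missing_flag_column_named_in_error():
    tab = make_variant_table([("A01", 100)])
    tab.variants = tab.variants.drop(columns=["flag_nigra_hit"])
    with pytest.raises(ValueError, match="flag_nigra_hit"):
        it.filter_a_genome_diagnostic(tab)


def test_survivors_equal_annotation_ground_truth():
    """Filter output matches brute-force application of the planted annotations."""
    tab = it.simulate_parental_variants(800, MIXED_RATES, np.random.default_rng(17))
    ann = tab.annotations
    expected = ann.index[~(ann["viol_i"] | ann["viol_ii"] | ann["viol_iii"]
                           | ann["viol_iv"] | ann["viol_v"] | ann["viol_vi"])]
    assert set(it.filter_a_genome_diagnostic(tab)) == set(expected)


def test_filter_is_idempotent_and_order_free():
    tab = it.simulate_parental_variants(300, MIXED_RATES, np.random.default_rng(3))
    once = it.filter_a_genome_diagnostic(tab)
    sub = it.ParentalVariantTable(tab.variants.loc[once].reset_index(drop=True),
                                  tab.recipients)
    assert set(it.filter_a_genome_diagnostic(sub)) == set(once)


# --------------------------------------------------------------- B filter

def test_b_detection_requires_uniform_a_and_homoeolog_contrast():
    tab = make_variant_table(
        [("A01", 100), ("A01", 200), ("A01", 300)],
        # locus 1: A-polymorphic (excluded); locus 2: homoeolog equals A allele
        # (excluded); locus 3: uniform A with A/B contrast (kept)
        gt_R1=[HOM_ALT, HOM_REF, HOM_REF],
        gt_R2=[HOM_ALT, HOM_REF, HOM_REF],
        bjub_R1=["C", "A", "C"], bjub_R2=["C", "A", "C"])
    assert list(it.filter_b_genome_detection(tab)) == ["A01:300"]


def test_b_detection_without_homoeolog_columns_rejected():
    tab = make_variant_table([("A01", 100)])
    tab.variants = tab.variants.drop(columns=[c for c in tab.variants if c.startswith("bjub_")])
    with pytest.raises(ValueError, match="bjub"):
        it.filter_b_genome_detection(tab)


def test_b_detection_survivors_equal_ground_truth():
    tab = it.simulate_parental_variants(800, MIXED_RATES, np.random.default_rng(29))
    assert set(it.filter_b_genome_detection(tab)) == \
        set(tab.annotations.index[tab.annotations["pass_b"]])


# -------------------------------------------------------- even spacing

def _spacing_fixture(positions, chrom_len=120_000_000):
    tab = make_variant_table([("A01", p) for p in positions])
    loci = pd.DataFrame({"id": ["a", "b"], "chrom": ["A01", "A01"],
                         "bp": [1, chrom_len], "cM": [0.0, 100.0]})
    gmap = it.GeneticMap(loci, {"A01": chrom_len})
    return tab, gmap


def test_target_equal_to_candidates_selects_all():
    pos = [int(p) for p in np.linspace(1e6, 1e8, 10)]
    tab, gmap = _spacing_fixture(pos)
    sel = it.select_evenly_spaced(tab, tab.variants.index, {"A01": 10}, gmap)
    assert sorted(m.bp for m in sel) == sorted(pos)


def test_maximin_forced_choice():
    tab, gmap = _spacing_fixture([1_000_000, 2_000_000, 100_000_000])
    sel = it.select_evenly_spaced(tab, tab.variants.index, {"A01": 2}, gmap)
    assert sorted(m.bp for m in sel) == [1_000_000, 100_000_000]


def test_target_exceeding_candidates_names_chromosome():
    tab, gmap = _spacing_fixture([1_000_000, 2_000_000])
    with pytest.raises(ValueError, match="A01"):
        it.select_evenly_spaced(tab, tab.variants.index, {"A01": 5}, gmap)


def test_selection_beats_random_subsets_on_minimum_gap():
    """Greedy maximin's smallest pairwise gap >= that of 1000 random subsets."""
    rng = np.random.default_rng(101)
    pos = sorted(rng.choice(np.arange(1, 120_000_000), size=40, replace=False).tolist())
    tab, gmap = _spacing_fixture(pos)
    k = 8
    sel = it.select_evenly_spaced(tab, tab.variants.index, {"A01": k}, gmap)
    chosen = sorted(m.bp for m in sel)
    min_gap = min(b - a for a, b in zip(chosen, chosen[1:]))
    for _ in range(1000):
        sub = np.sort(rng.choice(pos, size=k, replace=False))
        assert min_gap >= np.diff(sub).min()


def test_selection_is_subset_with_target_cardinality():
    tab = it.simulate_parental_variants(200, {}, np.random.default_rng(11))
    gmap = it.GeneticMap(
        pd.DataFrame({"id": ["x1", "x2", "y1", "y2", "z1", "z2"],
                      "chrom": ["A01", "A01", "A02", "A02", "A03", "A03"],
                      "bp": [1, 30_000_000] * 3, "cM": [0.0, 100.0] * 3}),
        {"A01": 30_000_000, "A02": 30_000_000, "A03": 30_000_000})
    targets = {"A01": 4, "A02": 3, "A03": 5}
    sel = it.select_evenly_spaced(tab, tab.variants.index, targets, gmap)
    frame = markers_to_frame(sel)
    assert frame.groupby("chrom").size().to_dict() == targets
    keys = frame["chrom"] + ":" + frame["bp"].astype(str)
    assert set(keys) <= set(tab.variants.index)


# --------------------------------------------------- distribution stats

def test_published_density_column_mean():
    """Genome-wide mean of the per-chromosome marker densities."""
    density = [1.649, 2.643, 1.710, 2.062, 2.958, 2.004, 1.862, 2.160, 2.885, 1.481]
    mean = it.genome_wide_means(pd.DataFrame({"density_mb": density}))["density_mb"]
    assert mean == pytest.approx(2.142, abs=0.005)


def test_published_genetic_interval_column_mean():
    interval = [4.113, 7.878, 6.535, 6.590, 10.658, 6.807, 5.328, 7.367, 6.523, 5.440]
    mean = it.genome_wide_means(pd.DataFrame({"cm": interval}))["cm"]
    assert mean == pytest.approx(6.72, abs=0.005)


def test_two_marker_chromosome_densities():
    markers = pd.DataFrame({"chrom": ["A01", "A01"], "bp": [1, 10_000_001],
                            "cM": [0.0, 40.0]})
    stats = it.distribution_stats(markers, {"A01": 20_000_000})
    row = stats.per_chromosome.loc["A01"]
    assert row["density_length_mb"] == pytest.approx(10.0)
    assert row["density_span_mb"] == pytest.approx(10.0)
    assert row["genetic_interval_cm"] == pytest.approx(40.0)


def test_single_marker_chromosome_span_undefined():
    markers = pd.DataFrame({"chrom": ["A01"], "bp": [5_000_000], "cM": [10.0]})
    stats = it.distribution_stats(markers, {"A01": 20_000_000})
    assert np.isnan(stats.per_chromosome.loc["A01", "density_span_mb"])


def test_genome_wide_means_invariant_to_chromosome_order():
    markers = pd.DataFrame({"chrom": ["A01"] * 3 + ["A02"] * 4,
                            "bp": [1, 5, 9, 2, 4, 6, 8],
                            "cM": [0.0, 5.0, 9.0, 0.0, 2.0, 4.0, 8.0]})
    lengths = {"A01": 10, "A02": 10}
    a = it.distribution_stats(markers, lengths).genome_wide
    b = it.distribution_stats(markers.iloc[::-1].reset_index(drop=True), lengths).genome_wide
    pd.testing.assert_series_equal(a.sort_index(), b.sort_index())


# ----------------------------------------------------------------- gaps

def _gap_map(end_cm=100.0):
    loci = pd.DataFrame({"id": ["a", "b"], "chrom": ["A01", "A01"],
                         "bp": [1, 1_000_000], "cM": [0.0, end_cm]})
    return it.GeneticMap(loci, {"A01": 1_000_000})


def test_dense_markers_have_no_gaps():
    gmap = _gap_map(100.0)
    markers = pd.DataFrame({"chrom": ["A01"] * 21, "bp": range(1, 22),
                            "cM": np.arange(0, 105, 5.0)})
    assert it.find_gaps(markers, gmap, 20.0).empty


def test_leading_end_gap_reported():
    gmap = _gap_map(100.0)
    markers = pd.DataFrame({"chrom": ["A01"] * 2, "bp": [10, 20], "cM": [25.0, 90.0]})
    gaps = it.find_gaps(markers, gmap, 20.0)
    kinds = set(gaps["kind"])
    assert "leading" in kinds and "internal" in kinds
    lead = gaps[gaps["kind"] == "leading"].iloc[0]
    assert lead["start_cm"] == 0.0 and lead["end_cm"] == 25.0


def test_gaps_match_brute_force_scan():
    rng = np.random.default_rng(55)
    gmap = _gap_map(100.0)
    for _ in range(20):
        cm = np.sort(rng.uniform(0, 100, size=rng.integers(2, 10)))
        markers = pd.DataFrame({"chrom": "A01", "bp": range(1, len(cm) + 1), "cM": cm})
        thr = float(rng.uniform(5, 40))
        got = it.find_gaps(markers, gmap, thr)
        edges = np.concatenate([[0.0], cm, [100.0]])
        expected = [(a, b) for a, b in zip(edges[:-1], edges[1:]) if b - a > thr]
        assert list(zip(got["start_cm"], got["end_cm"])) == pytest.approx(expected)
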