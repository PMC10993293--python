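"""Unit frequencies, enrichment folds, rare-k-mer binning and species clustering."""

import numpy as np
import pandas as pd
import pytest

from raritykit.corpus import NUCLEIC, PEPTIDE
from raritykit.composition import (
    EmptyStratumError,
    RarityBinProfile,
    _round_half_up,
    bin_rare_kmers,
    cluster_species,
    enrichment_ratio,
    species_occurrence_matrix,
    unit_frequency_by_rarity,
)
from raritykit.kmers import KmerSet, count_species_per_kmer, extract_kmer_set
from raritykit.rarity import build_rarity_table, _mapping_to_table

from conftest import make_entry


def test_monomer_frequency_hand_count():
    # AC and CC at the same rarity value: 4 characters, one A, three C
    table = _mapping_to_table({"AC": 0.2, "CC": 0.2}, 2, NUCLEIC, 5)
    freq = unit_frequency_by_rarity(table, "monomer")
    assert freq.loc[0.2, "A"] == pytest.approx(0.25)
    assert freq.loc[0.2, "C"] == pytest.approx(0.75)
    assert freq.loc[0.2].sum() == pytest.approx(1.0, abs=1e-9)


def test_dimer_frequency_single_kmer():
    table = _mapping_to_table({"AAA": 0.5}, 3, NUCLEIC, 2)
    freq = unit_frequency_by_rarity(table, "dimer")
    assert freq.loc[0.5, "AA"] == pytest.approx(1.0)


def test_frequency_vectors_sum_to_one_per_stratum():
    table = _mapping_to_table(
        {"ACG": 0.25, "GGT": 0.25, "TTT": 0.5, "CCA": 0.75}, 3, NUCLEIC, 4
    )
    for unit in ("monomer", "dimer"):
        freq = unit_frequency_by_rarity(table, unit)
        assert np.allclose(freq.sum(axis=1), 1.0, atol=1e-9)


def test_enrichment_hand_example():
    # high {AAW}: dimers AA, AW -> AA freq 1/2; low {AAA}: AA freq 2/2
    table = _mapping_to_table({"AAW": 0.96, "AAA": 0.5}, 3, PEPTIDE, 100)
    res = enrichment_ratio(table, "dimer", high_min=0.95, low_max=0.9)
    assert res.table.loc["AA", "frequency_high"] == pytest.approx(0.5)
    assert res.table.loc["AA", "frequency_low"] == pytest.approx(1.0)
    assert res.fold("AA") == pytest.approx(0.5)
    assert res.fold("AW") == np.inf  # absent from the low group entirely


def test_enrichment_identical_composition_gives_unit_folds():
    table = _mapping_to_table({"ACAC": 0.96, "CACA": 0.1}, 4, NUCLEIC, 100)
    res = enrichment_ratio(table, "monomer", high_min=0.95, low_max=0.9)
    present = res.table[res.table.frequency_low > 0]
    assert np.allclose(present.fold_ratio, 1.0)


def test_enrichment_threshold_exchange_inverts_fold():
    table = _mapping_to_table(
        {"AAT": 0.96, "ATT": 0.97, "CCG": 0.1, "GGC": 0.2}, 3, NUCLEIC, 100
    )
    fwd = enrichment_ratio(table, "monomer", high_min=0.95, low_max=0.9).table
    # swap the strata by inverting the rarity values
    flipped = _mapping_to_table(
        {"AAT": 0.04, "ATT": 0.03, "CCG": 0.9, "GGC": 0.8}, 3, NUCLEIC, 100
    )
    rev = enrichment_ratio(flipped, "monomer", high_min=0.5, low_max=0.4).table
    for unit in "ACGT":
        f, r = fwd.loc[unit, "fold_ratio"], rev.loc[unit, "fold_ratio"]
        if np.isfinite(f) and f > 0:
            assert r == pytest.approx(1 / f)


def test_enrichment_empty_stratum_named():
    table = _mapping_to_table({"AC": 0.5}, 2, NUCLEIC, 2)
    with pytest.raises(EmptyStratumError, match=">"):
        enrichment_ratio(table, "monomer", high_min=0.95, low_max=0.9)


def test_enrichment_pseudocount_keeps_folds_finite():
    table = _mapping_to_table({"AAW": 0.96, "AAA": 0.5}, 3, PEPTIDE, 100)
    res = enrichment_ratio(table, "dimer", high_min=0.95, low_max=0.9, pseudocount=True)
    assert np.isfinite(res.table.fold_ratio).all()


def test_bin_rare_kmers_top_quartile_and_rounding():
    entries = {f"K{i}": i / 10 for i in range(1, 9)}  # 0.1 ... 0.8
    table = _mapping_to_table(entries, 2, NUCLEIC, 10)
    bins = bin_rare_kmers(table, 3)
    member = {km for kmers in bins.values() for km in kmers}
    # 75th percentile ties included: quantile of 0.1..0.8 at 0.75 is 0.625
    assert member == {"K7", "K8"}
    assert _round_half_up(__import__("fractions").Fraction(98765, 100000), 3) == 0.988
    assert _round_half_up(__import__("fractions").Fraction(1, 8), 3) == 0.125
    assert _round_half_up(__import__("fractions").Fraction(25, 10000), 3) == 0.003  # half away from zero


def test_bin_rare_kmers_matches_brute_force():
    rng = np.random.default_rng(5)
    n = 40
    entries = {f"{i:02d}": int(rng.integers(0, n + 1)) / n for i in range(30)}
    table = _mapping_to_table(entries, 2, NUCLEIC, n)
    bins = bin_rare_kmers(table, 3)
    values = np.array(sorted(entries.values()))
    threshold = np.quantile(values, 0.75)
    expected = {km for km, v in entries.items() if v >= threshold}
    assert {km for kmers in bins.values() for km in kmers} == expected
    for value, kmers in bins.items():
        for km in kmers:
            assert value == pytest.approx(round(entries[km], 3))


def test_bin_rare_kmers_needs_four_kmers():
    with pytest.raises(ValueError, match="quartile"):
        bin_rare_kmers(_mapping_to_table({"AA": 0.5, "AC": 0.6}, 2, NUCLEIC, 2), 3)


def test_species_occurrence_matrix_hand_filled():
    sets = [
        KmerSet("s1", 2, NUCLEIC, frozenset({"AA", "AC", "CA", "CC"})),
        KmerSet("s2", 2, NUCLEIC, frozenset({"AA", "GG"})),
        KmerSet("s3", 2, NUCLEIC, frozenset()),
    ]
    bins = {0.9: ["AA", "AC"], 0.95: ["TT"]}
    profile = species_occurrence_matrix(sets, bins)
    assert profile.matrix.loc["s1", 0.9] == pytest.approx(0.5)
    assert profile.matrix.loc["s2", 0.9] == pytest.approx(0.5)
    assert (profile.matrix[0.95] == 0).all()  # bin with no present k-mer
    assert (profile.matrix.loc["s3"] == 0).all()  # empty species -> zero row
    assert ((profile.matrix >= 0) & (profile.matrix <= 1)).all().all()


def test_cluster_species_separates_disjoint_blocks():
    matrix = pd.DataFrame(
        {
            0.9: [0.5, 0.6, 0.0, 0.0],
            0.95: [0.4, 0.5, 0.01, 0.0],
            0.99: [0.0, 0.0, 0.5, 0.6],
        },
        index=["a1", "a2", "b1", "b2"],
    )
    result = cluster_species(RarityBinProfile(3, matrix))
    order = result.leaf_order
    assert {tuple(order[:2]), tuple(order[2:])} == {("a1", "a2"), ("b1", "b2")}
    assert result.newick.endswith(";") and "a1" in result.newick


def test_identical_rows_merge_at_zero_height():
    matrix = pd.DataFrame({0.9: [0.2, 0.2, 0.9]}, index=["x", "y", "z"])
    result = cluster_species(RarityBinProfile(3, matrix))
    assert result.linkage[0, 2] == 0.0  # first merge is the identical pair
    ids = sorted(matrix.index)
    merged = {ids[int(result.linkage[0, 0])], ids[int(result.linkage[0, 1])]}
    assert merged == {"x", "y"}
    # the identical pair stays adjacent in the leaf order
    positions = {sid: result.leaf_order.index(sid) for sid in ("x", "y")}
    assert abs(positions["x"] - positions["y"]) == 1


def test_cluster_matches_hand_computed_average_linkage():
    # 1-D rows at 0, 1, 5, 9: (0,1) merge at 1; (5,9) at 4; then average
    # linkage distance between clusters = mean pairwise = (5+9+4+8)/4 = 6.5
    matrix = pd.DataFrame({0.5: [0.0, 1.0, 5.0, 9.0]}, index=list("abcd"))
    result = cluster_species(RarityBinProfile(3, matrix))
    heights = sorted(result.linkage[:, 2])
    assert heights == pytest.approx([1.0, 4.0, 6.5])


def test_end_to_end_composition_on_tiny_corpus():
    corpus = [
        make_entry("s1", ["ACGTACGT"]),
        make_entry("s2", ["ACGTAAAA"]),
        make_entry("s3", ["GGGGCCCC"]),
        make_entry("s4", ["ACGTACGA"]),
    ]
    table = build_rarity_table(count_species_per_kmer(corpus, 2))
    bins = bin_rare_kmers(table, 3)
    sets = [extract_kmer_set(e, 2) for e in corpus]
    profile = species_occurrence_matrix(sets, bins)
    assert set(profile.matrix.index) == {"s1", "s2", "s3", "s4"}
    result = cluster_species(profile)
    assert len(result.leaf_order) == 4
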