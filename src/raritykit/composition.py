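"""Compositional structure of the rarity spectrum.

Links sequence composition to rarity: monomer/dimer frequency profiles per
rarity stratum, fold enrichment of units between high- and low-rarity
k-mers, decimal-digit binning of the rarest (top-quartile) k-mers, the
species x rarity-bin occurrence matrix normalized by per-species k-mer
richness, and hierarchical clustering of species on that matrix.

"Frequency" of a unit is compositional: occurrences of the unit over all
overlapping windows across the k-mer group (k windows per k-mer for
monomers, k-1 for dimers), so each stratum's frequency vector sums to 1.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .kmers import KmerSet
from .rarity import RarityTable

UnitType = Literal["monomer", "dimer"]


class EmptyStratumError(ValueError):
    """A rarity stratum needed for an enrichment ratio contains no k-mers."""


def _unit_alphabet(table_alphabet: str, unit_type: UnitType) -> list[str]:
    if unit_type == "monomer":
        return list(table_alphabet)
    return ["".join(p) for p in itertools.product(table_alphabet, repeat=2)]


def _unit_counts(kmers: Iterable[str], unit_type: UnitType) -> Counter:
    counts: Counter = Counter()
    if unit_type == "monomer":
        for kmer in kmers:
            counts.update(kmer)
    else:
        for kmer in kmers:
            counts.update(kmer[i : i + 2] for i in range(len(kmer) - 1))
    return counts


def _normalize(counts: Counter, units: list[str]) -> pd.Series:
    vec = pd.Series({u: counts.get(u, 0) for u in units}, dtype=float)
    total = vec.sum()
    return vec / total if total else vec


def unit_frequency_by_rarity(table: RarityTable, unit_type: UnitType) -> pd.DataFrame:
    """Unit frequency vectors per distinct rarity value.

    Rows are the distinct rarity indices present in the table (as floats,
    ascending); columns are the unit alphabet; each row sums to 1.  Empty
    strata cannot arise: every distinct value owns at least one k-mer.
    """
    units = _unit_alphabet(table.alphabet, unit_type)
    strata: dict[Fraction, list[str]] = {}
    for kmer, value in table.entries.items():
        strata.setdefault(value, []).append(kmer)
    rows = {
        float(value): _normalize(_unit_counts(kmers, unit_type), units)
        for value, kmers in strata.items()
    }
    return pd.DataFrame(rows).T.sort_index()[units]


@dataclass
class EnrichmentResult:
    """Per-unit frequencies in the high- and low-rarity groups and their fold ratio."""

    unit_type: UnitType
    high_min: float
    low_max: float
    table: pd.DataFrame  # columns: frequency_high, frequency_low, fold_ratio

    def fold(self, unit: str) -> float:
        return float(self.table.loc[unit, "fold_ratio"])


def enrichment_ratio(
    table: RarityTable,
    unit_type: UnitType,
    high_min: float,
    low_max: float,
    pseudocount: bool = False,
) -> EnrichmentResult:
    """Fold enrichment of each unit in rare (I > high_min) vs common (I < low_max) k-mers.

    A zero low-group frequency yields an infinite fold unless ``pseudocount``
    adds one occurrence of the unit to both groups.
    """
    if high_min <= low_max:
        raise ValueError(f"high_min ({high_min}) must exceed low_max ({low_max})")
    high = [kmer for kmer, v in table.entries.items() if v > high_min]
    low = [kmer for kmer, v in table.entries.items() if v < low_max]
    if not high:
        raise EmptyStratumError(f"no k-mers with rarity index > {high_min}")
    if not low:
        raise EmptyStratumError(f"no k-mers with rarity index < {low_max}")
    units = _unit_alphabet(table.alphabet, unit_type)
    counts_high = _unit_counts(high, unit_type)
    counts_low = _unit_counts(low, unit_type)
    if pseudocount:
        for u in units:
            counts_high[u] += 1
            counts_low[u] += 1
    freq_high = _normalize(counts_high, units)
    freq_low = _normalize(counts_low, units)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(
            freq_low.to_numpy() > 0,
            freq_high.to_numpy() / freq_low.to_numpy(),
            np.where(freq_high.to_numpy() > 0, np.inf, np.nan),
        )
    out = pd.DataFrame(
        {"frequency_high": freq_high, "frequency_low": freq_low, "fold_ratio": fold},
        index=units,
    )
    return EnrichmentResult(unit_type=unit_type, high_min=high_min, low_max=low_max, table=out)


def _round_half_up(value: Fraction, digits: int) -> float:
    quant = Decimal(1).scaleb(-digits)
    dec = Decimal(value.numerator) / Decimal(value.denominator)
    return float(dec.quantize(quant, rounding=ROUND_HALF_UP))


def bin_rare_kmers(table: RarityTable, bin_digits: int = 3) -> dict[float, list[str]]:
    """Group the rarest quartile of k-mers by their rarity index rounded to ``bin_digits``.

    Rare k-mers are the top quartile by rarity index: those at or above the
    75th percentile of the table's values (ties at the boundary included).
    Three decimal digits suit most lengths; four and five resolve the nearly
    saturated indices of 12-mer oligonucleotides and 6-mer oligopeptides.
    """
    if bin_digits not in (3, 4, 5):
        raise ValueError(f"bin_digits must be 3, 4 or 5, got {bin_digits}")
    if len(table.entries) < 4:
        raise ValueError("top quartile undefined for fewer than 4 distinct k-mers")
    values = np.array([float(v) for v in table.entries.values()])
    threshold = np.quantile(values, 0.75)
    bins: dict[float, list[str]] = {}
    for kmer, value in table.entries.items():
        if float(value) >= threshold:
            bins.setdefault(_round_half_up(value, bin_digits), []).append(kmer)
    for kmers in bins.values():
        kmers.sort()
    return dict(sorted(bins.items()))


@dataclass
class RarityBinProfile:
    """Species x rarity-bin matrix of normalized rare-k-mer occurrence proportions."""

    bin_digits: int
    matrix: pd.DataFrame  # rows: species_id; columns: bin values (ascending)

    @property
    def bins(self) -> list[float]:
        return list(self.matrix.columns)


def species_occurrence_matrix(
    kmer_sets: Iterable[KmerSet],
    bins: dict[float, list[str]],
    bin_digits: int = 3,
) -> RarityBinProfile:
    """Cell (s, b) = |bin b's k-mers present in species s| / |distinct k-mers of s|.

    The denominator normalizes for genome/proteome size so species of very
    different sequence lengths are comparable.
    """
    bin_members = {b: frozenset(kmers) for b, kmers in bins.items()}
    rows: dict[str, dict[float, float]] = {}
    for ks in kmer_sets:
        denom = len(ks)
        if denom == 0:
            import logging

            logging.getLogger(__name__).warning(
                "species %r has no k-mers; occurrence row is zero", ks.species_id
            )
            rows[ks.species_id] = {b: 0.0 for b in bin_members}
            continue
        rows[ks.species_id] = {
            b: len(members & ks.kmers) / denom for b, members in bin_members.items()
        }
    matrix = pd.DataFrame(rows).T
    matrix = matrix[sorted(matrix.columns)]
    return RarityBinProfile(bin_digits=bin_digits, matrix=matrix)


@dataclass
class ClusteringResult:
    leaf_order: list[str]
    linkage: np.ndarray
    newick: str


def cluster_species(profile: RarityBinProfile) -> ClusteringResult:
    """Agglomerative clustering of species occurrence rows.

    Euclidean distance with average linkage (UPGMA), the defaults of the
    usual clustered-heatmap tooling.  Rows are pre-sorted by species_id so
    identical rows merge in a deterministic order.
    """
    matrix = profile.matrix.sort_index()
    if len(matrix) < 2:
        raise ValueError("need at least 2 species to cluster")
    distances = pdist(matrix.to_numpy(), metric="euclidean")
    linkage = hierarchy.linkage(distances, method="average")
    ids = list(matrix.index)
    order = [ids[i] for i in hierarchy.leaves_list(linkage)]
    tree = hierarchy.to_tree(linkage)
    return ClusteringResult(leaf_order=order, linkage=linkage, newick=_to_newick(tree, ids))


def _to_newick(node: hierarchy.ClusterNode, labels: list[str]) -> str:
    def render(nd: hierarchy.ClusterNode, parent_height: float) -> str:
        length = parent_height - nd.dist
        if nd.is_leaf():
            return f"{labels[nd.id]}:{length:.6g}"
        left = render(nd.left, nd.dist)
        right = render(nd.right, nd.dist)
        return f"({left},{right}):{length:.6g}"

    return render(node, node.dist) + ";"
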