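"""The rarity index and per-taxonomy rarity tables.

The rarity index of a k-mer K over a reference set of n species is

    I_K = |{i : K not in S_i}| / n,

the fraction of species from which K is absent: 0 means K occurs in every
species, 1 means K occurs in none ("prime" k-mers).  Indices are held as
exact rationals internally — I_K * n is always an integer — and converted
to float only at the edges, because downstream decimal-digit binning is
sensitive to representation error.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .corpus import NUCLEIC, SpeciesEntry
from .kmers import PresenceCount, alphabet_for, count_species_per_kmer

logger = logging.getLogger(__name__)

#: Largest |alphabet|**k universe that ``enumerate_absent`` will materialize.
#: 4**12 covers every nucleic length in routine use; protein universes beyond
#: 20**5 must stay implicit.
DEFAULT_UNIVERSE_CAP = 4**12


class UniverseCapError(ValueError):
    """Requested enumeration of an absent-k-mer universe above the cap."""


@dataclass
class RarityTable:
    """k-mer -> rarity index for one scope (global or a single taxon)."""

    scope: str
    k: int
    seq_type: str
    n: int
    entries: dict[str, Fraction]
    enumerated: bool = False

    @property
    def alphabet(self) -> str:
        return alphabet_for(self.seq_type)

    def get(self, kmer: str) -> Fraction:
        """Rarity of ``kmer``; absent k-mers have the implicit index 1."""
        return self.entries.get(kmer, Fraction(1))

    def __len__(self) -> int:
        return len(self.entries)

    def as_floats(self) -> dict[str, float]:
        return {kmer: float(v) for kmer, v in self.entries.items()}


def rarity_index(species_with: int, n: int) -> Fraction:
    """Exact rarity index (n - species_with) / n."""
    if n < 1:
        raise ValueError("rarity index undefined for an empty scope (n = 0)")
    if not 0 <= species_with <= n:
        raise ValueError(f"species_with must be in [0, {n}], got {species_with}")
    return Fraction(n - species_with, n)


def build_rarity_table(
    pc: PresenceCount,
    scope: str = "global",
    enumerate_absent: bool = False,
    universe_cap: int = DEFAULT_UNIVERSE_CAP,
) -> RarityTable:
    """Apply the rarity index to every counted k-mer.

    With ``enumerate_absent`` the full |alphabet|**k universe is materialized
    so that k-mers absent from every species appear explicitly with index 1;
    this is required for prime detection and refused above ``universe_cap``.
    """
    entries = {kmer: rarity_index(c, pc.n) for kmer, c in pc.counts.items()}
    if enumerate_absent:
        alphabet = alphabet_for(pc.seq_type)
        universe = len(alphabet) ** pc.k
        if universe > universe_cap:
            raise UniverseCapError(
                f"universe {len(alphabet)}^{pc.k} = {universe} exceeds cap {universe_cap}; "
                "raise universe_cap to enumerate absent k-mers at this length"
            )
        one = Fraction(1)
        for tup in itertools.product(alphabet, repeat=pc.k):
            kmer = "".join(tup)
            if kmer not in entries:
                entries[kmer] = one
    return RarityTable(
        scope=scope, k=pc.k, seq_type=pc.seq_type, n=pc.n, entries=entries,
        enumerated=enumerate_absent,
    )


def mean_rarity(pc: PresenceCount, include_absent: bool = True) -> float:
    """Mean rarity index, over the full universe or over observed k-mers only.

    Over the full universe the mean needs no enumeration:
    1 - (sum of presence counts) / (n * |alphabet|**k).
    """
    total = sum(pc.counts.values())
    if include_absent:
        universe = len(alphabet_for(pc.seq_type)) ** pc.k
        return 1.0 - total / (pc.n * universe)
    if not pc.counts:
        raise ValueError("no observed k-mers")
    return 1.0 - total / (pc.n * len(pc.counts))


def find_primes(table: RarityTable) -> set[str]:
    """k-mers absent from every species in scope (rarity index exactly 1)."""
    if not table.enumerated:
        raise ValueError("find_primes requires a table built with enumerate_absent=True")
    one = Fraction(1)
    return {kmer for kmer, v in table.entries.items() if v == one}


@dataclass
class TaxonRarityBundle:
    """One rarity table per taxonomy, all at the same k and alphabet."""

    tables: dict[str, RarityTable]

    def __getitem__(self, taxon: str) -> RarityTable:
        return self.tables[taxon]

    @property
    def taxa(self) -> list[str]:
        return list(self.tables)


def build_taxon_rarity_tables(
    corpus: Iterable[SpeciesEntry],
    k: int,
    enumerate_absent: bool = False,
    universe_cap: int = DEFAULT_UNIVERSE_CAP,
    canonical: bool = False,
) -> TaxonRarityBundle:
    """Rarity tables computed within each taxonomy separately.

    Streams the corpus once, keeping one presence counter per taxon.
    """
    groups: dict[str, list[SpeciesEntry]] = {}
    for entry in corpus:
        groups.setdefault(entry.taxonomy, []).append(entry)
    tables: dict[str, RarityTable] = {}
    for taxon, entries in groups.items():
        if not entries:  # pragma: no cover - defensive
            logger.warning("taxon %r has no species; omitted", taxon)
            continue
        pc = count_species_per_kmer(entries, k, canonical=canonical)
        tables[taxon] = build_rarity_table(
            pc, scope=taxon, enumerate_absent=enumerate_absent, universe_cap=universe_cap
        )
    return TaxonRarityBundle(tables=tables)


def cross_taxonomy_correlation(bundle: TaxonRarityBundle) -> "pd.DataFrame":
    """Spearman rank-correlation matrix of per-taxon rarity indices.

    Correlations are computed over the union of k-mers observed in any of
    the compared taxa; a k-mer unobserved in a taxon contributes its
    implicit rarity index of 1 there, so primes remain comparable.  A taxon
    whose rarity vector has zero variance yields NaN against the others.
    Returns the coefficient matrix; p-values are in ``.attrs['pvalues']``.
    """
    import pandas as pd

    taxa = bundle.taxa
    if len(taxa) < 2:
        raise ValueError("need at least two taxa to correlate")
    universe = sorted(set().union(*(bundle[t].entries.keys() for t in taxa)))
    mat = np.ones((len(taxa), len(taxa)))
    pvals = np.zeros((len(taxa), len(taxa)))
    vectors = {
        t: np.array([float(bundle[t].get(kmer)) for kmer in universe]) for t in taxa
    }
    for i, ti in enumerate(taxa):
        for j in range(i + 1, len(taxa)):
            tj = taxa[j]
            if np.ptp(vectors[ti]) == 0 or np.ptp(vectors[tj]) == 0:
                rho, p = np.nan, np.nan
            else:
                rho, p = stats.spearmanr(vectors[ti], vectors[tj])
            mat[i, j] = mat[j, i] = rho
            pvals[i, j] = pvals[j, i] = p
    out = pd.DataFrame(mat, index=taxa, columns=taxa)
    out.attrs["pvalues"] = pd.DataFrame(pvals, index=taxa, columns=taxa)
    return out


def taxonomy_discriminative_kmers(
    bundle: TaxonRarityBundle,
    rare_min: float = 0.95,
    common_max: float = 0.5,
) -> dict[str, set[str]]:
    """k-mers rarest in one taxonomy while remaining common in all others.

    A k-mer is assigned to taxon t when its rarity there is >= ``rare_min``
    and its rarity in every other taxon is <= ``common_max``.
    """
    if rare_min <= common_max:
        raise ValueError(f"rare_min ({rare_min}) must exceed common_max ({common_max})")
    taxa = bundle.taxa
    universe = set().union(*(bundle[t].entries.keys() for t in taxa))
    out: dict[str, set[str]] = {t: set() for t in taxa}
    for kmer in universe:
        values = {t: bundle[t].get(kmer) for t in taxa}
        for t in taxa:
            if values[t] >= rare_min and all(
                values[s] <= common_max for s in taxa if s != t
            ):
                out[t].add(kmer)
    return out


def write_rarity_tsv(table: RarityTable, path: str | Path, decimals: int = 6) -> None:
    """Emit ``kmer<TAB>rarity_index<TAB>species_with<TAB>n`` for one scope."""
    alphabet = "dna" if table.seq_type == NUCLEIC else "protein"
    with open(path, "w") as handle:
        handle.write(f"#scope={table.scope} #k={table.k} #n={table.n} #alphabet={alphabet}\n")
        handle.write("kmer\trarity_index\tspecies_with\tn\n")
        for kmer in sorted(table.entries):
            frac = table.entries[kmer]
            species_with = table.n - frac.numerator * table.n // frac.denominator
            handle.write(f"{kmer}\t{float(frac):.{decimals}f}\t{species_with}\t{table.n}\n")


def read_rarity_tsv(path: str | Path) -> RarityTable:
    with open(path) as handle:
        meta = dict(part.lstrip("#").split("=") for part in handle.readline().split())
        handle.readline()
        entries: dict[str, Fraction] = {}
        for line in handle:
            if not line.strip():
                continue
            kmer, _, species_with, n = line.rstrip("\n").split("\t")
            entries[kmer] = rarity_index(int(species_with), int(n))
    seq_type = NUCLEIC if meta["alphabet"] == "dna" else "peptide"
    return RarityTable(
        scope=meta["scope"], k=int(meta["k"]), seq_type=seq_type, n=int(meta["n"]),
        entries=entries,
    )


def _mapping_to_table(
    entries: Mapping[str, float], k: int, seq_type: str, n: int, scope: str = "global"
) -> RarityTable:
    """Build a table from float rarity values (n-quantized); test convenience."""
    exact = {kmer: Fraction(round(v * n), n) for kmer, v in entries.items()}
    return RarityTable(scope=scope, k=k, seq_type=seq_type, n=n, entries=exact)
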