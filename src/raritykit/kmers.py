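"""Per-species k-mer sets and cross-species presence counts.

For every species the set of distinct k-mers is the union, over all FASTA
records, of every length-k window made up entirely of canonical characters;
windows never span record boundaries and windows overlapping a flagged
(ambiguous) position are skipped.  Aggregation then counts, for each k-mer,
the number of species whose set contains it — the complement of the rarity
index numerator.  Species are processed one at a time so peak memory is one
species' set plus the aggregate map.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .corpus import DNA_ALPHABET, NUCLEIC, PROTEIN_ALPHABET, SpeciesEntry

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def alphabet_for(seq_type: str) -> str:
    return DNA_ALPHABET if seq_type == NUCLEIC else PROTEIN_ALPHABET


def reverse_complement(kmer: str) -> str:
    return kmer.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class KmerSet:
    """The distinct k-mers of one species."""

    species_id: str
    k: int
    seq_type: str
    kmers: frozenset[str]

    def __len__(self) -> int:
        return len(self.kmers)


@dataclass
class PresenceCount:
    """k-mer -> number of species containing it, over a corpus of ``n`` species.

    Absent k-mers are implicit: a k-mer not stored occurs in zero species.
    """

    k: int
    seq_type: str
    n: int
    counts: Counter

    def species_with(self, kmer: str) -> int:
        return self.counts.get(kmer, 0)


def extract_kmer_set(entry: SpeciesEntry, k: int, canonical: bool = False) -> KmerSet:
    """Distinct k-mers of one species.

    Flagged positions split each record into canonical runs and k-mers are
    enumerated within runs only.  With ``canonical=True`` (nucleic only)
    each k-mer is replaced by the lexicographic minimum of itself and its
    reverse complement, merging the two strands.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if canonical and entry.seq_type != NUCLEIC:
        raise ValueError("canonical (strand-merged) k-mers apply to nucleic sequences only")
    kmers: set[str] = set()
    for _, seq in entry.records:
        for run in _canonical_runs(seq.sequence, seq.flagged):
            for i in range(len(run) - k + 1):
                kmers.add(run[i : i + k])
    if canonical:
        kmers = {min(km, reverse_complement(km)) for km in kmers}
    return KmerSet(species_id=entry.species_id, k=k, seq_type=entry.seq_type, kmers=frozenset(kmers))


def _canonical_runs(sequence: str, flagged: frozenset[int]) -> Iterator[str]:
    if not flagged:
        yield sequence
        return
    start = 0
    for pos in sorted(flagged):
        if pos > start:
            yield sequence[start:pos]
        start = pos + 1
    if start < len(sequence):
        yield sequence[start:]


def count_species_per_kmer(
    corpus: Iterable[SpeciesEntry], k: int, canonical: bool = False
) -> PresenceCount:
    """Number of species each k-mer is found in (streaming aggregation)."""
    counts: Counter = Counter()
    n = 0
    seq_type: str | None = None
    for entry in corpus:
        if seq_type is None:
            seq_type = entry.seq_type
        elif entry.seq_type != seq_type:
            raise ValueError(
                f"mixed sequence types in corpus: {seq_type!r} then {entry.seq_type!r} "
                f"(species {entry.species_id!r})"
            )
        counts.update(extract_kmer_set(entry, k, canonical=canonical).kmers)
        n += 1
    if n == 0:
        raise ValueError("empty corpus: no species to count")
    assert seq_type is not None
    return PresenceCount(k=k, seq_type=seq_type, n=n, counts=counts)


def species_unique_kmer_counts(
    corpus: Iterable[SpeciesEntry], k: int, canonical: bool = False
) -> dict[str, int]:
    """Total number of distinct k-mers per species (the occurrence-matrix denominator)."""
    return {
        entry.species_id: len(extract_kmer_set(entry, k, canonical=canonical))
        for entry in corpus
    }


def write_presence_tsv(pc: PresenceCount, path: str | Path) -> None:
    """Emit ``kmer<TAB>species_count`` with a metadata header comment."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    alphabet = "dna" if pc.seq_type == NUCLEIC else "protein"
    with opener(path, "wt") as handle:
        handle.write(f"#k={pc.k} #n={pc.n} #alphabet={alphabet}\n")
        handle.write("kmer\tspecies_count\n")
        for kmer in sorted(pc.counts):
            handle.write(f"{kmer}\t{pc.counts[kmer]}\n")


def read_presence_tsv(path: str | Path) -> PresenceCount:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        meta_line = handle.readline().strip()
        meta = dict(part.lstrip("#").split("=") for part in meta_line.split())
        handle.readline()  # column header
        counts: Counter = Counter()
        for line in handle:
            if not line.strip():
                continue
            kmer, count = line.rstrip("\n").split("\t")
            counts[kmer] = int(count)
    seq_type = NUCLEIC if meta["alphabet"] == "dna" else "peptide"
    return PresenceCount(k=int(meta["k"]), seq_type=seq_type, n=int(meta["n"]), counts=counts)
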