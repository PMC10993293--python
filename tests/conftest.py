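"""Shared fixtures: programmatic corpora and an independent presence-count oracle."""

from __future__ import annotations

import random
from pathlib import Path

import pytest

from raritykit.corpus import (
    DNA_ALPHABET,
    NUCLEIC,
    PROTEIN_ALPHABET,
    SpeciesEntry,
    sanitize_sequence,
)


def make_entry(
    species_id: str,
    sequences: list[str],
    seq_type: str = NUCLEIC,
    taxonomy: str = "bacteria",
) -> SpeciesEntry:
    """Build an in-memory species from raw sequence strings."""
    entry = SpeciesEntry(species_id=species_id, taxonomy=taxonomy, seq_type=seq_type)
    for i, seq in enumerate(sequences):
        entry.records.append((f"{species_id}_r{i}", sanitize_sequence(seq, seq_type)))
    return entry


def random_corpus(
    rng: random.Random,
    n_species: int,
    max_len: int = 200,
    seq_type: str = NUCLEIC,
    ambiguity_rate: float = 0.02,
) -> list[SpeciesEntry]:
    """Random small corpus, with occasional ambiguity characters sprinkled in."""
    alphabet = DNA_ALPHABET if seq_type == NUCLEIC else PROTEIN_ALPHABET
    noise = "N" if seq_type == NUCLEIC else "X"
    entries = []
    for s in range(n_species):
        n_records = rng.randint(1, 3)
        seqs = []
        for _ in range(n_records):
            length = rng.randint(1, max_len)
            chars = [
                noise if rng.random() < ambiguity_rate else rng.choice(alphabet)
                for _ in range(length)
            ]
            seqs.append("".join(chars))
        entries.append(make_entry(f"sp{s}", seqs, seq_type=seq_type))
    return entries


def naive_species_kmers(entry: SpeciesEntry, k: int) -> set[str]:
    """Independent oracle: enumerate every window, then drop non-canonical ones.

    The implementation splits records into canonical runs before windowing;
    this oracle windows first and filters after, so they share no code path.
    """
    canonical = set(DNA_ALPHABET if entry.seq_type == NUCLEIC else PROTEIN_ALPHABET)
    kmers: set[str] = set()
    for _, seq in entry.records:
        s = seq.sequence
        for i in range(len(s) - k + 1):
            window = s[i : i + k]
            if all(c in canonical for c in window):
                kmers.add(window)
    return kmers


def naive_presence_counts(corpus: list[SpeciesEntry], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for entry in corpus:
        for kmer in naive_species_kmers(entry, k):
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def write_corpus(tmp_path: Path, corpus: list[SpeciesEntry]) -> Path:
    """Write entries as FASTA + manifest TSV; returns the manifest path."""
    from raritykit.corpus import write_species_fasta

    fasta_dir = tmp_path / "fasta"
    fasta_dir.mkdir(parents=True, exist_ok=True)
    manifest = tmp_path / "manifest.tsv"
    with open(manifest, "w") as handle:
        handle.write("species_id\ttaxonomy\tfasta_path\tseq_type\n")
        for entry in corpus:
            path = fasta_dir / f"{entry.species_id}.fasta"
            write_species_fasta(entry, path)
            handle.write(
                f"{entry.species_id}\t{entry.taxonomy}\tfasta/{path.name}\t{entry.seq_type}\n"
            )
    return manifest


@pytest.fixture
def toy_nucleic_corpus() -> list[SpeciesEntry]:
    """Two species with hand-enumerable 2-mer content."""
    return [make_entry("sp1", ["ACG"]), make_entry("sp2", ["CGT"])]
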