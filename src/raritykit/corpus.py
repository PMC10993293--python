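"""Species manifests and FASTA input.

A corpus is described by a tab-separated manifest with one row per species
(columns ``species_id``, ``taxonomy``, ``fasta_path``, ``seq_type``) and one
FASTA file per species, possibly multi-record and possibly gzip-compressed.
Sequences are sanitized on load: uppercased, whitespace removed, and every
position holding a character outside the canonical alphabet flagged so that
the k-mer engine can skip windows overlapping it.  Ambiguity codes and stop
codons are therefore never fatal; they simply break k-mer windows.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

NUCLEIC = "nucleic"
PEPTIDE = "peptide"
SEQ_TYPES = (NUCLEIC, PEPTIDE)

DNA_ALPHABET = "ACGT"
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_CANONICAL = {NUCLEIC: frozenset(DNA_ALPHABET), PEPTIDE: frozenset(PROTEIN_ALPHABET)}

MANIFEST_COLUMNS = ("species_id", "taxonomy", "fasta_path", "seq_type")


class ManifestError(ValueError):
    """Malformed or inconsistent manifest."""


class CorpusInputError(ValueError):
    """Unreadable or empty sequence input."""


@dataclass(frozen=True)
class SanitizedSequence:
    """An uppercased sequence plus the positions of non-canonical characters."""

    sequence: str
    flagged: frozenset[int]

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


@dataclass(frozen=True)
class ManifestRow:
    species_id: str
    taxonomy: str
    fasta_path: Path
    seq_type: str


@dataclass(frozen=True)
class Manifest:
    """Ordered list of species rows; ``n`` is the corpus size used by the rarity index."""

    entries: tuple[ManifestRow, ...]

    @property
    def n(self) -> int:
        return len(self.entries)

    @property
    def taxa(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for row in self.entries:
            seen.setdefault(row.taxonomy)
        return tuple(seen)

    def __iter__(self) -> Iterator[ManifestRow]:
        return iter(self.entries)


@dataclass
class SpeciesEntry:
    """One species' sanitized sequences plus its taxonomy label."""

    species_id: str
    taxonomy: str
    seq_type: str
    records: list[tuple[str, SanitizedSequence]] = field(default_factory=list)


def sanitize_sequence(raw: str, seq_type: str) -> SanitizedSequence:
    """Uppercase ``raw``, drop whitespace and flag non-canonical positions.

    Characters outside the canonical alphabet (ACGT for nucleic sequences,
    the 20 standard residues for peptides) are kept in place but their
    positions are recorded; downstream k-mer extraction skips any window
    that overlaps a flagged position.
    """
    if seq_type not in SEQ_TYPES:
        raise ValueError(f"unknown seq_type {seq_type!r}; expected one of {SEQ_TYPES}")
    cleaned = "".join(raw.split()).upper()
    canonical = _CANONICAL[seq_type]
    flagged = frozenset(i for i, c in enumerate(cleaned) if c not in canonical)
    return SanitizedSequence(cleaned, flagged)


def load_manifest(path: str | Path) -> Manifest:
    """Parse a manifest TSV, validating columns and species_id uniqueness."""
    path = Path(path)
    if not path.exists():
        raise CorpusInputError(f"manifest not found: {path}")
    with open(path) as handle:
        header_line = handle.readline()
        if not header_line.strip():
            raise ManifestError(f"manifest {path} is empty (no header row)")
        header = header_line.rstrip("\n").split("\t")
        missing = [c for c in MANIFEST_COLUMNS if c not in header]
        if missing:
            raise ManifestError(f"manifest {path} is missing column(s): {', '.join(missing)}")
        idx = {c: header.index(c) for c in MANIFEST_COLUMNS}
        rows: list[ManifestRow] = []
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < len(header):
                raise ManifestError(f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}")
            seq_type = parts[idx["seq_type"]]
            if seq_type not in SEQ_TYPES:
                raise ManifestError(f"{path}:{lineno}: seq_type must be one of {SEQ_TYPES}, got {seq_type!r}")
            fasta = Path(parts[idx["fasta_path"]])
            if not fasta.is_absolute():
                fasta = path.parent / fasta
            rows.append(
                ManifestRow(
                    species_id=parts[idx["species_id"]],
                    taxonomy=parts[idx["taxonomy"]],
                    fasta_path=fasta,
                    seq_type=seq_type,
                )
            )
    seen: dict[str, int] = {}
    for row in rows:
        if not row.species_id:
            raise ManifestError(f"manifest {path} contains an empty species_id")
        seen[row.species_id] = seen.get(row.species_id, 0) + 1
    dupes = sorted(sid for sid, c in seen.items() if c > 1)
    if dupes:
        raise ManifestError(f"duplicate species_id in manifest {path}: {', '.join(dupes)}")
    return Manifest(entries=tuple(rows))


def _open_text(path: Path) -> io.TextIOBase:
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_species_sequences(row: ManifestRow) -> SpeciesEntry:
    """Load and sanitize all FASTA records for one manifest row."""
    if not row.fasta_path.exists():
        raise CorpusInputError(f"FASTA not found for species {row.species_id!r}: {row.fasta_path}")
    entry = SpeciesEntry(species_id=row.species_id, taxonomy=row.taxonomy, seq_type=row.seq_type)
    with _open_text(row.fasta_path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            entry.records.append((record.id, sanitize_sequence(str(record.seq), row.seq_type)))
    if not entry.records:
        raise CorpusInputError(f"no FASTA records in {row.fasta_path} (species {row.species_id!r})")
    return entry


def iter_corpus(manifest: Manifest) -> Iterator[SpeciesEntry]:
    """Stream species one at a time, in manifest order."""
    for row in manifest:
        yield read_species_sequences(row)


def write_species_fasta(entry: SpeciesEntry, path: str | Path, width: int = 70) -> None:
    """Write a SpeciesEntry back to FASTA (round-trip partner of read_species_sequences)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as handle:
        for record_id, seq in entry.records:
            handle.write(f">{record_id}\n")
            for start in range(0, len(seq.sequence), width):
                handle.write(seq.sequence[start : start + width] + "\n")
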