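"""Synthetic corpora and regression sets with known ground truth.

Sequences are drawn from a first-order (dimer-weighted) Markov chain per
taxon, so dimer-level compositional signal — the level at which real
genomes differ most (TA depletion, CpG suppression, GC skew) — can be
planted and later recovered by the enrichment, clustering and model
stages.  Corpora are written as FASTA plus a manifest TSV in exactly the
schema the corpus reader consumes; everything is deterministic under a
seed.

The default corpus emulates the structure of a reference-genome/proteome
collection at desk scale: four taxa (archaea, bacteria, eukaryota,
viruses) with differing sequence-length distributions (eukaryotes longest,
viruses far shortest) and a distinct planted dimer bias per taxon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .corpus import Manifest, NUCLEIC, load_manifest
from .kmers import alphabet_for
from .models import build_sequence_features


@dataclass
class TaxonConfig:
    """One taxon's species count, length range and dimer composition weights."""

    name: str
    species_count: int
    length_range: tuple[int, int]
    dimer_weights: dict[str, float] = field(default_factory=dict)  # unnamed dimers weight 1

    def __post_init__(self) -> None:
        if self.species_count < 1:
            raise ValueError(f"taxon {self.name!r}: species_count must be >= 1")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError(f"taxon {self.name!r}: bad length_range {self.length_range}")
        if any(w < 0 for w in self.dimer_weights.values()):
            raise ValueError(f"taxon {self.name!r}: dimer weights must be nonnegative")


@dataclass
class CorpusConfig:
    taxa: list[TaxonConfig]
    seq_type: str = NUCLEIC
    seed: int = 0
    records_per_species: int = 1


def default_corpus_config(seed: int = 0) -> CorpusConfig:
    """Desk-scale nucleic corpus: 4 taxa, skewed sizes and planted dimer biases."""
    return CorpusConfig(
        taxa=[
            TaxonConfig("archaea", 4, (3000, 5000), {"GC": 2.0, "CG": 2.0}),
            TaxonConfig("bacteria", 10, (3000, 6000), {"TA": 0.15}),
            TaxonConfig("eukaryota", 6, (8000, 12000), {"CG": 0.1}),
            TaxonConfig("viruses", 12, (500, 1500), {}),
        ],
        seq_type=NUCLEIC,
        seed=seed,
    )


def _transition_matrix(alphabet: str, dimer_weights: dict[str, float]) -> np.ndarray:
    size = len(alphabet)
    index = {c: i for i, c in enumerate(alphabet)}
    weights = np.ones((size, size))
    for dimer, w in dimer_weights.items():
        if len(dimer) != 2 or any(c not in index for c in dimer):
            raise ValueError(f"dimer weight key {dimer!r} is not over the alphabet {alphabet!r}")
        weights[index[dimer[0]], index[dimer[1]]] = w
    row_sums = weights.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError("a symbol has zero total outgoing weight; chain would stall")
    return weights / row_sums[:, None]


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary monomer distribution of the chain (left Perron eigenvector)."""
    values, vectors = np.linalg.eig(transition.T)
    idx = int(np.argmin(np.abs(values - 1.0)))
    pi = np.real(vectors[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def expected_unit_frequencies(
    taxon: TaxonConfig, seq_type: str = NUCLEIC
) -> tuple[dict[str, float], dict[str, float]]:
    """Long-run monomer and dimer frequencies implied by a taxon's chain."""
    alphabet = alphabet_for(seq_type)
    P = _transition_matrix(alphabet, taxon.dimer_weights)
    pi = stationary_distribution(P)
    mono = {c: float(pi[i]) for i, c in enumerate(alphabet)}
    dimer = {
        a + b: float(pi[i] * P[i, j])
        for i, a in enumerate(alphabet)
        for j, b in enumerate(alphabet)
    }
    return mono, dimer


def sample_sequence(
    rng: np.random.Generator, length: int, transition: np.ndarray, alphabet: str
) -> str:
    pi = stationary_distribution(transition)
    cumulative = np.cumsum(transition, axis=1)
    symbols = np.empty(length, dtype=np.int64)
    symbols[0] = rng.choice(len(alphabet), p=pi)
    draws = rng.random(length - 1) if length > 1 else np.empty(0)
    for i in range(1, length):
        symbols[i] = np.searchsorted(cumulative[symbols[i - 1]], draws[i - 1], side="right")
    letters = np.frombuffer(alphabet.encode(), dtype=np.uint8)
    return letters[symbols].tobytes().decode()


def generate_corpus(cfg: CorpusConfig, out_dir: str | Path) -> Manifest:
    """Write per-species FASTA files and a manifest TSV; returns the loaded manifest."""
    out_dir = Path(out_dir)
    fasta_dir = out_dir / "fasta"
    fasta_dir.mkdir(parents=True, exist_ok=True)
    alphabet = alphabet_for(cfg.seq_type)
    rng = np.random.default_rng(cfg.seed)
    manifest_path = out_dir / "manifest.tsv"
    with open(manifest_path, "w") as mf:
        mf.write("species_id\ttaxonomy\tfasta_path\tseq_type\n")
        for taxon in cfg.taxa:
            transition = _transition_matrix(alphabet, taxon.dimer_weights)
            for i in range(taxon.species_count):
                species_id = f"{taxon.name}_{i:03d}"
                fasta_path = fasta_dir / f"{species_id}.fasta"
                with open(fasta_path, "w") as fh:
                    for rec in range(cfg.records_per_species):
                        length = int(rng.integers(taxon.length_range[0], taxon.length_range[1] + 1))
                        seq = sample_sequence(rng, length, transition, alphabet)
                        fh.write(f">{species_id}_r{rec}\n")
                        for start in range(0, len(seq), 70):
                            fh.write(seq[start : start + 70] + "\n")
                mf.write(f"{species_id}\t{taxon.name}\tfasta/{fasta_path.name}\t{cfg.seq_type}\n")
    return load_manifest(manifest_path)


def corpus_config_from_yaml(path: str | Path) -> CorpusConfig:
    """Load a corpus description from YAML (taxa, seq_type, seed)."""
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    taxa = [
        TaxonConfig(
            name=t["name"],
            species_count=int(t["species_count"]),
            length_range=tuple(t["length_range"]),
            dimer_weights={str(k): float(v) for k, v in (t.get("dimer_weights") or {}).items()},
        )
        for t in raw["taxa"]
    ]
    return CorpusConfig(
        taxa=taxa,
        seq_type=raw.get("seq_type", NUCLEIC),
        seed=int(raw.get("seed", 0)),
        records_per_species=int(raw.get("records_per_species", 1)),
    )


#: Planted effects for the default regression set: a strong TA signal (the
#: dinucleotide whose depletion dominates real genomes), an opposing CC
#: effect and a weak symmetric monomer pair.  Kept small enough that the
#: linear response almost never leaves [0, 1], so clipping is negligible.
DEFAULT_PLANTED_COEFFICIENTS = {"TA": 0.12, "CC": -0.08, "A": 0.04, "T": -0.04}


@dataclass
class PlantedRegressionSet:
    """Feature matrix plus rarity-like responses with known generating model."""

    X: "pd.DataFrame"
    y: np.ndarray
    coefficients: dict[str, float]
    intercept: float
    noise_sd: float


def planted_rarity_regression_set(
    k: int = 6,
    seq_type: str = NUCLEIC,
    coefficients: dict[str, float] | None = None,
    noise_sd: float = 0.02,
    n: int = 5000,
    intercept: float = 0.5,
    seed: int = 0,
) -> PlantedRegressionSet:
    """Random k-mers whose pseudo-rarity is a known linear function of composition.

    y = clip(intercept + sum_f coef_f * count_f + N(0, noise_sd), 0, 1).
    """
    import pandas as pd  # local: keep module import light

    alphabet = alphabet_for(seq_type)
    rng = np.random.default_rng(seed)
    letters = np.array(list(alphabet))
    kmers = ["".join(row) for row in letters[rng.integers(0, len(letters), size=(n, k))]]
    X = build_sequence_features(kmers, seq_type)
    coefficients = dict(DEFAULT_PLANTED_COEFFICIENTS if coefficients is None else coefficients)
    unknown = sorted(set(coefficients) - set(X.columns))
    if unknown:
        raise ValueError(f"planted coefficients reference unknown features: {unknown}")
    coef_vec = np.array([coefficients.get(c, 0.0) for c in X.columns])
    y = intercept + X.to_numpy() @ coef_vec
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    y = np.clip(y, 0.0, 1.0)
    return PlantedRegressionSet(
        X=X, y=y, coefficients=coefficients, intercept=intercept, noise_sd=noise_sd
    )
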