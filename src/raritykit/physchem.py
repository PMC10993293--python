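"""Physicochemical descriptors of peptide k-mers.

Eight classical descriptors used as the biochemical feature space for
rarity models: average molecular weight, isoelectric point and net charge
under the EMBOSS pKa set, mean Kyte-Doolittle hydrophobicity, Eisenberg
hydrophobic moment at the alpha-helical 100 deg periodicity, the Boman
protein-interaction index, Ikai's aliphatic index and the Guruprasad
instability index.  All are computed from published per-residue (or, for
instability, per-dipeptide) scales over the 20 standard amino acids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from Bio.SeqUtils.ProtParamData import DIWV as _DIWV  # Guruprasad et al. dipeptide weights

from .corpus import PROTEIN_ALPHABET

#: Average (isotope-abundance weighted) residue masses, Da; a free peptide
#: adds one water (18.0153 Da).
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

#: Kyte & Doolittle (1982) hydropathy.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Eisenberg et al. (1984) consensus hydrophobicity, used for the moment.
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29, "Q": -0.85,
    "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38, "L": 1.06, "K": -1.50,
    "M": 0.64, "F": 1.19, "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81,
    "Y": 0.26, "V": 1.08,
}

#: EMBOSS pKa set (as in the EMBOSS `charge`/`iep` programs).
EMBOSS_PKA_BASIC = {"nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
EMBOSS_PKA_ACIDIC = {"cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}

#: Boman (2003) per-residue solubility values (cyclohexane-to-water side-chain
#: transfer free energies, kcal/mol; hydrophilic residues positive, Pro
#: unmeasured and set to 0).
BOMAN = {
    "L": -4.92, "I": -4.92, "V": -4.04, "F": -2.98, "M": -2.35, "W": -2.33,
    "A": -1.81, "C": -1.28, "G": -0.94, "Y": -0.14, "P": 0.0, "T": 2.57,
    "S": 3.40, "H": 4.66, "Q": 5.54, "K": 5.55, "N": 6.64, "E": 6.81,
    "D": 8.72, "R": 14.92,
}

#: Feature order used throughout the package.
DESCRIPTOR_COLUMNS = (
    "molecular_weight",
    "isoelectric_point",
    "net_charge",
    "hydrophobicity",
    "hydrophobic_moment",
    "boman_index",
    "aliphatic_index",
    "instability_index",
)

_CANONICAL = frozenset(PROTEIN_ALPHABET)


def _validate(peptide: str) -> str:
    if not peptide:
        raise ValueError("empty peptide")
    bad = sorted(set(peptide) - _CANONICAL)
    if bad:
        raise ValueError(f"non-canonical residue(s) {''.join(bad)!r} in peptide {peptide!r}")
    return peptide


def molecular_weight(peptide: str) -> float:
    """Average molecular weight in Da (residue masses plus one water)."""
    _validate(peptide)
    return sum(RESIDUE_MASS[r] for r in peptide) + WATER_MASS


def net_charge(peptide: str, pH: float = 7.0) -> float:
    """Net charge at ``pH`` by the Henderson-Hasselbalch sum, EMBOSS pKa set.

    Free termini are always titrated; His, Lys, Arg, Asp, Glu, Cys and Tyr
    side chains contribute per occurrence.
    """
    _validate(peptide)
    if not 0 < pH < 14:
        raise ValueError(f"pH must lie in (0, 14), got {pH}")
    charge = 1.0 / (1.0 + 10 ** (pH - EMBOSS_PKA_BASIC["nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (EMBOSS_PKA_ACIDIC["cterm"] - pH))
    for residue in peptide:
        if residue in EMBOSS_PKA_BASIC:
            charge += 1.0 / (1.0 + 10 ** (pH - EMBOSS_PKA_BASIC[residue]))
        elif residue in EMBOSS_PKA_ACIDIC:
            charge -= 1.0 / (1.0 + 10 ** (EMBOSS_PKA_ACIDIC[residue] - pH))
    return charge


def isoelectric_point(peptide: str, tol: float = 1e-4) -> float:
    """pH at which the net charge vanishes, by bisection on (0, 14).

    The charge is strictly decreasing in pH, so the root is unique.
    """
    _validate(peptide)
    lo, hi = 1e-9, 14.0 - 1e-9
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(peptide, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def mean_hydrophobicity(peptide: str) -> float:
    """Arithmetic mean of Kyte-Doolittle hydropathy values (the GRAVY score)."""
    _validate(peptide)
    return sum(KYTE_DOOLITTLE[r] for r in peptide) / len(peptide)


def hydrophobic_moment(peptide: str, angle_deg: float = 100.0) -> float:
    """Mean vector magnitude of Eisenberg hydrophobicities at ``angle_deg`` spacing.

    mu_H = sqrt((sum h_j sin(j*delta))^2 + (sum h_j cos(j*delta))^2) / L,
    the classical amphipathicity measure; 100 deg is the alpha-helical turn.
    """
    _validate(peptide)
    delta = math.radians(angle_deg)
    sin_sum = sum(EISENBERG[r] * math.sin(j * delta) for j, r in enumerate(peptide, start=1))
    cos_sum = sum(EISENBERG[r] * math.cos(j * delta) for j, r in enumerate(peptide, start=1))
    return math.hypot(sin_sum, cos_sum) / len(peptide)


def boman_index(peptide: str) -> float:
    """Mean Boman solubility value, kcal/mol per residue; high values mark
    peptides more prone to protein-protein interaction than membrane binding."""
    _validate(peptide)
    return sum(BOMAN[r] for r in peptide) / len(peptide)


def aliphatic_index(peptide: str) -> float:
    """Ikai (1980) aliphatic index: 100*(f_A + 2.9 f_V + 3.9 (f_I + f_L))."""
    _validate(peptide)
    length = len(peptide)
    f = {r: peptide.count(r) / length for r in "AVIL"}
    return 100.0 * (f["A"] + 2.9 * f["V"] + 3.9 * (f["I"] + f["L"]))


def instability_index(peptide: str) -> float:
    """Guruprasad et al. (1990) instability index, (10/L) * sum of dipeptide weights."""
    _validate(peptide)
    if len(peptide) < 2:
        raise ValueError("instability index undefined for a single residue")
    total = sum(_DIWV[a][b] for a, b in zip(peptide, peptide[1:]))
    return 10.0 / len(peptide) * total


@dataclass(frozen=True)
class PhyschemVector:
    """The eight descriptors of one peptide, in DESCRIPTOR_COLUMNS order."""

    molecular_weight: float
    isoelectric_point: float
    net_charge: float
    hydrophobicity: float
    hydrophobic_moment: float
    boman_index: float
    aliphatic_index: float
    instability_index: float


def describe_peptide(peptide: str, pH: float = 7.0) -> PhyschemVector:
    return PhyschemVector(
        molecular_weight=molecular_weight(peptide),
        isoelectric_point=isoelectric_point(peptide),
        net_charge=net_charge(peptide, pH),
        hydrophobicity=mean_hydrophobicity(peptide),
        hydrophobic_moment=hydrophobic_moment(peptide),
        boman_index=boman_index(peptide),
        aliphatic_index=aliphatic_index(peptide),
        instability_index=instability_index(peptide),
    )


def physchem_features(kmers: list[str], pH: float = 7.0) -> pd.DataFrame:
    """Descriptor matrix: one row per k-mer, eight columns, stable order."""
    rows = [describe_peptide(kmer, pH) for kmer in kmers]
    return pd.DataFrame(
        [[getattr(v, c) for c in DESCRIPTOR_COLUMNS] for v in rows],
        index=pd.Index(kmers, name="kmer"),
        columns=list(DESCRIPTOR_COLUMNS),
    )
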