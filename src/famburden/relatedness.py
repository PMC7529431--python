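"""Pairwise kinship from genotypes via the KING-robust estimator.

For a sample pair (i, j) over jointly non-missing sites,

    phi = (N_het,het - 2 * N_opp) / (N_het(i) + N_het(j))

where ``N_het,het`` counts sites at which both samples are heterozygous,
``N_opp`` counts opposite homozygotes (dosage 0 vs 2) and ``N_het(.)``
counts heterozygous sites per sample.  This is the between-family form
of the estimator (the one run by ``vcftools --relatedness2``); it needs
no allele-frequency input and is robust to population structure.
Relationship degrees follow the standard powers-of-two kinship bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Sequence

import numpy as np

from .datatypes import MISSING, GenotypeMatrix, SampleRecord
from .exceptions import UndefinedKinshipError

__all__ = [
    "KinshipEstimate",
    "king_kinship",
    "classify_degree",
    "relatedness_matrix",
    "DEGREE_BOUNDS",
]

# Upper kinship bound of each band: > 2^-1.5 duplicate/MZ, then first,
# second, third degree down to unrelated below 2^-4.5.
_B1 = 2 ** -1.5  # 0.3536
_B2 = 2 ** -2.5  # 0.1768
_B3 = 2 ** -3.5  # 0.0884
_B4 = 2 ** -4.5  # 0.0442
DEGREE_BOUNDS = (_B1, _B2, _B3, _B4)


@dataclass(frozen=True)
class KinshipEstimate:
    sample_i: str
    sample_j: str
    phi: float
    n_informative: int
    degree: str


def classify_degree(phi: float) -> str:
    """Map a kinship coefficient to a relationship-degree label."""
    if not np.isfinite(phi):
        raise ValueError(f"non-finite kinship {phi}")
    if phi > _B1:
        return "duplicate_or_MZ"
    if phi > _B2:
        return "first"
    if phi > _B3:
        return "second"
    if phi > _B4:
        return "third"
    return "unrelated"


def _pair_phi(gi: np.ndarray, gj: np.ndarray) -> tuple[float, int]:
    shared = (gi != MISSING) & (gj != MISSING)
    gi = gi[shared]
    gj = gj[shared]
    het_i = gi == 1
    het_j = gj == 1
    n_het_i = int(het_i.sum())
    n_het_j = int(het_j.sum())
    n_hh = int((het_i & het_j).sum())
    n_opp = int((((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))).sum())
    denom = n_het_i + n_het_j
    n_informative = n_hh + n_opp + int((het_i ^ het_j).sum())
    if denom == 0:
        raise UndefinedKinshipError(
            f"kinship undefined: no heterozygous shared site for the pair"
        )
    return (n_hh - 2.0 * n_opp) / denom, n_informative


def king_kinship(genotypes: GenotypeMatrix, i: str, j: str) -> KinshipEstimate:
    """KING-robust kinship for one sample pair.

    Sites with either sample missing are dropped pairwise; monomorphic
    and jointly homozygous-concordant sites contribute nothing to the
    numerator or denominator and are therefore skipped implicitly.
    """
    phi, n_inf = _pair_phi(genotypes.sample_row(i), genotypes.sample_row(j))
    return KinshipEstimate(i, j, phi, n_inf, classify_degree(phi))


def relatedness_matrix(
    genotypes: GenotypeMatrix, samples: Sequence[SampleRecord] | Sequence[str] | None = None
) -> list[KinshipEstimate]:
    """All unordered sample pairs, ordered lexicographically by id."""
    if samples is None:
        ids = list(genotypes.samples)
    else:
        ids = [s.sample_id if isinstance(s, SampleRecord) else s for s in samples]
    if len(ids) < 2:
        raise ValueError("relatedness matrix needs at least two samples")
    estimates = []
    for a_pos in range(len(ids)):
        for b_pos in range(a_pos + 1, len(ids)):
            a, b = sorted((ids[a_pos], ids[b_pos]))
            estimates.append(king_kinship(genotypes, a, b))
    estimates.sort(key=lambda e: (e.sample_i, e.sample_j))
    return estimates


def expected_kinship(degree: str) -> float:
    """Theoretical kinship for a relationship class (outbred pedigree)."""
    return {
        "duplicate_or_MZ": 0.5,
        "first": 0.25,
        "second": 0.125,
        "third": 0.0625,
        "unrelated": 0.0,
    }[degree]
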