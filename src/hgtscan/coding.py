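"""Coding-property convergence analysis.

Each coding sequence becomes an 81-feature profile: 4 nucleotide, 16
dinucleotide and 61 sense-codon frequencies (stop codons excluded from both
numerator and denominator), each block normalized to sum 1.  Profiles are
compared with the symmetric chi-square histogram distance
d(p, q) = sum_i (p_i - q_i)^2 / (p_i + q_i), skipping features absent from
both.  A focal transcript is called Vitis-like when its smallest distance
to a host-side homologue in the cluster beats its smallest distance to a
Malpighiales-side homologue (ties conservatively go Malpighiales-like).
An excess of Vitis-like calls over the control (background) rate is tested
with an exact upper-tail binomial test; the relation between host-likeness
and expression uses Spearman rank correlation on the affinity margin vs
RPKM.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .io import SequenceRecord
from .simulate import SENSE_CODONS
from .taxa import HOST_PROXY

__all__ = [
    "CodingProfile",
    "AffinityCall",
    "profile_transcript",
    "chi2_distance",
    "classify_affinity",
    "affinity_rates",
    "exact_binomial_test",
    "expression_affinity_correlation",
    "MALPIGHIALES_COMPARATORS",
]

NUCLEOTIDES = ("A", "C", "G", "T")
DINUCLEOTIDES = tuple("".join(p) for p in itertools.product("ACGT", repeat=2))
#: Malpighiales-side comparison genomes for a parasite focal transcript.
MALPIGHIALES_COMPARATORS = frozenset({"Manihot", "Ricinus"})

_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
_NT_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}
_DI_INDEX = {d: i for i, d in enumerate(DINUCLEOTIDES)}


@dataclass(frozen=True)
class CodingProfile:
    """81-dimensional coding-property profile of one transcript."""

    transcript_id: str
    nt: np.ndarray  # 4
    dint: np.ndarray  # 16
    codon: np.ndarray  # 61

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.nt, self.dint, self.codon])


def profile_transcript(record: SequenceRecord) -> CodingProfile:
    """Count nucleotide, dinucleotide and in-frame codon frequencies.

    N bases are excluded from every count; a trailing partial codon is
    dropped from the codon block; stop codons are excluded entirely.
    Raises on sequences without at least one complete codon of ACGT bases.
    """
    seq = record.seq
    nt = np.zeros(4)
    for ch in seq:
        if ch in _NT_INDEX:
            nt[_NT_INDEX[ch]] += 1
    if nt.sum() == 0:
        raise ValidationError(f"{record.id}: no countable bases")
    dint = np.zeros(16)
    for i in range(len(seq) - 1):
        d = seq[i : i + 2]
        if d in _DI_INDEX:
            dint[_DI_INDEX[d]] += 1
    codon = np.zeros(61)
    for i in range(0, len(seq) - 2, 3):
        c = seq[i : i + 3]
        if c in _CODON_INDEX:  # skips stops and codons containing N
            codon[_CODON_INDEX[c]] += 1
    if codon.sum() == 0:
        raise ValidationError(
            f"{record.id}: no complete sense codon (length {len(seq)})"
        )
    nt /= nt.sum()
    if dint.sum() > 0:
        dint /= dint.sum()
    codon /= codon.sum()
    return CodingProfile(record.id, nt, dint, codon)


def chi2_distance(p: CodingProfile, q: CodingProfile) -> float:
    """Symmetric chi-square distance over the concatenated 81 features,
    skipping features where p_i + q_i = 0."""
    pv, qv = p.vector, q.vector
    s = pv + qv
    mask = s > 0
    d = (pv - qv)[mask]
    return float(np.sum(d * d / s[mask]))


@dataclass(frozen=True)
class AffinityCall:
    transcript_id: str
    nearest_genome: str
    nearest_distance: float
    margin: float  # smallest Malpighiales distance - smallest Vitis distance
    label: str  # "Malpighiales-like" | "Vitis-like"


def classify_affinity(
    focal: CodingProfile,
    cluster_profiles: Mapping[str, Sequence[CodingProfile]],
    malpighiales_side: frozenset[str] = MALPIGHIALES_COMPARATORS,
    vitis_side: frozenset[str] = frozenset({HOST_PROXY}),
) -> AffinityCall | None:
    """Nearest-genome affinity call by smallest chi-square distance.

    ``cluster_profiles`` maps genome name to that genome's homologue
    profiles within the cluster.  Returns ``None`` (transcript excluded,
    not defaulted) when either comparison side has no homologue.
    """
    best: dict[str, tuple[float, str]] = {}
    for side, genomes in (("malp", malpighiales_side), ("vitis", vitis_side)):
        dists = [
            (chi2_distance(focal, prof), genome)
            for genome in genomes
            for prof in cluster_profiles.get(genome, [])
        ]
        if not dists:
            return None
        best[side] = min(dists)
    margin = best["malp"][0] - best["vitis"][0]
    nearest = min(best.values())
    return AffinityCall(
        transcript_id=focal.transcript_id,
        nearest_genome=nearest[1],
        nearest_distance=nearest[0],
        margin=margin,
        label="Vitis-like" if margin > 0 else "Malpighiales-like",
    )


def affinity_rates(calls_by_genome: Mapping[str, Sequence[AffinityCall]]) -> dict:
    """Per-focal-genome Vitis-like percentage with explicit numerator and
    denominator; an empty call set reports ``None``, never zero."""
    out = {}
    for genome, calls in calls_by_genome.items():
        n = len(calls)
        k = sum(1 for c in calls if c.label == "Vitis-like")
        out[genome] = {
            "n_vitis_like": k,
            "n_total": n,
            "pct_vitis_like": None if n == 0 else 100.0 * k / n,
        }
    return out


def exact_binomial_test(k: int, n: int, p0: float, tail: str = "upper") -> float:
    """Exact binomial tail probability, computed in log space.

    Upper tail: P(X >= k) for X ~ Binomial(n, p0); lower: P(X <= k).
    """
    if not 0 <= k <= n or n < 1:
        raise ValidationError(f"invalid counts k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValidationError(f"null proportion p0={p0} outside (0, 1)")
    if tail not in ("upper", "lower"):
        raise ValidationError(f"unknown tail {tail!r}")
    js = range(k, n + 1) if tail == "upper" else range(0, k + 1)
    log_p0, log_q0 = math.log(p0), math.log1p(-p0)
    log_terms = [
        math.lgamma(n + 1)
        - math.lgamma(j + 1)
        - math.lgamma(n - j + 1)
        + j * log_p0
        + (n - j) * log_q0
        for j in js
    ]
    m = max(log_terms)
    total = m + math.log(sum(math.exp(t - m) for t in log_terms))
    return min(1.0, math.exp(total))


def expression_affinity_correlation(
    calls: Sequence[AffinityCall],
    rpkm_by_transcript: Mapping[str, float],
) -> dict:
    """Spearman rank correlation between the affinity margin (larger =
    more Vitis-like) and RPKM; undefined (flagged) when either variable is
    constant or fewer than three transcripts pair up."""
    pairs = [
        (c.margin, rpkm_by_transcript[c.transcript_id])
        for c in calls
        if c.transcript_id in rpkm_by_transcript
    ]
    if len(pairs) < 3:
        return {"rho": None, "p": None, "n": len(pairs), "defined": False}
    margins, rpkms = zip(*pairs)
    if len(set(margins)) == 1 or len(set(rpkms)) == 1:
        return {"rho": None, "p": None, "n": len(pairs), "defined": False}
    rho, p = stats.spearmanr(margins, rpkms)
    return {"rho": float(rho), "p": float(p), "n": len(pairs), "defined": True}
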