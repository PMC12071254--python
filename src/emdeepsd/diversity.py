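"""Motif diversity scores and founder-profile deconvolution.

The motif diversity score (MDS) is the normalised Shannon entropy of a
256-motif frequency profile,

    MDS = sum_i -P_i * log(P_i) / log(256),

so it lies in [0, 1] with 1 at the uniform profile. Decomposition
subsequences can carry negative values, so their diversity variant
(MDS_Sub) first maps the subsequence through a softmax and then applies
the same normalised entropy. Two composites summarise a decomposition:
MDS-SSA is the singular-value-weighted mean of the three SSA subsequence
scores, and MDS-EMD is the plain mean of the two EMD subsequence scores.

A sample's profile can also be expressed as a non-negative mixture of six
"founder" end-motif profiles (F-profiles, each tied to a nuclease
cleavage signature); the mixture weights are estimated by non-negative
least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

from .decomposition import SSADecomposition, EMDDecomposition

N_MOTIFS = 256
_LOG_N = np.log(N_MOTIFS)

SUBSEQUENCE_NAMES_SSA = ("SSA1", "SSA2", "SSA3")
SUBSEQUENCE_NAMES_EMD = ("EMD1", "EMD2")


@dataclass
class DiversityScores:
    """MDS plus the seven decomposition-based diversity scores."""

    mds: float
    mds_sub: dict[str, float]  # keys SSA1..SSA3, EMD1, EMD2
    mds_ssa: float
    mds_emd: float


@dataclass
class ContributionVector:
    """Non-negative founder-profile mixture weights for one sample."""

    p: np.ndarray  # length 6, >= 0
    residual_norm: float

    @property
    def as_percent(self) -> np.ndarray:
        total = self.p.sum()
        if total == 0:
            return np.zeros_like(self.p)
        return 100.0 * self.p / total


def mds(frequencies: np.ndarray) -> float:
    """Normalised Shannon entropy of a frequency profile, in [0, 1]."""
    p = np.asarray(frequencies, dtype=float)
    if p.size != N_MOTIFS:
        raise ValueError(f"expected {N_MOTIFS} frequencies, got {p.size}")
    if (p < 0).any():
        raise ValueError("frequencies must be non-negative")
    total = p.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"frequencies must sum to 1 (got {total:.8f})")
    nz = p[p > 0]  # 0 * log 0 := 0
    return float(-np.sum(nz * np.log(nz)) / _LOG_N) + 0.0


def softmax_normalize(q: np.ndarray) -> np.ndarray:
    """Shift-invariant softmax; output is positive and sums to 1."""
    q = np.asarray(q, dtype=float)
    if not np.isfinite(q).all():
        raise ValueError("softmax input must be finite")
    z = np.exp(q - q.max())
    return z / z.sum()


def mds_sub(subsequence: np.ndarray) -> float:
    """Diversity of a decomposition subsequence: entropy after softmax."""
    return mds(softmax_normalize(subsequence))


def mds_ssa(sub_scores: Sequence[float], singular_values: np.ndarray) -> float:
    """Singular-value-weighted mean of the three SSA subsequence scores.

    Weights are the grouped singular-value masses (lambda_1; lambda_2 +
    lambda_3; lambda_4..lambda_8) normalised to sum to 1, so the score is
    invariant to the overall scale of the series.
    """
    s = np.asarray(singular_values, dtype=float)
    scores = np.asarray(sub_scores, dtype=float)
    if scores.size != 3:
        raise ValueError("expected 3 SSA subsequence scores")
    total = s.sum()
    if total <= 0:
        raise ValueError("all singular values are zero")
    w = np.array([s[0], s[1:3].sum(), s[3:8].sum()]) / total
    return float(np.dot(w, scores))


def mds_emd(sub_scores: Sequence[float]) -> float:
    """Mean of the two EMD subsequence scores."""
    scores = np.asarray(sub_scores, dtype=float)
    if scores.size != 2:
        raise ValueError("expected 2 EMD subsequence scores")
    return float(scores.mean())


def diversity_scores(
    frequencies: np.ndarray,
    ssa: SSADecomposition,
    emd: EMDDecomposition,
) -> DiversityScores:
    """All eight diversity scores for one sample's profile."""
    sub = {
        name: mds_sub(series)
        for name, series in zip(SUBSEQUENCE_NAMES_SSA, ssa.subsequences)
    }
    sub.update(
        {
            name: mds_sub(series)
            for name, series in zip(SUBSEQUENCE_NAMES_EMD, emd.subsequences)
        }
    )
    return DiversityScores(
        mds=mds(frequencies),
        mds_sub=sub,
        mds_ssa=mds_ssa(
            [sub["SSA1"], sub["SSA2"], sub["SSA3"]], ssa.singular_values
        ),
        mds_emd=mds_emd([sub["EMD1"], sub["EMD2"]]),
    )


@dataclass
class FounderMatrix:
    """256 x 6 matrix of founder end-motif profiles (columns F-I..F-VI)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_MOTIFS, 6):
            raise ValueError("founder matrix must be 256 x 6")
        if (self.values < 0).any():
            raise ValueError("founder matrix must be non-negative")


def deconvolve(profile: np.ndarray, founders: FounderMatrix) -> ContributionVector:
    """Non-negative least-squares mixture of the six founder profiles.

    Minimises ||profile - F p||_2 subject to p >= 0 and reports the
    residual norm alongside the weights.
    """
    a = np.asarray(profile, dtype=float)
    if a.size != N_MOTIFS:
        raise ValueError(
            f"profile has {a.size} entries; founder rows expect {N_MOTIFS} "
            "(motif row order must match)"
        )
    p, rnorm = nnls(founders.values, a)
    return ContributionVector(p=p, residual_norm=float(rnorm))
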