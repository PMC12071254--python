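"""Signal decomposition of end-motif series.

Two decompositions of the 256-point end-motif frequency series are
supported:

* **Singular spectrum analysis (SSA)** — embed the series into an L x K
  Hankel trajectory matrix, take its SVD, group the rank-1 components (by
  default the 1st, 2nd-3rd and 4th-8th singular triples with L = 8), and
  map each group back to a length-N series by anti-diagonal averaging.
  The three reconstructed subsequences SSA1-SSA3 sum exactly to the input.

* **Empirical mode decomposition (EMD)** — iterative sifting with cubic
  spline envelopes yields intrinsic mode functions (IMFs) plus a monotone
  residual. IMFs are then pooled by normalised permutation entropy into a
  high-PE subsequence E1 (PE >= 0.8) and a low-PE subsequence E2 (the rest
  plus the residual), so every sample yields exactly two subsequences
  regardless of how many IMFs sifting produced.

Both decompositions are deterministic and additively complete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline

DEFAULT_SSA_WINDOW = 8
#: 1-based component groups: trend, oscillatory pair, remainder
DEFAULT_SSA_GROUPING: tuple[tuple[int, ...], ...] = (
    (1,),
    (2, 3),
    (4, 5, 6, 7, 8),
)
DEFAULT_PE_THRESHOLD = 0.8


@dataclass
class SSADecomposition:
    singular_values: np.ndarray  # length L, non-increasing, >= 0
    grouping: tuple[tuple[int, ...], ...]
    subsequences: list[np.ndarray]  # one length-N series per group

    @property
    def group_weights(self) -> np.ndarray:
        """Singular-value mass of each group, normalised to sum to 1."""
        total = self.singular_values.sum()
        if total <= 0:
            raise ValueError("all singular values are zero")
        return np.array(
            [self.singular_values[[i - 1 for i in g]].sum() for g in self.grouping]
        ) / total


@dataclass
class EMDDecomposition:
    imfs: list[np.ndarray]
    residual: np.ndarray
    pe_values: np.ndarray  # one PE per IMF, in [0, 1]
    subsequences: list[np.ndarray]  # [E1 (high-PE), E2 (low-PE + residual)]


def embed(series: np.ndarray, L: int) -> np.ndarray:
    """Hankel trajectory matrix of shape L x (N - L + 1)."""
    series = np.asarray(series, dtype=float)
    n = series.size
    if not 2 <= L <= n // 2:
        raise ValueError(f"window length must satisfy 2 <= L <= N/2 "
                         f"(N={n}, got L={L})")
    k = n - L + 1
    # row i holds series[i : i + K]
    idx = np.arange(L)[:, None] + np.arange(k)[None, :]
    return series[idx]


def _diagonal_average(matrix: np.ndarray, n: int) -> np.ndarray:
    """Average a rank-grouped trajectory matrix back to a length-n series.

    Entry (i, j) contributes to series position i + j; each anti-diagonal
    is averaged with its element count as weight.
    """
    L, K = matrix.shape
    idx = (np.arange(L)[:, None] + np.arange(K)[None, :]).ravel()
    sums = np.bincount(idx, weights=matrix.ravel(), minlength=n)
    counts = np.bincount(idx, minlength=n)
    return sums / counts


def ssa_decompose(
    series: np.ndarray,
    L: int = DEFAULT_SSA_WINDOW,
    grouping: Sequence[Sequence[int]] = DEFAULT_SSA_GROUPING,
) -> SSADecomposition:
    """SSA with component grouping; returns one subsequence per group.

    ``grouping`` uses 1-based component indices and must partition
    {1, ..., L}. Groups are summed in the rank-1 expansion before
    anti-diagonal averaging, so the subsequences add back to the input
    exactly (up to float round-off).
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    grouping = tuple(tuple(int(i) for i in g) for g in grouping)
    flat = sorted(i for g in grouping for i in g)
    if flat != list(range(1, L + 1)):
        raise ValueError(f"grouping must partition {{1..{L}}}, got {grouping}")
    X = embed(series, L)
    # economy SVD of the L x K trajectory matrix; L <= K by construction
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    subsequences = []
    for group in grouping:
        idx = [i - 1 for i in group]
        Xg = (U[:, idx] * s[idx]) @ Vt[idx, :]
        subsequences.append(_diagonal_average(Xg, n))
    return SSADecomposition(
        singular_values=s, grouping=grouping, subsequences=subsequences
    )


# ---------------------------------------------------------------------------
# EMD


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict interior local maxima and minima."""
    d = np.diff(x)
    # treat flat runs by carrying the sign of the last non-zero difference
    sign = np.sign(d)
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    turn = np.diff(sign)
    maxima = np.where(turn < 0)[0] + 1
    minima = np.where(turn > 0)[0] + 1
    return maxima, minima


def _count_zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s)))


def _mirrored_envelope(x: np.ndarray, idx: np.ndarray, end_pad: int = 2) -> np.ndarray:
    """Cubic-spline envelope through the extrema at ``idx``.

    Boundaries are handled by mirroring up to ``end_pad`` extrema across
    each end of the support, which keeps the spline from swinging wildly
    outside the outermost extrema.
    """
    n = x.size
    pos = idx.astype(float)
    vals = x[idx]
    left_pos = 2 * 0 - pos[:end_pad][::-1] - 0.0  # reflect about sample 0
    left_vals = vals[:end_pad][::-1]
    right_pos = 2 * (n - 1) - pos[-end_pad:][::-1]
    right_vals = vals[-end_pad:][::-1]
    all_pos = np.concatenate([left_pos, pos, right_pos])
    all_vals = np.concatenate([left_vals, vals, right_vals])
    # mirroring can duplicate knots when an extremum sits on the boundary
    all_pos, keep = np.unique(all_pos, return_index=True)
    all_vals = all_vals[keep]
    if all_pos.size < 2:
        return np.full(n, float(all_vals[0]))
    if all_pos.size < 4:
        spline = CubicSpline(all_pos, all_vals, bc_type="natural")
    else:
        spline = CubicSpline(all_pos, all_vals)
    return spline(np.arange(n))


def _mean_envelope(x: np.ndarray) -> np.ndarray | None:
    """Mean of the upper and lower spline envelopes, or None if the
    series has too few interior extrema to sift."""
    maxima, minima = _local_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        return None
    upper = _mirrored_envelope(x, maxima)
    lower = _mirrored_envelope(x, minima)
    return 0.5 * (upper + lower)


def _counts_ok(x: np.ndarray) -> bool:
    maxima, minima = _local_extrema(x)
    return abs(maxima.size + minima.size - _count_zero_crossings(x)) <= 1


def _envelope_small(x: np.ndarray, mean_env: np.ndarray) -> bool:
    amplitude = np.abs(x).max()
    if amplitude == 0:
        return True
    return bool(np.abs(mean_env).max() < 0.05 * amplitude)


def sift_emd(
    series: np.ndarray,
    max_imfs: int = 10,
    max_sift_iter: int = 100,
    sd_tol: float = 0.2,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Empirical mode decomposition into IMFs plus a residual.

    Sifting of each mode stops when the candidate satisfies both IMF
    criteria (extrema/zero-crossing counts within one of each other and a
    near-zero mean envelope), when the Cauchy standard-deviation criterion
    between consecutive sifts drops below ``sd_tol``, or after
    ``max_sift_iter`` iterations. Decomposition stops when the residual is
    monotonic (fewer than two interior maxima or minima) or its amplitude
    falls below 1e-10 of the input's. The returned IMFs and residual sum
    to the input exactly by construction.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 8:
        raise ValueError("series too short for EMD (need >= 8 points)")
    amp0 = np.abs(series - series.mean()).max()
    imfs: list[np.ndarray] = []
    residual = series.copy()
    while len(imfs) < max_imfs:
        if amp0 == 0 or np.abs(residual - residual.mean()).max() < 1e-10 * amp0:
            break
        h = residual.copy()
        mean_env = _mean_envelope(h)
        if mean_env is None:  # residual is (near-)monotonic: stop
            break
        for _ in range(max_sift_iter):
            h_new = h - mean_env
            new_env = _mean_envelope(h_new)
            if new_env is None:
                h = h_new
                break
            denom = np.sum(h**2)
            sd = np.sum((h - h_new) ** 2) / denom if denom > 0 else 0.0
            h = h_new
            mean_env = new_env
            # the extrema/zero-crossing criterion is mandatory; the mean
            # envelope criterion is relaxed by the Cauchy SD fallback
            if _counts_ok(h) and (_envelope_small(h, mean_env) or sd < sd_tol):
                break
        imfs.append(h)
        residual = residual - h
    return imfs, residual


def permutation_entropy(series: np.ndarray, m: int = 4, tau: int = 1) -> float:
    """Normalised permutation entropy of a series, in [0, 1].

    Ordinal patterns of order ``m`` at delay ``tau`` are extracted with a
    stable sort (ties broken by index), their Shannon entropy is computed
    and normalised by log(m!). A monotone or constant series has a single
    pattern and PE 0; i.i.d. noise approaches 1.
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    n_windows = n - (m - 1) * tau
    if n_windows < 1:
        raise ValueError(
            f"series of length {n} too short for PE with m={m}, tau={tau}"
        )
    idx = np.arange(n_windows)[:, None] + tau * np.arange(m)[None, :]
    windows = series[idx]
    patterns = np.argsort(windows, axis=1, kind="stable")
    # encode each permutation as an integer in base m
    codes = (patterns * (m ** np.arange(m))[None, :]).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    entropy = -np.sum(p * np.log(p))
    return float(entropy / math.log(math.factorial(m))) + 0.0


def regroup_by_pe(
    imfs: Sequence[np.ndarray],
    residual: np.ndarray,
    threshold: float = DEFAULT_PE_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pool IMFs into high-PE (E1) and low-PE (E2) subsequences.

    E1 sums the IMFs whose PE >= ``threshold``; E2 sums the rest plus the
    residual (the residual is a trend, hence always low-complexity).
    Returns ``(e1, e2, pe_values)``; E1 + E2 equals the decomposed series.
    """
    residual = np.asarray(residual, dtype=float)
    pe_values = np.array([permutation_entropy(imf) for imf in imfs])
    e1 = np.zeros_like(residual)
    e2 = residual.copy()
    for imf, pe in zip(imfs, pe_values):
        if pe >= threshold:
            e1 = e1 + imf
        else:
            e2 = e2 + imf
    return e1, e2, pe_values


def emd_decompose(
    series: np.ndarray,
    max_imfs: int = 10,
    pe_threshold: float = DEFAULT_PE_THRESHOLD,
) -> EMDDecomposition:
    """EMD followed by permutation-entropy regrouping into E1/E2."""
    imfs, residual = sift_emd(series, max_imfs=max_imfs)
    e1, e2, pe_values = regroup_by_pe(imfs, residual, threshold=pe_threshold)
    return EMDDecomposition(
        imfs=imfs, residual=residual, pe_values=pe_values, subsequences=[e1, e2]
    )
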