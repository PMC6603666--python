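"""Permutation entropy of ordinal patterns.

Permutation entropy (PE) quantifies the irregularity of a time series by
the Shannon entropy of the distribution of ordinal (rank-order) patterns
among its delay-embedded vectors, normalized by ``ln(m!)`` so PE lies in
[0, 1].  Being a function of ranks only, it is invariant under any
strictly monotone amplitude transform and robust to slow baseline shifts,
which is why it is a workhorse feature for anesthesia EEG.

Per-minute values follow the convention of one PE per 10-s window
(N = 1000 samples at 100 Hz, lag τ = 1) averaged over the six windows of
a 1-minute epoch.  The default embedding dimension is m = 3.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np

from .preprocess import Epoch

__all__ = ["PeConfig", "ordinal_pattern", "permutation_entropy", "pe_per_minute"]


@dataclass(frozen=True)
class PeConfig:
    """Permutation-entropy parameters: m = 3, τ = 1, 10-s windows by default."""

    m: int = 3
    tau: int = 1
    window_n: int = 1000
    per_minute_average: int = 6

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("embedding dimension m must be ≥ 2")
        if self.tau < 1:
            raise ValueError("lag tau must be ≥ 1")
        if factorial(self.m) > self.window_n - (self.m - 1) * self.tau:
            raise ValueError(
                f"window_n={self.window_n} too short to populate m!={factorial(self.m)} "
                "ordinal patterns"
            )


def ordinal_pattern(vector: np.ndarray) -> int:
    """Ordinal-pattern id of one embedding vector, in ``[0, m!-1]``.

    The id is the Lehmer code of the permutation that sorts the vector
    ascending; ties are broken earliest-index-first (stable sort), so the
    all-equal vector maps to the same id as a strictly ascending one.
    """
    v = np.asarray(vector, float)
    m = v.size
    if m < 2:
        raise ValueError("pattern needs at least 2 values")
    perm = np.argsort(v, kind="stable")
    return _lehmer(perm[None, :])[0]


def _lehmer(perms: np.ndarray) -> np.ndarray:
    """Vectorized Lehmer encoding of permutation rows to integer ids."""
    n, m = perms.shape
    codes = np.zeros(n, dtype=np.int64)
    for i in range(m - 1):
        smaller_after = (perms[:, i + 1 :] < perms[:, i : i + 1]).sum(axis=1)
        codes = codes * (m - i) + smaller_after
    return codes


def _pattern_ids(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n_vec = x.size - (m - 1) * tau
    emb = np.lib.stride_tricks.sliding_window_view(x, (m - 1) * tau + 1)[:n_vec, ::tau]
    perms = np.argsort(emb, axis=1, kind="stable")
    return _lehmer(perms)


def permutation_entropy(x: np.ndarray, m: int = 3, tau: int = 1) -> float:
    """Normalized permutation entropy of ``x``.

    ``PE = -Σ p_j ln p_j / ln(m!)`` where ``p_j`` is the relative
    frequency of ordinal pattern ``j`` among the ``N - (m-1)·τ`` embedding
    vectors.  Returns a value in [0, 1]: 0 for a monotone series (single
    pattern), approaching 1 for iid noise (equidistributed patterns).
    """
    x = np.asarray(x, float)
    if x.ndim != 1:
        raise ValueError("input must be 1-D")
    n_vec = x.size - (m - 1) * tau
    if n_vec < 2:
        raise ValueError(
            f"series of length {x.size} too short for m={m}, tau={tau} "
            f"(need at least {(m - 1) * tau + 2} samples)"
        )
    ids = _pattern_ids(x, m, tau)
    counts = np.bincount(ids)
    p = counts[counts > 0] / n_vec
    return float(-(p * np.log(p)).sum() / np.log(factorial(m)))


def pe_per_minute(epoch: Epoch, config: PeConfig | None = None) -> float:
    """Per-minute PE: mean over six contiguous 10-s windows of one epoch."""
    config = config or PeConfig()
    x = epoch.samples
    n_windows = x.size // config.window_n
    if n_windows < 1:
        raise ValueError("epoch shorter than one PE window")
    vals = [
        permutation_entropy(
            x[i * config.window_n : (i + 1) * config.window_n], config.m, config.tau
        )
        for i in range(min(n_windows, config.per_minute_average))
    ]
    return float(np.mean(vals))
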