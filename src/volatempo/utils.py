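"""Shared numerical helpers: seed streams and factor-congruence utilities."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["rng_stream", "tucker_congruence", "congruence_matrix",
           "greedy_match", "quiet_matchms"]


def quiet_matchms() -> None:
    """Silence matchms's advisory metadata-harmonisation warnings.

    matchms (re)configures its logger at import time, so the level must be
    lowered after the import, not before.
    """
    import logging

    import matchms  # noqa: F401 - ensures the logger exists first

    logging.getLogger("matchms").setLevel(logging.ERROR)


def rng_stream(seed: int, name: str) -> np.random.Generator:
    """Named random stream derived from a global seed.

    Each pipeline stage draws from its own stream so that toggling one stage
    never perturbs another stage's randomness.  The stream identity is the
    (seed, crc32(name)) entropy pair, stable across platforms.
    """
    entropy = [int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode("utf8"))]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two factor vectors (Tucker's phi)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b / (na * nb))


def congruence_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise congruences between columns of ``A`` and columns of ``B``."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    na = np.linalg.norm(A, axis=0)
    nb = np.linalg.norm(B, axis=0)
    na[na == 0.0] = 1.0
    nb[nb == 0.0] = 1.0
    return (A / na).T @ (B / nb)


def greedy_match(A: np.ndarray, B: np.ndarray, use_abs: bool = True):
    """Greedily pair columns of ``A`` with columns of ``B`` by congruence.

    Factor models are identified only up to column permutation (and sign,
    when a mode is unconstrained), so estimated factors are compared to a
    reference after matching.  Returns ``(pairs, signs, values)`` where
    ``pairs[i] = (col_of_A, col_of_B)`` in decreasing congruence order,
    ``signs[i]`` is the sign of the matched congruence and ``values[i]`` its
    absolute (or raw) value.
    """
    C = congruence_matrix(A, B)
    M = np.abs(C) if use_abs else C.copy()
    pairs, signs, values = [], [], []
    M = M.copy()
    for _ in range(min(M.shape)):
        i, j = np.unravel_index(np.argmax(M), M.shape)
        pairs.append((int(i), int(j)))
        signs.append(1.0 if C[i, j] >= 0 else -1.0)
        values.append(float(M[i, j]))
        M[i, :] = -np.inf
        M[:, j] = -np.inf
    return pairs, np.array(signs), np.array(values)
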