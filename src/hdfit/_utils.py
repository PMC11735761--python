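"""Shared helpers: deterministic seed derivation and input validation."""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_seed", "check_matrix", "check_vector", "check_aligned"]

_MOD = 2**31 - 1


def child_seed(master: int, *keys: object) -> int:
    """Derive a reproducible child seed (< 2**31) from a master seed and a key path.

    Independent named streams are obtained by hashing ``(master, *keys)``;
    the derivation does not depend on call order, so adding or removing one
    randomized stage never perturbs the others.
    """
    token = repr((int(master),) + tuple(str(k) for k in keys)).encode()
    digest = hashlib.sha256(token).digest()
    return int.from_bytes(digest[:8], "big") % _MOD


def check_matrix(M, name: str = "X") -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got shape {M.shape}")
    if not np.all(np.isfinite(M)):
        raise ValueError(f"{name} contains non-finite values")
    return M


def check_vector(v, name: str = "y") -> np.ndarray:
    v = np.asarray(v, dtype=float).ravel()
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} contains non-finite values")
    return v


def check_aligned(M: np.ndarray, v: np.ndarray, mname: str = "X", vname: str = "y") -> None:
    if M.shape[0] != v.shape[0]:
        raise ValueError(
            f"{mname} has {M.shape[0]} rows but {vname} has {v.shape[0]} entries"
        )
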