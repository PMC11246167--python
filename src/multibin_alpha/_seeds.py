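"""Reproducible seed derivation helpers.

All randomness in the package flows through :func:`numpy.random.default_rng`.
Cohort-level operations that need one independent stream per sample derive
per-sample seeds from a single user seed with :func:`per_sample_seeds`; the
derivation depends only on the sorted sample ids, so it is invariant to input
order and shared across operations (which is what makes e.g. overall rarefying
at the cohort minimum reproduce the K=1 multi-bin analysis exactly).
"""

from __future__ import annotations

import numpy as np

__all__ = ["as_rng", "child_seeds", "per_sample_seeds"]


def as_rng(seed) -> np.random.Generator:
    """Return a Generator from an int seed, or pass a Generator through."""
    if isinstance(seed, np.random.Generator):
        return seed
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an int or Generator, got {type(seed).__name__}")
    if seed < 0:
        raise ValueError("seed must be nonnegative")
    return np.random.default_rng(int(seed))


def child_seeds(seed: int, n: int, key: int = 0) -> np.ndarray:
    """Derive ``n`` reproducible 32-bit sub-seeds from a master seed.

    Counter-based: child ``j`` depends only on ``(seed, key, j)``, never on
    child ``j-1``, so derived streams are parallel-safe.
    """
    if seed < 0:
        raise ValueError("seed must be nonnegative")
    ss = np.random.SeedSequence([int(seed), int(key)])
    return ss.generate_state(int(n), dtype=np.uint32)


def per_sample_seeds(sample_ids, seed: int, key: int = 0) -> dict:
    """Map each sample id to a sub-seed, by position in the sorted id list."""
    ordered = sorted(sample_ids)
    seeds = child_seeds(seed, len(ordered), key=key)
    return {sid: int(s) for sid, s in zip(ordered, seeds)}
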