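"""Shared numeric helpers: nearest-rank percentiles and add-one permutation p-values."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["nearest_rank_percentile", "add_one_p", "rng_from_seed"]


def nearest_rank_percentile(values: np.ndarray, pct: float) -> float:
    """Nearest-rank (ceil) percentile of an empirical distribution.

    Reproducible across platforms: no interpolation.  ``pct`` is on the
    0-100 scale; the returned value is always an element of ``values``.
    """
    v = np.sort(np.asarray(values, dtype=float))
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no finite values to take a percentile of")
    rank = math.ceil(pct / 100.0 * v.size)
    rank = min(max(rank, 1), v.size)
    return float(v[rank - 1])


def add_one_p(n_as_extreme: int, n_random: int) -> float:
    """Permutation p-value with the add-one (Davison-Hinkley) correction.

    ``(r + 1) / (n + 1)``: never returns 0; the floor at 10,000
    randomizations is 1/10001 = 9.999e-5.
    """
    return (n_as_extreme + 1) / (n_random + 1)


def rng_from_seed(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
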