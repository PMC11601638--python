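"""Bipolar hypervector primitives.

A hypervector is a plain :class:`numpy.ndarray` of signed integers of
length *d* (the dimensionality, typically 10,000).  Atomic vectors are
bipolar (entries in {-1, +1}); bundling (element-wise summation) produces
integer-valued superpositions.  Numeric values are encoded through an
ordered family of *level vectors* — quantisation bins of the data range in
which adjacent levels are similar and distant levels quasi-orthogonal.

The level family is built from a single uniform-random bipolar base vector
by flipping, at each of the L-1 steps, N = floor(d / 2 / L) coordinates
drawn without replacement from positions never flipped before.  Disjoint
flip sets give the exact closed-form geometry

    cosine(levels[i], levels[j]) = 1 - 2 * N * |i - j| / d

so similarity decays linearly with level distance, down to quasi-
orthogonality between the extremes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    InvalidInputError,
    InvalidParameterError,
    OutOfRangeError,
    UndefinedSimilarityError,
)

__all__ = [
    "LevelRegistry",
    "generate_levels",
    "value_to_level",
    "rotate",
    "bundle",
    "cosine",
]


@dataclass(frozen=True)
class LevelRegistry:
    """Ordered family of L quasi-orthogonal level vectors quantising [v_min, v_max].

    Parameters
    ----------
    levels
        ``(L, d)`` int8 array with entries in {-1, +1}; row ``i`` is level ``i``.
    v_min, v_max
        Bounds of the numeric range the registry quantises (same units as
        the data, e.g. relative-abundance percent).
    n_flips
        Number of coordinates flipped between consecutive levels,
        ``N = floor(d / 2 / L)``.
    """

    levels: np.ndarray
    v_min: float
    v_max: float
    n_flips: int

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels)
        if lv.ndim != 2:
            raise InvalidInputError("levels must be a 2-D (L, d) array")
        if not np.isin(lv, (-1, 1)).all():
            raise InvalidInputError("level vectors must be bipolar (-1/+1 entries only)")
        if self.v_min >= self.v_max:
            raise InvalidParameterError(
                f"v_min ({self.v_min}) must be strictly below v_max ({self.v_max})"
            )
        object.__setattr__(self, "levels", lv.astype(np.int8, copy=False))

    @property
    def n_levels(self) -> int:
        return self.levels.shape[0]

    @property
    def dimensionality(self) -> int:
        return self.levels.shape[1]

    @property
    def bin_width(self) -> float:
        return (self.v_max - self.v_min) / self.n_levels

    def level(self, index: int) -> np.ndarray:
        """Return level vector ``index`` as a fresh int array."""
        return np.array(self.levels[index], dtype=np.int64)

    def value_to_index(self, x):
        """Quantise value(s) ``x`` to level indices.

        Bins are uniform and half-open, ``[v_min + i*w, v_min + (i+1)*w)``,
        except the last bin which is closed so ``x == v_max`` maps to
        ``L - 1``.  Scalar input returns a Python int; array input returns
        an int array of the same shape.
        """
        arr = np.asarray(x, dtype=float)
        if np.any(arr < self.v_min) or np.any(arr > self.v_max):
            bad = arr[(arr < self.v_min) | (arr > self.v_max)].flat[0]
            raise OutOfRangeError(
                f"value {bad} outside registry range [{self.v_min}, {self.v_max}]"
            )
        idx = np.floor((arr - self.v_min) / self.bin_width).astype(np.int64)
        idx = np.minimum(idx, self.n_levels - 1)
        if np.isscalar(x) or arr.ndim == 0:
            return int(idx)
        return idx


def generate_levels(
    d: int,
    L: int,
    v_min: float = 0.0,
    v_max: float = 100.0,
    seed: int | None = None,
) -> LevelRegistry:
    """Generate the level-vector family for a numeric range.

    Starts from a uniform-random bipolar base vector of length ``d`` and
    derives each subsequent level by flipping ``N = floor(d / 2 / L)``
    coordinates never touched in an earlier step (the ``(L-1)*N`` flip
    positions are pre-sampled without replacement), so that

    * consecutive levels differ in exactly ``N`` positions, and
    * ``cosine(levels[i], levels[j]) = 1 - 2*N*|i-j|/d`` exactly.

    Parameters
    ----------
    d
        Vector dimensionality; must satisfy ``d >= 2*L`` so ``N >= 1``.
    L
        Number of levels, at least 2.
    v_min, v_max
        Range quantised by the registry (defaults suit relative-abundance
        percentages).
    seed
        Seed for :func:`numpy.random.default_rng`; a fixed seed gives an
        identical registry.
    """
    if L < 2:
        raise InvalidParameterError(f"need at least 2 levels, got L={L}")
    if d < 2 * L:
        raise InvalidParameterError(
            f"dimensionality d={d} too small for L={L} levels (need d >= 2L)"
        )
    n_flips = d // 2 // L
    rng = np.random.default_rng(seed)
    base = (rng.integers(0, 2, size=d, dtype=np.int8) * 2 - 1).astype(np.int8)
    flip_pool = rng.permutation(d)[: (L - 1) * n_flips]
    levels = np.empty((L, d), dtype=np.int8)
    levels[0] = base
    current = base.copy()
    for step in range(1, L):
        flips = flip_pool[(step - 1) * n_flips : step * n_flips]
        current[flips] *= -1
        levels[step] = current
    return LevelRegistry(levels=levels, v_min=float(v_min), v_max=float(v_max), n_flips=n_flips)


def value_to_level(registry: LevelRegistry, x: float) -> int:
    """Level index for value ``x`` (see :meth:`LevelRegistry.value_to_index`)."""
    return registry.value_to_index(x)


def rotate(hv: np.ndarray, p: int) -> np.ndarray:
    """Right circular shift of ``hv`` by ``p`` positions (reduced mod d).

    The element at index ``i`` moves to index ``(i + p) mod d``; the
    permutation is bijective, so ``rotate(rotate(v, p), d - p) == v``.
    Rotation tags which feature a level vector belongs to when samples are
    encoded.
    """
    hv = np.asarray(hv)
    return np.roll(hv, int(p) % hv.shape[-1], axis=-1)


def bundle(hvs) -> np.ndarray:
    """Element-wise integer sum of a non-empty sequence of hypervectors.

    Bundling superposes information: the result is an integer-valued
    hypervector whose cosine against each input stays high.  Commutative
    and associative by construction.
    """
    hvs = list(hvs)
    if not hvs:
        raise InvalidInputError("cannot bundle an empty sequence of hypervectors")
    arrs = [np.asarray(h, dtype=np.int64) for h in hvs]
    lengths = {a.shape[-1] for a in arrs}
    if len(lengths) != 1:
        raise InvalidInputError(f"hypervector lengths differ: {sorted(lengths)}")
    return np.sum(arrs, axis=0)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity ``dot(u, v) / (|u| |v|)`` in [-1, 1]."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise InvalidInputError(f"shape mismatch: {u.shape} vs {v.shape}")
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise UndefinedSimilarityError("cosine undefined for an all-zero vector")
    return float(np.dot(u, v) / (nu * nv))
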