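"""Monte-Carlo subsampling schemes along the reference-size axis.

Four schemes draw ``n`` distinct specimens from a measured size series,
emulating different collection/taphonomic regimes:

* ``random`` -- uniform without replacement over the whole series;
* ``even_length`` -- the reference range (raw mm) is split into ``n``
  equal-width bins, one specimen drawn per bin (best case: maximal, even
  coverage of the size axis); infeasible when a bin is empty;
* ``even_occupancy`` -- specimens sorted by reference size are split into
  ``n`` bins of (near-)equal occupancy, one specimen drawn per bin;
* ``adult_biased`` -- n-1 specimens from the "adult" class (reference size
  at least half the maximum) and exactly one from the smaller class,
  emulating the common bias against juveniles.

Each replicate draw gets its own named RNG substream derived from
(master seed, scheme, variable, n, replicate), so sweeps are reproducible
replicate-by-replicate.
"""

from __future__ import annotations

import zlib
from fractions import Fraction

import numpy as np

from .exceptions import (
    ConfigurationError,
    InfeasibleSubsampleError,
    SampleSizeError,
)

SCHEMES = ("random", "even_length", "even_occupancy", "adult_biased")
_SCHEME_CODES = {s: i for i, s in enumerate(SCHEMES)}


def substream(seed: int, scheme: str, variable_id, n: int, replicate: int) -> np.random.Generator:
    """Independent, reproducible RNG for one (scheme, variable, n, replicate)."""
    if scheme not in _SCHEME_CODES:
        raise ConfigurationError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    ss = np.random.SeedSequence(
        [
            int(seed) % (2**31),
            _SCHEME_CODES[scheme],
            zlib.crc32(str(variable_id).encode("utf-8")),
            int(n),
            int(replicate),
        ]
    )
    return np.random.default_rng(ss)


def random_subsample(N: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform sample of ``n`` distinct indices from ``range(N)``."""
    if n < 1:
        raise SampleSizeError(f"subsample size must be >= 1, got {n}")
    if n > N:
        raise SampleSizeError(f"subsample size {n} exceeds population size {N}")
    return np.sort(rng.choice(N, size=n, replace=False))


def even_length_bins(ref, n: int, rng: np.random.Generator) -> np.ndarray:
    """One specimen per equal-width bin of the raw reference range.

    Bins are half-open [edge_i, edge_{i+1}) except the last, which is closed
    at max(ref).  Any empty bin makes the draw infeasible.
    """
    ref = np.asarray(ref, dtype=float)
    if n < 2:
        raise SampleSizeError(f"binned subsample size must be >= 2, got {n}")
    if n > ref.size:
        raise SampleSizeError(f"subsample size {n} exceeds population size {ref.size}")
    lo, hi = float(ref.min()), float(ref.max())
    if hi == lo:
        raise InfeasibleSubsampleError("reference range has zero width")
    bin_of = np.minimum(((ref - lo) / (hi - lo) * n).astype(int), n - 1)
    chosen = np.empty(n, dtype=int)
    width = (hi - lo) / n
    for b in range(n):
        members = np.flatnonzero(bin_of == b)
        if members.size == 0:
            raise InfeasibleSubsampleError(
                f"even-length bin {b} of {n} "
                f"[{lo + b * width:g}, {lo + (b + 1) * width:g}) contains no specimens"
            )
        chosen[b] = members[rng.integers(members.size)]
    return np.sort(chosen)


def occupancy_bounds(N: int, n: int) -> list:
    """Bin boundaries of the even-occupancy split: round(i N / n), half-to-even."""
    return [0] + [int(round(Fraction(i * N, n))) for i in range(1, n)] + [N]


def even_occupancy_bins(ref, n: int, rng: np.random.Generator) -> np.ndarray:
    """One specimen per equal-occupancy bin of the size-sorted series.

    Ties in the reference value keep stable input order.
    """
    ref = np.asarray(ref, dtype=float)
    if n < 2:
        raise SampleSizeError(f"binned subsample size must be >= 2, got {n}")
    N = ref.size
    if n > N:
        raise SampleSizeError(f"subsample size {n} exceeds population size {N}")
    order = np.argsort(ref, kind="stable")
    bounds = occupancy_bounds(N, n)
    chosen = np.empty(n, dtype=int)
    for b in range(n):
        members = order[bounds[b] : bounds[b + 1]]
        chosen[b] = members[rng.integers(members.size)]
    return np.sort(chosen)


def adult_biased(ref, n: int, rng: np.random.Generator) -> np.ndarray:
    """n-1 specimens from the adult size class plus one smaller specimen.

    The adult class is closed at the boundary: specimens with reference size
    exactly half the maximum belong to it.
    """
    ref = np.asarray(ref, dtype=float)
    if n < 2:
        raise SampleSizeError(f"adult-biased subsample size must be >= 2, got {n}")
    half = float(ref.max()) / 2.0
    large = np.flatnonzero(ref >= half)
    small = np.flatnonzero(ref < half)
    if small.size < 1:
        raise InfeasibleSubsampleError(
            "small size class (reference < half the maximum) is empty"
        )
    if large.size < n - 1:
        raise InfeasibleSubsampleError(
            f"adult size class has {large.size} specimens; need {n - 1}"
        )
    sel = np.concatenate(
        [rng.choice(large, size=n - 1, replace=False), rng.choice(small, size=1)]
    )
    return np.sort(sel)


def feasible(scheme: str, ref, n: int) -> bool:
    """Whether a draw of size ``n`` is possible (without consuming randomness)."""
    ref = np.asarray(ref, dtype=float)
    N = ref.size
    if n < 3 or n > N:
        return False
    if scheme == "random" or scheme == "even_occupancy":
        return True
    if scheme == "even_length":
        lo, hi = float(ref.min()), float(ref.max())
        if hi == lo:
            return False
        bin_of = np.minimum(((ref - lo) / (hi - lo) * n).astype(int), n - 1)
        return np.unique(bin_of).size == n
    if scheme == "adult_biased":
        half = float(ref.max()) / 2.0
        return int((ref >= half).sum()) >= n - 1 and int((ref < half).sum()) >= 1
    raise ConfigurationError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


def draw(scheme: str, ref, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw one subsample under ``scheme``; sweeps require n >= 3."""
    if n < 3:
        raise SampleSizeError(f"sweep subsample size must be >= 3, got {n}")
    ref = np.asarray(ref, dtype=float)
    if scheme == "random":
        return random_subsample(ref.size, n, rng)
    if scheme == "even_length":
        return even_length_bins(ref, n, rng)
    if scheme == "even_occupancy":
        return even_occupancy_bins(ref, n, rng)
    if scheme == "adult_biased":
        return adult_biased(ref, n, rng)
    raise ConfigurationError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
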