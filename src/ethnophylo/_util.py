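"""Shared helpers: seeded substreams and tolerant tie counting."""

from __future__ import annotations

import zlib

import numpy as np

#: Relative tolerance for counting permutation/enumeration ties as "<=".
TIE_RTOL = 1e-12


def substream(seed: int, *keys) -> np.random.Generator:
    """Deterministic per-task RNG derived from (seed, keys).

    Keys are hashed with CRC32 so adding one sample/replicate never perturbs
    the stream of another.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy += [zlib.crc32(str(k).encode("utf-8")) for k in keys]
    return np.random.default_rng(entropy)


def count_le(values: np.ndarray, x: float) -> int:
    """Count entries <= x, with a tiny relative tolerance so exact ties
    produced by a different summation order still count as ties."""
    return int(np.count_nonzero(values <= x + TIE_RTOL * (1.0 + abs(x))))


def count_ge(values: np.ndarray, x: float) -> int:
    return int(np.count_nonzero(values >= x - TIE_RTOL * (1.0 + abs(x))))
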