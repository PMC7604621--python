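"""Shared helpers: seeded substreams and coordinate conventions.

Coordinate convention used throughout: image origin at the top-left corner,
x increasing rightward (columns), y increasing downward (rows), pixel centers
at half-integer pixel coordinates. Physical positions are in micrometres,
obtained by multiplying pixel coordinates by ``pixel_size``.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "pixel_centers_um"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return an independent RNG stream derived from a global seed and a stage name.

    The derivation hashes ``(seed, name)`` so that adding or reordering stages
    does not perturb the randomness of the others.
    """
    digest = hashlib.blake2b(f"{int(seed)}:{name}".encode(), digest_size=8).digest()
    return np.random.default_rng(int.from_bytes(digest, "little") % (2**31))


def pixel_centers_um(rows: np.ndarray, cols: np.ndarray, pixel_size: float) -> np.ndarray:
    """Convert integer pixel indices to (x, y) positions in micrometres."""
    x = (np.asarray(cols, dtype=float) + 0.5) * pixel_size
    y = (np.asarray(rows, dtype=float) + 0.5) * pixel_size
    return np.column_stack([x, y])
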