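"""Reproducible random-stream derivation.

All randomness in the package flows from a single integer seed.  Named
substreams are derived by hashing a string label (e.g. an individual id or a
stage name) so that results do not depend on iteration order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "stream_key"]


def stream_key(label: str) -> int:
    """Stable 32-bit key for a string label (CRC32; platform independent)."""
    return zlib.crc32(label.encode("utf-8")) & 0xFFFFFFFF


def substream(seed: int, *labels: str | int) -> np.random.Generator:
    """Return a Generator for the substream named by ``labels`` under ``seed``.

    The same (seed, labels) pair always yields the same stream, independent
    of how many other streams were drawn before it.
    """
    entropy = [int(seed)]
    for lab in labels:
        entropy.append(stream_key(lab) if isinstance(lab, str) else int(lab))
    return np.random.default_rng(np.random.SeedSequence(entropy))
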