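"""Deterministic, label-addressed random streams.

All stochastic stages derive their generator from a single integer seed plus
a string label, so that any stage can be re-run in isolation and still
produce the bytes it produced inside the full pipeline.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def _label_key(label: str) -> int:
    # crc32 is stable across platforms and Python versions
    return zlib.crc32(label.encode("utf-8"))


def stream(seed: int, *labels: str) -> np.random.Generator:
    """Return a Generator for ``seed`` split by one or more string labels."""
    key = tuple(_label_key(l) for l in labels)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))
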