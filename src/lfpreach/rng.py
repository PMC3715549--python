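"""Deterministic random-number substreams.

One master seed drives every stochastic element of a run.  Named substreams
are derived with ``numpy.random.SeedSequence`` so that, e.g., changing the
number of cells does not silently shift the spike-train realisations.
"""

from __future__ import annotations

import numpy as np

# fixed registry: each named stream hashes the master seed with its own tag
_STREAM_TAGS = {
    "pool": 1,
    "assignments": 2,
    "placements": 3,
    "rotations": 4,
    "layout": 5,
    "trials": 6,
}


def substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Generator for the named substream of a master seed."""
    try:
        tag = _STREAM_TAGS[name]
    except KeyError:
        raise KeyError(f"unknown rng stream {name!r}; known: {sorted(_STREAM_TAGS)}")
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag, int(index)]))
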