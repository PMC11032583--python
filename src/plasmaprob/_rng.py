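"""Named random substreams derived from a single top-level seed.

Every stochastic stage (cohort draw, CV fold shuffle, bootstrap resampling)
pulls its generator from :func:`substream` so stages are independently
reproducible: re-running one stage with the same top-level seed gives the
same stream regardless of what ran before it.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The label is folded in through CRC-32 so distinct stage names give
    statistically independent streams under ``SeedSequence``.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
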