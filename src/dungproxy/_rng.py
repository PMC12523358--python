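"""Named, reproducible random substreams.

Each stochastic stage of the virtual study (movement, monitoring-day
selection, deposition, decay, detection, drift) draws from its own
substream derived from the run seed and a stage name, so stages can be
re-run or swapped independently without perturbing the others.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Generator for a named stage, deterministic in (seed, name)."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
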