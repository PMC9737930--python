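"""Reproducible seeding.

One master seed expands to per-task child streams through
``numpy.random.SeedSequence`` spawn keys, so any subset of the work
(one recording, one Gibbs chain) can be regenerated without running
everything before it.  The spawn key is a tuple of small integers that
acts as a documented counter: e.g. recording ``i`` of a cohort uses
``(STREAM_RECORDING, i)``.
"""

from __future__ import annotations

import numpy as np

# stream ids, one per independent consumer of randomness
STREAM_RECORDING = 0
STREAM_SEVERITY = 1
STREAM_SESSION = 2
STREAM_GIBBS_STAGE1 = 3
STREAM_GIBBS_STAGE2 = 4
STREAM_MODEL = 5
STREAM_PRIOR = 6


def child_seed(master: int, *key: int) -> np.random.SeedSequence:
    """Derive a child ``SeedSequence`` from a master seed and a counter key."""
    return np.random.SeedSequence(int(master), spawn_key=tuple(int(k) for k in key))


def child_rng(master: int, *key: int) -> np.random.Generator:
    """Generator seeded from :func:`child_seed`."""
    return np.random.default_rng(child_seed(master, *key))
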