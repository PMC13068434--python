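"""Named, collision-free random streams derived from a single workflow seed.

Every stochastic step (a stimulus draw, a trial's initial phases, a synthetic
subject) pulls its own `numpy` Generator keyed by a tuple of small integers,
so results are reproducible and independent of execution order or parallelism.
"""

from __future__ import annotations

import numpy as np

DEFAULT_SEED = 1709026616

# stream-kind tags: keep distinct so (kind, *key) tuples never collide
STIMULUS = 1
PHASES = 2
BEHAVIOR = 3
GENERIC = 4


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Return a Generator for the stream identified by ``key`` under ``seed``.

    Keys are hashed through :class:`numpy.random.SeedSequence`'s spawn-key
    mechanism, which guarantees streams with different keys are statistically
    independent.
    """
    if any(k < 0 for k in key):
        raise ValueError("stream key components must be non-negative integers")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def as_rng(rng_or_seed) -> np.random.Generator:
    """Coerce an int seed, SeedSequence, Generator or None to a Generator."""
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)
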