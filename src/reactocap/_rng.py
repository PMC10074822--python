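"""Splittable random-number-generator plumbing.

Every stochastic operation in the package takes an integer ``seed`` and
derives independent child generators through :class:`numpy.random.SeedSequence`
spawning, so multi-stage simulations are exactly reproducible and adding a
stage never perturbs the streams of existing stages.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rng_from_seed", "spawn_seeds"]


def rng_from_seed(seed: int, *path: int) -> np.random.Generator:
    """Return a Generator for ``seed`` descended along a spawn ``path``.

    ``rng_from_seed(s, 0)`` and ``rng_from_seed(s, 1)`` are statistically
    independent streams; the same arguments always give the same stream.
    """
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(int(p) for p in path))
    return np.random.default_rng(ss)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent integer seeds from one master seed."""
    ss = np.random.SeedSequence(int(seed))
    return [int(s.generate_state(1)[0]) for s in ss.spawn(n)]
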