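"""Named, replayable random-number streams.

A single master seed spawns independent sub-streams, one per stochastic
rule (network construction, sprout initiation, collapse, surface sampling,
...), so that changing the draw count of one rule never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np


def named_stream(master_seed: int, *names: str) -> np.random.Generator:
    """Return a Generator derived from ``master_seed`` and a path of names.

    The same (seed, names) pair always yields the same stream; distinct
    names yield statistically independent streams.
    """
    if master_seed < 0:
        raise ValueError("master seed must be non-negative")
    keys = [int(master_seed)] + [zlib.crc32(n.encode("utf8")) for n in names]
    return np.random.default_rng(np.random.SeedSequence(keys))


def spawn_seeds(master_seed: int, n: int, *names: str) -> list[int]:
    """Derive ``n`` distinct 31-bit child seeds (e.g. one per ensemble run)."""
    rng = named_stream(master_seed, *names, "spawn")
    seeds: list[int] = []
    seen: set[int] = set()
    while len(seeds) < n:
        s = int(rng.integers(0, 2**31 - 1))
        if s not in seen:
            seen.add(s)
            seeds.append(s)
    return seeds
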