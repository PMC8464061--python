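"""Counter-based seed derivation.

One master seed drives the whole run.  Every stochastic step (a perturbation
at a node, a k-means restart, a resampling attempt) derives its own child
seed from (master seed, a stable node key, perturbation index, attempt
index), so results are independent of traversal order and of how many
perturbations other nodes consumed.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD31 = 2**31 - 1


def node_key(item_ids: list[str]) -> int:
    """Stable integer key for a node, derived from its (sorted) member ids."""
    payload = "|".join(sorted(item_ids)).encode("utf-8")
    return zlib.crc32(payload) & 0x7FFFFFFF


def child_seed_sequence(master_seed: int, *counters: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(master_seed) & _MOD31,
                                  spawn_key=tuple(int(c) for c in counters))


def child_rng(master_seed: int, *counters: int) -> np.random.Generator:
    return np.random.default_rng(child_seed_sequence(master_seed, *counters))


def child_int_seed(master_seed: int, *counters: int) -> int:
    """A plain int seed (< 2^31) for APIs that take one (e.g. sklearn)."""
    state = child_seed_sequence(master_seed, *counters).generate_state(1)[0]
    return int(state % _MOD31)
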