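"""Named random substreams.

All stochastic stages draw from generators derived from a single root seed
plus a stage name, so adding a new stage (or reordering stages) never
perturbs the draws of existing ones.
"""
from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "derive_seed"]


def _name_key(name: str) -> int:
    return zlib.crc32(name.encode("utf-8"))


def substream(root_seed: int, name: str) -> np.random.Generator:
    """Return a Generator keyed by ``(root_seed, name)``.

    Deterministic: same seed and name always give the same stream,
    independent of how many other substreams were requested before.
    """
    return np.random.default_rng(np.random.SeedSequence([int(root_seed), _name_key(name)]))


def derive_seed(root_seed: int, name: str) -> int:
    """Derive an integer seed (< 2**31) for APIs that take plain seeds."""
    ss = np.random.SeedSequence([int(root_seed), _name_key(name)])
    return int(ss.generate_state(1)[0] % (2**31))
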