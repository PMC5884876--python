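"""Named, independent random streams derived from one root seed.

Every stochastic component asks for its own stream so that re-running one
session (or one study arm) never perturbs the draws of another.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["stream", "substream_seed"]


def _key_ints(keys: tuple) -> tuple[int, ...]:
    out = []
    for k in keys:
        digest = hashlib.blake2b(repr(k).encode("utf-8"), digest_size=4).digest()
        out.append(int.from_bytes(digest, "big"))
    return tuple(out)


def stream(seed: int, *keys) -> np.random.Generator:
    """Return a Generator for the stream named by ``keys`` under ``seed``."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=_key_ints(keys))
    return np.random.default_rng(ss)


def substream_seed(seed: int, *keys) -> int:
    """A derived integer seed (for APIs that take a seed, not a Generator)."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=_key_ints(keys))
    return int(ss.generate_state(1, dtype=np.uint64)[0])
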