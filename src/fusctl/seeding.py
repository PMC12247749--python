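"""Named, collision-free random substreams from a single root seed.

Every stochastic consumer draws from its own named stream so that adding a
consumer never shifts the draws of the others.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["named_stream", "named_streams"]


def _key(name: str) -> int:
    return zlib.crc32(name.encode("utf-8"))


def named_stream(root_seed: int, name: str) -> np.random.Generator:
    """A generator deterministically derived from ``(root_seed, name)``."""
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=(_key(name),))
    return np.random.default_rng(ss)


def named_streams(root_seed: int, *names: str) -> dict[str, np.random.Generator]:
    if len(set(names)) != len(names):
        raise ValueError("stream names must be unique")
    return {name: named_stream(root_seed, name) for name in names}
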