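"""Per-operation random streams.

Every stochastic operation derives its own ``Generator`` from the user
seed and the operation name, so adding one randomized step to a pipeline
never perturbs the stream of another.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31


def derived_rng(seed: int, op_name: str) -> np.random.Generator:
    """Generator keyed by ``(seed, crc32(op_name))``."""
    key = zlib.crc32(op_name.encode("utf-8")) % _MOD
    return np.random.default_rng([int(seed) % _MOD, key])
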