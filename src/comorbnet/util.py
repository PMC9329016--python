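"""Small shared helpers."""

from __future__ import annotations

import zlib

import numpy as np


def stream(seed: int, label: str) -> np.random.Generator:
    """Independent, reproducible random stream derived from (seed, label).

    The label is hashed with CRC32 so that runs tagged differently (e.g. per
    phenotype stratum) consume disjoint streams: adding one stratum never
    perturbs another's draws.
    """
    return np.random.default_rng([int(seed), zlib.crc32(label.encode())])
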