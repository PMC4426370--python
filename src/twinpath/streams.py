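"""Named random streams.

All randomness in the package flows from one integer seed. Each stage (and
each gene / module within the generator) draws from a stream keyed by the
seed plus a name, so stages are independently reproducible and the output
for one gene does not depend on the order in which other genes are drawn.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream(seed: int, *names: object) -> np.random.Generator:
    """Deterministic generator keyed by ``seed`` and a sequence of names."""
    key = tuple(zlib.crc32(str(n).encode("utf-8")) for n in names)
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=key)
    return np.random.default_rng(ss)
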