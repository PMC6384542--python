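"""Named, independent random streams derived from a single user seed.

Every sampling operation in the package draws from its own stream,
keyed by the operation name, so that results are reproducible and do
not depend on the order in which operations run.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_rng(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for stream `name` under `seed`.

    The stream key is a CRC32 of the name mixed into a SeedSequence, so
    distinct operation names yield statistically independent streams.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
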