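"""Named random substreams derived from a single master seed.

Every stochastic operation in the package draws from a substream keyed by a
stable name, so a pipeline run is reproducible end to end from one integer
and adding a stage never perturbs the streams of other stages.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def _keys(names: tuple) -> list[int]:
    return [zlib.crc32(str(n).encode("utf8")) for n in names]


def substream_seed(seed: int, *names) -> np.random.SeedSequence:
    """A SeedSequence for the substream ``names`` of master ``seed``."""
    return np.random.SeedSequence([int(seed), *_keys(names)])


def substream(seed: int, *names) -> np.random.Generator:
    """A Generator for the substream ``names`` of master ``seed``.

    The mapping is stable across sessions and platforms (crc32 of the names).
    """
    return np.random.default_rng(substream_seed(seed, *names))
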