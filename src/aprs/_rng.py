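"""Named, independent RNG substreams derived from one master seed.

Every stochastic stage of the pipeline draws from its own substream so that
adding or re-running one stage never perturbs the draws of another.  Substreams
are identified by a short name; the (master seed, name) pair deterministically
fixes the stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _name_key(name: str) -> int:
    # crc32 is stable across platforms and Python versions (unlike hash()).
    return zlib.crc32(name.encode("utf-8"))


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The same (seed, name) pair always yields an identical stream; distinct
    names yield statistically independent streams via SeedSequence spawning.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_name_key(name),))
    return np.random.default_rng(ss)
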