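"""Counter-based substream seeding.

A single integer seed is expanded into independent named substreams via
``numpy.random.SeedSequence`` spawn keys, so each stage of the pipeline can be
re-run in isolation and still reproduce byte-identical output.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _stream_key(name: str) -> int:
    # stable across processes and Python versions, unlike hash()
    return zlib.crc32(name.encode("utf-8"))


def substream(seed: int, name: str, counter: int = 0) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    Parameters
    ----------
    seed : int
        The global pipeline seed.
    name : str
        Stage name, e.g. ``"regions"`` or ``"surveys"``.
    counter : int
        Optional replicate counter within the stage.
    """
    ss = np.random.SeedSequence(int(seed), spawn_key=(_stream_key(name), int(counter)))
    return np.random.Generator(np.random.PCG64(ss))
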