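"""Reproducible named random substreams.

A single master seed is expanded into independent streams keyed by
arbitrary tuples of names and indices (person index, variable name,
season, ...).  String keys are hashed with CRC-32 into the seed-sequence
spawn key, so adding a new stream name never perturbs existing streams —
the property that makes paired (common-random-number) scenario
comparisons exact.

Keep the master seed below 2**31 so it round-trips through every
front-end.
"""

from __future__ import annotations

import zlib
from functools import lru_cache

from numpy.random import Generator, PCG64, SeedSequence

__all__ = ["substream", "PersonStreams"]


def _key_int(key) -> int:
    if isinstance(key, (int,)):
        return key & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def substream(master_seed: int, *keys) -> Generator:
    """Independent generator for the named substream of ``master_seed``."""
    spawn = tuple(_key_int(k) for k in keys)
    return Generator(PCG64(SeedSequence(master_seed, spawn_key=spawn)))


class PersonStreams:
    """Named substreams for one simulated person.

    ``var(name)`` returns (and caches) the stream used to sample the input
    variable ``name`` for this person; ``diary``/``engine`` return fresh
    per-day streams for diary construction and event-level stochasticity.
    """

    def __init__(self, master_seed: int, age_group: str, person_index: int):
        self.master_seed = int(master_seed)
        self.age_group = age_group
        self.person_index = int(person_index)
        self._var_cache: dict[str, Generator] = {}

    def var(self, name: str) -> Generator:
        g = self._var_cache.get(name)
        if g is None:
            g = substream(self.master_seed, self.age_group,
                          self.person_index, "var", name)
            self._var_cache[name] = g
        return g

    def diary(self, season: str, day_type: str) -> Generator:
        return substream(self.master_seed, self.age_group,
                         self.person_index, "diary", season, day_type)

    def engine(self, season: str, day_type: str) -> Generator:
        return substream(self.master_seed, self.age_group,
                         self.person_index, "engine", season, day_type)
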