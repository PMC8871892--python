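"""Named random-number substreams.

Every stochastic element of a replication (each arrival process, each
station's service times, attribute assignment, doctor assignment, downtime
episodes) draws from its own generator, derived deterministically from
``(master_seed, replication_index, stream_name)``.  Keeping the substreams
separate implements common random numbers across scenario configurations: two
scenarios run with the same master seed share attribute and service-time
draws patient-for-patient, so paired comparisons against the base case are
variance-reduced.
"""

from __future__ import annotations

import numpy as np

__all__ = ["STREAM_NAMES", "Streams"]

STREAM_NAMES = (
    "arrivals_public",
    "arrivals_private",
    "arrivals_general",
    "attributes",
    "service_qms",
    "service_revenue",
    "service_og_counter",
    "service_private_counter",
    "service_vitals",
    "service_lab",
    "service_consult",
    "service_nurses",
    "service_discussion",
    "assignment",
    "downtime",
)

_INDEX = {name: i for i, name in enumerate(STREAM_NAMES)}


class Streams:
    """Per-replication bundle of named, independent generators."""

    def __init__(self, master_seed: int, replication: int = 0):
        self.master_seed = int(master_seed)
        self.replication = int(replication)
        self._gens: dict[str, np.random.Generator] = {}

    def __getitem__(self, name: str) -> np.random.Generator:
        gen = self._gens.get(name)
        if gen is None:
            try:
                idx = _INDEX[name]
            except KeyError:
                raise KeyError(f"unknown stream {name!r}; known: {STREAM_NAMES}") from None
            seq = np.random.SeedSequence((self.master_seed, self.replication, idx))
            gen = self._gens[name] = np.random.default_rng(seq)
        return gen
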