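"""Shared helpers: seeded substreams and run hashing."""

from __future__ import annotations

import hashlib
import json

import numpy as np


def substream(seed: int, *key: int) -> np.random.Generator:
    """Return a generator on an independent stream derived from ``seed``.

    Streams are keyed by fixed integer tuples so that adding a new
    component (e.g. one more simulated pathway) never perturbs the draws
    of existing components.
    """
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)


def stable_hash(obj) -> str:
    """Short deterministic hex digest of a JSON-serialisable object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
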