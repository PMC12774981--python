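"""Seed-stream management.

One master seed per replicate; every stage of a pipeline derives its own
child generator from the master seed plus a fixed string label, so stages
are independently reproducible and replicate streams never collide.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def _label_entropy(label: str | int) -> int:
    if isinstance(label, (int, np.integer)):
        return int(label)
    digest = hashlib.blake2b(str(label).encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "little")


def child_seed(master_seed: int, *labels: str | int) -> int:
    """Derive a deterministic 31-bit integer seed from a master seed and labels."""
    ss = np.random.SeedSequence([int(master_seed)] + [_label_entropy(x) for x in labels])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31 - 1)) + 1


def child_rng(master_seed: int, *labels: str | int) -> np.random.Generator:
    """Derive a child Generator from a master seed and a sequence of stage labels."""
    ss = np.random.SeedSequence([int(master_seed)] + [_label_entropy(x) for x in labels])
    return np.random.default_rng(ss)
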