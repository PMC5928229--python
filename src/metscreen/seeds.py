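"""Named random substreams.

All randomness in the package flows from one root seed.  Each stage (and each
pool, mouse, or replicate experiment within a stage) draws from a substream
derived from the root seed plus a stable string label, so stages can be re-run
independently and still reproduce the full-pipeline output bit for bit.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _label_entropy(label: str) -> int:
    digest = hashlib.blake2b(label.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "little")


def child_seed(root_seed: int, *labels: str) -> np.random.SeedSequence:
    """Seed sequence for the substream named by ``labels`` under ``root_seed``."""
    entropy = [int(root_seed) & 0x7FFFFFFF] + [_label_entropy(l) for l in labels]
    return np.random.SeedSequence(entropy)


def substream(root_seed: int, *labels: str) -> np.random.Generator:
    """Generator for the named substream; deterministic in (seed, labels)."""
    return np.random.default_rng(child_seed(root_seed, *labels))
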