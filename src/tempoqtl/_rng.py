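"""Seed handling.

One root seed drives every stochastic component; each component obtains its own
child generator keyed by a fixed string label, so adding a new component never
perturbs the draws of an existing one.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def _label_entropy(label: str) -> int:
    digest = hashlib.sha256(label.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little")


def child_seed(seed: int, label: str) -> np.random.SeedSequence:
    """SeedSequence for component `label` under root `seed`."""
    return np.random.SeedSequence([int(seed) % (2**31), _label_entropy(label)])


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Independent generator for component `label` under root `seed`."""
    return np.random.default_rng(child_seed(seed, label))
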