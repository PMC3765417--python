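"""Deterministic derivation of per-stage random seeds from one master seed.

Every stochastic stage of the pipeline receives a seed derived by stable
hashing of (master seed, stage label, ...), so a single master seed fixes the
whole analysis while stages stay statistically independent of one another.
"""

from __future__ import annotations

import hashlib

import numpy as np


def child_seed(master_seed: int, *labels: object) -> int:
    """Derive a stable 31-bit seed from a master seed and a label path."""
    h = hashlib.sha256()
    h.update(str(int(master_seed)).encode())
    for lab in labels:
        h.update(b"/")
        h.update(str(lab).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def rng_for(master_seed: int, *labels: object) -> np.random.Generator:
    """A ``numpy.random.Generator`` seeded from :func:`child_seed`."""
    return np.random.default_rng(child_seed(master_seed, *labels))
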