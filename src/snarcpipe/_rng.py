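"""Deterministic seed derivation for per-participant reproducibility."""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(master_seed: int, *keys: object) -> int:
    """Derive a child seed from a master seed and arbitrary string-able keys.

    Stable across runs and platforms (unlike ``hash``), so any participant can
    be re-simulated or re-bootstrapped independently of the others.
    """
    payload = ":".join([str(int(master_seed))] + [str(k) for k in keys])
    digest = hashlib.blake2b(payload.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "big")


def rng_for(master_seed: int, *keys: object) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, *keys))
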