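"""Shared helpers: errors, seeding, fingerprints."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np


class HicannoError(Exception):
    """Base class for all package errors."""


class ValidationError(HicannoError):
    """Raised when an input violates a documented precondition or invariant."""


def spawn_rng(seed: int, stream: str) -> np.random.Generator:
    """Derive an independent, reproducible RNG stream from a master seed.

    Each named stream (e.g. ``"split"``, ``"mask"``, ``"init"``) gets its own
    generator so that changing how one stream is consumed does not perturb
    the others.
    """
    h = hashlib.sha256(f"{seed}:{stream}".encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:4], "little"))


def sha256_of_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def sha256_of_file(path: str | Path, chunk: int = 1 << 20) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        while block := fh.read(chunk):
            h.update(block)
    return h.hexdigest()


def canonical_json(obj) -> str:
    """Deterministic JSON serialization used for fingerprinting."""
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))
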