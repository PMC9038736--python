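"""Small shared utilities: reproducible seed derivation and config hashing."""

from __future__ import annotations

import hashlib
import json
import zlib

_MASK64 = (1 << 64) - 1


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return (z ^ (z >> 31)) & _MASK64


def derive_seed(base_seed: int, *keys) -> int:
    """Derive an independent 31-bit stage seed from a global seed and keys.

    Splitmix-style mixing so every (stage, case) pair gets a reproducible,
    effectively independent stream; strings are folded in via CRC32.
    """
    x = int(base_seed) & _MASK64
    for k in keys:
        if isinstance(k, str):
            k = zlib.crc32(k.encode("utf-8"))
        x = _splitmix64(x ^ (int(k) & _MASK64))
    return int(x % ((1 << 31) - 1))


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode("utf-8")
    return hashlib.sha256(payload).hexdigest()[:12]
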