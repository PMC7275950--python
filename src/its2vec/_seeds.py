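"""Deterministic seed derivation.

One master seed expands into named per-stage streams, and per-SH streams are
derived by hashing (seed, sh_code), so random selections are independent of
record order and of each other.
"""

from __future__ import annotations

import hashlib

_MOD = 2**31


def derive_seed(master: int, *parts: object) -> int:
    """Derive a child seed from a master seed and a sequence of labels.

    The derivation is a SHA-256 hash of the stringified inputs, folded into
    [0, 2**31), so children are decorrelated and stable across platforms.
    """
    key = "|".join([str(int(master)), *map(str, parts)])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little") % _MOD
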