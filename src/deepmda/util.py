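"""Seed bookkeeping: every stage's randomness derives from one root seed."""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(root: int, *labels: object) -> int:
    """Stable child seed for a named stage, below 2**31.

    Hash-based so that adding a stage never shifts the seeds of the
    existing ones (unlike sequential draws from a generator).
    """
    digest = hashlib.sha256(repr((int(root), labels)).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
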