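"""Hierarchical seed derivation.

One master seed per run; each stage derives its own stream by stable hashing
of the stage name, so adding a stage never perturbs earlier stages' draws.
"""

from __future__ import annotations

import hashlib


def derive_seed(master: int, stage: str) -> int:
    """Deterministic 31-bit child seed for a named stage."""
    digest = hashlib.sha256(f"{int(master)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
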