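"""Deterministic seed derivation.

Sub-seeds are derived with a stable cryptographic hash rather than Python's
built-in ``hash`` (which is salted per process), so regenerating a dataset
from the same spec reproduces identical bytes in any session and is
independent of generation order.
"""

from __future__ import annotations

import hashlib


def stable_seed(*parts: int | str) -> int:
    """Collapse a tuple of ints/strings into a seed in [0, 2^31)."""
    h = hashlib.blake2b(digest_size=8)
    for part in parts:
        h.update(str(part).encode())
        h.update(b"\x00")
    return int.from_bytes(h.digest(), "little") % (2 ** 31)
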