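"""Stable seed derivation: one master seed fans out to per-stage streams.

Seeds are derived by hashing the master seed together with string labels
(stage name, trait id, replicate index ...), so adding one trait or stage
never reshuffles any other's random stream.  Derived seeds are < 2**31.
"""

from __future__ import annotations

import hashlib


def derive_seed(master: int, *labels) -> int:
    h = hashlib.sha256()
    h.update(str(int(master)).encode())
    for lab in labels:
        h.update(b"\x1f")
        h.update(str(lab).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)
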