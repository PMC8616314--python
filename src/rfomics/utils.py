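"""Shared helpers: namespaced seed derivation."""

from __future__ import annotations

import hashlib


def derive_seed(seed: int, *tokens) -> int:
    """Derive a child seed from a base seed and namespace tokens.

    Hash-based so CV shuffles, simulations and forest bootstraps each
    consume an independent, reproducible stream from one config seed.
    Result is in [0, 2^31).
    """
    payload = ":".join([str(int(seed)), *map(str, tokens)]).encode()
    return int.from_bytes(hashlib.sha256(payload).digest()[:4], "big") % (2**31)
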