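"""Deterministic seed derivation.

One user-facing integer seed is fanned out into independent substreams by
stable hashing of step names, so adding a step never perturbs the draws of
another.
"""

from __future__ import annotations

import hashlib


def derive_seed(seed: int, *tokens) -> int:
    """A substream seed (< 2**31) from a root seed and step-name tokens."""
    key = "/".join([str(int(seed)), *map(str, tokens)])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
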