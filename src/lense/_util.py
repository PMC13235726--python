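"""Internal helpers shared across modules."""

import hashlib


def derive_seed(seed: int, *parts: object) -> int:
    """Derive a stable sub-seed from a top-level seed and context labels.

    The derivation hashes ``(seed, *parts)`` with SHA-256 so that each
    (stage, config) pair receives an independent, reproducible seed that
    does not depend on execution order.  The result fits in 31 bits, as
    required by seed consumers such as umap-learn.
    """
    key = "\x1f".join(str(p) for p in (seed, *parts))
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
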