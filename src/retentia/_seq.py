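"""Small sequence helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def normalize(seq: str) -> str:
    """Uppercase and map U -> T (DNA frame used internally everywhere)."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
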