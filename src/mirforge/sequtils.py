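"""Tiny DNA-string helpers shared across modules."""

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case-preserving)."""
    return seq.translate(_COMP)[::-1]
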