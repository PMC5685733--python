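"""Small sequence helpers shared across modules.

All sequences are handled internally in the DNA alphabet (U is
normalized to T on input); user-facing isomiR labels are rendered with
U to match small-RNA convention.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def normalize(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T)."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Render a DNA string in the RNA alphabet, preserving case."""
    return seq.replace("T", "U").replace("t", "u")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_seq(rng, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
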