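"""2-bit nucleotide encoding shared by the aligner and the k-mer filter."""

from __future__ import annotations

import numpy as np

# A=0, C=1, G=2, T=3; anything else maps to the sentinel 255.
_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode a normalized DNA string as a uint8 array of 2-bit base codes."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _LUT[raw]
    if codes.size == 0:
        raise ValueError("empty sequence cannot be encoded")
    if (codes == 255).any():
        bad = sequence[int(np.argmax(codes == 255))]
        raise ValueError(f"sequence contains non-ACGT symbol {bad!r}")
    return codes
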