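"""Small shared sequence helpers (encoding, reverse complement)."""
from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn", "TGCAYRMKVBHDNtgcayrmkvbhdn")

# numeric codes: A,C,G,T -> 0..3, anything else -> 4 (never matches, even itself)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (ACGT -> 0..3, other -> 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def hamming_identity(a: str, b: str) -> float:
    """Ungapped identity = matches / length; ambiguity codes never match."""
    if len(a) != len(b):
        raise ValueError("hamming_identity requires equal lengths")
    if not a:
        return 0.0
    ca, cb = encode(a), encode(b)
    ok = (ca == cb) & (ca < 4)
    return float(ok.sum()) / len(a)
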