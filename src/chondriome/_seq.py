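"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: integer encoding used by the aligner; N maps to 4 and never matches
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode ACGT as 0..3 (uint8); anything else becomes 4 (never matches)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def gc_percent(seq: str, ndigits: int = 2) -> float:
    """GC as (G+C)/(A+C+G+T) x 100. N and other letters are excluded
    from the denominator."""
    enc = encode(seq)
    acgt = int(np.count_nonzero(enc < 4))
    if acgt == 0:
        return 0.0
    gc = int(np.count_nonzero((enc == 1) | (enc == 2)))
    return round(gc / acgt * 100.0, ndigits)


def validate_alphabet(seq: str, where: str = "sequence") -> None:
    if np.any(_ENCODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)] == 4):
        bad = sorted(set(seq.upper()) - set("ACGTN"))
        if bad:
            raise ValueError(f"{where} contains non-ACGTN characters: {bad}")


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random sequence with expected GC fraction ``gc``."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
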