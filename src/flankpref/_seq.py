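"""Small sequence utilities shared across modules."""

from __future__ import annotations

from itertools import product

BASES = "ACGT"

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# bisulfite conversion of a fully unmethylated strand: C -> T
_C2T = str.maketrans("Cc", "Tt")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC N preserved)."""
    return seq.translate(_COMP)[::-1]


def c_to_t(seq: str) -> str:
    return seq.translate(_C2T)


def all_contexts(central: str = "CG") -> list[str]:
    """All 256 NNxxNN 6-mers around a central dinucleotide, lexicographic."""
    return [a + b + central + c + d for a, b, c, d in product(BASES, repeat=4)]


def geometric_mean(values) -> float:
    import numpy as np

    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("geometric mean of empty set")
    if (v <= 0).any():
        raise ValueError("geometric mean requires positive values")
    return float(np.exp(np.mean(np.log(v))))
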