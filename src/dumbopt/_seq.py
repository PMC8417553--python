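"""In-frame coding-sequence validation shared by harmonization and %MinMax."""

from __future__ import annotations

from .codon_usage import STANDARD_CODE
from .errors import PrematureStopError, SequenceAlphabetError, SequenceFrameError

_DNA = frozenset("ACGT")


def split_codons(seq: str, *, reject_internal_stops: bool = True) -> list[str]:
    """Uppercase, transliterate U→T, and split into codons.

    Raises on out-of-frame length, ambiguity codes, and (by default)
    internal stop codons; a terminal stop codon is permitted.
    """
    s = str(seq).strip().upper().replace("U", "T")
    if len(s) == 0 or len(s) % 3 != 0:
        raise SequenceFrameError(
            f"sequence length {len(s)} is not a positive multiple of 3"
        )
    bad = sorted(set(s) - _DNA)
    if bad:
        raise SequenceAlphabetError(f"non-ACGT character(s): {bad}")
    codons = [s[i : i + 3] for i in range(0, len(s), 3)]
    if reject_internal_stops:
        for i, c in enumerate(codons[:-1]):
            if STANDARD_CODE[c] == "*":
                raise PrematureStopError(i, c)
    return codons


def translate(seq: str) -> str:
    """Codon-wise translation under the standard code; stops rendered ``*``."""
    codons = split_codons(seq, reject_internal_stops=False)
    return "".join(STANDARD_CODE[c] for c in codons)
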