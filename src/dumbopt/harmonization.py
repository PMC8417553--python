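"""Codon harmonization of heterologous expression constructs.

Three synonymous-recoding modes over a native coding sequence:

*DUMB optimization* (``dumb_optimize``) — at each codon position, choose the
host codon whose within-family relative usage best matches the native
codon's relative usage in the native organism, subject to a rare-codon
threshold: by default a host codon is eligible only when its relative usage
is at least ``threshold`` (default 5%) of the native codon's native relative
usage. The aim is to reproduce the native translation-speed profile in the
host and so preserve cotranslational folding, rather than to maximize raw
translation rate.

*Full optimization* (``fully_optimize``) — the conventional baseline: every
position uses the host's most frequent synonymous codon (most abundant
tRNA).

*Random control* (``random_control``) — each position drawn uniformly from
the synonymous family under a seed; the null profile against which the
other two are judged.

All modes preserve the encoded protein exactly and return a per-position
audit trail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import split_codons, translate
from .codon_usage import STANDARD_CODE, CodonUsageTable
from .errors import ConfigurationError

__all__ = [
    "HarmonizationConfig",
    "PositionRecord",
    "HarmonizationResult",
    "dumb_optimize",
    "fully_optimize",
    "random_control",
    "verify_synonymy",
]

THRESHOLD_MODES = ("relative_to_native", "absolute_floor")
TIE_BREAK = "higher_host_freq_then_lexicographic"


@dataclass
class HarmonizationConfig:
    """Parameters of the DUMB-optimization threshold rule.

    threshold
        τ in [0, 1]; default 0.05 (the 5% rule).
    threshold_mode
        ``"relative_to_native"`` (default): a host codon is eligible when
        its host relative fraction ≥ τ × the native codon's native relative
        fraction. ``"absolute_floor"``: host relative fraction ≥ τ — the
        common rare-codon-avoidance reading.
    seed
        required for the random control only.
    """

    threshold: float = 0.05
    threshold_mode: str = "relative_to_native"
    tie_break: str = TIE_BREAK
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= float(self.threshold) <= 1.0):
            raise ConfigurationError(
                f"threshold must be in [0, 1]; got {self.threshold}"
            )
        if self.threshold_mode not in THRESHOLD_MODES:
            raise ConfigurationError(
                f"threshold_mode must be one of {THRESHOLD_MODES}"
            )
        if self.tie_break != TIE_BREAK:
            raise ConfigurationError(f"unsupported tie_break {self.tie_break!r}")


@dataclass(frozen=True)
class PositionRecord:
    """Audit entry for one codon position (0-based codon index)."""

    position: int
    amino_acid: str
    native_codon: str
    native_rel_fraction: float
    chosen_codon: str
    host_rel_fraction: float
    match_error: float
    constrained: bool


@dataclass
class HarmonizationResult:
    """A recoded sequence plus its per-position audit trail."""

    output_sequence: str
    records: list[PositionRecord]
    mode: str
    config: HarmonizationConfig | None = None
    input_sequence: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": [r.position for r in self.records],
                "native_codon": [r.native_codon for r in self.records],
                "native_fraction": [r.native_rel_fraction for r in self.records],
                "chosen_codon": [r.chosen_codon for r in self.records],
                "host_fraction": [r.host_rel_fraction for r in self.records],
                "match_error": [r.match_error for r in self.records],
                "constrained": [r.constrained for r in self.records],
            }
        )

    def write_audit(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def total_match_error(self) -> float:
        """Sum of per-position match errors (NaN-aware)."""
        return float(np.nansum([r.match_error for r in self.records]))

    @property
    def n_constrained(self) -> int:
        return sum(r.constrained for r in self.records)


def _choice_key(native_codon: str, native_rel: float):
    """Sort key realizing: min |host − native|, then higher host fraction,
    then the native codon itself, then lexicographic order."""

    def key(item: tuple[str, float]):
        codon, frac = item
        return (abs(frac - native_rel), -frac, codon != native_codon, codon)

    return key


def _choose_codon(
    native_codon: str,
    native_rel: float,
    host_fracs: dict[str, float],
    config: HarmonizationConfig,
) -> tuple[str, float, float, bool]:
    """Threshold-constrained nearest-fraction choice for one position."""
    if config.threshold_mode == "relative_to_native":
        floor = config.threshold * native_rel
    else:
        floor = config.threshold
    key = _choice_key(native_codon, native_rel)
    best_overall = min(host_fracs.items(), key=key)
    eligible = {c: f for c, f in host_fracs.items() if f >= floor}
    if eligible:
        chosen, frac = min(eligible.items(), key=key)
        constrained = best_overall[0] not in eligible
    else:
        # no synonymous host codon clears the floor: relax, flag
        chosen, frac = best_overall
        constrained = True
    return chosen, frac, abs(frac - native_rel), constrained


def dumb_optimize(
    native_seq: str,
    native_table: CodonUsageTable,
    host_table: CodonUsageTable,
    config: HarmonizationConfig | None = None,
) -> HarmonizationResult:
    """Frequency-matched synonymous recoding with the rare-codon threshold.

    Deterministic given inputs and config. A terminal stop codon is copied
    verbatim; internal stops are rejected.
    """
    config = config or HarmonizationConfig()
    codons = split_codons(native_seq)
    records: list[PositionRecord] = []
    out: list[str] = []
    for i, codon in enumerate(codons):
        aa = STANDARD_CODE[codon]
        if aa == "*":  # terminal stop, copied verbatim
            out.append(codon)
            records.append(
                PositionRecord(i, aa, codon, native_table.rel_fraction(codon),
                               codon, host_table.rel_fraction(codon), 0.0, False)
            )
            continue
        native_rel = native_table.rel_fraction(codon)
        host_fracs = host_table.family_fractions(aa)
        chosen, frac, err, constrained = _choose_codon(
            codon, native_rel, host_fracs, config
        )
        out.append(chosen)
        records.append(
            PositionRecord(i, aa, codon, native_rel, chosen, frac, err, constrained)
        )
    return HarmonizationResult("".join(out), records, "dumb", config, "".join(codons))


def fully_optimize(
    native_seq: str, host_table: CodonUsageTable
) -> HarmonizationResult:
    """Recode every position to the host's most frequent synonymous codon."""
    codons = split_codons(native_seq)
    records: list[PositionRecord] = []
    out: list[str] = []
    for i, codon in enumerate(codons):
        aa = STANDARD_CODE[codon]
        if aa == "*":
            out.append(codon)
            records.append(
                PositionRecord(i, aa, codon, math.nan, codon,
                               host_table.rel_fraction(codon), math.nan, False)
            )
            continue
        fracs = host_table.family_fractions(aa)
        chosen = min(fracs.items(), key=lambda cf: (-cf[1], cf[0]))[0]
        records.append(
            PositionRecord(i, aa, codon, math.nan, chosen, fracs[chosen],
                           math.nan, False)
        )
        out.append(chosen)
    return HarmonizationResult("".join(out), records, "full", None, "".join(codons))


def random_control(
    native_seq: str, host_table: CodonUsageTable, seed: int | None = None
) -> HarmonizationResult:
    """Uniform synonymous reshuffle — the random reverse-transcription control."""
    if seed is None:
        raise ConfigurationError("random_control requires a seed")
    rng = np.random.default_rng(seed)
    codons = split_codons(native_seq)
    records: list[PositionRecord] = []
    out: list[str] = []
    for i, codon in enumerate(codons):
        aa = STANDARD_CODE[codon]
        if aa == "*":
            out.append(codon)
            records.append(
                PositionRecord(i, aa, codon, math.nan, codon,
                               host_table.rel_fraction(codon), math.nan, False)
            )
            continue
        family = host_table.family(aa)
        chosen = family[int(rng.integers(len(family)))]
        records.append(
            PositionRecord(i, aa, codon, math.nan, chosen,
                           host_table.rel_fraction(chosen), math.nan, False)
        )
        out.append(chosen)
    return HarmonizationResult("".join(out), records, "random", None, "".join(codons))


def verify_synonymy(a: str, b: str) -> bool:
    """True iff two equal-length in-frame sequences translate identically."""
    sa = str(a).strip().upper().replace("U", "T")
    sb = str(b).strip().upper().replace("U", "T")
    if len(sa) != len(sb):
        raise ValueError(f"length mismatch: {len(sa)} vs {len(sb)}")
    return translate(sa) == translate(sb)
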