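"""%MinMax sliding-window codon-usage profiling.

For a window of W codons the statistic compares four window means taken
over per-thousand codon usage: ``Actual`` (the codons actually used),
``Max`` (each amino acid's most-used codon), ``Min`` (least-used), and
``Avg`` (the synonymous-family mean). The window's value is

    100 · (Actual − Avg) / (Max − Avg)   when Actual ≥ Avg
    100 · (Actual − Avg) / (Avg − Min)   otherwise

so +100 means every codon in the window is its family's most common choice
and −100 the least common. Profiles of a native gene, its fully optimized
recoding, and its harmonized recoding visualize how far each construct sits
from the native translation-speed landscape.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import split_codons
from .codon_usage import STANDARD_CODE, SYNONYMOUS_FAMILIES, CodonUsageTable
from .errors import InsufficientLengthError

__all__ = ["MinMaxProfile", "minmax_profile", "profile_distance", "plot_profiles"]

_EPS = 1e-12


@dataclass
class MinMaxProfile:
    """Windowed %MinMax values at fully-contained window centers."""

    window: int
    centers: np.ndarray  # 0-based codon indices of window centers
    values: np.ndarray  # in [-100, 100]
    degenerate: np.ndarray  # True where the window had no synonymous freedom

    def to_frame(self, record_id: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "center": self.centers,
                "percent_minmax": self.values,
                "degenerate": self.degenerate,
            }
        )
        if record_id is not None:
            df.insert(0, "record_id", record_id)
        return df

    def __len__(self) -> int:
        return len(self.values)


def _window_mean(x: np.ndarray, w: int) -> np.ndarray:
    return np.convolve(x, np.ones(w), mode="valid") / w


def minmax_profile(
    seq: str, table: CodonUsageTable, window: int = 21
) -> MinMaxProfile:
    """Compute the %MinMax profile of an in-frame coding sequence.

    A terminal stop codon is excluded from the window statistics; windows
    are only computed where fully contained (no edge padding). Windows in
    which every amino acid has a single codon (no synonymous freedom) are
    reported as 0 with the degenerate flag set.
    """
    window = int(window)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd positive integer; got {window}")
    codons = split_codons(seq)
    if codons and STANDARD_CODE[codons[-1]] == "*":
        codons = codons[:-1]
    L = len(codons)
    if L < window:
        raise InsufficientLengthError(
            f"sequence has {L} non-stop codons; window is {window}"
        )

    actual = np.empty(L)
    fmax = np.empty(L)
    fmin = np.empty(L)
    fmean = np.empty(L)
    singleton = np.empty(L)
    for i, codon in enumerate(codons):
        aa = STANDARD_CODE[codon]
        st = table.family_stats(aa)
        actual[i] = table.usage(codon)
        fmax[i] = st.max_freq
        fmin[i] = st.min_freq
        fmean[i] = st.mean_freq
        singleton[i] = 1.0 if len(SYNONYMOUS_FAMILIES[aa]) == 1 else 0.0

    a = _window_mean(actual, window)
    mx = _window_mean(fmax, window)
    mn = _window_mean(fmin, window)
    av = _window_mean(fmean, window)
    degenerate = _window_mean(singleton, window) > 1.0 - _EPS

    num = a - av
    values = np.zeros_like(num)
    up = num >= 0
    den_up = mx - av
    den_dn = av - mn
    ok_up = up & (den_up > _EPS)
    ok_dn = (~up) & (den_dn > _EPS)
    # divide before scaling so that num == den yields exactly ±100
    values[ok_up] = 100.0 * (num[ok_up] / den_up[ok_up])
    values[ok_dn] = 100.0 * (num[ok_dn] / den_dn[ok_dn])
    values[degenerate] = 0.0
    np.clip(values, -100.0, 100.0, out=values)

    half = (window - 1) // 2
    centers = np.arange(half, L - half)
    return MinMaxProfile(window, centers, values, degenerate)


def profile_distance(a: MinMaxProfile, b: MinMaxProfile) -> float:
    """Mean absolute difference between two profiles on identical centers."""
    if a.window != b.window or not np.array_equal(a.centers, b.centers):
        raise ValueError("profiles are not aligned (different windows or centers)")
    return float(np.mean(np.abs(a.values - b.values)))


def plot_profiles(profiles: dict[str, MinMaxProfile], ax=None, title: str = ""):
    """Overlay profiles (e.g. native / DO / FO / random) on one axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    for label, prof in profiles.items():
        ax.plot(prof.centers, prof.values, label=label, lw=1.2)
    ax.axhline(0.0, color="0.6", lw=0.6)
    ax.set_xlabel("codon position (window center)")
    ax.set_ylabel("%MinMax")
    ax.set_ylim(-105, 105)
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    return ax
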