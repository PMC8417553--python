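"""Independent reference implementations used to cross-check the package.

These deliberately use plain loops and first-principles formulas rather
than calling into the code paths they verify.
"""

import math

from dumbopt.codon_usage import STANDARD_CODE, SYNONYMOUS_FAMILIES


def brute_force_codon_choice(native_codon, native_table, host_table, tau, mode):
    """Exhaustive threshold-constrained nearest-fraction codon choice.

    Mirrors the documented rule: eligible host codons have rel_fraction ≥
    τ·(native rel fraction) in relative mode or ≥ τ in absolute mode; if
    none qualify the constraint is dropped. Among eligible codons the one
    minimizing |host − native| wins; ties go to higher host fraction, then
    the native codon itself, then alphabetical order.
    """
    aa = STANDARD_CODE[native_codon]
    native_rel = native_table.rel_fraction(native_codon)
    floor = tau * native_rel if mode == "relative_to_native" else tau
    family = SYNONYMOUS_FAMILIES[aa]
    eligible = [c for c in family if host_table.rel_fraction(c) >= floor]
    if not eligible:
        eligible = list(family)
    best = None
    for codon in eligible:
        frac = host_table.rel_fraction(codon)
        key = (abs(frac - native_rel), -frac, codon != native_codon, codon)
        if best is None or key < best[0]:
            best = (key, codon)
    return best[1]


def naive_minmax(codon_list, table, window):
    """Window-by-window %MinMax recomputation with explicit loops."""
    values = []
    for start in range(len(codon_list) - window + 1):
        actual = maxs = mins = avgs = 0.0
        for codon in codon_list[start : start + window]:
            aa = STANDARD_CODE[codon]
            fam = SYNONYMOUS_FAMILIES[aa]
            freqs = [table.usage(c) for c in fam]
            actual += table.usage(codon)
            maxs += max(freqs)
            mins += min(freqs)
            avgs += sum(freqs) / len(freqs)
        actual /= window
        maxs /= window
        mins /= window
        avgs /= window
        if maxs - avgs < 1e-12 and avgs - mins < 1e-12:
            values.append(0.0)
        elif actual >= avgs:
            values.append(100.0 * (actual - avgs) / (maxs - avgs))
        else:
            values.append(100.0 * (actual - avgs) / (avgs - mins))
    return values


def pooled_t_test(a, b):
    """Classic two-sample pooled-variance Student t and two-tailed p."""
    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * tdist.sf(abs(t), na + nb - 2)
    return t, p
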