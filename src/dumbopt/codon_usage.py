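"""Organism codon-usage tables.

A :class:`CodonUsageTable` stores, for each of the 64 codons of the standard
genetic code, two views of how often an organism uses it:

``usage_per_1000``
    occurrences per 1000 codons across the organism's coding sequences —
    the per-thousand convention of published usage tables, consumed by the
    %MinMax profiler;

``rel_fraction``
    the codon's share of its synonymous family (fractions within each
    family sum to 1) — the cross-organism-comparable quantity the
    harmonizer matches on.

Either view determines the other within a family up to the family's total
usage, so ``rel_fraction`` is recomputed from ``usage_per_1000`` when a
table file omits it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Data import CodonTable as _bp_codon_table

from .errors import CodonTableSchemaError, GeneticCodeMismatchError

__all__ = [
    "STANDARD_CODE",
    "SYNONYMOUS_FAMILIES",
    "AMINO_ACIDS",
    "CodonUsageTable",
    "FamilyStats",
    "load_codon_table",
    "write_codon_table",
    "example_table",
    "family_stats",
]

_bp = _bp_codon_table.unambiguous_dna_by_id[1]

#: codon -> 1-letter amino acid, with "*" for the three stop codons
STANDARD_CODE: dict[str, str] = dict(_bp.forward_table)
STANDARD_CODE.update({c: "*" for c in _bp.stop_codons})

#: amino acid (incl. "*") -> tuple of synonymous codons, lexicographic order
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in STANDARD_CODE.items() if a == aa))
    for aa in sorted(set(STANDARD_CODE.values()))
}

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(STANDARD_CODE.values())))

_ALL_CODONS = frozenset(STANDARD_CODE)


@dataclass(frozen=True)
class FamilyStats:
    """Usage extrema and mean over one synonymous codon family.

    Frequencies are per-thousand (``usage_per_1000``). Ties on equal
    frequency resolve to the lexicographically first codon.
    """

    amino_acid: str
    max_codon: str
    min_codon: str
    max_freq: float
    min_freq: float
    mean_freq: float


def _normalize_codon(codon: str) -> str:
    return str(codon).strip().upper().replace("U", "T")


class CodonUsageTable:
    """Validated per-organism codon statistics for all 64 codons."""

    def __init__(self, organism_id: str, frame: pd.DataFrame):
        """Build from a frame with columns codon, amino_acid, usage_per_1000
        and optionally rel_fraction. Prefer the classmethod constructors.
        """
        self.organism_id = str(organism_id)
        self._frame = self._validate(frame)
        self._usage = self._frame["usage_per_1000"].to_dict()
        self._rel = self._frame["rel_fraction"].to_dict()
        self._stats: dict[str, FamilyStats] = {}

    # ------------------------------------------------------------------
    @staticmethod
    def _validate(frame: pd.DataFrame) -> pd.DataFrame:
        df = frame.copy()
        required = {"codon", "amino_acid", "usage_per_1000"}
        missing_cols = required - set(df.columns)
        if missing_cols:
            raise CodonTableSchemaError(
                f"missing required column(s): {sorted(missing_cols)}"
            )
        df["codon"] = df["codon"].map(_normalize_codon)
        df["amino_acid"] = df["amino_acid"].astype(str).str.strip().str.upper()

        dup = df["codon"][df["codon"].duplicated()]
        if len(dup):
            raise CodonTableSchemaError(f"duplicate codon(s): {sorted(set(dup))}")
        present = set(df["codon"])
        bad = present - _ALL_CODONS
        if bad:
            raise CodonTableSchemaError(f"unknown codon(s): {sorted(bad)}")
        absent = _ALL_CODONS - present
        if absent:
            raise CodonTableSchemaError(f"missing codon(s): {sorted(absent)}")

        for codon, aa in zip(df["codon"], df["amino_acid"]):
            expected = STANDARD_CODE[codon]
            if aa != expected:
                raise GeneticCodeMismatchError(
                    f"codon {codon} listed as {aa!r} but encodes {expected!r} "
                    "in the standard genetic code"
                )

        usage = pd.to_numeric(df["usage_per_1000"], errors="raise").astype(float)
        if (usage < 0).any():
            neg = df["codon"][usage < 0].tolist()
            raise CodonTableSchemaError(f"negative usage for codon(s): {neg}")
        total = float(usage.sum())
        if abs(total - 1000.0) > 1.0:
            raise CodonTableSchemaError(
                f"usage_per_1000 sums to {total:.3f}; expected 1000 ± 1 "
                "(per-thousand convention)"
            )
        df["usage_per_1000"] = usage

        df = df.set_index("codon").sort_index()

        # recompute rel_fraction from usage; validate against supplied values
        rel = pd.Series(0.0, index=df.index)
        for aa, family in SYNONYMOUS_FAMILIES.items():
            fam = list(family)
            fam_usage = df.loc[fam, "usage_per_1000"]
            s = float(fam_usage.sum())
            if s > 0:
                rel.loc[fam] = fam_usage / s
            else:
                rel.loc[fam] = 1.0 / len(fam)  # degenerate: uniform
        if "rel_fraction" in df.columns and df["rel_fraction"].notna().all():
            supplied = pd.to_numeric(df["rel_fraction"], errors="raise").astype(float)
            if ((supplied < 0) | (supplied > 1)).any():
                raise CodonTableSchemaError("rel_fraction outside [0, 1]")
            for aa, family in SYNONYMOUS_FAMILIES.items():
                fam = list(family)
                fam_sum = float(supplied.loc[fam].sum())
                if abs(fam_sum - 1.0) > 1e-6:
                    raise CodonTableSchemaError(
                        f"rel_fraction for family {aa!r} sums to {fam_sum}, not 1"
                    )
                if np.max(np.abs(supplied.loc[fam].to_numpy() - rel.loc[fam].to_numpy())) > 1e-6:
                    raise CodonTableSchemaError(
                        f"rel_fraction for family {aa!r} is not proportional to "
                        "usage_per_1000"
                    )
            df["rel_fraction"] = supplied
        else:
            df["rel_fraction"] = rel
        return df[["amino_acid", "usage_per_1000", "rel_fraction"]]

    # ------------------------------------------------------------------
    @classmethod
    def from_usage(
        cls, organism_id: str, usage: Mapping[str, float]
    ) -> "CodonUsageTable":
        """Build from a codon -> per-thousand-usage mapping."""
        rows = [
            {
                "codon": _normalize_codon(c),
                "amino_acid": STANDARD_CODE.get(_normalize_codon(c), "?"),
                "usage_per_1000": v,
            }
            for c, v in usage.items()
        ]
        return cls(organism_id, pd.DataFrame(rows))

    @classmethod
    def from_fractions(
        cls,
        organism_id: str,
        fractions: Mapping[str, Mapping[str, float]],
        family_weights: Mapping[str, float] | None = None,
    ) -> "CodonUsageTable":
        """Build from per-family relative fractions.

        ``fractions`` maps amino acid -> {codon: fraction}; families absent
        from the mapping get uniform fractions. Per-thousand usage is
        synthesized by giving each amino-acid family a total usage
        proportional to ``family_weights`` (uniform by default), so tables
        built this way are exact in ``rel_fraction`` and conventional in
        ``usage_per_1000``.
        """
        weights = dict(family_weights or {})
        aas = list(SYNONYMOUS_FAMILIES)
        w = np.array([weights.get(aa, 1.0) for aa in aas], dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise CodonTableSchemaError("family_weights must be non-negative")
        w = 1000.0 * w / w.sum()
        usage: dict[str, float] = {}
        for aa, fam_total in zip(aas, w):
            family = SYNONYMOUS_FAMILIES[aa]
            fr = fractions.get(aa)
            if fr is None:
                fr = {c: 1.0 / len(family) for c in family}
            fr = {_normalize_codon(c): float(v) for c, v in fr.items()}
            if set(fr) != set(family):
                raise CodonTableSchemaError(
                    f"fractions for {aa!r} must cover codons {family}"
                )
            s = sum(fr.values())
            if s <= 0:
                raise CodonTableSchemaError(f"fractions for {aa!r} sum to {s}")
            for c in family:
                usage[c] = fam_total * fr[c] / s
        return cls.from_usage(organism_id, usage)

    # ------------------------------------------------------------------
    def usage(self, codon: str) -> float:
        """Per-thousand usage of ``codon``."""
        return self._usage[_normalize_codon(codon)]

    def rel_fraction(self, codon: str) -> float:
        """Codon's fraction of its synonymous family."""
        return self._rel[_normalize_codon(codon)]

    def amino_acid(self, codon: str) -> str:
        return STANDARD_CODE[_normalize_codon(codon)]

    def family(self, amino_acid: str) -> tuple[str, ...]:
        aa = str(amino_acid).strip().upper()
        if aa not in SYNONYMOUS_FAMILIES:
            raise ValueError(f"unknown amino-acid symbol {amino_acid!r}")
        return SYNONYMOUS_FAMILIES[aa]

    def family_fractions(self, amino_acid: str) -> dict[str, float]:
        """{codon: rel_fraction} over the synonymous family, lexicographic order."""
        return {c: self._rel[c] for c in self.family(amino_acid)}

    def family_stats(self, amino_acid: str) -> FamilyStats:
        """Extrema and mean of per-thousand usage over a synonymous family."""
        aa = str(amino_acid).strip().upper()
        if aa not in self._stats:
            fam = self.family(aa)
            freqs = np.array([self._usage[c] for c in fam])
            # lexicographic tie-break: fam is sorted, argmax/argmin take first
            self._stats[aa] = FamilyStats(
                amino_acid=aa,
                max_codon=fam[int(np.argmax(freqs))],
                min_codon=fam[int(np.argmin(freqs))],
                max_freq=float(freqs.max()),
                min_freq=float(freqs.min()),
                mean_freq=float(freqs.mean()),
            )
        return self._stats[aa]

    def to_frame(self) -> pd.DataFrame:
        """Copy of the table as a DataFrame indexed by codon."""
        return self._frame.copy()

    def __repr__(self) -> str:  # pragma: no cover
        return f"CodonUsageTable(organism_id={self.organism_id!r}, 64 codons)"


def load_codon_table(
    path: str | Path, organism_id: str | None = None, *, rescale: bool = False
) -> CodonUsageTable:
    """Read a codon-usage CSV (``codon,amino_acid,usage_per_1000[,rel_fraction]``).

    With ``rescale=True`` the usage column is renormalized to sum to 1000
    before validation, accommodating tables given as raw counts or
    percentages.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if rescale and "usage_per_1000" in df.columns:
        total = pd.to_numeric(df["usage_per_1000"]).sum()
        if total > 0:
            df["usage_per_1000"] = df["usage_per_1000"] * (1000.0 / total)
        df = df.drop(columns=["rel_fraction"], errors="ignore")
    return CodonUsageTable(organism_id or path.stem, df)


def write_codon_table(table: CodonUsageTable, path: str | Path) -> None:
    """Write a table to CSV with full float precision (round-trips exactly)."""
    df = table.to_frame().reset_index()
    df.to_csv(path, index=False, float_format="%.17g")


def example_table(name: str) -> CodonUsageTable:
    """Load a bundled fixture table: ``"human"`` or ``"ecoli"``.

    These carry representative genome-wide usage values for each organism
    and exist so that every analysis is runnable with no download.
    """
    from importlib.resources import files

    name = name.lower()
    if name not in {"human", "ecoli"}:
        raise ValueError("example tables: 'human' or 'ecoli'")
    with (files("dumbopt") / "data" / f"{name}.csv").open("r") as fh:
        df = pd.read_csv(fh)
    return CodonUsageTable(name, df)


def family_stats(table: CodonUsageTable, amino_acid: str) -> FamilyStats:
    """Functional alias for :meth:`CodonUsageTable.family_stats`."""
    return table.family_stats(amino_acid)
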