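"""Seeded synthetic-data generators.

Each generator is a bit-reproducible function of its spec (including the
seed) and produces inputs with the statistical structure the matching
analysis assumes: genes whose codon choices follow a given usage table,
polarization titrations from the one-site depletion model with additive
Gaussian noise, and GTPase plates where RLU decreases linearly with the
hydrolyzed fraction on top of a blank background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .binding import BindingCurve, fraction_bound
from .codon_usage import SYNONYMOUS_FAMILIES, CodonUsageTable
from .gtpase import GTPaseExperiment

__all__ = [
    "GeneGenSpec",
    "BindingGenSpec",
    "GTPaseGenSpec",
    "generate_gene",
    "generate_binding_curve",
    "generate_gtpase",
]

_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class GeneGenSpec:
    """Random coding gene drawn codon-by-codon from a usage table.

    Give either an explicit ``protein`` sequence or a ``length``; with a
    bare length, residues are sampled with probabilities proportional to
    each amino-acid family's total usage in ``table``, so the synthetic
    gene has that organism's amino-acid composition too.
    """

    table: CodonUsageTable
    seed: int
    protein: str | None = None
    length: int | None = None
    include_stop: bool = True

    def __post_init__(self) -> None:
        if (self.protein is None) == (self.length is None):
            raise ValueError("give exactly one of protein or length")
        if self.protein is not None:
            bad = sorted(set(self.protein.upper()) - _RESIDUES)
            if bad:
                raise ValueError(f"invalid residue(s): {bad}")
        elif self.length < 1:
            raise ValueError("length must be positive")


def generate_gene(spec: GeneGenSpec) -> str:
    """Coding DNA whose codons are drawn from the table's family fractions."""
    rng = np.random.default_rng(spec.seed)
    table = spec.table
    if spec.protein is not None:
        protein = spec.protein.upper()
    else:
        aas = sorted(_RESIDUES)
        totals = np.array(
            [sum(table.usage(c) for c in SYNONYMOUS_FAMILIES[aa]) for aa in aas]
        )
        probs = totals / totals.sum()
        protein = "".join(rng.choice(aas, size=spec.length, p=probs))

    codons: list[str] = []
    for aa in protein:
        family = SYNONYMOUS_FAMILIES[aa]
        fracs = np.array([table.rel_fraction(c) for c in family])
        codons.append(family[int(rng.choice(len(family), p=fracs))])
    if spec.include_stop:
        stops = SYNONYMOUS_FAMILIES["*"]
        fracs = np.array([table.rel_fraction(c) for c in stops])
        codons.append(stops[int(rng.choice(len(stops), p=fracs))])
    return "".join(codons)


@dataclass
class BindingGenSpec:
    """One-site polarization titration with additive Gaussian noise.

    Defaults mirror the assay conditions the analysis targets: 100 nM
    labeled ligand, a receptor grid bracketing Kd values in the tens-of-nM
    range with a zero point, three replicates, and noise at a few percent
    of the polarization span.
    """

    kd: float  # molar
    seed: int
    ligand_total: float = 100e-9
    receptor_concs: Sequence[float] = (
        0.0, 2e-9, 5e-9, 10e-9, 20e-9, 50e-9,
        100e-9, 200e-9, 500e-9, 1e-6, 2e-6,
    )
    p_free: float = 0.05
    p_bound: float = 0.25
    noise_sd: float = 0.0
    replicates: int = 3
    orientation_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.kd < 0 or self.ligand_total <= 0 or self.noise_sd < 0:
            raise ValueError("kd ≥ 0, ligand_total > 0, noise_sd ≥ 0 required")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if not (0.0 < self.orientation_factor <= 1.0):
            raise ValueError("orientation_factor must be in (0, 1]")
        if 0.0 not in [float(c) for c in self.receptor_concs]:
            self.receptor_concs = (0.0, *self.receptor_concs)


def generate_binding_curve(spec: BindingGenSpec) -> BindingCurve:
    """Reads = P_free + (P_bound − P_free)·FB(f·R, L, Kd) + N(0, noise_sd)."""
    rng = np.random.default_rng(spec.seed)
    concs = np.asarray(spec.receptor_concs, dtype=float)
    span = spec.p_bound - spec.p_free
    reads = []
    for conc in concs:
        fb = fraction_bound(
            spec.orientation_factor * conc, spec.ligand_total, spec.kd
        )
        clean = spec.p_free + span * fb
        reads.append(clean + rng.normal(0.0, spec.noise_sd, size=spec.replicates))
    return BindingCurve.from_arrays(
        spec.ligand_total, concs, reads,
        orientation_factor=spec.orientation_factor,
    )


@dataclass
class GTPaseGenSpec:
    """GTPase plate: RLU = blank + standard_level·(1 − h) + noise.

    ``hydrolysis`` maps condition label → true hydrolyzed fraction h in
    [0, 1]; standard wells use h = 0 and blanks carry only the background
    level. Three replicates and three blanks follow assay convention.
    """

    hydrolysis: Mapping[str, float]
    seed: int
    standard_level: float = 1e6
    blank_level: float = 5e4
    noise_sd: float = 0.0
    replicates: int = 3
    n_blanks: int = 3
    n_standard: int = 3

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.standard_level <= 0 or self.blank_level < 0:
            raise ValueError("invalid level or noise parameters")
        if min(self.replicates, self.n_blanks, self.n_standard) < 1:
            raise ValueError("replicate counts must be positive")


def generate_gtpase(spec: GTPaseGenSpec) -> GTPaseExperiment:
    """Sample a full plate (conditions, blanks, no-hydrolysis standard)."""
    rng = np.random.default_rng(spec.seed)
    conditions = {}
    for label, h in spec.hydrolysis.items():
        clean = spec.blank_level + spec.standard_level * (1.0 - float(h))
        conditions[str(label)] = clean + rng.normal(
            0.0, spec.noise_sd, size=spec.replicates
        )
    standard = spec.blank_level + spec.standard_level + rng.normal(
        0.0, spec.noise_sd, size=spec.n_standard
    )
    blanks = spec.blank_level + rng.normal(0.0, spec.noise_sd, size=spec.n_blanks)
    return GTPaseExperiment(conditions, blanks, standard)
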