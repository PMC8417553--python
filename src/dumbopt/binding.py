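"""Fluorescence-polarization saturation binding analysis.

Polarization P = (I∥ − I⊥)/(I∥ + I⊥) of a fluorophore-labeled peptide
ligand rises as receptor binding slows its tumbling. Titrating receptor at
fixed labeled-ligand concentration L traces a saturation curve

    P(R) = P0 + ΔP · FB(f·R, L, Kd)

where f is the orientation factor (1.0 for open discs such as SMALPs, 0.5
for proteoliposomes, where on average half the receptors face inward and
cannot bind), and FB is the fraction of ligand bound. Because L here
(100 nM) is comparable to the dissociation constants being measured, the
default bound-fraction model is the exact one-site solution with ligand
depletion,

    FB = ((R + L + Kd) − sqrt((R + L + Kd)² − 4·R·L)) / (2·L),

with the hyperbolic approximation FB = R/(R + Kd) available for the
L ≪ Kd regime. Curves are normalized before fitting by subtracting the
lowest zero-point (no-receptor) read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    DataInsufficiencyError,
    FitFailureError,
    ZeroIntensityError,
)

__all__ = [
    "polarization",
    "BindingCurve",
    "normalize_curve",
    "fraction_bound",
    "fraction_bound_hyperbolic",
    "BindingFit",
    "fit_kd",
]

MODELS = ("depletion", "hyperbolic")


def polarization(i_par, i_perp):
    """P = (I∥ − I⊥)/(I∥ + I⊥); scalar or elementwise on arrays."""
    i_par = np.asarray(i_par, dtype=float)
    i_perp = np.asarray(i_perp, dtype=float)
    if (i_par < 0).any() or (i_perp < 0).any():
        raise ValueError("emission intensities must be non-negative")
    total = i_par + i_perp
    if (total <= 0).any():
        raise ZeroIntensityError(
            "polarization undefined where I_par + I_perp is zero"
        )
    out = (i_par - i_perp) / total
    return float(out) if out.ndim == 0 else out


@dataclass
class BindingCurve:
    """Receptor-titration polarization data at fixed labeled-ligand L.

    ``data`` is long-form with columns ``receptor_conc`` (nominal molar),
    ``replicate`` and ``polarization``. Concentrations are nominal; the
    effective concentration used in fitting is ``orientation_factor``
    times nominal.
    """

    ligand_total: float  # molar
    data: pd.DataFrame
    orientation_factor: float = 1.0
    normalized: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.orientation_factor <= 1.0):
            raise ValueError("orientation_factor must be in (0, 1]")
        if self.ligand_total <= 0:
            raise ValueError("ligand_total must be positive")
        required = {"receptor_conc", "replicate", "polarization"}
        if not required <= set(self.data.columns):
            raise ValueError(f"data must have columns {sorted(required)}")
        if (self.data["receptor_conc"] < 0).any():
            raise ValueError("receptor concentrations must be non-negative")

    @classmethod
    def from_arrays(
        cls,
        ligand_total: float,
        receptor_concs: Sequence[float],
        reads: Sequence[Sequence[float]],
        orientation_factor: float = 1.0,
        normalized: bool = False,
    ) -> "BindingCurve":
        """Build from a concentration grid and per-concentration replicate reads."""
        rows = []
        for conc, reps in zip(receptor_concs, reads):
            for j, p in enumerate(np.atleast_1d(reps)):
                rows.append(
                    {"receptor_conc": float(conc), "replicate": j,
                     "polarization": float(p)}
                )
        return cls(ligand_total, pd.DataFrame(rows), orientation_factor, normalized)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        ligand_total: float,
        orientation_factor: float = 1.0,
        conc_unit: float = 1e-9,
    ) -> "BindingCurve":
        """Read ``receptor_conc_nM,replicate,(polarization | I_parallel,I_perp)``."""
        df = pd.read_csv(path)
        if "polarization" not in df.columns:
            df["polarization"] = polarization(
                df["I_parallel"].to_numpy(), df["I_perp"].to_numpy()
            )
        out = pd.DataFrame(
            {
                "receptor_conc": df["receptor_conc_nM"].astype(float) * conc_unit,
                "replicate": df.get("replicate", pd.Series(range(len(df)))),
                "polarization": df["polarization"].astype(float),
            }
        )
        return cls(ligand_total, out, orientation_factor)

    @property
    def receptor_concs(self) -> np.ndarray:
        """Sorted unique nominal receptor concentrations."""
        return np.sort(self.data["receptor_conc"].unique())

    @property
    def zero_point_reads(self) -> np.ndarray:
        return self.data.loc[
            self.data["receptor_conc"] == 0.0, "polarization"
        ].to_numpy()


def normalize_curve(curve: BindingCurve) -> BindingCurve:
    """Subtract the lowest zero-point (no-receptor) read from every read."""
    zero = curve.zero_point_reads
    if zero.size == 0:
        raise ValueError("curve has no zero-point (receptor_conc == 0) reads")
    baseline = float(zero.min())
    data = curve.data.copy()
    data["polarization"] = data["polarization"] - baseline
    return replace(curve, data=data, normalized=True)


def fraction_bound(receptor, ligand_total, kd):
    """Exact one-site bound-ligand fraction with ligand depletion.

    Computed in the cancellation-free form FB = 2R / (b + sqrt(b² − 4RL))
    with b = R + L + Kd and the discriminant rewritten as
    (R − L + Kd)² + 4·L·Kd ≥ 0. Continuous and nondecreasing in R.
    """
    r = np.asarray(receptor, dtype=float)
    L = float(ligand_total)
    kd = float(kd)
    if (r < 0).any() or L <= 0 or kd < 0:
        raise ValueError("need receptor ≥ 0, ligand_total > 0, kd ≥ 0")
    b = r + L + kd
    disc = (r - L + kd) ** 2 + 4.0 * L * kd
    denom = b + np.sqrt(disc)
    out = np.where(denom > 0, 2.0 * r / np.where(denom > 0, denom, 1.0), 0.0)
    return float(out) if out.ndim == 0 else out


def fraction_bound_hyperbolic(receptor, kd):
    """Hyperbolic (no-depletion) approximation FB = R/(R + Kd)."""
    r = np.asarray(receptor, dtype=float)
    kd = float(kd)
    if (r < 0).any() or kd < 0:
        raise ValueError("need receptor ≥ 0 and kd ≥ 0")
    out = np.where(r + kd > 0, r / np.where(r + kd > 0, r + kd, 1.0), 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class BindingFit:
    """One-site fit results. ``se`` are asymptotic standard errors; ``ci95``
    are t-based intervals; bootstrap quantities are present when requested.
    The ±band a practitioner quotes may be SE, SD, or CI — all are reported
    under explicit names."""

    kd: float
    delta_p: float
    p0: float
    se: dict
    ci95: dict
    model: str
    ligand_total: float
    orientation_factor: float
    n_points: int
    dof: int
    residuals: np.ndarray
    bootstrap_kd: np.ndarray | None = None
    bootstrap_sd: float | None = None
    bootstrap_ci95: tuple[float, float] | None = None

    def predict(self, receptor_conc) -> np.ndarray:
        r_eff = np.asarray(receptor_conc, dtype=float) * self.orientation_factor
        if self.model == "depletion":
            fb = fraction_bound(r_eff, self.ligand_total, self.kd)
        else:
            fb = fraction_bound_hyperbolic(r_eff, self.kd)
        return self.p0 + self.delta_p * fb

    def summary(self) -> dict:
        out = {
            "model": self.model,
            "Kd_nM": self.kd / 1e-9,
            "Kd_se_nM": self.se["kd"] / 1e-9,
            "Kd_ci95_nM": [c / 1e-9 for c in self.ci95["kd"]],
            "delta_P": self.delta_p,
            "P0": self.p0,
            "orientation_factor": self.orientation_factor,
            "ligand_nM": self.ligand_total / 1e-9,
            "n_points": self.n_points,
        }
        if self.bootstrap_kd is not None:
            out["Kd_bootstrap_sd_nM"] = self.bootstrap_sd / 1e-9
            out["Kd_bootstrap_ci95_nM"] = [
                c / 1e-9 for c in self.bootstrap_ci95
            ]
        return out


def _initial_kd(r_eff: np.ndarray, reads: np.ndarray) -> float:
    """Effective concentration nearest the half-maximal mean read."""
    df = pd.DataFrame({"r": r_eff, "p": reads}).groupby("r")["p"].mean()
    target = df.max() / 2.0
    positive = df[df.index > 0]
    if positive.empty:
        raise DataInsufficiencyError("no nonzero receptor concentrations")
    idx = (positive - target).abs().idxmin()
    return float(idx)


def fit_kd(
    curve: BindingCurve,
    model: str = "depletion",
    *,
    bootstrap: int = 0,
    seed: int | None = None,
) -> BindingFit:
    """Nonlinear least squares of P(R) = P0 + ΔP·FB(f·R, L, Kd).

    Replicates are fit jointly as individual points. The curve is
    zero-point-normalized first if it is not already. Bootstrap confidence
    intervals resample replicates within each concentration (seeded).
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    if not curve.normalized:
        curve = normalize_curve(curve)

    r_nom = curve.data["receptor_conc"].to_numpy(dtype=float)
    reads = curve.data["polarization"].to_numpy(dtype=float)
    f = curve.orientation_factor
    L = curve.ligand_total
    r_eff = f * r_nom

    if len(reads) < 4:
        raise DataInsufficiencyError(
            f"{len(reads)} points cannot support a 3-parameter fit"
        )
    n_conc = len(np.unique(r_eff))
    if n_conc < 4:
        warnings.warn(
            f"only {n_conc} distinct effective concentrations; "
            "≥4 spanning the Kd are recommended",
            stacklevel=2,
        )
    if np.ptp(reads) < 1e-12:
        raise FitFailureError(
            "flat curve: zero signal span, Kd is unidentifiable",
            {"read_span": float(np.ptp(reads))},
        )

    def model_fn(r, kd, dp, p0):
        if model == "depletion":
            fb = fraction_bound(f * r, L, kd)
        else:
            fb = fraction_bound_hyperbolic(f * r, kd)
        return p0 + dp * fb

    kd0 = _initial_kd(r_eff, reads)
    p0_guess = (max(kd0, 1e-30), float(reads.max()), 0.0)
    tiny = 1e-30
    try:
        popt, pcov = optimize.curve_fit(
            model_fn,
            r_nom,
            reads,
            p0=p0_guess,
            bounds=([tiny, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitFailureError(
            f"curve fit did not converge: {exc}",
            {"p0": p0_guess, "n_points": len(reads)},
        ) from exc

    kd, dp, p0 = (float(v) for v in popt)
    perr = np.sqrt(np.diag(pcov))
    if not np.all(np.isfinite(perr)):
        raise FitFailureError(
            "singular covariance: parameters unidentifiable (flat or "
            "degenerate curve)",
            {"popt": popt.tolist()},
        )
    dof = len(reads) - 3
    tcrit = stats.t.ppf(0.975, dof) if dof > 0 else np.inf
    se = {"kd": float(perr[0]), "delta_p": float(perr[1]), "p0": float(perr[2])}
    ci95 = {
        name: (val - tcrit * s, val + tcrit * s)
        for name, val, s in zip(("kd", "delta_p", "p0"), (kd, dp, p0), perr.tolist())
    }
    residuals = reads - model_fn(r_nom, kd, dp, p0)

    fit = BindingFit(
        kd=kd,
        delta_p=dp,
        p0=p0,
        se=se,
        ci95=ci95,
        model=model,
        ligand_total=L,
        orientation_factor=f,
        n_points=len(reads),
        dof=dof,
        residuals=residuals,
    )

    if bootstrap > 0:
        if seed is None:
            raise ValueError("bootstrap requires a seed")
        rng = np.random.default_rng(seed)
        groups = [g.index.to_numpy() for _, g in curve.data.groupby("receptor_conc")]
        kds = []
        for _ in range(bootstrap):
            idx = np.concatenate(
                [rng.choice(g, size=len(g), replace=True) for g in groups]
            )
            sample = curve.data.loc[idx]
            try:
                bpopt, _ = optimize.curve_fit(
                    model_fn,
                    sample["receptor_conc"].to_numpy(dtype=float),
                    sample["polarization"].to_numpy(dtype=float),
                    p0=(kd, dp, p0),
                    bounds=([tiny, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
                    maxfev=20000,
                )
            except RuntimeError:
                continue
            kds.append(float(bpopt[0]))
        if kds:
            arr = np.array(kds)
            fit.bootstrap_kd = arr
            fit.bootstrap_sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
            fit.bootstrap_ci95 = (
                float(np.percentile(arr, 2.5)),
                float(np.percentile(arr, 97.5)),
            )
    return fit
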