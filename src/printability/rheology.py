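"""Power-law rheology and pneumatic pressure planning for extrusion printing.

Biomaterial inks for extrusion-based bioprinting are shear-thinning polymer
solutions.  Their flow curve is described by the Ostwald-de Waele (power-law)
model

    eta(gamma_dot) = K * gamma_dot**(n - 1)

with flow-behavior exponent ``n`` (dimensionless, n < 1 for shear thinning)
and consistency index ``K`` (Pa s^n).  Coupling this model with the
Hagen-Poiseuille relation for laminar flow of a power-law fluid through a
cylindrical capillary links the volumetric flow rate ``Q`` to the pneumatic
driving pressure ``p``:

    Q = v_bar * pi * R**2 = (n pi / (3n + 1)) * R**3 * (R p / (2 K l))**(1/n)

where ``R`` and ``l`` are the nozzle inner radius and length and ``v_bar`` the
mean extrusion velocity.  Solving for ``p`` gives the closed form

    p = 2 K l * ((3n + 1) v_bar / n)**n / R**(n + 1)

which is what a printer operator needs: the pressure that deposits material at
the same rate as the print-head travel speed, regardless of the ink's
viscosity.

Public interfaces use lab-bench units (mm, s, kPa, Pa s^n); conversion to SI
happens in exactly one place because the ``R**(n+1)`` term amplifies any unit
mistake enormously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ViscosityCurve",
    "PowerLawModel",
    "NozzleGeometry",
    "ExtrusionPlan",
    "fit_power_law",
    "viscosity_at",
    "flow_rate",
    "required_pressure",
    "plan_extrusion",
    "read_viscosity_csv",
]

_MM = 1e-3  # mm -> m
_KPA = 1e3  # kPa -> Pa


@dataclass(frozen=True)
class ViscosityCurve:
    """A rheometer flow sweep: apparent viscosity versus shear rate.

    Parameters
    ----------
    shear_rates : sequence of float
        Shear rates in 1/s; strictly positive, strictly increasing.
    viscosities : sequence of float
        Apparent viscosities in Pa s; strictly positive.
    replicate_label : str
        Free-text identifier of the replicate.
    """

    shear_rates: np.ndarray
    viscosities: np.ndarray
    replicate_label: str = ""

    def __post_init__(self) -> None:
        sr = np.asarray(self.shear_rates, dtype=float)
        visc = np.asarray(self.viscosities, dtype=float)
        if sr.ndim != 1 or visc.ndim != 1 or sr.size != visc.size or sr.size < 3:
            raise ValueError("invalid curve: need matched 1-D arrays of length >= 3")
        if not (np.all(sr > 0) and np.all(visc > 0)):
            raise ValueError("invalid curve: shear rates and viscosities must be positive")
        if not np.all(np.diff(sr) > 0):
            raise ValueError("invalid curve: shear rates must be strictly increasing")
        object.__setattr__(self, "shear_rates", sr)
        object.__setattr__(self, "viscosities", visc)


@dataclass(frozen=True)
class PowerLawModel:
    """Fitted Ostwald-de Waele parameters.

    Attributes
    ----------
    n : float
        Flow-behavior exponent (dimensionless, > 0; < 1 means shear thinning).
    K : float
        Consistency index in Pa s^n.
    fit_range : tuple of float
        Shear-rate interval (1/s) the fit was restricted to.
    fit_quality : float
        Coefficient of determination of the log-log regression.
    """

    n: float
    K: float
    fit_range: tuple[float, float] = (np.nan, np.nan)
    fit_quality: float = np.nan

    def __post_init__(self) -> None:
        if not (self.n > 0 and self.K > 0):
            raise ValueError("invalid model: n and K must be positive")


@dataclass(frozen=True)
class NozzleGeometry:
    """Cylindrical nozzle, default 0.61 mm inner diameter x 12.7 mm length."""

    radius: float = 0.305  # mm
    length: float = 12.7  # mm

    def __post_init__(self) -> None:
        if not (self.radius > 0 and self.length > 0):
            raise ValueError("invalid nozzle: radius and length must be positive")


@dataclass(frozen=True)
class ExtrusionPlan:
    """Mutually consistent (velocity, pressure, flow-rate) triple for one ink."""

    mean_velocity: float  # mm/s
    pressure: float  # kPa
    flow_rate: float  # mm^3/s
    model: PowerLawModel
    nozzle: NozzleGeometry


def fit_power_law(
    curves: ViscosityCurve | Iterable[ViscosityCurve],
    fit_range: tuple[float, float] = (1.0, math.inf),
) -> PowerLawModel:
    """Fit the Ostwald-de Waele model by least squares in log-log space.

    ``log eta = log K + (n - 1) log gamma_dot`` is linear, so ordinary least
    squares on the log-transformed data gives ``n`` from the slope and ``K``
    from the intercept.  Points outside ``fit_range`` are excluded; the default
    lower bound of 1 1/s skips the low-shear Newtonian plateau that
    alginate/GelMA inks exhibit, which the power law cannot describe.

    Parameters
    ----------
    curves : ViscosityCurve or iterable of ViscosityCurve
        One sweep, or several replicates that are pooled before fitting.
    fit_range : (float, float)
        Inclusive shear-rate window in 1/s.

    Returns
    -------
    PowerLawModel
    """
    if isinstance(curves, ViscosityCurve):
        curves = [curves]
    lo, hi = fit_range
    if not lo < hi:
        raise ValueError("invalid fit range: min must be below max")
    rates, viscs = [], []
    for c in curves:
        keep = (c.shear_rates >= lo) & (c.shear_rates <= hi)
        rates.append(c.shear_rates[keep])
        viscs.append(c.viscosities[keep])
    gamma = np.concatenate(rates)
    eta = np.concatenate(viscs)
    if gamma.size < 3:
        raise ValueError("insufficient data: fewer than 3 points in fit range")
    x = np.log(gamma)
    y = np.log(eta)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return PowerLawModel(
        n=float(slope + 1.0),
        K=float(np.exp(intercept)),
        fit_range=(float(gamma.min()), float(gamma.max())),
        fit_quality=r2,
    )


def viscosity_at(model: PowerLawModel, shear_rate: float) -> float:
    """Apparent viscosity K * gamma_dot**(n-1) in Pa s at ``shear_rate`` (1/s)."""
    shear_rate = np.asarray(shear_rate, dtype=float)
    if np.any(shear_rate <= 0):
        raise ValueError("invalid shear rate: must be positive")
    out = model.K * shear_rate ** (model.n - 1.0)
    return float(out) if out.ndim == 0 else out


def flow_rate(model: PowerLawModel, nozzle: NozzleGeometry, pressure: float) -> float:
    """Volumetric flow rate through the nozzle at a given pneumatic pressure.

    Evaluates the power-law Hagen-Poiseuille relation
    ``Q = (n pi / (3n+1)) R^3 (R p / (2 K l))^(1/n)``.

    Parameters
    ----------
    pressure : float
        Pneumatic pressure in kPa, > 0.

    Returns
    -------
    float
        Flow rate in mm^3/s.
    """
    if not pressure > 0:
        raise ValueError("invalid pressure: must be positive")
    n, K = model.n, model.K
    R = nozzle.radius * _MM
    l = nozzle.length * _MM
    p = pressure * _KPA
    q_si = (n * math.pi / (3 * n + 1)) * R**3 * (R * p / (2 * K * l)) ** (1 / n)
    return q_si / _MM**3


def required_pressure(
    model: PowerLawModel, nozzle: NozzleGeometry, mean_velocity: float
) -> float:
    """Pneumatic pressure (kPa) giving mean extrusion velocity ``v_bar`` (mm/s).

    Closed-form inversion of the power-law Hagen-Poiseuille relation at
    ``Q = v_bar pi R^2``:

        p = 2 K l ((3n + 1) v_bar / n)**n / R**(n + 1)

    Matching the print-head travel speed to ``v_bar`` deposits the same strand
    volume per unit path length for every ink, which is the premise of
    flow-rate-controlled printability comparisons.
    """
    if not mean_velocity > 0:
        raise ValueError("invalid velocity: must be positive")
    n, K = model.n, model.K
    R = nozzle.radius * _MM
    l = nozzle.length * _MM
    v = mean_velocity * _MM
    p_si = 2 * K * l * ((3 * n + 1) * v / n) ** n / R ** (n + 1)
    return p_si / _KPA


def plan_extrusion(
    model: PowerLawModel, nozzle: NozzleGeometry, mean_velocity: float
) -> ExtrusionPlan:
    """Build the consistent (v_bar, p, Q) triple for one ink and nozzle."""
    p = required_pressure(model, nozzle, mean_velocity)
    q = flow_rate(model, nozzle, p)
    return ExtrusionPlan(
        mean_velocity=mean_velocity, pressure=p, flow_rate=q, model=model, nozzle=nozzle
    )


def read_viscosity_csv(path) -> list[ViscosityCurve]:
    """Read rheometer sweeps from CSV.

    Expected columns: ``shear_rate_1_per_s``, ``viscosity_Pa_s`` and an
    optional ``replicate`` label; one curve is returned per replicate label
    (or a single curve if the column is absent).
    """
    df = pd.read_csv(path)
    required = {"shear_rate_1_per_s", "viscosity_Pa_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"invalid curve file: missing columns {sorted(missing)}")
    groups = df.groupby("replicate", sort=False) if "replicate" in df.columns else [("", df)]
    curves = []
    for label, g in groups:
        g = g.sort_values("shear_rate_1_per_s")
        curves.append(
            ViscosityCurve(
                shear_rates=g["shear_rate_1_per_s"].to_numpy(),
                viscosities=g["viscosity_Pa_s"].to_numpy(),
                replicate_label=str(label),
            )
        )
    return curves
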