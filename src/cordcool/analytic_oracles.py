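"""Closed-form Pennes solutions and manufactured sources for verification.

These oracles are written straight from the continuous equations —
independent of the solver's stencil code — so they can serve as an honest
reference for the finite-volume discretization:

* 1D steady slab with perfusion: k T'' + w_b c_b (Ta - T) + q_m = 0 has the
  exact solution T(x) = T_inf + A e^{-x/lam} + B e^{x/lam} with
  T_inf = Ta + q_m/(w_b c_b) and decay length lam = sqrt(k/(w_b c_b));
  the unperfused limit degenerates to the quadratic conduction profile.
* Method of manufactured solutions: for any smooth T*(x, y, t) the
  compensating source rho c dT*/dt - k lap T* - w_b c_b (Ta - T*) - q_m
  makes T* an exact solution; derivatives are taken symbolically (sympy).

Convergence-study drivers (grid and time-step refinement against these
references) live here as well and report observed orders as DataFrames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import sympy as sp

from .bioheat_solver import BoundarySpec, PennesOperator, SkinModel, TransientStepper
from .geometry import LABEL_CODES, LabelGrid
from .tissue_db import BloodModel, TissueProperties

__all__ = [
    "SlabSpec",
    "slab_steady_profile",
    "ManufacturedSolution",
    "mms_source",
    "uniform_grid",
    "slab_convergence_study",
    "spatial_convergence_study",
    "temporal_convergence_study",
]

X, Y, T_SYM = sp.symbols("x y t")


# ---------------------------------------------------------------------------
# 1D slab

@dataclass(frozen=True)
class SlabSpec:
    """1D steady slab: tissue occupying 0 <= x <= length with fixed face
    temperatures (degC) at both ends."""

    length: float
    tissue: TissueProperties
    blood: BloodModel
    left_temperature: float
    right_temperature: float

    @property
    def decay_length(self) -> float:
        wbcb = self.blood.perfusion_coefficient(self.tissue)
        if wbcb == 0:
            return math.inf
        return math.sqrt(self.tissue.thermal_conductivity / wbcb)

    @property
    def far_field_temperature(self) -> float:
        """T_inf = Ta + q_m / (w_b c_b); the zero-flux Pennes fixed point."""
        wbcb = self.blood.perfusion_coefficient(self.tissue)
        if wbcb == 0:
            raise ValueError("far-field temperature undefined for w_b = 0")
        return self.blood.arterial_temperature + self.tissue.metabolic_heat / wbcb


def slab_steady_profile(spec: SlabSpec, x) -> np.ndarray:
    """Exact steady temperature at position(s) ``x`` in the slab."""
    x = np.asarray(x, dtype=float)
    if np.any(x < -1e-12) or np.any(x > spec.length + 1e-12):
        raise ValueError("x outside the slab")
    L = spec.length
    k = spec.tissue.thermal_conductivity
    qm = spec.tissue.metabolic_heat
    wbcb = spec.blood.perfusion_coefficient(spec.tissue)
    T0, TL = spec.left_temperature, spec.right_temperature
    if wbcb == 0:
        # k T'' + q_m = 0: quadratic profile through the two face values
        part = -qm / (2 * k) * x * (x - L)
        return T0 + (TL - T0) * x / L + part
    Tinf = spec.far_field_temperature
    lam = spec.decay_length
    # homogeneous part A e^{-x/lam} + B' e^{(x-L)/lam}, the growing mode
    # anchored at the far face to stay overflow-safe for L >> lam
    e = math.exp(-L / lam)
    d0, dL = T0 - Tinf, TL - Tinf
    denom = 1.0 - e * e
    A = (d0 - dL * e) / denom
    Bp = (dL - d0 * e) / denom
    return Tinf + A * np.exp(-x / lam) + Bp * np.exp((x - L) / lam)


# ---------------------------------------------------------------------------
# manufactured solutions

class ManufacturedSolution:
    """A symbolic space-time temperature field T*(x, y, t) with lambdified
    value and compensating-source evaluators."""

    def __init__(self, expr: sp.Expr, tissue: TissueProperties,
                 blood: BloodModel):
        self.expr = sp.sympify(expr)
        self.tissue = tissue
        self.blood = blood
        rhoc = tissue.volumetric_heat_capacity
        k = tissue.thermal_conductivity
        wbcb = blood.perfusion_coefficient(tissue)
        Ta = blood.arterial_temperature
        qm = tissue.metabolic_heat
        src = (rhoc * sp.diff(self.expr, T_SYM)
               - k * (sp.diff(self.expr, X, 2) + sp.diff(self.expr, Y, 2))
               - wbcb * (Ta - self.expr) - qm)
        self._value = sp.lambdify((X, Y, T_SYM), self.expr, "numpy")
        self._source = sp.lambdify((X, Y, T_SYM), sp.simplify(src), "numpy")

    def value(self, x, y, t=0.0) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self._value(x, y, t), dtype=float),
            np.broadcast(x, y).shape).copy()

    def source(self, x, y, t=0.0) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self._source(x, y, t), dtype=float),
            np.broadcast(x, y).shape).copy()


def mms_source(expr, tissue: TissueProperties, blood: BloodModel,
               point: tuple[float, float], time: float = 0.0) -> float:
    """Compensating volumetric source (W/m^3) at one space-time point for
    the manufactured field ``expr`` (a sympy expression in x, y, t)."""
    mms = ManufacturedSolution(expr, tissue, blood)
    x, y = point
    return float(mms.source(np.asarray(x), np.asarray(y), time))


# ---------------------------------------------------------------------------
# convergence studies

def uniform_grid(tissue_name: str, nx: int, ny: int, spacing: float,
                 origin=(0.0, 0.0)) -> LabelGrid:
    """Single-tissue rectangular grid with no exterior (verification use)."""
    g = LabelGrid.empty(nx, ny, spacing, origin)
    g.labels[:, :] = LABEL_CODES[tissue_name]
    return g


def _border_mask(nx: int, ny: int) -> np.ndarray:
    m = np.zeros((ny, nx), dtype=bool)
    m[0, :] = m[-1, :] = True
    m[:, 0] = m[:, -1] = True
    return m


def _observed_orders(h: np.ndarray, err: np.ndarray) -> np.ndarray:
    orders = np.full(len(h), np.nan)
    for i in range(1, len(h)):
        orders[i] = math.log(err[i - 1] / err[i]) / math.log(h[i - 1] / h[i])
    return orders


def slab_convergence_study(tissue: TissueProperties, blood: BloodModel,
                           spacings, *, length: float = 0.060,
                           cold_face: float = 20.0) -> pd.DataFrame:
    """Solve the 1D cooled-slab problem at several spacings and compare
    with :func:`slab_steady_profile` (cold Dirichlet face at x = 0, far
    face held at the perfusion fixed point)."""
    spec = SlabSpec(length=length, tissue=tissue, blood=blood,
                    left_temperature=cold_face,
                    right_temperature=(blood.arterial_temperature
                                       + tissue.metabolic_heat
                                       / blood.perfusion_coefficient(tissue)))
    rows = []
    registry = {tissue.name: tissue}
    for h in spacings:
        n = int(round(length / h))
        grid = uniform_grid(tissue.name, nx=n, ny=1, spacing=h)
        op = PennesOperator(
            grid, registry, blood,
            BoundarySpec(phase="stoppage", catheter_mode="adiabatic",
                         skin=SkinModel(kind="constant", coefficient=0.0)),
            edge_bc={"left": ("dirichlet", spec.left_temperature),
                     "right": ("dirichlet", spec.right_temperature)})
        field = op.solve_stationary()
        xc = grid.xc
        exact = slab_steady_profile(spec, xc)
        err = np.abs(op.to_vector(field) - exact)
        rows.append({"spacing_m": h, "n_cells": n,
                     "Linf_degC": float(err.max()),
                     "L2_degC": float(np.sqrt(np.mean(err ** 2)))})
    df = pd.DataFrame(rows)
    df["order"] = _observed_orders(df["spacing_m"].to_numpy(),
                                   df["Linf_degC"].to_numpy())
    return df


def spatial_convergence_study(tissue: TissueProperties, blood: BloodModel,
                              spacings, *, side: float = 0.040,
                              amplitude: float = 2.0) -> pd.DataFrame:
    """Steady manufactured solution T* = Ta + a sin(pi x/L) sin(pi y/L) on a
    square single-tissue domain; Dirichlet ring of boundary cells."""
    L = side
    expr = (blood.arterial_temperature
            + amplitude * sp.sin(sp.pi * X / L) * sp.sin(sp.pi * Y / L))
    mms = ManufacturedSolution(expr, tissue, blood)
    registry = {tissue.name: tissue}
    rows = []
    for h in spacings:
        n = int(round(side / h))
        grid = uniform_grid(tissue.name, nx=n, ny=n, spacing=h)
        border = _border_mask(n, n)
        Xc, Yc = grid.center_mesh()
        op = PennesOperator(
            grid, registry, blood,
            BoundarySpec(phase="stoppage", catheter_mode="adiabatic",
                         skin=SkinModel(kind="constant", coefficient=0.0)),
            dirichlet_mask=border,
            dirichlet_values=mms.value(Xc[border], Yc[border]),
            source=lambda x, y, t: mms.source(x, y, t))
        field = op.solve_stationary()
        err = np.abs(op.to_vector(field)
                     - mms.value(op.xc_active, op.yc_active))
        rows.append({"spacing_m": h, "n_cells": n * n,
                     "Linf_degC": float(err.max()),
                     "L2_degC": float(np.sqrt(np.mean(err ** 2)))})
    df = pd.DataFrame(rows)
    df["order"] = _observed_orders(df["spacing_m"].to_numpy(),
                                   df["Linf_degC"].to_numpy())
    return df


def temporal_convergence_study(tissue: TissueProperties, blood: BloodModel,
                               dts, *, side: float = 0.040, n: int = 20,
                               t_end: float = 40.0, tau: float = 100.0,
                               amplitude: float = 3.0) -> pd.DataFrame:
    """Transient manufactured solution, spatially exact for the 5-point
    stencil (quadratic in x), so the measured error isolates the backward-
    Euler time discretization: T* = Ta + a (x/L)^2 e^{-t/tau}."""
    L = side
    expr = (blood.arterial_temperature
            + amplitude * (X / L) ** 2 * sp.exp(-T_SYM / tau))
    mms = ManufacturedSolution(expr, tissue, blood)
    registry = {tissue.name: tissue}
    h = side / n
    grid = uniform_grid(tissue.name, nx=n, ny=n, spacing=h)
    border = _border_mask(n, n)
    Xc, Yc = grid.center_mesh()
    xb, yb = Xc[border], Yc[border]
    rows = []
    for dt in dts:
        op = PennesOperator(
            grid, registry, blood,
            BoundarySpec(phase="stoppage", catheter_mode="adiabatic",
                         skin=SkinModel(kind="constant", coefficient=0.0)),
            dirichlet_mask=border,
            dirichlet_values=lambda t, xb=xb, yb=yb: mms.value(xb, yb, t),
            source=lambda x, y, t: mms.source(x, y, t))
        stepper = TransientStepper(op, dt)
        T = mms.value(op.xc_active, op.yc_active, 0.0)
        steps = int(round(t_end / dt))
        t = 0.0
        for _ in range(steps):
            t += dt
            T = stepper.step(T, t)
        err = np.abs(T - mms.value(op.xc_active, op.yc_active, t))
        rows.append({"dt_s": dt, "t_end_s": t,
                     "Linf_degC": float(err.max()),
                     "L2_degC": float(np.sqrt(np.mean(err ** 2)))})
    df = pd.DataFrame(rows)
    df["order"] = _observed_orders(df["dt_s"].to_numpy(),
                                   df["Linf_degC"].to_numpy())
    return df
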