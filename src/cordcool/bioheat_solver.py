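"""Finite-volume discretization and solvers for the Pennes bio-heat equation.

On the label raster the solver integrates

    rho c dT/dt = div(k grad T) + w_b c_b (Ta - T) + q_m

with a 5-point flux stencil.  Face conductances use the harmonic mean of
the two cell conductivities, so heat flux is continuous across tissue
interfaces; a sub-grid series resistance represents the catheter wall on
faces between lumen cells and surrounding tissue when the wall is thinner
than a cell.  Boundary closures:

* catheter lumen — Dirichlet at the coolant set-point during cooling,
  zero-flux (adiabatic) after the pump stops;
* skin — natural convection into ambient air, with a temperature-dependent
  film coefficient h = C (T_s - T_amb)^0.25 by default;
* domain edges — adiabatic unless a verification case asks for fixed-value
  faces.

The stationary problem is solved directly (sparse LU) with Picard updates
of the nonlinear film coefficient; transients use backward Euler, which is
unconditionally stable and monotone, with one LU factorization per phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
from scipy.sparse import coo_matrix, csc_matrix
from scipy.sparse.linalg import splu

from .geometry import EXTERIOR, LABEL_CODES, LabelGrid
from .tissue_db import BloodModel, TissueProperties, get_tissue

__all__ = [
    "SkinModel",
    "BoundarySpec",
    "TemperatureField",
    "PennesOperator",
    "TransientStepper",
    "SingularSystemError",
    "perfusion_source",
    "skin_heat_transfer",
    "harmonic_mean_conductivity",
    "energy_balance",
]


class SingularSystemError(RuntimeError):
    """The discrete system has no anchor (no Dirichlet/Robin boundary and no
    perfusion): the stationary problem is singular."""


def perfusion_source(w_b: float, c_b: float, Ta: float, T) -> float | np.ndarray:
    """Volumetric perfusion heat w_b c_b (Ta - T), W/m^3.

    Positive when tissue is colder than arterial blood (blood rewarms the
    tissue), negative when warmer, zero for unperfused tissue.
    """
    if w_b < 0:
        raise ValueError("perfusion mass rate must be >= 0")
    return w_b * c_b * (Ta - np.asarray(T, dtype=float))


def harmonic_mean_conductivity(k1: float, k2: float) -> float:
    """Series (harmonic-mean) conductivity of two half-cells."""
    return 2.0 * k1 * k2 / (k1 + k2)


@dataclass(frozen=True)
class SkinModel:
    """Film coefficient model for free convection at the skin.

    ``power_law`` gives h = coefficient * |dT|^exponent (laminar
    free-convection scaling); ``constant`` uses h = coefficient.  The
    coefficient is in W/(m^2 K^(1+exponent)) resp. W/(m^2 K); ambient in
    degC.
    """

    kind: str = "power_law"          # 'power_law' | 'constant'
    coefficient: float = 2.0
    exponent: float = 0.25
    ambient: float = 30.0

    def film_coefficient(self, T_surface) -> np.ndarray:
        dT = np.abs(np.asarray(T_surface, dtype=float) - self.ambient)
        if self.kind == "constant":
            return np.full_like(dT, self.coefficient)
        if self.kind == "power_law":
            return self.coefficient * dT ** self.exponent
        raise ValueError(f"unknown skin model kind {self.kind!r}")


def skin_heat_transfer(T_surface, ambient: float, model: SkinModel
                       ) -> float | np.ndarray:
    """Outward skin heat flux h(dT) * (T_surface - ambient), W/m^2."""
    m = replace(model, ambient=ambient)
    h = m.film_coefficient(T_surface)
    return h * (np.asarray(T_surface, dtype=float) - ambient)


@dataclass(frozen=True)
class BoundarySpec:
    """Boundary-condition bundle for one protocol phase."""

    phase: str = "stoppage"            # 'cooling' | 'stoppage'
    catheter_mode: str = "adiabatic"   # 'dirichlet' | 'adiabatic'
    setpoint: float = 20.0             # degC, used in dirichlet mode
    skin: SkinModel = field(default_factory=SkinModel)

    @classmethod
    def cooling(cls, setpoint: float = 20.0, skin: SkinModel | None = None):
        return cls(phase="cooling", catheter_mode="dirichlet",
                   setpoint=setpoint, skin=skin or SkinModel())

    @classmethod
    def stoppage(cls, skin: SkinModel | None = None):
        return cls(phase="stoppage", catheter_mode="adiabatic",
                   skin=skin or SkinModel())


@dataclass
class TemperatureField:
    """Per-cell temperatures (degC) on a label grid at a simulation time."""

    grid: LabelGrid
    values: np.ndarray   # (ny, nx) float64, NaN on exterior cells
    time: float = 0.0

    def at(self, index: tuple[int, int]) -> float:
        return float(self.values[index])

    def is_finite(self) -> bool:
        return bool(np.isfinite(self.values[self.grid.active]).all())


# ---------------------------------------------------------------------------

class PennesOperator:
    """Assembled discrete bio-heat operator on one grid + boundary spec.

    Parameters
    ----------
    grid, registry, blood
        Geometry and material data.
    bc
        Catheter/skin boundary bundle for the phase being solved.
    csf_conductivity_factor
        Multiplier on the cerebrospinal-fluid conductivity; an effective-
        conductivity surrogate for convective mixing of the fluid (1.0 =
        pure conduction).
    extra_density_factor
        If True, multiply the perfusion coefficient by the local tissue
        density (a published variant of the source term that is not
        dimensionally consistent with a mass-perfusion rate; kept only for
        sensitivity checks).
    edge_bc
        Per-side closure for *domain-edge* faces of active cells:
        mapping side ('left'|'right'|'bottom'|'top') to 'adiabatic',
        ('dirichlet', value) or 'skin'.  Defaults to adiabatic everywhere
        (the default anatomy never touches the domain edge).
    dirichlet_mask, dirichlet_values
        Extra fixed-temperature cells (verification cases).  Values may be
        a scalar, an array over the masked cells, or a callable t -> array.
    source
        Extra volumetric source W/m^3: callable (x, y, t) -> array over
        active-cell coordinates (manufactured solutions).
    """

    def __init__(self, grid: LabelGrid,
                 registry: Mapping[str, TissueProperties],
                 blood: BloodModel,
                 bc: BoundarySpec,
                 *,
                 csf_conductivity_factor: float = 1.0,
                 extra_density_factor: bool = False,
                 edge_bc: Mapping[str, object] | None = None,
                 dirichlet_mask: np.ndarray | None = None,
                 dirichlet_values=None,
                 source: Callable | None = None,
                 lumen_pin_value: float | None = None):
        self.grid = grid
        self.registry = registry
        self.blood = blood
        self.bc = bc
        self.source = source
        h = grid.spacing
        self.h = h

        active = grid.active
        self.active_mask = active
        idx = -np.ones(grid.labels.shape, dtype=np.int64)
        self.n = int(active.sum())
        idx[active] = np.arange(self.n)
        self.index = idx

        # per-cell property vectors (active ordering)
        codes = grid.labels[active]
        k = np.empty(self.n)
        rhoc = np.empty(self.n)
        wbcb = np.empty(self.n)
        qm = np.empty(self.n)
        for name, code in LABEL_CODES.items():
            sel = codes == code
            if not sel.any():
                continue
            t = get_tissue(name, registry)
            kk = t.thermal_conductivity
            if name == "cerebrospinal_fluid":
                kk *= csf_conductivity_factor
            k[sel] = kk
            rhoc[sel] = t.volumetric_heat_capacity
            coeff = blood.perfusion_coefficient(t)
            if extra_density_factor:
                coeff *= t.density
            wbcb[sel] = coeff
            qm[sel] = t.metabolic_heat
        self.k = k
        self.rhoc = rhoc
        self.wbcb = wbcb
        self.qm = qm

        X, Y = grid.center_mesh()
        self.xc_active = X[active]
        self.yc_active = Y[active]

        lumen_active = grid.lumen_mask[active]
        self.lumen_active = lumen_active

        # Dirichlet bookkeeping ------------------------------------------
        self.is_dirichlet = np.zeros(self.n, dtype=bool)
        self._dirichlet_entries: list[tuple[np.ndarray, object]] = []
        if bc.catheter_mode == "dirichlet":
            self.is_dirichlet |= lumen_active
            self._dirichlet_entries.append(
                (np.nonzero(lumen_active)[0], bc.setpoint))
        elif bc.catheter_mode == "adiabatic":
            # lumen cells are decoupled (zero-flux faces); pin them so the
            # system stays nonsingular.  The pinned value is display-only.
            self.is_dirichlet |= lumen_active
            pin = (blood.arterial_temperature if lumen_pin_value is None
                   else lumen_pin_value)
            self._dirichlet_entries.append(
                (np.nonzero(lumen_active)[0], pin))
        else:
            raise ValueError(f"unknown catheter_mode {bc.catheter_mode!r}")
        if dirichlet_mask is not None:
            cells = idx[dirichlet_mask & active]
            self.is_dirichlet[cells] = True
            self._dirichlet_entries.append((cells, dirichlet_values))

        self._build_faces(edge_bc or {})
        self._check_solvable()

    # -- static structure --------------------------------------------------
    def _build_faces(self, edge_bc) -> None:
        grid, idx, h = self.grid, self.index, self.h
        cath_code = LABEL_CODES["catheter"]
        wall = grid.meta.get("catheter_wall_thickness", 0.0)
        if wall > 0 or grid.lumen_mask.any():
            k_cath = get_tissue("catheter", self.registry).thermal_conductivity
        else:
            k_cath = np.inf
        r_wall = wall / k_cath if wall > 0 else 0.0
        cath_center = grid.meta.get("catheter_center")
        r_lumen = grid.meta.get("catheter_lumen_radius", 0.0)
        Xc, Yc = grid.center_mesh()

        if cath_center is not None:
            D = np.hypot(Xc - cath_center[0], Yc - cath_center[1])
        else:
            D = None

        fa_list, fb_list, g_list = [], [], []
        for axis in (0, 1):
            if axis == 0:   # vertical neighbours (iy, iy+1)
                sl_a, sl_b = (slice(None, -1), slice(None)), (slice(1, None), slice(None))
            else:           # horizontal neighbours (ix, ix+1)
                sl_a, sl_b = (slice(None), slice(None, -1)), (slice(None), slice(1, None))
            ia, ib = idx[sl_a], idx[sl_b]
            la, lb = grid.labels[sl_a], grid.labels[sl_b]
            lum_a, lum_b = grid.lumen_mask[sl_a], grid.lumen_mask[sl_b]
            valid = (ia >= 0) & (ib >= 0)
            a, b = ia[valid], ib[valid]
            ka, kb = self.k[a], self.k[b]
            la_v, lb_v = la[valid], lb[valid]
            lma, lmb = lum_a[valid], lum_b[valid]
            # Lumen cells hold well-mixed coolant, so they contribute no
            # conduction resistance of their own; the path from coolant to
            # the first tissue cell is the catheter wall (sub-grid when the
            # raster cannot resolve it) plus the remaining tissue gap,
            # measured from the actual lumen circle so the coarse raster
            # converges to the resolved catheter geometry.
            resist = (np.where(lma, 0.0, h / (2 * ka))
                      + np.where(lmb, 0.0, h / (2 * kb)))
            lumen_face = lma ^ lmb
            if lumen_face.any() and D is not None:
                d_other = np.where(lma, D[sl_b][valid], D[sl_a][valid])
                k_other = np.where(lma, kb, ka)
                other_is_wall = np.where(lma, lb_v, la_v) == cath_code
                wall_part = np.clip(d_other - r_lumen, 0.0, wall) / k_cath
                gap = np.clip(d_other - (r_lumen + wall), 0.05 * h, 0.5 * h)
                tissue_part = np.where(other_is_wall, 0.0, gap / k_other)
                resist = np.where(lumen_face, wall_part + tissue_part, resist)
            elif lumen_face.any() and r_wall > 0:
                wall_face = lumen_face & ((la_v != cath_code)
                                          | (lb_v != cath_code))
                resist = resist + np.where(wall_face, r_wall, 0.0)
            both_lumen = lma & lmb
            with np.errstate(divide="ignore"):
                G = np.where(both_lumen, 0.0,
                             h / np.where(resist > 0, resist, np.inf))
            if self.bc.catheter_mode == "adiabatic":
                G = np.where(lma | lmb, 0.0, G)
            fa_list.append(a)
            fb_list.append(b)
            g_list.append(G)
        self.face_a = np.concatenate(fa_list)
        self.face_b = np.concatenate(fb_list)
        self.face_G = np.concatenate(g_list)

        # skin faces: active cell next to an exterior cell ----------------
        ext = ~self.active_mask
        pad = np.pad(ext, 1, constant_values=False)
        n_ext_faces = (pad[:-2, 1:-1].astype(np.int8) + pad[2:, 1:-1]
                       + pad[1:-1, :-2] + pad[1:-1, 2:])
        skin = self.active_mask & (n_ext_faces > 0)
        self.skin_cells = self.index[skin]
        self.skin_face_count = n_ext_faces[skin].astype(float)

        # domain-edge faces of active cells -------------------------------
        self._edge_dirichlet: list[tuple[np.ndarray, object]] = []
        self._edge_skin_cells: list[np.ndarray] = []
        sides = {
            "left": idx[:, 0], "right": idx[:, -1],
            "bottom": idx[0, :], "top": idx[-1, :],
        }
        for side, cells in sides.items():
            mode = edge_bc.get(side, "adiabatic")
            cells = cells[cells >= 0]
            if len(cells) == 0 or mode == "adiabatic":
                continue
            if mode == "skin":
                self._edge_skin_cells.append(cells)
            elif isinstance(mode, tuple) and mode[0] == "dirichlet":
                self._edge_dirichlet.append((cells, mode[1]))
            else:
                raise ValueError(f"unknown edge bc {mode!r} for side {side}")

    def _check_solvable(self) -> None:
        anchored = (self.is_dirichlet.any()
                    or len(self.skin_cells) > 0
                    or self._edge_dirichlet
                    or self._edge_skin_cells
                    or (self.wbcb > 0).any())
        if not anchored:
            raise SingularSystemError(
                "stationary system is singular: every boundary is adiabatic "
                "and no tissue is perfused; add a Dirichlet/convective "
                "boundary or a perfused region")

    # -- value resolution ---------------------------------------------------
    @staticmethod
    def _resolve(values, cells: np.ndarray, t: float) -> np.ndarray:
        if callable(values):
            values = values(t)
        return np.broadcast_to(np.asarray(values, dtype=float),
                               cells.shape).copy()

    def _skin_U(self, T_ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Effective face conductance (per unit depth) of skin faces,
        combining half-cell conduction and the film coefficient."""
        cells = self.skin_cells
        if len(cells) == 0:
            return cells, np.zeros(0)
        h_film = self.bc.skin.film_coefficient(T_ref[cells])
        h_film = np.maximum(h_film, 1e-30)
        U = self.h / (self.h / (2 * self.k[cells]) + 1.0 / h_film)
        return cells, U * self.skin_face_count

    # -- assembly ----------------------------------------------------------
    def system(self, T_ref: np.ndarray | None = None, t: float = 0.0
               ) -> tuple[csc_matrix, np.ndarray]:
        """Assemble (A, b) with A T = b the stationary balance.

        Row i of ``A T - b`` is the net outflow of cell i (W per unit
        depth): conduction + perfusion sink + boundary losses minus
        sources.  Dirichlet rows are identity with b = the fixed value.
        ``T_ref`` linearizes the temperature-dependent film coefficient
        (defaults to arterial temperature everywhere).
        """
        n, h = self.n, self.h
        V = h * h
        if T_ref is None:
            T_ref = np.full(n, self.blood.arterial_temperature)

        rows = [self.face_a, self.face_b, self.face_a, self.face_b]
        cols = [self.face_a, self.face_b, self.face_b, self.face_a]
        vals = [self.face_G, self.face_G, -self.face_G, -self.face_G]

        diag = self.wbcb * V
        b = self.wbcb * V * self.blood.arterial_temperature + self.qm * V
        if self.source is not None:
            b = b + V * np.asarray(
                self.source(self.xc_active, self.yc_active, t), dtype=float)

        cells, U = self._skin_U(T_ref)
        amb = self.bc.skin.ambient
        if len(cells):
            np.add.at(diag, cells, U)
            np.add.at(b, cells, U * amb)
        for cells_e in self._edge_skin_cells:
            h_film = np.maximum(
                self.bc.skin.film_coefficient(T_ref[cells_e]), 1e-30)
            Ue = h / (h / (2 * self.k[cells_e]) + 1.0 / h_film)
            np.add.at(diag, cells_e, Ue)
            np.add.at(b, cells_e, Ue * amb)
        for cells_e, value in self._edge_dirichlet:
            Ge = 2.0 * self.k[cells_e]   # face area h over distance h/2
            vv = self._resolve(value, cells_e, t)
            np.add.at(diag, cells_e, Ge)
            np.add.at(b, cells_e, Ge * vv)

        rows.append(np.arange(n))
        cols.append(np.arange(n))
        vals.append(diag)

        row = np.concatenate(rows)
        col = np.concatenate(cols)
        val = np.concatenate(vals)

        # Dirichlet rows: wipe and replace with identity
        keep = ~self.is_dirichlet[row]
        row, col, val = row[keep], col[keep], val[keep]
        d_idx = np.nonzero(self.is_dirichlet)[0]
        row = np.concatenate([row, d_idx])
        col = np.concatenate([col, d_idx])
        val = np.concatenate([val, np.ones(len(d_idx))])
        for cells_d, value in self._dirichlet_entries:
            b[cells_d] = self._resolve(value, cells_d, t)

        A = coo_matrix((val, (row, col)), shape=(n, n)).tocsc()
        return A, b

    # -- conversions --------------------------------------------------------
    def to_field(self, vec: np.ndarray, time: float = 0.0) -> TemperatureField:
        full = np.full(self.grid.labels.shape, np.nan)
        full[self.active_mask] = vec
        return TemperatureField(grid=self.grid, values=full, time=time)

    def to_vector(self, field: TemperatureField | np.ndarray) -> np.ndarray:
        arr = field.values if isinstance(field, TemperatureField) else field
        return np.asarray(arr, dtype=float)[self.active_mask].copy()

    # -- solvers ------------------------------------------------------------
    def solve_stationary(self, *, tol: float = 1e-10, max_iter: int = 60,
                         fill_lumen: bool = True) -> TemperatureField:
        """Direct stationary solve with Picard iteration on the film
        coefficient; final relative residual is checked against ``tol``."""
        from scipy.sparse.linalg import spsolve

        T = np.full(self.n, self.blood.arterial_temperature)
        A = b = None
        delta = np.inf
        for _ in range(max_iter):
            A, b = self.system(T_ref=T)
            T_new = spsolve(A, b)
            delta = float(np.max(np.abs(T_new - T)))
            T = T_new
            if delta < 1e-9:
                break
        else:
            if len(self.skin_cells) or self._edge_skin_cells:
                raise RuntimeError(
                    f"film-coefficient iteration stalled (last update "
                    f"{delta:.2e} degC)")
        resid = float(np.max(np.abs(A @ T - b)) / max(np.max(np.abs(b)), 1e-300))
        if resid > tol:
            raise RuntimeError(
                f"stationary solve residual {resid:.3e} exceeds {tol:.0e}")
        if fill_lumen and self.bc.catheter_mode == "adiabatic":
            T = self._fill_lumen(T)
        return self.to_field(T, time=0.0)

    def _fill_lumen(self, T: np.ndarray) -> np.ndarray:
        """Replace the pinned (decoupled) lumen values by the mean of their
        non-lumen neighbours, for presentation only."""
        lum = self.lumen_active
        if not lum.any():
            return T
        a, b_ = self.face_a, self.face_b
        # faces stored with G possibly zeroed; use adjacency regardless
        out = T.copy()
        neigh_sum = np.zeros(self.n)
        neigh_cnt = np.zeros(self.n)
        m = lum[a] & ~lum[b_]
        np.add.at(neigh_sum, a[m], T[b_[m]])
        np.add.at(neigh_cnt, a[m], 1.0)
        m = lum[b_] & ~lum[a]
        np.add.at(neigh_sum, b_[m], T[a[m]])
        np.add.at(neigh_cnt, b_[m], 1.0)
        has = lum & (neigh_cnt > 0)
        out[has] = neigh_sum[has] / neigh_cnt[has]
        # lumen cells with only lumen neighbours take the filled average
        rest = lum & (neigh_cnt == 0)
        if rest.any() and has.any():
            out[rest] = out[has].mean()
        return out


class TransientStepper:
    """Backward-Euler time stepper with a frozen LU factorization.

    The film coefficient is linearized about ``T_ref`` (typically the
    phase-start field) and held for the whole phase; skin temperatures move
    by well under a degree over a phase, so the induced flux error is
    negligible next to the film-model uncertainty itself.
    """

    def __init__(self, op: PennesOperator, dt: float,
                 T_ref: np.ndarray | None = None):
        if dt <= 0:
            raise ValueError("dt must be > 0")
        self.op = op
        self.dt = dt
        self._t_dependent = (op.source is not None or any(
            callable(v) for _, v in op._dirichlet_entries) or any(
            callable(v) for _, v in op._edge_dirichlet))
        A, b = op.system(T_ref=T_ref, t=0.0)
        self._A = A
        self._b0 = b
        mass = op.rhoc * op.h ** 2 / dt
        mass[op.is_dirichlet] = 0.0
        self.mass = mass
        M = coo_matrix((mass, (np.arange(op.n), np.arange(op.n))),
                       shape=A.shape).tocsc()
        self._T_ref = T_ref
        self.lu = splu((M + A).tocsc())

    def step(self, T: np.ndarray, t_new: float) -> np.ndarray:
        """Advance one backward-Euler step to time ``t_new``."""
        if not np.isfinite(T).all():
            raise FloatingPointError("non-finite temperature state")
        if self._t_dependent:
            _, b = self.op.system(T_ref=self._T_ref, t=t_new)
        else:
            b = self._b0
        return self.lu.solve(self.mass * T + b)


def energy_balance(op: PennesOperator, field: TemperatureField) -> dict:
    """Global steady-state heat budget of a solved field (W per unit depth).

    Returns metabolic input, net perfusion input, skin loss, net flow into
    Dirichlet (coolant) cells, and the relative imbalance
    |in - out| / max(in, out).
    """
    T = op.to_vector(field)
    V = op.h ** 2
    free = ~op.is_dirichlet
    q_met = float(np.sum(op.qm[free] * V))
    q_perf = float(np.sum(op.wbcb[free] * V
                          * (op.blood.arterial_temperature - T[free])))
    cells, U = op._skin_U(T)
    q_skin = float(np.sum(U * (T[cells] - op.bc.skin.ambient))) if len(cells) else 0.0
    # conduction into Dirichlet cells
    a, b_, G = op.face_a, op.face_b, op.face_G
    da, db = op.is_dirichlet[a], op.is_dirichlet[b_]
    q_dir = float(np.sum(G[da & ~db] * (T[a[da & ~db]] - T[b_[da & ~db]]) * -1.0)
                  + np.sum(G[db & ~da] * (T[a[db & ~da]] - T[b_[db & ~da]])))
    q_in = q_met + q_perf
    q_out = q_skin + q_dir
    denom = max(abs(q_in), abs(q_out), 1e-300)
    return {
        "metabolic_W": q_met,
        "perfusion_W": q_perf,
        "skin_loss_W": q_skin,
        "catheter_W": q_dir,
        "imbalance": abs(q_in - q_out) / denom,
    }
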