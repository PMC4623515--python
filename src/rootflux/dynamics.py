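"""Reaction–diffusion–transport dynamics on a rasterized cross-section.

Both hormones obey dC/dt = b - delta*C + transport.  Production and decay act
at cell-interior grid points only.  Diffusion couples two 4-adjacent points of
the same cell (symplastic coefficient) or two wall points (apoplastic
coefficient).  A cell/wall point pair is a membrane face: auxin crosses it
through carrier-dependent permeabilities (efflux replaced, not summed, by the
background leak on carrier-free faces), cytokinin either diffuses freely
across membranes (default) or crosses with a symmetric permeability P_cyt.

The time integrator is a Peaceman–Rachford alternating-direction-implicit
scheme; the membrane coupling terms are linear in the two concentrations
flanking a face and are folded into the implicit tridiagonal sweeps.  The
fixed point of the scheme solves the same discrete balance as the sparse
steady-state system assembled by the direct solver, which is used when only
the steady state is of interest (the nonlinearity introduced by hormonal
regulation is handled by a damped fixed-point iteration on the activities).
No randomness exists anywhere: trajectories are fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix, identity
from scipy.sparse.linalg import splu

from .geometry import RasterGrid, WALL
from .layouts import EXPORTER_KINDS, BoundLayout, TransporterLayout, bind_layout
from .regulation import RegulationParams, hill_down, hill_up, cytokinin_synthesis_rate

__all__ = [
    "SimulationParams",
    "HormoneState",
    "ConvergenceReport",
    "Pulse",
    "InstabilityError",
    "Simulator",
    "membrane_flux_auxin",
    "membrane_flux_cytokinin",
]


class InstabilityError(RuntimeError):
    """The integration produced a negative or divergent concentration."""


@dataclass(frozen=True)
class Pulse:
    """Clamp a transporter's activity in one cell to a value for a time window."""

    cell_id: int
    start: float  # s
    duration: float  # s
    transporter: str = "importer"
    value: float = 1.0

    def active(self, t: float) -> bool:
        return self.start <= t < self.start + self.duration


@dataclass(frozen=True)
class SimulationParams:
    """Solver controls, transport and metabolic parameters.

    Units: time s, space um, diffusion um^2/s, permeability um/s,
    concentration a.u., production a.u./s (per grid point), decay 1/s.
    ``D_cyt_apo``/``P_cyt`` default to free cytokinin movement (apoplastic
    diffusion unchanged, no membrane barrier); gradient-feasibility scans set
    both.  ``cyt_source_cells`` confines cytokinin production to those cells;
    ``cyt_auxin_driven`` replaces it by the auxin-controlled synthesis rate.
    """

    dt: float = 0.1
    D_auxin: float = 600.0
    D_auxin_apo: float = 60.0
    D_cyt: float = 600.0
    D_cyt_apo: float | None = None  # None -> D_cyt (free apoplastic movement)
    P_i_bg: float = 5.0
    P_i_AUX: float = 20.0
    P_e_bg: float = 1.0
    P_e_PIN: float = 20.0
    P_cyt: float | None = None  # None -> cytokinin ignores membranes
    b_auxin: float = 1e-4
    delta_auxin: float = 1e-5
    b_cyt: float = 1e-3
    delta_cyt: float = 1e-4
    delta_cyt_source: float | None = None  # decay override inside source cells
    cyt_source_cells: tuple[int, ...] | None = None
    cyt_auxin_driven: bool = False
    add_bg_efflux_on_pin_faces: bool = False
    eps_steady: float = 1e-8  # a.u./s, max per-point |dC|/dt
    max_time: float = 2.0e5  # s
    regulation: RegulationParams = field(default_factory=RegulationParams)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in (
            "D_auxin", "D_auxin_apo", "D_cyt", "P_i_bg", "P_i_AUX",
            "P_e_bg", "P_e_PIN", "b_auxin", "delta_auxin", "b_cyt", "delta_cyt",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class HormoneState:
    """Concentration fields, per-cell transporter activities and the clock."""

    auxin: np.ndarray
    cytokinin: np.ndarray
    activities: np.ndarray  # (n_kinds, n_cells), each in [0, 1]
    t: float = 0.0

    def copy(self) -> "HormoneState":
        return HormoneState(self.auxin.copy(), self.cytokinin.copy(), self.activities.copy(), self.t)


@dataclass
class ConvergenceReport:
    converged: bool
    t: float
    steps: int
    residual_auxin: float
    residual_cyt: float
    method: str = "adi"


# ---------------------------------------------------------------------------
# pure membrane-flux functions (Eq-level contracts; positive = into the cell)
# ---------------------------------------------------------------------------


def membrane_flux_auxin(
    C_in: float,
    C_out: float,
    carriers: Mapping[str, float],
    activities: Mapping[str, float],
    params: SimulationParams,
) -> float:
    """Auxin flux across one membrane face (a.u.*um/s along the inward normal).

    ``carriers`` maps transporter kind to placement strength on this face;
    ``activities`` maps kind to its activity E.  On faces carrying at least
    one efflux carrier the background efflux leak is replaced by the summed
    carrier permeability; influx always includes the background leak.
    """
    if min(C_in, C_out) < 0:
        raise ValueError("concentrations must be non-negative")
    efflux = 0.0
    has_exporter = False
    for kind, s in carriers.items():
        if kind in EXPORTER_KINDS and s > 0:
            has_exporter = True
            efflux += s * activities.get(kind, 1.0) * params.P_e_PIN
    if not has_exporter:
        efflux = params.P_e_bg
    elif params.add_bg_efflux_on_pin_faces:
        efflux += params.P_e_bg
    s_imp = carriers.get("importer", 0.0)
    influx = params.P_i_bg + s_imp * activities.get("importer", 1.0) * params.P_i_AUX
    return -efflux * C_in + influx * C_out


def membrane_flux_cytokinin(C_in: float, C_out: float, P_cyt: float) -> float:
    """Passive symmetric cytokinin flux -P_cyt*C_in + P_cyt*C_out."""
    if P_cyt < 0:
        raise ValueError("P_cyt must be non-negative")
    return P_cyt * (C_out - C_in)


# ---------------------------------------------------------------------------
# tridiagonal solver (rows solved independently, vectorized / numba)
# ---------------------------------------------------------------------------


def _thomas_rows_numpy(dl, d, du, b):
    m, n = d.shape
    w = np.empty_like(d)
    g = np.empty_like(d)
    w[:, 0] = du[:, 0] / d[:, 0]
    g[:, 0] = b[:, 0] / d[:, 0]
    for i in range(1, n):
        den = d[:, i] - dl[:, i] * w[:, i - 1]
        w[:, i] = du[:, i] / den
        g[:, i] = (b[:, i] - dl[:, i] * g[:, i - 1]) / den
    x = np.empty_like(d)
    x[:, n - 1] = g[:, n - 1]
    for i in range(n - 2, -1, -1):
        x[:, i] = g[:, i] - w[:, i] * x[:, i + 1]
    return x


try:  # numba gives a large speed-up on long pulse runs; numpy path is exact too
    from numba import njit

    @njit(cache=False)
    def _thomas_rows_numba(dl, d, du, b):  # pragma: no cover - numerics identical
        m, n = d.shape
        x = np.empty_like(d)
        w = np.empty(n)
        g = np.empty(n)
        for r in range(m):
            w[0] = du[r, 0] / d[r, 0]
            g[0] = b[r, 0] / d[r, 0]
            for i in range(1, n):
                den = d[r, i] - dl[r, i] * w[i - 1]
                w[i] = du[r, i] / den
                g[i] = (b[r, i] - dl[r, i] * g[i - 1]) / den
            x[r, n - 1] = g[n - 1]
            for i in range(n - 2, -1, -1):
                x[r, i] = g[i] - w[i] * x[r, i + 1]
        return x

    _thomas_rows = _thomas_rows_numba
except Exception:  # pragma: no cover
    _thomas_rows = _thomas_rows_numpy


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

_OVERFLOW = 1e12


class Simulator:
    """Bind a grid, a transporter layout and parameters into a stepping engine.

    ``static=True`` runs the unregulated ('static') variant in which every
    carrier is fully active.  ``schedule`` is a sequence of :class:`Pulse`
    events (activity clamps).
    """

    def __init__(
        self,
        grid: RasterGrid,
        layout: TransporterLayout | BoundLayout,
        params: SimulationParams | None = None,
        static: bool = False,
        schedule: Sequence[Pulse] = (),
    ):
        self.grid = grid
        self.params = params or SimulationParams()
        self.static = static
        self.schedule = list(schedule)
        self.bound = layout if isinstance(layout, BoundLayout) else bind_layout(layout, grid)

        lab = grid.labels
        self.ny, self.nx = lab.shape
        self.cell_mask = lab > 0
        self.wall_mask = lab == WALL
        self.inside = lab >= 0

        # compact cell indexing for per-cell reductions
        ids = [int(c) for c in grid.cell_ids]
        self.cell_ids = np.array(ids)
        self.n_cells = len(ids)
        self.cix = np.full(lab.shape, -1, dtype=np.int64)
        for cid, k in self.bound.cell_index.items():
            self.cix[lab == cid] = k
        self._cell_counts = np.bincount(self.cix[self.cell_mask], minlength=self.n_cells)

        # per-cell cell-type info for reaction masks
        tpl = grid.template
        self._source_px = None
        if self.params.cyt_source_cells is not None:
            self._source_px = np.isin(lab, np.array(self.params.cyt_source_cells, dtype=int))
        # per-point cytokinin decay (a source-confined override is allowed)
        self._delta_cyt_px = np.where(self.cell_mask, self.params.delta_cyt, 0.0)
        if self.params.delta_cyt_source is not None and self._source_px is not None:
            self._delta_cyt_px[self._source_px] = self.params.delta_cyt_source

        self._build_static_edges()
        self._prepare_faces()
        self._auxin_coeffs_current = False

        # schedule bookkeeping: (kind index, compact cell, value)
        self._clamps: list[tuple[Pulse, int, int]] = []
        for p in self.schedule:
            if p.cell_id not in self.bound.cell_index:
                raise ValueError(f"schedule references unknown cell {p.cell_id}")
            self._clamps.append(
                (p, self.bound.kind_index(p.transporter), self.bound.cell_index[p.cell_id])
            )

    # -- construction -------------------------------------------------------

    def _build_static_edges(self) -> None:
        """Diffusive edge coefficients (1/s) for both hormones.

        Arrays A*/B* have the grid shape; entry (j, i) describes the edge to
        the +x (resp. +y) neighbour: A = gain of the low point from the high
        point, B = loss of the low point across that edge.  Membrane entries
        for auxin are refreshed whenever activities change.
        """
        p = self.params
        lab = self.grid.labels
        dx2 = self.grid.dx ** 2
        D_cyt_apo = p.D_cyt if p.D_cyt_apo is None else p.D_cyt_apo

        def build(D_sym: float, D_apo: float, D_mem: float | None):
            A_x = np.zeros(lab.shape)
            A_y = np.zeros(lab.shape)
            for axis, A in ((0, A_x), (1, A_y)):
                if axis == 0:
                    a, b = lab[:, :-1], lab[:, 1:]
                    view = A[:, :-1]
                else:
                    a, b = lab[:-1, :], lab[1:, :]
                    view = A[:-1, :]
                same_cell = (a > 0) & (a == b)
                both_wall = (a == WALL) & (b == WALL)
                view[same_cell] = D_sym / dx2
                view[both_wall] = D_apo / dx2
                if D_mem is not None:  # free movement across membranes
                    mem = ((a > 0) & (b == WALL)) | ((a == WALL) & (b > 0))
                    view[mem] = D_mem / dx2
            return A_x, A_y

        self._aux_Ax, self._aux_Ay = build(p.D_auxin, p.D_auxin_apo, None)
        self._aux_Bx, self._aux_By = self._aux_Ax.copy(), self._aux_Ay.copy()
        D_mem = p.D_cyt if p.P_cyt is None else None
        self._cyt_Ax, self._cyt_Ay = build(p.D_cyt, D_cyt_apo, D_mem)
        self._cyt_Bx, self._cyt_By = self._cyt_Ax.copy(), self._cyt_Ay.copy()
        if p.P_cyt is not None:
            self._apply_face_coeffs(
                self._cyt_Ax, self._cyt_Bx, self._cyt_Ay, self._cyt_By,
                np.full(self.grid.n_faces, p.P_cyt),
                np.full(self.grid.n_faces, p.P_cyt),
            )

    def _prepare_faces(self) -> None:
        g = self.grid
        self._face_cix = np.array(
            [self.bound.cell_index[int(c)] for c in g.face_cell_id], dtype=np.int64
        )
        s = self.bound.strength
        exp_rows = [k for k, kind in enumerate(self.bound.kinds) if kind in EXPORTER_KINDS]
        self._exporter_rows = np.array(exp_rows)
        self._has_exporter = s[exp_rows].sum(axis=0) > 0
        self._imp_row = self.bound.kind_index("importer")
        self._s_imp = s[self._imp_row]

    def _apply_face_coeffs(self, Ax, Bx, Ay, By, P_in, P_out) -> None:
        """Scatter per-face permeabilities (um/s) into the edge arrays."""
        g = self.grid
        dx = g.dx
        j, i = g.face_edge[:, 0], g.face_edge[:, 1]
        for axis, (A, B) in ((0, (Ax, Bx)), (1, (Ay, By))):
            m = g.face_axis == axis
            cl = g.face_cell_low[m]
            jj, ii = j[m], i[m]
            # cell low: A (gain of cell from wall) = P_in; B (loss of cell) = P_out
            A[jj[cl], ii[cl]] = P_in[m][cl] / dx
            B[jj[cl], ii[cl]] = P_out[m][cl] / dx
            # cell high: low point is wall: gains cell efflux, loses influx
            A[jj[~cl], ii[~cl]] = P_out[m][~cl] / dx
            B[jj[~cl], ii[~cl]] = P_in[m][~cl] / dx

    # -- state and activities ------------------------------------------------

    def initial_state(self) -> HormoneState:
        z = np.zeros(self.grid.labels.shape)
        E = np.ones((len(self.bound.kinds), self.n_cells))
        st = HormoneState(z.copy(), z.copy(), E, 0.0)
        self.update_activities(st)
        return st

    def cell_means(self, fld: np.ndarray) -> np.ndarray:
        sums = np.bincount(
            self.cix[self.cell_mask], weights=fld[self.cell_mask], minlength=self.n_cells
        )
        return sums / np.maximum(self._cell_counts, 1)

    def update_activities(self, state: HormoneState) -> None:
        """Recompute E from current cell averages; apply active clamps."""
        r = self.params.regulation
        aux = self.cell_means(state.auxin)
        ck = self.cell_means(state.cytokinin)
        E = np.ones((len(self.bound.kinds), self.n_cells))
        if not self.static:
            up_aux_pin = hill_up(aux, r.K_A_PIN, r.n)
            up_aux_imp = hill_up(aux, r.K_A_AUX, r.n)
            ck_up_aux_down = hill_up(ck, r.K_A_cyt, r.n) * hill_down(aux, r.K_A_PIN, r.n)
            for k, kind in enumerate(self.bound.kinds):
                code = self.bound.mode_code[k]
                up = up_aux_imp if kind == "importer" else up_aux_pin
                E[k] = np.where(code == 0, 1.0, np.where(code == 1, up, ck_up_aux_down))
        for pulse, k, c in self._clamps:
            if pulse.active(state.t):
                E[k, c] = pulse.value
        state.activities = E
        self._auxin_coeffs_current = False
        self._E_cache = E

    def _refresh_auxin_membranes(self, state: HormoneState) -> None:
        if self._auxin_coeffs_current:
            return
        p = self.params
        E = state.activities
        Ef = E[:, self._face_cix]  # (n_kinds, n_faces)
        s = self.bound.strength
        efflux = p.P_e_PIN * (s[self._exporter_rows] * Ef[self._exporter_rows]).sum(axis=0)
        P_out = np.where(self._has_exporter, efflux, p.P_e_bg)
        if p.add_bg_efflux_on_pin_faces:
            P_out = P_out + np.where(self._has_exporter, p.P_e_bg, 0.0)
        P_in = p.P_i_bg + p.P_i_AUX * self._s_imp * Ef[self._imp_row]
        self._apply_face_coeffs(self._aux_Ax, self._aux_Bx, self._aux_Ay, self._aux_By, P_in, P_out)
        self._auxin_coeffs_current = True

    # -- reaction ------------------------------------------------------------

    def _cyt_production(self, state: HormoneState) -> np.ndarray:
        p = self.params
        if p.cyt_auxin_driven:
            rate = cytokinin_synthesis_rate(
                self.cell_means(state.auxin), p.regulation, p.b_cyt
            )
            out = np.zeros(state.auxin.shape)
            out[self.cell_mask] = rate[self.cix[self.cell_mask]]
            return out
        out = np.zeros(state.auxin.shape)
        if self._source_px is not None:
            out[self._source_px] = p.b_cyt
        else:
            out[self.cell_mask] = p.b_cyt
        return out

    def reaction_step(self, state: HormoneState) -> HormoneState:
        """Explicit production/decay update at cell-interior points."""
        p = self.params
        dt = p.dt
        m = self.cell_mask
        state.auxin[m] += dt * (p.b_auxin - p.delta_auxin * state.auxin[m])
        bc = self._cyt_production(state)
        state.cytokinin[m] += dt * (bc[m] - self._delta_cyt_px[m] * state.cytokinin[m])
        for fld, name in ((state.auxin, "auxin"), (state.cytokinin, "cytokinin")):
            if fld[m].min() < 0:
                j, i = np.unravel_index(np.argmin(np.where(m, fld, np.inf)), fld.shape)
                raise InstabilityError(
                    f"negative {name} concentration at grid point ({j}, {i}); reduce dt={dt}"
                )
        return state

    # -- ADI diffusion/transport ---------------------------------------------

    def _apply_L(self, C, A, B, axis: int) -> np.ndarray:
        out = np.zeros_like(C)
        if axis == 0:
            out[:, :-1] += A[:, :-1] * C[:, 1:] - B[:, :-1] * C[:, :-1]
            out[:, 1:] += B[:, :-1] * C[:, :-1] - A[:, :-1] * C[:, 1:]
        else:
            out[:-1, :] += A[:-1, :] * C[1:, :] - B[:-1, :] * C[:-1, :]
            out[1:, :] += B[:-1, :] * C[:-1, :] - A[:-1, :] * C[1:, :]
        return out

    def _solve_implicit_x(self, rhs, A, B, mu) -> np.ndarray:
        ny, nx = rhs.shape
        d = np.ones_like(rhs)
        dl = np.zeros_like(rhs)
        du = np.zeros_like(rhs)
        d[:, :-1] += mu * B[:, :-1]
        d[:, 1:] += mu * A[:, :-1]
        du[:, :-1] = -mu * A[:, :-1]
        dl[:, 1:] = -mu * B[:, :-1]
        return _thomas_rows(dl, d, du, np.ascontiguousarray(rhs))

    def _adi(self, C, Ax, Bx, Ay, By, dt) -> np.ndarray:
        mu = 0.5 * dt
        # x-implicit half step
        rhs = C + mu * self._apply_L(C, Ay, By, axis=1)
        Cs = self._solve_implicit_x(rhs, Ax, Bx, mu)
        # y-implicit half step (solve on transposed arrays)
        rhs = Cs + mu * self._apply_L(Cs, Ax, Bx, axis=0)
        Ct = self._solve_implicit_x(
            np.ascontiguousarray(rhs.T),
            np.ascontiguousarray(Ay.T),
            np.ascontiguousarray(By.T),
            mu,
        )
        return np.ascontiguousarray(Ct.T)

    def diffusion_step(self, state: HormoneState) -> HormoneState:
        """One ADI sweep (x- then y-implicit half-steps) for both hormones."""
        self._refresh_auxin_membranes(state)
        dt = self.params.dt
        state.auxin = self._adi(state.auxin, self._aux_Ax, self._aux_Bx, self._aux_Ay, self._aux_By, dt)
        state.cytokinin = self._adi(
            state.cytokinin, self._cyt_Ax, self._cyt_Bx, self._cyt_Ay, self._cyt_By, dt
        )
        for fld in (state.auxin, state.cytokinin):
            if not np.isfinite(fld).all() or np.abs(fld).max() > _OVERFLOW:
                raise InstabilityError(f"field diverged; dt={dt}")
        return state

    def step(self, state: HormoneState) -> HormoneState:
        """Apply schedule, refresh activities, react, transport, advance t."""
        self.update_activities(state)
        self.reaction_step(state)
        self.diffusion_step(state)
        state.t += self.params.dt
        return state

    # -- steady state ----------------------------------------------------------

    def run_to_steady_state(
        self,
        state: HormoneState | None = None,
        eps: float | None = None,
        max_time: float | None = None,
        method: str = "adi",
        check_every: int = 50,
    ) -> tuple[HormoneState, ConvergenceReport]:
        """Iterate to a steady state.

        ``method='adi'`` time-steps until max |dC|/dt < eps for both hormones;
        ``method='direct'`` solves the identical discrete balance with a
        sparse factorization (plus damped fixed-point iteration on the
        regulated activities) and reports in solver iterations.
        """
        state = state or self.initial_state()
        eps = self.params.eps_steady if eps is None else eps
        if eps <= 0:
            raise ValueError("eps must be positive")
        max_time = self.params.max_time if max_time is None else max_time
        if method == "direct":
            return self._steady_direct(state, eps)
        if method != "adi":
            raise ValueError(f"unknown method {method!r}")
        dt = self.params.dt
        steps = 0
        ra = rc = np.inf
        while state.t < max_time:
            for _ in range(check_every - 1):
                self.step(state)
                steps += 1
                if state.t >= max_time:
                    break
            prev_a = state.auxin.copy()
            prev_c = state.cytokinin.copy()
            self.step(state)
            steps += 1
            ra = float(np.abs(state.auxin - prev_a).max() / dt)
            rc = float(np.abs(state.cytokinin - prev_c).max() / dt)
            if ra < eps and rc < eps:
                return state, ConvergenceReport(True, state.t, steps, ra, rc, "adi")
        return state, ConvergenceReport(False, state.t, steps, ra, rc, "adi")

    # direct sparse solve of  (delta - L) C = b  given activities
    def _unknown_index(self):
        flat = np.full(self.grid.labels.size, -1, dtype=np.int64)
        ins = self.inside.ravel()
        flat[ins] = np.arange(ins.sum())
        return flat, int(ins.sum())

    def _assemble(self, Ax, Bx, Ay, By, delta_cells):
        """Sparse (delta - L) operator; ``delta_cells`` scalar or per-point array."""
        lab = self.grid.labels
        ny, nx = lab.shape
        flat, n_un = self._unknown_index()
        rows, cols, vals = [], [], []
        diag = np.zeros(n_un)
        if np.ndim(delta_cells) == 0:
            diag[flat[self.cell_mask.ravel()]] += delta_cells
        else:
            diag[flat[self.cell_mask.ravel()]] += np.asarray(delta_cells)[self.cell_mask]
        for axis, (A, B) in ((0, (Ax, Bx)), (1, (Ay, By))):
            if axis == 0:
                low = (np.arange(ny)[:, None] * nx + np.arange(nx - 1)[None, :]).ravel()
                high = low + 1
                a = A[:, :-1].ravel()
                b = B[:, :-1].ravel()
            else:
                low = (np.arange(ny - 1)[:, None] * nx + np.arange(nx)[None, :]).ravel()
                high = low + nx
                a = A[:-1, :].ravel()
                b = B[:-1, :].ravel()
            act = (a != 0) | (b != 0)
            lo, hi = flat[low[act]], flat[high[act]]
            aa, bb = a[act], b[act]
            ok = (lo >= 0) & (hi >= 0)
            lo, hi, aa, bb = lo[ok], hi[ok], aa[ok], bb[ok]
            np.add.at(diag, lo, bb)
            np.add.at(diag, hi, aa)
            rows.append(lo); cols.append(hi); vals.append(-aa)
            rows.append(hi); cols.append(lo); vals.append(-bb)
        rows.append(np.arange(n_un)); cols.append(np.arange(n_un)); vals.append(diag)
        M = coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_un, n_un),
        ).tocsc()
        return M, flat, n_un

    def _steady_direct(self, state: HormoneState, eps: float):
        p = self.params
        flat, n_un = self._unknown_index()
        ins = self.inside

        def solve(M, b_field):
            rhs = np.zeros(n_un)
            rhs[flat[ins.ravel()]] = b_field[ins]
            x = splu(M).solve(rhs)
            out = np.zeros(self.grid.labels.shape)
            out[ins] = x[flat[ins.ravel()]]
            return out

        b_aux = np.zeros(ins.shape)
        b_aux[self.cell_mask] = p.b_auxin
        M_aux_static_part = None

        max_iter = 400
        omega = 0.5
        last_E = state.activities.copy()
        resid = np.inf
        for it in range(max_iter):
            # cytokinin given current auxin (activities do not gate cytokinin)
            M_c, _, _ = self._assemble(
                self._cyt_Ax, self._cyt_Bx, self._cyt_Ay, self._cyt_By, self._delta_cyt_px
            )
            state.cytokinin = np.maximum(solve(M_c, self._cyt_production(state)), 0.0)
            self.update_activities(state)
            if not self.static:
                state.activities = (1 - omega) * last_E + omega * state.activities
            self._auxin_coeffs_current = False
            self._refresh_auxin_membranes(state)
            M_a, _, _ = self._assemble(
                self._aux_Ax, self._aux_Bx, self._aux_Ay, self._aux_By, p.delta_auxin
            )
            new_aux = np.maximum(solve(M_a, b_aux), 0.0)
            resid = float(np.abs(new_aux - state.auxin).max())
            state.auxin = new_aux
            dE = float(np.abs(state.activities - last_E).max())
            last_E = state.activities.copy()
            if self.static and not p.cyt_auxin_driven:
                self.update_activities(state)
                return state, ConvergenceReport(True, state.t, 1, 0.0, 0.0, "direct")
            if dE < 1e-9 and resid < 1e-8 * max(1.0, float(np.abs(new_aux).max())):
                self.update_activities(state)
                return state, ConvergenceReport(True, state.t, it + 1, 0.0, 0.0, "direct")
        self.update_activities(state)
        return state, ConvergenceReport(False, state.t, max_iter, resid, 0.0, "direct")

    # -- reference integrator (tests / oracle) ---------------------------------

    def explicit_euler_step(self, state: HormoneState, dt: float) -> HormoneState:
        """Fully explicit reference update (for small-grid oracle checks)."""
        p = self.params
        self.update_activities(state)
        self._refresh_auxin_membranes(state)
        m = self.cell_mask
        da = self._apply_L(state.auxin, self._aux_Ax, self._aux_Bx, 0) + self._apply_L(
            state.auxin, self._aux_Ay, self._aux_By, 1
        )
        dc = self._apply_L(state.cytokinin, self._cyt_Ax, self._cyt_Bx, 0) + self._apply_L(
            state.cytokinin, self._cyt_Ay, self._cyt_By, 1
        )
        bc = self._cyt_production(state)
        da[m] += p.b_auxin - p.delta_auxin * state.auxin[m]
        dc[m] += bc[m] - self._delta_cyt_px[m] * state.cytokinin[m]
        state.auxin = state.auxin + dt * da
        state.cytokinin = state.cytokinin + dt * dc
        state.t += dt
        return state

    def total_mass(self, state: HormoneState) -> tuple[float, float]:
        ins = self.inside
        return float(state.auxin[ins].sum()), float(state.cytokinin[ins].sum())
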