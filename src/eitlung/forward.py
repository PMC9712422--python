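"""Complete-electrode-model (CEM) forward problem for adjacent-drive EIT.

The CEM couples the interior potential u (piecewise-linear FEM on the
triangulated thorax) to the 16 electrode potentials U through per-electrode
contact impedances z_l, enforcing a prescribed net current on each electrode.
The weak form leads to the symmetric block system

    [ K(sigma) + Mz   -W ] [u]   [0]
    [    -W^T          D ] [U] = [I],

with K the conductivity-weighted stiffness matrix, Mz the boundary mass terms
1/z_l * int_{e_l} phi_i phi_j ds, W_{il} = 1/z_l * int_{e_l} phi_i ds and
D_ll = |e_l| / z_l.  A Lagrange multiplier pins sum(U) = 0 (ground).

The drive protocol is adjacent-adjacent: current is injected between
neighboring electrode pairs (i, i+1 mod 16); for each injection, voltages are
read on the 13 adjacent pairs not sharing an electrode with the injecting
pair, giving 16 x 13 = 208 channels per frame in injection-major,
measurement-minor order.

The conductivity Jacobian is computed by the adjoint method: because the CEM
system is symmetric, the derivative of the channel voltage with respect to an
element conductivity is -int_e grad(u_drive) . grad(u_meas) dx, where u_meas
is the field generated by injecting a unit current through the measurement
pair.  With P1 elements gradients are constant per triangle, so the integral
is area_e * grad_d . grad_m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .errors import ContractError, NumericalFailureError
from .mesh import Mesh, N_ELECTRODES

__all__ = [
    "DrivePattern",
    "ConductivityField",
    "VoltageFrame",
    "VoltageFrameSeries",
    "CEMSystem",
    "solve_forward",
    "compute_jacobian",
]


@dataclass(frozen=True)
class DrivePattern:
    """Adjacent-adjacent stimulation/measurement protocol.

    ``current_amplitude`` is the injected current in amperes peak-to-peak
    (default 1 mApp, the regulatory ceiling for this device class).
    """

    current_amplitude: float = 1e-3
    n_electrodes: int = N_ELECTRODES

    def __post_init__(self):
        if self.current_amplitude <= 0:
            raise ContractError("current_amplitude must be positive")

    @property
    def injection_pairs(self):
        n = self.n_electrodes
        return [(i, (i + 1) % n) for i in range(n)]

    def measurement_pairs(self, injection: int):
        """The 13 adjacent pairs not touching the injecting electrodes."""
        n = self.n_electrodes
        a, b = injection, (injection + 1) % n
        return [
            (k, (k + 1) % n)
            for k in range(n)
            if len({k, (k + 1) % n} & {a, b}) == 0
        ]

    @property
    def channels(self):
        """All (injection_pair, measurement_pair) tuples, injection-major."""
        out = []
        for i, inj in enumerate(self.injection_pairs):
            for meas in self.measurement_pairs(i):
                out.append((inj, meas))
        return out

    @property
    def n_channels(self) -> int:
        return len(self.channels)


@dataclass(frozen=True)
class ConductivityField:
    """Per-element conductivity (S/m) plus electrode contact impedances (Ohm*m)."""

    sigma: np.ndarray
    contact_impedances: np.ndarray = field(
        default_factory=lambda: np.full(N_ELECTRODES, 0.01)
    )

    def __post_init__(self):
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        object.__setattr__(
            self, "contact_impedances", np.asarray(self.contact_impedances, dtype=float)
        )
        if np.any(self.sigma <= 0) or not np.all(np.isfinite(self.sigma)):
            bad = int(np.argmin(self.sigma))
            raise NumericalFailureError(
                f"non-positive or non-finite conductivity at element {bad}"
            )
        if np.any(self.contact_impedances <= 0):
            raise ContractError("contact impedances must be positive")

    @classmethod
    def homogeneous(cls, mesh: Mesh, sigma: float = 1.0, z: float = 0.01):
        return cls(np.full(mesh.n_elements, sigma), np.full(N_ELECTRODES, z))


@dataclass(frozen=True)
class VoltageFrame:
    """One frame of 208 differential boundary voltages (V)."""

    values: np.ndarray
    frame_time: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ContractError("voltage frame contains non-finite values")


@dataclass
class VoltageFrameSeries:
    """Voltage frames over time at a fixed frame rate.

    ``values`` is (n_frames, n_channels); ``times`` is seconds.
    """

    values: np.ndarray
    times: np.ndarray
    fps: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.times.shape[0]:
            raise ContractError("frame values and times are inconsistent")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def frame(self, i: int) -> VoltageFrame:
        return VoltageFrame(self.values[i], self.times[i])


class CEMSystem:
    """Assembled CEM machinery for one mesh + drive pattern.

    Precomputes element gradients, the stiffness assembly map and boundary
    integrals once; per-conductivity solves then only rebuild the sparse data
    vector and refactorize.
    """

    def __init__(self, mesh: Mesh, pattern: DrivePattern | None = None):
        self.mesh = mesh
        self.pattern = pattern or DrivePattern()
        self._precompute()

    # ------------------------------------------------------------------ setup
    def _precompute(self):
        mesh = self.mesh
        tri = mesh.elements
        pts = mesh.nodes
        E = mesh.n_elements
        N = mesh.n_nodes
        L = len(mesh.electrode_arcs)

        # P1 gradients: for triangle with vertices p0,p1,p2, grad phi_k are
        # constant; G[e] is (2,3) with grad u = G[e] @ u[tri[e]]
        p = pts[tri]  # (E,3,2)
        b = np.stack(
            [
                p[:, 1, 1] - p[:, 2, 1],
                p[:, 2, 1] - p[:, 0, 1],
                p[:, 0, 1] - p[:, 1, 1],
            ],
            axis=1,
        )
        c = np.stack(
            [
                p[:, 2, 0] - p[:, 1, 0],
                p[:, 0, 0] - p[:, 2, 0],
                p[:, 1, 0] - p[:, 0, 0],
            ],
            axis=1,
        )
        areas = mesh.element_areas
        self.grad_coeff = np.stack([b, c], axis=1) / (2 * areas)[:, None, None]  # (E,2,3)

        # element stiffness, flattened: K_e = area * G^T G, shape (E,3,3)
        ke = areas[:, None, None] * np.einsum("exi,exj->eij", self.grad_coeff, self.grad_coeff)
        rows = np.repeat(tri, 3, axis=1).reshape(E, 3, 3)  # rows[e,i,j] = tri[e,i]
        cols = np.tile(tri[:, None, :], (1, 3, 1))  # cols[e,i,j] = tri[e,j]
        self._k_rows = rows.ravel()
        self._k_cols = cols.ravel()
        self._k_data_unit = ke.reshape(E, 9)  # scale by sigma_e per frame

        # boundary electrode integrals
        self._electrode_len = np.zeros(L)
        mz_rows, mz_cols, mz_vals = [], [], []  # 1/z-independent parts, per electrode
        w_rows, w_cols, w_vals = [], [], []
        self._mz_parts = []
        for l, arc in enumerate(mesh.electrode_arcs):
            r_, c_, v_, wr_, wv_ = [], [], [], [], []
            total = 0.0
            for a, bnode in zip(arc[:-1], arc[1:]):
                seg = np.linalg.norm(pts[bnode] - pts[a])
                total += seg
                # mass: [l/3 l/6; l/6 l/3]
                r_ += [a, a, bnode, bnode]
                c_ += [a, bnode, a, bnode]
                v_ += [seg / 3, seg / 6, seg / 6, seg / 3]
                wr_ += [a, bnode]
                wv_ += [seg / 2, seg / 2]
            self._electrode_len[l] = total
            self._mz_parts.append((np.array(r_), np.array(c_), np.array(v_), np.array(wr_), np.array(wv_)))

        self.N, self.L, self.E = N, L, E

        # unit current patterns for all adjacent pairs (also the measurement
        # fields, by reciprocity)
        I = np.zeros((L, L))
        for i, (a, bb) in enumerate(self.pattern.injection_pairs):
            I[a, i] = 1.0
            I[bb, i] = -1.0
        self._unit_currents = I  # (L, n_patterns)

    # --------------------------------------------------------------- assembly
    def _assemble(self, fld: ConductivityField):
        N, L = self.N, self.L
        n = N + L + 1
        data = (self._k_data_unit * fld.sigma[:, None]).ravel()
        rows = [self._k_rows]
        cols = [self._k_cols]
        vals = [data]
        for l in range(L):
            zinv = 1.0 / fld.contact_impedances[l]
            r_, c_, v_, wr_, wv_ = self._mz_parts[l]
            rows += [r_, wr_, np.full(len(wr_), N + l)]
            cols += [c_, np.full(len(wr_), N + l), wr_]
            vals += [zinv * v_, -zinv * wv_, -zinv * wv_]
            rows += [np.array([N + l])]
            cols += [np.array([N + l])]
            vals += [np.array([self._electrode_len[l] * zinv])]
        # ground constraint: sum(U) = 0 via Lagrange multiplier
        rows += [np.full(L, n - 1), N + np.arange(L)]
        cols += [N + np.arange(L), np.full(L, n - 1)]
        vals += [np.ones(L), np.ones(L)]
        A = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsc()
        return A

    def solve_unit_patterns(self, fld: ConductivityField):
        """Solve the CEM for all 16 unit adjacent-pair current patterns.

        Returns (u, U): nodal potentials (N, 16) and electrode potentials
        (16, 16) for unit (1 A) injections.
        """
        if fld.sigma.shape[0] != self.E:
            raise ContractError(
                f"conductivity has {fld.sigma.shape[0]} elements, mesh has {self.E}"
            )
        A = self._assemble(fld)
        rhs = np.zeros((self.N + self.L + 1, self.L))
        rhs[self.N : self.N + self.L, :] = self._unit_currents
        try:
            lu = splu(A)
        except RuntimeError as exc:  # pragma: no cover - singular assembly
            raise NumericalFailureError(f"CEM system factorization failed: {exc}")
        sol = lu.solve(rhs)
        if not np.all(np.isfinite(sol)):
            raise NumericalFailureError("CEM solve produced non-finite potentials")
        return sol[: self.N], sol[self.N : self.N + self.L]

    # ------------------------------------------------------------------ frame
    def measure(self, U: np.ndarray) -> np.ndarray:
        """Differential channel voltages from electrode potentials (L, n_inj)."""
        amp = self.pattern.current_amplitude
        vals = np.empty(self.pattern.n_channels)
        idx = 0
        for i in range(self.L):
            for (k, k1) in self.pattern.measurement_pairs(i):
                vals[idx] = amp * (U[k, i] - U[k1, i])
                idx += 1
        return vals

    def solve(self, fld: ConductivityField, frame_time: float = 0.0) -> VoltageFrame:
        _, U = self.solve_unit_patterns(fld)
        return VoltageFrame(self.measure(U), frame_time)

    def jacobian(self, fld: ConductivityField) -> np.ndarray:
        """Sensitivity matrix (n_channels, n_elements) at the reference field."""
        u, _ = self.solve_unit_patterns(fld)
        # per-element gradients of every unit-pattern field: (E, 2, L)
        g = np.einsum("exi,eil->exl", self.grad_coeff, u[self.mesh.elements])
        areas = self.mesh.element_areas
        amp = self.pattern.current_amplitude
        J = np.empty((self.pattern.n_channels, self.E))
        idx = 0
        for i in range(self.L):
            gd = g[:, :, i]
            for (k, _k1) in self.pattern.measurement_pairs(i):
                # measurement field = unit pattern k (current +1 at k, -1 at k+1)
                J[idx] = -amp * areas * np.einsum("ex,ex->e", gd, g[:, :, k])
                idx += 1
        return J


def solve_forward(
    mesh: Mesh, fld: ConductivityField, pattern: DrivePattern | None = None
) -> VoltageFrame:
    """Solve the CEM forward problem for one conductivity field."""
    return CEMSystem(mesh, pattern).solve(fld)


def compute_jacobian(
    mesh: Mesh, reference_field: ConductivityField, pattern: DrivePattern | None = None
) -> np.ndarray:
    """Adjoint-method conductivity Jacobian at ``reference_field``."""
    return CEMSystem(mesh, pattern).jacobian(reference_field)
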