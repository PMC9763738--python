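"""Quasi-static electromagnetic core: voxel solver, charge and admittance.

The electric problem at ~1 MHz is governed by the electro-quasistatic
equation ``div(eps_c grad(phi)) = 0`` where ``eps_c = eps0*eps_r - j*sigma/omega``
is the complex permittivity (e^{+j omega t} phasor convention).  The solver
discretises this on a regular voxel grid with a 7-point stencil and harmonic
face averaging of ``eps_c``; Dirichlet values are imposed on electrode voxel
sets and a zero-flux (Neumann) condition holds on every other boundary,
including internal tissue/air boundaries (air is excluded from the domain).

Admittance follows from the total charge enclosing one electrode,
``Y = j*omega*Q/V0``, reported together with the parallel-equivalent
capacitance ``C = Im(Y)/omega`` and resistance ``R = 1/Re(Y)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m

__all__ = [
    "EPS0",
    "ComplexDielectric",
    "VoxelDielectricMap",
    "ElectrodePair",
    "PotentialField",
    "ChargeResult",
    "SolverError",
    "make_dielectric",
    "solve_quasistatic",
    "total_charge",
    "boundary_charge",
]


class SolverError(RuntimeError):
    """Raised when the linear solve does not reach the requested residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class ComplexDielectric:
    """Complex permittivity of a lossy dielectric at a fixed angular frequency.

    ``value = eps0*eps_r - j*sigma/omega`` under the e^{+j omega t} convention,
    so that a passive medium has ``Re(value) > 0`` and ``Im(value) <= 0``.
    """

    eps_r: float
    sigma: float
    omega: float

    def __post_init__(self):
        if self.eps_r <= 0:
            raise ValueError(f"eps_r must be > 0, got {self.eps_r}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.omega <= 0:
            raise ValueError(f"omega must be > 0, got {self.omega}")

    @property
    def value(self) -> complex:
        return EPS0 * self.eps_r - 1j * self.sigma / self.omega

    @property
    def frequency(self) -> float:
        return self.omega / (2.0 * np.pi)

    def scaled(self, eps_r_factor: float = 1.0, sigma_factor: float = 1.0) -> "ComplexDielectric":
        return ComplexDielectric(self.eps_r * eps_r_factor, self.sigma * sigma_factor, self.omega)


def make_dielectric(eps_r: float, sigma: float, frequency: float) -> ComplexDielectric:
    """Build a :class:`ComplexDielectric` from engineering parameters.

    Parameters are the relative permittivity (dimensionless), conductivity
    in S/m and frequency in Hz.
    """
    if frequency <= 0:
        raise ValueError(f"frequency must be > 0, got {frequency}")
    return ComplexDielectric(eps_r, sigma, 2.0 * np.pi * frequency)


@dataclass
class VoxelDielectricMap:
    """Labelled voxel volume with a tissue-id -> dielectric table.

    Label 0 is reserved for excluded background (air); every other label
    present in ``labels`` must have an entry in ``materials``.  ``spacing``
    is the voxel edge length per axis in meters and ``origin`` the world
    coordinate of the corner of voxel (0,0,0).
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    materials: dict[int, ComplexDielectric]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.materials)
        if missing:
            raise ValueError(f"labels without material entry: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def eps_array(self) -> np.ndarray:
        """Complex permittivity per voxel; 0 outside the domain."""
        eps = np.zeros(self.labels.shape, dtype=complex)
        for lab, mat in self.materials.items():
            eps[self.labels == lab] = mat.value
        return eps

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        axes = [
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        ]
        return tuple(axes)

    @property
    def omega(self) -> float:
        return next(iter(self.materials.values())).omega


@dataclass
class ElectrodePair:
    """Two disjoint Dirichlet voxel sets driving the solve.

    Patch masks select voxels held at a fixed potential: ``patch_a`` at
    ``v0`` and ``patch_b`` at 0.  Electrode voxels may be background voxels
    adjacent to tissue (surface electrodes: the Dirichlet value is then
    imposed at the shared face, half a voxel from the first tissue center)
    or labelled voxels (embedded electrodes).
    """

    patch_a: np.ndarray
    patch_b: np.ndarray
    v0: float = 1.0
    frequency: float = 1e6
    patch_edge: float = 0.016

    def __post_init__(self):
        self.patch_a = np.asarray(self.patch_a, dtype=bool)
        self.patch_b = np.asarray(self.patch_b, dtype=bool)
        if not self.patch_a.any() or not self.patch_b.any():
            raise ValueError("electrode patches must be non-empty")
        if (self.patch_a & self.patch_b).any():
            raise ValueError("electrode patches must be disjoint")

    def dirichlet(self) -> tuple[np.ndarray, np.ndarray]:
        """Pinned-voxel mask and per-voxel potential values."""
        pin = self.patch_a | self.patch_b
        values = np.zeros(self.patch_a.shape, dtype=complex)
        values[self.patch_a] = self.v0
        return pin, values


@dataclass
class PotentialField:
    """Solution of the quasi-static solve on the voxel grid.

    ``phi`` holds the complex potential on the full grid (pinned voxels carry
    their imposed value, excluded voxels 0), ``free`` flags the solved
    unknowns and ``residual`` is the final relative residual of the linear
    system.
    """

    phi: np.ndarray
    free: np.ndarray
    pin: np.ndarray
    pin_values: np.ndarray
    residual: float


def _face_conductance(eps_a, eps_b, pin_a, pin_b, area, h):
    """Conductance of the face between two voxel columns.

    Harmonic mean of the two permittivities over the center-to-center
    distance; a pinned background voxel (eps == 0) imposes its value at the
    shared face, giving the half-distance single-sided coefficient.
    """
    g = np.zeros(np.broadcast(eps_a, eps_b).shape, dtype=complex)
    both = (eps_a != 0) & (eps_b != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g[both] = 2.0 * (eps_a * eps_b)[both] / (eps_a + eps_b)[both] * area / h
    face_a = (eps_a == 0) & pin_a & (eps_b != 0)
    face_b = (eps_b == 0) & pin_b & (eps_a != 0)
    g[face_a] = 2.0 * eps_b[face_a] * area / h
    g[face_b] = 2.0 * eps_a[face_b] * area / h
    return g


def _assemble(vmap: VoxelDielectricMap, pin: np.ndarray, pin_values: np.ndarray):
    eps = vmap.eps_array()
    active = (eps != 0) | pin
    free = active & ~pin
    n = int(free.sum())
    if n == 0:
        raise ValueError("no free voxels to solve for")
    index = -np.ones(vmap.shape, dtype=np.int64)
    index[free] = np.arange(n)

    hx, hy, hz = vmap.spacing
    areas = (hy * hz, hx * hz, hx * hy)
    dists = (hx, hy, hz)

    rows, cols, vals = [], [], []
    diag = np.zeros(n, dtype=complex)
    b = np.zeros(n, dtype=complex)

    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(0, -1)
        sl_b[axis] = slice(1, None)
        sl_a, sl_b = tuple(sl_a), tuple(sl_b)
        g = _face_conductance(
            eps[sl_a], eps[sl_b], pin[sl_a], pin[sl_b], areas[axis], dists[axis]
        )
        ia, ib = index[sl_a], index[sl_b]
        pa, pb = pin[sl_a], pin[sl_b]
        va, vb = pin_values[sl_a], pin_values[sl_b]

        both_free = (ia >= 0) & (ib >= 0) & (g != 0)
        gv = g[both_free]
        rows.append(ia[both_free])
        cols.append(ib[both_free])
        vals.append(-gv)
        rows.append(ib[both_free])
        cols.append(ia[both_free])
        vals.append(-gv)
        np.add.at(diag, ia[both_free], gv)
        np.add.at(diag, ib[both_free], gv)

        fa_pb = (ia >= 0) & pb & (g != 0)
        np.add.at(diag, ia[fa_pb], g[fa_pb])
        np.add.at(b, ia[fa_pb], g[fa_pb] * vb[fa_pb])
        fb_pa = (ib >= 0) & pa & (g != 0)
        np.add.at(diag, ib[fb_pa], g[fb_pa])
        np.add.at(b, ib[fb_pa], g[fb_pa] * va[fb_pa])

    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    return A, b, free, index


def _solve_linear(A, b, tol, maxiter):
    """Direct sparse solve with an iterative fallback for large systems."""
    n = A.shape[0]
    is_real = (abs(A.imag).max() == 0.0) and (abs(b.imag).max() == 0.0)
    if is_real:
        A = sp.csr_matrix(
            (np.ascontiguousarray(A.data.real), A.indices, A.indptr), shape=A.shape
        )
        b = np.ascontiguousarray(b.real)
        if n > 30_000:
            # SPD system: Jacobi-preconditioned CG beats a 3D direct factorisation
            M = sp.diags(1.0 / A.diagonal())
            x, info = spla.cg(A, b, rtol=tol * 1e-2, maxiter=maxiter, M=M)
            if info == 0:
                return x.astype(complex)
        return spla.spsolve(A, b).astype(complex)
    if n <= 220_000:
        return spla.spsolve(A, b).astype(complex)
    M = sp.diags(1.0 / A.diagonal())
    x, info = spla.bicgstab(A, b, rtol=tol * 1e-2, maxiter=maxiter, M=M)
    if info != 0:
        res = float(np.linalg.norm(A @ x - b) / np.linalg.norm(b))
        raise SolverError(f"linear solve did not converge (info={info})", residual=res)
    return x.astype(complex)


def solve_quasistatic(
    vmap: VoxelDielectricMap,
    electrodes: ElectrodePair | tuple[np.ndarray, np.ndarray],
    tol: float = 1e-10,
    maxiter: int = 50_000,
) -> PotentialField:
    """Solve ``div(eps_c grad(phi)) = 0`` on the voxel map.

    ``electrodes`` is either an :class:`ElectrodePair` or a ``(mask, values)``
    Dirichlet specification.  Raises :class:`SolverError` if the relative
    residual cannot be brought below ``tol``.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if isinstance(electrodes, ElectrodePair):
        pin, pin_values = electrodes.dirichlet()
    else:
        pin, pin_values = electrodes
        pin = np.asarray(pin, dtype=bool)
        pin_values = np.asarray(pin_values, dtype=complex)
    if pin.shape != vmap.shape:
        raise ValueError("Dirichlet mask shape does not match the voxel map")

    A, b, free, index = _assemble(vmap, pin, pin_values)
    x = _solve_linear(A, b, tol, maxiter)
    bnorm = np.linalg.norm(b)
    residual = float(np.linalg.norm(A @ x - b) / bnorm) if bnorm > 0 else 0.0
    if residual > tol:
        raise SolverError(
            f"relative residual {residual:.3e} above tolerance {tol:.1e}", residual
        )
    phi = np.zeros(vmap.shape, dtype=complex)
    phi[free] = x
    phi[pin] = pin_values[pin]
    return PotentialField(phi=phi, free=free, pin=pin, pin_values=pin_values, residual=residual)


@dataclass
class ChargeResult:
    """Total charge and derived admittance/impedance of one solve.

    ``c`` and ``r`` are the parallel-equivalent capacitance and resistance:
    ``Y = G + j*omega*C`` with ``C = Im(Y)/omega`` and ``R = 1/G``.
    """

    q: complex
    y: complex
    z: complex
    c: float
    r: float
    v0: float
    omega: float

    @classmethod
    def from_charge(cls, q: complex, v0: float, omega: float) -> "ChargeResult":
        y = 1j * omega * q / v0
        z = 1.0 / y if y != 0 else complex(np.inf)
        c = y.imag / omega
        r = 1.0 / y.real if y.real != 0 else np.inf
        return cls(q=q, y=y, z=z, c=c, r=r, v0=v0, omega=omega)


def _shell_flux(field: PotentialField, vmap: VoxelDielectricMap, shell: np.ndarray) -> complex:
    """Flux of D = eps_c*E through the boundary faces of a voxel-set shell."""
    eps = vmap.eps_array()
    phi = field.phi
    pin = field.pin
    total = 0.0 + 0.0j
    hx, hy, hz = vmap.spacing
    areas = (hy * hz, hx * hz, hx * hy)
    dists = (hx, hy, hz)
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(0, -1)
        sl_b[axis] = slice(1, None)
        sl_a, sl_b = tuple(sl_a), tuple(sl_b)
        g = _face_conductance(
            eps[sl_a], eps[sl_b], pin[sl_a], pin[sl_b], areas[axis], dists[axis]
        )
        in_a = shell[sl_a] & ~shell[sl_b]
        in_b = shell[sl_b] & ~shell[sl_a]
        # D.n_out * A = g * (phi_in - phi_out)
        total += np.sum(g[in_a] * (phi[sl_a][in_a] - phi[sl_b][in_a]))
        total += np.sum(g[in_b] * (phi[sl_b][in_b] - phi[sl_a][in_b]))
    return complex(total)


def total_charge(
    field: PotentialField,
    vmap: VoxelDielectricMap,
    electrodes: ElectrodePair,
    shell: np.ndarray | None = None,
) -> ChargeResult:
    """Charge enclosing electrode ``patch_a`` and the derived admittance.

    ``shell`` is a boolean voxel mask whose boundary faces form the closed
    integration surface; it must contain all of ``patch_a`` and none of
    ``patch_b``.  Defaults to the ``patch_a`` voxels themselves.
    """
    if shell is None:
        shell = electrodes.patch_a
    shell = np.asarray(shell, dtype=bool)
    if not electrodes.patch_a[~shell].sum() == 0 or not shell[electrodes.patch_a].all():
        raise ValueError("shell must enclose electrode patch_a entirely")
    if shell[electrodes.patch_b].any():
        raise ValueError("shell must not enclose electrode patch_b")
    q = _shell_flux(field, vmap, shell)
    omega = 2.0 * np.pi * electrodes.frequency
    return ChargeResult.from_charge(q, electrodes.v0, omega)


def boundary_charge(
    field: PotentialField,
    vmap: VoxelDielectricMap,
    v0: float,
    weighted: bool = True,
) -> complex:
    """Potential-weighted charge on the pinned boundary, (1/V0) * sum(V*sigma*A).

    For a two-level (electrode/ground) boundary this equals the charge on the
    V0 electrode; for a smoothly varying Dirichlet boundary it is the charge
    functional for which the reciprocity perturbation identity is exact.
    """
    eps = vmap.eps_array()
    phi = field.phi
    pin = field.pin
    vals = field.pin_values
    total = 0.0 + 0.0j
    hx, hy, hz = vmap.spacing
    areas = (hy * hz, hx * hz, hx * hy)
    dists = (hx, hy, hz)
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(0, -1)
        sl_b[axis] = slice(1, None)
        sl_a, sl_b = tuple(sl_a), tuple(sl_b)
        g = _face_conductance(
            eps[sl_a], eps[sl_b], pin[sl_a], pin[sl_b], areas[axis], dists[axis]
        )
        fa = pin[sl_a] & ~pin[sl_b] & (g != 0)
        fb = pin[sl_b] & ~pin[sl_a] & (g != 0)
        wa = vals[sl_a][fa] / v0 if weighted else 1.0
        wb = vals[sl_b][fb] / v0 if weighted else 1.0
        total += np.sum(wa * g[fa] * (phi[sl_a][fa] - phi[sl_b][fa]))
        total += np.sum(wb * g[fb] * (phi[sl_b][fb] - phi[sl_a][fb]))
    return complex(total)
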