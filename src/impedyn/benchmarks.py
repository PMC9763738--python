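"""Analytic verification benchmarks and the direct-difference dQ oracle.

Four closed-form or semi-analytic geometries exercise the perturbation
formulas against a brute-force oracle (two independent full solutions):

* 1D two-slab capacitor (piecewise-uniform field; fully closed form),
* 2D concentric two-region cylinder (cylindrical-harmonic series, optional
  inner electrode; uniform limit is the logarithmic coaxial formula),
* 2D eccentric dielectric cylinder (Moebius map to the concentric problem —
  the closed form that image-charge series sum to; interface motion is not
  aligned with the normal when the disc translates),
* 3D concentric spheres (Legendre series).

The measured quantity is the potential-weighted boundary charge
``Q = (1/V0) * integral V(s) sigma(s) ds`` over the Dirichlet boundary,
which reduces to the charge on the driven electrode for two-level boundary
data and is the functional for which the reciprocity identity is exact.
Slab/coaxial gauge convention: the electrode adjacent to region 1 is
grounded, so the open-interface form of the dielectric-change formula holds
without an electrode-junction term.

``error_sweep`` perturbs each geometry (interface shift, region-1
permittivity change, or both along the equal-fractional-amplitude diagonal)
by up to 10% and reports the relative deviation between the
reciprocity-formula dQ and the direct two-solve difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import eval_legendre

from .em_core import ChargeResult, ComplexDielectric
from .perturbation import InterfaceFieldState, PerturbResult, dq_combined

__all__ = [
    "SlabSpec",
    "ConcentricCylinderSpec",
    "OffsetCylinderSpec",
    "ConcentricSphereSpec",
    "SweepResult",
    "slab_solution",
    "concentric_cylinder_solution",
    "offset_cylinder_solution",
    "concentric_sphere_solution",
    "dq_direct",
    "error_sweep",
    "BENCHMARK_FAMILIES",
    "default_spec",
]


def _diel(eps_r, sigma=0.0, frequency=1e6) -> ComplexDielectric:
    return ComplexDielectric(eps_r, sigma, 2 * np.pi * frequency)


@dataclass
class FaceSet:
    """Minimal per-face geometry (duck-typed TriSurface) for analytic interfaces."""

    face_centroids: np.ndarray
    face_normals: np.ndarray
    face_areas: np.ndarray

    @property
    def n_faces(self) -> int:
        return len(self.face_areas)


# ---------------------------------------------------------------------------
# 1D slab benchmark
# ---------------------------------------------------------------------------


@dataclass
class SlabSpec:
    """Two dielectric slabs in series between full-face plate electrodes.

    Region 1 occupies [0, p*L] next to the grounded electrode; region 2
    occupies [p*L, L] next to the electrode at v0.  Unit cross-section area
    unless stated.
    """

    length: float = 0.1
    p: float = 0.5
    eps1: ComplexDielectric = field(default_factory=lambda: _diel(2.0))
    eps2: ComplexDielectric = field(default_factory=lambda: _diel(10.0))
    v0: float = 1.0
    area: float = 1.0

    def __post_init__(self):
        if not 0 < self.p < 1:
            raise ValueError(f"interface fraction p must lie in (0,1), got {self.p}")


class SlabSolution:
    def __init__(self, spec: SlabSpec):
        self.spec = spec
        e1, e2 = spec.eps1.value, spec.eps2.value
        L, p = spec.length, spec.p
        # uniform displacement field D, phi(0)=0, phi(L)=v0
        self.d_field = spec.v0 / (p * L / e1 + (1 - p) * L / e2)

    def phi(self, x):
        s = self.spec
        e1, e2 = s.eps1.value, s.eps2.value
        x = np.asarray(x, dtype=float)
        xi = s.p * s.length
        return np.where(
            x <= xi,
            self.d_field * x / e1,
            self.d_field * (xi / e1 + (x - xi) / e2),
        )

    def charge(self) -> complex:
        """Charge on the driven (v0) electrode."""
        return complex(self.d_field * self.spec.area)

    def charge_result(self) -> ChargeResult:
        return ChargeResult.from_charge(self.charge(), self.spec.v0, self.spec.eps1.omega)

    def interface_state(self) -> InterfaceFieldState:
        s = self.spec
        e1, e2 = s.eps1.value, s.eps2.value
        side = np.sqrt(s.area)
        xi = s.p * s.length
        surface = FaceSet(
            face_centroids=np.array([[xi, side / 2, side / 2]]),
            face_normals=np.array([[1.0, 0.0, 0.0]]),
            face_areas=np.array([s.area]),
        )
        return InterfaceFieldState(
            surface=surface,
            en_plus=np.array([-self.d_field / e2]),
            et=np.zeros((1, 3), dtype=complex),
            phi_r1=np.array([self.d_field * xi / e1]),
            dphidn_minus=np.array([self.d_field / e1]),
            dphidn_plus=np.array([self.d_field / e2]),
            eps1=s.eps1,
            eps2=s.eps2,
            v0=s.v0,
        )


def slab_solution(spec: SlabSpec) -> SlabSolution:
    """Closed-form series-capacitor solution: Q/A = V0/(pL/eps1 + (1-p)L/eps2)."""
    return SlabSolution(spec)


# ---------------------------------------------------------------------------
# 2D concentric cylinder benchmark (cylindrical harmonics)
# ---------------------------------------------------------------------------


class ConvergenceError(RuntimeError):
    pass


@dataclass
class ConcentricCylinderSpec:
    """Dielectric disc (or annulus around an inner electrode) in a circular boundary.

    Region 1 (``eps_in``) spans rho < r_interface (or inner_radius < rho <
    r_interface when an inner electrode is present); region 2 (``eps_out``)
    spans r_interface < rho < r_outer.  Boundary potentials are Fourier
    series {m: (cos_coef, sin_coef)}; the default outer data v0*cos(theta)
    creates a uniform applied field in the homogeneous limit.  Quantities
    are per unit axial depth.
    """

    r_outer: float = 1.0
    r_interface: float = 0.5
    eps_in: ComplexDielectric = field(default_factory=lambda: _diel(2.0))
    eps_out: ComplexDielectric = field(default_factory=lambda: _diel(10.0))
    v0: float = 1.0
    outer_coeffs: dict | None = None
    inner_radius: float | None = None
    inner_coeffs: dict | None = None
    order: int = 64

    def __post_init__(self):
        if not 0 < self.r_interface < self.r_outer:
            raise ValueError("need 0 < r_interface < r_outer")
        if self.inner_radius is not None and not 0 < self.inner_radius < self.r_interface:
            raise ValueError("inner electrode must lie inside the interface")
        if self.order < 1:
            raise ValueError("truncation order must be >= 1")
        if self.outer_coeffs is None:
            self.outer_coeffs = {1: (self.v0, 0.0)}
        if self.inner_radius is not None and self.inner_coeffs is None:
            self.inner_coeffs = {0: (0.0, 0.0)}


class _HarmonicRadial:
    """Radial basis pair for harmonic m: (rho^m, rho^-m) or (1, ln rho)."""

    def __init__(self, m: int):
        self.m = m

    def val(self, rho):
        rho = np.asarray(rho, dtype=float)
        if self.m == 0:
            return np.ones_like(rho), np.log(rho)
        return rho**self.m, rho ** (-self.m)

    def der(self, rho):
        rho = np.asarray(rho, dtype=float)
        if self.m == 0:
            return np.zeros_like(rho), 1.0 / rho
        return self.m * rho ** (self.m - 1), -self.m * rho ** (-self.m - 1)


class ConcentricCylinderSolution:
    def __init__(self, spec: ConcentricCylinderSpec):
        self.spec = spec
        e1, e2 = spec.eps_in.value, spec.eps_out.value
        rm, b, a = spec.r_interface, spec.r_outer, spec.inner_radius
        ms = sorted(
            set(spec.outer_coeffs) | set(spec.inner_coeffs or {}) | {0}
        )
        ms = [m for m in ms if m <= spec.order]
        self.coeffs: dict = {}
        for m in ms:
            rad = _HarmonicRadial(m)
            for pi, par in enumerate(("cos", "sin")):
                if m == 0 and par == "sin":
                    continue
                vout = complex(np.atleast_1d(spec.outer_coeffs.get(m, (0, 0)))[pi])
                if a is None:
                    # unknowns: alpha (region 1 regular), gamma, delta (region 2)
                    A = np.zeros((3, 3), dtype=complex)
                    rhs = np.zeros(3, dtype=complex)
                    r1a, _ = rad.val(rm)
                    d1a, _ = rad.der(rm)
                    r2a, r2b = rad.val(rm)
                    d2a, d2b = rad.der(rm)
                    r2ab, r2bb = rad.val(b)
                    A[0] = [r1a, -r2a, -r2b]
                    A[1] = [e1 * d1a, -e2 * d2a, -e2 * d2b]
                    A[2] = [0.0, r2ab, r2bb]
                    rhs[2] = vout
                    alpha, gamma, delta = np.linalg.solve(A, rhs)
                    self.coeffs[(m, par)] = (alpha, 0.0 + 0j, gamma, delta)
                else:
                    vin = complex(np.atleast_1d((spec.inner_coeffs or {}).get(m, (0, 0)))[pi])
                    A = np.zeros((4, 4), dtype=complex)
                    rhs = np.zeros(4, dtype=complex)
                    r1aa, r1ba = rad.val(a)
                    r1am, r1bm = rad.val(rm)
                    d1am, d1bm = rad.der(rm)
                    r2am, r2bm = rad.val(rm)
                    d2am, d2bm = rad.der(rm)
                    r2ab, r2bb = rad.val(b)
                    A[0] = [r1aa, r1ba, 0.0, 0.0]
                    A[1] = [r1am, r1bm, -r2am, -r2bm]
                    A[2] = [e1 * d1am, e1 * d1bm, -e2 * d2am, -e2 * d2bm]
                    A[3] = [0.0, 0.0, r2ab, r2bb]
                    rhs[0] = vin
                    rhs[3] = vout
                    self.coeffs[(m, par)] = tuple(np.linalg.solve(A, rhs))

    def _angular(self, m, par, theta):
        return np.cos(m * theta) if par == "cos" else np.sin(m * theta)

    def _dangular(self, m, par, theta):
        return -m * np.sin(m * theta) if par == "cos" else m * np.cos(m * theta)

    def eval(self, region: int, rho, theta):
        """phi, dphi/drho, dphi/dtheta in the given region (1 inner, 2 outer)."""
        rho = np.asarray(rho, dtype=float)
        theta = np.asarray(theta, dtype=float)
        phi = np.zeros(np.broadcast(rho, theta).shape, dtype=complex)
        drho = np.zeros_like(phi)
        dtheta = np.zeros_like(phi)
        for (m, par), (al, be, ga, de) in self.coeffs.items():
            rad = _HarmonicRadial(m)
            va, vb = rad.val(rho)
            da, db = rad.der(rho)
            c1, c2 = (al, be) if region == 1 else (ga, de)
            radial = c1 * va + c2 * vb
            dradial = c1 * da + c2 * db
            phi += radial * self._angular(m, par, theta)
            drho += dradial * self._angular(m, par, theta)
            dtheta += radial * self._dangular(m, par, theta)
        return phi, drho, dtheta

    def phi(self, rho, theta):
        region = np.where(np.asarray(rho) <= self.spec.r_interface, 1, 2)
        out = np.zeros(np.broadcast(np.asarray(rho), np.asarray(theta)).shape, dtype=complex)
        for reg in (1, 2):
            sel = region == reg
            if np.any(sel):
                p, _, _ = self.eval(reg, np.asarray(rho)[sel], np.asarray(theta)[sel])
                out[sel] = p
        return out

    def charge(self) -> complex:
        """Potential-weighted boundary charge per unit depth, (1/V0) * sum V*sigma*ds."""
        s = self.spec
        e2 = s.eps_out.value
        b = s.r_outer
        total = 0j
        for (m, par), (al, be, ga, de) in self.coeffs.items():
            rad = _HarmonicRadial(m)
            da, db = rad.der(b)
            dphi = ga * da + de * db
            vcoef = complex(np.atleast_1d(s.outer_coeffs.get(m, (0, 0)))[0 if par == "cos" else 1])
            weight = 2 * np.pi if m == 0 else np.pi
            total += vcoef * dphi * weight
        return complex(e2 * b * total / s.v0)

    def charge_result(self) -> ChargeResult:
        return ChargeResult.from_charge(self.charge(), self.spec.v0, self.spec.eps_in.omega)

    def interface_condition_residual(self, n: int = 100) -> float:
        """Max relative violation of phi / normal-current continuity at the interface."""
        theta = (np.arange(n) + 0.5) * 2 * np.pi / n
        rm = self.spec.r_interface
        p1, d1, _ = self.eval(1, rm, theta)
        p2, d2, _ = self.eval(2, rm, theta)
        e1, e2 = self.spec.eps_in.value, self.spec.eps_out.value
        scale_p = max(np.abs(p1).max(), np.abs(p2).max(), abs(self.spec.v0))
        scale_f = max(np.abs(e1 * d1).max(), np.abs(e2 * d2).max(), 1e-300)
        return float(
            max(np.abs(p1 - p2).max() / scale_p, np.abs(e1 * d1 - e2 * d2).max() / scale_f)
        )

    def interface_state(self, n_theta: int = 720) -> InterfaceFieldState:
        s = self.spec
        rm = s.r_interface
        theta = (np.arange(n_theta) + 0.5) * 2 * np.pi / n_theta
        dtheta = 2 * np.pi / n_theta
        normals = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=1)
        surface = FaceSet(
            face_centroids=rm * normals,
            face_normals=normals,
            face_areas=np.full(n_theta, rm * dtheta),
        )
        p1, d1r, d1t = self.eval(1, rm, theta)
        p2, d2r, d2t = self.eval(2, rm, theta)
        # E = -grad phi; tangential component from the theta derivative
        et_mag = -d2t / rm
        tang = np.stack([-np.sin(theta), np.cos(theta), np.zeros_like(theta)], axis=1)
        return InterfaceFieldState(
            surface=surface,
            en_plus=-d2r,
            et=et_mag[:, None] * tang,
            phi_r1=p1,
            dphidn_minus=d1r,
            dphidn_plus=d2r,
            eps1=s.eps_in,
            eps2=s.eps_out,
            v0=s.v0,
        )


def concentric_cylinder_solution(spec: ConcentricCylinderSpec) -> ConcentricCylinderSolution:
    """Semi-analytic two-region cylinder solution; checks series consistency."""
    sol = ConcentricCylinderSolution(spec)
    res = sol.interface_condition_residual()
    if res > 1e-8:
        raise ConvergenceError(
            f"interface conditions violated at relative level {res:.2e}; "
            "increase the truncation order"
        )
    return sol


# ---------------------------------------------------------------------------
# 2D eccentric (offset) cylinder benchmark via Moebius transformation
# ---------------------------------------------------------------------------


@dataclass
class OffsetCylinderSpec:
    """Dielectric cylinder of radius ``r_cylinder`` offset by ``offset`` along +x
    inside a circular boundary of radius ``r_outer`` with Fourier Dirichlet data.

    Contact with the outer boundary (offset + r_cylinder -> r_outer) is an
    admitted edge case; the harmonic truncation requirement grows as the gap
    closes and is checked at solve time.
    """

    r_outer: float = 1.0
    r_cylinder: float = 0.5
    offset: float = 0.2
    eps_in: ComplexDielectric = field(default_factory=lambda: _diel(2.0))
    eps_out: ComplexDielectric = field(default_factory=lambda: _diel(10.0))
    v0: float = 1.0
    outer_coeffs: dict | None = None
    order: int = 64
    n_boundary_samples: int = 4096

    def __post_init__(self):
        if self.offset < 0:
            raise ValueError("offset must be >= 0 (rotate the boundary data instead)")
        if self.offset + self.r_cylinder > self.r_outer + 1e-12:
            raise ValueError("cylinder must lie inside the outer boundary")
        if self.outer_coeffs is None:
            self.outer_coeffs = {1: (self.v0, 0.0)}


def _moebius_param(c0: float, r0: float) -> float:
    """Real Moebius parameter s mapping circle (c0, r0) inside the unit disc
    to a circle concentric with the origin, via T(z) = (z - s)/(1 - s z)."""
    if c0 == 0.0:
        return 0.0
    u, v = c0 - r0, c0 + r0
    # T(u) = -T(v)  =>  s^2 (u+v) - 2 s (1+uv) + (u+v) = 0
    disc = (1 + u * v) ** 2 - (u + v) ** 2
    if disc < 0:
        raise ValueError("circles intersect; no concentrifying map")
    s = ((1 + u * v) - np.sqrt(disc)) / (u + v)
    return float(s)


class OffsetCylinderSolution:
    def __init__(self, spec: OffsetCylinderSpec):
        self.spec = spec
        b = spec.r_outer
        c0 = spec.offset / b
        r0 = spec.r_cylinder / b
        self.s = _moebius_param(c0, r0)
        tv = self._map(c0 + r0)
        self.rho_m = float(abs(tv))

        # boundary data transported to the mapped plane
        n = spec.n_boundary_samples
        theta_w = 2 * np.pi * np.arange(n) / n
        zb = self._inv_map(np.exp(1j * theta_w))
        theta_z = np.angle(zb)
        v_bound = self._boundary_potential(theta_z)
        fft = np.fft.fft(v_bound) / n
        coeffs: dict = {0: (complex(fft[0]), 0.0)}
        for m in range(1, spec.order + 1):
            cm, cmm = fft[m], fft[-m]
            coeffs[m] = (cm + cmm, 1j * (cm - cmm))
        tail = np.abs(fft[spec.order - 4 : spec.order + 1]).max() if spec.order >= 4 else 0.0
        head = max(np.abs(v_bound).max(), 1e-300)
        self.truncation_bound = float(tail / head)
        if self.truncation_bound > 1e-6:
            raise ConvergenceError(
                f"mapped boundary series not converged (tail {self.truncation_bound:.2e}); "
                "increase order (gap may be closing toward contact)"
            )
        mapped = ConcentricCylinderSpec(
            r_outer=1.0,
            r_interface=self.rho_m,
            eps_in=spec.eps_in,
            eps_out=spec.eps_out,
            v0=spec.v0,
            outer_coeffs=coeffs,
            order=spec.order,
        )
        self.mapped_solution = ConcentricCylinderSolution(mapped)

    # Moebius helpers on the unit-normalised plane
    def _map(self, z):
        return (z - self.s) / (1.0 - self.s * z)

    def _inv_map(self, w):
        return (w + self.s) / (1.0 + self.s * w)

    def _map_deriv(self, z):
        return (1.0 - self.s**2) / (1.0 - self.s * z) ** 2

    def _boundary_potential(self, theta):
        out = np.zeros_like(theta, dtype=complex)
        for m, (ac, as_) in self.spec.outer_coeffs.items():
            out += ac * np.cos(m * theta) + as_ * np.sin(m * theta)
        return out

    def phi(self, x, y):
        b = self.spec.r_outer
        w = self._map((np.asarray(x) + 1j * np.asarray(y)) / b)
        return self.mapped_solution.phi(np.abs(w), np.angle(w))

    def charge(self) -> complex:
        """Weighted boundary charge; conformally invariant, computed in the mapped plane."""
        return self.mapped_solution.charge()

    def charge_result(self) -> ChargeResult:
        return ChargeResult.from_charge(self.charge(), self.spec.v0, self.spec.eps_in.omega)

    def interface_state(self, n_theta: int = 720) -> InterfaceFieldState:
        s = self.spec
        b, rc, c = s.r_outer, s.r_cylinder, s.offset
        theta = (np.arange(n_theta) + 0.5) * 2 * np.pi / n_theta
        dtheta = 2 * np.pi / n_theta
        normals = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=1)
        cent = np.stack(
            [c + rc * np.cos(theta), rc * np.sin(theta), np.zeros_like(theta)], axis=1
        )
        surface = FaceSet(
            face_centroids=cent,
            face_normals=normals,
            face_areas=np.full(n_theta, rc * dtheta),
        )
        zn = (cent[:, 0] + 1j * cent[:, 1]) / b
        w = self._map(zn)
        theta_w = np.angle(w)
        dT = self._map_deriv(zn)
        a_re, a_im = dT.real, dT.imag

        def grad_physical(region):
            # polar derivatives in the mapped plane at the exact mapped radius
            _, drho, dth = self.mapped_solution.eval(region, self.rho_m, theta_w)
            gu = np.cos(theta_w) * drho - np.sin(theta_w) * dth / self.rho_m
            gv = np.sin(theta_w) * drho + np.cos(theta_w) * dth / self.rho_m
            # pull back through the conformal map, then undo the 1/b scaling
            gx = (a_re * gu + a_im * gv) / b
            gy = (-a_im * gu + a_re * gv) / b
            return gx, gy

        g1x, g1y = grad_physical(1)
        g2x, g2y = grad_physical(2)
        p1, _, _ = self.mapped_solution.eval(1, self.rho_m, theta_w)
        nx, ny = normals[:, 0], normals[:, 1]
        d1n = g1x * nx + g1y * ny
        d2n = g2x * nx + g2y * ny
        etx = -(g2x - d2n * nx)
        ety = -(g2y - d2n * ny)
        return InterfaceFieldState(
            surface=surface,
            en_plus=-d2n,
            et=np.stack([etx, ety, np.zeros_like(etx)], axis=1),
            phi_r1=p1,
            dphidn_minus=d1n,
            dphidn_plus=d2n,
            eps1=s.eps_in,
            eps2=s.eps_out,
            v0=s.v0,
        )


def offset_cylinder_solution(spec: OffsetCylinderSpec) -> OffsetCylinderSolution:
    """Eccentric-cylinder solution via a Moebius map to the concentric problem."""
    return OffsetCylinderSolution(spec)


# ---------------------------------------------------------------------------
# 3D concentric sphere benchmark (Legendre series)
# ---------------------------------------------------------------------------


@dataclass
class ConcentricSphereSpec:
    """Dielectric sphere (or shell around an inner electrode) in a spherical
    boundary with axisymmetric Legendre-series Dirichlet data.

    Default boundary data v0*P1(cos theta) and radius ratio 0.8 — a thin
    outer shell, the geometry regime of a brain surface inside the skull.
    """

    r_outer: float = 1.0
    r_interface: float = 0.8
    eps_in: ComplexDielectric = field(default_factory=lambda: _diel(2.0))
    eps_out: ComplexDielectric = field(default_factory=lambda: _diel(10.0))
    v0: float = 1.0
    outer_coeffs: dict | None = None
    inner_radius: float | None = None
    inner_coeffs: dict | None = None
    order: int = 64

    def __post_init__(self):
        if not 0 < self.r_interface < self.r_outer:
            raise ValueError("need 0 < r_interface < r_outer")
        if self.inner_radius is not None and not 0 < self.inner_radius < self.r_interface:
            raise ValueError("inner electrode must lie inside the interface")
        if self.outer_coeffs is None:
            self.outer_coeffs = {1: self.v0}
        if self.inner_radius is not None and self.inner_coeffs is None:
            self.inner_coeffs = {0: 0.0}


class _SphericalRadial:
    def __init__(self, l: int):
        self.l = l

    def val(self, r):
        r = np.asarray(r, dtype=float)
        return r**self.l, r ** (-(self.l + 1))

    def der(self, r):
        r = np.asarray(r, dtype=float)
        da = self.l * r ** (self.l - 1) if self.l > 0 else np.zeros_like(r)
        return da, -(self.l + 1) * r ** (-(self.l + 2))


class ConcentricSphereSolution:
    def __init__(self, spec: ConcentricSphereSpec):
        self.spec = spec
        e1, e2 = spec.eps_in.value, spec.eps_out.value
        rm, b, a = spec.r_interface, spec.r_outer, spec.inner_radius
        ls = sorted(set(spec.outer_coeffs) | set(spec.inner_coeffs or {}) | {0})
        ls = [l for l in ls if l <= spec.order]
        self.coeffs: dict = {}
        for l in ls:
            rad = _SphericalRadial(l)
            vout = complex(spec.outer_coeffs.get(l, 0.0))
            if a is None:
                A = np.zeros((3, 3), dtype=complex)
                rhs = np.zeros(3, dtype=complex)
                r1a, _ = rad.val(rm)
                d1a, _ = rad.der(rm)
                r2a, r2b = rad.val(rm)
                d2a, d2b = rad.der(rm)
                r2ab, r2bb = rad.val(b)
                A[0] = [r1a, -r2a, -r2b]
                A[1] = [e1 * d1a, -e2 * d2a, -e2 * d2b]
                A[2] = [0.0, r2ab, r2bb]
                rhs[2] = vout
                alpha, gamma, delta = np.linalg.solve(A, rhs)
                self.coeffs[l] = (alpha, 0.0 + 0j, gamma, delta)
            else:
                vin = complex((spec.inner_coeffs or {}).get(l, 0.0))
                A = np.zeros((4, 4), dtype=complex)
                rhs = np.zeros(4, dtype=complex)
                r1aa, r1ba = rad.val(a)
                r1am, r1bm = rad.val(rm)
                d1am, d1bm = rad.der(rm)
                r2am, r2bm = rad.val(rm)
                d2am, d2bm = rad.der(rm)
                r2ab, r2bb = rad.val(b)
                A[0] = [r1aa, r1ba, 0.0, 0.0]
                A[1] = [r1am, r1bm, -r2am, -r2bm]
                A[2] = [e1 * d1am, e1 * d1bm, -e2 * d2am, -e2 * d2bm]
                A[3] = [0.0, 0.0, r2ab, r2bb]
                rhs[0] = vin
                rhs[3] = vout
                self.coeffs[l] = tuple(np.linalg.solve(A, rhs))

    def eval(self, region: int, r, theta):
        """phi, dphi/dr, dphi/dtheta for axisymmetric Legendre series."""
        r = np.asarray(r, dtype=float)
        theta = np.asarray(theta, dtype=float)
        x = np.cos(theta)
        phi = np.zeros(np.broadcast(r, theta).shape, dtype=complex)
        dr = np.zeros_like(phi)
        dth = np.zeros_like(phi)
        for l, (al, be, ga, de) in self.coeffs.items():
            rad = _SphericalRadial(l)
            va, vb = rad.val(r)
            da, db = rad.der(r)
            c1, c2 = (al, be) if region == 1 else (ga, de)
            pl = eval_legendre(l, x)
            # dP_l/dtheta = -sin(theta) P_l'(x); use P_l' = l (x P_l - P_{l-1})/(x^2-1)
            if l == 0:
                dpl_dtheta = np.zeros_like(x)
            else:
                plm1 = eval_legendre(l - 1, x)
                with np.errstate(divide="ignore", invalid="ignore"):
                    dpl_dx = l * (x * pl - plm1) / (x**2 - 1.0)
                dpl_dx = np.where(np.abs(x) >= 1.0, 0.0, dpl_dx)
                dpl_dtheta = -np.sin(theta) * dpl_dx
            phi += (c1 * va + c2 * vb) * pl
            dr += (c1 * da + c2 * db) * pl
            dth += (c1 * va + c2 * vb) * dpl_dtheta
        return phi, dr, dth

    def charge(self) -> complex:
        s = self.spec
        e2 = s.eps_out.value
        b = s.r_outer
        total = 0j
        for l, (al, be, ga, de) in self.coeffs.items():
            rad = _SphericalRadial(l)
            da, db = rad.der(b)
            dphi = ga * da + de * db
            vcoef = complex(s.outer_coeffs.get(l, 0.0))
            total += vcoef * dphi * 4 * np.pi * b**2 / (2 * l + 1)
        return complex(e2 * total / s.v0)

    def charge_result(self) -> ChargeResult:
        return ChargeResult.from_charge(self.charge(), self.spec.v0, self.spec.eps_in.omega)

    def interface_condition_residual(self, n: int = 100) -> float:
        theta = (np.arange(n) + 0.5) * np.pi / n
        rm = self.spec.r_interface
        p1, d1, _ = self.eval(1, rm, theta)
        p2, d2, _ = self.eval(2, rm, theta)
        e1, e2 = self.spec.eps_in.value, self.spec.eps_out.value
        scale_p = max(np.abs(p1).max(), np.abs(p2).max(), abs(self.spec.v0))
        scale_f = max(np.abs(e1 * d1).max(), np.abs(e2 * d2).max(), 1e-300)
        return float(
            max(np.abs(p1 - p2).max() / scale_p, np.abs(e1 * d1 - e2 * d2).max() / scale_f)
        )

    def interface_state(self, n_theta: int = 720) -> InterfaceFieldState:
        """Axisymmetric face bands at azimuth 0; band areas carry the azimuthal integral."""
        s = self.spec
        rm = s.r_interface
        theta = (np.arange(n_theta) + 0.5) * np.pi / n_theta
        dtheta = np.pi / n_theta
        normals = np.stack(
            [np.sin(theta), np.zeros_like(theta), np.cos(theta)], axis=1
        )
        surface = FaceSet(
            face_centroids=rm * normals,
            face_normals=normals,
            face_areas=2 * np.pi * rm**2 * np.sin(theta) * dtheta,
        )
        p1, d1r, d1t = self.eval(1, rm, theta)
        p2, d2r, d2t = self.eval(2, rm, theta)
        et_mag = -d2t / rm
        tang = np.stack([np.cos(theta), np.zeros_like(theta), -np.sin(theta)], axis=1)
        return InterfaceFieldState(
            surface=surface,
            en_plus=-d2r,
            et=et_mag[:, None] * tang,
            phi_r1=p1,
            dphidn_minus=d1r,
            dphidn_plus=d2r,
            eps1=s.eps_in,
            eps2=s.eps_out,
            v0=s.v0,
        )


def concentric_sphere_solution(spec: ConcentricSphereSpec) -> ConcentricSphereSolution:
    sol = ConcentricSphereSolution(spec)
    res = sol.interface_condition_residual()
    if res > 1e-8:
        raise ConvergenceError(
            f"interface conditions violated at relative level {res:.2e}"
        )
    return sol


# ---------------------------------------------------------------------------
# Direct-difference oracle and error sweeps
# ---------------------------------------------------------------------------


def dq_direct(before, after) -> complex:
    """Direct two-solve oracle: dQ = Q_perturbed - Q_base (the Eq. dY = Y* - Y sign)."""
    qb = before.q if isinstance(before, ChargeResult) else complex(before)
    qa = after.q if isinstance(after, ChargeResult) else complex(after)
    return qa - qb


@dataclass
class SweepResult:
    """Error-sweep table: amplitude, kind, dq_direct, dq_formula, rel_error."""

    family: str
    table: pd.DataFrame

    @property
    def max_rel_error(self) -> float:
        return float(self.table["rel_error"].max())

    def max_rel_error_percent(self) -> float:
        return 100.0 * self.max_rel_error


def _scale_eps(eps: ComplexDielectric, factor: float) -> ComplexDielectric:
    return ComplexDielectric(eps.eps_r * factor, eps.sigma * factor, eps.omega)


class _Family:
    """One benchmark family: base solve, formula inputs and perturbed re-solve."""

    def __init__(self, name, solver, spec, shift_builder, eps_attr="eps1"):
        self.name = name
        self.solver = solver
        self.spec = spec
        self.shift_builder = shift_builder
        self.eps_attr = eps_attr


def _slab_shift(spec: SlabSpec, state, amp):
    delta = amp * spec.p * spec.length
    disp = np.zeros((state.surface.n_faces, 3))
    disp[:, 0] = delta
    perturbed = replace(spec, p=spec.p * (1 + amp))
    return disp, perturbed


def _cyl_shift(spec: ConcentricCylinderSpec, state, amp):
    delta = amp * spec.r_interface
    disp = delta * state.surface.face_normals
    perturbed = replace(spec, r_interface=spec.r_interface * (1 + amp))
    return disp, perturbed


def _offset_shift(spec: OffsetCylinderSpec, state, amp):
    delta = amp * spec.r_cylinder
    disp = delta * state.surface.face_normals
    perturbed = replace(spec, r_cylinder=spec.r_cylinder * (1 + amp))
    return disp, perturbed


def _offset_shift_translate(spec: OffsetCylinderSpec, state, amp):
    """Radius growth plus an equal rigid drift: displacement not aligned with n."""
    delta = amp * spec.r_cylinder
    disp = delta * state.surface.face_normals
    disp[:, 0] += delta
    perturbed = replace(
        spec, r_cylinder=spec.r_cylinder * (1 + amp), offset=spec.offset + delta
    )
    return disp, perturbed


def _sphere_shift(spec: ConcentricSphereSpec, state, amp):
    delta = amp * spec.r_interface
    disp = delta * state.surface.face_normals
    perturbed = replace(spec, r_interface=spec.r_interface * (1 + amp))
    return disp, perturbed


def default_spec(family: str):
    if family == "slab":
        return SlabSpec()
    if family in ("cyl", "cylinder"):
        return ConcentricCylinderSpec()
    if family in ("cyl-offset", "offset"):
        return OffsetCylinderSpec()
    if family == "sphere":
        return ConcentricSphereSpec()
    raise ValueError(f"unknown benchmark family {family!r}")


def _family_handlers(family: str):
    if family == "slab":
        return slab_solution, _slab_shift, "eps1", ("shift", "eps", "both")
    if family in ("cyl", "cylinder"):
        return concentric_cylinder_solution, _cyl_shift, "eps_in", ("shift", "eps", "both")
    if family in ("cyl-offset", "offset"):
        return (
            offset_cylinder_solution,
            _offset_shift,
            "eps_in",
            ("shift", "eps", "both", "shift_translate"),
        )
    if family == "sphere":
        return concentric_sphere_solution, _sphere_shift, "eps_in", ("shift", "eps", "both")
    raise ValueError(f"unknown benchmark family {family!r}")


def error_sweep(
    family: str,
    spec=None,
    kinds: tuple[str, ...] | None = None,
    max_amplitude: float = 0.10,
    steps: int = 10,
    signs: tuple[int, ...] = (1, -1),
) -> SweepResult:
    """Sweep perturbation amplitudes and compare formula dQ with the oracle.

    Kinds: ``shift`` (interface displacement, fractional), ``eps`` (region-1
    permittivity scaling), ``both`` (equal fractional amplitudes applied
    simultaneously) and, for the offset cylinder, ``shift_translate`` (radius
    growth plus an equal rigid drift of the cylinder).  Relative error is
    |dq_direct - dq_formula| / |dq_direct|.
    """
    solver, shift_builder, eps_attr, default_kinds = _family_handlers(family)
    if spec is None:
        spec = default_spec(family)
    if kinds is None:
        kinds = default_kinds
    base = solver(spec)
    state = base.interface_state()
    q0 = base.charge()
    amplitudes = max_amplitude * np.arange(1, steps + 1) / steps

    rows = []
    for kind in kinds:
        for amp in amplitudes:
            for sign in signs:
                a = sign * amp
                disp = np.zeros((state.surface.n_faces, 3))
                d_eps1 = 0j
                perturbed = spec
                if kind in ("shift", "both", "shift_translate"):
                    builder = (
                        _offset_shift_translate if kind == "shift_translate" else shift_builder
                    )
                    disp, perturbed = builder(perturbed, state, a)
                if kind in ("eps", "both"):
                    eps_old = getattr(perturbed, eps_attr)
                    perturbed = replace(
                        perturbed, **{eps_attr: _scale_eps(eps_old, 1 + a)}
                    )
                    d_eps1 = getattr(spec, eps_attr).value * a
                formula = dq_combined(state, disp, d_eps1).dq
                direct = solver(perturbed).charge() - q0
                rel = abs(direct - formula) / abs(direct)
                rows.append(
                    {
                        "kind": kind,
                        "amplitude": a,
                        "dq_direct_re": direct.real,
                        "dq_direct_im": direct.imag,
                        "dq_formula_re": formula.real,
                        "dq_formula_im": formula.imag,
                        "rel_error": rel,
                    }
                )
    return SweepResult(family=family, table=pd.DataFrame(rows))


BENCHMARK_FAMILIES = ("slab", "cylinder", "cyl-offset", "sphere")
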