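"""Linear stability of the uniform equilibria on 1D rings.

For each analyzed variant the growth rate of a small perturbation of
wavenumber k depends on the lattice only through nu = cos(2*pi*k/N):

* compartment-free model (O): lambda(nu) = 4 c2 nu^2 + 2 c1 nu + c0 - 2 c2,
  a parabola in nu whose interior maximum nu* = -c1/(4 c2) selects a finite
  fastest-growing wavelength L* = 2*pi/arccos(nu*) when |nu*| < 1 and
  lambda(nu*) > 0;
* apoplast model (A): lambda(nu) = 2 c1 nu + c0 is affine in nu, so the
  fastest-growing mode sits at the endpoint nu = -1 -- wavelength 2 apoplast
  spaces -- whenever the equilibrium is unstable at all;
* mediator model (B6, with polarization by X only): the same parabolic form
  as O holds approximately, with coefficients attenuated by the X transfer
  factor kappa = Dx*Gx / ((2*Dx + Gx)(2*Dx + V*Gx)).

The analytic coefficients are cross-checked by
:func:`reduced_jacobian_spectrum`, a brute-force oracle that linearizes the
(QSS-reduced) right-hand side by complex-step differentiation and
block-diagonalizes the circulant Jacobian in the discrete Fourier basis,
and by :func:`measure_mode_growth`, which reads the growth rate of a seeded
cosine mode off a short simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import Lattice, build_ring
from .models import (ModelSpec, Params, State, auxin_equilibrium, equilibrium,
                     ModelError, rhs, x_equilibrium)
from .regulation import RegulatorySet

__all__ = [
    "DispersionResult", "PatternCondition", "SpectrumResult",
    "StabilityError", "RegimeError",
    "dispersion_coefficients", "dispersion", "pattern_condition",
    "reduced_jacobian_spectrum", "measure_mode_growth",
]

_ANALYZED = ("O", "A", "B6")


class StabilityError(ValueError):
    """Invalid stability-analysis request."""


class RegimeError(RuntimeError):
    """Mode-growth measurement left the linear regime before a slope fit."""


@dataclass(frozen=True)
class PatternCondition:
    unstable: bool
    nu_star: float | None
    lambda_star: float | None
    L_star: float | None
    units_of_L: str


@dataclass(frozen=True)
class DispersionResult:
    model: str
    coefficients: dict
    k: np.ndarray
    nu_grid: np.ndarray
    lambda_k: np.ndarray
    condition: PatternCondition

    @property
    def nu_star(self):
        return self.condition.nu_star

    @property
    def L_star(self):
        return self.condition.L_star

    @property
    def unstable(self):
        return self.condition.unstable


@dataclass(frozen=True)
class SpectrumResult:
    k: np.ndarray
    nu: np.ndarray
    leading: np.ndarray          # leading eigenvalue real part per k
    eigenvalues: np.ndarray      # (N, n_fields) complex
    residual: float


def _model_key(model) -> str:
    key = model.variant if isinstance(model, ModelSpec) else str(model)
    if key == "O_qss":
        key = "O"
    if key not in _ANALYZED:
        raise StabilityError(
            f"analytic dispersion available for {_ANALYZED}, got {key!r}")
    return key


def dispersion_coefficients(model, params: Params,
                            reg: RegulatorySet) -> dict:
    """Analytic dispersion coefficients at the 1D (K = 2) equilibrium.

    Returns c0, c1 (all models), c2 (parabolic models), plus the helper
    constants entering them (alpha/beta for the apoplast model;
    gamma/kappa and the diffusion-transport ratios Ra, Rx for the mediator
    model).
    """
    key = _model_key(model)
    P = params
    Ept = P.Ep * P.p
    if key == "O":
        a_eq = P.A
        c1 = Ept + P.Da
        c2 = -Ept * a_eq * reg.phi0.logderiv(a_eq) / 2.0
        c0 = -(P.Ga + 2.0 * c1 + 2.0 * c2)
        return {"c0": float(c0), "c1": float(c1), "c2": float(c2),
                "a_eq": float(a_eq), "Ra": P.Da / Ept if Ept else np.inf}
    if key == "A":
        a_eq, a_apo_eq = auxin_equilibrium(P, K=2)
        denom = P.V * (2.0 * Ept + 2.0 * P.Da + P.Ga)
        alpha = 2.0 * (Ept + P.Da) * (P.Eq * P.q + P.Da) / denom
        beta = (Ept * (2.0 * (P.Eq * P.q + P.Da) * a_apo_eq + P.Ga * P.A)
                * reg.phia.logderiv(a_apo_eq) / denom)
        c0 = alpha + beta - (2.0 * (P.Eq * P.q + P.Da) / P.V + P.Ga)
        c1 = (alpha - beta) / 2.0
        return {"c0": float(c0), "c1": float(c1),
                "alpha": float(alpha), "beta": float(beta),
                "a_eq": float(a_eq), "a_apo_eq": float(a_apo_eq)}
    # mediator model with polarization by apoplast X (simple X diffusion)
    if isinstance(model, ModelSpec) and model.x_mode != "simple":
        raise StabilityError(
            "the mediator dispersion relation applies to the simple "
            "cytoplasm<->apoplast X diffusion mode")
    a_eq, _ = auxin_equilibrium(P, K=2)
    theta_eq = float(reg.theta(a_eq))
    _, x_apo_eq = x_equilibrium(P, K=2, theta_eq=theta_eq, x_mode="simple")
    gamma = (P.Eq * P.q + P.Da) / (2.0 * P.Eq * P.q + 2.0 * P.Da + P.V * P.Ga)
    kappa = (P.Dx * P.Gx
             / ((2.0 * P.Dx + P.Gx) * (2.0 * P.Dx + P.V * P.Gx)))
    c1 = gamma * (Ept + P.Da)
    c2 = (-gamma * kappa * Ept * a_eq * float(reg.theta.derivative(a_eq))
          * float(reg.phix.logderiv(x_apo_eq)) / 2.0)
    c0 = 2.0 * c1 - 2.0 * c2 - (2.0 * Ept + 2.0 * P.Da + P.Ga)
    return {"c0": float(c0), "c1": float(c1), "c2": float(c2),
            "gamma": float(gamma), "kappa": float(kappa),
            "a_eq": float(a_eq), "x_apo_eq": float(x_apo_eq),
            "Ra": P.Da / Ept if Ept else np.inf,
            "Rx": P.Dx / P.Gx if P.Gx else np.inf}


def _lambda_of_nu(key: str, co: dict, nu):
    nu = np.asarray(nu, dtype=float)
    if key == "A":
        return 2.0 * co["c1"] * nu + co["c0"]
    return 4.0 * co["c2"] * nu ** 2 + 2.0 * co["c1"] * nu + co["c0"] - 2.0 * co["c2"]


def pattern_condition(model, params: Params,
                      reg: RegulatorySet) -> PatternCondition:
    """Instability of the uniform state and the fastest-growing wavelength.

    Parabolic models: unstable iff the continuous maximizer
    nu* = -c1/(4 c2) lies strictly inside (-1, 1) with lambda(nu*) > 0;
    L* = 2*pi/arccos(nu*) cells. Apoplast model: unstable iff
    lambda(-1) > 0; L* = 2 apoplast spaces regardless of parameters.
    """
    key = _model_key(model)
    co = dispersion_coefficients(model, params, reg)
    if key == "A":
        lam = float(_lambda_of_nu(key, co, -1.0))
        unstable = lam > 0
        return PatternCondition(unstable, -1.0 if unstable else None,
                                lam if unstable else None,
                                2.0 if unstable else None,
                                "apoplast spaces")
    if co["c2"] == 0.0:
        return PatternCondition(False, None, None, None, "cells")
    nu_star = -co["c1"] / (4.0 * co["c2"])
    lam_star = float(_lambda_of_nu(key, co, nu_star))
    unstable = abs(nu_star) < 1.0 and lam_star > 0.0
    L_star = 2.0 * np.pi / np.arccos(nu_star) if unstable else None
    return PatternCondition(unstable, float(nu_star), lam_star, L_star, "cells")


def dispersion(model, params: Params, reg: RegulatorySet,
               N: int) -> DispersionResult:
    """Analytic growth rate lambda_k for every lattice wavenumber k on a ring
    of N cells, plus the continuous-nu instability summary."""
    key = _model_key(model)
    co = dispersion_coefficients(model, params, reg)
    k = np.arange(N)
    nu = np.cos(2.0 * np.pi * k / N)
    lam = _lambda_of_nu(key, co, nu)
    cond = pattern_condition(model, params, reg)
    return DispersionResult(model=key, coefficients=co, k=k, nu_grid=nu,
                            lambda_k=lam, condition=cond)


# ----------------------------------------------------------------------------
# brute-force linearization oracle


def _cs_jacobian(f, x0: np.ndarray, h: float = 1e-100) -> np.ndarray:
    """Complex-step Jacobian of f at x0 (machine-precision derivatives)."""
    n = x0.size
    J = np.empty((n, n))
    for j in range(n):
        x = x0.astype(complex)
        x[j] += 1j * h
        J[:, j] = np.imag(f(x)) / h
    return J


def _symbol_spectrum(J: np.ndarray, layout: list[tuple[str, float]],
                     N: int) -> SpectrumResult:
    """Eigenvalues per wavenumber of a circulant-by-blocks Jacobian.

    ``layout`` lists (field, positional offset) pairs, each field of length
    N; a plane wave e^{i theta (n + offset)} per field spans an invariant
    subspace of J for each k, giving an F x F symbol matrix whose
    eigenvalues are the per-k growth rates. The projection residual is
    returned and must be small, otherwise J was not translation-invariant.
    """
    F = len(layout)
    M = F * N
    if J.shape != (M, M):
        raise StabilityError("Jacobian size does not match layout")
    pos = np.arange(N, dtype=float)
    leading = np.empty(N)
    eigs = np.empty((N, F), dtype=complex)
    worst = 0.0
    jnorm = np.linalg.norm(J)
    for k in range(N):
        theta = 2.0 * np.pi * k / N
        B = np.zeros((M, F), dtype=complex)
        for f_idx, (_, off) in enumerate(layout):
            B[f_idx * N:(f_idx + 1) * N, f_idx] = np.exp(1j * theta * (pos + off))
        JB = J @ B
        Mk = (B.conj().T @ JB) / N
        resid = np.linalg.norm(JB - B @ Mk) / max(jnorm, 1.0)
        worst = max(worst, resid)
        ev = np.linalg.eigvals(Mk)
        eigs[k] = ev
        leading[k] = ev.real.max()
    if worst > 1e-8:
        raise StabilityError(
            f"non-circulant residual {worst:.2e}: the linearization is not "
            "translation invariant")
    nu = np.cos(2.0 * np.pi * np.arange(N) / N)
    return SpectrumResult(k=np.arange(N), nu=nu, leading=leading,
                          eigenvalues=eigs, residual=worst)


def reduced_jacobian_spectrum(spec: ModelSpec, params: Params, N: int,
                              reduction: str = "pin") -> SpectrumResult:
    """Numerically linearize the (reduced) dynamics on a ring of N cells and
    return the spectrum per wavenumber.

    reduction = "pin"
        PIN1 is slaved to its quasi-steady allocation; remaining fields
        (cell auxin, apoplast auxin, and the mediator fields where present)
        are linearized in full.
    reduction = "adiabatic" (apoplast model only)
        Additionally slaves the fast cytosolic auxin to the surrounding
        apoplast concentrations, leaving the single apoplast-auxin field
        whose linearization the printed affine dispersion relation is exact
        for.
    """
    lat = build_ring(N)
    qss = ModelSpec(variant=spec.variant, x_mode=spec.x_mode, reg=spec.reg,
                    pin_qss=True)
    eq = equilibrium(qss, params, lat)

    if reduction == "adiabatic":
        if qss.family != "A":
            raise StabilityError("adiabatic reduction applies to the apoplast model")
        P = params
        slave_denom = P.Ga + lat.K * (P.Ep * P.p + P.Da)
        coeff = P.Eq * P.q + P.Da

        def f(vec):
            a_apo = vec
            a = (P.Ga * P.A + coeff * a_apo[lat.edge_at].sum(axis=1)) / slave_denom
            st = State(a=a, a_apo=a_apo)
            return rhs(qss, params, lat, st).a_apo

        J = _cs_jacobian(f, eq.a_apo)
        return _symbol_spectrum(J, [("a_apo", 0.5)], N)

    if reduction != "pin":
        raise StabilityError(f"unknown reduction {reduction!r}")

    layout = [("a", 0.0)]
    if qss.has_apoplast:
        layout.append(("a_apo", 0.5))
    if qss.has_x:
        layout += [("x", 0.0), ("x_apo", 0.5)]
    template = eq

    def f(vec):
        st = template.from_vector(vec)
        return rhs(qss, params, lat, st).to_vector()

    J = _cs_jacobian(f, template.to_vector())
    return _symbol_spectrum(J, layout, N)


# ----------------------------------------------------------------------------
# simulation-side validation


def measure_mode_growth(spec: ModelSpec, params: Params, lattice: Lattice,
                        k: int, amplitude: float = 1e-5, dt: float = 2e-4,
                        t_max: float = 2.0, record_every: int = 5,
                        burn_in: float = 0.2) -> float:
    """Empirical growth rate of mode k: seed a pure cosine perturbation on
    cell auxin, integrate briefly, and fit the slope of
    log |DFT amplitude of mode k| against time over the linear window.

    Raises :class:`RegimeError` if the amplitude leaves the linear regime
    (1% of equilibrium) before enough samples accumulate.
    """
    if lattice.kind != "ring":
        raise StabilityError("mode growth measurement is defined on 1D rings")
    N = lattice.n_cells
    eq = equilibrium(spec, params, lattice)
    st = eq.copy()
    st.a = eq.a * (1.0 + amplitude * np.cos(2.0 * np.pi * k * np.arange(N) / N))
    a_scale = float(np.mean(eq.a))
    limit = 0.01 * a_scale

    times, amps = [], []
    n_steps = int(round(t_max / dt))
    for step in range(1, n_steps + 1):
        st.axpy(dt, rhs(spec, params, lattice, st))
        if step % record_every:
            continue
        scale_k = 1.0 if k % N == 0 else 2.0
        amp = scale_k * np.abs(np.fft.fft(st.a - eq.a)[k % N]) / N
        if amp > limit:
            break
        times.append(step * dt)
        amps.append(amp)
    if len(times) < 5:
        raise RegimeError(
            "amplitude left the linear regime before a slope could be "
            "established; reduce the seed amplitude")
    i0 = int(len(times) * burn_in)
    t = np.asarray(times[i0:])
    y = np.log(np.asarray(amps[i0:]))
    slope = np.polyfit(t, y, 1)[0]
    return float(slope)
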