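"""Regulatory functions for carrier polarization and synthesis control.

Each regulatory step in the models (PIN1 polarization by auxin or by the
mediator X, X synthesis by auxin, carrier-amount modulation) is a scalar
function of one concentration. Four forms are supported:

``power``
    f(c) = c**e. The standard form for PIN1 polarization
    (phi0, phia, phix), with any real exponent including negative ones.
``hill_normalized``
    f(c) = 2 c**e / (c_ref**e + c**e), normalized so f(c_ref) = 1 exactly.
    Used for the X-synthesis function theta and, by default, for the
    modulation functions psi1/psi2 so that uniform equilibria of the
    feedback-free model are preserved.
``power_normalized``
    f(c) = (c / c_ref)**e; the alternative normalized form, also f(c_ref) = 1.
``constant_one``
    f(c) = 1 (used when a feedback channel is switched off, e.g. phia in the
    reduced mediator model).
``hill_ceiling``
    f(c) = c**e / (1 + (c/R)**e): the power form with an optional saturation
    ceiling R, provided for 2D runs behind an explicit flag; approaches
    c**e for c << R and saturates near R**e.

Analytic first derivatives are provided because the linear-stability module
needs f'(c_eq) at the uniform equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["RegFunc", "RegulatorySet", "DomainError", "power", "hill", "one"]

_FORMS = ("power", "hill_normalized", "power_normalized", "constant_one",
          "hill_ceiling")


class DomainError(ValueError):
    """Argument outside a regulatory function's domain (e.g. c <= 0 with e < 0)."""


@dataclass(frozen=True)
class RegFunc:
    """Specification of one regulatory function.

    Parameters
    ----------
    form : str
        One of ``power``, ``hill_normalized``, ``power_normalized``,
        ``constant_one``, ``hill_ceiling``.
    exponent : float
        Regulatory strength (Hill coefficient / power-law exponent).
    reference : float
        Reference concentration c_ref for the normalized forms; normalized
        forms evaluate to exactly 1 there.
    ceiling : float, optional
        Saturation level R for ``hill_ceiling``.
    """

    form: str = "constant_one"
    exponent: float = 1.0
    reference: float = 1.0
    ceiling: float | None = None

    def __post_init__(self):
        if self.form not in _FORMS:
            raise ValueError(f"unknown regulatory form {self.form!r}")
        if self.form in ("hill_normalized", "power_normalized") and not self.reference > 0:
            raise DomainError(
                f"{self.form} needs a positive reference level, got {self.reference}"
            )
        if self.form == "hill_ceiling" and (self.ceiling is None or self.ceiling <= 0):
            raise DomainError("hill_ceiling needs a positive ceiling R")

    def _check_domain(self, c):
        c = np.asarray(c)
        if np.iscomplexobj(c):
            # complex-step differentiation path: the domain was already
            # checked at the underlying real point
            return c
        c = c.astype(float)
        e = self.exponent
        needs_positive = (e < 0) or (e != int(e))
        if needs_positive and np.any(c <= 0):
            raise DomainError(
                f"form {self.form!r} with exponent {e} requires c > 0"
            )
        if np.any(c < 0):
            raise DomainError("concentration must be non-negative")
        return c

    def __call__(self, c):
        """Evaluate f(c); accepts scalars or arrays."""
        if self.form == "constant_one":
            return np.ones(np.shape(c))
        c = self._check_domain(c)
        e = self.exponent
        if self.form == "power":
            return c ** e
        if self.form == "power_normalized":
            return (c / self.reference) ** e
        if self.form == "hill_normalized":
            r = self.reference ** e
            ce = c ** e
            return 2.0 * ce / (r + ce)
        # hill_ceiling
        return c ** e / (1.0 + (c / self.ceiling) ** e)

    def derivative(self, c):
        """Analytic first derivative f'(c)."""
        if self.form == "constant_one":
            return np.zeros(np.shape(c))
        c = self._check_domain(c)
        e = self.exponent
        if self.form == "power":
            return e * c ** (e - 1.0)
        if self.form == "power_normalized":
            return (e / self.reference) * (c / self.reference) ** (e - 1.0)
        if self.form == "hill_normalized":
            r = self.reference ** e
            ce = c ** e
            return 2.0 * e * c ** (e - 1.0) * r / (r + ce) ** 2
        # hill_ceiling: d/dc [c^e / (1 + (c/R)^e)] = e c^(e-1) / (1 + (c/R)^e)^2
        s = 1.0 + (c / self.ceiling) ** e
        return e * c ** (e - 1.0) / s ** 2

    def logderiv(self, c):
        """f'(c)/f(c), the quantity entering dispersion coefficients."""
        return self.derivative(c) / self(c)

    def with_reference(self, reference: float) -> "RegFunc":
        return replace(self, reference=reference)


def power(exponent: float) -> RegFunc:
    return RegFunc(form="power", exponent=exponent)


def hill(exponent: float, reference: float) -> RegFunc:
    return RegFunc(form="hill_normalized", exponent=exponent, reference=reference)


def one() -> RegFunc:
    return RegFunc(form="constant_one")


@dataclass(frozen=True)
class RegulatorySet:
    """The six regulatory functions the model family draws on.

    phi0
        PIN1 polarization by neighboring-cell auxin (compartment-free model).
    phia
        PIN1 polarization by neighboring-apoplast auxin (models with apoplast).
    phix
        PIN1 polarization by the mediator X (apoplast X, or neighboring-cell X
        in the symplast-diffusion mode).
    theta
        X synthesis as a function of cytosolic auxin.
    psi1
        Modulation by cytosolic X of the influx-carrier amount, PIN1 amount,
        or auxin synthesis (feedback variants acting through the cell).
    psi2
        Modulation by apoplast X of carrier efficiencies (feedback variants
        acting at the interface).
    """

    phi0: RegFunc = power(2.0)
    phia: RegFunc = power(2.0)
    phix: RegFunc = one()
    theta: RegFunc = hill(1.0, 1.0)
    psi1: RegFunc = one()
    psi2: RegFunc = one()
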