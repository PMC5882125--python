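"""Model family for auxin-PIN1 patterning on periodic cell lattices.

Three nested families are implemented:

* **O** -- the compartment-free ("up-the-gradient") model: auxin moves
  directly between cells, carried by PIN1 against its gradient and by
  diffusion, while PIN1 is allocated to each membrane in proportion to a
  regulatory function of the *neighboring cell's* auxin.
* **A** -- the apoplast model: every cell-cell interface carries an
  extracellular compartment. Auxin is pumped cell -> apoplast by PIN1,
  apoplast -> cell by influx carriers, and diffuses between cytoplasm and
  apoplast; PIN1 polarization reads the *neighboring apoplast's* auxin.
  Optional direct symplast (cell-cell) or apoplast (interface-interface)
  auxin diffusion can be added on 1D rings.
* **B1..B6** -- the mediator models: a diffusible molecule X, synthesized
  under auxin control, feeds back on one step of the auxin-PIN1 machinery
  (influx-carrier amount, PIN1 amount, auxin synthesis, carrier
  efficiencies, or PIN1 polarization). X itself moves by simple
  cytoplasm<->apoplast exchange, by symplast diffusion, or by secretion
  plus apoplast diffusion.

The right-hand sides are exact transcriptions of the corresponding ODE
systems; uniform equilibria are available in closed form. PIN1 can be
treated dynamically (first-order relaxation toward its normalized
allocation, rate ``Gp``) or eliminated by a quasi-steady-state (QSS)
assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .lattice import Lattice, LatticeError
from .regulation import RegFunc, RegulatorySet, DomainError, hill, one, power

__all__ = [
    "ModelSpec", "Params", "State",
    "ModelError", "ShapeError", "DegenerateStateError",
    "equilibrium", "default_regulation", "make_model", "flux", "rhs",
    "pin_allocation",
]

VARIANTS = ("O", "O_qss", "A", "A_symplast", "A_apoplast",
            "B1", "B2", "B3", "B4", "B5", "B6")
X_MODES = ("simple", "symplast", "apoplast")


class ModelError(ValueError):
    """Invalid model configuration."""


class ShapeError(ModelError):
    """State dimensions inconsistent with lattice/variant."""


class DegenerateStateError(ModelError):
    """PIN1 allocation denominator vanished (all regulatory weights zero)."""


@dataclass(frozen=True)
class ModelSpec:
    """Which model variant to run, and with which regulatory functions.

    ``variant`` is one of ``O``, ``O_qss``, ``A``, ``A_symplast``,
    ``A_apoplast``, ``B1``..``B6``. ``x_mode`` selects how the mediator X
    moves (B variants only). ``pin_qss`` replaces the PIN1 ODE by its
    quasi-steady allocation (implied by variant ``O_qss``).
    """

    variant: str = "O"
    x_mode: str = "simple"
    reg: RegulatorySet = field(default_factory=RegulatorySet)
    pin_qss: bool = False

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ModelError(f"unknown variant {self.variant!r}")
        if self.x_mode not in X_MODES:
            raise ModelError(f"unknown x_mode {self.x_mode!r}")
        if self.variant == "O_qss":
            object.__setattr__(self, "pin_qss", True)

    @property
    def family(self) -> str:
        return self.variant[0]  # "O", "A" or "B"

    @property
    def a_mode(self) -> str:
        if self.variant == "A_symplast":
            return "symplast"
        if self.variant == "A_apoplast":
            return "apoplast"
        return "simple"

    @property
    def has_apoplast(self) -> bool:
        return self.family in ("A", "B")

    @property
    def has_x(self) -> bool:
        return self.family == "B"


@dataclass(frozen=True)
class Params:
    """Rate constants and geometric factors (units: concentration and 1/time
    in the model's nondimensional scales).

    A     auxin synthesis level (equilibrium auxin of the O model)
    Ga    auxin turnover rate
    Da    auxin diffusion coefficient (cell<->cell in O; cytoplasm<->apoplast
          in A/B)
    Ep    PIN1 efflux efficiency
    p     PIN1 density scale (Kp is the per-cell PIN1 pool)
    Gp    PIN1 turnover rate
    Eq    influx-carrier efficiency
    q     influx-carrier density per cell side
    V     apoplast/cytoplasm volume ratio
    Gx    mediator X turnover rate
    Dx    X diffusion coefficient (cytoplasm<->apoplast)
    S     X secretion coefficient (apoplast-diffusion X mode)
    Da1   symplast (cell-cell) auxin diffusion coefficient
    Da2   apoplast (interface-interface) auxin diffusion coefficient
    Dx1   symplast X diffusion coefficient
    Dx2   apoplast X diffusion coefficient
    kappa_T  optional flux-saturation constant of the O-model flux, default 0
    """

    A: float = 1.0
    Ga: float = 0.2
    Da: float = 1.0
    Ep: float = 1.0
    p: float = 1.0
    Gp: float = 1.0
    Eq: float = 1.0
    q: float = 1.0
    V: float = 1.0
    Gx: float = 1.0
    Dx: float = 1.0
    S: float = 1.0
    Da1: float = 0.0
    Da2: float = 0.0
    Dx1: float = 0.0
    Dx2: float = 0.0
    kappa_T: float = 0.0

    def validate(self, spec: ModelSpec) -> None:
        for name in ("A", "Ga", "Da", "Ep", "p", "Gp", "Eq", "q", "Gx", "Dx",
                     "S", "Da1", "Da2", "Dx1", "Dx2", "kappa_T"):
            if getattr(self, name) < 0:
                raise ModelError(f"parameter {name} must be >= 0")
        if spec.has_apoplast and not self.V > 0:
            raise ModelError("V must be > 0 where apoplast compartments exist")
        if not spec.pin_qss and not self.Gp > 0:
            raise ModelError("Gp must be > 0 for dynamic PIN1")

    def replace(self, **kw) -> "Params":
        return replace(self, **kw)


@dataclass
class State:
    """Per-cell, per-edge and per-directed-edge fields of one model variant.

    a      (n_cells,) cytosolic auxin
    p      (n_cells, K) directed PIN1 density, or None under QSS
    a_apo  (n_edges,) apoplast auxin (A/B families)
    x      (n_cells,) cytosolic X (B family)
    x_apo  (n_edges,) apoplast X (B family)
    """

    a: np.ndarray
    p: np.ndarray | None = None
    a_apo: np.ndarray | None = None
    x: np.ndarray | None = None
    x_apo: np.ndarray | None = None

    FIELDS = ("a", "p", "a_apo", "x", "x_apo")

    def copy(self) -> "State":
        return State(*(None if v is None else v.copy() for v in
                       (self.a, self.p, self.a_apo, self.x, self.x_apo)))

    def fields(self):
        for name in self.FIELDS:
            v = getattr(self, name)
            if v is not None:
                yield name, v

    def to_vector(self) -> np.ndarray:
        return np.concatenate([v.ravel() for _, v in self.fields()])

    def from_vector(self, vec: np.ndarray) -> "State":
        out = self.copy()
        i = 0
        for name, v in out.fields():
            setattr(out, name, vec[i:i + v.size].reshape(v.shape))
            i += v.size
        if i != vec.size:
            raise ShapeError("vector length does not match state layout")
        return out

    def axpy(self, dt: float, deriv: "State") -> None:
        """In-place Euler update: self += dt * deriv."""
        for name, v in self.fields():
            dv = getattr(deriv, name)
            if dv is not None:
                v += dt * dv


# ----------------------------------------------------------------------------
# equilibria


def auxin_equilibrium(params: Params, K: int) -> tuple[float, float]:
    """Uniform (cytosol, apoplast) auxin equilibrium of the apoplast models."""
    P = params
    a0 = P.A / (K * P.V * (P.Ep * P.p + P.Da)
                + 2.0 * (P.Eq * P.q + P.Da) + P.V * P.Ga)
    a_eq = (2.0 * (P.Eq * P.q + P.Da) + P.V * P.Ga) * a0
    a_apo_eq = 2.0 * (P.Ep * P.p + P.Da) * a0
    return a_eq, a_apo_eq


def x_equilibrium(params: Params, K: int, theta_eq: float,
                  x_mode: str) -> tuple[float, float]:
    """Uniform (cytosol, apoplast) X equilibrium for the given diffusion mode.

    ``theta_eq`` is the X-synthesis function evaluated at the auxin
    equilibrium (exactly 1 for the normalized default).
    """
    P = params
    if x_mode == "simple":
        x0 = theta_eq / ((K * P.V + 2.0) * P.Dx + P.V * P.Gx)
        return (2.0 * P.Dx + P.V * P.Gx) * x0, 2.0 * P.Dx * x0
    if x_mode == "symplast":
        return theta_eq, 0.0
    # apoplast: secretion at rate S per side, degradation everywhere
    x_eq = P.Gx * theta_eq / (P.Gx + K * P.S)
    x_apo_eq = 2.0 * P.S * theta_eq / (P.V * (P.Gx + K * P.S))
    return x_eq, x_apo_eq


def equilibrium(spec: ModelSpec, params: Params, lattice: Lattice) -> State:
    """Spatially uniform equilibrium state (closed form) of any variant."""
    params.validate(spec)
    _validate_topology(spec, lattice)
    n, K, ne = lattice.n_cells, lattice.K, lattice.n_edges
    p_dir = None if spec.pin_qss else np.full((n, K), params.p)
    if spec.family == "O":
        return State(a=np.full(n, params.A), p=p_dir)
    a_eq, a_apo_eq = auxin_equilibrium(params, K)
    st = State(a=np.full(n, a_eq), p=p_dir, a_apo=np.full(ne, a_apo_eq))
    if spec.has_x:
        theta_eq = float(spec.reg.theta(a_eq))
        x_eq, x_apo_eq = x_equilibrium(params, K, theta_eq, spec.x_mode)
        st.x = np.full(n, x_eq)
        st.x_apo = np.full(ne, x_apo_eq)
    return st


def default_regulation(variant: str, params: Params, K: int, *,
                       n: float = 2.0, m: float = 1.0, r: float = 1.0,
                       x_mode: str = "simple",
                       psi_form: str = "hill_normalized",
                       phia_constant: bool = False,
                       ceiling: float | None = None) -> RegulatorySet:
    """Regulatory set matching the printed conventions of each variant.

    Polarization functions are power laws (exponent ``n`` for auxin, ``m``
    for X); X synthesis is the normalized Hill function of exponent ``r``
    referenced at the auxin equilibrium; the modulation functions psi1/psi2
    default to normalized Hill forms referenced at the corresponding X
    equilibrium so that the feedback-free equilibria are preserved
    (``psi_form="power_normalized"`` selects the alternative form).
    ``ceiling`` switches the polarization functions to the saturating form
    used for 2D runs.
    """
    if psi_form not in ("hill_normalized", "power_normalized"):
        raise ModelError(f"psi_form must be a normalized form, got {psi_form!r}")

    def polar(e):
        if ceiling is not None:
            return RegFunc(form="hill_ceiling", exponent=e, ceiling=ceiling)
        return power(e)

    phi0 = polar(n)
    phia = one() if phia_constant else polar(n)
    phix = polar(m) if variant == "B6" else one()
    theta = hill(1.0, 1.0)
    psi1 = one()
    psi2 = one()
    if variant.startswith("B"):
        a_eq, a_apo_eq = auxin_equilibrium(params, K)
        theta = hill(r, a_eq)
        x_eq, x_apo_eq = x_equilibrium(params, K, 1.0, x_mode)
        if variant in ("B1", "B2", "B3"):
            psi1 = RegFunc(form=psi_form, exponent=m, reference=x_eq)
        elif variant in ("B4", "B5"):
            if x_apo_eq <= 0:
                raise ModelError(
                    f"{variant} with x_mode={x_mode!r}: apoplast X equilibrium "
                    "is 0, so a normalized apoplast-X modulation is undefined"
                )
            psi2 = RegFunc(form=psi_form, exponent=m, reference=x_apo_eq)
    return RegulatorySet(phi0=phi0, phia=phia, phix=phix, theta=theta,
                         psi1=psi1, psi2=psi2)


def make_model(variant: str, params: Params, K: int, **reg_kw) -> ModelSpec:
    """Convenience constructor: variant + default regulatory set."""
    x_mode = reg_kw.pop("x_mode", "simple")
    pin_qss = reg_kw.pop("pin_qss", False)
    reg = default_regulation(variant, params, K, x_mode=x_mode, **reg_kw)
    return ModelSpec(variant=variant, x_mode=x_mode, reg=reg, pin_qss=pin_qss)


# ----------------------------------------------------------------------------
# right-hand sides


def _validate_topology(spec: ModelSpec, lattice: Lattice) -> None:
    needs_ring = (spec.a_mode in ("symplast", "apoplast")
                  or (spec.has_x and spec.x_mode == "apoplast"))
    if needs_ring and lattice.kind != "ring":
        raise ModelError(
            f"variant {spec.variant}/{spec.x_mode} requires a 1D ring lattice"
        )


def _check_shapes(spec: ModelSpec, lattice: Lattice, state: State) -> None:
    n, K, ne = lattice.n_cells, lattice.K, lattice.n_edges
    if state.a.shape != (n,):
        raise ShapeError(f"a has shape {state.a.shape}, expected ({n},)")
    if spec.pin_qss:
        if state.p is not None:
            raise ShapeError("QSS PIN1 state must not carry a p field")
    elif state.p is None or state.p.shape != (n, K):
        raise ShapeError(f"p must have shape ({n}, {K})")
    if spec.has_apoplast:
        if state.a_apo is None or state.a_apo.shape != (ne,):
            raise ShapeError(f"a_apo must have shape ({ne},)")
    if spec.has_x:
        if state.x is None or state.x.shape != (n,):
            raise ShapeError(f"x must have shape ({n},)")
        if state.x_apo is None or state.x_apo.shape != (ne,):
            raise ShapeError(f"x_apo must have shape ({ne},)")


def _polarization_weights(spec: ModelSpec, params: Params, lattice: Lattice,
                          state: State) -> np.ndarray:
    """Unnormalized PIN1 allocation weights per (cell, slot)."""
    reg = spec.reg
    if spec.family == "O":
        return reg.phi0(state.a[lattice.neighbors])
    w = reg.phia(state.a_apo[lattice.edge_at])
    if spec.variant == "B6":
        if spec.x_mode == "symplast":
            # apoplast X is vestigial here; polarization reads the
            # neighboring cell's X, the route the mediator actually travels
            w = w * reg.phix(state.x[lattice.neighbors])
        else:
            w = w * reg.phix(state.x_apo[lattice.edge_at])
    return w


def pin_allocation(spec: ModelSpec, params: Params, lattice: Lattice,
                   state: State) -> np.ndarray:
    """Normalized PIN1 target allocation K*p*w_ij / sum_j w_ij per (cell, slot).

    This is both the QSS PIN1 density and the relaxation target of the
    dynamic PIN1 equation. Rows sum to K*p (times psi1(x_i) in the
    PIN1-amount feedback variant) exactly.
    """
    w = _polarization_weights(spec, params, lattice, state)
    denom = w.sum(axis=1, keepdims=True)
    if np.any(denom == 0.0):
        raise DegenerateStateError(
            "PIN1 allocation denominator vanished (all weights zero)"
        )
    scale = lattice.K * params.p
    alloc = scale * w / denom
    if spec.variant == "B2":
        alloc = spec.reg.psi1(state.x)[:, None] * alloc
    return alloc


def _directed_flux(spec: ModelSpec, params: Params, lattice: Lattice,
                   state: State, p_dir: np.ndarray) -> np.ndarray:
    """Directed auxin flux per (cell, slot).

    O family: net PIN1-carried flow cell i -> neighbor j (antisymmetric).
    A/B families: flow cell i -> apoplast (i,j) (efflux minus influx).
    """
    P, reg = params, spec.reg
    a = state.a
    if spec.family == "O":
        nbr, rev = lattice.neighbors, lattice.reverse_slot
        a_nbr = a[nbr]
        p_rev = p_dir[nbr, rev]
        if P.kappa_T:
            return P.Ep * (p_dir * a[:, None] / (1.0 + P.kappa_T * a_nbr)
                           - p_rev * a_nbr / (1.0 + P.kappa_T * a[:, None]))
        return P.Ep * (p_dir * a[:, None] - p_rev * a_nbr)
    apo = state.a_apo[lattice.edge_at]
    efflux = P.Ep * p_dir * a[:, None]
    influx = P.Eq * P.q * apo
    if spec.variant == "B1":
        influx = reg.psi1(state.x)[:, None] * influx
    elif spec.variant == "B4":
        influx = reg.psi2(state.x_apo[lattice.edge_at]) * influx
    elif spec.variant == "B5":
        efflux = reg.psi2(state.x_apo[lattice.edge_at]) * efflux
    return efflux - influx


def flux(spec: ModelSpec, params: Params, lattice: Lattice, state: State,
         cell: int, neighbor: int) -> float:
    """Auxin flow rate from ``cell`` toward ``neighbor`` (O family) or into
    the apoplast between them (A/B families)."""
    slots = np.nonzero(lattice.neighbors[cell] == neighbor)[0]
    if slots.size == 0:
        raise LatticeError(f"cells {cell} and {neighbor} are not adjacent")
    p_dir = (pin_allocation(spec, params, lattice, state)
             if spec.pin_qss else state.p)
    f = _directed_flux(spec, params, lattice, state, p_dir)
    return float(f[cell, slots[0]])


def rhs(spec: ModelSpec, params: Params, lattice: Lattice,
        state: State) -> State:
    """Time derivatives of every dynamic field of the given variant."""
    _validate_topology(spec, lattice)
    _check_shapes(spec, lattice, state)
    P, reg = params, spec.reg
    n, K = lattice.n_cells, lattice.K
    a = state.a

    alloc = pin_allocation(spec, params, lattice, state)
    p_dir = alloc if spec.pin_qss else state.p
    f = _directed_flux(spec, params, lattice, state, p_dir)

    if spec.family == "O":
        a_nbr = a[lattice.neighbors]
        da = (P.Ga * (P.A - a) - f.sum(axis=1)
              + P.Da * (a_nbr - a[:, None]).sum(axis=1))
        dp = None if spec.pin_qss else P.Gp * (alloc - state.p)
        return State(a=da, p=dp)

    # apoplast families
    ec0, ec1 = lattice.edge_cells[:, 0], lattice.edge_cells[:, 1]
    es0, es1 = lattice.edge_slots[:, 0], lattice.edge_slots[:, 1]
    apo = state.a_apo
    apo_at = apo[lattice.edge_at]

    A_eff = reg.psi1(state.x) * P.A if spec.variant == "B3" else P.A
    da = (P.Ga * (A_eff - a) - f.sum(axis=1)
          + P.Da * (apo_at - a[:, None]).sum(axis=1))
    if spec.a_mode == "symplast":
        da = da + P.Da1 * (a[lattice.neighbors] - a[:, None]).sum(axis=1)

    f_edge = f[ec0, es0] + f[ec1, es1]
    da_apo = (-P.Ga * apo + f_edge / P.V
              + (P.Da / P.V) * (a[ec0] + a[ec1] - 2.0 * apo))
    if spec.a_mode == "apoplast":
        en = lattice.edge_neighbors
        da_apo = da_apo + (P.Da2 / P.V) * (apo[en] - apo[:, None]).sum(axis=1)

    dp = None if spec.pin_qss else P.Gp * (alloc - state.p)

    dx = dx_apo = None
    if spec.has_x:
        x, x_apo = state.x, state.x_apo
        synth = P.Gx * (reg.theta(a) - x)
        if spec.x_mode == "simple":
            x_apo_at = x_apo[lattice.edge_at]
            dx = synth + P.Dx * (x_apo_at - x[:, None]).sum(axis=1)
            dx_apo = -P.Gx * x_apo + (P.Dx / P.V) * (x[ec0] + x[ec1]
                                                     - 2.0 * x_apo)
        elif spec.x_mode == "symplast":
            dx = synth + P.Dx1 * (x[lattice.neighbors] - x[:, None]).sum(axis=1)
            dx_apo = -P.Gx * x_apo
        else:  # apoplast secretion + interface diffusion
            dx = synth - K * P.S * x
            en = lattice.edge_neighbors
            dx_apo = (-P.Gx * x_apo + (P.S / P.V) * (x[ec0] + x[ec1])
                      + (P.Dx2 / P.V) * (x_apo[en] - x_apo[:, None]).sum(axis=1))

    return State(a=da, p=dp, a_apo=da_apo, x=dx, x_apo=dx_apo)
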