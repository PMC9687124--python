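"""Constitutive models for the abdomen phantom.

Three tissue models are provided, matching the material cards used in the
palpation simulations:

* liver — visco-hyperelastic: an Ogden strain-energy function in principal
  stretches for the long-term (equilibrium) response, plus a Prony-series
  shear-relaxation overstress integrated with the standard per-term
  exponential recurrence (internal-variable form);
* lumped abdominal tissue ("flesh") — nearly incompressible neo-Hookean
  deviatoric response with a quadratic volumetric penalty and a linear
  viscous stress scaled by the card's damping coefficient;
* ribs — small-strain von Mises plasticity with linear isotropic hardening
  (piecewise-linear elastic/plastic response).

Unit system: mm–kg–ms.  Stress and moduli are in GPa (= kN/mm^2), density
in kg/mm^3, time in ms, force in kN.  All tensor-valued functions accept
arrays of shape (..., 3, 3) and broadcast over leading axes, so the same
code serves a single material point and a whole element block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "OgdenParams",
    "PronySeries",
    "FleshCard",
    "RibCard",
    "MaterialCards",
    "ViscoState",
    "RibState",
    "PrincipalStresses",
    "InversionError",
    "default_cards",
    "ogden_energy",
    "ogden_cauchy_stress",
    "prony_modulus",
    "visco_overstress_update",
    "flesh_stress",
    "rib_plastic_update",
    "principal_stresses",
    "elastic_moduli",
]

_I3 = np.eye(3)


class InversionError(ValueError):
    """Raised when a deformation gradient has non-positive determinant."""


# ---------------------------------------------------------------------------
# Material cards
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OgdenParams:
    """Ogden hyperelastic constants for the liver parenchyma.

    ``terms`` holds (mu_p [GPa], alpha_p [-]) pairs of the strain-energy
    function  Psi = sum_p (mu_p/alpha_p) (l1^a_p + l2^a_p + l3^a_p - 3)
    evaluated on isochoric principal stretches.  The ground-state shear
    modulus is mu0 = sum_p mu_p * alpha_p / 2 and must be positive even
    when individual pairs are negative (the fitted liver card has one
    negative pair).

    ``bulk_modulus`` may be given explicitly; when omitted it is derived
    from the Poisson ratio and the *instantaneous* shear modulus
    (mu0 + extra_shear), where ``extra_shear`` is typically the t=0 Prony
    overstress modulus.  Using the instantaneous stiffness keeps the
    volumetric response on the same scale as the short-time shear response.
    """

    terms: tuple[tuple[float, float], ...]
    poisson_ratio: float
    density: float
    bulk_modulus: float | None = None
    extra_shear: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple((float(m), float(a)) for m, a in self.terms))
        if self.poisson_ratio >= 0.5:
            raise ValueError("Poisson ratio must be < 0.5")
        if self.ground_shear_modulus <= 0:
            raise ValueError("sum(mu_p * alpha_p) must be positive (ground-state stiffness)")
        if self.bulk_modulus is None:
            mu = self.ground_shear_modulus + self.extra_shear
            nu = self.poisson_ratio
            object.__setattr__(self, "bulk_modulus", 2.0 * mu * (1.0 + nu) / (3.0 * (1.0 - 2.0 * nu)))

    @property
    def ground_shear_modulus(self) -> float:
        return 0.5 * sum(m * a for m, a in self.terms)

    @property
    def mus(self) -> np.ndarray:
        return np.array([m for m, _ in self.terms])

    @property
    def alphas(self) -> np.ndarray:
        return np.array([a for _, a in self.terms])


@dataclass(frozen=True)
class PronySeries:
    """Shear relaxation modulus G(t) = sum_i G_i exp(-t / tau_i).

    ``terms`` holds (G_i [GPa], tau_i [ms]) pairs.  The decay constants of
    the liver card are interpreted in the solver time unit (ms).
    """

    terms: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple((float(g), float(t)) for g, t in self.terms))
        if any(t <= 0 for _, t in self.terms):
            raise ValueError("all Prony decay constants tau_i must be positive")
        if not all(np.isfinite(g) for g, _ in self.terms):
            raise ValueError("all Prony moduli G_i must be finite")

    @property
    def g0(self) -> float:
        """Instantaneous overstress modulus G(0) = sum_i G_i."""
        return sum(g for g, _ in self.terms)

    @property
    def gis(self) -> np.ndarray:
        return np.array([g for g, _ in self.terms])

    @property
    def taus(self) -> np.ndarray:
        return np.array([t for _, t in self.terms])


@dataclass(frozen=True)
class FleshCard:
    """Lumped abdominal tissue: density, bulk modulus, damping, shear modulus."""

    density: float
    bulk_modulus: float
    damping_coefficient: float
    shear_modulus: float

    def __post_init__(self) -> None:
        if min(self.density, self.bulk_modulus, self.damping_coefficient, self.shear_modulus) <= 0:
            raise ValueError("all flesh card entries must be positive")


@dataclass(frozen=True)
class RibCard:
    """Rib cortical bone: linear elasticity with linear isotropic hardening."""

    density: float
    young_modulus: float
    poisson_ratio: float
    yield_stress: float
    tangent_modulus: float

    def __post_init__(self) -> None:
        if not (0.0 < self.tangent_modulus < self.young_modulus):
            raise ValueError("tangent modulus must satisfy 0 < Et < E")
        if self.yield_stress <= 0:
            raise ValueError("yield stress must be positive")

    @property
    def shear_modulus(self) -> float:
        return self.young_modulus / (2.0 * (1.0 + self.poisson_ratio))

    @property
    def bulk_modulus(self) -> float:
        return self.young_modulus / (3.0 * (1.0 - 2.0 * self.poisson_ratio))

    @property
    def hardening_modulus(self) -> float:
        """Plastic hardening modulus H = E Et / (E - Et)."""
        e, et = self.young_modulus, self.tangent_modulus
        return e * et / (e - et)


@dataclass(frozen=True)
class MaterialCards:
    """Bundle of the three tissue cards used by the solver."""

    flesh: FleshCard
    rib: RibCard
    liver_ogden: OgdenParams
    liver_prony: PronySeries

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MaterialCards":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            flesh=FleshCard(**d["flesh"]),
            rib=RibCard(**d["rib"]),
            liver_ogden=OgdenParams(
                terms=tuple(tuple(t) for t in d["liver_ogden"]["terms"]),
                poisson_ratio=d["liver_ogden"]["poisson_ratio"],
                density=d["liver_ogden"]["density"],
                bulk_modulus=d["liver_ogden"]["bulk_modulus"],
                extra_shear=d["liver_ogden"].get("extra_shear", 0.0),
            ),
            liver_prony=PronySeries(terms=tuple(tuple(t) for t in d["liver_prony"]["terms"])),
        )


def default_cards() -> MaterialCards:
    """The validated tissue cards (GPa, kg/mm^3, ms).

    Flesh: rho 1.06e-6, K 2, damping 0.4, G 4e-3.
    Ribs:  rho 1.00e-6, E 0.04, nu 0.45, sigma_y 1.8e-3, Et 1e-3.
    Liver: rho 1.05e-6, nu 0.49, three Ogden pairs and three Prony pairs.
    """
    prony = PronySeries(terms=((6.9701e-6, 10.0), (5.8327e-5, 1.0e2), (3.5291e-5, 1.0e3)))
    return MaterialCards(
        flesh=FleshCard(
            density=1.06e-6, bulk_modulus=2.0, damping_coefficient=0.4, shear_modulus=400e-5
        ),
        rib=RibCard(
            density=1.00e-6,
            young_modulus=0.04,
            poisson_ratio=0.45,
            yield_stress=0.0018,
            tangent_modulus=0.001,
        ),
        liver_ogden=OgdenParams(
            terms=((8.914e-8, 1.0000), (9.965e-9, 19.0656), (-9.275e-8, -10.9604)),
            poisson_ratio=0.49,
            density=1.05e-6,
            extra_shear=prony.g0,
        ),
        liver_prony=prony,
    )


# ---------------------------------------------------------------------------
# Small tensor helpers (broadcast over leading axes)
# ---------------------------------------------------------------------------


def _dev(t: np.ndarray) -> np.ndarray:
    tr = np.trace(t, axis1=-2, axis2=-1)[..., None, None]
    return t - tr * _I3 / 3.0


def _sym(t: np.ndarray) -> np.ndarray:
    return 0.5 * (t + np.swapaxes(t, -1, -2))


# ---------------------------------------------------------------------------
# Ogden hyperelasticity
# ---------------------------------------------------------------------------


def ogden_energy(stretches: Sequence[float] | np.ndarray, params: OgdenParams) -> np.ndarray:
    """Ogden strain-energy density at the given principal stretches.

    The energy sum is evaluated on the isochoric stretches
    lbar_i = J^(-1/3) lambda_i, so a pure dilation carries no Ogden energy
    (the volumetric response is a separate quadratic penalty).
    Broadcasts over leading axes of ``stretches`` (shape (..., 3)).
    """
    lam = np.asarray(stretches, dtype=float)
    if lam.shape[-1] != 3:
        raise ValueError("stretches must have shape (..., 3)")
    if np.any(lam <= 0):
        raise ValueError("principal stretches must be positive")
    j = np.prod(lam, axis=-1)
    lbar = lam * j[..., None] ** (-1.0 / 3.0)
    psi = np.zeros(lam.shape[:-1])
    for mu, alpha in params.terms:
        psi = psi + (mu / alpha) * (np.sum(lbar**alpha, axis=-1) - 3.0)
    return psi if psi.ndim else float(psi)


def _ogden_principal_dev_stress(lbar: np.ndarray, params: OgdenParams) -> np.ndarray:
    """Deviatoric principal Kirchhoff stresses beta_i from isochoric stretches.

    beta_i = sum_p mu_p (lbar_i^a_p - (1/3) sum_j lbar_j^a_p); sum_i beta_i = 0.
    """
    beta = np.zeros_like(lbar)
    for mu, alpha in params.terms:
        la = lbar**alpha
        beta = beta + mu * (la - np.mean(la, axis=-1, keepdims=True))
    return beta


def ogden_cauchy_stress(defgrad: np.ndarray, params: OgdenParams) -> np.ndarray:
    """Cauchy stress of the Ogden model with quadratic volumetric penalty.

    sigma = (1/J) sum_i beta_i n_i (x) n_i + K (J - 1) I, where n_i are the
    principal directions of the isochoric left Cauchy–Green tensor and
    beta_i the deviatoric principal Kirchhoff stresses.
    """
    f = np.asarray(defgrad, dtype=float)
    j = np.linalg.det(f)
    if np.any(j <= 0):
        raise InversionError("deformation gradient with det F <= 0")
    b = f @ np.swapaxes(f, -1, -2)
    bbar = b * j[..., None, None] ** (-2.0 / 3.0)
    w, v = np.linalg.eigh(bbar)
    lbar = np.sqrt(np.clip(w, 1e-30, None))
    beta = _ogden_principal_dev_stress(lbar, params)
    # rebuild sum_i beta_i n_i n_i^T
    dev = np.einsum("...i,...ai,...bi->...ab", beta, v, v)
    sig = dev / j[..., None, None] + (params.bulk_modulus * (j - 1.0))[..., None, None] * _I3
    return _sym(sig)


# ---------------------------------------------------------------------------
# Prony-series viscoelasticity
# ---------------------------------------------------------------------------


def prony_modulus(t: float | np.ndarray, series: PronySeries) -> float | np.ndarray:
    """Relaxation modulus G(t) = sum_i G_i exp(-t/tau_i), t in ms."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    g = sum(gi * np.exp(-t / ti) for gi, ti in series.terms)
    return float(g) if np.ndim(g) == 0 else g


@dataclass
class ViscoState:
    """Internal variables of the Prony overstress recurrence.

    ``h`` holds one deviatoric overstress tensor per Prony term
    (shape (n_terms, ..., 3, 3)); ``strain`` is the last Green–Lagrange
    strain seen, kept for bookkeeping.  Both start at zero.
    """

    h: np.ndarray
    strain: np.ndarray

    @classmethod
    def zero(cls, series: PronySeries, shape: tuple[int, ...] = ()) -> "ViscoState":
        n = len(series.terms)
        return cls(h=np.zeros((n, *shape, 3, 3)), strain=np.zeros((*shape, 3, 3)))


def visco_overstress_update(
    state: ViscoState, strain_increment: np.ndarray, dt: float, series: PronySeries
) -> tuple[ViscoState, np.ndarray]:
    """Advance the Prony overstress by one step of size ``dt``.

    Per term:  h_i <- exp(-dt/tau_i) h_i
                      + G_i tau_i / dt * (1 - exp(-dt/tau_i)) * dev(dE),
    which is the exact update of the relaxation convolution for a strain
    rate held constant over the step.  Returns the new state and the total
    overstress sum_i h_i (a second Piola–Kirchhoff–type deviatoric tensor;
    the caller adds it to the long-term stress).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    de = _dev(np.asarray(strain_increment, dtype=float))
    gis, taus = series.gis, series.taus
    decay = np.exp(-dt / taus)
    gain = gis * taus / dt * (1.0 - decay)
    shape_pad = (slice(None),) + (None,) * de.ndim
    h_new = decay[shape_pad] * state.h + gain[shape_pad] * de[None, ...]
    new_state = ViscoState(h=h_new, strain=state.strain + np.asarray(strain_increment, dtype=float))
    return new_state, np.sum(h_new, axis=0)


# ---------------------------------------------------------------------------
# Flesh (lumped abdominal tissue)
# ---------------------------------------------------------------------------


def flesh_stress(defgrad: np.ndarray, rate_of_deformation: np.ndarray, card: FleshCard) -> np.ndarray:
    """Nearly incompressible neo-Hookean + linear viscosity.

    sigma = (G/J) dev(bbar) + K (J - 1) I + c G dev(D), with c the card's
    damping coefficient interpreted as a viscous time scale in ms (so the
    product c*G*D is a stress in GPa for D in 1/ms).
    """
    f = np.asarray(defgrad, dtype=float)
    d = np.asarray(rate_of_deformation, dtype=float)
    j = np.linalg.det(f)
    if np.any(j <= 0):
        raise InversionError("deformation gradient with det F <= 0")
    b = f @ np.swapaxes(f, -1, -2)
    bbar = b * j[..., None, None] ** (-2.0 / 3.0)
    sig = (
        card.shear_modulus / j[..., None, None] * _dev(bbar)
        + (card.bulk_modulus * (j - 1.0))[..., None, None] * _I3
        + card.damping_coefficient * card.shear_modulus * _dev(_sym(d))
    )
    return _sym(sig)


# ---------------------------------------------------------------------------
# Ribs (von Mises plasticity, radial return)
# ---------------------------------------------------------------------------


@dataclass
class RibState:
    """Small-strain plasticity state: current stress and equivalent plastic strain."""

    sigma: np.ndarray
    eq_plastic_strain: np.ndarray

    @classmethod
    def zero(cls, shape: tuple[int, ...] = ()) -> "RibState":
        return cls(sigma=np.zeros((*shape, 3, 3)), eq_plastic_strain=np.zeros(shape))


def rib_plastic_update(
    strain_increment: np.ndarray, state: RibState, card: RibCard
) -> tuple[np.ndarray, RibState]:
    """Radial-return update with linear isotropic hardening.

    Elastic trial stress, von Mises check against the hardened yield
    surface sigma_y + H * ep, plastic multiplier
    dgamma = (seq_trial - sy) / (3G + H), deviator scaled back radially.
    """
    deps = _sym(np.asarray(strain_increment, dtype=float))
    g, k, h = card.shear_modulus, card.bulk_modulus, card.hardening_modulus
    tr = np.trace(deps, axis1=-2, axis2=-1)[..., None, None]
    sig_tr = state.sigma + 2.0 * g * (deps - tr * _I3 / 3.0) + k * tr * _I3
    s = _dev(sig_tr)
    seq = np.sqrt(np.maximum(1.5 * np.sum(s * s, axis=(-2, -1)), 0.0))
    sy = card.yield_stress + h * state.eq_plastic_strain
    yielding = seq > sy
    dgamma = np.where(yielding, (seq - sy) / (3.0 * g + h), 0.0)
    scale = np.where(seq > 0, 1.0 - 3.0 * g * dgamma / np.where(seq > 0, seq, 1.0), 1.0)
    sig_new = sig_tr - (1.0 - scale)[..., None, None] * s
    new_state = RibState(sigma=sig_new, eq_plastic_strain=state.eq_plastic_strain + dgamma)
    return sig_new, new_state


# ---------------------------------------------------------------------------
# Principal stresses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrincipalStresses:
    """Ordered eigenvalues sigma1 <= sigma2 <= sigma3 of a symmetric stress."""

    sigma1: float
    sigma2: float
    sigma3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma1, self.sigma2, self.sigma3])


def principal_stresses(sigma: np.ndarray, sym_tol: float = 1e-8) -> PrincipalStresses:
    """Eigenvalues of a symmetric 3x3 stress tensor, ascending.

    sigma3 (the maximum principal stress) is the quantity visualised on
    the liver edge downstream.  Inputs that are asymmetric beyond
    ``sym_tol`` (relative to the tensor norm) are rejected.
    """
    s = np.asarray(sigma, dtype=float)
    if s.shape != (3, 3):
        raise ValueError("stress tensor must be 3x3")
    scale = max(np.linalg.norm(s), 1e-300)
    if np.linalg.norm(s - s.T) > sym_tol * max(scale, 1.0):
        raise ValueError("stress tensor is not symmetric within tolerance")
    w = np.linalg.eigvalsh(_sym(s))
    return PrincipalStresses(*np.sort(w))


def max_principal_stress_field(sigma: np.ndarray) -> np.ndarray:
    """sigma3 for a block of symmetric tensors (..., 3, 3) — vectorised."""
    w = np.linalg.eigvalsh(_sym(np.asarray(sigma, dtype=float)))
    return w[..., -1]


def elastic_moduli(part_card) -> tuple[float, float, float]:
    """(K, G, rho) of a card, used for wave speeds and penalty scaling.

    For the liver the shear modulus is the instantaneous one
    (ground-state Ogden + Prony G(0)).
    """
    if isinstance(part_card, FleshCard):
        return part_card.bulk_modulus, part_card.shear_modulus, part_card.density
    if isinstance(part_card, RibCard):
        return part_card.bulk_modulus, part_card.shear_modulus, part_card.density
    if isinstance(part_card, tuple):  # (OgdenParams, PronySeries)
        ogden, prony = part_card
        g = ogden.ground_shear_modulus + prony.g0
        return ogden.bulk_modulus, g, ogden.density
    raise TypeError(f"unknown material card {part_card!r}")
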