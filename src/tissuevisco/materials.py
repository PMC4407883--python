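"""Elastic and short-term viscous stress laws for ligament and cartilage.

Both tissues are modelled as an isotropic ground matrix reinforced by one
collagen-fiber family. The fibers carry load only in tension (``I4 > 1``);
every fiber term carries an ``(I4 − 1)`` factor so stress is continuous at
the tension–compression switch. The elastic potentials are

ligament (Neo-Hookean matrix + exponentially stiffening fibers)::

    Ψᵉ = a1 (I1 − 3) + a2/(2 a3) · exp[a3 (I4 − 1)²]          (I4 > 1)

cartilage (Neo-Hookean matrix + quadratic/cubic fiber law)::

    Ψᵉ = b1 (I1 − 3) + ½ b2 (I4 − 1)² + ⅓ b3 (I4 − 1)³        (I4 > 1)

The short-term viscous potentials are quadratic in the deformation rate
through ``J5 = Ċ² : N0``,

    Ψˢᵛ = ½ a4 (I4 − 1) exp[a5 (I4 − 1)²] J5        (ligament)
    Ψˢᵛ = b4 (I4 − 1) ln(I4) J5                      (cartilage)

giving viscous second Piola-Kirchhoff stresses ``Sᵛ = 2 ∂Ψˢᵛ/∂Ċ`` that are
linear in the rate ``Ċ``. All material constants must be non-negative for
convexity of the potentials.

For incompressible uniaxial tension along the fiber (λ, λ̇), the nominal
stress in the loading direction reduces to closed form; with u = λ² − 1:

    ligament  P11 = 2a1(λ − 1/λ²) + 2a2 λ u e^{a3 u²} + 4a4 λ² u e^{a5 u²} λ̇
    cartilage P11 = 2b1(λ − 1/λ²) + 2b2 λ u + 2b3 λ u² + 8b4 λ² ln(λ²) u λ̇

(fiber/viscous terms only for λ > 1; the matrix term alone in compression).
The incompressibility pressure p = −2a1/λ (resp. −2b1/λ) enforcing zero
lateral stress is already folded into the matrix term.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .kinematics import (
    DeformationState,
    FiberFrame,
    StretchPoint,
    nominal_from_second_pk,
    uniaxial_state,
)

__all__ = [
    "LigamentParams",
    "CartilageParams",
    "VolumetricConfig",
    "TissueModel",
    "elastic_energy",
    "elastic_stress",
    "short_term_viscous_stress",
    "uniaxial_pressure",
    "uniaxial_nominal_stress",
    "confined_compression_equilibrium",
    "material_tangents_uniaxial",
    "load_reference_params",
]

_I3 = np.eye(3)


def _check_nonneg(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value < 0.0:
            raise ValueError(f"material constant {name} must be >= 0, got {value}")


@dataclass(frozen=True)
class LigamentParams:
    """Ligament constants: a1 [Pa] matrix, a2 [Pa]/a3 [-] fiber elastic,
    a4 [Pa·s]/a5 [-] short-term viscous. a1 is typically 0 (the compressive
    matrix stiffness is negligible in tensile fits)."""

    a1: float = 0.0
    a2: float = 0.0
    a3: float = 0.0
    a4: float = 0.0
    a5: float = 0.0

    def __post_init__(self) -> None:
        _check_nonneg(a1=self.a1, a2=self.a2, a3=self.a3, a4=self.a4, a5=self.a5)


@dataclass(frozen=True)
class CartilageParams:
    """Cartilage constants: b1 [Pa] non-fibrillar matrix, b2/b3 [Pa] fiber
    elastic (quadratic + cubic), b4 [Pa·s] short-term viscous."""

    b1: float = 0.0
    b2: float = 0.0
    b3: float = 0.0
    b4: float = 0.0

    def __post_init__(self) -> None:
        _check_nonneg(b1=self.b1, b2=self.b2, b3=self.b3, b4=self.b4)


@dataclass(frozen=True)
class VolumetricConfig:
    """Volumetric law Ψvol = (κ/2)(ln J)² for the confined-compression helper.

    κ may be given absolutely (``kappa``, Pa) or relative to the matrix
    stiffness (``kappa_ratio``, default 10 — a soft-tissue-typical mild
    near-incompressibility; used when ``kappa`` is None).
    """

    kappa: float | None = None
    kappa_ratio: float = 10.0

    def effective_kappa(self, b1: float) -> float:
        k = self.kappa if self.kappa is not None else self.kappa_ratio * b1
        if k < 0.0:
            raise ValueError("volumetric stiffness must be >= 0")
        return k


@dataclass(frozen=True)
class TissueModel:
    """One tissue material point: parameters, fiber frame and (optionally)
    the long-term relaxation spectrum used by the protocol simulator."""

    params: LigamentParams | CartilageParams
    frame: FiberFrame = field(default_factory=FiberFrame.along_x)
    spectrum: "object | None" = None  # RelaxationSpectrum, kept untyped to avoid cycle

    @property
    def tissue(self) -> str:
        return "ligament" if isinstance(self.params, LigamentParams) else "cartilage"


def elastic_energy(state: DeformationState, model: TissueModel) -> float:
    """Helmholtz free energy density Ψᵉ [Pa] of the equilibrium response.

    Note the ligament exponential fiber law has a nonzero constant
    a2/(2 a3) at the reference state I4 = 1; the stress is unaffected.
    """
    p = model.params
    I1, I4 = state.I1, state.I4
    if isinstance(p, LigamentParams):
        psi = p.a1 * (I1 - 3.0)
        # the tension branch is taken at I4 = 1 so the energy carries its
        # tension-side limit a2/(2a3) there; all stress terms have an
        # (I4 - 1) factor, so the stress is unaffected either way
        if I4 >= 1.0:
            if p.a3 > 0.0:
                psi += p.a2 / (2.0 * p.a3) * np.exp(p.a3 * (I4 - 1.0) ** 2)
            else:  # a3 → 0 limit of the deformation-dependent part
                psi += 0.5 * p.a2 * (I4 - 1.0) ** 2
        return float(psi)
    psi = p.b1 * (I1 - 3.0)
    if I4 > 1.0:
        u = I4 - 1.0
        psi += 0.5 * p.b2 * u ** 2 + p.b3 * u ** 3 / 3.0
    return float(psi)


def elastic_stress(state: DeformationState, model: TissueModel) -> np.ndarray:
    """Elastic second Piola-Kirchhoff stress Sᵉ [Pa], without the pressure term."""
    p = model.params
    I4 = state.I4
    N0 = model.frame.N0
    u = I4 - 1.0
    if isinstance(p, LigamentParams):
        S = 2.0 * p.a1 * _I3
        if I4 > 1.0:
            S = S + 2.0 * p.a2 * np.exp(p.a3 * u ** 2) * u * N0
        return S
    S = 2.0 * p.b1 * _I3
    if I4 > 1.0:
        S = S + (2.0 * p.b2 * u + 2.0 * p.b3 * u ** 2) * N0
    return S


def short_term_viscous_stress(state: DeformationState, model: TissueModel) -> np.ndarray:
    """Short-term viscous stress Sᵛ = 2 ∂Ψˢᵛ/∂Ċ [Pa]; zero for I4 ≤ 1."""
    p = model.params
    I4 = state.I4
    if I4 <= 1.0:
        return np.zeros((3, 3))
    N0 = model.frame.N0
    sym = N0 @ state.Cdot + state.Cdot @ N0
    u = I4 - 1.0
    if isinstance(p, LigamentParams):
        return p.a4 * u * np.exp(p.a5 * u ** 2) * sym
    return 2.0 * p.b4 * np.log(I4) * u * sym


def uniaxial_pressure(lam: float, model: TissueModel) -> float:
    """Incompressibility Lagrange multiplier p = −2a1/λ (resp. −2b1/λ)
    enforcing S22 = S33 = 0 in uniaxial tension."""
    if not lam > 0.0:
        raise ValueError("stretch must be positive")
    p = model.params
    matrix = p.a1 if isinstance(p, LigamentParams) else p.b1
    return -2.0 * matrix / lam


def uniaxial_nominal_stress(pt: StretchPoint, model: TissueModel) -> float:
    """Instantaneous nominal stress P11 [Pa]: elastic + short-term viscous.

    The long-term relaxation term is added by the protocol simulator; this
    closed form is the material's rate-dependent response at one instant.
    """
    lam, lamdot = pt.lam, pt.lamdot
    if not lam > 0.0:
        raise ValueError("stretch must be positive")
    p = model.params
    u = lam * lam - 1.0
    if isinstance(p, LigamentParams):
        P = 2.0 * p.a1 * (lam - lam ** -2)
        if lam > 1.0:
            P += 2.0 * p.a2 * lam * u * np.exp(p.a3 * u ** 2)
            P += 4.0 * p.a4 * u * lam ** 2 * np.exp(p.a5 * u ** 2) * lamdot
        return float(P)
    P = 2.0 * p.b1 * (lam - lam ** -2)
    if lam > 1.0:
        P += 2.0 * p.b2 * lam * u + 2.0 * p.b3 * lam * u ** 2
        P += 8.0 * p.b4 * lam ** 2 * np.log(lam ** 2) * u * lamdot
    return float(P)


def confined_compression_equilibrium(
    lam_axial: float | np.ndarray,
    params: CartilageParams,
    vol_config: VolumetricConfig | None = None,
) -> float | np.ndarray:
    """Equilibrium nominal axial stress in confined compression [Pa].

    Uniaxial-strain kinematics F = diag(λ, 1, 1) with λ ≤ 1: the lateral
    confinement keeps the fibers slack (I4 = 1), so only the non-fibrillar
    matrix resists. A compressible Neo-Hookean with a logarithmic volumetric
    term is used,

        Ψ = b1 (I1 − 3 − 2 ln J) + (κ/2)(ln J)²,
        P11 = 2 b1 (λ − 1/λ) + κ ln(λ)/λ.

    The volumetric stiffness κ comes from ``vol_config``; this functional
    form is this package's own modelling choice for the equilibrium
    confined-compression response (see the methods note).
    """
    lam = np.asarray(lam_axial, dtype=float)
    if np.any(lam <= 0.0) or np.any(lam > 1.0 + 1e-12):
        raise ValueError("confined compression requires 0 < λ ≤ 1")
    vol = vol_config or VolumetricConfig()
    kappa = vol.effective_kappa(params.b1)
    P = 2.0 * params.b1 * (lam - 1.0 / lam) + kappa * np.log(lam) / lam
    return float(P) if np.isscalar(lam_axial) else P


def material_tangents_uniaxial(pt: StretchPoint, model: TissueModel) -> tuple[float, float]:
    """Analytic (∂P11/∂λ, ∂P11/∂λ̇) of the instantaneous uniaxial response.

    Only the tension branch (λ > 1) is supported; the response is linear in
    λ̇ so ∂P11/∂λ̇ is the coefficient of the rate term.
    """
    lam, lamdot = pt.lam, pt.lamdot
    if not lam > 1.0:
        raise ValueError("tangents are defined on the tension branch (λ > 1)")
    p = model.params
    u = lam * lam - 1.0
    if isinstance(p, LigamentParams):
        E3 = np.exp(p.a3 * u ** 2)
        E5 = np.exp(p.a5 * u ** 2)
        dP_dlam = 2.0 * p.a1 * (1.0 + 2.0 * lam ** -3)
        dP_dlam += 2.0 * p.a2 * E3 * (3.0 * lam ** 2 - 1.0 + 4.0 * p.a3 * lam ** 2 * u ** 2)
        dP_dlam += 8.0 * p.a4 * lamdot * lam * E5 * (
            2.0 * lam ** 2 - 1.0 + 2.0 * p.a5 * lam ** 2 * u ** 2
        )
        dP_drate = 4.0 * p.a4 * u * lam ** 2 * E5
        return float(dP_dlam), float(dP_drate)
    lnl2 = np.log(lam ** 2)
    dP_dlam = 2.0 * p.b1 * (1.0 + 2.0 * lam ** -3)
    dP_dlam += 2.0 * p.b2 * (u + 2.0 * lam ** 2)
    dP_dlam += 2.0 * p.b3 * (u ** 2 + 4.0 * lam ** 2 * u)
    dP_dlam += 8.0 * p.b4 * lamdot * (
        2.0 * lam * u * lnl2 + 2.0 * lam * u + 2.0 * lam ** 3 * lnl2
    )
    dP_drate = 8.0 * p.b4 * lam ** 2 * lnl2 * u
    return float(dP_dlam), float(dP_drate)


def uniaxial_components(
    lam: np.ndarray, lamdot: np.ndarray, params: LigamentParams | CartilageParams
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (P11_elastic, P11_viscous_short) along a stretch history.

    Same closed forms as :func:`uniaxial_nominal_stress`, split into the
    equilibrium part and the rate-dependent part; used by the protocol
    simulator.
    """
    lam = np.asarray(lam, dtype=float)
    lamdot = np.asarray(lamdot, dtype=float)
    u = lam * lam - 1.0
    tension = lam > 1.0
    if isinstance(params, LigamentParams):
        P_el = 2.0 * params.a1 * (lam - lam ** -2)
        fiber = 2.0 * params.a2 * lam * u * np.exp(params.a3 * u ** 2)
        P_el = P_el + np.where(tension, fiber, 0.0)
        visc = 4.0 * params.a4 * u * lam ** 2 * np.exp(params.a5 * u ** 2) * lamdot
    else:
        P_el = 2.0 * params.b1 * (lam - lam ** -2)
        fiber = 2.0 * params.b2 * lam * u + 2.0 * params.b3 * lam * u ** 2
        P_el = P_el + np.where(tension, fiber, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            visc = (
                8.0 * params.b4 * lam ** 2
                * np.log(np.where(tension, lam ** 2, 1.0)) * u * lamdot
            )
    P_visc = np.where(tension, visc, 0.0)
    return P_el, P_visc


# -- bundled reference parameter sets ---------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("tissuevisco").joinpath("data", name)))


def load_reference_params(tissue: str):
    """Load the bundled literature parameter set for 'ligament' or 'cartilage'.

    Returns (params, spectrum_dict) where spectrum_dict has keys 'tau_s'
    and 'w'. The values are the published fits for anterior cruciate
    ligament tension and articular cartilage tension/compression.
    """
    from .history import RelaxationSpectrum

    name = {"ligament": "ligament_acl.json", "cartilage": "cartilage.json"}.get(tissue)
    if name is None:
        raise ValueError(f"unknown tissue {tissue!r}")
    raw = json.loads(_data_path(name).read_text())
    # printed table weights round to ~3 digits; renormalize to Σw = 1 exactly
    spectrum = RelaxationSpectrum.from_table(raw["spectrum"]["tau_s"], raw["spectrum"]["w"])
    if tissue == "ligament":
        params = LigamentParams(**{k: raw[k] for k in ("a1", "a2", "a3", "a4", "a5")})
    else:
        params = CartilageParams(**{k: raw[k] for k in ("b1", "b2", "b3", "b4")})
    return params, spectrum


def reference_model(tissue: str) -> TissueModel:
    """Convenience: TissueModel with the bundled parameters and spectrum."""
    params, spectrum = load_reference_params(tissue)
    return TissueModel(params=params, spectrum=spectrum)


def uniaxial_nominal_stress_tensor_route(pt: StretchPoint, model: TissueModel) -> float:
    """P11 via the full tensor pipeline (state → S + pressure → P = J⁻¹FS).

    Slower than the closed form; used as an internal consistency route and
    by tests.
    """
    state = uniaxial_state(pt, model.frame)
    S = elastic_stress(state, model) + short_term_viscous_stress(state, model)
    p = uniaxial_pressure(pt.lam, model)
    S = S + p * np.linalg.inv(state.C)
    P = nominal_from_second_pk(state.F, S)
    return float(P[0, 0])
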