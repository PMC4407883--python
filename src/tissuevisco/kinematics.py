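"""Deformation measures, invariants and stress-measure conversions.

This layer holds the continuum-mechanics bookkeeping shared by both tissue
models: the right Cauchy-Green tensor ``C = FᵀF``, its rate ``Ċ``, the fiber
structure tensor ``N0 = n0 ⊗ n0`` of a transversely isotropic material, and
the scalar invariants that the energy functions depend on,

    I1 = tr C,   I3 = det C,   I4 = C : N0 = λ_f²,   J5 = Ċ² : N0,

where ``λ_f`` is the stretch along the fiber direction and ``J5`` carries the
strain-rate dependence of the short-term viscous potential.

Uniaxial, incompressible tension along the fiber axis (the configuration of
every tensile test handled here) has closed-form kinematics

    F = diag(λ, λ^{-1/2}, λ^{-1/2}),   C = diag(λ², 1/λ, 1/λ),
    Ċ = diag(2λλ̇, −λ̇/λ², −λ̇/λ²),

so the fiber invariants reduce to ``I4 = λ²`` and ``J5 = 4λ²λ̇²``.

The loading axis is fixed to x with ``n0 = x̂`` for all 1D helpers; general
fiber frames are accepted only by the tensor-level operations. Stretch rates
are in absolute units (1/s) throughout the library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FiberFrame",
    "StretchPoint",
    "DeformationState",
    "uniaxial_state",
    "invariants",
    "rate_invariant_J5",
    "nominal_from_second_pk",
    "cauchy_from_second_pk",
]

_SYM_TOL = 1e-9


def _as_tensor(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.shape != (3, 3):
        raise ValueError(f"{name} must be a 3x3 tensor, got shape {a.shape}")
    return a


def _require_symmetric(a: np.ndarray, name: str) -> np.ndarray:
    scale = max(1.0, float(np.abs(a).max()))
    if np.abs(a - a.T).max() > _SYM_TOL * scale:
        raise ValueError(f"{name} must be symmetric")
    return a


@dataclass(frozen=True)
class FiberFrame:
    """Unit fiber direction ``n0`` and its structure tensor ``N0 = n0 ⊗ n0``."""

    n0: np.ndarray
    N0: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n0 = np.asarray(self.n0, dtype=float).reshape(3)
        norm = float(np.linalg.norm(n0))
        if abs(norm - 1.0) > 1e-12:
            if norm == 0.0:
                raise ValueError("fiber direction must be a non-zero vector")
            n0 = n0 / norm
        object.__setattr__(self, "n0", n0)
        object.__setattr__(self, "N0", np.outer(n0, n0))

    @classmethod
    def along_x(cls) -> "FiberFrame":
        return cls(np.array([1.0, 0.0, 0.0]))


@dataclass(frozen=True)
class StretchPoint:
    """Instantaneous stretch ratio λ (> 0) and stretch rate λ̇ (1/s)."""

    lam: float
    lamdot: float = 0.0

    def __post_init__(self) -> None:
        if not self.lam > 0.0:
            raise ValueError(f"stretch ratio must be positive, got {self.lam}")


@dataclass(frozen=True)
class DeformationState:
    """F, C, Ċ and cached invariants for one material point at one instant."""

    F: np.ndarray
    C: np.ndarray
    Cdot: np.ndarray
    frame: FiberFrame
    J: float
    I1: float
    I3: float
    I4: float
    J5: float

    @classmethod
    def from_F(cls, F, Cdot, frame: FiberFrame) -> "DeformationState":
        F = _as_tensor(F, "F")
        Cdot = _require_symmetric(_as_tensor(Cdot, "Cdot"), "Cdot")
        J = float(np.linalg.det(F))
        if J <= 0.0:
            raise ValueError("det F must be positive")
        C = F.T @ F
        I1, I3, I4 = invariants(C, frame)
        J5 = rate_invariant_J5(Cdot, frame)
        return cls(F=F, C=C, Cdot=Cdot, frame=frame, J=J, I1=I1, I3=I3, I4=I4, J5=J5)


def uniaxial_state(pt: StretchPoint, frame: FiberFrame | None = None) -> DeformationState:
    """Incompressible uniaxial tension/compression state along the x axis.

    The fiber direction is assumed to coincide with the loading axis; passing
    a frame that is not aligned with x is rejected because the closed-form
    diagonal kinematics would be wrong for it.
    """
    if frame is None:
        frame = FiberFrame.along_x()
    elif abs(abs(frame.n0[0]) - 1.0) > 1e-12:
        raise ValueError("uniaxial_state requires the fiber frame aligned with x")
    lam, lamdot = pt.lam, pt.lamdot
    F = np.diag([lam, lam ** -0.5, lam ** -0.5])
    Cdot = np.diag([2.0 * lam * lamdot, -lamdot / lam ** 2, -lamdot / lam ** 2])
    state = DeformationState.from_F(F, Cdot, frame)
    # det of the closed-form diagonal F is 1 exactly up to roundoff
    return DeformationState(
        F=state.F, C=state.C, Cdot=state.Cdot, frame=frame, J=1.0,
        I1=state.I1, I3=state.I3, I4=state.I4, J5=state.J5,
    )


def invariants(C, frame: FiberFrame) -> tuple[float, float, float]:
    """Return (I1, I3, I4) of a symmetric positive-definite C."""
    C = _require_symmetric(_as_tensor(C, "C"), "C")
    I3 = float(np.linalg.det(C))
    if I3 <= 0.0 or np.any(np.linalg.eigvalsh(C) <= 0.0):
        raise ValueError("C must be positive-definite")
    I1 = float(np.trace(C))
    I4 = float(np.tensordot(C, frame.N0))
    return I1, I3, I4


def rate_invariant_J5(Cdot, frame: FiberFrame) -> float:
    """J5 = (Ċ·Ċ) : N0, the rate invariant driving short-term viscosity."""
    Cdot = _require_symmetric(_as_tensor(Cdot, "Cdot"), "Cdot")
    return float(np.tensordot(Cdot @ Cdot, frame.N0))


def nominal_from_second_pk(F, S) -> np.ndarray:
    """Nominal (first Piola-Kirchhoff) stress ``P = J⁻¹ F S``.

    For the incompressible uniaxial states used in tensile testing J = 1 and
    this coincides with the standard P = F S.
    """
    F = _as_tensor(F, "F")
    S = _as_tensor(S, "S")
    J = float(np.linalg.det(F))
    if abs(J) < 1e-14:
        raise ValueError("F is singular")
    if J < 0.0:
        raise ValueError("det F must be positive")
    return (F @ S) / J


def cauchy_from_second_pk(F, S) -> np.ndarray:
    """Push-forward to Cauchy stress ``σ = J⁻¹ F S Fᵀ``."""
    F = _as_tensor(F, "F")
    S = _as_tensor(S, "S")
    J = float(np.linalg.det(F))
    if abs(J) < 1e-14:
        raise ValueError("F is singular")
    if J < 0.0:
        raise ValueError("det F must be positive")
    return (F @ S @ F.T) / J
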