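"""Time-history machinery: long-term relaxation branches and QLV.

Two viscous mechanisms with different time scales are modelled:

* **Short-term** — algebraic in the current rate (handled by
  :mod:`tissuevisco.materials`); it vanishes the instant loading stops.
* **Long-term** — relaxation of the peak short-term viscous stress
  ``S_δ`` reached at the end of a loading phase (time δ). Each
  loading→hold transition spawns a :class:`RelaxationBranch`; in the
  default *prony* mode a branch contributes

      S_lᵛ(t) = S_δ · Σᵢ wᵢ exp[−(t − δ)/τᵢ],   t ≥ δ,

  with weights summing to one, so the total stress is continuous at δ
  (the long-term term takes over exactly where the short-term term
  switches off) and decays to the elastic equilibrium. A *literal* mode
  retains the alternative reading of the evolution law in which each
  weight acts as a rate (units 1/s) on the antiderivative,

      S_lᵛ(t) = S_δ · Σᵢ wᵢ τᵢ (1 − exp[−(t − δ)/τᵢ]),

  which grows toward Σ wᵢ τᵢ S_δ instead of decaying; it is kept for
  fidelity to that formulation and is regression-tested so the mode
  distinction cannot be silently lost.

The quasi-linear viscoelastic (QLV) reference model convolves the elastic
stress rate with a reduced relaxation function,

    S(t) = Sᵉ(t) + Σᵢ gᵢ ∫₀ᵗ exp[−(t−T)/τᵢ] Ṡᵉ(T) dT,

and is integrated with an exponential recurrence that treats the kernel
exactly per step (unconditionally stable for widely spread τᵢ) and the
integrand as linear within a step — second-order accurate overall and exact
for piecewise-linear Sᵉ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RelaxationSpectrum",
    "QLVParams",
    "RelaxationBranch",
    "long_term_stress",
    "handoff_detect",
    "qlv_stress",
    "convolution_step",
    "load_reference_qlv",
]


@dataclass(frozen=True)
class RelaxationSpectrum:
    """Relaxation time constants τᵢ [s] and weights wᵢ (Σwᵢ = 1)."""

    tau: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        w = np.atleast_1d(np.asarray(self.w, dtype=float))
        if tau.shape != w.shape or tau.ndim != 1:
            raise ValueError("tau and w must be 1-D arrays of equal length")
        if np.any(tau <= 0.0):
            raise ValueError("time constants must be positive")
        if np.any(w <= 0.0):
            raise ValueError("weights must be positive")
        if abs(float(w.sum()) - 1.0) > 1e-9:
            raise ValueError(
                f"weights must sum to 1 (got {float(w.sum()):.6g}); "
                "use RelaxationSpectrum.from_table to renormalize printed values"
            )
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "w", w)

    @classmethod
    def from_table(cls, tau, w) -> "RelaxationSpectrum":
        """Build from printed table values: sorts by τ and renormalizes the
        weights to sum exactly to one (published tables round to ~3 digits)."""
        tau = np.asarray(tau, dtype=float)
        w = np.asarray(w, dtype=float)
        order = np.argsort(tau)
        tau, w = tau[order], w[order]
        return cls(tau=tau, w=w / w.sum())

    def reduced_relaxation(self, dt: np.ndarray | float) -> np.ndarray | float:
        """R(Δt) = Σ wᵢ exp(−Δt/τᵢ), the normalized relaxation function."""
        dt_arr = np.atleast_1d(np.asarray(dt, dtype=float))
        R = np.exp(-dt_arr[:, None] / self.tau[None, :]) @ self.w
        return float(R[0]) if np.isscalar(dt) or np.asarray(dt).ndim == 0 else R


@dataclass(frozen=True)
class QLVParams:
    """QLV ratios gᵢ (short-term vs equilibrium stress) and τᵢ [s]."""

    g: np.ndarray
    tau: np.ndarray

    def __post_init__(self) -> None:
        g = np.atleast_1d(np.asarray(self.g, dtype=float))
        tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        if g.shape != tau.shape or g.ndim != 1:
            raise ValueError("g and tau must be 1-D arrays of equal length")
        if np.any(g < 0.0):
            raise ValueError("g ratios must be >= 0")
        if np.any(tau <= 0.0):
            raise ValueError("time constants must be positive")
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "tau", tau)


@dataclass(frozen=True)
class RelaxationBranch:
    """One live relaxation branch: start time δ [s] and the peak short-term
    viscous stress S_δ [Pa] it relaxes from."""

    delta: float
    S_delta: float
    spectrum: RelaxationSpectrum

    def __post_init__(self) -> None:
        if self.delta < 0.0:
            raise ValueError("branch start time must be >= 0")


def long_term_stress(
    branches: list[RelaxationBranch] | tuple[RelaxationBranch, ...],
    t: float | np.ndarray,
    mode: str = "prony",
    inclusive: bool = True,
) -> float | np.ndarray:
    """Long-term viscous stress at time(s) t from all live branches [Pa].

    With ``inclusive`` (default) a branch already contributes at t = δ,
    where the prony form returns S_δ exactly (Σw = 1). The simulator passes
    ``inclusive=False`` because its sample at δ still belongs to the ramp,
    where the short-term term carries that same stress.
    """
    if mode not in ("prony", "literal"):
        raise ValueError(f"unknown long-term mode {mode!r}")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t_arr)
    for br in branches:
        dt = t_arr - br.delta
        active = dt >= 0.0 if inclusive else dt > 0.0
        if not np.any(active):
            continue
        tau, w = br.spectrum.tau, br.spectrum.w
        if mode == "prony":
            contrib = np.exp(-dt[active, None] / tau[None, :]) @ w
        else:  # literal: weights act as rates [1/s] on the antiderivative
            contrib = (-np.expm1(-dt[active, None] / tau[None, :]) * tau[None, :]) @ w
        out[active] += br.S_delta * contrib
    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return float(out[0])
    return out


def handoff_detect(t, lamdot, tol: float = 1e-9) -> list[float]:
    """Detect loading→hold handoff times δ in a sampled stretch-rate history.

    A δ is recorded at the last sample of each moving run (|λ̇| > tol)
    that is followed by a quiet sample (|λ̇| ≤ tol) — the end of a ramp.
    """
    t = np.asarray(t, dtype=float)
    lamdot = np.asarray(lamdot, dtype=float)
    if t.shape != lamdot.shape or t.ndim != 1:
        raise ValueError("t and lamdot must be 1-D arrays of equal length")
    if t.size > 1 and np.any(np.diff(t) <= 0.0):
        raise ValueError("time must be strictly increasing")
    moving = np.abs(lamdot) > tol
    deltas = [float(t[i]) for i in range(t.size - 1) if moving[i] and not moving[i + 1]]
    return deltas


def _phi1(x: np.ndarray) -> np.ndarray:
    """(1 − e^{−x})/x, stable for small x."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x < 1e-8
    out[small] = 1.0 - x[small] / 2.0 + x[small] ** 2 / 6.0
    xs = x[~small]
    out[~small] = -np.expm1(-xs) / xs
    return out


def _phi2(x: np.ndarray) -> np.ndarray:
    """(1 − e^{−x}(1 + x))/x², stable for small x (→ 1/2)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x < 1e-3
    xs = x[small]
    out[small] = 0.5 - xs / 3.0 + xs ** 2 / 8.0 - xs ** 3 / 30.0
    xl = x[~small]
    out[~small] = (1.0 - np.exp(-xl) * (1.0 + xl)) / xl ** 2
    return out


def convolution_step(h, dt: float, tau, f0, f1=None):
    """One exponential-recurrence update of hereditary integrals.

    Advances h = ∫ exp[−(t−T)/τ] f(T) dT by one step of size dt:

        h ← e^{−dt/τ} h + ∫_step e^{−(t+dt−T)/τ} f(T) dT,

    with the step integral evaluated in closed form for f linear between
    f0 and f1 (pass f1=None for a constant/midpoint-valued integrand).
    The kernel is treated exactly, so the update is unconditionally stable
    for any τ spread; accuracy is second order in dt for smooth f and
    exact when f is piecewise constant (or linear) per step.
    """
    if not dt > 0.0:
        raise ValueError("dt must be positive")
    tau = np.asarray(tau, dtype=float)
    h = np.asarray(h, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    x = dt / tau
    decay = np.exp(-x)
    if f1 is None:
        inc = dt * f0 * _phi1(x)
    else:
        f1 = np.asarray(f1, dtype=float)
        inc = dt * (f1 * _phi1(x) - (f1 - f0) * _phi2(x))
    return decay * h + inc


def qlv_stress(t, S_elastic, params: QLVParams) -> np.ndarray:
    """Total QLV stress on the sample grid of an elastic stress history.

    Integrates S(t) = Sᵉ(t) + Σᵢ gᵢ ∫₀ᵗ e^{−(t−T)/τᵢ} Ṡᵉ dT with the
    exponential recurrence, treating Sᵉ as piecewise linear between samples
    (for which the result is exact).
    """
    t = np.asarray(t, dtype=float)
    Se = np.asarray(S_elastic, dtype=float)
    if t.size == 0:
        raise ValueError("empty elastic stress series")
    if t.shape != Se.shape or t.ndim != 1:
        raise ValueError("t and S_elastic must be 1-D arrays of equal length")
    if t.size > 1 and np.any(np.diff(t) <= 0.0):
        raise ValueError("time must be strictly increasing")
    n_terms = params.tau.size
    h = np.zeros(n_terms)
    total = np.empty_like(Se)
    total[0] = Se[0]
    for n in range(t.size - 1):
        dt = t[n + 1] - t[n]
        rate = (Se[n + 1] - Se[n]) / dt  # piecewise-constant Ṡᵉ per interval
        h = convolution_step(h, dt, params.tau, rate)
        total[n + 1] = Se[n + 1] + float(params.g @ h)
    return total


def load_reference_qlv() -> QLVParams:
    """Bundled literature QLV parameter set (3 terms)."""
    import json

    from .materials import _data_path

    raw = json.loads(_data_path("qlv_cartilage.json").read_text())
    return QLVParams(g=raw["g"], tau=raw["tau_s"])
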