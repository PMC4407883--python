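"""Staged material identification from uniaxial test data.

The parameters of each tissue are identified in stages that mirror how the
experiments separate the mechanisms:

ligament
    1. *equilibrium tension* → elastic fiber constants a2, a3 (the matrix
       constant a1 is negligible in tension and held fixed, default 0);
    2. *single-rate ramp tension* → short-term viscous constants a4, a5,
       with the elastic part fixed;
    3. *stress relaxation* (normalized viscous decay) → relaxation spectrum
       (τᵢ, wᵢ) under the constraints wᵢ > 0, τᵢ > 0, Σwᵢ = 1.

cartilage
    1. *confined compression at equilibrium* → non-fibrillar matrix b1;
    2. *tensile equilibria* (multistep end-of-hold points) → fiber b2, b3;
    3. *first ramp* of the multistep record → short-term b4 (linear);
    4. *first relaxation phase* (normalized) → spectrum.

All fits are bound-constrained least squares (scipy trust-region
reflective); the Σw = 1 equality is enforced exactly by eliminating the
last weight. Multi-exponential spectrum fitting is ill-conditioned, so it
is multi-started from seeded, log-spaced time-constant initializations and
judged primarily at curve level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, nnls

from .history import RelaxationSpectrum
from .materials import (
    CartilageParams,
    LigamentParams,
    TissueModel,
    VolumetricConfig,
    confined_compression_equilibrium,
    uniaxial_components,
)

__all__ = [
    "ExperimentDataset",
    "StageResult",
    "CalibrationResult",
    "fit_elastic",
    "fit_short_term",
    "fit_spectrum",
    "fit_confined_compression",
    "staged_calibration",
]

_KINDS = ("equilibrium_tension", "ramp_tension", "relaxation", "confined_compression")
_TENSION_KINDS = ("equilibrium_tension", "ramp_tension", "relaxation")


@dataclass
class ExperimentDataset:
    """One experimental record.

    ``table`` columns: ``stretch, P11_Pa`` for equilibrium/confined kinds;
    ``time_s, stretch, P11_Pa`` for ramp and relaxation kinds. Relaxation
    tables may instead carry a dimensionless ``R`` column (already
    normalized viscous decay).
    """

    kind: str
    table: pd.DataFrame
    rate: float | None = None
    weights: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown dataset kind {self.kind!r}")
        if len(self.table) < 5:
            raise ValueError("dataset needs at least 5 points")
        for col in ("P11_Pa", "R"):
            if col in self.table and not np.all(np.isfinite(self.table[col])):
                raise ValueError(f"non-finite values in {col}")
        if "stretch" in self.table:
            lam = self.table["stretch"].to_numpy(dtype=float)
            if self.kind in _TENSION_KINDS and np.any(lam < 1.0 - 1e-9):
                raise ValueError(f"{self.kind} dataset must have stretch >= 1")
            if self.kind == "confined_compression" and np.any(lam > 1.0 + 1e-9):
                raise ValueError("confined compression dataset contains tension samples")


@dataclass
class StageResult:
    """Diagnostics of one fitting stage."""

    name: str
    params: dict
    residual_rms: float
    n_iterations: int
    converged: bool
    active_constraints: list[str] = field(default_factory=list)


@dataclass
class CalibrationResult:
    """Fitted parameters, per-stage residuals and reproducibility log."""

    tissue: str
    params: LigamentParams | CartilageParams
    spectrum: RelaxationSpectrum | None
    stages: list[StageResult]
    converged: bool
    log: dict = field(default_factory=dict)

    @property
    def residual_rms(self) -> dict[str, float]:
        return {s.name: s.residual_rms for s in self.stages}

    @property
    def active_constraints(self) -> list[str]:
        return [c for s in self.stages for c in s.active_constraints]

    def to_dict(self) -> dict:
        out = {
            "tissue": self.tissue,
            "params": asdict(self.params),
            "spectrum": None
            if self.spectrum is None
            else {"tau_s": self.spectrum.tau.tolist(), "w": self.spectrum.w.tolist()},
            "stages": [
                {
                    "name": s.name,
                    "params": s.params,
                    "residual_rms": s.residual_rms,
                    "n_iterations": s.n_iterations,
                    "converged": s.converged,
                    "active_constraints": s.active_constraints,
                }
                for s in self.stages
            ],
            "converged": self.converged,
            "log": self.log,
        }
        return out


def _weights_of(data: ExperimentDataset, n: int) -> np.ndarray:
    if data.weights is None:
        return np.ones(n)
    w = np.asarray(data.weights, dtype=float)
    if w.shape != (n,):
        raise ValueError("weights length must match number of points")
    return w


def fit_elastic(
    data: ExperimentDataset,
    tissue: str,
    matrix_constant: float = 0.0,
    viscous_correction: np.ndarray | None = None,
) -> StageResult:
    """Fit the equilibrium (λ̇ = 0) branch of the uniaxial stress law.

    ``matrix_constant`` is the isotropic constant (a1 or b1) fixed from an
    external stage; ``viscous_correction`` optionally subtracts a known
    small rate term when the "equilibrium" data were collected at a slow
    but nonzero rate.
    """
    if data.kind != "equilibrium_tension":
        raise ValueError("fit_elastic expects an equilibrium_tension dataset")
    lam = data.table["stretch"].to_numpy(dtype=float)
    P = data.table["P11_Pa"].to_numpy(dtype=float)
    if viscous_correction is not None:
        P = P - np.asarray(viscous_correction, dtype=float)
    wts = _weights_of(data, lam.size)
    u = lam * lam - 1.0
    matrix_term = 2.0 * matrix_constant * (lam - lam ** -2)
    target = P - matrix_term

    if tissue == "cartilage":
        if lam.size < 2:
            raise ValueError("need at least as many points as parameters")
        A = np.column_stack([2.0 * lam * u, 2.0 * lam * u ** 2]) * wts[:, None]
        coef, _ = nnls(A, target * wts)
        b2, b3 = float(coef[0]), float(coef[1])
        resid = A @ coef - target * wts
        active = [name for name, v in (("b2", b2), ("b3", b3)) if v == 0.0]
        return StageResult(
            name="elastic",
            params={"b1": matrix_constant, "b2": b2, "b3": b3},
            residual_rms=float(np.sqrt(np.mean(resid ** 2))),
            n_iterations=1,
            converged=True,
            active_constraints=active,
        )

    if tissue != "ligament":
        raise ValueError(f"unknown tissue {tissue!r}")
    if lam.size < 2:
        raise ValueError("need at least as many points as parameters")

    if np.all(target <= 0.0):
        return StageResult(
            name="elastic",
            params={"a1": matrix_constant, "a2": 0.0, "a3": 0.0},
            residual_rms=float(np.sqrt(np.mean(target ** 2))),
            n_iterations=0,
            converged=True,
            active_constraints=["a2", "a3"],
        )

    # log-linearization for the initial guess: ln[P/(2λu)] = ln a2 + a3 u²
    pos = (u > 1e-8) & (target > 0.0)
    y = np.log(target[pos] / (2.0 * lam[pos] * u[pos]))
    slope, intercept = np.polyfit(u[pos] ** 2, y, 1)
    x0 = np.array([np.exp(intercept), max(slope, 0.0)])

    def resid(x):
        a2, a3 = x
        return wts * (2.0 * a2 * lam * u * np.exp(a3 * u ** 2) - target)

    sol = least_squares(
        resid, x0, bounds=([0.0, 0.0], [np.inf, np.inf]), xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    a2, a3 = map(float, sol.x)
    active = [n for n, v in (("a2", a2), ("a3", a3)) if v == 0.0]
    return StageResult(
        name="elastic",
        params={"a1": matrix_constant, "a2": a2, "a3": a3},
        residual_rms=float(np.sqrt(np.mean(sol.fun ** 2))),
        n_iterations=int(sol.nfev),
        converged=bool(sol.success),
        active_constraints=active,
    )


def fit_short_term(
    data: ExperimentDataset,
    elastic_params: LigamentParams | CartilageParams,
    rate: float | None = None,
    t_max: float | None = None,
) -> StageResult:
    """Fit the short-term viscous constants from one constant-rate ramp.

    The elastic prediction is subtracted and the remainder is fit against
    the rate term. ``t_max`` restricts the fit to an initial portion of the
    record (used to isolate the first ramp of a multistep test).
    """
    if data.kind != "ramp_tension":
        raise ValueError("fit_short_term expects a ramp_tension dataset")
    rate = data.rate if rate is None else rate
    if rate is None or not rate > 0.0:
        raise ValueError("ramp dataset needs a positive stretch rate")
    tbl = data.table
    wts = _weights_of(data, len(tbl))
    if t_max is not None:
        keep = tbl["time_s"].to_numpy(dtype=float) <= t_max + 1e-12
        tbl = tbl[keep]
        wts = wts[keep]
    lam = tbl["stretch"].to_numpy(dtype=float)
    P = tbl["P11_Pa"].to_numpy(dtype=float)
    P_el, _ = uniaxial_components(lam, np.zeros_like(lam), elastic_params)
    target = P - P_el
    u = lam * lam - 1.0
    tension = u > 1e-8
    if tension.sum() < 2:
        raise ValueError("ramp dataset has too few tension samples")

    if isinstance(elastic_params, CartilageParams):
        x = 8.0 * lam[tension] ** 2 * np.log(lam[tension] ** 2) * u[tension] * rate
        w2 = wts[tension]
        denom = float(np.sum(w2 * x * x))
        b4 = max(float(np.sum(w2 * x * target[tension]) / denom), 0.0) if denom > 0 else 0.0
        resid = w2 * (b4 * x - target[tension])
        return StageResult(
            name="short_term",
            params={"b4": b4},
            residual_rms=float(np.sqrt(np.mean(resid ** 2))),
            n_iterations=1,
            converged=True,
            active_constraints=["b4"] if b4 == 0.0 else [],
        )

    lam_t, u_t, y_t, w_t = lam[tension], u[tension], target[tension], wts[tension]
    base = 4.0 * u_t * lam_t ** 2 * rate
    pos = y_t > 0.0
    if pos.sum() < 2:
        return StageResult(
            name="short_term",
            params={"a4": 0.0, "a5": 0.0},
            residual_rms=float(np.sqrt(np.mean(y_t ** 2))),
            n_iterations=0,
            converged=True,
            active_constraints=["a4", "a5"],
        )
    z = np.log(y_t[pos] / base[pos])
    slope, intercept = np.polyfit(u_t[pos] ** 2, z, 1)
    x0 = np.array([np.exp(intercept), max(slope, 0.0)])

    def resid(x):
        a4, a5 = x
        return w_t * (a4 * base * np.exp(a5 * u_t ** 2) - y_t)

    sol = least_squares(
        resid, x0, bounds=([0.0, 0.0], [np.inf, np.inf]), xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    a4, a5 = map(float, sol.x)
    return StageResult(
        name="short_term",
        params={"a4": a4, "a5": a5},
        residual_rms=float(np.sqrt(np.mean(sol.fun ** 2))),
        n_iterations=int(sol.nfev),
        converged=bool(sol.success),
        active_constraints=[n for n, v in (("a4", a4), ("a5", a5)) if v == 0.0],
    )


def _spectrum_curve(t, log10tau, w):
    return np.exp(-t[:, None] / 10.0 ** log10tau[None, :]) @ w


def fit_spectrum(
    data: "ExperimentDataset | tuple",
    n_terms: int = 3,
    seed: int = 0,
    n_starts: int = 8,
) -> tuple[RelaxationSpectrum, StageResult]:
    """Fit Σ wᵢ exp(−t/τᵢ) to a normalized relaxation record.

    Input is either a relaxation ``ExperimentDataset`` whose ``R`` (or
    normalized ``P11_Pa``) column starts at ≈1 and decays, or a plain
    ``(t, R)`` pair with t measured from the start of relaxation. The
    constraint Σw = 1 is enforced exactly by eliminating the last weight;
    positivity of all weights and time constants is enforced by bounds and
    candidate rejection. Multi-started (seeded) because multi-exponential
    fitting is ill-conditioned.
    """
    if isinstance(data, ExperimentDataset):
        if data.kind != "relaxation":
            raise ValueError("fit_spectrum expects a relaxation dataset")
        t = data.table["time_s"].to_numpy(dtype=float)
        col = "R" if "R" in data.table else "P11_Pa"
        y = data.table[col].to_numpy(dtype=float)
    else:
        t, y = (np.asarray(a, dtype=float) for a in data)
    t = t - t[0]
    # guard against raw Pa-scale input; noisy normalized data are O(1)
    if y[0] <= 0.0 or np.max(np.abs(y)) > 100.0:
        raise ValueError(
            "relaxation input does not look normalized (expected to start at ~1)"
        )
    if n_terms < 1:
        raise ValueError("need at least one spectrum term")
    t_pos = t[t > 0.0]
    if t_pos.size == 0:
        raise ValueError("relaxation record has no positive times")
    span = t_pos.max() / t_pos.min()
    if span < 10.0:
        warnings.warn("relaxation record spans less than one decade in time")

    rng = np.random.default_rng(seed)
    tau_base = np.geomspace(t_pos.min(), t_pos.max(), n_terms + 2)[1:-1] if n_terms > 1 else np.array(
        [np.sqrt(t_pos.min() * t_pos.max())]
    )
    lo = np.concatenate([np.full(n_terms, np.log10(t_pos.min()) - 2.0), np.zeros(max(n_terms - 1, 0))])
    hi = np.concatenate([np.full(n_terms, np.log10(t_pos.max()) + 3.0), np.ones(max(n_terms - 1, 0))])

    def resid(x):
        log10tau = x[:n_terms]
        w_free = x[n_terms:]
        w_last = 1.0 - w_free.sum()
        w = np.concatenate([w_free, [w_last]])
        r = _spectrum_curve(t, log10tau, w) - y
        return np.concatenate([r, [100.0 * max(0.0, -w_last)]])

    best = None
    for k in range(n_starts):
        if k == 0:
            tau0 = tau_base
        else:
            tau0 = tau_base * 10.0 ** rng.uniform(-1.0, 1.0, size=n_terms)
        tau0 = np.clip(np.sort(tau0), 10.0 ** (lo[0] + 0.01), 10.0 ** (hi[0] - 0.01))
        w0 = np.full(max(n_terms - 1, 0), 1.0 / n_terms)
        x0 = np.concatenate([np.log10(tau0), w0])
        try:
            sol = least_squares(
                resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000
            )
        except ValueError:
            continue
        w_last = 1.0 - sol.x[n_terms:].sum()
        if w_last < -1e-9:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("spectrum fit failed from every start")

    log10tau = best.x[:n_terms]
    w_free = best.x[n_terms:]
    w = np.concatenate([w_free, [1.0 - w_free.sum()]])
    active = []
    if np.any(w < 1e-12):
        active.append("w_positivity")
        w = np.maximum(w, 1e-12)
    w[-1] = 1.0 - w[:-1].sum()  # Σw = 1 holds exactly by elimination
    tau = 10.0 ** log10tau
    order = np.argsort(tau)
    spectrum = RelaxationSpectrum(tau=tau[order], w=w[order])
    curve_rms = float(np.sqrt(np.mean((_spectrum_curve(t, np.log10(spectrum.tau), spectrum.w) - y) ** 2)))
    stage = StageResult(
        name="spectrum",
        params={"tau_s": spectrum.tau.tolist(), "w": spectrum.w.tolist()},
        residual_rms=curve_rms,
        n_iterations=int(best.nfev),
        converged=bool(best.success),
        active_constraints=active,
    )
    return spectrum, stage


def fit_confined_compression(
    data: ExperimentDataset,
    vol_config: VolumetricConfig | None = None,
) -> StageResult:
    """Scalar least-squares fit of the matrix stiffness b1 from equilibrium
    confined-compression points (linear once κ is tied to b1 or given)."""
    if data.kind != "confined_compression":
        raise ValueError("fit_confined_compression expects a confined_compression dataset")
    vol = vol_config or VolumetricConfig()
    lam = data.table["stretch"].to_numpy(dtype=float)
    P = data.table["P11_Pa"].to_numpy(dtype=float)
    wts = _weights_of(data, lam.size)
    if vol.kappa is None:
        phi = 2.0 * (lam - 1.0 / lam) + vol.kappa_ratio * np.log(lam) / lam
        target = P
    else:
        phi = 2.0 * (lam - 1.0 / lam)
        target = P - vol.kappa * np.log(lam) / lam
    denom = float(np.sum(wts * phi * phi))
    b1 = max(float(np.sum(wts * phi * target) / denom), 0.0) if denom > 0 else 0.0
    pred = confined_compression_equilibrium(lam, CartilageParams(b1=b1), vol)
    resid = wts * (pred - P)
    return StageResult(
        name="confined_compression",
        params={"b1": b1, "kappa": vol.effective_kappa(b1)},
        residual_rms=float(np.sqrt(np.mean(resid ** 2))),
        n_iterations=1,
        converged=True,
        active_constraints=["b1"] if b1 == 0.0 else [],
    )


def _normalized_relaxation(
    data: ExperimentDataset, params
) -> tuple[np.ndarray, np.ndarray]:
    """Convert a raw relaxation record to the normalized viscous decay
    (P(t) − P_eq)/S_δ using the fitted equilibrium stress.

    When the short-term viscous constants and the ramp rate are known, the
    peak viscous stress S_δ is the model prediction at the hold stretch —
    robust to measurement noise on the single peak sample; otherwise the
    first (peak) sample's excess is used.
    """
    t = data.table["time_s"].to_numpy(dtype=float)
    lam = data.table["stretch"].to_numpy(dtype=float)
    P = data.table["P11_Pa"].to_numpy(dtype=float)
    P_eq, _ = uniaxial_components(lam, np.zeros_like(lam), params)
    excess = P - P_eq
    peak = 0.0
    if data.rate is not None and data.rate > 0.0:
        _, Sd = uniaxial_components(lam[:1], np.array([data.rate]), params)
        peak = float(Sd[0])
    if peak <= 0.0:
        peak = excess[0]
    if peak <= 0.0:
        raise ValueError("relaxation record has no viscous stress above equilibrium")
    return t - t[0], excess / peak


def staged_calibration(
    datasets: list[ExperimentDataset],
    tissue: str,
    seed: int = 0,
    n_starts: int = 8,
    n_terms: int = 3,
    vol_config: VolumetricConfig | None = None,
    short_term_rate: float | None = None,
    matrix_constant: float = 0.0,
) -> CalibrationResult:
    """Run the staged identification workflow for one tissue.

    Datasets are matched by ``kind`` (their order is irrelevant); a missing
    stage raises a ``ValueError`` naming the absent dataset kind. Fixed
    parameters are threaded forward between stages. For ligament,
    ``short_term_rate`` selects which ramp dataset calibrates the viscous
    stage (default: the one with rate closest to 0.25/s, the conventional
    calibration rate; faster ramps are left as predictions).
    """
    by_kind: dict[str, list[ExperimentDataset]] = {k: [] for k in _KINDS}
    for ds in datasets:
        by_kind[ds.kind].append(ds)

    def require(kind: str) -> ExperimentDataset:
        if not by_kind[kind]:
            raise ValueError(f"missing required dataset kind: {kind}")
        return by_kind[kind][0]

    stages: list[StageResult] = []
    log = {
        "seed": seed,
        "n_starts": n_starts,
        "n_terms": n_terms,
        "solver": "scipy.optimize.least_squares (trf, bounded)",
        "tolerances": {"xtol": 1e-14, "ftol": 1e-14, "gtol": 1e-14},
    }

    if tissue == "ligament":
        st_el = fit_elastic(require("equilibrium_tension"), "ligament", matrix_constant)
        stages.append(st_el)
        elastic = LigamentParams(
            a1=st_el.params["a1"], a2=st_el.params["a2"], a3=st_el.params["a3"]
        )

        ramps = by_kind["ramp_tension"]
        if not ramps:
            raise ValueError("missing required dataset kind: ramp_tension")
        want = short_term_rate if short_term_rate is not None else 0.25
        ramp = min(ramps, key=lambda d: abs((d.rate or 0.0) - want))
        st_visc = fit_short_term(ramp, elastic)
        stages.append(st_visc)
        params = LigamentParams(
            a1=elastic.a1,
            a2=elastic.a2,
            a3=elastic.a3,
            a4=st_visc.params["a4"],
            a5=st_visc.params["a5"],
        )
        log["short_term_rate"] = ramp.rate

        relax = require("relaxation")
        t, R = _normalized_relaxation(relax, params)
        spectrum, st_spec = fit_spectrum((t, R), n_terms=n_terms, seed=seed, n_starts=n_starts)
        stages.append(st_spec)

    elif tissue == "cartilage":
        st_cc = fit_confined_compression(require("confined_compression"), vol_config)
        stages.append(st_cc)
        b1 = st_cc.params["b1"]

        st_el = fit_elastic(require("equilibrium_tension"), "cartilage", b1)
        stages.append(st_el)
        elastic = CartilageParams(b1=b1, b2=st_el.params["b2"], b3=st_el.params["b3"])

        ramp = require("ramp_tension")
        t_max = ramp.metadata.get("first_ramp_end")
        st_visc = fit_short_term(ramp, elastic, t_max=t_max)
        stages.append(st_visc)
        params = CartilageParams(
            b1=b1, b2=elastic.b2, b3=elastic.b3, b4=st_visc.params["b4"]
        )

        relax = require("relaxation")
        t, R = _normalized_relaxation(relax, params)
        spectrum, st_spec = fit_spectrum((t, R), n_terms=n_terms, seed=seed, n_starts=n_starts)
        stages.append(st_spec)
    else:
        raise ValueError(f"unknown tissue {tissue!r}")

    converged = all(s.converged for s in stages)
    return CalibrationResult(
        tissue=tissue,
        params=params,
        spectrum=spectrum,
        stages=stages,
        converged=converged,
        log=log,
    )


def fitted_model(result: CalibrationResult) -> TissueModel:
    """TissueModel assembled from a calibration result."""
    return TissueModel(params=result.params, spectrum=result.spectrum)
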