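"""Synthetic experimental datasets with known ground truth.

The raw tissue curves behind the published parameter fits exist only as
figures, so every calibration stage is exercised against generated stand-ins
instead: the generator simulates the same test protocols with known
parameters, subsamples to realistic point counts and applies multiplicative
Gaussian noise (load-cell error scales with signal; an additive floor is
available for near-zero readings).

``reference_suite`` reproduces the test batteries the published fits used:

ligament
    near-equilibrium tensile curve to 16 % strain, constant-rate ramps at
    25/38/50 %/s to the same strain, and a ramp–relaxation record at 16 %
    stretch (relaxation truncated at 5·τ_max, emulating a finite
    experiment);
cartilage
    confined-compression equilibrium points, a 5-step 2 %-per-step tensile
    record at 0.15 %/s with full relaxation between steps, the tensile
    equilibrium point per step (the experiment holds until equilibrium is
    complete, so these carry the elastic values), and the first relaxation
    phase.

Identical seeds reproduce identical datasets.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .calibration import ExperimentDataset
from .materials import (
    CartilageParams,
    TissueModel,
    VolumetricConfig,
    confined_compression_equilibrium,
    reference_model,
    uniaxial_components,
)
from .protocol import LoadingProtocol, make_multistep, make_ramp_hold, simulate

__all__ = ["NoiseSpec", "generate_dataset", "confined_compression_dataset", "reference_suite"]

#: relaxation records are cut at this multiple of the slowest time constant
RELAXATION_TRUNCATION = 5.0


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative Gaussian measurement noise (+ optional additive floor)."""

    relative_sd: float = 0.02
    seed: int = 0
    floor_sd: float = 0.0  # Pa

    def __post_init__(self) -> None:
        if self.relative_sd < 0.0 or self.floor_sd < 0.0:
            raise ValueError("noise standard deviations must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        out = values * (1.0 + self.relative_sd * rng.standard_normal(values.shape))
        if self.floor_sd > 0.0:
            out = out + self.floor_sd * rng.standard_normal(values.shape)
        return out


def _subsample(n: int, k: int) -> np.ndarray:
    return np.unique(np.linspace(0, n - 1, min(k, n)).round().astype(int))


def _truth(model: TissueModel) -> dict:
    truth = {"params": asdict(model.params)}
    if model.spectrum is not None:
        truth["spectrum"] = {
            "tau_s": model.spectrum.tau.tolist(),
            "w": model.spectrum.w.tolist(),
        }
    return truth


def generate_dataset(
    model: TissueModel,
    protocol: LoadingProtocol,
    noise: NoiseSpec | None,
    kind: str,
    n_points: int = 120,
    rng: np.random.Generator | None = None,
    mode: str = "prony",
) -> ExperimentDataset:
    """Simulate a protocol and package one dataset of the requested kind.

    ``equilibrium_tension`` samples the elastic branch over the protocol's
    stretch range (a fully equilibrated experiment); ``ramp_tension``
    records the whole time series; ``relaxation`` keeps the record from the
    first handoff δ on (the δ sample itself is the peak).
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed if noise is not None else 0)
    meta = {"ground_truth": _truth(model), "kind": kind, "mode": mode}
    if kind == "equilibrium_tension":
        lam_knots = protocol.knot_stretches()
        lam = np.linspace(lam_knots.min(), lam_knots.max(), n_points)
        P, _ = uniaxial_components(lam, np.zeros_like(lam), model.params)
        if noise is not None:
            P = noise.apply(P, rng)
        table = pd.DataFrame({"stretch": lam, "P11_Pa": P})
        return ExperimentDataset(kind=kind, table=table, metadata=meta)

    series = simulate(model, protocol, mode=mode)
    rate = next((s.rate for s in protocol.segments if s.kind == "ramp"), None)
    if kind == "ramp_tension":
        idx = _subsample(series.t.size, n_points)
        ramp_ends = [
            float(te)
            for s, te in zip(protocol.segments, protocol.knot_times()[1:])
            if s.kind == "ramp"
        ]
        meta["first_ramp_end"] = ramp_ends[0] if ramp_ends else None
        meta["delta_events"] = list(series.delta_events)
    elif kind == "relaxation":
        if not series.delta_events:
            raise ValueError("relaxation dataset needs a protocol with a hold")
        delta = series.delta_events[0]
        i0 = series.index_at(delta)
        # end of the first hold (relaxation phase only)
        knot_t = protocol.knot_times()
        seg_after = next(
            i for i, s in enumerate(protocol.segments) if s.kind == "hold" and knot_t[i] >= delta - 1e-9
        )
        t_end = knot_t[seg_after + 1]
        i1 = int(np.searchsorted(series.t, t_end + 1e-9))
        idx = i0 + _subsample(i1 - i0, n_points)
        meta["delta"] = float(delta)
        meta["hold_stretch"] = float(series.lam[i0])
    else:
        raise ValueError(f"generate_dataset cannot build kind {kind!r}")

    P = series.P11_total[idx]
    if noise is not None:
        P = noise.apply(P, rng)
    table = pd.DataFrame(
        {"time_s": series.t[idx], "stretch": series.lam[idx], "P11_Pa": P}
    )
    return ExperimentDataset(
        kind=kind, table=table, rate=rate, metadata=meta
    )


def confined_compression_dataset(
    params: CartilageParams,
    noise: NoiseSpec | None = None,
    vol_config: VolumetricConfig | None = None,
    lam_range: tuple[float, float] = (0.85, 1.0),
    n_points: int = 12,
    rng: np.random.Generator | None = None,
) -> ExperimentDataset:
    """Equilibrium confined-compression stress–stretch points."""
    if rng is None:
        rng = np.random.default_rng(noise.seed if noise is not None else 0)
    vol = vol_config or VolumetricConfig()
    lam = np.linspace(lam_range[0], lam_range[1], n_points)
    P = np.asarray(confined_compression_equilibrium(lam, params, vol))
    if noise is not None:
        P = noise.apply(P, rng)
    table = pd.DataFrame({"stretch": lam, "P11_Pa": P})
    meta = {
        "ground_truth": {"params": asdict(params), "kappa": vol.effective_kappa(params.b1)},
        "kind": "confined_compression",
    }
    return ExperimentDataset(kind="confined_compression", table=table, metadata=meta)


def reference_suite(
    tissue: str,
    noise: NoiseSpec | None = None,
    model: TissueModel | None = None,
    vol_config: VolumetricConfig | None = None,
) -> list[ExperimentDataset]:
    """The stand-in experimental battery for one tissue (see module docs).

    With ``noise=None`` the curves are exact; all randomness flows from
    ``noise.seed`` through a single generator, so a suite regenerates
    identically for the same spec.
    """
    if model is None:
        model = reference_model(tissue)
    rng = np.random.default_rng(noise.seed if noise is not None else 0)
    tau_max = float(np.max(model.spectrum.tau))
    hold = RELAXATION_TRUNCATION * tau_max

    if tissue == "ligament":
        datasets = [
            generate_dataset(
                model, make_ramp_hold(0.16, 0.012, 0.0), noise,
                "equilibrium_tension", n_points=60, rng=rng,
            )
        ]
        for rate in (0.25, 0.38, 0.50):
            datasets.append(
                generate_dataset(
                    model, make_ramp_hold(0.16, rate, 0.0), noise,
                    "ramp_tension", n_points=120, rng=rng,
                )
            )
        datasets.append(
            generate_dataset(
                model, make_ramp_hold(0.16, 0.25, hold), noise,
                "relaxation", n_points=160, rng=rng,
            )
        )
        return datasets

    if tissue == "cartilage":
        protocol = make_multistep(5, 0.02, 0.0015, hold)
        cc = confined_compression_dataset(
            model.params, noise, vol_config, rng=rng
        )
        multistep = generate_dataset(
            model, protocol, noise, "ramp_tension", n_points=220, rng=rng
        )
        # fully equilibrated tensile points: origin + the 5 step stretches
        lam_steps = np.array([1.0 + 0.02 * k for k in range(6)])
        P_eq, _ = uniaxial_components(lam_steps, np.zeros_like(lam_steps), model.params)
        if noise is not None:
            P_eq = noise.apply(P_eq, rng)
        equilibrium = ExperimentDataset(
            kind="equilibrium_tension",
            table=pd.DataFrame({"stretch": lam_steps, "P11_Pa": P_eq}),
            metadata={"ground_truth": _truth(model), "kind": "equilibrium_tension"},
        )
        relaxation = generate_dataset(
            model, make_ramp_hold(0.02, 0.0015, hold), noise,
            "relaxation", n_points=160, rng=rng,
        )
        return [cc, multistep, equilibrium, relaxation]

    raise ValueError(f"unknown tissue {tissue!r}")
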