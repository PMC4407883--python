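"""Loading protocols and the uniaxial test simulator.

A :class:`LoadingProtocol` is an ordered list of constant-rate ramp and hold
segments defining a continuous piecewise-linear stretch history λ(t). The
simulator marches a tissue model through the protocol and reports the
decomposed nominal stress

    P11(t) = P11ᵉ(λ) + P11ˢᵛ(λ, λ̇) + P11ˡᵛ(t),

where the elastic and short-term viscous parts are algebraic in (λ, λ̇) and
the long-term part is the superposition of relaxation branches spawned at
every ramp→hold handoff (see :mod:`tissuevisco.history`). Because all three
parts have closed forms in time for piecewise-linear λ(t), the reported
stresses are exact at the sample instants — the sampling grid only controls
output resolution, not accuracy.

Stretch rates are absolute (1/s); strains are engineering strains ε = λ − 1
at the user-facing constructors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .history import RelaxationBranch, long_term_stress
from .materials import TissueModel, uniaxial_components, uniaxial_nominal_stress
from .kinematics import StretchPoint

__all__ = [
    "Segment",
    "LoadingProtocol",
    "StressSeries",
    "make_ramp_hold",
    "make_multistep",
    "relaxation_branches",
    "evaluate_protocol",
    "simulate",
    "normalize_to_peak",
    "peak_stress_ratio",
    "rate_sweep",
]

#: default maximum number of samples placed in one very long hold segment
HOLD_SAMPLE_CAP = 600
#: default maximum number of samples per ramp segment
RAMP_SAMPLE_CAP = 4000


@dataclass(frozen=True)
class Segment:
    """One protocol segment: a constant-rate ramp or a hold."""

    kind: str  # "ramp" | "hold"
    duration: float  # s
    rate: float = 0.0  # stretch rate 1/s, ramps only

    def __post_init__(self) -> None:
        if self.kind not in ("ramp", "hold"):
            raise ValueError(f"segment kind must be 'ramp' or 'hold', got {self.kind!r}")
        if not self.duration > 0.0:
            raise ValueError("segment duration must be positive")
        if self.kind == "hold" and self.rate != 0.0:
            raise ValueError("hold segments have zero rate")


@dataclass(frozen=True)
class LoadingProtocol:
    """Piecewise-linear stretch history λ(t) built from ramp/hold segments."""

    segments: tuple[Segment, ...]
    lam0: float = 1.0

    def __post_init__(self) -> None:
        segments = tuple(self.segments)
        if not segments:
            raise ValueError("protocol needs at least one segment")
        object.__setattr__(self, "segments", segments)
        if not self.lam0 > 0.0:
            raise ValueError("initial stretch must be positive")
        if np.any(np.asarray(self.knot_stretches()) <= 0.0):
            raise ValueError("protocol drives stretch non-positive")

    def knot_times(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum([s.duration for s in self.segments])])

    def knot_stretches(self) -> np.ndarray:
        lam = [self.lam0]
        for s in self.segments:
            lam.append(lam[-1] + (s.rate * s.duration if s.kind == "ramp" else 0.0))
        return np.asarray(lam)

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    def stretch_at(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.knot_times(), self.knot_stretches())

    def min_ramp_duration(self) -> float | None:
        durs = [s.duration for s in self.segments if s.kind == "ramp"]
        return min(durs) if durs else None


@dataclass(frozen=True)
class StressSeries:
    """Time-resolved decomposed nominal stress along a protocol."""

    t: np.ndarray
    lam: np.ndarray
    lamdot: np.ndarray
    P11_total: np.ndarray
    P11_elastic: np.ndarray
    P11_visc_short: np.ndarray
    P11_visc_long: np.ndarray
    delta_events: tuple[float, ...] = ()
    mode: str = "prony"

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.size > 1 and np.any(np.diff(t) <= 0.0):
            raise ValueError("time must be strictly increasing")
        comp_sum = self.P11_elastic + self.P11_visc_short + self.P11_visc_long
        scale = max(1.0, float(np.abs(self.P11_total).max(initial=0.0)))
        if np.abs(self.P11_total - comp_sum).max(initial=0.0) > 1e-9 * scale:
            raise ValueError("stress components do not sum to the total")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.t,
                "stretch": self.lam,
                "stretch_rate_per_s": self.lamdot,
                "P11_total_Pa": self.P11_total,
                "P11_elastic_Pa": self.P11_elastic,
                "P11_visc_short_Pa": self.P11_visc_short,
                "P11_visc_long_Pa": self.P11_visc_long,
            }
        )

    def index_at(self, time: float) -> int:
        i = int(np.argmin(np.abs(self.t - time)))
        return i

    @property
    def peak(self) -> float:
        return float(self.P11_total.max())


def make_ramp_hold(strain: float, rate: float, hold: float) -> LoadingProtocol:
    """Ramp to engineering strain at a constant stretch rate, then hold."""
    if not strain > 0.0:
        raise ValueError("strain must be positive")
    if not rate > 0.0:
        raise ValueError("rate must be positive")
    if hold < 0.0:
        raise ValueError("hold duration must be >= 0")
    segments = [Segment("ramp", strain / rate, rate)]
    if hold > 0.0:
        segments.append(Segment("hold", hold))
    return LoadingProtocol(tuple(segments))


def make_multistep(n: int, step_strain: float, rate: float, hold: float) -> LoadingProtocol:
    """n repetitions of (ramp by step_strain at rate, hold); cumulative
    strain n·step_strain."""
    if n < 1:
        raise ValueError("need at least one step")
    one = make_ramp_hold(step_strain, rate, hold)
    return LoadingProtocol(one.segments * n)


def _default_dt(protocol: LoadingProtocol, model: TissueModel) -> float:
    """Δt resolving both the fastest ramp and the fastest relaxation time."""
    candidates = []
    ramp = protocol.min_ramp_duration()
    if ramp is not None:
        candidates.append(ramp / 200.0)
    if model.spectrum is not None:
        candidates.append(float(np.min(model.spectrum.tau)) / 20.0)
    if not candidates:
        candidates.append(protocol.total_duration / 200.0)
    return min(candidates)


def _segment_times(t0: float, seg: Segment, dt: float, first: bool) -> np.ndarray:
    """Sample times for one segment (start point only for the first segment).

    Long holds get a hybrid linear+geometric grid so early relaxation is
    resolved without millions of samples; stresses are closed-form in t so
    this costs no accuracy.
    """
    n_policy = int(np.ceil(seg.duration / dt))
    if n_policy < 10:
        raise ValueError(
            f"dt policy yields {n_policy} samples for a {seg.duration} s segment; "
            "need at least 10"
        )
    if seg.kind == "ramp":
        n = min(max(n_policy, 50), RAMP_SAMPLE_CAP)
        local = np.linspace(0.0, seg.duration, n + 1)
    else:
        if n_policy <= HOLD_SAMPLE_CAP:
            local = np.linspace(0.0, seg.duration, n_policy + 1)
        else:
            head = np.linspace(0.0, dt * 10, 11)
            tail = np.geomspace(dt * 10, seg.duration, HOLD_SAMPLE_CAP)
            local = np.unique(np.concatenate([head, tail]))
    times = t0 + local
    return times if first else times[1:]


def relaxation_branches(model: TissueModel, protocol: LoadingProtocol) -> list[RelaxationBranch]:
    """Branches spawned by the protocol: one per ramp→hold handoff, carrying
    the ramp-end short-term viscous stress."""
    if model.spectrum is None:
        raise ValueError("model needs a relaxation spectrum")
    knot_t = protocol.knot_times()
    knot_lam = protocol.knot_stretches()
    branches = []
    for i, seg in enumerate(protocol.segments):
        next_is_hold = i + 1 < len(protocol.segments) and protocol.segments[i + 1].kind == "hold"
        if seg.kind == "ramp" and next_is_hold:
            lam_end = knot_lam[i + 1]
            S_delta = uniaxial_nominal_stress(
                StretchPoint(lam_end, seg.rate), model
            ) - uniaxial_nominal_stress(StretchPoint(lam_end, 0.0), model)
            branches.append(RelaxationBranch(float(knot_t[i + 1]), S_delta, model.spectrum))
    return branches


def evaluate_protocol(
    model: TissueModel,
    protocol: LoadingProtocol,
    times,
    mode: str = "prony",
) -> dict[str, np.ndarray]:
    """Closed-form decomposed stress at arbitrary times along a protocol.

    A time that falls exactly on a ramp→hold boundary is attributed to the
    ramp (short-term term active, its branch not yet); the prony total is
    continuous there either way.
    """
    if mode not in ("prony", "literal"):
        raise ValueError(f"unknown long-term mode {mode!r}")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0.0) or np.any(t > protocol.total_duration + 1e-9):
        raise ValueError("times fall outside the protocol")
    knot_t = protocol.knot_times()
    seg_idx = np.searchsorted(knot_t[1:], t, side="left")
    seg_idx = np.minimum(seg_idx, len(protocol.segments) - 1)
    rates = np.asarray([s.rate if s.kind == "ramp" else 0.0 for s in protocol.segments])
    lam = protocol.stretch_at(t)
    lamdot = rates[seg_idx]
    P_el, P_vs = uniaxial_components(lam, lamdot, model.params)
    has_hold = any(s.kind == "hold" for s in protocol.segments)
    if has_hold:
        branches = relaxation_branches(model, protocol)
        P_vl = np.asarray(long_term_stress(branches, t, mode=mode, inclusive=False))
    else:
        P_vl = np.zeros_like(t)
    return {
        "t": t,
        "lam": lam,
        "lamdot": lamdot,
        "P11_elastic": np.asarray(P_el, dtype=float),
        "P11_visc_short": P_vs,
        "P11_visc_long": P_vl,
        "P11_total": P_el + P_vs + P_vl,
    }


def simulate(
    model: TissueModel,
    protocol: LoadingProtocol,
    dt: float | None = None,
    mode: str = "prony",
) -> StressSeries:
    """March a tissue model through a protocol; return decomposed stress.

    Each ramp→hold handoff spawns a relaxation branch carrying the ramp-end
    short-term viscous stress; branches persist (and keep decaying) through
    any subsequent ramps. Holds require the model to carry a relaxation
    spectrum.
    """
    if mode not in ("prony", "literal"):
        raise ValueError(f"unknown long-term mode {mode!r}")
    has_hold = any(s.kind == "hold" for s in protocol.segments)
    if has_hold and model.spectrum is None:
        raise ValueError("protocol contains holds: model needs a relaxation spectrum")
    if dt is None:
        dt = _default_dt(protocol, model)
    if not dt > 0.0:
        raise ValueError("dt must be positive")

    knot_t = protocol.knot_times()
    t_parts = [
        _segment_times(knot_t[i], seg, dt, first=(i == 0))
        for i, seg in enumerate(protocol.segments)
    ]
    t = np.concatenate(t_parts)
    out = evaluate_protocol(model, protocol, t, mode=mode)
    deltas = [
        float(knot_t[i + 1])
        for i, seg in enumerate(protocol.segments)
        if seg.kind == "ramp"
        and i + 1 < len(protocol.segments)
        and protocol.segments[i + 1].kind == "hold"
    ]
    lam, lamdot = out["lam"], out["lamdot"]
    P_el, P_vs, P_vl = out["P11_elastic"], out["P11_visc_short"], out["P11_visc_long"]
    return StressSeries(
        t=t,
        lam=lam,
        lamdot=lamdot,
        P11_total=P_el + P_vs + P_vl,
        P11_elastic=P_el,
        P11_visc_short=P_vs,
        P11_visc_long=P_vl,
        delta_events=tuple(deltas),
        mode=mode,
    )


def normalize_to_peak(series: StressSeries) -> StressSeries:
    """Divide all stress columns by the total stress at the first handoff δ
    (the ramp-end peak), as relaxation data are conventionally reported."""
    if not series.delta_events:
        raise ValueError("series has no hold phase to normalize against")
    i = series.index_at(series.delta_events[0])
    peak = float(series.P11_total[i])
    if peak == 0.0:
        raise ValueError("peak stress is zero; cannot normalize")
    return replace(
        series,
        P11_total=series.P11_total / peak,
        P11_elastic=series.P11_elastic / peak,
        P11_visc_short=series.P11_visc_short / peak,
        P11_visc_long=series.P11_visc_long / peak,
    )


def rate_sweep(
    model: TissueModel,
    strain: float,
    rates: list[float],
    mode: str = "prony",
) -> pd.DataFrame:
    """Peak total stress per ramp rate at a fixed strain, normalized to the
    elastic equilibrium stress at that strain."""
    if not rates:
        raise ValueError("need at least one rate")
    P_eq = uniaxial_nominal_stress(StretchPoint(1.0 + strain, 0.0), model)
    rows = []
    for rate in rates:
        series = simulate(model, make_ramp_hold(strain, rate, hold=0.0), mode=mode)
        peak = series.peak
        rows.append(
            {
                "rate_per_s": rate,
                "peak_P11_Pa": peak,
                "normalized_peak": peak / P_eq if P_eq != 0.0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def qlv_rate_sweep(
    model: TissueModel,
    qlv,
    strain: float,
    rates: list[float],
) -> pd.DataFrame:
    """Equilibrium-normalized QLV peak stress per ramp rate.

    The QLV model convolves this tissue's elastic stress history with the
    reduced relaxation function of ``qlv`` (a :class:`~tissuevisco.history.QLVParams`);
    integration uses the exponential recurrence on a grid resolving both the
    ramp and the fastest QLV time constant.
    """
    from .history import qlv_stress

    if not rates:
        raise ValueError("need at least one rate")
    P_eq = uniaxial_nominal_stress(StretchPoint(1.0 + strain, 0.0), model)
    rows = []
    for rate in rates:
        duration = strain / rate
        n = max(400, int(np.ceil(duration / (float(np.min(qlv.tau)) / 50.0))))
        t = np.linspace(0.0, duration, min(n, 20000) + 1)
        lam = 1.0 + rate * t
        P_el, _ = uniaxial_components(lam, np.zeros_like(lam), model.params)
        total = qlv_stress(t, P_el, qlv)
        rows.append(
            {
                "rate_per_s": rate,
                "peak_P11_Pa": float(total.max()),
                "normalized_peak": float(total.max()) / P_eq if P_eq != 0.0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def peak_stress_ratio(
    model: TissueModel,
    strain: float,
    rates: list[float],
    normalization: str = "equilibrium",
) -> float:
    """max/min of equilibrium-normalized ramp peak stresses over the rates."""
    if normalization != "equilibrium":
        raise ValueError("only equilibrium normalization is supported")
    if len(rates) < 2:
        raise ValueError("need at least two rates")
    table = rate_sweep(model, strain, rates)
    peaks = table["normalized_peak"].to_numpy()
    return float(peaks.max() / peaks.min())
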