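"""File formats and provenance helpers.

CSV dialects (fixed headers, version-stable):

* equilibrium tension / confined compression: ``stretch,P11_Pa``
* ramp tension / relaxation: ``time_s,stretch,P11_Pa``
* simulated series: ``time_s,stretch,stretch_rate_per_s,P11_total_Pa,
  P11_elastic_Pa,P11_visc_short_Pa,P11_visc_long_Pa``

Floats are written with 17 significant digits so a write→read→write cycle
is byte-identical. Material parameter files are JSON or YAML with the
schema ``{tissue, a1..a5 | b1..b4, spectrum: {tau_s: [...], w: [...]}}``
(SI units: Pa, Pa·s, s).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import ExperimentDataset
from .history import RelaxationSpectrum
from .materials import CartilageParams, LigamentParams, TissueModel, load_reference_params

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_series",
    "load_material",
    "save_material",
    "file_sha256",
    "provenance",
]

_FLOAT_FMT = "%.17g"

_COLUMNS = {
    "equilibrium_tension": ["stretch", "P11_Pa"],
    "confined_compression": ["stretch", "P11_Pa"],
    "ramp_tension": ["time_s", "stretch", "P11_Pa"],
    "relaxation": ["time_s", "stretch", "P11_Pa"],
}


def write_dataset(ds: ExperimentDataset, path: str | Path) -> Path:
    """Write a dataset in its kind-specific CSV dialect."""
    path = Path(path)
    cols = _COLUMNS[ds.kind]
    missing = [c for c in cols if c not in ds.table]
    if missing:
        raise ValueError(f"dataset table lacks columns {missing}")
    ds.table[cols].to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_dataset(
    path: str | Path,
    kind: str,
    rate: float | None = None,
) -> ExperimentDataset:
    """Read a dataset CSV; schema mismatches report the offending columns.

    For ramp records with no explicit rate, the constant loading rate is
    inferred as the median positive stretch increment per unit time.
    """
    path = Path(path)
    table = pd.read_csv(path, float_precision="round_trip")
    expected = _COLUMNS[kind]
    missing = [c for c in expected if c not in table.columns]
    if missing:
        raise ValueError(
            f"{path.name}: schema mismatch for kind {kind!r}; missing columns {missing}"
        )
    if rate is None and kind == "ramp_tension":
        t = table["time_s"].to_numpy(dtype=float)
        lam = table["stretch"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            slopes = np.diff(lam) / np.diff(t)
        slopes = slopes[np.isfinite(slopes) & (slopes > 1e-12)]
        rate = float(np.median(slopes)) if slopes.size else None
    return ExperimentDataset(kind=kind, table=table[expected], rate=rate, metadata={"source": str(path)})


def write_series(series, path: str | Path) -> Path:
    """Write a simulated stress series CSV."""
    path = Path(path)
    series.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def load_material(source: str | Path) -> TissueModel:
    """Load a tissue model from a bundled name or a JSON/YAML file.

    ``source`` may be ``'ligament'`` / ``'cartilage'`` (the bundled
    literature parameter sets) or a path to a parameter file.
    """
    if str(source) in ("ligament", "cartilage"):
        params, spectrum = load_reference_params(str(source))
        return TissueModel(params=params, spectrum=spectrum)
    path = Path(source)
    text = path.read_text()
    raw = yaml.safe_load(text) if path.suffix.lower() in (".yml", ".yaml") else json.loads(text)
    tissue = raw.get("tissue")
    spectrum = None
    if raw.get("spectrum"):
        spectrum = RelaxationSpectrum.from_table(raw["spectrum"]["tau_s"], raw["spectrum"]["w"])
    if tissue == "ligament":
        params = LigamentParams(**{k: float(raw.get(k, 0.0)) for k in ("a1", "a2", "a3", "a4", "a5")})
    elif tissue == "cartilage":
        params = CartilageParams(**{k: float(raw.get(k, 0.0)) for k in ("b1", "b2", "b3", "b4")})
    else:
        raise ValueError(f"{path.name}: 'tissue' must be 'ligament' or 'cartilage'")
    return TissueModel(params=params, spectrum=spectrum)


def save_material(model: TissueModel, path: str | Path) -> Path:
    path = Path(path)
    payload = {"tissue": model.tissue, **asdict(model.params)}
    if model.spectrum is not None:
        payload["spectrum"] = {
            "tau_s": model.spectrum.tau.tolist(),
            "w": model.spectrum.w.tolist(),
        }
    if path.suffix.lower() in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def provenance(seed: int | None = None, mode: str | None = None, inputs: dict | None = None) -> dict:
    """Reproducibility trail embedded in every CLI output."""
    out: dict = {"package": "tissuevisco", "version": __version__}
    if seed is not None:
        out["seed"] = seed
    if mode is not None:
        out["mode"] = mode
    if inputs:
        out["input_hashes"] = {name: file_sha256(p) for name, p in inputs.items()}
    return out
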