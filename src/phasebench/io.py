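"""HDF5 / TIFF / CSV / JSON persistence for phantoms, fields and results."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .detector import Measurement
from .metrics import FRCCurve
from .optics import ComplexField
from .phantoms import Phantom
from .retrieval import RAARConfig, ReconstructionResult

__all__ = [
    "save_phantom", "load_phantom",
    "save_measurement", "load_measurement",
    "save_field", "load_field",
    "save_reconstruction",
    "export_tiff", "frc_to_csv", "save_json",
]


def save_phantom(path, phantom: Phantom) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("phase", data=phantom.phase, compression="gzip")
        f.create_dataset("support", data=phantom.support, compression="gzip")
        f.attrs["kind"] = phantom.kind
        f.attrs["seed"] = phantom.seed
        f.attrs["block_size"] = phantom.block_size
        f.attrs["bit_values"] = phantom.bit_values
        f.attrs["meta"] = json.dumps(phantom.meta)


def load_phantom(path) -> Phantom:
    with h5py.File(path, "r") as f:
        return Phantom(
            phase=f["phase"][()],
            support=f["support"][()].astype(bool),
            kind=str(f.attrs["kind"]),
            seed=int(f.attrs["seed"]),
            block_size=int(f.attrs["block_size"]),
            bit_values=tuple(f.attrs["bit_values"]),
            meta=json.loads(f.attrs.get("meta", "{}")),
        )


def save_measurement(path, m: Measurement, **extra_attrs) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=m.counts, compression="gzip")
        f.attrs["noisy"] = m.noisy
        if m.regime is not None:
            f.attrs["regime"] = m.regime
        if m.fluence is not None:
            f.attrs["fluence"] = m.fluence
        if m.seed is not None:
            f.attrs["seed"] = m.seed
        for k, v in extra_attrs.items():
            f.attrs[k] = v


def load_measurement(path) -> Measurement:
    with h5py.File(path, "r") as f:
        return Measurement(
            counts=f["counts"][()],
            regime=str(f.attrs["regime"]) if "regime" in f.attrs else None,
            fluence=float(f.attrs["fluence"]) if "fluence" in f.attrs else None,
            noisy=bool(f.attrs["noisy"]),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )


def save_field(path, field: ComplexField, **extra_attrs) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=field.values, compression="gzip")
        f.attrs["plane"] = field.plane
        if field.regime is not None:
            f.attrs["regime"] = field.regime
        for k, v in extra_attrs.items():
            f.attrs[k] = v


def load_field(path) -> ComplexField:
    with h5py.File(path, "r") as f:
        return ComplexField(
            values=f["values"][()],
            plane=str(f.attrs["plane"]),
            regime=str(f.attrs["regime"]) if "regime" in f.attrs else None,
        )


def save_reconstruction(path, result: ReconstructionResult) -> None:
    cfg = result.config
    with h5py.File(path, "w") as f:
        f.create_dataset("field_after_pm", data=result.field_after_pm.values,
                         compression="gzip")
        f.create_dataset("field_after_ps", data=result.field_after_ps.values,
                         compression="gzip")
        f.create_dataset("betas", data=result.betas)
        f.create_dataset("residuals", data=result.residuals)
        f.attrs["regime"] = result.regime
        if result.fresnel_number is not None:
            f.attrs["fresnel_number"] = result.fresnel_number
        for key in ("beta0", "beta_max", "beta_switch", "n_iter", "binary"):
            f.attrs[key] = getattr(cfg, key)
        if cfg.seed is not None:
            f.attrs["seed"] = cfg.seed


def export_tiff(path, array: np.ndarray, dtype=np.float32) -> None:
    """Write a real array as a single-page TIFF (inspection export)."""
    tifffile.imwrite(path, np.asarray(array).astype(dtype))


def frc_to_csv(path, curve: FRCCurve) -> None:
    pd.DataFrame({
        "freq": curve.freq,
        "corr": curve.corr,
        "threshold": curve.threshold,
        "ring_pixel_count": curve.ring_pixel_counts,
    }).to_csv(path, index=False)


def save_json(path, obj: dict) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
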