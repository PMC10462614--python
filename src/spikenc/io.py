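"""File I/O and model persistence.

Conventions: trial order equals lexicographic filename order for image
directories; response matrices are comma-separated UTF-8 text with a
mandatory header row of voxel ids (or HDF5 with ``values``/``voxel_ids``
datasets); models are stored in HDF5 with a format-version tag.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .encoding import EncodingModel, ResponseMatrix, VoxelModel
from .errors import DataError, FormatError, IntegrityError
from .frontend import (
    DoGFilterBank,
    DoGKernel,
    ImageStimulus,
    dog_kernel,
    preprocess_image,
)
from .scnn import IFConvLayer

__all__ = [
    "load_image_dir",
    "load_response_matrix",
    "save_response_matrix",
    "save_layer",
    "load_layer",
    "save_model",
    "load_model",
]

_RASTER_SUFFIXES = {".png", ".tif", ".tiff", ".bmp"}
_LAYER_VERSION = "spikenc-scnn-1"
_MODEL_VERSION = "spikenc-encmodel-1"


def load_image_dir(path, target_size: tuple[int, int]) -> list[ImageStimulus]:
    """Load every raster in a directory, in lexicographic filename order."""
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"image directory {root} does not exist")
    files = sorted(
        p for p in root.iterdir() if p.suffix.lower() in _RASTER_SUFFIXES
    )
    images = []
    for p in files:
        try:
            images.append(preprocess_image(p, target_size))
        except Exception as exc:
            raise FormatError(f"unreadable raster {p.name}: {exc}") from exc
    return images


def load_response_matrix(path, n_expected_trials: int | None = None) -> ResponseMatrix:
    """Load a trials-by-voxels response matrix from CSV or HDF5."""
    p = Path(path)
    if p.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(p, "r") as f:
            values = np.asarray(f["values"])
            ids = [s.decode() if isinstance(s, bytes) else str(s)
                   for s in f["voxel_ids"][()]]
    else:
        df = pd.read_csv(p, float_precision="round_trip")
        ids = [str(c) for c in df.columns]
        values = df.to_numpy(dtype=float)
    bad = [ids[c] for c in np.nonzero(~np.isfinite(values).all(axis=0))[0]]
    if bad:
        raise DataError(f"non-finite responses in voxels: {bad}")
    if n_expected_trials is not None and values.shape[0] != n_expected_trials:
        raise DataError(
            f"{values.shape[0]} trials in {p.name}, expected {n_expected_trials}"
        )
    return ResponseMatrix(values, voxel_ids=ids)


def save_response_matrix(rm: ResponseMatrix, path) -> None:
    """Write a response matrix as CSV (``.csv``) or HDF5 (``.h5``)."""
    p = Path(path)
    if p.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(p, "w") as f:
            f.create_dataset("values", data=rm.values, track_times=False)
            f.create_dataset(
                "voxel_ids", data=np.array(rm.voxel_ids, dtype="S"),
                track_times=False,
            )
    else:
        pd.DataFrame(rm.values, columns=rm.voxel_ids).to_csv(p, index=False)


def _write_layer(group: h5py.Group, layer: IFConvLayer) -> None:
    group.create_dataset("weights", data=layer.weights, track_times=False)
    group.attrs["v_th"] = layer.v_th
    group.attrs["pad"] = layer.pad


def _read_layer(group: h5py.Group) -> IFConvLayer:
    return IFConvLayer(
        np.asarray(group["weights"]),
        v_th=float(group.attrs["v_th"]),
        pad=int(group.attrs["pad"]),
    )


def save_layer(layer: IFConvLayer, path, config: dict | None = None) -> None:
    """Serialize an IF convolutional layer to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _LAYER_VERSION
        _write_layer(f, layer)
        if config is not None:
            f.attrs["config"] = json.dumps(config)


def load_layer(path) -> tuple[IFConvLayer, dict]:
    """Load an IF convolutional layer (and its stored config) from HDF5."""
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("format_version") != _LAYER_VERSION:
                raise IntegrityError(
                    f"{path}: not a spikenc layer file (bad version tag)"
                )
            layer = _read_layer(f)
            config = json.loads(f.attrs.get("config", "{}"))
    except (OSError, KeyError) as exc:
        raise IntegrityError(f"cannot read layer file {path}: {exc}") from exc
    return layer, config


def _write_bank(group: h5py.Group, bank: DoGFilterBank) -> None:
    group.attrs["pad"] = bank.pad
    group.attrs["common_window"] = bank.common_window
    group.attrs["spike_threshold"] = bank.spike_threshold
    group.create_dataset("sizes", data=[k.size for k in bank.kernels], track_times=False)
    group.create_dataset(
        "sigmas", data=[list(k.sigmas) for k in bank.kernels], track_times=False
    )
    group.create_dataset(
        "polarities",
        data=np.array([k.polarity for k in bank.kernels], dtype="S"),
        track_times=False,
    )


def _read_bank(group: h5py.Group) -> DoGFilterBank:
    sizes = np.asarray(group["sizes"])
    sigmas = np.asarray(group["sigmas"])
    pols = [s.decode() for s in group["polarities"][()]]
    kernels = []
    for size, (s1, s2), pol in zip(sizes, sigmas, pols):
        k = dog_kernel(int(size), float(s1), float(s2))
        if pol == "OFF":
            k = -k
        kernels.append(DoGKernel(k, pol, int(size), (float(s1), float(s2))))
    return DoGFilterBank(
        kernels,
        common_window=int(group.attrs["common_window"]),
        pad=int(group.attrs["pad"]),
        spike_threshold=float(group.attrs["spike_threshold"]),
    )


def save_model(model: EncodingModel, path) -> None:
    """Serialize a complete encoding model to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _MODEL_VERSION
        f.attrs["T"] = model.T
        if model.preset is not None:
            f.attrs["preset"] = model.preset
        _write_layer(f.create_group("scnn"), model.layer)
        _write_bank(f.create_group("frontend"), model.bank)
        g = f.create_group("voxels")
        g.create_dataset(
            "ids",
            data=np.array([vm.voxel_id for vm in model.voxel_models], dtype="S"),
            track_times=False,
        )
        g.create_dataset(
            "rf",
            data=np.array([vm.rf_location for vm in model.voxel_models], dtype=int),
            track_times=False,
        )
        g.create_dataset(
            "weights",
            data=np.array([vm.weights for vm in model.voxel_models]),
            track_times=False,
        )
        g.create_dataset(
            "intercept",
            data=np.array([vm.intercept for vm in model.voxel_models]),
            track_times=False,
        )
        g.create_dataset(
            "cv_r2",
            data=np.array([vm.cv_r2 for vm in model.voxel_models]),
            track_times=False,
        )
        if model.noise_cov is not None:
            f.create_dataset("noise_cov", data=model.noise_cov, track_times=False)


def load_model(path) -> EncodingModel:
    """Load an encoding model saved by :func:`save_model`.

    ``load(save(m))`` reproduces predictions bit-exactly.
    """
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("format_version") != _MODEL_VERSION:
                raise IntegrityError(
                    f"{path}: not a spikenc model file (bad version tag)"
                )
            layer = _read_layer(f["scnn"])
            bank = _read_bank(f["frontend"])
            g = f["voxels"]
            ids = [s.decode() for s in g["ids"][()]]
            rf = np.asarray(g["rf"])
            weights = np.asarray(g["weights"])
            intercepts = np.asarray(g["intercept"])
            cv_r2 = np.asarray(g["cv_r2"])
            vms = [
                VoxelModel(
                    ids[v],
                    (int(rf[v, 0]), int(rf[v, 1])),
                    weights[v],
                    float(intercepts[v]),
                    float(cv_r2[v]),
                )
                for v in range(len(ids))
            ]
            noise_cov = (
                np.asarray(f["noise_cov"]) if "noise_cov" in f else None
            )
            preset = f.attrs.get("preset")
            return EncodingModel(
                bank, layer, vms, T=int(f.attrs["T"]),
                noise_cov=noise_cov,
                preset=str(preset) if preset is not None else None,
            )
    except (OSError, KeyError) as exc:
        raise IntegrityError(f"cannot read model file {path}: {exc}") from exc
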