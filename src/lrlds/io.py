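"""Readers and writers for epoch containers and serialized artifacts.

The canonical epoch container is a single HDF5 file with datasets ``data``
(trials x channels x samples), ``labels``, ``fs`` and ``channel_names``
plus a ``schema_version`` and a JSON provenance attribute; round trips are
bit-exact.  A plain-text fallback dialect stores one CSV per trial next to
a JSON manifest.  EDF/EDF+ recordings import through MNE, with epochs cut
on annotation events using half-open, 0-based sample windows.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .epochs import EpochSet
from .lds import LDSModel
from .lowrank import DecompositionResult
from .metrics import DistanceMatrix

SCHEMA_VERSION = "1"

# h5py tracks modification times by default, which breaks bit-identical
# re-runs; every dataset here is created with track_times=False.
_H5_OPTS = {"track_times": False}


def _is_hdf5(path: Path) -> bool:
    return path.suffix.lower() in (".h5", ".hdf5", ".hdf")


def write_epochs(epochs: EpochSet, path: str | Path) -> Path:
    """Write an epoch container; HDF5 for ``.h5``-like suffixes, otherwise
    the CSV + JSON manifest dialect (``path`` is the manifest file)."""
    path = Path(path)
    if _is_hdf5(path):
        with h5py.File(path, "w", track_order=True) as f:
            f.create_dataset("data", data=epochs.data, **_H5_OPTS)
            f.create_dataset("labels", data=epochs.labels, **_H5_OPTS)
            f.create_dataset("fs", data=float(epochs.fs), **_H5_OPTS)
            f.create_dataset(
                "channel_names",
                data=np.array(epochs.channel_names, dtype="S"),
                **_H5_OPTS,
            )
            f.attrs["schema_version"] = SCHEMA_VERSION
            f.attrs["provenance"] = json.dumps(
                _jsonable(epochs.meta), sort_keys=True
            )
        return path
    return _write_csv_dialect(epochs, path)


def read_epochs(path: str | Path) -> EpochSet:
    """Read an epoch container in either dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_hdf5(path):
        with h5py.File(path, "r") as f:
            for key in ("data", "labels", "fs", "channel_names"):
                if key not in f:
                    raise ValueError(f"epoch container missing dataset '{key}'")
            if "schema_version" not in f.attrs:
                raise ValueError("epoch container missing 'schema_version'")
            version = str(f.attrs["schema_version"])
            if version != SCHEMA_VERSION:
                raise ValueError(
                    f"unknown schema_version {version!r}; expected {SCHEMA_VERSION!r}"
                )
            meta = json.loads(f.attrs.get("provenance", "{}"))
            return EpochSet(
                data=f["data"][()],
                labels=f["labels"][()],
                fs=float(f["fs"][()]),
                channel_names=[s.decode() for s in f["channel_names"][()]],
                meta=meta,
            )
    return _read_csv_dialect(path)


def _write_csv_dialect(epochs: EpochSet, manifest_path: Path) -> Path:
    directory = manifest_path.parent
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for i in range(epochs.n_trials):
        name = f"trial_{i:04d}.csv"
        # 17 significant digits round-trips float64 exactly
        np.savetxt(directory / name, epochs.data[i], delimiter=",", fmt="%.17g")
        files.append(name)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "fs": float(epochs.fs),
        "labels": epochs.labels.tolist(),
        "channel_names": list(epochs.channel_names),
        "files": files,
        "provenance": _jsonable(epochs.meta),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path


def _read_csv_dialect(manifest_path: Path) -> EpochSet:
    manifest = json.loads(manifest_path.read_text())
    for key in ("schema_version", "fs", "labels", "channel_names", "files"):
        if key not in manifest:
            raise ValueError(f"manifest missing field '{key}'")
    if str(manifest["schema_version"]) != SCHEMA_VERSION:
        raise ValueError(
            f"unknown schema_version {manifest['schema_version']!r}"
        )
    if len(manifest["labels"]) != len(manifest["files"]):
        raise ValueError(
            "manifest field 'labels' has "
            f"{len(manifest['labels'])} entries for {len(manifest['files'])} trials"
        )
    trials = [
        np.atleast_2d(np.loadtxt(manifest_path.parent / name, delimiter=","))
        for name in manifest["files"]
    ]
    shapes = {t.shape for t in trials}
    if len(shapes) > 1:
        raise ValueError(f"trial files have inconsistent shapes: {sorted(shapes)}")
    return EpochSet(
        data=np.stack(trials) if trials else np.empty((0, 0, 0)),
        labels=np.asarray(manifest["labels"], dtype=int),
        fs=float(manifest["fs"]),
        channel_names=list(manifest["channel_names"]),
        meta=manifest.get("provenance", {}),
    )


def import_edf(
    path: str | Path,
    channel_subset: list[str] | None = None,
    t_start: float = 0.5,
    t_end: float = 3.0,
    event_codes: list[str] | None = None,
) -> EpochSet:
    """Epoch an EDF/EDF+ recording on its annotation events.

    Windows are half-open ``[t_start, t_end)`` in seconds relative to each
    matching event onset, cut with 0-based sample indexing, so a window of
    2.5 s at 100 Hz yields exactly 250 samples.  ``event_codes`` selects
    annotation descriptions (all annotations when omitted); labels are the
    index of each event's description in the sorted code list.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    available = list(raw.ch_names)
    if channel_subset is not None:
        missing = [ch for ch in channel_subset if ch not in available]
        if missing:
            raise ValueError(
                f"channels {missing} absent from recording; available: {available}"
            )
        raw.pick(channel_subset)
    fs = float(raw.info["sfreq"])

    ann = raw.annotations
    descriptions = sorted(set(ann.description))
    codes = sorted(event_codes) if event_codes else descriptions
    onsets = [
        (on, codes.index(desc))
        for on, desc in zip(ann.onset, ann.description)
        if desc in codes
    ]
    if not onsets:
        raise ValueError(
            f"no annotations matching {codes}; found descriptions: {descriptions}"
        )
    n_samp = int(round((t_end - t_start) * fs))
    sig = raw.get_data()
    trials, labels = [], []
    for onset, label in onsets:
        start = int(round(onset * fs)) + int(round(t_start * fs))
        stop = start + n_samp
        if start < 0 or stop > sig.shape[1]:
            raise ValueError(
                f"epoch [{start}, {stop}) exceeds recording length {sig.shape[1]}"
            )
        trials.append(sig[:, start:stop])
        labels.append(label)
    return EpochSet(
        data=np.stack(trials), labels=np.asarray(labels), fs=fs,
        channel_names=list(raw.ch_names),
        meta={"source": str(path), "t_start": t_start, "t_end": t_end,
              "event_codes": codes},
    )


def write_model(model: LDSModel, path: str | Path, *, group: str | None = None,
                extra_attrs: dict | None = None) -> Path:
    """Serialize a fitted model: datasets A, C, ybar, singular_values plus a
    JSON attribute block (state dim, source trial, package version)."""
    from . import __version__

    path = Path(path)
    mode = "a" if group else "w"
    with h5py.File(path, mode, track_order=True) as f:
        g = f.require_group(group) if group else f
        for name, arr in (("A", model.A), ("C", model.C), ("ybar", model.ybar),
                          ("singular_values", model.singular_values)):
            if name in g:
                del g[name]
            g.create_dataset(name, data=np.asarray(arr), **_H5_OPTS)
        attrs = {
            "n": model.n, "m": model.m,
            "source_trial": model.meta.get("trial"),
            "label": model.meta.get("label"),
            "package_version": __version__,
        }
        attrs.update(extra_attrs or {})
        g.attrs["model_json"] = json.dumps(_jsonable(attrs), sort_keys=True)
    return path


def read_model(path: str | Path, *, group: str | None = None) -> LDSModel:
    with h5py.File(path, "r") as f:
        g = f[group] if group else f
        attrs = json.loads(g.attrs["model_json"])
        model = LDSModel(
            A=g["A"][()], C=g["C"][()], ybar=g["ybar"][()],
            states=np.zeros((g["A"].shape[0], 0)),
            singular_values=g["singular_values"][()],
            meta={"trial": attrs.get("source_trial"), "label": attrs.get("label")},
        )
    return model


def write_decomposition(
    result: DecompositionResult, path: str | Path, *, group: str | None = None
) -> Path:
    """Serialize decomposition components with a JSON diagnostics block."""
    path = Path(path)
    mode = "a" if group else "w"
    with h5py.File(path, mode, track_order=True) as f:
        g = f.require_group(group) if group else f
        g.create_dataset("lowrank", data=result.lowrank, **_H5_OPTS)
        g.create_dataset("sparse", data=result.sparse, **_H5_OPTS)
        if result.common is not None:
            g.create_dataset("common", data=result.common, **_H5_OPTS)
        g.attrs["diagnostics_json"] = json.dumps(
            decomposition_diagnostics(result), sort_keys=True
        )
    return path


def decomposition_diagnostics(result: DecompositionResult) -> dict:
    return _jsonable({
        "iterations": result.iterations,
        "converged": result.converged,
        "final_residual": result.final_residual,
        "rank_lowrank": result.rank_lowrank,
        "sparsity_fraction": result.sparsity_fraction,
        "params": result.params,
    })


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> Path:
    """Square CSV with item ids as header row/column + JSON params sidecar."""
    path = Path(path)
    ids = [str(i) for i in dm.item_ids]
    pd.DataFrame(dm.values, index=ids, columns=ids).to_csv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        {"metric_name": dm.metric_name, "params": _jsonable(dm.params)},
        indent=2, sort_keys=True,
    ))
    return path


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    path = Path(path)
    frame = pd.read_csv(path, index_col=0)
    sidecar = path.with_suffix(path.suffix + ".json")
    info = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return DistanceMatrix(
        values=frame.to_numpy(dtype=float),
        item_ids=list(frame.index),
        metric_name=info.get("metric_name", "unknown"),
        params=info.get("params", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
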