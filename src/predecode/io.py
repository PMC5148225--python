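"""Readers and writers for the package's matrix containers.

HDF5 is the primary on-disk format: each container is a file with one or
more 2-D datasets ("S" for stimuli/observations, "R" for responses,
"L"/"P"/"F" for detector traces, "Q"/"q0" for predictive fields) and
``dt`` (seconds) plus optional ``channels`` (Hz) stored as root
attributes.  Small matrices can round-trip through CSV, where the
metadata lives in ``#``-prefixed header comments.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .generative import ReceptorObservations, Spectrogram
from .inference import DetectorTrace


class SchemaError(ValueError):
    """A container file is missing a required dataset or attribute."""


def write_matrix_container(
    path,
    matrices: dict[str, np.ndarray],
    dt: float,
    channels: np.ndarray | None = None,
    attrs: dict | None = None,
) -> None:
    """Write named 2-D matrices with shared metadata to one HDF5 file."""
    with h5py.File(path, "w") as f:
        for name, mat in matrices.items():
            f.create_dataset(name, data=np.asarray(mat))
        f.attrs["dt"] = float(dt)
        if channels is not None:
            f.attrs["channels"] = np.asarray(channels, dtype=float)
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def read_matrix_container(path) -> tuple[dict[str, np.ndarray], dict]:
    """Read every dataset and the metadata from an HDF5 or CSV container.

    Raises :class:`SchemaError` naming the missing attribute when the
    file lacks ``dt``.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_csv(path)
    with h5py.File(path, "r") as f:
        mats = {k: f[k][()] for k in f.keys()}
        meta = dict(f.attrs)
    if "dt" not in meta:
        raise SchemaError(f"{path}: missing required attribute 'dt'")
    return mats, meta


def write_csv(path, matrix: np.ndarray, dt: float, channels=None, name: str = "S") -> None:
    """CSV fallback for small matrices (rows = channels, cols = bins)."""
    matrix = np.asarray(matrix)
    if matrix.size > 1_000_000:
        raise ValueError("CSV fallback limited to 1e6 cells; use HDF5")
    with open(path, "w") as fh:
        fh.write(f"# name={name}\n# dt={dt!r}\n")
        if channels is not None:
            fh.write("# channels=" + ",".join(f"{c!r}" for c in channels) + "\n")
        np.savetxt(fh, matrix, delimiter=",")


def _read_csv(path: Path) -> tuple[dict[str, np.ndarray], dict]:
    meta: dict = {}
    name = "S"
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            key = key.strip()
            if key == "dt":
                meta["dt"] = float(val)
            elif key == "channels":
                meta["channels"] = np.array([float(v) for v in val.split(",")])
            elif key == "name":
                name = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        mat = np.loadtxt(fh, delimiter=",", ndmin=2)
    if "dt" not in meta:
        raise SchemaError(f"{path}: missing required attribute 'dt'")
    return {name: mat}, meta


# ---------------------------------------------------------------- typed helpers

def save_spectrogram(path, spec: Spectrogram) -> None:
    write_matrix_container(path, {"S": spec.S}, spec.dt, channels=spec.channels)


def load_spectrogram(path) -> Spectrogram:
    mats, meta = read_matrix_container(path)
    if "S" not in mats:
        raise SchemaError(f"{path}: missing dataset 'S'")
    channels = meta.get("channels")
    if channels is None:
        from .generative import log_spaced_channels

        channels = log_spaced_channels(mats["S"].shape[0])
    return Spectrogram(S=mats["S"], dt=float(meta["dt"]), channels=channels)


def save_observations(path, obs: ReceptorObservations) -> None:
    write_matrix_container(path, {"S": obs.S}, obs.dt)


def load_observations(path) -> ReceptorObservations:
    mats, meta = read_matrix_container(path)
    key = "S" if "S" in mats else "R" if "R" in mats else None
    if key is None:
        raise SchemaError(f"{path}: missing dataset 'S' (or 'R')")
    return ReceptorObservations(S=mats[key], dt=float(meta["dt"]))


def save_trace(path, trace: DetectorTrace) -> None:
    write_matrix_container(
        path, {"L": trace.L, "P": trace.P, "F": trace.F}, trace.dt
    )


def load_trace(path) -> DetectorTrace:
    mats, meta = read_matrix_container(path)
    for key in ("L", "P", "F"):
        if key not in mats:
            raise SchemaError(f"{path}: missing dataset {key!r}")
    return DetectorTrace(
        L=mats["L"], P=mats["P"], F=mats["F"], dt=float(meta["dt"])
    )


def save_pfs(path, Q: np.ndarray, q0: np.ndarray, dt: float = 0.01, **attrs) -> None:
    """Write a predictive-field matrix with provenance attributes."""
    write_matrix_container(
        path, {"Q": Q, "q0": np.atleast_2d(q0)}, dt, attrs=attrs
    )


def load_pfs(path) -> tuple[np.ndarray, np.ndarray, dict]:
    mats, meta = read_matrix_container(path)
    if "Q" not in mats:
        raise SchemaError(f"{path}: missing dataset 'Q'")
    q0 = mats.get("q0")
    if q0 is None:
        q0 = np.full(mats["Q"].shape[0], 1e-6)
    return mats["Q"], np.asarray(q0).ravel(), meta
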