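"""File formats and in-memory containers.

Supported on disk:

* BrainVision triads (``.vhdr``/``.vmrk``/``.eeg``) — multiplexed binary,
  IEEE float32 or int16 with resolution scaling.  Reading delegates to
  :mod:`mne` after the header triad has been validated; a small writer
  covers the same two dialects for fixture generation and export.
* FreeSurfer per-vertex overlays ("curv" format, via nibabel) and plain
  text vectors for fMRI statistic maps; FreeSurfer surface geometry for
  source spaces.
* A documented internal matrix container: binary dialect (JSON header +
  little-endian float64, bit-exact round trips) and a delimited-text
  dialect for human inspection.  Binary is canonical.
* A single-file source-estimate format (JSON metadata + float64 block).

Unit contract: EEG amplitudes are microvolts end-to-end, dipole moments
nA·m, lead fields µV/(nA·m); loading never silently rescales.  The
FreeSurfer curv overlay stores float32, so bit-exact round-trips through
it hold for float32-representable statistics; float64-exact storage goes
through the matrix container or text vectors.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import nibabel.freesurfer.io as fsio

from .forward_model import SourceSpace, adjacency_from_faces

__all__ = [
    "EEGEpochs",
    "MatrixContainer",
    "read_brainvision",
    "write_brainvision",
    "read_matrix",
    "write_matrix",
    "read_stat_overlay",
    "write_stat_overlay",
    "read_source_estimate",
    "write_source_estimate",
    "read_surface_source_space",
    "write_surface_source_space",
    "read_electrode_positions",
    "write_electrode_positions",
]

_MATRIX_MAGIC = b"MXC1\n"
_ESTIMATE_MAGIC = b"STSE1\n"
_TEXT_SUFFIXES = {".txt", ".csv", ".tsv", ".vec", ".dat"}


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclasses.dataclass
class EEGEpochs:
    """Epoched (or continuous, n_epochs=1) multichannel EEG in microvolts.

    ``t0`` is the time of the first sample in seconds relative to
    stimulus onset (negative for pre-stimulus baseline).
    """

    data: np.ndarray          # (n_epochs, m, d), µV
    sfreq: float
    t0: float
    channel_names: list[str]
    condition: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[np.newaxis]
        if self.data.ndim != 3:
            raise ValueError("data must be (n_epochs, channels, samples)")
        n, m, d = self.data.shape
        if m < 2 or d < 1:
            raise ValueError("need at least 2 channels and 1 sample")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if len(self.channel_names) != m:
            raise ValueError("channel_names length must equal channel count")
        if len(set(self.channel_names)) != m:
            raise ValueError("channel names must be unique")
        if len(self.condition) != n:
            raise ValueError("one condition label per epoch required")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data contains non-finite values")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sfreq


@dataclasses.dataclass
class MatrixContainer:
    """Named matrix with row/column semantics (internal plumbing format)."""

    name: str
    values: np.ndarray
    row_semantics: str = ""
    col_semantics: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


# --------------------------------------------------------------------------
# internal matrix container
# --------------------------------------------------------------------------

def write_matrix(mat: MatrixContainer, path, dialect: str = "binary") -> None:
    """Write the container; ``binary`` (canonical, bit-exact) or ``text``."""
    path = Path(path)
    header = {
        "name": mat.name,
        "shape": list(mat.shape),
        "row_semantics": mat.row_semantics,
        "col_semantics": mat.col_semantics,
        "dtype": "<f8",
    }
    if dialect == "binary":
        with open(path, "wb") as fh:
            fh.write(_MATRIX_MAGIC)
            fh.write((json.dumps(header) + "\n").encode("utf-8"))
            fh.write(np.ascontiguousarray(mat.values, dtype="<f8").tobytes())
    elif dialect == "text":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# " + json.dumps(header) + "\n")
            np.savetxt(fh, mat.values, fmt="%.17g", delimiter="\t")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_matrix(path) -> MatrixContainer:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(len(_MATRIX_MAGIC))
        if magic == _MATRIX_MAGIC:
            header = json.loads(fh.readline().decode("utf-8"))
            shape = tuple(header["shape"])
            values = np.frombuffer(fh.read(), dtype="<f8").reshape(shape).copy()
        else:
            fh.seek(0)
            first = fh.readline().decode("utf-8")
            if not first.startswith("# "):
                raise ValueError(f"{path} is not a matrix container")
            header = json.loads(first[2:])
            values = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return MatrixContainer(
        name=header["name"],
        values=values,
        row_semantics=header.get("row_semantics", ""),
        col_semantics=header.get("col_semantics", ""),
    )


# --------------------------------------------------------------------------
# BrainVision
# --------------------------------------------------------------------------

_SUPPORTED_BV_FORMATS = {"IEEE_FLOAT_32", "INT_16"}


def _parse_vhdr(header_path: Path) -> dict:
    text = header_path.read_text(encoding="utf-8", errors="replace")
    fields: dict[str, str] = {}
    resolutions: dict[int, float] = {}
    names: dict[int, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if "=" not in line or line.startswith(";"):
            continue
        key, val = line.split("=", 1)
        if key.startswith("Ch") and key[2:].isdigit():
            parts = val.split(",")
            idx = int(key[2:]) - 1
            names[idx] = parts[0]
            if len(parts) >= 3 and parts[2] != "":
                resolutions[idx] = float(parts[2])
        else:
            fields[key] = val
    fields["_names"] = names          # type: ignore[assignment]
    fields["_resolutions"] = resolutions  # type: ignore[assignment]
    return fields


def read_brainvision(
    header_path,
    epoch_window: tuple[float, float] | None = None,
    stim_prefix: str = "Stimulus",
) -> EEGEpochs:
    """Read a BrainVision triad into microvolt :class:`EEGEpochs`.

    Without ``epoch_window`` the continuous recording is returned as one
    epoch (condition ``"continuous"``, ``t0 = 0``).  With
    ``epoch_window=(tmin, tmax)`` seconds, the data are epoched around
    every marker whose description starts with ``stim_prefix``; the
    marker description becomes the epoch's condition label.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(f"BrainVision header file missing: {header_path}")
    fields = _parse_vhdr(header_path)
    for role, key in (("data", "DataFile"), ("marker", "MarkerFile")):
        fname = fields.get(key)
        if fname is None:
            raise ValueError(f"header {header_path.name} does not declare a {role} file")
        if not (header_path.parent / fname).exists():
            raise FileNotFoundError(
                f"BrainVision {role} file missing from triad: {fname} "
                f"(referenced by {header_path.name})"
            )
    fmt = fields.get("BinaryFormat", "").strip()
    if fmt not in _SUPPORTED_BV_FORMATS:
        raise ValueError(
            f"unsupported BrainVision binary format code {fmt!r}; "
            f"supported: {sorted(_SUPPORTED_BV_FORMATS)}"
        )

    import mne

    raw = mne.io.read_raw_brainvision(header_path, preload=True, verbose="error")
    sfreq = float(raw.info["sfreq"])
    names = [str(ch) for ch in raw.ch_names]
    if epoch_window is None:
        data = raw.get_data() * 1e6  # volts → µV
        return EEGEpochs(
            data=data[np.newaxis],
            sfreq=sfreq,
            t0=0.0,
            channel_names=names,
            condition=["continuous"],
        )
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    keep = {desc: code for desc, code in event_id.items() if desc.startswith(stim_prefix)}
    if not keep:
        raise ValueError(f"no markers with prefix {stim_prefix!r} found for epoching")
    tmin, tmax = epoch_window
    picks = events[np.isin(events[:, 2], list(keep.values()))]
    epochs = mne.Epochs(
        raw, picks, event_id=keep, tmin=tmin, tmax=tmax,
        baseline=None, preload=True, verbose="error",
    )
    inv = {code: desc for desc, code in keep.items()}
    cond = [inv[code] for code in epochs.events[:, 2]]
    return EEGEpochs(
        data=epochs.get_data(copy=True) * 1e6,
        sfreq=sfreq,
        t0=float(epochs.times[0]),
        channel_names=names,
        condition=cond,
    )


def write_brainvision(
    basename,
    data: np.ndarray,
    sfreq: float,
    channel_names: list[str],
    markers: list[tuple[str, int]] | None = None,
    fmt: str = "IEEE_FLOAT_32",
    resolution: float = 0.1,
) -> Path:
    """Write a continuous recording (m × d, µV) as a BrainVision triad.

    ``markers`` is a list of (description, 0-based sample) stimulus
    marks.  ``fmt`` is IEEE_FLOAT_32 (resolution ignored, stored as 1.0)
    or INT_16, where stored integers are ``round(value/resolution)``.
    Returns the header path.
    """
    base = Path(basename)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    m, d = data.shape
    if len(channel_names) != m:
        raise ValueError("one channel name per row required")
    if fmt not in _SUPPORTED_BV_FORMATS:
        raise ValueError(f"unsupported BrainVision binary format code {fmt!r}")
    vhdr = base.with_suffix(".vhdr")
    vmrk = base.with_suffix(".vmrk")
    eeg = base.with_suffix(".eeg")

    if fmt == "IEEE_FLOAT_32":
        res = 1.0
        payload = np.ascontiguousarray(data.T, dtype="<f4").tobytes()
    else:
        res = float(resolution)
        ints = np.round(data.T / res)
        if np.abs(ints).max(initial=0) > 32767:
            raise ValueError("data exceeds INT_16 range at this resolution")
        payload = np.ascontiguousarray(ints, dtype="<i2").tobytes()
    eeg.write_bytes(payload)

    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={m}",
        f"SamplingInterval={1e6 / sfreq:g}",
        "[Binary Infos]",
        f"BinaryFormat={fmt}",
        "[Channel Infos]",
    ]
    for i, name in enumerate(channel_names, start=1):
        lines.append(f"Ch{i}={name},,{res:g},µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,20200101000000000000",
    ]
    for k, (desc, sample) in enumerate(markers or [], start=2):
        mlines.append(f"Mk{k}=Stimulus,{desc},{sample + 1},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")
    return vhdr


# --------------------------------------------------------------------------
# stat overlays
# --------------------------------------------------------------------------

def read_stat_overlay(path, mesh: SourceSpace):
    """Per-vertex statistic overlay → unthresholded ActivationMap.

    Text suffixes (.txt/.csv/.tsv/.vec/.dat) are one float per line;
    anything else is read as a FreeSurfer curv overlay.
    """
    from .fmri_priors import ActivationMap

    path = Path(path)
    if path.suffix in _TEXT_SUFFIXES:
        stat = np.loadtxt(path, dtype=float).ravel()
    else:
        stat = np.asarray(fsio.read_morph_data(path), dtype=float)
    if stat.shape[0] != mesh.n_vertices:
        raise ValueError(
            f"overlay has {stat.shape[0]} values but mesh has {mesh.n_vertices} vertices"
        )
    return ActivationMap(stat=stat)


def write_stat_overlay(stat: np.ndarray, path) -> None:
    path = Path(path)
    stat = np.asarray(stat, dtype=float).ravel()
    if path.suffix in _TEXT_SUFFIXES:
        np.savetxt(path, stat, fmt="%.17g")
    else:
        fsio.write_morph_data(path, stat.astype(np.float32))


# --------------------------------------------------------------------------
# source estimates
# --------------------------------------------------------------------------

def write_source_estimate(est, path) -> None:
    """Single-file format: magic, JSON metadata line, float64 J block."""
    path = Path(path)
    J = np.ascontiguousarray(est.J, dtype="<f8")
    meta = {
        "shape": list(J.shape),
        "window_boundaries": np.asarray(est.window_boundaries, dtype=int).tolist(),
        "method": est.method,
        "sfreq": est.sfreq,
        "t0": est.t0,
        "per_window_F": [None if f is None else float(f) for f in est.per_window_F],
    }
    try:
        with open(path, "wb") as fh:
            fh.write(_ESTIMATE_MAGIC)
            fh.write((json.dumps(meta) + "\n").encode("utf-8"))
            fh.write(J.tobytes())
    except OSError as err:
        raise OSError(f"cannot write source estimate to {path}: {err}") from err


def read_source_estimate(path):
    from .pipeline import SourceEstimate

    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(len(_ESTIMATE_MAGIC))
        if magic != _ESTIMATE_MAGIC:
            raise ValueError(f"{path} is not a source-estimate file")
        meta = json.loads(fh.readline().decode("utf-8"))
        J = np.frombuffer(fh.read(), dtype="<f8").reshape(tuple(meta["shape"])).copy()
    return SourceEstimate(
        J=J,
        window_boundaries=np.asarray(meta["window_boundaries"], dtype=int),
        method=meta["method"],
        sfreq=meta["sfreq"],
        t0=meta["t0"],
        per_window_F=list(meta["per_window_F"]),
    )


# --------------------------------------------------------------------------
# surfaces and electrodes
# --------------------------------------------------------------------------

def read_surface_source_space(path) -> SourceSpace:
    """FreeSurfer geometry → SourceSpace (vertex normals from triangles)."""
    import trimesh

    verts, faces = fsio.read_geometry(path)
    verts = np.asarray(verts, dtype=float)
    faces = np.asarray(faces, dtype=int)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    normals = np.array(mesh.vertex_normals, dtype=float, copy=True)
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return SourceSpace(
        vertices=verts,
        normals=normals,
        adjacency=adjacency_from_faces(verts.shape[0], faces),
        faces=faces,
    )


def write_surface_source_space(src: SourceSpace, path) -> None:
    if src.faces is None:
        raise ValueError("source space has no triangles to write")
    fsio.write_geometry(path, src.vertices, src.faces)


def read_electrode_positions(path) -> tuple[list[str], np.ndarray]:
    """Delimited text ``label x y z`` (meters) → (labels, positions)."""
    labels, rows = [], []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        labels.append(parts[0])
        rows.append([float(v) for v in parts[1:4]])
    return labels, np.asarray(rows, dtype=float)


def write_electrode_positions(labels: list[str], positions: np.ndarray, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# label x y z (meters)\n")
        for lab, (x, y, z) in zip(labels, np.asarray(positions, dtype=float)):
            fh.write(f"{lab}\t{x:.17g}\t{y:.17g}\t{z:.17g}\n")
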