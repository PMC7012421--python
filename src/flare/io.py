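"""Reading cytometry inputs, persisting fitted models, exporting tables.

Inputs are FCS 3.0/3.1 list-mode files or delimited tables with a header
row.  The optional pre-model transform is the arcsinh with a configurable
cofactor (``x -> arcsinh(x / cofactor)``), the standard variance-stabilizing
transform for fluorescence intensities; data already on a transformed scale
should be read with ``transform="none"``.

Fitted models persist to a self-describing HDF5 container that restores the
full variational state, so summaries and zoom refits of a loaded model match
the in-memory original exactly.
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import pandas as pd

from .fcs import FcsFormatError, read_fcs
from .inference import FitResult
from .model import EventMatrix, ResolvedHyperparameters, VariationalState

__all__ = [
    "ChannelNotFoundError",
    "IncompatibleModelFileError",
    "read_sample",
    "write_events_csv",
    "save_model",
    "load_model",
    "export_assignments",
]

MODEL_FORMAT = "flare-model-1"


class ChannelNotFoundError(KeyError):
    """A requested channel is missing from the input file."""


class IncompatibleModelFileError(ValueError):
    """The file is not a model container this version can read."""


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext == ".fcs":
        return "fcs"
    if ext in (".csv",):
        return "csv"
    if ext in (".tsv", ".txt", ".tab"):
        return "tsv"
    raise ValueError(f"cannot infer format from extension {ext!r}; pass format=")


def read_sample(
    path: str,
    format: str | None = None,
    channels: list[str] | None = None,
    transform: str = "none",
    cofactor: float = 150.0,
    sample_id: str | None = None,
) -> EventMatrix:
    """Read one sample into an events x channels matrix.

    ``channels`` selects and orders columns; a missing channel raises
    :class:`ChannelNotFoundError` listing what is available.  ``transform``
    is ``"none"`` or ``"arcsinh"`` (elementwise, with ``cofactor > 0``).
    """
    fmt = format or _infer_format(path)
    if fmt == "fcs":
        data, names, _ = read_fcs(path)
    elif fmt in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if fmt == "csv" else "\t")
        names = [str(c) for c in df.columns]
        data = df.to_numpy(dtype=np.float64)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if channels is not None:
        missing = [c for c in channels if c not in names]
        if missing:
            raise ChannelNotFoundError(
                f"channels {missing} not found; available: {names}"
            )
        data = data[:, [names.index(c) for c in channels]]
        names = list(channels)

    if transform == "arcsinh":
        if cofactor <= 0:
            raise ValueError("cofactor must be positive")
        data = np.arcsinh(data / cofactor)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")

    sid = sample_id or os.path.splitext(os.path.basename(path))[0]
    return EventMatrix(sid, data, names)


def write_events_csv(sample: EventMatrix, path: str) -> None:
    """Write an event matrix as a headered CSV (round-trips with read_sample)."""
    pd.DataFrame(sample.data, columns=sample.marker_names).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

_STATE_ARRAYS = ["alpha", "Nk", "xbar", "S", "omega", "Gamma", "xi", "Upsilon",
                 "Psi", "sigma", "Phi"]


def _ds(f: h5py.File, name: str, value: np.ndarray) -> None:
    f.create_dataset(name, data=np.asarray(value), track_times=False)


def save_model(result: FitResult, path: str) -> None:
    """Persist a fit (full variational state, hyperparameters, traces)."""
    st = result.state
    with h5py.File(path, "w", track_order=False) as f:
        f.attrs["format"] = MODEL_FORMAT
        f.attrs["seed"] = result.seed
        f.attrs["converged"] = bool(result.converged)
        f.attrs["n_sweeps"] = result.n_sweeps
        f.attrs["n_effective_components"] = result.n_effective_components
        f.attrs["nu"] = float(st.nu)
        for name in ("K", "D", "alpha0", "beta0", "sigma0", "nu0", "epsilon0"):
            f.attrs[f"hp_{name}"] = getattr(result.hp, name)
        _ds(f, "hp_Phi0", result.hp.Phi0)
        _ds(f, "hp_xi0", result.hp.xi0)
        for name in _STATE_ARRAYS:
            _ds(f, name, getattr(st, name))
        _ds(f, "active", st.active.astype(np.uint8))
        _ds(f, "presence", result.presence.astype(np.uint8))
        _ds(f, "elbo_trace", np.asarray(result.elbo_trace, dtype=np.float64))
        _ds(f, "sample_ids", np.array([s.encode() for s in result.sample_ids]))
        _ds(f, "marker_names", np.array([s.encode() for s in result.marker_names]))
        for m in range(len(result.sample_ids)):
            _ds(f, f"r__{m}", st.r[m])
            _ds(f, f"log_rho__{m}", st.log_rho[m])
            _ds(f, f"hard_labels__{m}", result.hard_labels[m].astype(np.int64))


def load_model(path: str) -> FitResult:
    """Load a fit saved by :func:`save_model`."""
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != MODEL_FORMAT:
            raise IncompatibleModelFileError(
                f"{path!r} is not a {MODEL_FORMAT} container"
            )
        hp = ResolvedHyperparameters(
            K=int(f.attrs["hp_K"]), D=int(f.attrs["hp_D"]),
            alpha0=float(f.attrs["hp_alpha0"]), beta0=float(f.attrs["hp_beta0"]),
            sigma0=float(f.attrs["hp_sigma0"]), nu0=float(f.attrs["hp_nu0"]),
            epsilon0=float(f.attrs["hp_epsilon0"]),
            Phi0=f["hp_Phi0"][()], xi0=f["hp_xi0"][()],
        )
        sample_ids = [s.decode() for s in f["sample_ids"][()]]
        marker_names = [s.decode() for s in f["marker_names"][()]]
        M = len(sample_ids)
        arrays = {name: f[name][()] for name in _STATE_ARRAYS}
        state = VariationalState(
            r=[f[f"r__{m}"][()] for m in range(M)],
            log_rho=[f[f"log_rho__{m}"][()] for m in range(M)],
            nu=float(f.attrs["nu"]),
            active=f["active"][()].astype(bool),
            **arrays,
        )
        return FitResult(
            state=state,
            elbo_trace=[float(x) for x in f["elbo_trace"][()]],
            hard_labels=[f[f"hard_labels__{m}"][()] for m in range(M)],
            presence=f["presence"][()].astype(bool),
            n_effective_components=int(f.attrs["n_effective_components"]),
            converged=bool(f.attrs["converged"]),
            n_sweeps=int(f.attrs["n_sweeps"]),
            hp=hp,
            sample_ids=sample_ids,
            marker_names=marker_names,
            seed=int(f.attrs["seed"]),
        )


def export_assignments(result: FitResult, path: str) -> None:
    """One row per event: sample id, 0-based event index, hard label, max
    responsibility."""
    frames = []
    for m, sid in enumerate(result.sample_ids):
        r = result.state.r[m]
        frames.append(pd.DataFrame({
            "sample": sid,
            "event_index": np.arange(r.shape[0]),
            "component": result.hard_labels[m],
            "max_responsibility": r.max(axis=1),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
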