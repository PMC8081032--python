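"""HDF5 / NPZ containers for RF frames, scatterer fields and images.

HDF5 layout for an acquisition::

    /frames/000/rf        (n_t, n_el) float64
    /frames/000/delays    (n_el,)
    /frames/000  attrs: fs, t0, kind, angle, focus_x, focus_z, truncated
    root attrs: n_elements, pitch, f0, fs, c, seed, sequence_log (JSON)

The NPZ form stores the same content flat (``rf_000``, ``delays_000``, a
JSON ``meta`` string).  The loaders accept either format by extension.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Tuple

import h5py
import numpy as np

from .beamform import BeamformedImage
from .geometry import ArrayGeometry, TransmitEvent
from .scene import ScattererField
from .simulate import RFFrame

__all__ = [
    "save_frames",
    "load_frames",
    "save_image",
    "load_image",
    "save_scatterers",
    "load_scatterers",
]


def _tx_meta(tx: TransmitEvent) -> dict:
    return {
        "kind": tx.kind,
        "angle": float(tx.angle) if tx.angle is not None else None,
        "focus": [float(v) for v in tx.focus] if tx.focus is not None else None,
    }


def _tx_from_meta(meta: dict, delays: np.ndarray) -> TransmitEvent:
    focus = tuple(meta["focus"]) if meta.get("focus") is not None else None
    return TransmitEvent(kind=meta["kind"], delays=delays, focus=focus, angle=meta.get("angle"))


def save_frames(path, frames: List[RFFrame], array: ArrayGeometry, meta: dict | None = None) -> None:
    """Write RF frames plus array metadata to ``.h5``/``.hdf5`` or ``.npz``."""
    path = Path(path)
    header = {
        "n_elements": array.n_elements,
        "pitch": array.pitch,
        "f0": array.f0,
        "fs": array.fs,
        "c": array.c,
    }
    if meta:
        header.update(meta)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            for k, v in header.items():
                fh.attrs[k] = json.dumps(v) if isinstance(v, (dict, list)) else v
            grp = fh.create_group("frames")
            for i, fr in enumerate(frames):
                g = grp.create_group(f"{i:03d}")
                g.create_dataset("rf", data=fr.data)
                g.create_dataset("delays", data=fr.tx.delays)
                g.attrs["fs"] = fr.fs
                g.attrs["t0"] = fr.t0
                g.attrs["truncated"] = fr.truncated
                g.attrs["tx"] = json.dumps(_tx_meta(fr.tx))
    elif path.suffix == ".npz":
        payload = {}
        frame_meta = []
        for i, fr in enumerate(frames):
            payload[f"rf_{i:03d}"] = fr.data
            payload[f"delays_{i:03d}"] = fr.tx.delays
            frame_meta.append(
                {"fs": fr.fs, "t0": fr.t0, "truncated": fr.truncated, "tx": _tx_meta(fr.tx)}
            )
        payload["meta"] = np.frombuffer(
            json.dumps({"header": header, "frames": frame_meta}).encode(), dtype=np.uint8
        )
        np.savez(path, **payload)
    else:
        raise ValueError(f"unsupported container extension {path.suffix!r}")


def load_frames(path) -> Tuple[List[RFFrame], ArrayGeometry, dict]:
    """Read an acquisition container; returns (frames, array, extra header)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            header = {k: fh.attrs[k] for k in fh.attrs}
            frames = []
            for name in sorted(fh["frames"]):
                g = fh["frames"][name]
                tx = _tx_from_meta(json.loads(g.attrs["tx"]), g["delays"][...])
                frames.append(
                    RFFrame(
                        data=g["rf"][...],
                        fs=float(g.attrs["fs"]),
                        t0=float(g.attrs["t0"]),
                        tx=tx,
                        truncated=bool(g.attrs["truncated"]),
                    )
                )
    elif path.suffix == ".npz":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["meta"]).decode())
            header = meta["header"]
            frames = []
            for i, fm in enumerate(meta["frames"]):
                tx = _tx_from_meta(fm["tx"], npz[f"delays_{i:03d}"])
                frames.append(
                    RFFrame(
                        data=npz[f"rf_{i:03d}"],
                        fs=float(fm["fs"]),
                        t0=float(fm["t0"]),
                        tx=tx,
                        truncated=bool(fm["truncated"]),
                    )
                )
    else:
        raise ValueError(f"unsupported container extension {path.suffix!r}")
    array = ArrayGeometry(
        n_elements=int(header["n_elements"]),
        pitch=float(header["pitch"]),
        f0=float(header["f0"]),
        fs=float(header["fs"]),
        c=float(header["c"]),
    )
    extra = {k: v for k, v in header.items() if k not in ("n_elements", "pitch", "f0", "fs", "c")}
    return frames, array, extra


def save_image(path, img: BeamformedImage, **attrs) -> None:
    """Write a beamformed image (values + grids + kind) to NPZ or HDF5."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(
            path,
            values=img.values,
            x_grid=img.x_grid,
            z_grid=img.z_grid,
            kind=np.array(img.kind),
            attrs=np.frombuffer(json.dumps(attrs).encode(), dtype=np.uint8),
        )
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("values", data=img.values)
            fh.create_dataset("x_grid", data=img.x_grid)
            fh.create_dataset("z_grid", data=img.z_grid)
            fh.attrs["kind"] = img.kind
            for k, v in attrs.items():
                fh.attrs[k] = v
    else:
        raise ValueError(f"unsupported image extension {path.suffix!r}")


def load_image(path) -> BeamformedImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npz":
        with np.load(path) as npz:
            return BeamformedImage(
                values=npz["values"],
                x_grid=npz["x_grid"],
                z_grid=npz["z_grid"],
                kind=str(npz["kind"]),
            )
    with h5py.File(path, "r") as fh:
        return BeamformedImage(
            values=fh["values"][...],
            x_grid=fh["x_grid"][...],
            z_grid=fh["z_grid"][...],
            kind=str(fh.attrs["kind"]),
        )


def save_scatterers(path, field: ScattererField) -> None:
    np.savez(
        Path(path),
        x=field.x,
        z=field.z,
        amplitude=field.amplitude,
        labels=field.labels,
        seed=np.array(field.seed),
        c=np.array(field.c),
    )


def load_scatterers(path) -> ScattererField:
    with np.load(Path(path)) as npz:
        return ScattererField(
            x=npz["x"],
            z=npz["z"],
            amplitude=npz["amplitude"],
            labels=npz["labels"],
            seed=int(npz["seed"]),
            c=float(npz["c"]),
        )
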