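"""Plain-text and TIFF readers/writers binding the pipeline together.

Force curves travel as CSV with commented header lines (spring constant,
seed, acquisition metadata) and columns ``z_nm, deflection_nm``; images
and movies travel as TIFF with a JSON sidecar carrying the physical
metadata (pixel size, frame interval, channel names, axis order), which
is more portable than packing it into TIFF tags.  All writers round-trip:
write-then-read reproduces arrays and metadata.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import tifffile

from .afm import ForceCurve
from .errors import FormatError

_META_KEYS = {
    "spring_constant_N_per_m": ("spring_constant", float),
    "seed": ("seed", int),
    "approach_velocity_um_per_s": ("approach_velocity_um_per_s", float),
    "max_force_nN": ("max_force_nN", float),
}


def write_force_curve_csv(curve: ForceCurve, path) -> None:
    path = Path(path)
    lines = [f"# spring_constant_N_per_m = {float(curve.spring_constant)!r}"]
    for key in ("seed", "approach_velocity_um_per_s", "max_force_nN"):
        if key in curve.meta:
            value = curve.meta[key]
            value = int(value) if key == "seed" else float(value)
            lines.append(f"# {key} = {value!r}")
    lines.append("z_nm,deflection_nm")
    for z, d in zip(curve.z, curve.deflection):
        lines.append(f"{float(z)!r},{float(d)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_force_curve_csv(path) -> ForceCurve:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, value = line.lstrip("# ").partition("=")
                key = key.strip()
                if key in _META_KEYS:
                    name, cast = _META_KEYS[key]
                    meta[name] = cast(value.strip())
    if "spring_constant" not in meta:
        raise FormatError(f"{path}: missing header field spring_constant_N_per_m")
    table = pd.read_csv(path, comment="#", float_precision="round_trip")
    for col in ("z_nm", "deflection_nm"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing column {col}")
    spring_constant = meta.pop("spring_constant")
    return ForceCurve(
        table["z_nm"].to_numpy(),
        table["deflection_nm"].to_numpy(),
        spring_constant=spring_constant,
        meta=meta,
    )


def write_tiff_stack(stack: np.ndarray, path, sidecar: dict, sidecar_path=None) -> None:
    """Write a normalised (frame, channel, row, col) stack to TIFF plus a
    JSON sidecar.  The sidecar's ``axes`` (one of YX, CYX, TYX, TCYX)
    selects the on-disk layout; singleton axes absent from ``axes`` are
    squeezed out on write and restored on read."""
    path = Path(path)
    stack = np.asarray(stack, dtype=np.float32)
    if stack.ndim != 4:
        raise FormatError("stack must be a (frame, channel, row, col) array")
    axes = sidecar.get("axes", "TCYX")
    arr = stack
    if "C" not in axes:
        if stack.shape[1] != 1:
            raise FormatError("axes without C require a single channel")
        arr = arr[:, 0]
    if "T" not in axes:
        if stack.shape[0] != 1:
            raise FormatError("axes without T require a single frame")
        arr = arr[0]
    tifffile.imwrite(path, arr)
    sidecar_path = Path(sidecar_path) if sidecar_path else Path(str(path) + ".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=2) + "\n")


def read_tiff_stack(path, sidecar_path=None) -> Tuple[np.ndarray, dict]:
    """Read a TIFF stack and its sidecar, normalising to (frame, channel,
    row, col)."""
    path = Path(path)
    sidecar_path = Path(sidecar_path) if sidecar_path else Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    arr = tifffile.imread(path)
    axes = sidecar.get("axes", "TCYX")
    if sorted(axes) not in (["X", "Y"], ["C", "X", "Y"], ["T", "X", "Y"], ["C", "T", "X", "Y"]):
        raise FormatError(f"unsupported axes {axes!r}")
    if arr.ndim != len(axes):
        raise FormatError(f"array rank {arr.ndim} does not match axes {axes!r}")
    # reorder stated axes to T, C, Y, X and insert missing singletons
    order = [axes.index(a) for a in "TCYX" if a in axes]
    arr = np.transpose(arr, order)
    if "C" not in axes:
        arr = np.expand_dims(arr, 1 if "T" in axes else 0)
    if "T" not in axes:
        arr = np.expand_dims(arr, 0)
    if arr.ndim == 3:
        arr = np.expand_dims(arr, 1)
    names = sidecar.get("channel_names")
    if names is not None and len(names) != arr.shape[1]:
        raise FormatError("channel_names length does not match channel axis")
    return arr, sidecar


def read_mask_csv(path, shape) -> np.ndarray:
    """Boolean mask from a CSV of ``row,col`` pixel coordinates."""
    table = pd.read_csv(path)
    for col in ("row", "col"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing column {col}")
    mask = np.zeros(shape, dtype=bool)
    rows = table["row"].to_numpy(int)
    cols = table["col"].to_numpy(int)
    if rows.min() < 0 or cols.min() < 0 or rows.max() >= shape[0] or cols.max() >= shape[1]:
        raise FormatError(f"{path}: mask coordinates outside image")
    mask[rows, cols] = True
    return mask


def write_mask_csv(mask: np.ndarray, path) -> None:
    rows, cols = np.nonzero(mask)
    pd.DataFrame({"row": rows, "col": cols}).to_csv(path, index=False)


def read_lines_csv(path) -> list:
    """Measurement lines from a CSV with columns r0,c0,r1,c1."""
    table = pd.read_csv(path)
    for col in ("r0", "c0", "r1", "c1"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing column {col}")
    return [
        ((row.r0, row.c0), (row.r1, row.c1)) for row in table.itertuples(index=False)
    ]
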