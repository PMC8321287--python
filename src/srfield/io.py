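"""File I/O: grey-scale images, activation stacks, run logs, config snapshots.

Images are exchanged as 8-bit PNG (display, clipped or min-max normalised)
and 32-bit float TIFF (raw, unclamped); activation stacks as HDF5 (see
:mod:`srfield.lifting`); per-iteration logs as CSV; resolved configurations
as flat-section TOML snapshots readable by stdlib ``tomllib``.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np


def read_image(path) -> np.ndarray:
    """Read a grey-scale image and normalise integer data to [0, 1]."""
    import imageio.v3 as iio

    data = np.asarray(iio.imread(path))
    if data.ndim == 3:  # collapse colour/alpha channels
        data = data[..., :3].mean(axis=-1)
    data = data.astype(float)
    if np.issubdtype(np.asarray(iio.imread(path)).dtype, np.integer):
        data = data / np.iinfo(np.asarray(iio.imread(path)).dtype).max
    return data


def write_png(path, image: np.ndarray, normalise: bool = False) -> None:
    """Write an 8-bit grey PNG; optionally min-max normalise first."""
    import imageio.v3 as iio

    image = np.asarray(image, dtype=float)
    if normalise:
        lo, hi = image.min(), image.max()
        image = np.zeros_like(image) if hi - lo < 1e-300 else (image - lo) / (hi - lo)
    data = np.clip(np.round(image * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), data)


def write_tiff(path, image: np.ndarray) -> None:
    """Write a raw 32-bit float TIFF (unclamped)."""
    import tifffile

    tifffile.imwrite(Path(path), np.asarray(image, dtype=np.float32))


def read_tiff(path) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(Path(path)), dtype=float)


def write_csv_log(path, rows: list[dict]) -> None:
    """Write per-iteration diagnostics; column order follows the first row."""
    if not rows:
        return
    fieldnames = list(rows[0].keys())
    for row in rows:
        for key in row:
            if key not in fieldnames:
                fieldnames.append(key)
    with open(path, "w", newline="") as f:
        writer = csv.DictWriter(f, fieldnames=fieldnames)
        writer.writeheader()
        writer.writerows(rows)


def _toml_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float, np.integer, np.floating)):
        return repr(float(value)) if isinstance(value, (float, np.floating)) else str(int(value))
    if isinstance(value, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_toml_value(v) for v in value) + "]"
    return '"' + str(value).replace("\\", "\\\\").replace('"', '\\"') + '"'


def write_toml(path, sections: dict[str, dict]) -> None:
    """Minimal TOML emitter for flat sections of scalar/list values."""
    lines = []
    for section, values in sections.items():
        lines.append(f"[{section}]")
        for key, value in values.items():
            if value is None:
                continue
            lines.append(f"{key} = {_toml_value(value)}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_toml(path) -> dict:
    import tomllib

    with open(path, "rb") as f:
        return tomllib.load(f)
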