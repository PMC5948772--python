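"""Minimal ENVI-style cube I/O: flat binary BIL file + plain-text header.

Supports what the pipeline needs: band-interleaved-by-line (BIL) layout,
float32 or uint16 data, a wavelength list in the header.  Little-endian,
no offsets.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .grid import WavelengthGrid

_DTYPE_CODES = {4: np.float32, 12: np.uint16, 5: np.float64, 2: np.int16}
_CODE_FOR_DTYPE = {np.dtype(v): k for k, v in _DTYPE_CODES.items()}


def write_envi_cube(
    path_stem: str | Path, cube: np.ndarray, grid: WavelengthGrid
) -> tuple[Path, Path]:
    """Write ``cube`` (lines x pixels x bands) as <stem>.bil + <stem>.hdr."""
    cube = np.ascontiguousarray(cube)
    if cube.ndim != 3:
        raise ValueError("cube must be 3-D (lines x pixels x bands)")
    lines, samples, bands = cube.shape
    if bands != grid.count:
        raise ValueError("cube band count does not match grid")
    code = _CODE_FOR_DTYPE.get(cube.dtype)
    if code is None:
        cube = cube.astype(np.float32)
        code = 4
    stem = Path(path_stem)
    bil_path = stem.with_suffix(".bil")
    hdr_path = stem.with_suffix(".hdr")
    # BIL: for each line, band-major then pixel
    np.transpose(cube, (0, 2, 1)).tofile(bil_path)
    wl = ", ".join(f"{w:.6f}" for w in grid.centers)
    hdr_path.write_text(
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {code}\n"
        "interleave = bil\n"
        "byte order = 0\n"
        f"wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    return bil_path, hdr_path


def _parse_header(hdr_path: Path) -> dict[str, str]:
    text = hdr_path.read_text()
    # join brace-delimited multi-line values
    fields: dict[str, str] = {}
    buf = ""
    key = None
    for line in text.splitlines():
        if key is not None:
            buf += " " + line.strip()
            if "}" in line:
                fields[key] = buf
                key, buf = None, ""
            continue
        if "=" not in line:
            continue
        k, v = (part.strip() for part in line.split("=", 1))
        if "{" in v and "}" not in v:
            key, buf = k.lower(), v
        else:
            fields[k.lower()] = v
    return fields


def read_envi_cube(hdr_path: str | Path) -> tuple[np.ndarray, WavelengthGrid]:
    """Read a BIL cube written by :func:`write_envi_cube` (or compatible)."""
    hdr_path = Path(hdr_path)
    fields = _parse_header(hdr_path)
    if fields.get("interleave", "bil").lower() != "bil":
        raise ValueError("only BIL interleave is supported")
    lines = int(fields["lines"])
    samples = int(fields["samples"])
    bands = int(fields["bands"])
    dtype = _DTYPE_CODES[int(fields["data type"])]
    raw = np.fromfile(hdr_path.with_suffix(".bil"), dtype=dtype)
    if raw.size != lines * samples * bands:
        raise ValueError("binary file size does not match header dimensions")
    cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    wl_field = fields.get("wavelength", "")
    wl = np.array(
        [float(x) for x in wl_field.strip("{} ").split(",") if x.strip()]
    )
    if wl.size != bands:
        raise ValueError("wavelength list does not match band count")
    return cube.astype(np.float64), WavelengthGrid(wl)
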