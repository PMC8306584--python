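"""Reading and writing spectra and label manifests.

Supported text formats:

* two-column CSV (``wavenumber,intensity``, header required);
* a JCAMP-DX subset: ``##XYDATA=(X++(Y..Y))`` tables with AFFN numbers,
  and ``##XYPOINTS=(XY..XY)`` pair tables;
* a labels manifest as TSV with columns ``subject_id`` and ``label``.

Files stored in descending wavenumber order (common for dispersive-Raman
exports) are re-sorted to the canonical ascending order on read.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path

import numpy as np

from .exceptions import FormatError
from .spectra import Spectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_manifest",
    "write_manifest",
]

_FORMATS = ("csv", "jcamp-dx")
VALID_LABELS = ("CD", "nonCD")


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in _FORMATS:
            raise FormatError(f"unknown format {format!r}; expected one of {_FORMATS}")
        return format
    return "jcamp-dx" if path.suffix.lower() in (".jdx", ".dx", ".jcm") else "csv"


def read_spectrum(path, format: str | None = None) -> Spectrum:
    """Read one spectrum file into a canonical :class:`Spectrum`.

    ``format`` is ``"csv"`` or ``"jcamp-dx"``; when omitted it is inferred
    from the file extension (``.jdx``/``.dx`` means JCAMP-DX).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        nu, y, meta = _read_csv(path)
    else:
        nu, y, meta = _read_jcamp(path)
    try:
        return Spectrum(nu, y, subject_id=meta.pop("subject_id", path.stem), meta=meta)
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_spectrum(spectrum: Spectrum, path, format: str | None = None) -> None:
    """Write a spectrum so that :func:`read_spectrum` reproduces it.

    CSV values use ``repr``-faithful floats, so a round trip is exact to
    well below 1e-9.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        _write_csv(spectrum, path)
    else:
        _write_jcamp(spectrum, path)


def _read_csv(path: Path):
    nu, y = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise FormatError(f"{path}: empty file")
        if len(header) < 2:
            raise FormatError(f"{path}: expected two columns, got header {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields, got {len(row)}")
            try:
                nu.append(float(row[0]))
                y.append(float(row[1]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric cell: {exc}") from exc
    return np.array(nu), np.array(y), {}


def _write_csv(spectrum: Spectrum, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["wavenumber", "intensity"])
        for x, v in zip(spectrum.wavenumbers, spectrum.intensities):
            writer.writerow([repr(float(x)), repr(float(v))])


_NUM = re.compile(r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?")


def _read_jcamp(path: Path):
    """Minimal JCAMP-DX reader: XYDATA=(X++(Y..Y)) and XYPOINTS tables."""
    headers: dict[str, str] = {}
    mode = None
    xs: list[float] = []
    ys: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("$$"):
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper()
                value = value.strip()
                if key == "XYDATA":
                    mode = "xydata"
                elif key == "XYPOINTS":
                    mode = "xypoints"
                elif key == "END":
                    mode = None
                else:
                    headers[key] = value
                continue
            nums = [float(m) for m in _NUM.findall(line)]
            if mode == "xydata":
                if len(nums) < 2:
                    raise FormatError(f"{path}:{lineno}: XYDATA line needs x then y values")
                x0, yvals = nums[0], nums[1:]
                dx = float(headers.get("DELTAX", "nan"))
                if not np.isfinite(dx):
                    first = float(headers.get("FIRSTX", "nan"))
                    last = float(headers.get("LASTX", "nan"))
                    npts = float(headers.get("NPOINTS", "nan"))
                    if np.isfinite(first) and np.isfinite(last) and npts > 1:
                        dx = (last - first) / (npts - 1)
                    else:
                        raise FormatError(f"{path}: XYDATA needs DELTAX or FIRSTX/LASTX/NPOINTS")
                xf = float(headers.get("XFACTOR", "1"))
                yf = float(headers.get("YFACTOR", "1"))
                for i, yv in enumerate(yvals):
                    xs.append((x0 + i * dx / xf) * xf)
                    ys.append(yv * yf)
            elif mode == "xypoints":
                if len(nums) % 2:
                    raise FormatError(f"{path}:{lineno}: odd number of values in XYPOINTS")
                xs.extend(nums[0::2])
                ys.extend(nums[1::2])
    if not xs:
        raise FormatError(f"{path}: no XYDATA or XYPOINTS table found")
    meta = {"jcamp_title": headers.get("TITLE", ""), "xunits": headers.get("XUNITS", "")}
    return np.array(xs), np.array(ys), meta


def _write_jcamp(spectrum: Spectrum, path: Path) -> None:
    nu, y = spectrum.wavenumbers, spectrum.intensities
    lines = [
        f"##TITLE={spectrum.subject_id or path.stem}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=RAMAN SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ARBITRARY UNITS",
        "##XFACTOR=1",
        "##YFACTOR=1",
        f"##FIRSTX={float(nu[0])!r}",
        f"##LASTX={float(nu[-1])!r}",
        f"##NPOINTS={nu.size}",
        "##XYPOINTS=(XY..XY)",
    ]
    lines += [f"{float(x)!r}, {float(v)!r}" for x, v in zip(nu, y)]
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path) -> dict[str, str]:
    """Read a subject_id -> label mapping from a TSV manifest.

    The file must have a header row ``subject_id<TAB>label``; labels are
    restricted to ``CD``/``nonCD`` and subject ids must be unique.
    """
    path = Path(path)
    manifest: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["subject_id", "label"]:
            raise FormatError(f"{path}: expected header 'subject_id\\tlabel', got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or not row[0].strip():
                continue
            if len(row) < 2:
                raise FormatError(f"{path}:{lineno}: missing label column")
            sid, label = row[0].strip(), row[1].strip()
            if label not in VALID_LABELS:
                raise FormatError(
                    f"{path}:{lineno}: unknown label {label!r}; expected CD or nonCD"
                )
            if sid in manifest:
                raise FormatError(f"{path}:{lineno}: duplicate subject_id {sid!r}")
            manifest[sid] = label
    return manifest


def write_manifest(manifest: dict[str, str], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["subject_id", "label"])
        for sid, label in manifest.items():
            writer.writerow([sid, label])
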