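"""Frequency-domain 1D NMR spectrum container and file I/O.

The :class:`Spectrum` is the exchange currency of the whole pipeline: a
strictly ascending ppm axis, an intensity vector (real, or complex before
phase correction), the spectrometer proton frequency in MHz, and a metadata
dict that records provenance (acquisition scheme label, normalization state,
processing history).

Spectra round-trip through two plain-text formats:

* JCAMP-DX 4.24 ``##XYDATA=(X++(Y..Y))``, written in AFFN and read in AFFN
  or ASDF (SQZ/DIF/DUP) compressed form, and
* two-column CSV (``ppm,intensity``) with ``#`` header comments.

Axes are stored ascending; files with descending ppm are flipped on read
(display follows the NMR convention of reversing the axis, which is a
plotting concern only).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import __version__


class SpectrumIOError(ValueError):
    """Malformed spectrum file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass
class Spectrum:
    """A 1D frequency-domain spectrum on a strictly ascending ppm grid."""

    ppm: np.ndarray
    intensity: np.ndarray
    field_MHz: float
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity)
        if self.ppm.ndim != 1 or self.ppm.size < 2:
            raise ValueError("ppm axis must be a 1D array of length >= 2")
        if self.intensity.shape != self.ppm.shape:
            raise ValueError("ppm and intensity must have equal length")
        diffs = np.diff(self.ppm)
        if np.any(diffs <= 0):
            raise ValueError("ppm axis must be strictly ascending")
        if self.field_MHz <= 0:
            raise ValueError("field_MHz must be positive")

    @property
    def real(self) -> np.ndarray:
        return np.real(self.intensity)

    @property
    def is_normalized(self) -> bool:
        return bool(self.metadata.get("normalized", False))

    def copy(self) -> "Spectrum":
        return Spectrum(self.ppm.copy(), self.intensity.copy(),
                        self.field_MHz, dict(self.metadata))

    def interp(self, ppm: np.ndarray) -> np.ndarray:
        """Linear interpolation of the (real) intensity onto another grid."""
        return np.interp(ppm, self.ppm, self.real, left=0.0, right=0.0)


def _header_comment(seed=None) -> str:
    s = f"benchnmr v{__version__}"
    if seed is not None:
        s += f" seed={seed}"
    return s


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def write_csv(spectrum: Spectrum, path: str | Path, seed=None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {_header_comment(seed)}\n")
        fh.write(f"# field_MHz={spectrum.field_MHz}\n")
        for k, v in sorted(spectrum.metadata.items()):
            if isinstance(v, (str, int, float, bool)):
                fh.write(f"# {k}={v}\n")
        fh.write("ppm,intensity\n")
        for x, y in zip(spectrum.ppm, spectrum.real):
            fh.write(f"{x:.9g},{y:.9g}\n")


def read_csv(path: str | Path, field_MHz: float | None = None) -> Spectrum:
    path = Path(path)
    meta: dict = {}
    xs: list[float] = []
    ys: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*([\w.]+)\s*=\s*(.+)", line)
                if m:
                    meta[m.group(1)] = m.group(2)
                continue
            if line.lower().startswith("ppm"):
                continue
            parts = re.split(r"[,\t;]\s*|\s+", line)
            if len(parts) < 2:
                raise SpectrumIOError("expected two columns", lineno)
            try:
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumIOError(str(exc), lineno) from None
    if len(xs) < 2:
        raise SpectrumIOError("fewer than 2 data rows; file truncated?")
    if field_MHz is None:
        if "field_MHz" not in meta:
            raise SpectrumIOError("field_MHz neither in header nor given")
        field_MHz = float(meta.pop("field_MHz"))
    else:
        meta.pop("field_MHz", None)
    x = np.array(xs)
    y = np.array(ys)
    if x[0] > x[-1]:  # descending file -> ascending storage
        x, y = x[::-1], y[::-1]
    return Spectrum(x, y, field_MHz, meta)


# ---------------------------------------------------------------------------
# JCAMP-DX
# ---------------------------------------------------------------------------

_SQZ = dict(zip("@ABCDEFGHI", range(10)))
_SQZ.update(zip("abcdefghi", range(-1, -10, -1)))
_DIF = dict(zip("%JKLMNOPQR", range(10)))
_DIF.update(zip("jklmnopqr", range(-1, -10, -1)))
_DUP = dict(zip("STUVWXYZs", range(1, 10)))


def write_jcamp(spectrum: Spectrum, path: str | Path, seed=None,
                title: str = "benchnmr spectrum") -> None:
    """Write an AFFN ``(X++(Y..Y))`` JCAMP-DX file."""
    path = Path(path)
    y = spectrum.real
    ymax = float(np.max(np.abs(y))) or 1.0
    yfactor = ymax / 2**20  # ~6 significant digits after integer rounding
    yi = np.round(y / yfactor).astype(np.int64)
    n = len(y)
    buf = io.StringIO()
    buf.write(f"##TITLE={title}\n")
    buf.write("##JCAMP-DX=4.24\n")
    buf.write("##DATA TYPE=NMR SPECTRUM\n")
    buf.write(f"##$COMMENT={_header_comment(seed)}\n")
    buf.write("##XUNITS=PPM\n##YUNITS=ARBITRARY UNITS\n")
    buf.write(f"##.OBSERVE FREQUENCY={spectrum.field_MHz}\n")
    for k, v in sorted(spectrum.metadata.items()):
        if isinstance(v, (str, int, float, bool)):
            buf.write(f"##${k.upper()}={v}\n")
    buf.write(f"##FIRSTX={spectrum.ppm[0]:.10g}\n")
    buf.write(f"##LASTX={spectrum.ppm[-1]:.10g}\n")
    buf.write(f"##XFACTOR={(spectrum.ppm[-1] - spectrum.ppm[0]) / (n - 1):.12g}\n")
    buf.write(f"##YFACTOR={yfactor:.12g}\n")
    buf.write(f"##NPOINTS={n}\n")
    buf.write("##XYDATA=(X++(Y..Y))\n")
    step = (n - 1)
    xfac = (spectrum.ppm[-1] - spectrum.ppm[0]) / step
    per_line = 8
    for i in range(0, n, per_line):
        xi = round((spectrum.ppm[i] - spectrum.ppm[0]) / xfac)
        vals = " ".join(str(v) for v in yi[i:i + per_line])
        buf.write(f"{xi} {vals}\n")
    buf.write("##END=\n")
    path.write_text(buf.getvalue())


def _decode_asdf_line(body: str, lineno: int) -> tuple[list[int], bool]:
    """Decode one ASDF/AFFN data line (without the leading X value).

    Returns (y values, last_was_dif) so the caller can drop the DIF
    check-point value that starts the next line.
    """
    tokens = re.findall(r"[+-]?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?|[@-IJ-Ra-ij-r%][0-9]*|[S-Zs]\d*", body)
    ys: list[int] = []
    last_dif = False
    prev_token_vals: list[int] = []
    for tok in tokens:
        c = tok[0]
        if c in _SQZ:
            v = _SQZ[c]
            rest = tok[1:]
            mag = int(rest) if rest else 0
            v = v * 10 ** len(rest) + (mag if v >= 0 else -mag)
            ys.append(v)
            last_dif = False
            prev_token_vals = [v]
        elif c in _DIF:
            d = _DIF[c]
            rest = tok[1:]
            mag = int(rest) if rest else 0
            d = d * 10 ** len(rest) + (mag if d >= 0 else -mag)
            if not ys:
                raise SpectrumIOError("DIF code with no previous Y", lineno)
            v = ys[-1] + d
            ys.append(v)
            last_dif = True
            prev_token_vals = [d]
        elif c in _DUP:
            count = _DUP[c]
            rest = tok[1:]
            if rest:
                count = count * 10 ** len(rest) + int(rest)
            if not prev_token_vals:
                raise SpectrumIOError("DUP code with nothing to repeat", lineno)
            for _ in range(count - 1):
                if last_dif:
                    ys.append(ys[-1] + prev_token_vals[0])
                else:
                    ys.append(prev_token_vals[0])
        else:  # plain AFFN number
            v = int(round(float(tok)))
            ys.append(v)
            last_dif = False
            prev_token_vals = [v]
    return ys, last_dif


def read_jcamp(path: str | Path) -> Spectrum:
    path = Path(path)
    headers: dict[str, str] = {}
    data_lines: list[tuple[int, str]] = []
    in_data = False
    ended = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                if in_data and not line.upper().startswith("##END"):
                    in_data = False
                if line.upper().startswith("##END"):
                    ended = True
                    in_data = False
                    continue
                if "=" not in line:
                    raise SpectrumIOError("malformed JCAMP header record", lineno)
                key, _, val = line[2:].partition("=")
                key = key.strip().upper()
                headers[key] = val.strip()
                if key == "XYDATA":
                    in_data = True
                continue
            if in_data:
                data_lines.append((lineno, line))
    for req in ("FIRSTX", "LASTX", "NPOINTS", "YFACTOR"):
        if req not in headers:
            raise SpectrumIOError(f"missing required ##{req}= header")
    if not ended:
        raise SpectrumIOError("no ##END= record; file truncated?")
    firstx = float(headers["FIRSTX"])
    lastx = float(headers["LASTX"])
    npoints = int(headers["NPOINTS"])
    yfactor = float(headers["YFACTOR"])
    field = float(headers.get(".OBSERVE FREQUENCY", 0)) or None

    ys: list[int] = []
    pending_dif = False
    for lineno, line in data_lines:
        m = re.match(r"\s*([+-]?\d+(?:\.\d+)?)\s*(.*)$", line)
        if not m:
            raise SpectrumIOError("data line does not start with an X value", lineno)
        body = m.group(2)
        vals, last_dif = _decode_asdf_line(body, lineno)
        if pending_dif and vals:
            # first Y of a line following a DIF line is a check value
            vals = vals[1:]
        ys.extend(vals)
        pending_dif = last_dif
    if len(ys) != npoints:
        raise SpectrumIOError(
            f"expected {npoints} points, decoded {len(ys)}; file truncated?")
    y = np.array(ys, dtype=float) * yfactor
    x = np.linspace(firstx, lastx, npoints)
    if field is None:
        raise SpectrumIOError("missing ##.OBSERVE FREQUENCY= header")
    meta = {}
    for k, v in headers.items():
        if k.startswith("$") and k != "$COMMENT":
            meta[k[1:].lower()] = v
    if x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    # normalized flag survives the round trip as a string
    if "normalized" in meta:
        meta["normalized"] = meta["normalized"] in ("True", "true", "1")
    return Spectrum(x, y, field, meta)


def read_spectrum(path: str | Path, field_MHz: float | None = None) -> Spectrum:
    """Dispatch on content: JCAMP-DX if the file starts with ``##``, else CSV."""
    path = Path(path)
    with open(path) as fh:
        head = fh.read(2)
    if head == "##":
        return read_jcamp(path)
    return read_csv(path, field_MHz=field_MHz)


def write_spectrum(spectrum: Spectrum, path: str | Path, seed=None) -> None:
    """Dispatch on extension: ``.jdx``/``.dx`` -> JCAMP-DX, else CSV."""
    path = Path(path)
    if path.suffix.lower() in (".jdx", ".dx", ".jcamp"):
        write_jcamp(spectrum, path, seed=seed)
    else:
        write_csv(spectrum, path, seed=seed)
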