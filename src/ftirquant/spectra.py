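"""Spectrum container and file I/O (JCAMP-DX subset and two-column CSV).

The internal axis convention is a strictly ascending wavenumber grid in
cm⁻¹; readers reorder descending instrument exports on ingest.  Intensities
carry a channel tag: percent transmittance (``%T``), absorbance (AU), or a
derivative trace (AU·cm⁻¹ per derivative order).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd


class Channel(str, Enum):
    """Intensity channel of a spectrum."""

    TRANSMITTANCE_PCT = "transmittance_pct"
    ABSORBANCE = "absorbance"
    DERIVATIVE = "derivative"


class SpectrumFormatError(ValueError):
    """Raised when a spectrum file cannot be parsed."""


class SpectrumDataError(ValueError):
    """Raised when parsed data violate spectrum invariants (e.g. duplicate axis points)."""


@dataclass
class Spectrum:
    """A sampled intensity trace on an ascending wavenumber axis.

    Parameters
    ----------
    wavenumbers : array of float
        Axis in cm⁻¹, strictly increasing.
    intensities : array of float
        Same length as ``wavenumbers``; units depend on ``channel``.
    channel : Channel
        transmittance_pct, absorbance, or derivative.
    derivative_order : int
        0 for raw channels, ≥ 1 iff ``channel`` is derivative.
    meta : dict of str → str
        Free-form provenance (source file, instrument notes, parent window).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    channel: Channel = Channel.TRANSMITTANCE_PCT
    derivative_order: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.channel = Channel(self.channel)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise SpectrumDataError("wavenumbers and intensities must be 1-D arrays")
        if self.wavenumbers.size != self.intensities.size:
            raise SpectrumDataError(
                f"axis length {self.wavenumbers.size} != intensity length {self.intensities.size}"
            )
        if self.wavenumbers.size < 2:
            raise SpectrumDataError("a spectrum needs at least 2 points")
        d = np.diff(self.wavenumbers)
        if np.any(d <= 0):
            raise SpectrumDataError("wavenumbers must be strictly increasing")
        if self.channel is Channel.TRANSMITTANCE_PCT and np.any(self.intensities <= 0):
            bad = self.wavenumbers[np.argmax(self.intensities <= 0)]
            raise SpectrumDataError(
                f"%T channel requires positive intensities (violated at {bad:g} cm⁻¹)"
            )
        if (self.derivative_order > 0) != (self.channel is Channel.DERIVATIVE):
            raise SpectrumDataError(
                "derivative_order > 0 exactly when channel is 'derivative'"
            )

    def __len__(self) -> int:
        return self.wavenumbers.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavenumbers[0]), float(self.wavenumbers[-1])

    def copy(self) -> "Spectrum":
        return replace(
            self,
            wavenumbers=self.wavenumbers.copy(),
            intensities=self.intensities.copy(),
            meta=dict(self.meta),
        )


def _order_axis(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort (x, y) ascending in x; duplicate x values are a data error."""
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    dup = np.flatnonzero(np.diff(x) == 0)
    if dup.size:
        raise SpectrumDataError(
            f"duplicate wavenumber {x[dup[0]]:g} cm⁻¹; refusing to average"
        )
    return x, y


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def _read_csv(path: Path, *, channel: Channel | None, regional: bool) -> Spectrum:
    sep, decimal = (";", ",") if regional else (",", ".")
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith("#"):
            m = re.match(r"#\s*([\w.-]+)\s*=\s*(.*)", line)
            if m:
                meta[m.group(1)] = m.group(2).strip()
            continue
        if line.strip():
            body_lines.append(line)
    if not body_lines:
        raise SpectrumFormatError(f"{path}: no data rows")
    # optional single header line
    first = body_lines[0].split(sep)
    try:
        float(first[0].replace(decimal, "."))
    except ValueError:
        body_lines = body_lines[1:]
    try:
        df = pd.read_csv(
            io.StringIO("\n".join(body_lines)),
            sep=sep,
            decimal=decimal,
            header=None,
            usecols=[0, 1],
        )
        x = df[0].to_numpy(dtype=float)
        y = df[1].to_numpy(dtype=float)
    except (ValueError, KeyError, pd.errors.ParserError) as exc:
        raise SpectrumFormatError(f"{path}: cannot parse CSV body ({exc})") from exc
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise SpectrumFormatError(f"{path}: non-numeric value in CSV body")
    x, y = _order_axis(x, y)
    ch = channel or Channel(meta.get("channel", Channel.TRANSMITTANCE_PCT))
    order = int(meta.get("derivative_order", 1 if ch is Channel.DERIVATIVE else 0))
    meta.setdefault("source", str(path))
    return Spectrum(x, y, channel=ch, derivative_order=order, meta=meta)


def _write_csv(s: Spectrum, path: Path, *, regional: bool) -> None:
    sep, decimal = (";", ",") if regional else (",", ".")
    with open(path, "w") as fh:
        fh.write(f"# channel={s.channel.value}\n")
        fh.write(f"# derivative_order={s.derivative_order}\n")
        for k, v in s.meta.items():
            if k not in ("channel", "derivative_order"):
                fh.write(f"# {k}={v}\n")
        fh.write(f"wavenumber_cm-1{sep}intensity\n")
        for x, y in zip(s.wavenumbers, s.intensities):
            row = f"{x:.12g}{sep}{y:.12g}"
            if regional:
                row = row.replace(".", ",").replace(f"{sep}", ";")  # decimal comma
            fh.write(row + "\n")


# ---------------------------------------------------------------------------
# JCAMP-DX (##XYDATA=(X++(Y..Y)), AFFN + simple SQZ; single block only)
# ---------------------------------------------------------------------------

_SQZ_POS = {c: str(i) for i, c in enumerate("@ABCDEFGHI")}
_SQZ_NEG = {c: str(i) for i, c in enumerate("abcdefghi", start=1)}
_DIF_DUP = set("JKLMNOPQR%jklmnopqrSTUVWXYZs")


def _tokenize_asdf(line: str, lineno: int) -> list[float]:
    """Split one XYDATA line into numbers, decoding SQZ pseudo-digits.

    'e'/'E' after a digit and followed by a digit or sign is read as an AFFN
    exponent, not as the SQZ pseudo-digit ±5 — SQZ streams are scaled
    integers and do not carry exponents.
    """
    out: list[str] = []
    cur = ""
    for i, ch in enumerate(line):
        nxt = line[i + 1] if i + 1 < len(line) else ""
        is_exponent = (
            ch in "eE" and cur and cur[-1].isdigit() and (nxt.isdigit() or nxt in "+-")
        )
        if ch in " \t,;":
            if cur:
                out.append(cur)
            cur = ""
        elif is_exponent:
            cur += ch
        elif ch in "+-" and cur and cur[-1] not in "eE":
            out.append(cur)
            cur = ch
        elif ch in _SQZ_POS:
            if cur:
                out.append(cur)
            cur = _SQZ_POS[ch]
        elif ch in _SQZ_NEG:
            if cur:
                out.append(cur)
            cur = "-" + _SQZ_NEG[ch]
        elif ch in _DIF_DUP:
            raise SpectrumFormatError(
                f"line {lineno}: DIF/DUP compressed JCAMP data are not supported"
            )
        else:
            cur += ch
    if cur:
        out.append(cur)
    try:
        return [float(t) for t in out if t not in ("+", "-")]
    except ValueError as exc:
        raise SpectrumFormatError(f"line {lineno}: bad numeric token ({exc})") from exc


def _read_jcamp(path: Path, *, channel: Channel | None) -> Spectrum:
    ldrs: dict[str, str] = {}
    data_rows: list[tuple[float, list[float]]] = []
    in_data = False
    n_titles = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("$$")[0].rstrip()
        if not line:
            continue
        if line.startswith("##"):
            in_data = False
            try:
                key, _, val = line[2:].partition("=")
            except ValueError:
                raise SpectrumFormatError(f"{path}: line {lineno}: malformed label '{raw}'")
            key = key.strip().upper().replace(" ", "")
            ldrs[key] = val.strip()
            if key == "TITLE":
                n_titles += 1
                if n_titles > 1:
                    raise SpectrumFormatError(
                        f"{path}: line {lineno}: multi-block JCAMP files are not supported"
                    )
            if key == "BLOCKS":
                raise SpectrumFormatError(
                    f"{path}: line {lineno}: compound (##BLOCKS) JCAMP files are not supported"
                )
            if key == "XYDATA":
                if "(X++(Y..Y))" not in val.replace(" ", ""):
                    raise SpectrumFormatError(
                        f"{path}: line {lineno}: only ##XYDATA=(X++(Y..Y)) is supported, got '{val}'"
                    )
                in_data = True
            continue
        if in_data:
            nums = _tokenize_asdf(line, lineno)
            if len(nums) < 2:
                raise SpectrumFormatError(f"{path}: line {lineno}: XYDATA row needs X and ≥1 Y")
            data_rows.append((nums[0], nums[1:]))
    if not data_rows:
        raise SpectrumFormatError(f"{path}: no ##XYDATA table found")
    if ldrs.get("XUNITS", "1/CM").upper() not in ("1/CM", "1/CM."):
        raise SpectrumFormatError(f"{path}: unsupported XUNITS '{ldrs['XUNITS']}'")

    xfactor = float(ldrs.get("XFACTOR", 1.0))
    yfactor = float(ldrs.get("YFACTOR", 1.0))
    firstx = float(ldrs["FIRSTX"]) if "FIRSTX" in ldrs else data_rows[0][0] * xfactor
    lastx = float(ldrs["LASTX"]) if "LASTX" in ldrs else None

    ys: list[float] = []
    for _, row in data_rows:
        ys.extend(row)
    npoints = int(ldrs.get("NPOINTS", len(ys)))
    if npoints != len(ys):
        raise SpectrumFormatError(
            f"{path}: ##NPOINTS={npoints} but {len(ys)} Y values present"
        )
    y = np.asarray(ys, dtype=float) * yfactor
    if lastx is None:
        raise SpectrumFormatError(f"{path}: ##LASTX required for (X++(Y..Y)) data")
    if npoints < 2:
        raise SpectrumFormatError(f"{path}: need at least 2 points")
    x = np.linspace(firstx, lastx, npoints)
    if firstx > lastx:  # descending export: reorder in lockstep
        x, y = x[::-1], y[::-1]
    x, y = _order_axis(x, y)

    meta = {"source": str(path)}
    if "TITLE" in ldrs:
        meta["title"] = ldrs["TITLE"]
    ch_label = ldrs.get("$CHANNEL")
    if channel is not None:
        ch = channel
    elif ch_label:
        ch = Channel(ch_label.lower())
    else:
        yunits = ldrs.get("YUNITS", "").upper()
        if "ABSORBANCE" in yunits:
            ch = Channel.ABSORBANCE
        elif "DERIVATIVE" in yunits:
            ch = Channel.DERIVATIVE
        else:
            ch = Channel.TRANSMITTANCE_PCT
    order = int(ldrs.get("$DERIVATIVEORDER", 1 if ch is Channel.DERIVATIVE else 0))
    return Spectrum(x, y, channel=ch, derivative_order=order, meta=meta)


_YUNITS = {
    Channel.TRANSMITTANCE_PCT: "TRANSMITTANCE",
    Channel.ABSORBANCE: "ABSORBANCE",
    Channel.DERIVATIVE: "DERIVATIVE ABSORBANCE",
}


def _write_jcamp(s: Spectrum, path: Path) -> None:
    x, y = s.wavenumbers, s.intensities
    with open(path, "w") as fh:
        fh.write(f"##TITLE={s.meta.get('title', 'ftirquant spectrum')}\n")
        fh.write("##JCAMP-DX=4.24\n")
        fh.write("##DATA TYPE=INFRARED SPECTRUM\n")
        fh.write("##XUNITS=1/CM\n")
        fh.write(f"##YUNITS={_YUNITS[s.channel]}\n")
        fh.write(f"##$CHANNEL={s.channel.value}\n")
        fh.write(f"##$DERIVATIVE ORDER={s.derivative_order}\n")
        fh.write("##XFACTOR=1.0\n")
        fh.write("##YFACTOR=1.0\n")
        fh.write(f"##FIRSTX={x[0]:.12g}\n")
        fh.write(f"##LASTX={x[-1]:.12g}\n")
        fh.write(f"##NPOINTS={x.size}\n")
        fh.write("##XYDATA=(X++(Y..Y))\n")
        per_line = 6
        for i in range(0, x.size, per_line):
            ys = " ".join(f"{v:.12g}" for v in y[i : i + per_line])
            fh.write(f"{x[i]:.12g} {ys}\n")
        fh.write("##END=\n")


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def read_spectrum(
    path,
    format: str = "auto",
    *,
    channel: Channel | str | None = None,
    regional_csv: bool = False,
) -> Spectrum:
    """Read a spectrum from JCAMP-DX or CSV, normalizing to an ascending axis.

    ``format`` is ``jcamp``, ``csv``, or ``auto`` (sniff: ``##TITLE`` marks
    JCAMP).  ``channel`` overrides any channel recorded in the file;
    absent both, %transmittance is assumed.  ``regional_csv`` switches CSV
    parsing to semicolon separators with comma decimals.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ch = Channel(channel) if channel is not None else None
    if format == "auto":
        head = path.read_text()[:200].lstrip()
        format = "jcamp" if head.startswith("##") else "csv"
    if format == "jcamp":
        return _read_jcamp(path, channel=ch)
    if format == "csv":
        return _read_csv(path, channel=ch, regional=regional_csv)
    raise ValueError(f"unknown format '{format}'")


def write_spectrum(s: Spectrum, path, format: str = "auto", *, regional_csv: bool = False) -> None:
    """Write a spectrum; round-trips through :func:`read_spectrum` within 1e-9.

    ``format='auto'`` picks by extension (``.jdx``/``.dx``/``.jcamp`` →
    JCAMP, anything else CSV).
    """
    path = Path(path)
    if format == "auto":
        format = "jcamp" if path.suffix.lower() in (".jdx", ".dx", ".jcamp") else "csv"
    if format == "jcamp":
        _write_jcamp(s, path)
    elif format == "csv":
        _write_csv(s, path, regional=regional_csv)
    else:
        raise ValueError(f"unknown format '{format}'")


def transmittance_to_absorbance(s: Spectrum) -> Spectrum:
    """Convert %T to absorbance, A(ν) = 2 − log10(T%(ν))."""
    if s.channel is not Channel.TRANSMITTANCE_PCT:
        raise ValueError(f"expected transmittance_pct channel, got {s.channel.value}")
    bad = np.flatnonzero(s.intensities <= 0)
    if bad.size:
        raise ValueError(
            f"nonpositive %T at {s.wavenumbers[bad[0]]:g} cm⁻¹; cannot take log"
        )
    a = 2.0 - np.log10(s.intensities)
    meta = dict(s.meta)
    return Spectrum(s.wavenumbers.copy(), a, channel=Channel.ABSORBANCE, meta=meta)


def absorbance_to_transmittance(s: Spectrum) -> Spectrum:
    """Inverse of :func:`transmittance_to_absorbance`: T% = 10^(2 − A)."""
    if s.channel is not Channel.ABSORBANCE:
        raise ValueError(f"expected absorbance channel, got {s.channel.value}")
    t = np.power(10.0, 2.0 - s.intensities)
    return Spectrum(s.wavenumbers.copy(), t, channel=Channel.TRANSMITTANCE_PCT, meta=dict(s.meta))


def resample_uniform(s: Spectrum, step: float) -> Spectrum:
    """Linearly interpolate onto an equispaced grid spanning the full axis.

    Both endpoints are preserved; when the span is not an exact multiple of
    ``step`` the actual step is adjusted to the nearest value that divides
    the span (recorded in ``meta['resample_step']``).
    """
    lo, hi = s.span
    span = hi - lo
    if step <= 0:
        raise ValueError("step must be positive")
    if step > span:
        raise ValueError(f"step {step:g} exceeds axis span {span:g}")
    n = max(1, round(span / step))
    grid = np.linspace(lo, hi, n + 1)
    y = np.interp(grid, s.wavenumbers, s.intensities)
    meta = dict(s.meta)
    meta["resample_step"] = f"{span / n:.12g}"
    return Spectrum(grid, y, channel=s.channel, derivative_order=s.derivative_order, meta=meta)


def is_uniform(s: Spectrum, rtol: float = 1e-6) -> bool:
    """True if the wavenumber grid is equispaced to relative tolerance ``rtol``."""
    d = np.diff(s.wavenumbers)
    return bool(np.all(np.abs(d - d.mean()) <= rtol * abs(d.mean())))
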