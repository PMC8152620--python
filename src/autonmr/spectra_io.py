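"""Raw NMR data input and Fourier processing.

Reads time-domain data from a minimal Bruker-style acquisition directory
(binary ``fid`` plus an ``acqus`` key/value parameter file) or from a 1D
JCAMP-DX file, and turns a free induction decay into a frequency-domain
spectrum with a calibrated ppm axis.

Only one Bruker dialect is supported -- the parameter set written by the
synthetic fixture generator (sweep width, carrier offset, spectrometer
frequency, point count, byte order, data type, group delay).  Anything
else is rejected explicitly rather than misread silently.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "RawFID",
    "Spectrum",
    "InputError",
    "UnsupportedFormatError",
    "read_bruker",
    "read_jcamp",
    "write_bruker",
    "write_jcamp",
    "transform",
]


class InputError(ValueError):
    """Raised when an input file is missing, truncated or inconsistent."""


class UnsupportedFormatError(InputError):
    """Raised for dialects the reader deliberately does not handle."""


@dataclass
class RawFID:
    """Complex time-domain NMR signal with acquisition metadata.

    Attributes
    ----------
    points : ndarray of complex
        The free induction decay.
    spectrometer_frequency : float
        Observe frequency in MHz.
    sweep_width : float
        Spectral width in Hz.
    frequency_offset : float
        Carrier position in Hz relative to the zero-ppm reference.
    nucleus : str
        ``"H1"`` or ``"C13"``.
    solvent : str
        Solvent label, e.g. ``"chloroform"``.
    group_delay : float
        Digital-filter group delay in points (0 when absent).
    """

    points: np.ndarray
    spectrometer_frequency: float
    sweep_width: float
    frequency_offset: float = 0.0
    nucleus: str = "H1"
    solvent: str = "chloroform"
    group_delay: float = 0.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=complex)
        if self.points.size == 0:
            raise InputError("FID contains no points")
        if self.sweep_width <= 0:
            raise InputError("sweep_width must be positive")
        if self.spectrometer_frequency <= 0:
            raise InputError("spectrometer_frequency must be positive")

    @property
    def dwell_time(self) -> float:
        return 1.0 / self.sweep_width


@dataclass
class Spectrum:
    """Frequency-domain trace over a descending ppm axis."""

    intensity: np.ndarray
    ppm_axis: np.ndarray
    nucleus: str = "H1"
    solvent: str = "chloroform"
    spectrometer_frequency: float = 400.0
    noise_sigma: float | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=complex)
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=float)
        if self.intensity.shape != self.ppm_axis.shape:
            raise InputError("intensity and ppm_axis lengths differ")
        d = np.diff(self.ppm_axis)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise InputError("ppm_axis must be strictly monotone")

    @property
    def real(self) -> np.ndarray:
        return self.intensity.real

    @property
    def n_points(self) -> int:
        return self.intensity.size

    @property
    def ppm_per_point(self) -> float:
        return abs(float(self.ppm_axis[1] - self.ppm_axis[0]))

    @property
    def hz_per_point(self) -> float:
        return self.ppm_per_point * self.spectrometer_frequency

    def index_of_ppm(self, ppm: float) -> int:
        """Index of the axis point closest to ``ppm``."""
        return int(np.argmin(np.abs(self.ppm_axis - ppm)))

    def copy(self) -> "Spectrum":
        return Spectrum(
            self.intensity.copy(),
            self.ppm_axis.copy(),
            nucleus=self.nucleus,
            solvent=self.solvent,
            spectrometer_frequency=self.spectrometer_frequency,
            noise_sigma=self.noise_sigma,
        )


# ---------------------------------------------------------------------------
# Bruker-style directory I/O
# ---------------------------------------------------------------------------

_NUCLEUS_MAP = {"1H": "H1", "13C": "C13"}
_NUCLEUS_INV = {v: k for k, v in _NUCLEUS_MAP.items()}

#: acqus keys the reader requires.
_REQUIRED_KEYS = ("SW_h", "SFO1", "O1", "TD", "BYTORDA", "DTYPA")

_DTYPES = {0: np.dtype("i4"), 2: np.dtype("f8")}


def _parse_acqus(path: Path) -> dict[str, str]:
    params: dict[str, str] = {}
    for line in path.read_text().splitlines():
        m = re.match(r"##\$?([A-Za-z0-9_]+)\s*=\s*(.*)", line.strip())
        if m:
            params[m.group(1)] = m.group(2).strip()
    return params


def read_bruker(directory_path: str | Path) -> RawFID:
    """Read a minimal Bruker-style acquisition directory.

    The directory must contain a binary ``fid`` (interleaved real/imaginary
    values) and an ``acqus`` parameter file declaring sweep width (SW_h),
    spectrometer frequency (SFO1), carrier offset (O1), total point count
    (TD, counting real and imaginary separately), byte order (BYTORDA,
    0=little 1=big endian), data type (DTYPA, 0=int32 2=float64) and
    optionally GRPDLY, NUC1 and SOLVENT.
    """
    directory_path = Path(directory_path)
    acqus = directory_path / "acqus"
    fid_path = directory_path / "fid"
    if not acqus.is_file():
        raise InputError(f"missing parameter file: {acqus}")
    if not fid_path.is_file():
        raise InputError(f"missing FID file: {fid_path}")
    params = _parse_acqus(acqus)
    for key in _REQUIRED_KEYS:
        if key not in params:
            raise InputError(f"acqus is missing required key {key}")

    dtypa = int(params["DTYPA"])
    if dtypa not in _DTYPES:
        raise UnsupportedFormatError(f"unsupported DTYPA={dtypa} (expected 0 or 2)")
    dtype = _DTYPES[dtypa]
    byte_order = "<" if int(params["BYTORDA"]) == 0 else ">"
    raw = np.frombuffer(fid_path.read_bytes(), dtype=dtype.newbyteorder(byte_order))

    td = int(params["TD"])
    if raw.size < td:
        raise InputError(
            f"truncated FID: expected {td} values, found {raw.size}"
        )
    raw = raw[:td].astype(float)
    points = raw[0::2] + 1j * raw[1::2]

    nuc = params.get("NUC1", "<1H>").strip("<>")
    return RawFID(
        points=points,
        spectrometer_frequency=float(params["SFO1"]),
        sweep_width=float(params["SW_h"]),
        frequency_offset=float(params["O1"]),
        nucleus=_NUCLEUS_MAP.get(nuc, nuc),
        solvent=params.get("SOLVENT", "<chloroform>").strip("<>"),
        group_delay=float(params.get("GRPDLY", 0.0)),
    )


def write_bruker(
    fid: RawFID,
    directory_path: str | Path,
    *,
    byte_order: str = "<",
    dtype: str = "f8",
) -> Path:
    """Write a RawFID as a fixture acquisition directory (inverse of read)."""
    directory_path = Path(directory_path)
    directory_path.mkdir(parents=True, exist_ok=True)
    dtypa = {"i4": 0, "f8": 2}[dtype]
    interleaved = np.empty(2 * fid.points.size)
    interleaved[0::2] = fid.points.real
    interleaved[1::2] = fid.points.imag
    np_dtype = _DTYPES[dtypa].newbyteorder(byte_order)
    (directory_path / "fid").write_bytes(interleaved.astype(np_dtype).tobytes())
    lines = [
        "##TITLE= synthetic fixture",
        f"##$TD= {2 * fid.points.size}",
        f"##$SW_h= {fid.sweep_width!r}",
        f"##$SFO1= {fid.spectrometer_frequency!r}",
        f"##$O1= {fid.frequency_offset!r}",
        f"##$BYTORDA= {0 if byte_order == '<' else 1}",
        f"##$DTYPA= {dtypa}",
        f"##$GRPDLY= {fid.group_delay!r}",
        f"##$NUC1= <{_NUCLEUS_INV.get(fid.nucleus, fid.nucleus)}>",
        f"##$SOLVENT= <{fid.solvent}>",
        "##END=",
    ]
    (directory_path / "acqus").write_text("\n".join(lines) + "\n")
    return directory_path


# ---------------------------------------------------------------------------
# JCAMP-DX (AFFN only)
# ---------------------------------------------------------------------------

def _jcamp_headers(text: str) -> dict[str, str]:
    headers: dict[str, str] = {}
    for m in re.finditer(r"^##([^=]+)=\s*(.*)$", text, flags=re.M):
        headers[m.group(1).strip().upper().replace(" ", "")] = m.group(2).strip()
    return headers


_ASDF_CHARS = re.compile(r"[A-DF-Zia-dh-z@%]")


def _parse_affn_table(block: str, yfactor: float) -> np.ndarray:
    values: list[float] = []
    for line in block.strip().splitlines():
        line = line.strip()
        if not line or line.startswith("##"):
            continue
        if _ASDF_CHARS.search(line):
            raise UnsupportedFormatError(
                "ASDF-compressed JCAMP data tables are not supported (AFFN only)"
            )
        nums = [float(v) for v in re.split(r"[,\s]+", line) if v]
        values.extend(nums[1:])  # first value per line is the X check value
    return np.asarray(values) * yfactor


def read_jcamp(file_path: str | Path):
    """Read a 1D JCAMP-DX record (AFFN encoding only).

    Time-domain records (``NMR FID``, stored as an NTUPLES block with real
    and imaginary pages) map to :class:`RawFID`; frequency-domain records
    (``NMR SPECTRUM`` with an ``##XYDATA`` table) map to :class:`Spectrum`.
    """
    file_path = Path(file_path)
    if not file_path.is_file():
        raise InputError(f"no such file: {file_path}")
    text = file_path.read_text()
    if "##TITLE" not in text:
        raise InputError(f"{file_path} is not a JCAMP-DX file (missing ##TITLE)")
    headers = _jcamp_headers(text)
    datatype = headers.get("DATATYPE", "").upper()

    if "FID" in datatype or "##NTUPLES" in text:
        return _read_jcamp_fid(text, headers)
    if "##XYDATA" in text:
        return _read_jcamp_spectrum(text, headers)
    raise UnsupportedFormatError(
        f"unsupported JCAMP-DX dialect (DATATYPE={datatype!r})"
    )


def _require(headers: dict[str, str], key: str) -> float:
    if key not in headers:
        raise InputError(f"JCAMP record is missing ##{key}")
    return float(headers[key].split()[0])


def _read_jcamp_spectrum(text: str, headers: dict[str, str]) -> Spectrum:
    first = _require(headers, "FIRSTX")
    last = _require(headers, "LASTX")
    npoints = int(_require(headers, "NPOINTS"))
    yfactor = float(headers.get("YFACTOR", "1"))
    sfo = float(headers.get(".OBSERVEFREQUENCY", "400.0"))
    block = text.split("##XYDATA=", 1)[1]
    block = block.split("##END", 1)[0]
    block = "\n".join(block.splitlines()[1:])  # drop the (X++(Y..Y)) form line
    y = _parse_affn_table(block, yfactor)
    if y.size != npoints:
        raise InputError(f"JCAMP NPOINTS={npoints} but table holds {y.size}")
    xunits = headers.get("XUNITS", "PPM").upper()
    axis = np.linspace(first, last, npoints)
    if "HZ" in xunits:
        axis = axis / sfo
    nuc = headers.get(".OBSERVENUCLEUS", "^1H").strip("^")
    return Spectrum(
        intensity=y.astype(complex),
        ppm_axis=axis,
        nucleus=_NUCLEUS_MAP.get(nuc, nuc),
        solvent=headers.get(".SOLVENTNAME", "chloroform"),
        spectrometer_frequency=sfo,
    )


def _read_jcamp_fid(text: str, headers: dict[str, str]) -> RawFID:
    pages = re.split(r"##PAGE=", text)[1:]
    if len(pages) < 2:
        raise UnsupportedFormatError("JCAMP FID must carry real and imaginary pages")
    comps: list[np.ndarray] = []
    for page in pages[:2]:
        body = re.split(r"##DATA\s?TABLE=", page, maxsplit=1)
        if len(body) != 2:
            raise InputError("JCAMP FID page lacks a ##DATA TABLE")
        table = body[1].split("##", 1)[0]
        table = "\n".join(table.splitlines()[1:])
        comps.append(_parse_affn_table(table, 1.0))
    real, imag = comps
    if real.size != imag.size:
        raise InputError("real and imaginary pages differ in length")
    sw = _require(headers, ".SPECTRALWIDTH" if ".SPECTRALWIDTH" in headers else "SW_H")
    sfo = float(headers.get(".OBSERVEFREQUENCY", "400.0"))
    nuc = headers.get(".OBSERVENUCLEUS", "^1H").strip("^")
    return RawFID(
        points=real + 1j * imag,
        spectrometer_frequency=sfo,
        sweep_width=sw,
        frequency_offset=float(headers.get("$O1", "0.0")),
        nucleus=_NUCLEUS_MAP.get(nuc, nuc),
        solvent=headers.get(".SOLVENTNAME", "chloroform"),
        group_delay=float(headers.get("$GRPDLY", "0.0")),
    )


def write_jcamp(obj: RawFID | Spectrum, file_path: str | Path) -> Path:
    """Write a RawFID (NTUPLES pages) or Spectrum (XYDATA) as AFFN JCAMP-DX."""
    file_path = Path(file_path)
    lines = ["##TITLE= synthetic fixture", "##JCAMP-DX= 5.00"]
    if isinstance(obj, Spectrum):
        y = obj.real
        lines += [
            "##DATA TYPE= NMR SPECTRUM",
            f"##.OBSERVE FREQUENCY= {float(obj.spectrometer_frequency)!r}",
            f"##.OBSERVE NUCLEUS= ^{_NUCLEUS_INV.get(obj.nucleus, obj.nucleus)}",
            f"##.SOLVENT NAME= {obj.solvent}",
            "##XUNITS= PPM",
            "##YUNITS= ARBITRARY",
            f"##FIRSTX= {float(obj.ppm_axis[0])!r}",
            f"##LASTX= {float(obj.ppm_axis[-1])!r}",
            f"##NPOINTS= {y.size}",
            "##YFACTOR= 1.0",
            "##XYDATA= (X++(Y..Y))",
        ]
        for i in range(0, y.size, 6):
            chunk = " ".join(repr(float(v)) for v in y[i : i + 6])
            lines.append(f"{float(obj.ppm_axis[i])!r} {chunk}")
    else:
        lines += [
            "##DATA TYPE= NMR FID",
            f"##.OBSERVE FREQUENCY= {obj.spectrometer_frequency!r}",
            f"##.OBSERVE NUCLEUS= ^{_NUCLEUS_INV.get(obj.nucleus, obj.nucleus)}",
            f"##.SOLVENT NAME= {obj.solvent}",
            f"##.SPECTRAL WIDTH= {obj.sweep_width!r}",
            f"##$O1= {obj.frequency_offset!r}",
            f"##$GRPDLY= {obj.group_delay!r}",
            "##NTUPLES= NMR FID",
        ]
        for name, comp in (("R", obj.points.real), ("I", obj.points.imag)):
            lines.append(f"##PAGE= N={name}")
            lines.append("##DATA TABLE= (X++(R..R)), XYDATA")
            for i in range(0, comp.size, 6):
                chunk = " ".join(repr(float(v)) for v in comp[i : i + 6])
                lines.append(f"{i} {chunk}")
        lines.append("##END NTUPLES= NMR FID")
    lines.append("##END=")
    file_path.write_text("\n".join(lines) + "\n")
    return file_path


# ---------------------------------------------------------------------------
# Fourier processing
# ---------------------------------------------------------------------------

def _next_pow2(n: int) -> int:
    return 1 << (n - 1).bit_length()


def transform(
    fid: RawFID,
    line_broadening: float | None = None,
    zero_fill_factor: int = 2,
) -> Spectrum:
    """Apodize, zero fill and Fourier transform a FID.

    Parameters
    ----------
    fid : RawFID
    line_broadening : float, optional
        Exponential line broadening in Hz.  Defaults to 0.3 Hz for proton
        and 1.0 Hz for carbon spectra.
    zero_fill_factor : int
        Data are zero filled to ``zero_fill_factor`` times the next power
        of two above the acquired length.

    Returns
    -------
    Spectrum
        Frequency-domain spectrum on a descending ppm axis; the carrier
        sits at ``frequency_offset / spectrometer_frequency`` ppm in the
        centre of the sweep.
    """
    if line_broadening is None:
        line_broadening = 0.3 if fid.nucleus == "H1" else 1.0
    if line_broadening < 0:
        raise ValueError("line_broadening must be non-negative")
    if zero_fill_factor < 1:
        raise ValueError("zero_fill_factor must be >= 1")

    points = fid.points
    shift = int(round(fid.group_delay))
    if shift:
        # circular left shift puts the first genuine point at t=0
        points = np.roll(points, -shift)

    n = points.size
    t = np.arange(n) * fid.dwell_time
    apod = np.exp(-math.pi * line_broadening * t)
    data = points * apod

    n_out = zero_fill_factor * _next_pow2(n)
    spec = np.fft.fftshift(np.fft.fft(data, n=n_out))
    freqs = np.fft.fftshift(np.fft.fftfreq(n_out, d=fid.dwell_time))

    carrier_ppm = fid.frequency_offset / fid.spectrometer_frequency
    ppm = carrier_ppm + freqs / fid.spectrometer_frequency
    # descending ppm (display convention)
    return Spectrum(
        intensity=spec[::-1],
        ppm_axis=ppm[::-1],
        nucleus=fid.nucleus,
        solvent=fid.solvent,
        spectrometer_frequency=fid.spectrometer_frequency,
    )
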