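"""Recording data model, on-disk formats, and global pre-analysis corrections.

The central containers are :class:`Trace` (one uniformly sampled channel),
:class:`StepProtocol` (the command waveform shared by a family of sweeps) and
:class:`SweepSeries` (the sweeps plus recording metadata).  All downstream
analysis modules consume these types only.

Two interchangeable on-disk representations are provided: a columnar text
format with a ``key: value`` header block (inspectable, bit-exact round
trips) and an HDF5 container for large files.  Voltages are stored
uncorrected; the liquid-junction-potential correction is applied explicitly
with :func:`apply_junction_correction` and recorded in the metadata so it can
never be applied twice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Trace",
    "StepProtocol",
    "SweepSeries",
    "QCReport",
    "FormatError",
    "load_recording",
    "write_recording",
    "apply_junction_correction",
    "qc_recording",
]

VALID_UNITS = ("mV", "pA", "dF/F", "AU")
VALID_ROLES = ("membrane_voltage", "membrane_current", "command", "fluorescence")

#: units admissible for each trace role
ROLE_UNITS = {
    "membrane_voltage": ("mV",),
    "membrane_current": ("pA",),
    "command": ("mV", "pA"),
    "fluorescence": ("dF/F", "AU"),
}


class FormatError(ValueError):
    """Raised when an on-disk recording is malformed."""


@dataclass(frozen=True)
class Trace:
    """One uniformly sampled channel.

    Parameters
    ----------
    samples : array-like
        Sample values in ``units``.
    dt : float
        Seconds per sample (``> 0``).
    units : str
        One of ``mV``, ``pA``, ``dF/F``, ``AU``; must be consistent with
        ``role`` (a membrane-voltage trace is always in mV).
    role : str
        ``membrane_voltage``, ``membrane_current``, ``command`` or
        ``fluorescence``.
    lowpass_cutoff : float, optional
        Acquisition low-pass filter corner (Hz), if known.
    """

    samples: np.ndarray
    dt: float
    units: str
    role: str
    lowpass_cutoff: float | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("trace needs a 1-D array of at least 2 samples")
        object.__setattr__(self, "samples", samples)
        if not (self.dt > 0):
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.units not in VALID_UNITS:
            raise ValueError(f"unknown units {self.units!r}")
        if self.role not in VALID_ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.units not in ROLE_UNITS[self.role]:
            raise ValueError(
                f"units {self.units!r} inconsistent with role {self.role!r}"
            )

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Sweep duration in seconds (t=0 at the first sample)."""
        return self.samples.size * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt

    def index_at(self, t: float) -> int:
        """Sample index containing time ``t`` (seconds from sweep start)."""
        return int(round(t / self.dt))


@dataclass(frozen=True)
class StepProtocol:
    """Square-step command protocol shared by a sweep family.

    ``holding`` and ``step_levels`` are in the native command units: pA for
    current clamp, mV for voltage clamp.  Times are seconds from sweep start.
    ``step_levels`` must be strictly monotone — one sweep per level, which
    also makes minimal-level searches (rheobase) unambiguous.
    """

    holding: float
    step_onset: float
    step_offset: float
    step_levels: np.ndarray

    def __post_init__(self) -> None:
        levels = np.asarray(self.step_levels, dtype=np.float64)
        if levels.ndim != 1 or levels.size == 0:
            raise ValueError("step_levels must be a non-empty 1-D sequence")
        object.__setattr__(self, "step_levels", levels)
        if not (0 <= self.step_onset < self.step_offset):
            raise ValueError("need 0 <= step_onset < step_offset")
        d = np.diff(levels)
        if levels.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("step_levels must be strictly monotone")

    @property
    def n_steps(self) -> int:
        return self.step_levels.size

    @property
    def step_duration(self) -> float:
        return self.step_offset - self.step_onset


@dataclass(frozen=True)
class SweepSeries:
    """Ordered sweeps sharing a command protocol.

    ``metadata`` holds recording conditions (temperature, blockers,
    ``junction_corrected`` flag, ``access_resistance`` in MΩ, ...) as a flat
    mapping of JSON-representable values.
    """

    sweeps: tuple[Trace, ...]
    protocol: StepProtocol
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sweeps = tuple(self.sweeps)
        if not sweeps:
            raise ValueError("SweepSeries needs at least one sweep")
        object.__setattr__(self, "sweeps", sweeps)
        dt0, n0 = sweeps[0].dt, sweeps[0].n
        for s in sweeps[1:]:
            if s.dt != dt0 or s.n != n0:
                raise ValueError("all sweeps must share dt and length")
        if len(sweeps) != self.protocol.n_steps:
            raise ValueError(
                f"{len(sweeps)} sweeps for {self.protocol.n_steps} protocol levels"
            )
        if self.protocol.step_offset > sweeps[0].duration + dt0 / 2:
            raise ValueError("protocol step extends beyond sweep duration")

    @property
    def dt(self) -> float:
        return self.sweeps[0].dt

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)

    @property
    def junction_corrected(self) -> bool:
        return bool(self.metadata.get("junction_corrected", False))

    def sweep_for_level(self, level: float) -> Trace:
        idx = np.flatnonzero(np.isclose(self.protocol.step_levels, level))
        if idx.size != 1:
            raise KeyError(f"no unique sweep at level {level}")
        return self.sweeps[int(idx[0])]


@dataclass(frozen=True)
class QCReport:
    """Outcome of pre-analysis quality-control gates."""

    access_resistance: float | None
    passed: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must be False iff reasons is nonempty")


# ---------------------------------------------------------------------------
# on-disk formats


_HEADER_MAGIC = "# neurotracekit-trace v1"


def _format_float(x: float) -> str:
    return repr(float(x))


def write_recording(series: SweepSeries, path: str | Path, format: str = "tsv") -> Path:
    """Write a :class:`SweepSeries` to disk.

    ``format`` is ``tsv`` (columnar text, one column per sweep, header block
    of ``key: value`` lines) or ``hdf5``.  Round trips through
    :func:`load_recording` are lossless: floats are written with ``repr`` so
    every IEEE double survives exactly.
    """
    path = Path(path)
    if format == "tsv":
        _write_tsv(series, path)
    elif format == "hdf5":
        _write_hdf5(series, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def _write_tsv(series: SweepSeries, path: Path) -> None:
    s0 = series.sweeps[0]
    lines = [_HEADER_MAGIC]
    lines.append(f"dt: {_format_float(s0.dt)}")
    lines.append(f"units: {s0.units}")
    lines.append(f"role: {s0.role}")
    if s0.lowpass_cutoff is not None:
        lines.append(f"lowpass_cutoff: {_format_float(s0.lowpass_cutoff)}")
    p = series.protocol
    lines.append(f"holding: {_format_float(p.holding)}")
    lines.append(f"step_onset: {_format_float(p.step_onset)}")
    lines.append(f"step_offset: {_format_float(p.step_offset)}")
    lines.append("step_levels: " + ",".join(_format_float(v) for v in p.step_levels))
    for key in sorted(series.metadata):
        lines.append(f"meta.{key}: {json.dumps(series.metadata[key])}")
    lines.append("---")
    data = np.column_stack([s.samples for s in series.sweeps])
    body = "\n".join("\t".join(_format_float(v) for v in row) for row in data)
    path.write_text("\n".join(lines) + "\n" + body + "\n")


def _write_hdf5(series: SweepSeries, path: Path) -> None:
    import h5py

    s0 = series.sweeps[0]
    with h5py.File(path, "w") as f:
        f.attrs["magic"] = _HEADER_MAGIC
        f.attrs["dt"] = s0.dt
        f.attrs["units"] = s0.units
        f.attrs["role"] = s0.role
        if s0.lowpass_cutoff is not None:
            f.attrs["lowpass_cutoff"] = s0.lowpass_cutoff
        f.attrs["metadata"] = json.dumps(series.metadata)
        f.create_dataset("sweeps", data=np.column_stack([s.samples for s in series.sweeps]))
        g = f.create_group("protocol")
        g.attrs["holding"] = series.protocol.holding
        g.attrs["step_onset"] = series.protocol.step_onset
        g.attrs["step_offset"] = series.protocol.step_offset
        g.create_dataset("step_levels", data=series.protocol.step_levels)


_REQUIRED_HEADER = ("dt", "units", "role", "holding", "step_onset", "step_offset", "step_levels")


def load_recording(path: str | Path, format: str | None = None) -> SweepSeries:
    """Load a recording written by :func:`write_recording`.

    ``format`` is inferred from the file when omitted (HDF5 magic bytes vs
    text header).  Raises :class:`FormatError` naming the missing field for a
    malformed header, and a structural error for ragged sweep columns.
    """
    path = Path(path)
    if format is None:
        with open(path, "rb") as f:
            format = "hdf5" if f.read(8).startswith(b"\x89HDF") else "tsv"
    if format == "hdf5":
        return _load_hdf5(path)
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    return _load_tsv(path)


def _load_tsv(path: Path) -> SweepSeries:
    text = path.read_text()
    if "---" not in text:
        raise FormatError(f"{path}: missing header/body separator '---'")
    head, body = text.split("\n---\n", 1)
    header: dict[str, str] = {}
    metadata: dict = {}
    for line in head.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise FormatError(f"{path}: malformed header line {line!r}")
        key, _, value = line.partition(":")
        key, value = key.strip(), value.strip()
        if key.startswith("meta."):
            metadata[key[5:]] = json.loads(value)
        else:
            header[key] = value
    for key in _REQUIRED_HEADER:
        if key not in header:
            raise FormatError(f"{path}: header missing required field {key!r}")
    rows = [line.split("\t") for line in body.splitlines() if line.strip()]
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"{path}: sweeps have unequal lengths (ragged columns)")
    data = np.array([[float(v) for v in r] for r in rows], dtype=np.float64)
    protocol = StepProtocol(
        holding=float(header["holding"]),
        step_onset=float(header["step_onset"]),
        step_offset=float(header["step_offset"]),
        step_levels=np.array([float(v) for v in header["step_levels"].split(",")]),
    )
    if data.shape[1] != protocol.n_steps:
        raise FormatError(
            f"{path}: {data.shape[1]} sweep columns for {protocol.n_steps} protocol levels"
        )
    lp = float(header["lowpass_cutoff"]) if "lowpass_cutoff" in header else None
    sweeps = [
        Trace(data[:, j], dt=float(header["dt"]), units=header["units"],
              role=header["role"], lowpass_cutoff=lp)
        for j in range(data.shape[1])
    ]
    return SweepSeries(tuple(sweeps), protocol, metadata)


def _load_hdf5(path: Path) -> SweepSeries:
    import h5py

    with h5py.File(path, "r") as f:
        for key in ("dt", "units", "role"):
            if key not in f.attrs:
                raise FormatError(f"{path}: missing attribute {key!r}")
        data = f["sweeps"][()]
        g = f["protocol"]
        protocol = StepProtocol(
            holding=float(g.attrs["holding"]),
            step_onset=float(g.attrs["step_onset"]),
            step_offset=float(g.attrs["step_offset"]),
            step_levels=g["step_levels"][()],
        )
        lp = float(f.attrs["lowpass_cutoff"]) if "lowpass_cutoff" in f.attrs else None
        sweeps = [
            Trace(data[:, j], dt=float(f.attrs["dt"]), units=str(f.attrs["units"]),
                  role=str(f.attrs["role"]), lowpass_cutoff=lp)
            for j in range(data.shape[1])
        ]
        metadata = json.loads(f.attrs.get("metadata", "{}"))
    return SweepSeries(tuple(sweeps), protocol, metadata)


# ---------------------------------------------------------------------------
# global corrections and QC


def apply_junction_correction(series: SweepSeries, jp: float = 10.0) -> SweepSeries:
    """Correct all reported membrane potentials for the liquid junction potential.

    Every voltage-valued quantity — membrane-voltage samples in current
    clamp, command levels and holding in voltage clamp — is shifted by
    ``-jp`` mV (default 10 mV, the calculated junction potential for a
    potassium-gluconate internal against ACSF).  Current-valued samples are
    untouched.  The series is flagged so a second application is refused.
    """
    if series.junction_corrected:
        raise ValueError("series is already junction-corrected")
    role = series.sweeps[0].role
    if role == "membrane_voltage":
        sweeps = tuple(replace(s, samples=s.samples - jp) for s in series.sweeps)
        protocol = series.protocol  # command levels are currents (pA)
    elif role == "membrane_current":
        sweeps = series.sweeps
        protocol = replace(
            series.protocol,
            holding=series.protocol.holding - jp,
            step_levels=series.protocol.step_levels - jp,
        )
    else:
        raise ValueError(f"junction correction undefined for role {role!r}")
    metadata = dict(series.metadata)
    metadata["junction_corrected"] = True
    metadata["junction_potential_mV"] = jp
    return SweepSeries(sweeps, protocol, metadata)


def qc_recording(series: SweepSeries, ra_limit: float = 25.0) -> QCReport:
    """Quality-control gate on pipette access resistance.

    Whole-cell recordings with access resistance above ``ra_limit`` MΩ
    (default 25 MΩ) fail with reason ``"access_resistance"``; a missing
    measurement fails with reason ``"indeterminate"``.
    """
    ra = series.metadata.get("access_resistance")
    reasons: list[str] = []
    if ra is None:
        reasons.append("indeterminate")
    elif ra > ra_limit:
        reasons.append("access_resistance")
    return QCReport(
        access_resistance=None if ra is None else float(ra),
        passed=not reasons,
        reasons=tuple(reasons),
    )
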