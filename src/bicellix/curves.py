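"""1D small-angle scattering curves and their on-disk representation.

The package-wide currency is the :class:`SASCurve`: a 1D profile
``(q, I(q), sigma)`` with ``q`` in inverse Angstrom and intensity in
arbitrary units.  Curves are immutable; every transformation returns a new
curve.  The canonical on-disk dialect is whitespace-separated three-column
ASCII with ``#`` comments (the de-facto 1D SAS exchange format); two-column
files yield a curve without uncertainties.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "SASCurve",
    "CurveSeries",
    "ValidationError",
    "read_sas_curve",
    "write_sas_curve",
    "read_series",
]

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


def _as_readonly(a) -> np.ndarray:
    arr = np.asarray(a, dtype=float).copy()
    arr.flags.writeable = False
    return arr


@dataclass(frozen=True, eq=False)
class SASCurve:
    """A 1D scattering profile I(q).

    Parameters
    ----------
    q : array
        Scattering-vector magnitudes, strictly increasing, all > 0 [1/Å].
    intensity : array
        I(q), arbitrary units; same length as ``q``.
    sigma : array, optional
        Per-point uncertainty, same units as intensity, all > 0.
    label : str
        Free-text sample / timepoint tag.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "q", _as_readonly(self.q))
        object.__setattr__(self, "intensity", _as_readonly(self.intensity))
        if self.sigma is not None:
            object.__setattr__(self, "sigma", _as_readonly(self.sigma))
        if self.q.ndim != 1 or len(self.q) == 0:
            raise ValidationError("q must be a non-empty 1D array")
        if np.any(self.q <= 0):
            raise ValidationError("all q must be > 0")
        if np.any(np.diff(self.q) <= 0):
            raise ValidationError("q must be strictly increasing")
        if self.intensity.shape != self.q.shape:
            raise ValidationError("intensity and q must have identical length")
        if self.sigma is not None:
            if self.sigma.shape != self.q.shape:
                raise ValidationError("sigma and q must have identical length")
            if np.any(self.sigma <= 0):
                raise ValidationError("all sigma must be > 0")

    def __len__(self) -> int:
        return len(self.q)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SASCurve):
            return NotImplemented
        same_sigma = (
            (self.sigma is None and other.sigma is None)
            or (
                self.sigma is not None
                and other.sigma is not None
                and np.array_equal(self.sigma, other.sigma)
            )
        )
        return (
            np.array_equal(self.q, other.q)
            and np.array_equal(self.intensity, other.intensity)
            and same_sigma
            and self.label == other.label
        )

    __hash__ = object.__hash__

    @property
    def q_range(self) -> tuple[float, float]:
        """(q_min, q_max) of the measured window [1/Å]."""
        return float(self.q[0]), float(self.q[-1])

    def window(self, q_lo: float, q_hi: float) -> "SASCurve":
        """Return the sub-curve with q_lo <= q <= q_hi."""
        m = (self.q >= q_lo) & (self.q <= q_hi)
        if not np.any(m):
            raise ValidationError(f"no points in window [{q_lo}, {q_hi}]")
        return SASCurve(
            self.q[m],
            self.intensity[m],
            None if self.sigma is None else self.sigma[m],
            label=self.label,
        )

    def with_(self, **kw) -> "SASCurve":
        """Functional update returning a new validated curve."""
        return replace(self, **kw)


@dataclass(frozen=True)
class CurveSeries:
    """An ordered time series of SAS curves (acquisition times in days)."""

    curves: tuple[SASCurve, ...]
    times: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "curves", tuple(self.curves))
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        if len(self.times) != len(self.curves):
            raise ValidationError("times and curves must have equal length")
        if any(b < a for a, b in zip(self.times, self.times[1:])):
            raise ValidationError("times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.curves)

    def __iter__(self) -> Iterator[tuple[float, SASCurve]]:
        return iter(zip(self.times, self.curves))


def read_sas_curve(
    path: str | Path,
    dialect: str = "plain3col",
    allow_comma: bool = False,
    label: str | None = None,
) -> SASCurve:
    """Read a 1D SAS curve from whitespace-separated ASCII.

    Lines starting with ``#`` are comments; rows with q <= 0 are rejected
    (their count is logged).  Two numeric columns yield a curve without
    sigma; three or more use the third column as sigma.

    Raises
    ------
    ValidationError
        On a malformed numeric row (naming the line number) or
        non-increasing q.
    """
    if dialect not in ("plain3col", "cansas1d-text"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    path = Path(path)
    rows: list[list[float]] = []
    ncols: int | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if allow_comma:
                s = s.replace(",", " ")
            parts = s.split()
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise ValidationError(
                    f"{path}: malformed numeric row at line {lineno}: {line!r}"
                ) from exc
            if len(vals) < 2:
                raise ValidationError(
                    f"{path}: need >= 2 numeric columns at line {lineno}"
                )
            if ncols is None:
                ncols = min(len(vals), 3)
            rows.append(vals[:3])
    if not rows:
        raise ValidationError(f"{path}: no data rows")
    n_in = len(rows)
    kept = [r for r in rows if r[0] > 0]
    n_rejected = n_in - len(kept)
    if n_rejected:
        logger.warning("%s: rejected %d rows with q <= 0", path, n_rejected)
    if not kept:
        raise ValidationError(f"{path}: all rows have q <= 0")
    q = np.array([r[0] for r in kept])
    i = np.array([r[1] for r in kept])
    sigma = None
    if ncols is not None and ncols >= 3 and all(len(r) >= 3 for r in kept):
        sigma = np.array([r[2] for r in kept])
    return SASCurve(q, i, sigma, label=label if label is not None else path.stem)


def write_sas_curve(curve: SASCurve, path: str | Path) -> None:
    """Write a curve as three-column (or two-column, if no sigma) ASCII.

    The round trip ``read_sas_curve(write_sas_curve(c))`` reproduces all
    columns to better than 1e-12 relative (full float repr is written).
    """
    path = Path(path)
    cols = [curve.q, curve.intensity]
    header = "# q[1/A]  I(q)[a.u.]"
    if curve.sigma is not None:
        cols.append(curve.sigma)
        header += "  sigma(I)"
    with path.open("w") as fh:
        if curve.label:
            fh.write(f"# {curve.label}\n")
        fh.write(header + "\n")
        for row in zip(*cols):
            fh.write("  ".join(repr(float(v)) for v in row) + "\n")


def read_series(manifest: str | Path) -> CurveSeries:
    """Load a time series from a manifest of ``time_days curve_path`` pairs.

    Curve paths are resolved relative to the manifest location.  Entries
    out of time order are sorted ascending with a warning.  An empty
    manifest yields an empty series.
    """
    manifest = Path(manifest)
    entries: list[tuple[float, Path]] = []
    with manifest.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.replace(",", " ").split()
            if len(parts) < 2:
                raise ValidationError(
                    f"{manifest}: line {lineno}: expected 'time_days path'"
                )
            try:
                t = float(parts[0])
            except ValueError as exc:
                raise ValidationError(
                    f"{manifest}: line {lineno}: bad time {parts[0]!r}"
                ) from exc
            entries.append((t, manifest.parent / parts[1]))
    if any(b[0] < a[0] for a, b in zip(entries, entries[1:])):
        warnings.warn(f"{manifest}: entries out of time order; sorting ascending")
        entries.sort(key=lambda e: e[0])
    curves = []
    for t, p in entries:
        if not p.exists():
            raise IOError(f"{manifest}: referenced file not found: {p}")
        curves.append(read_sas_curve(p))
    return CurveSeries(tuple(curves), tuple(t for t, _ in entries))
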