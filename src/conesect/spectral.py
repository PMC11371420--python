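"""Sampled spectral functions: axes, channel sets, resampling and metrics.

The colour-matching formalism treats every spectral quantity — a colour
matching function (CMF), a cone fundamental, a camera quantum efficiency,
a test light — as an N-vector sampled on a wavelength grid.  A set of k
such functions sharing one grid is an N x k matrix.  This module provides
those two containers (:class:`SpectralAxis`, :class:`ChannelSet`), the
constrained three-channel container for cone fundamentals
(:class:`ConeFundamentals`), resampling onto common grids, and the
scale-free comparison metrics used throughout the package.

Conventions
-----------
* Wavelengths are in nanometres; the default working grid is 380-780 nm in
  5 nm steps.
* A spectral sensitivity is defined only up to a scalar, so comparisons are
  either angular (ray-based) or made after normalizing each curve to peak 1.
* Interpolation is piecewise linear and never extrapolates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AxisError, RangeError, UsageError

__all__ = [
    "SpectralAxis",
    "ChannelSet",
    "ConeFundamentals",
    "default_axis",
    "resample",
    "common_axis",
    "angular_error",
    "log10_difference",
    "Log10Difference",
    "read_channelset_csv",
    "write_channelset_csv",
]

_UNIFORM_RTOL = 1e-9


@dataclass(frozen=True)
class SpectralAxis:
    """An ordered grid of sample wavelengths in nanometres.

    Wavelengths must be strictly increasing with at least 3 samples.
    Uniform spacing is not required; :attr:`is_uniform` reports whether the
    grid is (numerically) evenly spaced.
    """

    wavelengths: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 3:
            raise AxisError(f"axis needs >= 3 samples, got shape {wl.shape}")
        if not np.all(np.isfinite(wl)):
            raise AxisError("axis wavelengths must be finite")
        if not np.all(np.diff(wl) > 0):
            raise AxisError("axis wavelengths must be strictly increasing")
        wl.flags.writeable = False
        object.__setattr__(self, "wavelengths", wl)

    @property
    def n(self) -> int:
        return self.wavelengths.size

    @property
    def start(self) -> float:
        return float(self.wavelengths[0])

    @property
    def stop(self) -> float:
        return float(self.wavelengths[-1])

    @property
    def is_uniform(self) -> bool:
        d = np.diff(self.wavelengths)
        return bool(np.all(np.abs(d - d[0]) <= _UNIFORM_RTOL * max(abs(d[0]), 1.0)))

    @property
    def step(self) -> float | None:
        """Grid spacing if uniform, else None."""
        if not self.is_uniform:
            return None
        return float(self.wavelengths[1] - self.wavelengths[0])

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpectralAxis):
            return NotImplemented
        return self.wavelengths.shape == other.wavelengths.shape and bool(
            np.array_equal(self.wavelengths, other.wavelengths)
        )

    def __hash__(self):
        return hash((self.n, self.start, self.stop))

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:
        u = f" @{self.step:g} nm" if self.is_uniform else " (non-uniform)"
        return f"SpectralAxis({self.start:g}-{self.stop:g} nm, N={self.n}{u})"

    @classmethod
    def from_range(cls, start: float, stop: float, step: float) -> "SpectralAxis":
        """Uniform grid start..stop inclusive with the given step."""
        n = int(round((stop - start) / step)) + 1
        return cls(start + step * np.arange(n))

    @classmethod
    def from_spec(cls, spec: str) -> "SpectralAxis":
        """Parse a 'start:stop:step' string, e.g. '380:780:5'."""
        try:
            start, stop, step = (float(t) for t in spec.split(":"))
        except ValueError as exc:
            raise UsageError(f"bad axis spec {spec!r}, expected start:stop:step") from exc
        return cls.from_range(start, stop, step)


def default_axis() -> SpectralAxis:
    """The package's default working grid: 380-780 nm in 5 nm steps."""
    return SpectralAxis.from_range(380.0, 780.0, 5.0)


@dataclass(frozen=True)
class ChannelSet:
    """k spectral functions sampled on one shared axis (an N x k matrix).

    Holds CMFs, camera quantum efficiencies, joined matrices and lights
    alike; values are unitless relative sensitivities/energies.
    """

    axis: SpectralAxis
    values: np.ndarray
    labels: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        if v.ndim != 2:
            raise UsageError(f"values must be 2-D, got shape {v.shape}")
        if v.shape[0] != self.axis.n:
            raise AxisError(
                f"row count {v.shape[0]} does not match axis length {self.axis.n}"
            )
        if v.shape[1] < 1:
            raise UsageError("need at least one channel")
        if not np.all(np.isfinite(v)):
            raise UsageError("channel values must be finite")
        labels = self.labels
        if labels is None:
            labels = tuple(f"ch{i}" for i in range(v.shape[1]))
        else:
            labels = tuple(str(x) for x in labels)
            if len(labels) != v.shape[1]:
                raise UsageError(
                    f"{len(labels)} labels for {v.shape[1]} channels"
                )
        v.flags.writeable = False
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", labels)

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def channel(self, key: int | str) -> np.ndarray:
        """A single channel as a 1-D vector, by index or label."""
        if isinstance(key, str):
            try:
                key = self.labels.index(key)
            except ValueError:
                raise UsageError(f"no channel labelled {key!r}") from None
        return self.values[:, key]

    def with_values(self, values: np.ndarray, labels=None) -> "ChannelSet":
        return ChannelSet(self.axis, values, labels if labels is not None else self.labels)

    def peak_normalized(self) -> "ChannelSet":
        """Each channel divided by its maximum absolute value (peak -> 1)."""
        peaks = np.max(np.abs(self.values), axis=0)
        if np.any(peaks == 0):
            raise UsageError("cannot peak-normalize an all-zero channel")
        return self.with_values(self.values / peaks)

    def hstack(self, other: "ChannelSet", negate_other: bool = False) -> "ChannelSet":
        """Join two channel sets column-wise (same axis required).

        ``negate_other`` builds the signed joined matrix [C, -C~] used by
        the intersection null-space problem.
        """
        if self.axis != other.axis:
            raise AxisError("cannot join channel sets on different axes")
        ov = -other.values if negate_other else other.values
        return ChannelSet(
            self.axis,
            np.hstack([self.values, ov]),
            self.labels + other.labels,
        )

    def __repr__(self) -> str:
        return f"ChannelSet({self.axis!r}, channels={list(self.labels)})"


class ConeFundamentals(ChannelSet):
    """Three non-negative cone spectral sensitivities labelled L, M, S.

    Each channel is normalized to peak 1.  Small negative excursions (below
    ``clip_tol`` in magnitude) from numerical round-off are clipped to zero;
    anything larger is rejected.
    """

    LABELS = ("L", "M", "S")

    def __init__(self, axis, values, labels=LABELS, clip_tol: float = 1e-8):
        v = np.asarray(values, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise UsageError("cone fundamentals require exactly 3 channels")
        if np.min(v) < -clip_tol:
            raise UsageError(
                f"cone fundamentals must be non-negative (min {np.min(v):.3g})"
            )
        v = np.clip(v, 0.0, None)
        peaks = np.max(v, axis=0)
        if np.any(peaks == 0):
            raise UsageError("a cone fundamental is identically zero")
        v = v / peaks
        if tuple(labels) != self.LABELS:
            raise UsageError(f"labels must be {self.LABELS}")
        super().__init__(axis=axis, values=v, labels=self.LABELS)

    @property
    def l(self) -> np.ndarray:  # noqa: E743 - domain name
        return self.values[:, 0]

    @property
    def m(self) -> np.ndarray:
        return self.values[:, 1]

    @property
    def s(self) -> np.ndarray:
        return self.values[:, 2]

    def pair(self, missing: str) -> ChannelSet:
        """The two fundamentals retained by a reduction dichromat.

        ``missing`` is the absent cone class: 'L' (protan) keeps [M, S],
        'M' (deutan) keeps [L, S], 'S' (tritan) keeps [L, M].
        """
        keep = [c for c in self.LABELS if c != missing.upper()]
        if len(keep) != 2:
            raise UsageError(f"unknown cone class {missing!r}")
        idx = [self.LABELS.index(c) for c in keep]
        return ChannelSet(self.axis, self.values[:, idx], tuple(keep))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def resample(cs: ChannelSet, target: SpectralAxis) -> ChannelSet:
    """Piecewise-linear resampling of every channel onto ``target``.

    Never extrapolates: the target range must lie within the source range.
    """
    if target == cs.axis:
        return cs
    src = cs.axis.wavelengths
    if target.start < src[0] or target.stop > src[-1]:
        raise RangeError(
            f"target range {target.start:g}-{target.stop:g} nm extends beyond "
            f"source range {src[0]:g}-{src[-1]:g} nm"
        )
    out = np.column_stack(
        [np.interp(target.wavelengths, src, cs.values[:, j]) for j in range(cs.n_channels)]
    )
    return ChannelSet(target, out, cs.labels)


def common_axis(a: ChannelSet | SpectralAxis, b: ChannelSet | SpectralAxis) -> SpectralAxis:
    """The finer of the two grids, restricted to the overlapping range.

    "Finer" compares median sample spacing.  The overlap must retain at
    least 3 samples of the chosen grid.
    """
    ax_a = a if isinstance(a, SpectralAxis) else a.axis
    ax_b = b if isinstance(b, SpectralAxis) else b.axis
    lo = max(ax_a.start, ax_b.start)
    hi = min(ax_a.stop, ax_b.stop)
    if hi <= lo:
        raise AxisError(
            f"axes do not overlap ({ax_a.start:g}-{ax_a.stop:g} vs {ax_b.start:g}-{ax_b.stop:g})"
        )
    if ax_a == ax_b:
        return ax_a
    step_a = float(np.median(np.diff(ax_a.wavelengths)))
    step_b = float(np.median(np.diff(ax_b.wavelengths)))
    finer = ax_a if step_a <= step_b else ax_b
    wl = finer.wavelengths
    keep = wl[(wl >= lo) & (wl <= hi)]
    if keep.size < 3:
        raise AxisError(f"axes overlap on only {keep.size} samples of the finer grid")
    return SpectralAxis(keep)


def angular_error(u: np.ndarray, v: np.ndarray) -> float:
    """Angle in radians between the rays spanned by u and v.

    arccos(|<u,v>| / (||u|| ||v||)): invariant to scaling and sign of either
    vector, so it compares spectral sensitivities defined only up to a
    scalar.  Range [0, pi/2].  Evaluated via atan2 of the rejection norm,
    which stays accurate for tiny angles where arccos saturates.
    """
    u = np.ravel(np.asarray(u, dtype=float))
    v = np.ravel(np.asarray(v, dtype=float))
    if u.shape != v.shape:
        raise UsageError(f"shape mismatch {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise UsageError("angular_error undefined for a zero vector")
    u = u / nu
    v = v / nv
    c = float(u @ v)
    if c < 0:
        v, c = -v, -c
    rejection = float(np.linalg.norm(u - c * v))
    return float(np.arctan2(rejection, c))


@dataclass(frozen=True)
class Log10Difference:
    """Per-wavelength log10(est) - log10(ref), masked where ref <= floor.

    ``values`` is a masked N x k array; samples where the reference falls at
    or below ``floor`` (fraction of its peak, default 0.05) are masked.
    ``undefined`` flags unmasked samples where the (peak-normalized)
    estimate was non-positive so the log is undefined; those entries hold
    NaN rather than raising.
    """

    axis: SpectralAxis
    values: np.ma.MaskedArray
    undefined: np.ndarray
    floor: float

    def max_abs(self, channel: int | None = None) -> float:
        v = self.values if channel is None else self.values[:, channel]
        ok = ~np.isnan(np.ma.filled(v, 0.0))
        return float(np.max(np.abs(np.ma.filled(v, 0.0)[ok & ~np.ma.getmaskarray(v)]), initial=0.0))

    def median_abs(self, channel: int | None = None) -> float:
        v = self.values if channel is None else self.values[:, channel]
        data = np.ma.filled(v, np.nan)
        data = data[~np.ma.getmaskarray(v)]
        data = data[~np.isnan(data)]
        return float(np.median(np.abs(data))) if data.size else 0.0

    @property
    def n_unmasked(self) -> int:
        return int((~np.ma.getmaskarray(self.values)).sum())


def log10_difference(
    est: ChannelSet, ref: ChannelSet, floor: float = 0.05
) -> Log10Difference:
    """log10 difference between estimate and reference curves.

    Both sets are peak-normalized channel-wise; the difference is computed
    only where the reference exceeds ``floor`` (a fraction of its peak, so
    with peak = 1 the default keeps reference values > 0.05).  A
    non-positive estimate at an unmasked sample yields NaN there and is
    flagged in ``undefined`` instead of raising.
    """
    if est.axis != ref.axis:
        raise AxisError("log10_difference requires a shared axis (resample first)")
    if est.n_channels != ref.n_channels:
        raise UsageError("channel count mismatch")
    e = est.peak_normalized().values
    r = ref.peak_normalized().values
    masked_out = r <= floor
    undefined = (~masked_out) & (e <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = np.log10(e) - np.log10(r)
    diff = np.where(undefined, np.nan, diff)
    values = np.ma.MaskedArray(diff, mask=masked_out)
    return Log10Difference(axis=est.axis, values=values, undefined=undefined, floor=floor)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------
# Dialect: header row; first column "wavelength_nm"; remaining columns are
# channel labels; rows sorted ascending by wavelength; UTF-8.  The reader
# accepts comma- or whitespace-separated tables; the writer emits commas
# with round-trip float precision.

def read_channelset_csv(path_or_buffer) -> ChannelSet:
    """Read a spectral table in the package CSV dialect."""
    if hasattr(path_or_buffer, "read"):
        text = path_or_buffer.read()
    else:
        with open(path_or_buffer, "r", encoding="utf-8") as fh:
            text = fh.read()
    header = next((ln for ln in text.splitlines() if ln.strip()), "")
    if "," in header:
        df = pd.read_csv(io.StringIO(text), float_precision="round_trip")
    else:
        df = pd.read_csv(io.StringIO(text), sep=r"\s+", engine="python")
    if df.shape[1] < 2:
        raise UsageError("spectral table needs a wavelength column and >= 1 channel")
    first = df.columns[0]
    if first.strip() != "wavelength_nm":
        raise UsageError(f"first column must be 'wavelength_nm', got {first!r}")
    wl = df[first].to_numpy(dtype=float)
    order = np.argsort(wl)
    if not np.array_equal(order, np.arange(len(wl))):
        df = df.iloc[order]
        wl = wl[order]
    axis = SpectralAxis(wl)
    labels = tuple(str(c).strip() for c in df.columns[1:])
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return ChannelSet(axis, values, labels)


def write_channelset_csv(cs: ChannelSet, path) -> None:
    """Write a spectral table in the package CSV dialect."""
    df = pd.DataFrame(cs.values, columns=list(cs.labels))
    df.insert(0, "wavelength_nm", cs.axis.wavelengths)
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format=lambda x: np.format_float_positional(
        x, unique=True, trim="0"))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())
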