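"""Least-squares linear maps between channel sets, and curve comparison.

Two standard operations around the intersection method:

* :func:`fit_linear_map` — the conventional way to relate two sensor
  systems (or to align CMF sets measured with different primaries): the
  j x k matrix T minimizing ||S T - R||_F for source S and target R.
* :func:`compare_to_reference` — per-cone log10 agreement between an
  estimated and a reference set of fundamentals, evaluated only where the
  reference exceeds a floor (default 0.05 of peak), the customary way of
  reporting cone-fundamental agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .errors import UsageError
from .spectral import (
    ChannelSet,
    ConeFundamentals,
    Log10Difference,
    common_axis,
    log10_difference,
    resample,
)

__all__ = ["LinearMapFit", "ComparisonSummary", "fit_linear_map", "compare_to_reference"]


@dataclass(frozen=True)
class LinearMapFit:
    """Result of a least-squares fit target ~= source @ matrix."""

    matrix: np.ndarray
    rms_residual: np.ndarray  # per target channel
    variance_explained: np.ndarray  # per target channel, in [0, 1]

    def apply(self, source: ChannelSet, labels=None) -> ChannelSet:
        return ChannelSet(source.axis, source.values @ self.matrix, labels)


def _dependent_columns(values: np.ndarray, labels, tol: float) -> list[str]:
    """Names of columns that are linear combinations of earlier ones,
    identified by column-pivoted QR."""
    _, r, piv = linalg.qr(values, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    thresh = tol * diag[0] if diag[0] > 0 else tol
    rank = int(np.sum(diag > thresh))
    return [labels[j] for j in sorted(piv[rank:])]


def fit_linear_map(source: ChannelSet, target: ChannelSet) -> LinearMapFit:
    """Least-squares T minimizing ||source @ T - target||_F.

    Requires a shared axis, more samples than source channels, and a
    full-rank source; a rank-deficient source raises an error naming the
    dependent columns.  Returns the matrix plus per-target-channel RMS
    residual and fraction of (uncentred) target variance explained.
    """
    if source.axis != target.axis:
        raise UsageError("source and target must share an axis (resample first)")
    n, j = source.values.shape
    if n <= j:
        raise UsageError(f"need more samples ({n}) than source channels ({j})")
    sv = np.linalg.svd(source.values, compute_uv=False)
    if sv[-1] <= 1e-10 * sv[0]:
        dep = _dependent_columns(source.values, source.labels, 1e-10)
        raise UsageError(
            f"source is rank-deficient; dependent columns: {', '.join(dep) or 'unknown'}"
        )
    t, *_ = np.linalg.lstsq(source.values, target.values, rcond=None)
    resid = source.values @ t - target.values
    rms = np.sqrt(np.mean(resid**2, axis=0))
    total = np.sum(target.values**2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ve = np.where(total > 0, 1.0 - np.sum(resid**2, axis=0) / total, 0.0)
    return LinearMapFit(matrix=t, rms_residual=rms, variance_explained=np.clip(ve, 0.0, 1.0))


@dataclass(frozen=True)
class ComparisonSummary:
    """Per-cone log10 agreement between estimated and reference curves."""

    max_abs: dict[str, float]
    median_abs: dict[str, float]
    series: Log10Difference

    @property
    def overall_max_abs(self) -> float:
        return max(self.max_abs.values())


def compare_to_reference(
    est: ConeFundamentals | ChannelSet,
    ref: ConeFundamentals | ChannelSet,
    floor: float = 0.05,
) -> ComparisonSummary:
    """Per-cone max/median |log10(est) - log10(ref)| above the floor.

    Both sets are resampled to their common axis and peak-normalized; the
    floor applies to the reference curve only.  Raises if no sample of any
    channel survives the floor.
    """
    if est.n_channels != ref.n_channels:
        raise UsageError("estimate and reference must have matching channel counts")
    ax = common_axis(est, ref)
    est_r = resample(est, ax)
    ref_r = resample(ref, ax)
    diff = log10_difference(est_r, ref_r, floor=floor)
    if diff.n_unmasked == 0:
        raise UsageError(f"no reference sample exceeds the floor {floor:g}")
    labels = ref.labels
    max_abs, median_abs = {}, {}
    for jj, lab in enumerate(labels):
        col = diff.values[:, jj]
        if int((~np.ma.getmaskarray(col)).sum()) == 0:
            raise UsageError(f"channel {lab!r}: no sample exceeds the floor {floor:g}")
        max_abs[lab] = diff.max_abs(jj)
        median_abs[lab] = diff.median_abs(jj)
    return ComparisonSummary(max_abs=max_abs, median_abs=median_abs, series=diff)
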