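"""Cone fundamental estimation by subspace intersection.

Each reduction dichromat's two colour matching functions (CMFs) span a
plane in wavelength space — the plane spanned by that observer's two cone
fundamentals, whatever primaries were used.  Two dichromats of different
classes share one cone class, so their planes intersect in the ray of the
shared fundamental.  Writing the shared fundamental as C1 x1 = C2 x2 and
subtracting gives

    [C1, -C2] [x1; x2] = 0,

so the coefficients lie in the null space of the joined N x 4 matrix.
With exact reduction dichromats and no noise that null space is
one-dimensional; with measurement noise the joined matrix has no exact
null vector and we take the right singular vector of the smallest singular
value — the minimum-residual direction under the unit-norm constraint
||x1||^2 + ||x2||^2 = 1.  The same problem can be posed as an explicit
constrained optimization, which additionally admits a non-negativity
constraint on the estimated fundamental.

Because the method only ever uses the span of each observer's CMFs, the
estimate is invariant to the (unknown, possibly different) primary lights:
right-multiplying either CMF matrix by any invertible 2x2 matrix leaves
the reported fundamental unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import ConvergenceError, DegeneracyError, UsageError
from .spectral import ChannelSet, ConeFundamentals, SpectralAxis, common_axis, resample
from .synthetic import SHARED_CONE, DichromatCMF

__all__ = [
    "IntersectionResult",
    "DerivedFundamentals",
    "intersect_pair",
    "intersect_optim",
    "derive_all_fundamentals",
    "DEGENERACY_TOL",
]

#: Relative threshold on the second-smallest singular value below which the
#: joined matrix has a (near-)two-dimensional null space and the
#: intersection is not a unique ray.
DEGENERACY_TOL = 1e-8

#: Minimum number of shared wavelength samples for a meaningful fit.
MIN_SAMPLES = 10


@dataclass(frozen=True)
class IntersectionResult:
    """Estimate of the cone fundamental shared by two dichromats.

    The two one-sided reconstructions C1 x_first and C2 x_second coincide
    in the noiseless case and differ under measurement noise;
    ``estimate_reported`` is the first-observer reconstruction,
    peak-normalized with the sign chosen so its sum is positive.
    ``alpha`` rescales the raw coefficient vector so that
    ||alpha x_first||^2 + ||alpha x_second||^2 = 1 (already unity for the
    SVD path).  ``singular_value_ratio`` (smallest/largest singular value
    of the joined matrix) is the residual diagnostic: near zero means the
    two planes genuinely intersect.
    """

    cone: str
    observer_pair: tuple[str, str]
    method: str
    axis: SpectralAxis
    x_first: np.ndarray
    x_second: np.ndarray
    alpha: float
    estimate_first: np.ndarray
    estimate_second: np.ndarray
    estimate_reported: np.ndarray
    smallest_singular_value: float
    singular_value_ratio: float
    singular_values: np.ndarray

    @property
    def estimate_average(self) -> np.ndarray:
        """Peak-normalized average of the two one-sided reconstructions
        (after aligning their signs)."""
        a, b = self.estimate_first, self.estimate_second
        if float(a @ b) < 0:
            b = -b
        avg = 0.5 * (a / np.max(np.abs(a)) + b / np.max(np.abs(b)))
        avg = avg if avg.sum() >= 0 else -avg
        return avg / np.max(np.abs(avg))


def _shared_cone(first: DichromatCMF, second: DichromatCMF) -> str:
    if first.observer_class == second.observer_class:
        raise UsageError(
            f"both observers are {first.observer_class}: a pair must span two "
            "different dichromat classes"
        )
    key = frozenset({first.observer_class, second.observer_class})
    try:
        return SHARED_CONE[key]
    except KeyError:
        raise UsageError(
            f"observer pair {sorted(key)} shares no cone class"
        ) from None


def _to_common_axis(first: DichromatCMF, second: DichromatCMF):
    axis = common_axis(first.cmf, second.cmf)
    if axis.n < MIN_SAMPLES:
        raise UsageError(
            f"observers share only {axis.n} wavelength samples (need >= {MIN_SAMPLES})"
        )
    return axis, resample(first.cmf, axis), resample(second.cmf, axis)


def _report_convention(est: np.ndarray) -> tuple[np.ndarray, float]:
    """Peak = 1, positive-sum sign; returns (curve, applied scale)."""
    sign = 1.0 if est.sum() >= 0 else -1.0
    peak = np.max(np.abs(est))
    if peak == 0:
        raise DegeneracyError("intersection estimate is identically zero")
    return sign * est / peak, sign / peak


def _check_degeneracy(sv: np.ndarray) -> None:
    if sv[-2] < DEGENERACY_TOL * sv[0]:
        raise DegeneracyError(
            "joined matrix has a null space of dimension >= 2 "
            f"(second-smallest/largest singular value = {sv[-2] / sv[0]:.3g}); "
            "the observers' CMF planes coincide (e.g. duplicated observers) "
            "and the shared fundamental is not a unique ray"
        )


def _build_result(
    cone, pair, method, axis, c1, c2, x, sv
) -> IntersectionResult:
    x1, x2 = x[:2], x[2:]
    est1 = c1.values @ x1
    est2 = c2.values @ x2
    reported, scale = _report_convention(est1)
    # carry the reporting sign back into the coefficients
    sgn = 1.0 if scale >= 0 else -1.0
    nrm = np.linalg.norm(x)
    return IntersectionResult(
        cone=cone,
        observer_pair=pair,
        method=method,
        axis=axis,
        x_first=sgn * x1,
        x_second=sgn * x2,
        alpha=1.0 / nrm,
        estimate_first=sgn * est1,
        estimate_second=sgn * est2,
        estimate_reported=reported,
        smallest_singular_value=float(sv[-1]),
        singular_value_ratio=float(sv[-1] / sv[0]),
        singular_values=sv,
    )


def intersect_pair(
    first: DichromatCMF, second: DichromatCMF, method: str = "svd"
) -> IntersectionResult:
    """Estimate the cone fundamental shared by two dichromats.

    The pair must span two different dichromat classes (protan+tritan give
    M, deutan+tritan give L, protan+deutan give S).  Both CMF sets are
    resampled to their common axis; the joined matrix [C1, -C2] is formed
    and its (approximate) null vector taken as the right singular vector
    of the smallest singular value (``method='svd'``) or found by explicit
    constrained optimization (``method='optim'``, see
    :func:`intersect_optim`).

    Raises :class:`DegeneracyError` when the null space is not
    one-dimensional (e.g. the two observers' CMF planes coincide).
    """
    if method == "optim":
        return intersect_optim(first, second)
    if method != "svd":
        raise UsageError(f"unknown method {method!r} (expected 'svd' or 'optim')")
    cone = _shared_cone(first, second)
    axis, c1, c2 = _to_common_axis(first, second)
    joined = np.hstack([c1.values, -c2.values])
    _, sv, vt = np.linalg.svd(joined, full_matrices=False)
    _check_degeneracy(sv)
    x = vt[-1]  # unit norm: ||x1||^2 + ||x2||^2 = 1
    return _build_result(
        cone, (first.observer_class, second.observer_class), "svd", axis, c1, c2, x, sv
    )


def intersect_optim(
    first: DichromatCMF,
    second: DichromatCMF,
    nonneg: bool = False,
) -> IntersectionResult:
    """Intersection by explicit numerical optimization.

    Unconstrained variant: minimize ||C1 x - C2 y||^2 subject to
    ||x||^2 + ||y||^2 = 1 — the same problem the SVD solves, so the two
    must agree (up to sign).  With ``nonneg=True`` the estimated
    fundamental is additionally required to be non-negative elementwise;
    the norm constraint is then replaced by the linear constraint
    mean(C1 x) = 1, which excludes the degenerate all-zero solution while
    keeping the problem a convex quadratic programme.
    """
    cone = _shared_cone(first, second)
    axis, c1, c2 = _to_common_axis(first, second)
    joined = np.hstack([c1.values, -c2.values])
    sv = np.linalg.svd(joined, compute_uv=False)
    _check_degeneracy(sv)
    gram = joined.T @ joined

    def objective(z):
        return float(z @ gram @ z)

    def grad(z):
        return 2.0 * gram @ z

    if nonneg:
        x = _nonneg_solution(c1.values, c2.values)
        return _build_result(
            cone, (first.observer_class, second.observer_class), "optim-nonneg",
            axis, c1, c2, x, sv,
        )

    constraints = [
        {
            "type": "eq",
            "fun": lambda z: float(z @ z) - 1.0,
            "jac": lambda z: 2.0 * z,
        }
    ]
    # deterministic starts spread over the sphere; the objective's
    # constrained minima are +/- the bottom eigenvector, so a few
    # starts suffice to avoid saddle points
    starts = [
        np.array(s) / np.linalg.norm(s)
        for s in ([1.0, 0, 0, 0], [0, 1.0, 0, 0], [1.0, -1, 1, -1], [1.0, 1, -1, -1])
    ]

    best = None
    diags = []
    for z0 in starts:
        res = optimize.minimize(
            objective,
            z0,
            jac=grad,
            method="SLSQP",
            constraints=constraints,
            options={"maxiter": 500, "ftol": 1e-16},
        )
        diags.append({"success": bool(res.success), "message": res.message, "fun": res.fun})
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise ConvergenceError(
            "optimization failed to converge from all starts",
            diagnostics={"attempts": diags},
        )
    x = best.x / np.linalg.norm(best.x)
    return _build_result(
        cone, (first.observer_class, second.observer_class), "optim", axis, c1, c2, x, sv
    )


def _nonneg_solution(C1: np.ndarray, C2: np.ndarray) -> np.ndarray:
    """Exact solution of min ||C1 x - C2 y||^2 s.t. C1 x >= 0, mean(C1 x) = 1.

    The coefficient vector x is two-dimensional, so the normalization set
    {x : mean(C1 x) = 1} is a line; clipping it against the N half-planes
    c_i . x >= 0 leaves an interval (possibly empty -> infeasible).
    Eliminating y (ordinary least squares given x, linear in x) makes the
    objective a scalar quadratic in the line parameter, minimized in
    closed form over the interval.  This honours the non-negativity
    constraint to rounding error, unlike a tolerance-based NLP solver.
    """
    a = np.mean(C1, axis=0)
    if np.linalg.norm(a) < 1e-300:
        raise ConvergenceError("mean(C1 x) = 1 is unsatisfiable: C1 has zero column means")
    # the normalization plane is the line x(t) = x0 + t d in coefficient space
    x0 = a / float(a @ a)
    d = np.array([-a[1], a[0]]) / np.linalg.norm(a)
    # clip the line against every half-plane c_i . x >= 0
    intercept = C1 @ x0
    slope = C1 @ d
    lo, hi = -np.inf, np.inf
    scale = np.max(np.abs(C1))
    for b, s in zip(intercept, slope):
        if abs(s) <= 1e-15 * scale:
            if b < -1e-15 * scale:
                lo, hi = np.inf, -np.inf
                break
            continue
        bound = -b / s
        if s > 0:
            lo = max(lo, bound)
        else:
            hi = min(hi, bound)
    if lo > hi:
        raise ConvergenceError(
            "non-negativity constraint is infeasible: no x with C1 x >= 0 "
            "and mean(C1 x) = 1 exists (noise at wavelengths where the "
            "matching functions vanish rules out every direction)"
        )
    # eliminate y: least squares given x is linear in t, so the residual is
    # affine in t and the objective a scalar quadratic on [lo, hi]
    y0, *_ = np.linalg.lstsq(C2, C1 @ x0, rcond=None)
    yd, *_ = np.linalg.lstsq(C2, C1 @ d, rcond=None)
    u = C1 @ x0 - C2 @ y0
    v = C1 @ d - C2 @ yd
    vv = float(v @ v)
    t = 0.0 if vv == 0 else float(-(u @ v) / vv)
    t = float(np.clip(t, lo, hi))
    return np.concatenate([x0 + t * d, y0 + t * yd])


@dataclass(frozen=True)
class DerivedFundamentals:
    """The three per-cone intersection results.

    Each cone may live on a different wavelength axis (a tritanope measured
    over a narrower range restricts the L and M estimates to the overlap
    while leaving S untouched); use :meth:`as_cone_fundamentals` to resample
    all three onto their mutual common axis as a single container.
    """

    results: dict[str, IntersectionResult]

    def __getitem__(self, cone: str) -> IntersectionResult:
        return self.results[cone.upper()]

    @property
    def diagnostics(self) -> dict[str, dict]:
        return {
            cone: {
                "observer_pair": list(r.observer_pair),
                "method": r.method,
                "smallest_singular_value": r.smallest_singular_value,
                "singular_value_ratio": r.singular_value_ratio,
                "axis_start_nm": r.axis.start,
                "axis_stop_nm": r.axis.stop,
                "n_samples": r.axis.n,
            }
            for cone, r in self.results.items()
        }

    def as_cone_fundamentals(self, clip_tol: float = 0.01) -> ConeFundamentals:
        """All three estimates on their mutual common axis.

        Negative excursions up to ``clip_tol`` (a fraction of peak; under
        measurement noise the estimates acquire small negative tails) are
        clipped to satisfy the container's non-negativity; anything larger
        raises.  The signed estimates remain available per cone on the
        individual results.
        """
        axes = [r.axis for r in self.results.values()]
        ax = axes[0]
        for other in axes[1:]:
            ax = common_axis(ax, other)
        cols = []
        for cone in ("L", "M", "S"):
            r = self.results[cone]
            cs = ChannelSet(r.axis, r.estimate_reported, (cone,))
            cols.append(resample(cs, ax).values[:, 0])
        return ConeFundamentals(ax, np.column_stack(cols), clip_tol=clip_tol)


#: Which dichromat pair determines each cone (first observer is reported).
PAIR_FOR_CONE = {
    "L": ("deutan", "tritan"),
    "M": ("protan", "tritan"),
    "S": ("protan", "deutan"),
}


def derive_all_fundamentals(
    protan: DichromatCMF,
    deutan: DichromatCMF,
    tritan: DichromatCMF,
    method: str = "svd",
    nonneg: bool = False,
) -> DerivedFundamentals:
    """Estimate all three cone fundamentals from a dichromat triple.

    L comes from the (deutan, tritan) pair, M from (protan, tritan), S
    from (protan, deutan); each pair is resampled to its own common axis.
    Failures of an individual pair propagate with the pair named.
    """
    observers = {"protan": protan, "deutan": deutan, "tritan": tritan}
    for name, obs in observers.items():
        if obs.observer_class != name:
            raise UsageError(
                f"argument {name!r} holds a {obs.observer_class} observer"
            )
    results = {}
    for cone, (a, b) in PAIR_FOR_CONE.items():
        try:
            if nonneg or method == "optim":
                results[cone] = intersect_optim(observers[a], observers[b], nonneg=nonneg)
            else:
                results[cone] = intersect_pair(observers[a], observers[b], method=method)
        except Exception as exc:
            raise type(exc)(
                f"{cone}-cone estimate from ({a}, {b}) failed: {exc}"
            ) from exc
    return DerivedFundamentals(results)
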