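"""Synthetic ground truth: fundamentals, dichromat CMFs, lights, cameras.

Every estimator in this package can be exercised without external data by
generating the structures the theory assumes:

* smooth, non-negative, unimodal cone-fundamental-like curves
  (:func:`make_fundamentals`);
* dichromat colour matching functions formed as unknown invertible 2x2
  mixes of the appropriate fundamental pair, optionally with additive
  measurement noise (:func:`make_dichromat`) — a protanope's CMFs span
  span{m, s}, a deuteranope's span{l, s}, a tritanope's span{l, m};
* primary intensities matching a test light (:func:`match_light`);
* pairs of 3-channel camera sensor sets whose channel subspaces intersect
  in a chosen dimension 0..3 (:func:`make_camera_pair`).

The curve family is a split Gaussian in log-wavelength (independent left
and right widths).  It is a smooth unimodal stand-in, not a photopigment
model: the estimators are shape-agnostic, so any smooth family serves for
parameter-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConstructionError, UsageError
from .spectral import ChannelSet, ConeFundamentals, SpectralAxis, default_axis

__all__ = [
    "SyntheticFundamentalSpec",
    "DichromatCMF",
    "OBSERVER_CLASSES",
    "MISSING_CONE",
    "SHARED_CONE",
    "make_fundamentals",
    "make_dichromat",
    "make_observer_triple",
    "match_light",
    "monochromatic_light",
    "make_camera_pair",
    "smooth_random_curves",
]

OBSERVER_CLASSES = ("protan", "deutan", "tritan")

#: The cone class each reduction dichromat lacks.
MISSING_CONE = {"protan": "L", "deutan": "M", "tritan": "S"}

#: The cone class shared by each dichromat pair (keys are frozensets).
SHARED_CONE = {
    frozenset({"protan", "tritan"}): "M",
    frozenset({"deutan", "tritan"}): "L",
    frozenset({"protan", "deutan"}): "S",
}

#: Default peak wavelengths (nm) and bandwidths for L, M, S stand-ins,
#: in the neighbourhood of human cone sensitivity peaks.
DEFAULT_PEAKS = (565.0, 535.0, 440.0)
DEFAULT_BANDWIDTHS = (55.0, 50.0, 35.0)


@dataclass(frozen=True)
class SyntheticFundamentalSpec:
    """Parameters of the synthetic L, M, S curves.

    peaks / bandwidths are in nm; ``asymmetry`` in (-1, 1) skews each curve
    by widening one flank and narrowing the other (0 = symmetric in
    log-wavelength).  Generation is fully deterministic given the spec.
    """

    peaks: tuple[float, float, float] = DEFAULT_PEAKS
    bandwidths: tuple[float, float, float] = DEFAULT_BANDWIDTHS
    asymmetry: tuple[float, float, float] = (0.15, 0.15, 0.1)
    axis: SpectralAxis = field(default_factory=default_axis)

    def __post_init__(self):
        pl, pm, ps = self.peaks
        if not (pl > pm > ps):
            raise UsageError("peak wavelengths must satisfy L > M > S")
        for p in self.peaks:
            if not (self.axis.start <= p <= self.axis.stop):
                raise UsageError(f"peak {p:g} nm outside axis range")
        if any(b <= 0 for b in self.bandwidths):
            raise UsageError("bandwidths must be positive")
        if any(abs(a) >= 1 for a in self.asymmetry):
            raise UsageError("asymmetry must be in (-1, 1)")


def _split_log_gaussian(
    wl: np.ndarray, peak: float, bandwidth: float, asymmetry: float
) -> np.ndarray:
    """Unimodal curve: Gaussian in log-wavelength with split flank widths.

    ``bandwidth`` is the nominal width in nm at the peak; internally the
    width in log-wavelength is bandwidth/peak, scaled per flank by
    (1 -+ asymmetry).
    """
    x = np.log(wl / peak)
    sigma = bandwidth / peak
    s_left = sigma * (1.0 - asymmetry)
    s_right = sigma * (1.0 + asymmetry)
    s = np.where(x < 0, s_left, s_right)
    return np.exp(-0.5 * (x / s) ** 2)


def make_fundamentals(spec: SyntheticFundamentalSpec | None = None) -> ConeFundamentals:
    """Generate smooth synthetic L, M, S fundamentals, peak-normalized.

    Deterministic: the same spec always yields bit-identical curves.
    """
    spec = spec or SyntheticFundamentalSpec()
    wl = spec.axis.wavelengths
    cols = [
        _split_log_gaussian(wl, p, b, a)
        for p, b, a in zip(spec.peaks, spec.bandwidths, spec.asymmetry)
    ]
    return ConeFundamentals(spec.axis, np.column_stack(cols))


@dataclass(frozen=True)
class DichromatCMF:
    """A dichromat's two colour matching functions.

    ``cmf`` holds the N x 2 matrix; for synthetic observers
    ``true_mixing`` retains the 2x2 matrix A such that
    cmf = [fundamental pair] @ A + noise (A is unknown in real data and
    kept only for ground-truth checks), and ``noise_sd`` the noise level
    as a fraction of peak.
    """

    observer_class: str
    cmf: ChannelSet
    true_mixing: np.ndarray | None = None
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.observer_class not in OBSERVER_CLASSES:
            raise UsageError(
                f"observer_class must be one of {OBSERVER_CLASSES}, got {self.observer_class!r}"
            )
        if self.cmf.n_channels != 2:
            raise UsageError("a dichromat CMF has exactly 2 channels")
        if self.true_mixing is not None:
            a = np.asarray(self.true_mixing, dtype=float)
            if a.shape != (2, 2):
                raise UsageError("mixing matrix must be 2x2")
            if abs(np.linalg.det(a)) == 0:
                raise UsageError("mixing matrix is singular")
            a.flags.writeable = False
            object.__setattr__(self, "true_mixing", a)

    @property
    def missing_cone(self) -> str:
        return MISSING_CONE[self.observer_class]

    @property
    def axis(self) -> SpectralAxis:
        return self.cmf.axis


def _random_mixing(rng: np.random.Generator, max_cond: float = 50.0) -> np.ndarray:
    """2x2 matrix with entries uniform on [-1, 1], redrawn until its
    condition number is at most ``max_cond``."""
    for _ in range(1000):
        a = rng.uniform(-1.0, 1.0, size=(2, 2))
        if np.linalg.cond(a) <= max_cond:
            return a
    raise ConstructionError("failed to draw a well-conditioned mixing matrix")


def make_dichromat(
    fundamentals: ConeFundamentals,
    observer_class: str,
    mixing: np.ndarray | str = "random",
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    max_cond: float = 50.0,
) -> DichromatCMF:
    """Simulate a dichromat's CMFs under (possibly unknown) primaries.

    The CMF matrix is [pair of fundamentals] @ A + eps, where A is the
    supplied 2x2 mixing (or a random well-conditioned draw) and eps is
    i.i.d. Gaussian per sample with sd ``noise_sd`` (curves are
    peak-normalized, so noise_sd is a fraction of peak).  Reproducible
    given the seed.
    """
    if observer_class not in OBSERVER_CLASSES:
        raise UsageError(f"unknown observer class {observer_class!r}")
    if noise_sd < 0:
        raise UsageError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(mixing, str):
        if mixing != "random":
            raise UsageError(f"mixing must be a 2x2 matrix or 'random', got {mixing!r}")
        a = _random_mixing(rng, max_cond=max_cond)
    else:
        a = np.asarray(mixing, dtype=float)
        if a.shape != (2, 2):
            raise UsageError("mixing matrix must be 2x2")
        cond = np.linalg.cond(a)
        if not np.isfinite(cond) or cond > 1e6:
            raise UsageError(f"mixing matrix is singular or ill-conditioned (cond={cond:.3g})")
    pair = fundamentals.pair(MISSING_CONE[observer_class])
    values = pair.values @ a
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    cmf = ChannelSet(
        fundamentals.axis,
        values,
        (f"{observer_class}_1", f"{observer_class}_2"),
    )
    return DichromatCMF(observer_class, cmf, true_mixing=a, noise_sd=noise_sd)


def make_observer_triple(
    fundamentals: ConeFundamentals,
    noise_sd: float = 0.0,
    seed: int = 0,
    mixing: str | dict[str, np.ndarray] = "random",
) -> dict[str, DichromatCMF]:
    """Protan, deutan and tritan CMFs from one set of fundamentals.

    A convenience wrapper drawing independent mixings (and noise) for the
    three observers from a single seed.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for cls in OBSERVER_CLASSES:
        mix = mixing[cls] if isinstance(mixing, dict) else mixing
        out[cls] = make_dichromat(fundamentals, cls, mixing=mix, noise_sd=noise_sd, seed=rng)
    return out


def match_light(cmf: ChannelSet, light: np.ndarray | ChannelSet) -> np.ndarray:
    """Primary intensities matching a test light: C^T e.

    By Grassmann additivity a match is an inner product of each matching
    function with the light's spectral energy; matches are therefore
    additive over lights.
    """
    if isinstance(light, ChannelSet):
        if light.axis != cmf.axis:
            raise UsageError("light and CMF must share an axis")
        e = light.values[:, 0]
    else:
        e = np.ravel(np.asarray(light, dtype=float))
        if e.size != cmf.axis.n:
            raise UsageError(
                f"light has {e.size} samples but axis has {cmf.axis.n}"
            )
    return cmf.values.T @ e


def monochromatic_light(axis: SpectralAxis, wavelength: float) -> np.ndarray:
    """Unit-energy spike at the grid sample nearest ``wavelength``."""
    e = np.zeros(axis.n)
    e[int(np.argmin(np.abs(axis.wavelengths - wavelength)))] = 1.0
    return e


def smooth_random_curves(
    axis: SpectralAxis, k: int, rng: np.random.Generator, n_bumps: int = 4
) -> np.ndarray:
    """k smooth random spectra: sums of Gaussian bumps with random centres,
    widths and signed amplitudes.  Generic draws are linearly independent."""
    wl = axis.wavelengths
    span = axis.stop - axis.start
    out = np.empty((axis.n, k))
    for j in range(k):
        centres = rng.uniform(axis.start, axis.stop, size=n_bumps)
        widths = rng.uniform(0.08 * span, 0.3 * span, size=n_bumps)
        amps = rng.uniform(-1.0, 1.0, size=n_bumps)
        out[:, j] = sum(
            a * np.exp(-0.5 * ((wl - c) / w) ** 2)
            for a, c, w in zip(amps, centres, widths)
        )
    return out


def make_camera_pair(
    shared_dim: int,
    channels_per_camera: int = 3,
    axis: SpectralAxis | None = None,
    seed: int | np.random.Generator = 0,
    max_tries: int = 50,
) -> tuple[ChannelSet, ChannelSet, ChannelSet | None]:
    """Two camera sensor sets whose channel subspaces share ``shared_dim``
    dimensions.

    Builds ``shared_dim`` common smooth basis curves plus independent
    smooth fillers per camera, then mixes each camera's columns by a random
    invertible matrix so the shared curves are hidden in both.  The
    construction is verified: the joined matrix [A, B] must have rank
    2*channels_per_camera - shared_dim, else it is redrawn (bounded
    retries).

    Returns (camera_a, camera_b, shared_basis); shared_basis is None when
    shared_dim == 0, otherwise a ChannelSet holding the planted curves.
    """
    k = channels_per_camera
    if not (0 <= shared_dim <= k):
        raise UsageError(f"shared_dim must be in 0..{k}, got {shared_dim}")
    axis = axis or default_axis()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    expected_rank = 2 * k - shared_dim
    for _ in range(max_tries):
        shared = smooth_random_curves(axis, shared_dim, rng) if shared_dim else None
        fill_a = smooth_random_curves(axis, k - shared_dim, rng)
        fill_b = smooth_random_curves(axis, k - shared_dim, rng)
        base_a = fill_a if shared is None else np.hstack([shared, fill_a])
        base_b = fill_b if shared is None else np.hstack([shared, fill_b])
        mix_a = rng.uniform(-1.0, 1.0, size=(k, k))
        mix_b = rng.uniform(-1.0, 1.0, size=(k, k))
        if max(np.linalg.cond(mix_a), np.linalg.cond(mix_b)) > 1e3:
            continue
        va, vb = base_a @ mix_a, base_b @ mix_b
        joined = np.hstack([va, vb])
        sv = np.linalg.svd(joined, compute_uv=False)
        rank = int(np.sum(sv > 1e-9 * sv[0]))
        if rank != expected_rank:
            continue
        cam_a = ChannelSet(axis, va, tuple(f"A{i}" for i in range(k)))
        cam_b = ChannelSet(axis, vb, tuple(f"B{i}" for i in range(k)))
        shared_cs = (
            None
            if shared is None
            else ChannelSet(axis, shared, tuple(f"shared{i}" for i in range(shared_dim)))
        )
        return cam_a, cam_b, shared_cs
    raise ConstructionError(
        f"could not construct a camera pair with shared_dim={shared_dim} "
        f"(rank {expected_rank}) in {max_tries} tries"
    )
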