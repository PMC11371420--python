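"""Virtual channels: spectral sensitivities shared by two sensor sets.

Given two cameras with channel matrices C (N x k1) and C~ (N x k2), a
virtual channel is a spectral sensitivity in the intersection of their
column spaces: a pair of coefficient vectors (v, v~) with C v = C~ v~.
Such a channel is realizable by linear combination in both systems though
present in neither, and it lets image data from the two systems be
compared quantitatively on common ground.

As in the cone-fundamental problem, the intersection is the null space of
the joined matrix J = [C, C~]: a null vector w satisfies C w[:k1] +
C~ w[k1:] = 0, i.e. v = w[:k1] and v~ = -w[k1:].  The number of virtual
channels is (k1 + k2) - rank(J).  For the common case of two 3-channel
cameras the rank classifies as:

====  ==================  =================================
rank  class               meaning
====  ==================  =================================
3     identical_space     same 3-D channel space
4     plane               virtual channels span a plane
5     single              a single virtual channel
6     none                no commonality
====  ==================  =================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import AxisError, UsageError
from .spectral import ChannelSet, common_axis, resample

__all__ = ["VirtualChannelResult", "virtual_channels", "contrast_on_light", "RANK_CLASSES"]

RANK_CLASSES = {3: "identical_space", 4: "plane", 5: "single", 6: "none"}


@dataclass(frozen=True)
class VirtualChannelResult:
    """Rank classification and shared-channel basis for two sensor sets.

    ``v_first`` / ``v_second`` hold one coefficient vector per virtual
    channel (columns), satisfying C v ~= C~ v~; ``channels`` holds the
    A-side reconstructions C v, orthonormalized as a basis then
    peak-normalized per channel.  ``rank_class`` is populated only for the
    two-3-channel-camera case; otherwise it is the raw rank as a string.
    When the intersection has dimension > 1 any basis of it is equally
    valid; the orthonormalized basis returned here is one choice.
    """

    rank: int
    rank_class: str
    v_first: np.ndarray
    v_second: np.ndarray
    channels: ChannelSet | None
    singular_values: np.ndarray
    residuals: np.ndarray
    warnings: tuple[str, ...] = ()

    @property
    def n_virtual(self) -> int:
        return self.v_first.shape[1]


def _camera_rank_warning(cs: ChannelSet, name: str, rel_tol: float) -> str | None:
    sv = np.linalg.svd(cs.values, compute_uv=False)
    r = int(np.sum(sv > rel_tol * sv[0]))
    if r < cs.n_channels:
        return (
            f"camera {name} is rank-deficient on its own "
            f"({r} of {cs.n_channels} independent channels)"
        )
    return None


def virtual_channels(
    a: ChannelSet, b: ChannelSet, rel_tol: float = 1e-9
) -> VirtualChannelResult:
    """Classify the joined-matrix rank and extract shared virtual channels.

    The numerical rank counts singular values above ``rel_tol`` times the
    largest; each joined-matrix null vector yields one (v, v~) pair.  A
    camera whose own channels are linearly dependent triggers a warning
    recorded on the result (processing continues).
    """
    if a.axis != b.axis:
        ax = common_axis(a, b)
        a, b = resample(a, ax), resample(b, ax)
    if np.any(np.all(a.values == 0, axis=0)) or np.any(np.all(b.values == 0, axis=0)):
        raise UsageError("a sensor set contains an all-zero channel")
    k1, k2 = a.n_channels, b.n_channels
    notes = []
    for cs, name in ((a, "A"), (b, "B")):
        msg = _camera_rank_warning(cs, name, rel_tol)
        if msg:
            notes.append(msg)
            warnings.warn(msg, stacklevel=2)

    joined = np.hstack([a.values, b.values])
    _, sv, vt = np.linalg.svd(joined, full_matrices=False)
    rank = int(np.sum(sv > rel_tol * sv[0]))
    n_virtual = (k1 + k2) - rank
    if k1 == 3 and k2 == 3:
        rank_class = RANK_CLASSES.get(rank, str(rank))
    else:
        rank_class = str(rank)

    if n_virtual == 0:
        return VirtualChannelResult(
            rank=rank,
            rank_class=rank_class,
            v_first=np.zeros((k1, 0)),
            v_second=np.zeros((k2, 0)),
            channels=None,
            singular_values=sv,
            residuals=np.zeros(0),
            warnings=tuple(notes),
        )

    null = vt[rank:].T  # (k1+k2) x n_virtual, J @ null = 0
    v = null[:k1]
    vt_b = -null[k1:]  # C v = C~ v~ requires the sign flip
    spectra = a.values @ v  # N x n_virtual, A-side reconstructions
    # orthonormalize the basis of the intersection, then peak-normalize
    q, r = np.linalg.qr(spectra)
    try:
        r_inv = np.linalg.inv(r)
    except np.linalg.LinAlgError:
        # degenerate spectra (rank-deficient camera); keep correspondence
        r_inv = np.linalg.pinv(r)
    v = v @ r_inv
    vt_b = vt_b @ r_inv
    spectra = q
    peaks = np.max(np.abs(spectra), axis=0)
    peaks = np.where(peaks == 0, 1.0, peaks)
    signs = np.where(spectra.sum(axis=0) >= 0, 1.0, -1.0)
    scale = signs / peaks
    spectra = spectra * scale
    v = v * scale
    vt_b = vt_b * scale
    recon_b = b.values @ vt_b
    residuals = np.array(
        [
            np.linalg.norm(spectra[:, j] - recon_b[:, j]) / np.linalg.norm(spectra[:, j])
            for j in range(n_virtual)
        ]
    )
    channels = ChannelSet(
        a.axis, spectra, tuple(f"virtual{i}" for i in range(n_virtual))
    )
    return VirtualChannelResult(
        rank=rank,
        rank_class=rank_class,
        v_first=v,
        v_second=vt_b,
        channels=channels,
        singular_values=sv,
        residuals=residuals,
        warnings=tuple(notes),
    )


def contrast_on_light(
    result: VirtualChannelResult,
    a: ChannelSet,
    b: ChannelSet,
    light: np.ndarray,
) -> np.ndarray:
    """Responses of each virtual channel to a light, from both cameras.

    Returns an (n_virtual, 2) array of pairs (<C v, e>, <C~ v~, e>); the
    two members of each pair agree up to the intersection residual, so a
    scene's contrast can be compared across the two systems.
    """
    if a.axis != b.axis:
        raise AxisError("cameras must share an axis")
    e = np.ravel(np.asarray(light, dtype=float))
    if e.size != a.axis.n:
        raise AxisError(f"light has {e.size} samples but axis has {a.axis.n}")
    resp_a = (a.values @ result.v_first).T @ e
    resp_b = (b.values @ result.v_second).T @ e
    return np.column_stack([resp_a, resp_b])
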