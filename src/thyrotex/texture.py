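"""The hand-crafted texture feature core.

A nodule is tiled into 20 x 20 px patches; each patch is read out as four
1-D signals (row-major, column-major, and two diagonal zig-zag scans, each
a permutation of the 400 pixels); each signal is split into three frequency
bands (echo level, macro-texture, speckle scale) by a zero-phase filter
bank; and each band is summarized by an order-2 autoregressive fit, giving
2 coefficients + log residual variance per band. 4 signals x 3 bands x 3
numbers = 36 features per patch. Everything here is deterministic.
"""

from __future__ import annotations

import dataclasses
import functools
import warnings
from typing import Sequence

import numpy as np

from .config import DEFAULT_BAND_EDGES

__all__ = [
    "TexturePatch",
    "PatchSignalSet",
    "BandSet",
    "PatchFeatures",
    "ARFit",
    "extract_patches",
    "patch_to_signals",
    "decompose_bands",
    "ar_fit",
    "patch_features",
    "feature_names",
]

LOG_VAR_FLOOR = 1e-12  # added inside the log so a zero-variance band is finite

SIGNAL_NAMES = ("row", "col", "diag", "adiag")
BAND_NAMES = ("low", "mid", "high")


@dataclasses.dataclass(frozen=True)
class TexturePatch:
    """A square intensity block cut from a source image."""

    pixels: np.ndarray
    origin_px: tuple[int, int]
    inside_fraction: float

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("patch must be square 2-D")
        if not 0.0 <= self.inside_fraction <= 1.0:
            raise ValueError("inside_fraction must lie in [0, 1]")
        object.__setattr__(self, "pixels", p)


@dataclasses.dataclass(frozen=True)
class PatchSignalSet:
    """Four same-length 1-D readouts of one patch."""

    signals: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]

    def __post_init__(self) -> None:
        if len(self.signals) != 4:
            raise ValueError("exactly 4 signals required")
        n = {s.size for s in self.signals}
        if len(n) != 1:
            raise ValueError("signals must share one length")
        if not all(np.all(np.isfinite(s)) for s in self.signals):
            raise ValueError("signals must be finite")


@dataclasses.dataclass(frozen=True)
class BandSet:
    """Per signal, the (low, mid, high) zero-phase band components."""

    bands: tuple[tuple[np.ndarray, np.ndarray, np.ndarray], ...]


@dataclasses.dataclass(frozen=True)
class PatchFeatures:
    """Ordered feature vector: signal-major, band-minor, each contributing
    [ar_coef_1 .. ar_coef_p, log_residual_variance]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or not np.all(np.isfinite(v)):
            raise ValueError("feature vector must be 1-D and finite")
        object.__setattr__(self, "values", v)


@dataclasses.dataclass(frozen=True)
class ARFit:
    coefficients: np.ndarray
    residual_variance: float


def extract_patches(
    image: np.ndarray,
    mask: np.ndarray,
    stride_px: int = 10,
    min_inside_fraction: float = 0.8,
    patch_size_px: int = 20,
) -> list[TexturePatch]:
    """Tile the mask's bounding box with patches on a stride grid.

    Only patches whose fraction of in-mask pixels reaches
    ``min_inside_fraction`` are kept, ordered row-major by origin.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask must share a shape")
    if stride_px < 1:
        raise ValueError("stride_px must be >= 1")
    if not mask.any():
        return []
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    r0, r1 = int(rows[0]), int(rows[-1])
    c0, c1 = int(cols[0]), int(cols[-1])
    ps = patch_size_px
    patches: list[TexturePatch] = []
    for r in range(r0, max(r0, r1 - ps + 2), stride_px):
        if r + ps > image.shape[0]:
            break
        for c in range(c0, max(c0, c1 - ps + 2), stride_px):
            if c + ps > image.shape[1]:
                break
            frac = float(mask[r : r + ps, c : c + ps].mean())
            if frac >= min_inside_fraction:
                patches.append(
                    TexturePatch(image[r : r + ps, c : c + ps].copy(), (r, c), frac)
                )
    if not patches:
        warnings.warn("mask too small to host one qualifying patch", stacklevel=2)
    return patches


@functools.lru_cache(maxsize=8)
def _zigzag_order(n: int) -> np.ndarray:
    """Flat indices of the JPEG-style zig-zag scan of an n x n block."""
    idx = []
    for s in range(2 * n - 1):
        diag = [(i, s - i) for i in range(max(0, s - n + 1), min(n, s + 1))]
        if s % 2 == 1:
            diag.reverse()
        idx.extend(diag)
    return np.array([i * n + j for i, j in idx])


def patch_to_signals(patch: TexturePatch) -> PatchSignalSet:
    """Read the patch out in four scan orders.

    (1) row-major, (2) column-major, (3) zig-zag along anti-diagonals,
    (4) zig-zag along main diagonals; each is a permutation of the pixels.
    """
    p = patch.pixels
    n = p.shape[0]
    zz = _zigzag_order(n)
    return PatchSignalSet(
        signals=(
            p.ravel(order="C"),
            p.ravel(order="F"),
            p.ravel(order="C")[zz],
            np.fliplr(p).ravel(order="C")[zz],
        )
    )


def _band_masks(n: int, edges: tuple[float, float]) -> list[np.ndarray]:
    freqs = np.fft.rfftfreq(n)
    lo, hi = edges
    return [freqs <= lo, (freqs > lo) & (freqs <= hi), freqs > hi]


def decompose_bands(
    signals: PatchSignalSet, edges: tuple[float, float] = DEFAULT_BAND_EDGES
) -> BandSet:
    """Zero-phase three-band split of each signal.

    Implemented as an ideal filter bank in the discrete Fourier domain, so
    the three bands are exactly zero-phase and sum exactly to the input;
    the DC component (mean echo level) is retained in the low band.
    """
    out = []
    for s in signals.signals:
        spec = np.fft.rfft(s)
        out.append(
            tuple(np.fft.irfft(spec * m, n=s.size) for m in _band_masks(s.size, edges))
        )
    return BandSet(bands=tuple(out))


def ar_fit(band: np.ndarray, order: int = 2) -> ARFit:
    """Autoregressive fit by Burg's method (stable on short records).

    Returns regression-convention coefficients phi such that
    x_t ≈ phi_1 x_{t-1} + ... + phi_p x_{t-p}, and the final prediction
    error power as the residual variance. A zero-variance input returns
    all-zero coefficients and zero variance (documented degenerate case).
    """
    x = np.asarray(band, dtype=float).ravel()
    n = x.size
    if order < 1:
        raise ValueError("order must be >= 1")
    if n <= 10 * order:
        raise ValueError(f"sequence length {n} must exceed 10 x order ({10 * order})")
    if not np.all(np.isfinite(x)):
        raise ValueError("band must be finite")
    if np.ptp(x) == 0.0:
        return ARFit(np.zeros(order), 0.0)

    # Burg recursion on forward/backward prediction errors
    ef = x.copy()
    eb = x.copy()
    a = np.zeros(order)
    energy = float(x @ x) / n
    for m in range(order):
        efp = ef[1:]
        ebp = eb[:-1]
        den = float(efp @ efp + ebp @ ebp)
        if den <= 0.0:
            break
        k = -2.0 * float(efp @ ebp) / den
        ef = efp + k * ebp
        eb = ebp + k * efp
        if m > 0:
            a[:m] = a[:m] + k * a[:m][::-1]
        a[m] = k
        energy *= 1.0 - k * k
    return ARFit(coefficients=-a, residual_variance=max(float(energy), 0.0))


def patch_features(
    patch: TexturePatch,
    order: int = 2,
    edges: tuple[float, float] = DEFAULT_BAND_EDGES,
) -> PatchFeatures:
    """Full feature vector for one patch: 4 signals x 3 bands x (order + 1)
    values, 36 at the defaults."""
    bands = decompose_bands(patch_to_signals(patch), edges)
    values: list[float] = []
    for per_signal in bands.bands:
        for band in per_signal:
            fit = ar_fit(band, order)
            values.extend(fit.coefficients.tolist())
            values.append(float(np.log(fit.residual_variance + LOG_VAR_FLOOR)))
    return PatchFeatures(values=np.array(values))


def feature_names(order: int = 2) -> list[str]:
    """Column names matching the feature-vector layout."""
    names = []
    for sig in SIGNAL_NAMES:
        for band in BAND_NAMES:
            names.extend(f"{sig}_{band}_ar{i + 1}" for i in range(order))
            names.append(f"{sig}_{band}_logvar")
    return names
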