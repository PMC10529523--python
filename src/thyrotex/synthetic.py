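"""Seeded synthetic ultrasound phantoms with known solid/cystic composition.

Real thyroid ultrasound frames are not redistributable, so every pipeline
stage is exercised on synthetic nodules built here: a speckled background,
an elliptical nodule containing an echoic textured (solid) compartment and
one or more hypoechoic (cystic) blobs whose summed area hits a requested
cystic fraction, plus simulated annotators whose boundary jitter, bias and
noise stand in for physicians of varying experience.

Speckle is modelled as multiplicative gamma noise on a piecewise-constant
echogenicity map followed by a Gaussian point-spread blur — the standard
fully-developed-speckle approximation. Every generator is a pure function
of its arguments including the seed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SpeckleParams",
    "NoduleSpec",
    "SyntheticNodule",
    "AnnotatorModel",
    "BACKGROUND_PARAMS",
    "SOLID_PARAMS",
    "CYSTIC_PARAMS",
    "LABEL_BACKGROUND",
    "LABEL_SOLID",
    "LABEL_CYSTIC",
    "generate_speckle_field",
    "render_nodule",
    "simulate_annotator_mask",
    "simulate_observer_table",
    "make_default_suite",
    "default_annotators",
]

LABEL_BACKGROUND = 0
LABEL_SOLID = 1
LABEL_CYSTIC = 2

_AREA_TOL = 0.02  # max |achieved - requested| cystic area fraction


@dataclasses.dataclass(frozen=True)
class SpeckleParams:
    """Echogenicity and speckle statistics of one tissue compartment.

    mean_intensity: target grayscale level in [0, 1].
    speckle_shape: gamma shape of the multiplicative noise (smaller = grainier).
    smoothing_sigma_px: Gaussian point-spread blur, pixels.
    """

    mean_intensity: float
    speckle_shape: float
    smoothing_sigma_px: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_intensity <= 1.0:
            raise ValueError("mean_intensity must lie in [0, 1]")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive")
        if self.smoothing_sigma_px < 0:
            raise ValueError("smoothing_sigma_px must be non-negative")


# Defaults follow the qualitative ultrasound convention: cysts are
# near-anechoic and smooth, solid tissue is brighter than parenchyma.
BACKGROUND_PARAMS = SpeckleParams(0.35, 3.0, 1.0)
SOLID_PARAMS = SpeckleParams(0.55, 3.0, 0.8)
CYSTIC_PARAMS = SpeckleParams(0.06, 6.0, 1.2)


@dataclasses.dataclass(frozen=True)
class NoduleSpec:
    """Geometry and composition of one synthetic nodule."""

    center_px: tuple[float, float]
    axes_px: tuple[float, float]
    cystic_fraction_true: float
    solid_params: SpeckleParams = SOLID_PARAMS
    cystic_params: SpeckleParams = CYSTIC_PARAMS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cystic_fraction_true <= 1.0:
            raise ValueError("cystic_fraction_true must lie in [0, 1]")
        if min(self.axes_px) <= 0:
            raise ValueError("axes_px must be positive")


@dataclasses.dataclass
class SyntheticNodule:
    """A rendered phantom: image, masks and the ground-truth composition."""

    image: np.ndarray
    pixel_spacing_mm: float
    nodule_mask: np.ndarray
    label_mask: np.ndarray
    cystic_fraction_true: float
    nodule_id: str = "nodule"

    @property
    def cystic_fraction_achieved(self) -> float:
        n = int(self.nodule_mask.sum())
        return float((self.label_mask == LABEL_CYSTIC).sum() / n) if n else 0.0


@dataclasses.dataclass(frozen=True)
class AnnotatorModel:
    """One simulated annotator.

    boundary_jitter_px controls segmentation sloppiness; cystic_bias_pct and
    cystic_noise_pct are systematic and random errors (percentage points) on
    the reported cystic percentage, which is rounded to rounding_step_pct and
    clipped to [0, 100].
    """

    boundary_jitter_px: float = 0.0
    cystic_bias_pct: float = 0.0
    cystic_noise_pct: float = 0.0
    rounding_step_pct: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boundary_jitter_px < 0:
            raise ValueError("boundary_jitter_px must be non-negative")
        if self.cystic_noise_pct < 0:
            raise ValueError("cystic_noise_pct must be non-negative")
        if self.rounding_step_pct <= 0:
            raise ValueError("rounding_step_pct must be positive")


def generate_speckle_field(
    shape: tuple[int, int], params: SpeckleParams, seed: int
) -> np.ndarray:
    """Homogeneous speckle texture: gamma noise around a level, then blur.

    Deterministic in (shape, params, seed); values clipped to [0, 1].
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 2 or min(shape) <= 0:
        raise ValueError(f"shape must be positive 2-D, got {shape}")
    if params.mean_intensity == 0.0:
        return np.zeros(shape)
    rng = np.random.default_rng(seed)
    field = params.mean_intensity * rng.gamma(
        params.speckle_shape, 1.0 / params.speckle_shape, size=shape
    )
    if params.smoothing_sigma_px > 0:
        field = ndimage.gaussian_filter(field, params.smoothing_sigma_px)
    return np.clip(field, 0.0, 1.0)


def _ellipse_mask(
    shape: tuple[int, int], center: tuple[float, float], axes: tuple[float, float]
) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = center
    ay, ax = axes
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _cystic_blob_union(
    shape: tuple[int, int],
    centers: np.ndarray,
    radii: np.ndarray,
    scale: float,
    nodule_mask: np.ndarray,
) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    for (cy, cx), (ry, rx) in zip(centers, radii):
        out |= _ellipse_mask(shape, (cy, cx), (max(ry * scale, 0.5), max(rx * scale, 0.5)))
    return out & nodule_mask


def render_nodule(
    image_shape: tuple[int, int],
    spec: NoduleSpec,
    background: SpeckleParams = BACKGROUND_PARAMS,
    pixel_spacing_mm: float = 5.296 / 20.0,
    nodule_id: str = "nodule",
) -> SyntheticNodule:
    """Render a phantom whose cystic area fraction matches the spec ±2%.

    The cystic compartment is 1–3 random ellipses inside the nodule, grown
    by bisection on a common scale until the summed area fraction lands
    within tolerance of ``cystic_fraction_true``.
    """
    shape = tuple(int(s) for s in image_shape)
    cy, cx = spec.center_px
    ay, ax = spec.axes_px
    if cy - ay < 0 or cy + ay >= shape[0] or cx - ax < 0 or cx + ax >= shape[1]:
        raise ValueError("nodule ellipse does not fit inside the image frame")

    rng = np.random.default_rng(spec.seed)
    nodule_mask = _ellipse_mask(shape, (cy, cx), (ay, ax))
    n_nod = int(nodule_mask.sum())
    target = spec.cystic_fraction_true

    if target <= 0.0:
        cystic = np.zeros(shape, dtype=bool)
    elif target >= 1.0:
        cystic = nodule_mask.copy()
    else:
        n_blobs = int(rng.integers(1, 4))
        # blob centres inside the nodule, away from the rim
        theta = rng.uniform(0, 2 * np.pi, n_blobs)
        rho = np.sqrt(rng.uniform(0, 1, n_blobs)) * 0.7
        centers = np.column_stack(
            [cy + rho * np.sin(theta) * ay, cx + rho * np.cos(theta) * ax]
        )
        radii = rng.uniform(0.4, 1.0, (n_blobs, 2)) * np.array([ay, ax]) / np.sqrt(n_blobs)
        lo, hi = 0.0, 4.0
        cystic = np.zeros(shape, dtype=bool)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            cystic = _cystic_blob_union(shape, centers, radii, mid, nodule_mask)
            frac = cystic.sum() / n_nod
            if abs(frac - target) <= 0.5 * _AREA_TOL:
                break
            if frac < target:
                lo = mid
            else:
                hi = mid
        achieved = cystic.sum() / n_nod
        if abs(achieved - target) > _AREA_TOL:
            raise RuntimeError(
                f"could not reach cystic fraction {target:.3f}; achieved {achieved:.3f}"
            )

    label_mask = np.full(shape, LABEL_BACKGROUND, dtype=np.uint8)
    label_mask[nodule_mask] = LABEL_SOLID
    label_mask[cystic] = LABEL_CYSTIC

    sub = rng.integers(0, 2**31 - 1, size=3)
    bg_field = generate_speckle_field(shape, background, int(sub[0]))
    solid_field = generate_speckle_field(shape, spec.solid_params, int(sub[1]))
    cyst_field = generate_speckle_field(shape, spec.cystic_params, int(sub[2]))
    image = np.where(
        label_mask == LABEL_CYSTIC,
        cyst_field,
        np.where(label_mask == LABEL_SOLID, solid_field, bg_field),
    )
    return SyntheticNodule(
        image=image,
        pixel_spacing_mm=float(pixel_spacing_mm),
        nodule_mask=nodule_mask,
        label_mask=label_mask,
        cystic_fraction_true=float(target),
        nodule_id=nodule_id,
    )


def simulate_annotator_mask(truth: SyntheticNodule, model: AnnotatorModel) -> np.ndarray:
    """Annotator's nodule segmentation: the true boundary warped by a smooth
    random displacement field with RMS amplitude ``boundary_jitter_px``.

    Exactly reproduces ``truth.nodule_mask`` when the jitter is zero.
    """
    mask = truth.nodule_mask
    if model.boundary_jitter_px == 0.0:
        return mask.copy()
    rng = np.random.default_rng(model.seed)
    shape = mask.shape
    disp = []
    for _ in range(2):
        f = ndimage.gaussian_filter(rng.standard_normal(shape), 8.0)
        rms = np.sqrt(np.mean(f**2))
        disp.append(f / rms * model.boundary_jitter_px)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    warped = ndimage.map_coordinates(
        mask.astype(float), [yy + disp[0], xx + disp[1]], order=1, mode="constant"
    )
    out = warped >= 0.5
    out = ndimage.binary_fill_holes(out)
    labels, n = ndimage.label(out)
    if n > 1:  # keep the largest connected component
        sizes = ndimage.sum_labels(out, labels, index=np.arange(1, n + 1))
        out = labels == (1 + int(np.argmax(sizes)))
    return out


def _report_percentage(truth_pct: float, model: AnnotatorModel, rng) -> float:
    raw = truth_pct + model.cystic_bias_pct + rng.normal(0.0, model.cystic_noise_pct)
    step = model.rounding_step_pct
    return float(np.clip(step * np.round(raw / step), 0.0, 100.0))


def simulate_observer_table(
    truths: Sequence[SyntheticNodule],
    annotators: Sequence[AnnotatorModel],
    observer_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-nodule cystic-percentage reports by each simulated annotator.

    Returns a DataFrame indexed by nodule id, one column per annotator;
    entry = clip(round-to-step(true% + bias + noise), 0, 100), seeded per
    annotator.
    """
    if not truths or not annotators:
        raise ValueError("truths and annotators must be non-empty")
    if observer_names is None:
        observer_names = [f"P{i + 1}" for i in range(len(annotators))]
    data = {}
    for name, model in zip(observer_names, annotators):
        rng = np.random.default_rng(model.seed)
        data[name] = [
            _report_percentage(100.0 * t.cystic_fraction_true, model, rng) for t in truths
        ]
    idx = pd.Index([t.nodule_id for t in truths], name="nodule_id")
    return pd.DataFrame(data, index=idx)


def default_annotators(seed: int = 0) -> list[AnnotatorModel]:
    """Three annotators with experience-dependent error levels.

    The first (most experienced) has the tightest jitter and noise; the
    other two are noisier and biased, mirroring readers with fewer years
    of ultrasound practice.
    """
    return [
        AnnotatorModel(1.5, 0.0, 4.0, 5.0, seed=seed * 7919 + 11),
        AnnotatorModel(3.0, 5.0, 8.0, 5.0, seed=seed * 7919 + 13),
        AnnotatorModel(3.0, -5.0, 10.0, 5.0, seed=seed * 7919 + 17),
    ]


def make_default_suite(
    n_nodules: int = 20,
    seed: int = 0,
    image_shape: tuple[int, int] = (256, 256),
    fractions: Sequence[float] | None = None,
    pixel_spacing_mm: float = 5.296 / 20.0,
) -> list[SyntheticNodule]:
    """The default seeded phantom suite: nodules whose true cystic
    fractions span 10–90%, with randomized size and placement."""
    if fractions is None:
        fractions = np.linspace(0.10, 0.90, n_nodules)
    rng = np.random.default_rng(seed)
    suite = []
    h, w = image_shape
    for i, frac in enumerate(fractions):
        ay = rng.uniform(45, 70)
        ax = rng.uniform(40, 65)
        cy = rng.uniform(ay + 2, h - ay - 2)
        cx = rng.uniform(ax + 2, w - ax - 2)
        spec = NoduleSpec(
            center_px=(cy, cx),
            axes_px=(ay, ax),
            cystic_fraction_true=float(frac),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        suite.append(
            render_nodule(
                image_shape, spec, pixel_spacing_mm=pixel_spacing_mm,
                nodule_id=f"syn{i + 1:02d}",
            )
        )
    return suite
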