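"""Synthetic multi-stain IF case generator and Gaussian defocus degradation.

The generator renders parameterized caricatures of the four diseases'
characteristic immune-deposit morphologies on a 7-stain stack:

* **IgAN** — granular mesangial deposits: many small bright blobs clustered
  around the glomerular center, dominant in IgA with C3 co-positivity.
* **MN** — capillary-loop pattern: fine granular deposits beaded along a
  ring (the glomerular basement membrane), dominant in IgG.
* **DN** — linear staining: smooth, continuous intensity along the same
  capillary-loop contour, without granularity; IgG-dominant like MN, so
  only the fine-scale beading texture separates the two.
* **LN** — "full house": blobs plus ring segments, positive in all seven
  stains.

Each case carries the rendered deposit mask as ground truth, so downstream
attention/localization claims can be scored against known deposit pixels.
Defocus is modeled as convolution with a normalized, truncated Gaussian
kernel (reflect padding), the standard optical-blur surrogate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import convolve1d

from .case import LABELS, N_STAINS, IFCase, ValidationError
from .utils import round_half_up

# ---------------------------------------------------------------------------
# Specs

#: Per-class relative stain intensities, STAINS order (IgG, IgA, IgM, C3,
#: C4, C1q, Fib). LN is positive in every stain ("full house"). MN and DN
#: share an IgG/C3-dominant profile on purpose: in real biopsies both are
#: IgG-positive and are told apart by morphology (granular capillary-loop
#: deposits vs linear basement-membrane staining), so intensity profiles
#: alone must not separate them.
DEFAULT_STAIN_GAINS: dict[str, tuple[float, ...]] = {
    "IgAN": (0.15, 0.90, 0.20, 0.60, 0.05, 0.08, 0.25),
    "MN": (0.90, 0.08, 0.15, 0.50, 0.25, 0.10, 0.08),
    "DN": (0.85, 0.06, 0.10, 0.45, 0.18, 0.07, 0.09),
    "LN": (0.80, 0.55, 0.60, 0.70, 0.55, 0.70, 0.45),
}

#: Morphology knobs per class (merged over by SynthSpec overrides).
DEFAULT_PATTERN_PARAMS: dict[str, dict] = {
    "IgAN": {"blob_count": (15, 25), "blob_radius": (1.5, 3.0), "cluster_sd": 0.16},
    "MN": {"ring_radius": (0.26, 0.36), "ring_thickness": 1.6, "bead_step_deg": 9.0},
    "DN": {"ring_radius": (0.26, 0.36), "line_width": 1.8, "diffuse_gain": 1.0},
    "LN": {
        "blob_count": (8, 14),
        "blob_radius": (1.5, 2.5),
        "cluster_sd": 0.20,
        "ring_radius": (0.26, 0.36),
        "ring_thickness": 1.4,
        "bead_step_deg": 12.0,
    },
}


@dataclass
class SynthSpec:
    """Parameters of one synthetic dataset draw.

    ``n_per_class`` cases are generated for each of the four labels;
    ``deposit_pattern_params`` / ``stain_gains`` override individual entries
    of the class defaults.
    """

    n_per_class: int = 50
    image_size: int = 64
    noise_sd: float = 0.02
    background: float = 0.04
    brightness_jitter: tuple[float, float] = (0.6, 1.15)
    mask_threshold: float = 0.25
    deposit_pattern_params: Mapping[str, dict] = field(default_factory=dict)
    stain_gains: Mapping[str, Sequence[float]] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> "SynthSpec":
        if self.n_per_class < 1:
            raise ValidationError(f"n_per_class must be >= 1, got {self.n_per_class}")
        if self.image_size < 16:
            raise ValidationError(f"image_size must be >= 16, got {self.image_size}")
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0 < self.mask_threshold < 1:
            raise ValidationError(
                f"mask_threshold must be in (0, 1), got {self.mask_threshold}"
            )
        for key in self.deposit_pattern_params:
            if key not in LABELS:
                raise ValidationError(f"deposit_pattern_params: unknown class {key!r}")
        for key, gains in self.stain_gains.items():
            if key not in LABELS:
                raise ValidationError(f"stain_gains: unknown class {key!r}")
            if len(gains) != N_STAINS:
                raise ValidationError(
                    f"stain_gains[{key!r}] must have {N_STAINS} entries"
                )
        return self

    def pattern_params(self, label: str) -> dict:
        merged = dict(DEFAULT_PATTERN_PARAMS[label])
        merged.update(self.deposit_pattern_params.get(label, {}))
        return merged

    def gains(self, label: str) -> np.ndarray:
        return np.asarray(
            self.stain_gains.get(label, DEFAULT_STAIN_GAINS[label]), dtype=np.float64
        )


@dataclass
class BlurSpec:
    """Gaussian defocus: standard deviation in pixels, odd kernel width.

    ``kernel_size=None`` derives the width as ``2*ceil(3*sigma)+1`` so the
    kernel covers +/-3 sigma.
    """

    sigma: float = 2.0
    kernel_size: int | None = None

    def validate(self) -> "BlurSpec":
        if self.sigma < 0:
            raise ValidationError(f"sigma must be >= 0, got {self.sigma}")
        k = self.resolved_kernel_size()
        if k < 1 or k % 2 == 0:
            raise ValidationError(f"kernel_size must be odd and >= 1, got {k}")
        return self

    def resolved_kernel_size(self) -> int:
        if self.kernel_size is not None:
            return self.kernel_size
        return 2 * math.ceil(3 * self.sigma) + 1


# ---------------------------------------------------------------------------
# Pattern rendering


def _add_bumps(img: np.ndarray, ys, xs, radii, amps) -> None:
    """Accumulate isotropic Gaussian bumps in place."""
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    for y, x, r, a in zip(ys, xs, radii, amps):
        img += a * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * r * r))


def _granular_blobs(size: int, params: dict, rng: np.random.Generator) -> np.ndarray:
    lo, hi = params["blob_count"]
    n = int(rng.integers(lo, hi + 1))
    center = size / 2 + rng.normal(0, 0.04 * size, size=2)
    pos = rng.normal(center, params["cluster_sd"] * size, size=(n, 2))
    radii = rng.uniform(*params["blob_radius"], size=n)
    amps = rng.uniform(0.7, 1.0, size=n)
    img = np.zeros((size, size))
    _add_bumps(img, pos[:, 0], pos[:, 1], radii, amps)
    return img


def _capillary_ring(size: int, params: dict, rng: np.random.Generator) -> np.ndarray:
    center = size / 2 + rng.normal(0, 0.03 * size, size=2)
    radius = rng.uniform(*params["ring_radius"]) * size
    step = math.radians(params["bead_step_deg"])
    angles = np.arange(0, 2 * math.pi, step) + rng.uniform(0, step)
    angles = angles + rng.normal(0, 0.25 * step, size=angles.size)
    ys = center[0] + radius * np.sin(angles)
    xs = center[1] + radius * np.cos(angles)
    radii = np.full(angles.size, params["ring_thickness"])
    amps = rng.uniform(0.6, 1.0, size=angles.size)
    img = np.zeros((size, size))
    _add_bumps(img, ys, xs, radii, amps)
    return img


def _linear_ring(size: int, params: dict, rng: np.random.Generator) -> np.ndarray:
    """Smooth continuous staining along the capillary-loop contour.

    Same geometry as the membranous beaded ring but without granularity —
    the two are distinguished by fine-scale texture, not layout.
    """
    center = size / 2 + rng.normal(0, 0.03 * size, size=2)
    radius = rng.uniform(*params["ring_radius"]) * size
    width = params["line_width"]
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.sqrt((yy - center[0]) ** 2 + (xx - center[1]) ** 2)
    img = rng.uniform(0.55, 0.8) * np.exp(-((r - radius) ** 2) / (2 * width * width))
    return img * params["diffuse_gain"]


def _render_pattern(label: str, size: int, params: dict, rng: np.random.Generator) -> np.ndarray:
    if label == "IgAN":
        img = _granular_blobs(size, params, rng)
    elif label == "MN":
        img = _capillary_ring(size, params, rng)
    elif label == "DN":
        img = _linear_ring(size, params, rng)
    elif label == "LN":
        img = _granular_blobs(size, params, rng) + _capillary_ring(size, params, rng)
    else:  # pragma: no cover - guarded by SynthSpec validation
        raise ValidationError(f"unknown label {label!r}")
    return np.clip(img, 0.0, 1.0)


def _quantize16(x: np.ndarray) -> np.ndarray:
    """Snap intensities to the 16-bit grid so PNG round-trips are exact."""
    return (np.round(x * 65535.0) / 65535.0).astype(np.float32)


def generate_case(
    label: str, case_id: str, spec: SynthSpec, rng: np.random.Generator
) -> IFCase:
    size = spec.image_size
    pattern = _render_pattern(label, size, spec.pattern_params(label), rng)
    mask = pattern > spec.mask_threshold
    # per-stain jitter models staining variability; the case-level
    # brightness factor models exposure variation, so absolute intensity
    # alone is a weak cue and morphology has to carry class information
    gains = spec.gains(label) * rng.uniform(0.75, 1.15, size=N_STAINS)
    gains *= rng.uniform(*spec.brightness_jitter)
    channels = (
        spec.background
        + gains[:, None, None] * pattern[None, :, :]
        + rng.normal(0.0, spec.noise_sd, size=(N_STAINS, size, size))
    )
    channels = _quantize16(np.clip(channels, 0.0, 1.0))
    return IFCase(
        case_id=case_id,
        channels=channels,
        label=label,
        quality_gt=1,
        deposit_mask=mask,
    ).validate()


def generate_dataset(spec: SynthSpec) -> list[IFCase]:
    """Render ``4 * n_per_class`` sharp cases, balanced over the labels.

    Deterministic: identical spec (including seed) reproduces identical
    pixel values.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cases: list[IFCase] = []
    for label in LABELS:
        for i in range(spec.n_per_class):
            cases.append(generate_case(label, f"{label}_{i:03d}", spec, rng))
    return cases


# ---------------------------------------------------------------------------
# Gaussian degradation


def gaussian_kernel_1d(blur: BlurSpec) -> np.ndarray:
    """Normalized sampled Gaussian, length ``kernel_size`` (sigma=0 -> [1])."""
    blur.validate()
    k = blur.resolved_kernel_size()
    if blur.sigma == 0:
        kernel = np.zeros(k)
        kernel[k // 2] = 1.0
        return kernel
    offsets = np.arange(k) - k // 2
    kernel = np.exp(-(offsets**2) / (2.0 * blur.sigma**2))
    return kernel / kernel.sum()


def gaussian_kernel_2d(blur: BlurSpec) -> np.ndarray:
    k1 = gaussian_kernel_1d(blur)
    return np.outer(k1, k1)


def gaussian_blur(case: IFCase, blur: BlurSpec) -> IFCase:
    """Defocus a case: separable Gaussian convolution, reflect padding.

    The output is clipped to [0, 1] and marked blurred (``quality_gt=0``);
    label and deposit mask are unchanged.
    """
    case.validate()
    blur.validate()
    k1 = gaussian_kernel_1d(blur)
    out = convolve1d(case.channels.astype(np.float64), k1, axis=1, mode="reflect")
    out = convolve1d(out, k1, axis=2, mode="reflect")
    out = np.clip(out, 0.0, 1.0).astype(np.float32)
    return case.with_channels(out, quality_gt=0)


def blur_dataset(
    cases: list[IFCase],
    sigma: float | tuple[float, float] = (1.0, 3.0),
    seed: int = 0,
    kernel_size: int | None = None,
) -> list[IFCase]:
    """Blur every case; ``sigma`` may be fixed or a per-case uniform range."""
    rng = np.random.default_rng(seed)
    blurred = []
    for case in cases:
        s = float(rng.uniform(*sigma)) if isinstance(sigma, tuple) else float(sigma)
        blurred.append(gaussian_blur(case, BlurSpec(sigma=s, kernel_size=kernel_size)))
    return blurred


# ---------------------------------------------------------------------------
# Splitting


def split_dataset(
    cases: list[IFCase],
    ratio: float = 0.8,
    seed: int = 0,
    test_counts: Mapping[str, int] | None = None,
) -> tuple[list[IFCase], list[IFCase]]:
    """Stratified train/test split.

    Per label, the test count is ``round_half_up((1 - ratio) * n_label)``
    unless ``test_counts`` pins it explicitly (historical tabulations do not
    always follow one rounding rule, so exact bookkeeping can be forced).
    """
    if not 0 < ratio < 1:
        raise ValidationError(f"ratio must be in (0, 1), got {ratio}")
    by_label: dict[str, list[IFCase]] = {}
    for case in cases:
        by_label.setdefault(case.label, []).append(case)
    for label, group in by_label.items():
        if len(group) < 2:
            raise ValidationError(
                f"label {label!r} has {len(group)} case(s); need at least 2 to split"
            )
    rng = np.random.default_rng(seed)
    train: list[IFCase] = []
    test: list[IFCase] = []
    for label in sorted(by_label, key=lambda l: LABELS.index(l) if l in LABELS else 99):
        group = by_label[label]
        n = len(group)
        if test_counts is not None:
            n_test = int(test_counts[label])
        else:
            n_test = int(round_half_up((1.0 - ratio) * n))
        n_test = max(1, min(n_test, n - 1))
        order = rng.permutation(n)
        test_idx = set(order[:n_test].tolist())
        for i, case in enumerate(group):
            (test if i in test_idx else train).append(case)
    return train, test
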