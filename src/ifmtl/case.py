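"""Core sample container for multi-stain renal immunofluorescence stacks.

One case is one patient: seven single-channel stain images (IgG, IgA, IgM,
C3, C4, C1q, Fibrinogen) acquired on the same glomerular field, a four-way
disease label, a binary quality ground truth (1 = sharp, 0 = blurred) and —
for synthetic data only — a binary mask of the pixels carrying immune
deposits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Canonical stain channel order. Fixed everywhere in the package.
STAINS: tuple[str, ...] = ("IgG", "IgA", "IgM", "C3", "C4", "C1q", "Fib")

#: Canonical disease label order (index = class index in every report).
LABELS: tuple[str, ...] = ("IgAN", "MN", "DN", "LN")

N_STAINS = len(STAINS)


class ValidationError(ValueError):
    """Raised when a case, spec or config violates its invariants."""


@dataclass
class IFCase:
    """A single patient's 7-channel IF stack.

    Attributes
    ----------
    case_id : str
        Unique identifier.
    channels : ndarray, shape (7, H, W), float32 in [0, 1]
        Stain images in :data:`STAINS` order.
    label : str
        One of :data:`LABELS`.
    quality_gt : int
        1 for sharp (non-blurred), 0 for blurred.
    deposit_mask : ndarray of bool, shape (H, W), optional
        Ground-truth deposit pixels; present for synthetic cases.
    """

    case_id: str
    channels: np.ndarray
    label: str
    quality_gt: int = 1
    deposit_mask: np.ndarray | None = field(default=None, repr=False)

    def validate(self) -> "IFCase":
        ch = np.asarray(self.channels)
        if ch.ndim != 3 or ch.shape[0] != N_STAINS:
            raise ValidationError(
                f"case {self.case_id}: channels must be (7, H, W), got {ch.shape}"
            )
        if not np.all(np.isfinite(ch)):
            raise ValidationError(f"case {self.case_id}: non-finite intensities")
        if ch.min() < 0.0 or ch.max() > 1.0:
            raise ValidationError(
                f"case {self.case_id}: intensities outside [0, 1]"
            )
        if self.label not in LABELS:
            raise ValidationError(
                f"case {self.case_id}: unknown label {self.label!r}"
            )
        if self.quality_gt not in (0, 1):
            raise ValidationError(
                f"case {self.case_id}: quality_gt must be 0 or 1, got {self.quality_gt}"
            )
        if self.deposit_mask is not None and self.deposit_mask.shape != ch.shape[1:]:
            raise ValidationError(
                f"case {self.case_id}: deposit_mask shape {self.deposit_mask.shape} "
                f"does not match image shape {ch.shape[1:]}"
            )
        return self

    @property
    def image_size(self) -> tuple[int, int]:
        return self.channels.shape[1], self.channels.shape[2]

    def with_channels(self, channels: np.ndarray, quality_gt: int | None = None) -> "IFCase":
        """Copy with replaced pixel data (mask and label carried over)."""
        return replace(
            self,
            channels=channels,
            quality_gt=self.quality_gt if quality_gt is None else quality_gt,
        )


def stack_cases(cases: list[IFCase]) -> np.ndarray:
    """Stack cases into a (N, 7, H, W) float32 batch array."""
    if not cases:
        raise ValidationError("empty case list")
    return np.stack([np.asarray(c.channels, dtype=np.float32) for c in cases])


def case_labels(cases: list[IFCase]) -> np.ndarray:
    return np.array([c.label for c in cases])


def label_indices(cases: list[IFCase]) -> np.ndarray:
    lut = {name: i for i, name in enumerate(LABELS)}
    return np.array([lut[c.label] for c in cases], dtype=np.int64)
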