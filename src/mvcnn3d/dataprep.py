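"""From raw nodule slice stacks to standardized multi-view training volumes.

The pipeline per nodule:

1. **slice balancing** — every nodule is represented by exactly 6 axial
   slices: nodules with ``n >= 6`` slices keep slice 1, slice n and the four
   interior slices ``1 + round((n-1) * k / 5)`` (k = 1..4, half-away-from-zero
   rounding); nodules with fewer slices are padded with all-zero slices.
2. **multi-view cropping** — square patches of several side lengths
   (default 40/50/60 px) are cut around the nodule's in-slice center; regions
   falling outside the image are zero-filled.
3. **resizing** — each view's 6-slice stack is resized in-plane to the target
   size (default 50x50) by cubic spline interpolation; no interpolation is
   performed across slices.  The views are stacked on the channel axis.
4. **labeling** — diagnosis codes {0 unknown, 1 benign, 2 primary malignant,
   3 metastatic malignant} at nodule level, falling back to patient level
   when the nodule code is 0, map to 2-class or 3-class labels.
5. **rotation augmentation** — each volume is rotated in-plane about the
   patch center on a fixed angle grid (e.g. every 9 degrees -> 40 copies).

Slice numbers are 1-based in the balancing rule (matching clinical slice
numbering) and converted to 0-based indices at the array boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "DIAG_UNKNOWN",
    "DIAG_BENIGN",
    "DIAG_PRIMARY",
    "DIAG_METASTATIC",
    "BINARY_CLASS_NAMES",
    "TERNARY_CLASS_NAMES",
    "NoduleStack",
    "ViewSpec",
    "VolumeSample",
    "AugmentationPlan",
    "UnlabelableError",
    "select_slices",
    "crop_views",
    "resize_to_target",
    "assign_label",
    "rotate_augment",
    "prepare_stack",
    "build_dataset",
    "samples_to_arrays",
]

DIAG_UNKNOWN, DIAG_BENIGN, DIAG_PRIMARY, DIAG_METASTATIC = 0, 1, 2, 3
VALID_DIAG = {0, 1, 2, 3}
N_SLICES = 6

BINARY_CLASS_NAMES = ("benign", "malignant")
TERNARY_CLASS_NAMES = ("benign", "primary_malignant", "metastatic_malignant")


class UnlabelableError(ValueError):
    """Both nodule- and patient-level diagnosis codes are 0 (unknown)."""


@dataclass
class NoduleStack:
    """Ordered axial CT slices of one nodule plus its metadata."""

    patient_id: str
    nodule_id: str
    slices: list[np.ndarray]
    center: tuple[int, int]  # (row, col), 0-based, shared by all slices
    nodule_diag: int
    patient_diag: int

    def __post_init__(self) -> None:
        if len(self.slices) < 1:
            raise ValueError("a nodule stack needs at least one slice")
        shapes = {s.shape for s in self.slices}
        if len(shapes) != 1 or any(len(sh) != 2 for sh in shapes):
            raise ValueError("all slices must be 2D and share dimensions")
        r, c = self.center
        h, w = self.slices[0].shape
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"center {self.center} outside slice bounds {h}x{w}")
        if self.nodule_diag not in VALID_DIAG or self.patient_diag not in VALID_DIAG:
            raise ValueError("diagnosis codes must be in {0, 1, 2, 3}")

    @property
    def n_slices(self) -> int:
        return len(self.slices)


@dataclass
class ViewSpec:
    """Crop sizes and the standardized volume shape."""

    crop_sizes: tuple[int, ...] = (40, 50, 60)
    target_shape: tuple[int, int, int] = (6, 50, 50)
    n_views: int | None = None

    def __post_init__(self) -> None:
        self.crop_sizes = tuple(self.crop_sizes)
        self.target_shape = tuple(self.target_shape)
        if list(self.crop_sizes) != sorted(self.crop_sizes):
            raise ValueError("crop_sizes must be sorted ascending")
        if self.n_views is None:
            self.n_views = len(self.crop_sizes)
        if self.n_views not in (1, len(self.crop_sizes)):
            raise ValueError("n_views must be 1 or len(crop_sizes)")

    def effective_sizes(self) -> tuple[int, ...]:
        """The crop sizes actually used (the middle one for a single view)."""
        if self.n_views == len(self.crop_sizes):
            return self.crop_sizes
        return (self.crop_sizes[len(self.crop_sizes) // 2],)


@dataclass
class VolumeSample:
    """A standardized (Z, M, N, K) volume with its label and provenance."""

    data: np.ndarray
    label: int
    patient_id: str
    nodule_id: str
    rotation_deg: float = 0.0


@dataclass
class AugmentationPlan:
    """In-plane rotation grid {0, interval, 2*interval, ...} < 360."""

    interval_deg: int
    angles: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.interval_deg <= 0 or 360 % self.interval_deg != 0:
            raise ValueError("360 must be divisible by the rotation interval")
        self.angles = tuple(float(a) for a in range(0, 360, self.interval_deg))

    @property
    def n_angles(self) -> int:
        return len(self.angles)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def select_slices(n: int) -> tuple[list[int], int]:
    """Balanced 6-slice selection for a nodule with ``n`` slices.

    Returns 1-based slice numbers and the count of all-zero padding slices.
    For ``n >= 6`` the selection is {1, n} plus the four interior slices
    ``1 + round((n-1)*k/5)``; e.g. ``n = 10`` gives [1, 3, 5, 6, 8, 10].
    For ``n < 6`` all slices are kept and ``6 - n`` zero slices are appended.
    """
    if n < 1:
        raise ValueError("slice count must be >= 1")
    if n < N_SLICES:
        return list(range(1, n + 1)), N_SLICES - n
    interior = {1 + _round_half_away((n - 1) * k / 5) for k in range(1, 5)}
    indices = sorted({1, n} | interior)
    return indices, 0


def crop_views(
    slice_image: np.ndarray,
    center: tuple[int, int],
    crop_sizes,
) -> list[np.ndarray]:
    """Square crops of each requested size centered on ``center``.

    The center pixel sits at offset ``size // 2`` from the crop's top-left
    corner (rows ``[row - size//2, row + size - size//2 - 1]``), and regions
    extending past the image boundary are zero-filled.
    """
    img = np.asarray(slice_image)
    if img.ndim != 2:
        raise ValueError("slice_image must be 2D")
    h, w = img.shape
    row, col = center
    if not (0 <= row < h and 0 <= col < w):
        raise ValueError(f"center {center} outside image bounds {h}x{w}")
    crops = []
    for size in crop_sizes:
        if size < 1:
            raise ValueError("crop size must be positive")
        out = np.zeros((size, size), dtype=img.dtype)
        r0, c0 = row - size // 2, col - size // 2
        rs, re = max(r0, 0), min(r0 + size, h)
        cs, ce = max(c0, 0), min(c0 + size, w)
        if rs < re and cs < ce:
            out[rs - r0 : re - r0, cs - c0 : ce - c0] = img[rs:re, cs:ce]
        crops.append(out)
    return crops


def resize_to_target(
    crops_per_view: list[list[np.ndarray]],
    target_shape: tuple[int, int, int] = (6, 50, 50),
    order: int = 3,
) -> np.ndarray:
    """Stack per-view crop lists into a (Z, M, N, K) volume.

    ``crops_per_view[v]`` is the list of ``Z`` square crops of view ``v``.
    Each crop is resized in-plane to ``(M, N)`` by spline interpolation of
    the given order (cubic by default); the slice axis is never interpolated.
    A crop already at the target size passes through bit-identically.
    """
    z, m, n = target_shape
    lengths = {len(view) for view in crops_per_view}
    if lengths != {z}:
        raise ValueError(f"every view needs exactly {z} slices, got {sorted(lengths)}")
    out = np.empty((z, m, n, len(crops_per_view)), dtype=np.float32)
    for v, view in enumerate(crops_per_view):
        for i, crop in enumerate(view):
            crop = np.asarray(crop, dtype=np.float32)
            if crop.shape == (m, n):
                out[i, :, :, v] = crop
            else:
                out[i, :, :, v] = ndimage.zoom(
                    crop,
                    (m / crop.shape[0], n / crop.shape[1]),
                    order=order,
                    mode="mirror",
                    grid_mode=False,
                )
    return out


def assign_label(nodule_diag: int, patient_diag: int, task: str = "binary") -> int:
    """Class index from the diagnosis code pair.

    Code 1 is benign; codes 2 and 3 are malignant (ternary: 2 = primary,
    3 = metastatic).  A nodule-level code of 0 defers to the patient-level
    code; if both are 0 the sample is unlabelable and excluded.
    """
    if task not in ("binary", "ternary"):
        raise ValueError("task must be 'binary' or 'ternary'")
    if nodule_diag not in VALID_DIAG or patient_diag not in VALID_DIAG:
        raise ValueError("diagnosis codes must be in {0, 1, 2, 3}")
    code = nodule_diag if nodule_diag != DIAG_UNKNOWN else patient_diag
    if code == DIAG_UNKNOWN:
        raise UnlabelableError("both nodule- and patient-level diagnoses are unknown")
    if code == DIAG_BENIGN:
        return 0
    if task == "binary":
        return 1
    return 1 if code == DIAG_PRIMARY else 2


def _rotate_volume(data: np.ndarray, angle: float) -> np.ndarray:
    """In-plane rotation of a (Z, M, N, K) volume about the patch center.

    Quarter turns are exact array rotations; other angles use bilinear
    interpolation with zero fill.
    """
    angle = float(angle) % 360.0
    if angle == 0.0:
        return data.copy()
    if angle in (90.0, 180.0, 270.0):
        return np.ascontiguousarray(np.rot90(data, int(angle // 90), axes=(1, 2)))
    return ndimage.rotate(
        data, angle, axes=(1, 2), reshape=False, order=1, mode="constant", cval=0.0
    )


def rotate_augment(sample: VolumeSample, plan: AugmentationPlan) -> list[VolumeSample]:
    """One rotated copy of ``sample`` per angle of the plan (angle 0 first).

    The same angle is applied to every slice and view; the copy count is
    ``360 / interval_deg``.
    """
    out = []
    for angle in plan.angles:
        out.append(
            VolumeSample(
                data=_rotate_volume(sample.data, angle),
                label=sample.label,
                patient_id=sample.patient_id,
                nodule_id=sample.nodule_id,
                rotation_deg=angle,
            )
        )
    return out


def prepare_stack(
    stack: NoduleStack,
    view_spec: ViewSpec,
    task: str = "binary",
    normalize: bool = False,
    interp_order: int = 3,
) -> VolumeSample:
    """Slice-balance, crop, resize and label one nodule stack (no rotation)."""
    label = assign_label(stack.nodule_diag, stack.patient_diag, task)
    indices, n_pad = select_slices(stack.n_slices)
    sizes = view_spec.effective_sizes()
    crops_per_view = [[] for _ in sizes]
    for idx in indices:
        crops = crop_views(stack.slices[idx - 1], stack.center, sizes)
        for v, crop in enumerate(crops):
            crops_per_view[v].append(crop)
    for _ in range(n_pad):
        for v, size in enumerate(sizes):
            crops_per_view[v].append(np.zeros((size, size), dtype=np.float32))
    data = resize_to_target(crops_per_view, view_spec.target_shape, order=interp_order)
    if normalize:
        lo, hi = float(data.min()), float(data.max())
        if hi > lo:
            data = (data - lo) / (hi - lo)
    return VolumeSample(
        data=data,
        label=label,
        patient_id=stack.patient_id,
        nodule_id=stack.nodule_id,
    )


def build_dataset(
    stacks,
    view_spec: ViewSpec | None = None,
    task: str = "binary",
    augmentation: dict[int, AugmentationPlan] | AugmentationPlan | None = None,
    normalize: bool = False,
) -> list[VolumeSample]:
    """Standardized, labeled, rotation-augmented samples for a stack list.

    ``augmentation`` maps class index -> rotation plan (or one plan for all
    classes; ``None`` disables augmentation).  Output size is the sum over
    classes of ``n_lesions * 360 / interval``; the procedure is deterministic
    and every sample keeps its source patient id.
    """
    view_spec = view_spec or ViewSpec()
    samples: list[VolumeSample] = []
    for stack in stacks:
        base = prepare_stack(stack, view_spec, task, normalize=normalize)
        plan = (
            augmentation.get(base.label)
            if isinstance(augmentation, dict)
            else augmentation
        )
        if plan is None:
            samples.append(base)
        else:
            samples.extend(rotate_augment(base, plan))
    return samples


def samples_to_arrays(samples) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(X, y, patient_ids) arrays for training code."""
    x = np.stack([s.data for s in samples]).astype(np.float32)
    y = np.array([s.label for s in samples], dtype=np.int64)
    pid = np.array([s.patient_id for s in samples])
    return x, y, pid
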