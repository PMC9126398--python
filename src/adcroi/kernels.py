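"""2D ROI kernel footprints for sliding-window ADC measurement.

A kernel is the set of integer (row, col) pixel offsets, relative to an
anchor pixel at (0, 0), over which the ADC mean is taken.  Two families are
provided:

* **square** kernels of odd side length (1x1, 3x3, 5x5, 7x7), and
* **near-circular** kernels of an arbitrary pixel count *n*, defined as the
  *n* offsets closest to the origin in Euclidean distance, ties broken by
  ascending ``(distance, row, col)``.

The near-circular family is nested by construction: the kernel of n pixels
is always a strict subset of the kernel of n' > n pixels.  The study size
set is {1, 2, 3, 5, 9, 17, 25, 33, 49}; sizes with an odd integer square
root (1, 9, 25, 49) map to square kernels, the rest to near-circular ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: ROI pixel counts used by the reference computation, ascending.
STUDY_SIZES: tuple[int, ...] = (1, 2, 3, 5, 9, 17, 25, 33, 49)

#: Sizes realised as square kernels (odd side lengths 1, 3, 5, 7).
SQUARE_SIZES: frozenset[int] = frozenset({1, 9, 25, 49})


@dataclass(frozen=True)
class KernelMask:
    """An ROI footprint: ``n_pixels`` offsets around the (0, 0) anchor.

    Attributes
    ----------
    n_pixels : int
        Number of pixels in the footprint.
    offsets : tuple of (int, int)
        Sorted ``(row, col)`` offsets relative to the anchor; always
        contains ``(0, 0)``.
    shape_tag : str
        ``"square"`` or ``"near_circular"``.
    """

    n_pixels: int
    offsets: tuple[tuple[int, int], ...]
    shape_tag: str = field(default="near_circular")

    def __post_init__(self) -> None:
        if len(self.offsets) != self.n_pixels:
            raise ValueError(
                f"kernel has {len(self.offsets)} offsets but n_pixels={self.n_pixels}"
            )
        if (0, 0) not in self.offsets:
            raise ValueError("kernel must contain the anchor offset (0, 0)")

    @property
    def radius(self) -> int:
        """Largest absolute row/col offset (padding margin for sliding)."""
        return max(max(abs(r), abs(c)) for r, c in self.offsets)

    def __len__(self) -> int:
        return self.n_pixels


def make_square_kernel(side: int) -> KernelMask:
    """Square ``side x side`` kernel centred on the anchor.

    Parameters
    ----------
    side : odd positive int
        Side length in pixels; the study uses 1, 3, 5 and 7.
    """
    if not isinstance(side, (int,)) or side < 1 or side % 2 == 0:
        raise ValueError(f"side must be an odd positive integer, got {side!r}")
    half = (side - 1) // 2
    offsets = tuple(
        (dr, dc) for dr in range(-half, half + 1) for dc in range(-half, half + 1)
    )
    return KernelMask(n_pixels=side * side, offsets=offsets, shape_tag="square")


def make_near_circular_kernel(n_pixels: int) -> KernelMask:
    """Near-circular kernel: the ``n_pixels`` offsets nearest the origin.

    Ties in Euclidean distance are broken by ascending ``(row, col)``, which
    makes construction deterministic and the family nested across sizes.
    """
    if not isinstance(n_pixels, int) or n_pixels < 1:
        raise ValueError(f"n_pixels must be a positive integer, got {n_pixels!r}")
    # Candidate window large enough to contain the n nearest offsets: a disk
    # of n pixels has radius ~ sqrt(n/pi); +2 gives a safe margin.
    r = int(math.isqrt(n_pixels)) + 2
    candidates = [
        (dr * dr + dc * dc, dr, dc)
        for dr in range(-r, r + 1)
        for dc in range(-r, r + 1)
    ]
    candidates.sort()
    offsets = tuple((dr, dc) for _, dr, dc in candidates[:n_pixels])
    return KernelMask(n_pixels=n_pixels, offsets=offsets, shape_tag="near_circular")


def kernel_for_size(
    n_pixels: int,
    shape_policy: str = "study",
    allow_any: bool = False,
) -> KernelMask:
    """Kernel for one of the study ROI sizes.

    Parameters
    ----------
    n_pixels : int
        Pixel count; must be in :data:`STUDY_SIZES` unless ``allow_any``.
    shape_policy : {"study", "all_near_circular"}
        ``"study"`` (the measurement-protocol mix) uses square kernels for sizes with an odd-integer square
        root (1, 9, 25, 49) and near-circular kernels otherwise;
        ``"all_near_circular"`` uses the near-circular family throughout.
    allow_any : bool
        Permit sizes outside the study set (always near-circular unless the
        size is a perfect odd square and the policy is ``"study"``).
    """
    if shape_policy not in ("study", "all_near_circular"):
        raise ValueError(f"unknown shape_policy {shape_policy!r}")
    if not isinstance(n_pixels, int) or n_pixels < 1:
        raise ValueError(f"n_pixels must be a positive integer, got {n_pixels!r}")
    if not allow_any and n_pixels not in STUDY_SIZES:
        raise ValueError(
            f"n_pixels={n_pixels} not in the study size set {STUDY_SIZES}; "
            "pass allow_any=True to override"
        )
    if shape_policy == "study":
        side = math.isqrt(n_pixels)
        if side * side == n_pixels and side % 2 == 1:
            return make_square_kernel(side)
    return make_near_circular_kernel(n_pixels)


def roi_area_mm2(n_pixels: int, pixel_spacing: float) -> float:
    """ROI area in mm^2 for a pixel count at a given in-plane spacing."""
    if not isinstance(n_pixels, int) or n_pixels < 1:
        raise ValueError(f"n_pixels must be a positive integer, got {n_pixels!r}")
    if pixel_spacing <= 0:
        raise ValueError(f"pixel_spacing must be > 0, got {pixel_spacing!r}")
    return n_pixels * pixel_spacing**2


def pixels_for_area(area_mm2: float, pixel_spacing: float) -> int:
    """Nearest pixel count for an ROI of ``area_mm2`` at ``pixel_spacing``."""
    if area_mm2 <= 0:
        raise ValueError(f"area_mm2 must be > 0, got {area_mm2!r}")
    if pixel_spacing <= 0:
        raise ValueError(f"pixel_spacing must be > 0, got {pixel_spacing!r}")
    return max(1, round(area_mm2 / pixel_spacing**2))
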