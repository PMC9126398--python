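"""Computer-calculated lesion reference ADC values.

Implements the reference measurements against which human readers are
judged:

* :func:`min_mean_adc` — slide a 2D ROI kernel over every slice of a 3D
  lesion mask, keeping only placements whose footprint lies wholly inside
  the mask, and return the minimum kernel-mean ADC with its location.
* :func:`multi_size_reference` — the minimum-mean series across ROI sizes,
  with the fallback rule: a size whose kernel fits nowhere inherits the
  next smaller size's value.
* :func:`percentile_adc` / :func:`median_pz_adc` — whole-lesion histogram
  percentile (10th percentile by convention) and the median ADC of the
  peripheral-zone parenchyma.

All ADC values are in 1e-6 mm^2/s.  Coordinates are 0-based
(slice, row, col).  Ties among equal-minimum placements resolve to the
first anchor in (slice, row, col) scan order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import KernelMask, kernel_for_size


@dataclass(frozen=True)
class ADCVolume:
    """A 3D ADC map in 1e-6 mm^2/s, indexed (slice, row, col)."""

    values: np.ndarray
    pixel_spacing: float = 1.0
    slice_thickness: float = 4.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError(f"ADC volume must be 3D, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("ADC volume contains non-finite values")
        if np.any(v < 0):
            raise ValueError("ADC values must be >= 0")
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("pixel spacing and slice thickness must be > 0")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return self.pixel_spacing**2 * self.slice_thickness


@dataclass(frozen=True)
class LesionMask3D:
    """Boolean voxel membership grid congruent with an :class:`ADCVolume`."""

    voxels: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.voxels)
        if m.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {m.shape}")
        if m.dtype != bool:
            uniq = np.unique(m)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(f"mask values must be 0/1, found {uniq}")
            m = m.astype(bool)
        if not m.any():
            raise ValueError("mask is empty")
        object.__setattr__(self, "voxels", m)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass(frozen=True)
class ReferenceValue:
    """Minimum sliding-kernel mean for one lesion and one ROI size.

    ``effective_size`` differs from ``requested_size`` when the fallback
    rule substituted a smaller kernel's value; ``anchor`` is the 0-based
    (slice, row, col) of the winning placement.
    """

    requested_size: int
    effective_size: int
    value: float
    anchor: tuple[int, int, int]
    n_placements: int

    def __post_init__(self) -> None:
        if self.effective_size > self.requested_size:
            raise ValueError("effective_size cannot exceed requested_size")
        if self.n_placements < 1:
            raise ValueError("a ReferenceValue requires >= 1 placement")


class NoFit:
    """Sentinel: no placement of the kernel fits inside the mask."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "NoFit"

    def __bool__(self) -> bool:
        return False


NO_FIT = NoFit()


def _check_congruent(volume: ADCVolume, mask: LesionMask3D) -> None:
    if volume.shape != mask.shape:
        raise ValueError(
            f"volume shape {volume.shape} != mask shape {mask.shape}"
        )


def _sliding_stats(
    values: np.ndarray, mask: np.ndarray, kernel: KernelMask
) -> tuple[np.ndarray, np.ndarray]:
    """Kernel sums and footprint-containment counts at every anchor.

    Operates on a full 3D stack at once; offsets act in-plane only.
    Returns (sums, counts) with the volume's shape; an anchor is a valid
    placement iff counts == kernel.n_pixels.
    """
    s, r, c = values.shape
    m = kernel.radius
    pv = np.zeros((s, r + 2 * m, c + 2 * m))
    pm = np.zeros((s, r + 2 * m, c + 2 * m), dtype=np.int32)
    pv[:, m : m + r, m : m + c] = values * mask
    pm[:, m : m + r, m : m + c] = mask
    sums = np.zeros_like(values, dtype=float)
    counts = np.zeros(values.shape, dtype=np.int32)
    for dr, dc in kernel.offsets:
        sums += pv[:, m + dr : m + dr + r, m + dc : m + dc + c]
        counts += pm[:, m + dr : m + dr + r, m + dc : m + dc + c]
    return sums, counts


def valid_placements(mask_slice: np.ndarray, kernel: KernelMask) -> set[tuple[int, int]]:
    """Anchors whose full kernel footprint lies inside a 2D mask slice.

    An anchor ``a`` is valid iff for every offset ``o`` in the kernel,
    ``a + o`` is inside the grid and ``mask_slice[a + o]`` is true.
    An empty mask slice yields the empty set.
    """
    m2 = np.asarray(mask_slice)
    if m2.ndim != 2:
        raise ValueError(f"mask slice must be 2D, got shape {m2.shape}")
    m2 = m2.astype(bool)
    _, counts = _sliding_stats(
        np.zeros((1,) + m2.shape), m2[None, :, :], kernel
    )
    rows, cols = np.nonzero(counts[0] == kernel.n_pixels)
    return {(int(r), int(c)) for r, c in zip(rows, cols)}


def min_mean_adc(
    volume: ADCVolume, mask: LesionMask3D, kernel: KernelMask
) -> ReferenceValue | NoFit:
    """Minimum kernel-mean ADC over all valid placements on all slices.

    Placements are evaluated independently on every slice of the 3D mask
    (in-plane kernels only).  Returns :data:`NO_FIT` when no placement
    exists anywhere; ties resolve to the first anchor in scan order.
    """
    _check_congruent(volume, mask)
    sums, counts = _sliding_stats(volume.values, mask.voxels, kernel)
    valid = counts == kernel.n_pixels
    n_placements = int(valid.sum())
    if n_placements == 0:
        return NO_FIT
    means = np.where(valid, sums / kernel.n_pixels, np.inf)
    flat_idx = int(np.argmin(means))  # first minimum in (slice,row,col) order
    anchor = np.unravel_index(flat_idx, means.shape)
    # Recompute the winning mean directly from the footprint so the reported
    # value is exactly the mean of the covered voxels (no accumulated
    # shifted-sum rounding).
    s0, r0, c0 = (int(a) for a in anchor)
    footprint = volume.values[
        s0,
        [r0 + dr for dr, _ in kernel.offsets],
        [c0 + dc for _, dc in kernel.offsets],
    ]
    return ReferenceValue(
        requested_size=kernel.n_pixels,
        effective_size=kernel.n_pixels,
        value=float(footprint.mean()),
        anchor=(s0, r0, c0),
        n_placements=n_placements,
    )


def multi_size_reference(
    volume: ADCVolume,
    mask: LesionMask3D,
    sizes: tuple[int, ...] | list[int] = None,
    shape_policy: str = "study",
    allow_any: bool = False,
) -> dict[int, ReferenceValue]:
    """Minimum-mean reference value for each ROI size, with fallback.

    Sizes must be ascending and include 1, which guarantees a base case for
    any nonempty mask.  When a size has no valid placement, the next
    smaller size's result is carried forward with ``requested_size``
    recording the requested size and ``effective_size`` the one actually
    measured (applied recursively down the size ladder).
    """
    from .kernels import STUDY_SIZES

    if sizes is None:
        sizes = STUDY_SIZES
    sizes = tuple(int(s) for s in sizes)
    if list(sizes) != sorted(set(sizes)):
        raise ValueError(f"sizes must be ascending and unique, got {sizes}")
    if sizes[0] != 1:
        raise ValueError("size 1 must be included as the fallback base case")
    _check_congruent(volume, mask)

    out: dict[int, ReferenceValue] = {}
    prev: ReferenceValue | None = None
    for n in sizes:
        kernel = kernel_for_size(n, shape_policy=shape_policy, allow_any=allow_any)
        res = min_mean_adc(volume, mask, kernel)
        if isinstance(res, NoFit):
            assert prev is not None  # size 1 always fits a nonempty mask
            res = ReferenceValue(
                requested_size=n,
                effective_size=prev.effective_size,
                value=prev.value,
                anchor=prev.anchor,
                n_placements=prev.n_placements,
            )
        out[n] = res
        prev = res
    return out


def percentile_adc(
    volume: ADCVolume,
    mask: LesionMask3D,
    q: float,
    method: str = "linear",
) -> float:
    """q-th percentile of the masked voxel ADC histogram.

    ``method`` selects the order-statistic convention ("linear" — linear
    interpolation, the default — or "lower" / "nearest").
    """
    _check_congruent(volume, mask)
    if not 0 <= q <= 100:
        raise ValueError(f"percentile q must be in [0, 100], got {q}")
    if method not in ("linear", "lower", "nearest"):
        raise ValueError(f"unknown percentile method {method!r}")
    vals = volume.values[mask.voxels]
    return float(np.percentile(vals, q, method=method))


def median_pz_adc(volume: ADCVolume, pz_mask: LesionMask3D, method: str = "linear") -> float:
    """Median ADC of the peripheral-zone parenchyma mask."""
    return percentile_adc(volume, pz_mask, 50.0, method=method)
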