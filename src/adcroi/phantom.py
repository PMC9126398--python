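"""Synthetic ADC phantoms with known ground truth.

The phantom emulates the structure the lesion analysis assumes: a
higher-ADC parenchyma background (smooth Gaussian field around ~1400
1e-6 mm^2/s), an ellipsoidal lesion of intermediate ADC (~900)
containing a small low-ADC focus (~600) standing in for a sparse
high-grade tumor component, plus i.i.d. Gaussian voxel noise.  A
peripheral-zone (PZ) parenchyma mask is emitted as an ellipsoidal shell
around the lesion.

Ground-truth reference values are computed at generation time by an
exhaustive brute-force search (independent of the optimized sliding-window
path) so recovery tests have an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .kernels import STUDY_SIZES, KernelMask, kernel_for_size
from .reference import ADCVolume, LesionMask3D, ReferenceValue, NO_FIT, NoFit


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and intensity parameters of one synthetic lesion volume.

    All ADC parameters are in 1e-6 mm^2/s; centers and radii are in voxel
    units as (slice, row, col).  ``background_sd`` is the SD of the smooth
    parenchyma field; ``noise_sd`` the i.i.d. voxel noise SD.
    """

    shape: tuple[int, int, int] = (10, 64, 64)
    pixel_spacing: float = 1.0
    slice_thickness: float = 4.0
    background_mean: float = 1400.0
    background_sd: float = 100.0
    background_smoothness: float = 4.0
    lesion_center: tuple[float, float, float] = (5.0, 32.0, 32.0)
    lesion_radii: tuple[float, float, float] = (2.5, 9.0, 9.0)
    lesion_adc: float = 900.0
    lesion_texture_sd: float = 120.0
    texture_smoothness: float = 2.5
    focus_center: tuple[float, float, float] = (5.0, 32.0, 32.0)
    focus_radius: float = 2.5
    focus_adc: float = 600.0
    boundary_smooth_sigma: float = 1.2
    pz_scale: float = 2.2
    noise_sd: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.focus_adc < self.lesion_adc < self.background_mean):
            raise ValueError(
                "require focus_adc < lesion_adc < background_mean, got "
                f"{self.focus_adc}, {self.lesion_adc}, {self.background_mean}"
            )
        if self.noise_sd < 0 or self.background_sd < 0 or self.lesion_texture_sd < 0:
            raise ValueError("noise/background/texture SDs must be >= 0")
        if min(self.lesion_radii) <= 0 or self.focus_radius <= 0:
            raise ValueError("radii must be > 0")
        # Focus sphere must sit inside the lesion ellipsoid: the scaled
        # center displacement plus the scaled radius must stay within 1.
        d = np.array(self.focus_center) - np.array(self.lesion_center)
        rad = np.array(self.lesion_radii, dtype=float)
        margin = np.sqrt(np.sum((d / rad) ** 2)) + self.focus_radius / rad.min()
        if margin > 1.0 + 1e-9:
            raise ValueError("focus sphere extends outside the lesion ellipsoid")


@dataclass(frozen=True)
class PhantomTruth:
    """A generated phantom and its analytically known reference values."""

    config: PhantomConfig
    volume: ADCVolume
    lesion: LesionMask3D
    pz: LesionMask3D
    truth: dict[int, float] = field(default_factory=dict)


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    center: tuple[float, float, float],
    radii: tuple[float, float, float],
) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    d = (
        ((zz - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((xx - center[2]) / radii[2]) ** 2
    )
    return d <= 1.0


def brute_force_min_mean(
    values: np.ndarray, mask: np.ndarray, kernel: KernelMask
) -> tuple[float, tuple[int, int, int]] | NoFit:
    """Exhaustive minimum kernel-mean search (the test oracle).

    Loops over every anchor on every slice, checks full footprint
    containment in the mask, and tracks the minimum mean.  First anchor in
    (slice, row, col) order wins ties.  Independent of the optimized
    sliding-window implementation by construction.
    """
    n_s, n_r, n_c = values.shape
    offs = np.array(kernel.offsets)
    best: tuple[float, tuple[int, int, int]] | None = None
    for s in range(n_s):
        sl_mask = mask[s]
        if not sl_mask.any():
            continue
        # The anchor itself must be in the mask ((0,0) is in every kernel),
        # so only mask pixels are candidate anchors.
        for r, c in zip(*np.nonzero(sl_mask)):
            rr = offs[:, 0] + r
            cc = offs[:, 1] + c
            if rr.min() < 0 or cc.min() < 0 or rr.max() >= n_r or cc.max() >= n_c:
                continue
            if not sl_mask[rr, cc].all():
                continue
            m = float(values[s][rr, cc].mean())
            if best is None or m < best[0]:
                best = (m, (s, int(r), int(c)))
    return NO_FIT if best is None else best


def brute_force_reference_map(
    values: np.ndarray,
    mask: np.ndarray,
    sizes: tuple[int, ...] = STUDY_SIZES,
) -> dict[int, float]:
    """Brute-force minimum-mean per size with the fallback rule applied."""
    out: dict[int, float] = {}
    prev: float | None = None
    for n in sizes:
        res = brute_force_min_mean(values, mask, kernel_for_size(n))
        if isinstance(res, NoFit):
            assert prev is not None, "size 1 must fit a nonempty mask"
            out[n] = prev
        else:
            out[n] = res[0]
        prev = out[n]
    return out


def generate_phantom(config: PhantomConfig, compute_truth: bool = True) -> PhantomTruth:
    """Generate one phantom volume, its masks and (optionally) its truth map.

    The volume is a smooth background field with the lesion and focus
    painted as level sets, plus i.i.d. Gaussian noise, clipped at zero.
    Identical (config, seed) pairs produce bit-identical volumes.
    """
    rng = np.random.default_rng(config.seed)
    smooth = ndimage.gaussian_filter(
        rng.standard_normal(config.shape), sigma=config.background_smoothness
    )
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd * config.background_sd
    vol = config.background_mean + smooth

    lesion = _ellipsoid_mask(config.shape, config.lesion_center, config.lesion_radii)
    if not lesion.any():
        raise ValueError("lesion ellipsoid contains no voxels on this grid")
    focus = _ellipsoid_mask(
        config.shape, config.focus_center, (config.focus_radius,) * 3
    )
    vol[lesion] = config.lesion_adc
    if config.lesion_texture_sd > 0:
        # Smooth intra-lesion heterogeneity: low-grade tumor tissue is not
        # uniform, and whole-lesion percentiles inherit that structure.
        texture = ndimage.gaussian_filter(
            rng.standard_normal(config.shape), sigma=config.texture_smoothness
        )
        tsd = texture.std()
        if tsd > 0:
            vol[lesion] += texture[lesion] / tsd * config.lesion_texture_sd
    vol[focus] = config.focus_adc
    if config.boundary_smooth_sigma > 0:
        # Partial-volume blur: lesion boundaries in real ADC maps grade
        # into parenchyma over a few voxels (strongest through-slice, where
        # voxels are thickest), which is what makes whole-lesion
        # percentiles sensitive to exactly where a contour is drawn.
        s = config.boundary_smooth_sigma
        vol = ndimage.gaussian_filter(vol, sigma=(s, 0.5 * s, 0.5 * s))
    if config.noise_sd > 0:
        vol = vol + rng.normal(0.0, config.noise_sd, size=config.shape)
    vol = np.clip(vol, 0.0, None)

    pz_radii = tuple(r * config.pz_scale for r in config.lesion_radii)
    pz = _ellipsoid_mask(config.shape, config.lesion_center, pz_radii) & ~lesion
    if not pz.any():  # degenerate geometry: fall back to everything outside
        pz = ~lesion

    truth: dict[int, float] = {}
    if compute_truth:
        truth = brute_force_reference_map(vol, lesion)

    return PhantomTruth(
        config=config,
        volume=ADCVolume(
            values=vol,
            pixel_spacing=config.pixel_spacing,
            slice_thickness=config.slice_thickness,
        ),
        lesion=LesionMask3D(voxels=lesion),
        pz=LesionMask3D(voxels=pz),
        truth=truth,
    )


def random_lesion_config(rng: np.random.Generator, seed: int) -> PhantomConfig:
    """Draw a lesion phantom configuration with realistic case-to-case
    heterogeneity in size, ADC level and focus conspicuity."""
    base = PhantomConfig()
    lesion_adc = float(np.clip(rng.normal(900.0, 150.0), 650.0, 1200.0))
    focus_adc = float(
        np.clip(lesion_adc - rng.normal(290.0, 80.0), 300.0, lesion_adc - 120.0)
    )
    radii = (
        float(rng.uniform(1.8, 3.2)),
        float(rng.uniform(7.0, 12.0)),
        float(rng.uniform(7.0, 12.0)),
    )
    # Focus sphere sized to the smallest lesion semi-axis so it always
    # fits, then placed off-center within the remaining margin.
    rad = np.array(radii)
    focus_radius = float(rad.min() * rng.uniform(0.30, 0.55))
    max_frac = 0.95 - focus_radius / rad.min()
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    frac = direction * rng.uniform(0.0, max_frac)
    center = np.array(base.lesion_center)
    focus_center = tuple(float(v) for v in center + frac * rad)
    return replace(
        base,
        lesion_center=tuple(float(v) for v in center),
        lesion_radii=radii,
        lesion_adc=lesion_adc,
        focus_center=focus_center,
        focus_radius=focus_radius,
        focus_adc=focus_adc,
        background_mean=float(max(lesion_adc + 150.0, rng.normal(1400.0, 100.0))),
        lesion_texture_sd=float(rng.uniform(80.0, 160.0)),
        seed=seed,
    )
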