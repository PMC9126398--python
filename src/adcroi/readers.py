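"""Virtual readers: simulate the three measurement sessions.

Each simulated radiologist carries a behavioural profile:

* a log-normal distribution of habitual free-ROI areas (session 1) —
  real readers ranged from ~7.5 to ~103 mm^2 on average;
* Gaussian placement jitter (in pixels) around the true lowest-ADC
  location, separately for the free session and the instructed 9-pixel
  session (readers are more careful when told what to look for);
* a contour-perturbation scale for the 3D whole-lesion session, realised
  as a random morphological dilation/erosion of the true lesion mask.

Sessions:

1. free 2D small-ROI — reader-specific size, jittered placement; the ROI
   is centred on a mask pixel but may extend beyond the lesion boundary,
   which is exactly how oversized clinical ROIs dilute the low-ADC focus;
2. 9-pixel 2D small-ROI covering the lowest ADC area — fixed kernel,
   jittered anchor snapped to the nearest fully-contained placement;
3. 10th percentile of a 3D whole-lesion ROI drawn by the reader —
   percentile of the morphologically perturbed mask.

:func:`run_virtual_study` assembles the complete-block measurement table
plus the computer reference values, ready for the agreement analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .kernels import kernel_for_size, make_near_circular_kernel, pixels_for_area
from .phantom import PhantomConfig, PhantomTruth, generate_phantom, random_lesion_config
from .reference import (
    LesionMask3D,
    NoFit,
    ReferenceValue,
    min_mean_adc,
    percentile_adc,
)


#: Bound (voxels) on the signed contour dilation/erosion radius; draws are
#: soft-capped with a tanh so extreme contouring errors saturate.
CONTOUR_RADIUS_CAP = 3.5


@dataclass(frozen=True)
class ReaderProfile:
    """Behavioural parameters of one virtual radiologist.

    ``area_median_mm2``/``area_log_sigma`` parameterise the log-normal
    free-ROI area; jitter SDs are in pixels; ``contour_sd`` is the SD (in
    voxels) of the signed dilation/erosion radius applied to the lesion
    contour in session 3.
    """

    name: str
    area_median_mm2: float = 10.0
    area_log_sigma: float = 0.55
    jitter_sd_s1: float = 1.5
    jitter_sd_s2: float = 0.8
    contour_sd: float = 1.0
    contour_bias: float = 0.0
    shift_sd_s3: float = 1.0

    def __post_init__(self) -> None:
        if self.area_median_mm2 <= 0 or self.area_log_sigma <= 0:
            raise ValueError("area distribution scales must be > 0")
        if min(self.jitter_sd_s1, self.jitter_sd_s2, self.contour_sd, self.shift_sd_s3) < 0:
            raise ValueError("jitter, contour and shift SDs must be >= 0")


def default_reader_profiles() -> list[ReaderProfile]:
    """Ten profiles spanning the observed behavioural range.

    Free-ROI median areas span ~7.5-103 mm^2 (one reader habitually uses
    very large ROIs); jitter and contour scales vary from meticulous to
    hasty so the simulated ICC spread covers a wide band.
    """
    areas = [13.2, 7.5, 12.6, 10.5, 8.4, 103.0, 11.9, 23.3, 15.8, 24.2]
    j1 = [2.7, 2.1, 1.2, 1.5, 1.4, 3.9, 1.4, 3.3, 2.1, 2.2]
    j2 = [2.4, 2.0, 1.1, 1.8, 1.1, 2.4, 1.1, 2.0, 1.1, 1.6]
    c3 = [3.8, 2.5, 1.8, 2.3, 2.3, 3.8, 1.6, 3.1, 2.3, 2.3]
    cb = [1.4, 0.3, -0.7, -0.7, 0.0, 2.4, -0.3, 0.3, 1.0, 0.0]
    s3 = [1.8, 1.2, 0.9, 1.0, 1.0, 1.8, 0.8, 1.4, 1.0, 1.0]
    return [
        ReaderProfile(
            name=f"reader_{i + 1:02d}",
            area_median_mm2=areas[i],
            jitter_sd_s1=j1[i],
            jitter_sd_s2=j2[i],
            contour_sd=c3[i],
            contour_bias=cb[i],
            shift_sd_s3=s3[i],
        )
        for i in range(10)
    ]


def _nearest_mask_pixel(
    mask_slice: np.ndarray, row: int, col: int
) -> tuple[int, int]:
    """Closest true pixel to (row, col) on a 2D mask slice."""
    if mask_slice[row, col]:
        return row, col
    rows, cols = np.nonzero(mask_slice)
    d2 = (rows - row) ** 2 + (cols - col) ** 2
    i = int(np.argmin(d2))
    return int(rows[i]), int(cols[i])


def _snap_to_valid(
    valid: np.ndarray, slice_idx: int, row: int, col: int
) -> tuple[int, int, int]:
    """Snap a jittered anchor to the nearest valid placement.

    Preference order: same slice, then any slice (penalising slice moves
    heavily so the reader stays on their chosen image)."""
    ss, rr, cc = np.nonzero(valid)
    d2 = (rr - row) ** 2 + (cc - col) ** 2 + 10_000 * (ss - slice_idx) ** 2
    i = int(np.argmin(d2))
    return int(ss[i]), int(rr[i]), int(cc[i])


def _clipped_kernel_mean(
    values: np.ndarray, slice_idx: int, row: int, col: int, kernel
) -> float:
    """Kernel mean at an anchor, footprint clipped to the grid bounds."""
    n_r, n_c = values.shape[1:]
    offs = np.array(kernel.offsets)
    rr = offs[:, 0] + row
    cc = offs[:, 1] + col
    keep = (rr >= 0) & (rr < n_r) & (cc >= 0) & (cc < n_c)
    return float(values[slice_idx][rr[keep], cc[keep]].mean())


def _translate_field(field: np.ndarray, dr: int, dc: int, fill: float) -> np.ndarray:
    """Shift a 3D scalar field in-plane by integer (dr, dc), edge-filling."""
    if dr == 0 and dc == 0:
        return field
    out = np.full_like(field, fill)
    n_r, n_c = field.shape[1:]
    r_src = slice(max(0, -dr), min(n_r, n_r - dr))
    c_src = slice(max(0, -dc), min(n_c, n_c - dc))
    r_dst = slice(max(0, dr), min(n_r, n_r + dr))
    c_dst = slice(max(0, dc), min(n_c, n_c + dc))
    out[:, r_dst, c_dst] = field[:, r_src, c_src]
    return out


def _translate_mask(mask: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Shift a 3D mask in-plane by integer (dr, dc), zero-filling edges."""
    if dr == 0 and dc == 0:
        return mask
    out = np.zeros_like(mask)
    n_r, n_c = mask.shape[1:]
    r_src = slice(max(0, -dr), min(n_r, n_r - dr))
    c_src = slice(max(0, -dc), min(n_c, n_c - dc))
    r_dst = slice(max(0, dr), min(n_r, n_r + dr))
    c_dst = slice(max(0, dc), min(n_c, n_c + dc))
    out[:, r_dst, c_dst] = mask[:, r_src, c_src]
    return out if out.any() else mask


def _perturb_mask(
    mask: np.ndarray,
    radius: float,
    dr: int = 0,
    dc: int = 0,
    slice_weight: float = 1.0,
) -> np.ndarray:
    """Reader contour error: in-plane translation plus a continuous
    signed-distance dilation (radius > 0) or erosion (radius < 0).

    The perturbed contour is the level set ``signed_distance <= radius`` of
    the translated mask, so every nonzero radius yields a distinct contour
    (no integer-step degeneracy).  ``slice_weight`` makes through-slice
    steps cost more than in-plane steps, mirroring the anisotropic voxels;
    over-inclusion of adjacent slices is what drives the several-fold
    spread in contoured volumes between readers.  An erosion that would
    empty the mask falls back to the unperturbed contour.
    """
    out = _translate_mask(mask, dr, dc)
    if radius == 0:
        return out
    sampling = (slice_weight, 1.0, 1.0)
    signed = ndimage.distance_transform_edt(~out, sampling=sampling) - \
        ndimage.distance_transform_edt(out, sampling=sampling)
    perturbed = signed <= radius
    return perturbed if perturbed.any() else out


class _MinAnchorCache:
    """Per-lesion cache of minimum-mean anchors, placement maps and the
    signed distance field (shared by all readers measuring the lesion)."""

    def __init__(self, truth: PhantomTruth) -> None:
        self.truth = truth
        self._cache: dict[int, ReferenceValue | NoFit] = {}
        self._valid9: np.ndarray | None = None
        self._signed_edt: np.ndarray | None = None

    def valid_placements_9px(self) -> np.ndarray:
        if self._valid9 is None:
            from .reference import _sliding_stats

            kernel = kernel_for_size(9)
            _, counts = _sliding_stats(
                self.truth.volume.values, self.truth.lesion.voxels, kernel
            )
            self._valid9 = counts == 9
        return self._valid9

    def signed_edt(self, slice_weight: float = 1.0) -> np.ndarray:
        """Signed Euclidean distance to the lesion contour (negative
        inside).  Translation-equivariant, so shifted contours reuse it."""
        if self._signed_edt is None:
            mask = self.truth.lesion.voxels
            sampling = (slice_weight, 1.0, 1.0)
            self._signed_edt = ndimage.distance_transform_edt(
                ~mask, sampling=sampling
            ) - ndimage.distance_transform_edt(mask, sampling=sampling)
        return self._signed_edt

    def get(self, n_pixels: int) -> ReferenceValue | NoFit:
        if n_pixels not in self._cache:
            kernel = kernel_for_size(n_pixels, allow_any=True)
            self._cache[n_pixels] = min_mean_adc(
                self.truth.volume, self.truth.lesion, kernel
            )
        return self._cache[n_pixels]

    def target_anchor(self, n_pixels: int) -> tuple[int, int, int]:
        """Anchor of the lowest-mean placement, falling back to smaller
        kernels (ultimately the single lowest voxel) when none fits."""
        n = n_pixels
        while n >= 1:
            res = self.get(n)
            if not isinstance(res, NoFit):
                return res.anchor
            n = max(1, n // 2) if n > 1 else 0
        raise RuntimeError("unreachable: 1-pixel kernel always fits")


def simulate_reader_session(
    truth: PhantomTruth,
    profile: ReaderProfile,
    session: int,
    rng: np.random.Generator,
    cache: _MinAnchorCache | None = None,
) -> dict:
    """One reader's measurement of one lesion in one session.

    Returns a measurement-table row dict.  With zero jitter (sessions 1-2)
    or zero contour perturbation (session 3) the measurement equals the
    corresponding computed reference exactly.
    """
    if session not in (1, 2, 3):
        raise ValueError(f"unknown session {session!r}")
    if cache is None:
        cache = _MinAnchorCache(truth)
    vol = truth.volume
    spacing = vol.pixel_spacing
    row: dict = {"session": session}

    if session in (1, 2):
        if session == 1:
            area = profile.area_median_mm2 * float(
                np.exp(rng.normal(0.0, profile.area_log_sigma))
            )
            n_pixels = pixels_for_area(area, spacing)
            kernel = make_near_circular_kernel(n_pixels)
            jitter_sd = profile.jitter_sd_s1
        else:
            n_pixels = 9
            kernel = kernel_for_size(9)
            jitter_sd = profile.jitter_sd_s2
        s0, r0, c0 = cache.target_anchor(n_pixels)
        jr, jc = (int(round(v)) for v in rng.normal(0.0, jitter_sd, size=2))
        r1 = int(np.clip(r0 + jr, 0, vol.shape[1] - 1))
        c1 = int(np.clip(c0 + jc, 0, vol.shape[2] - 1))
        if session == 2:
            res = cache.get(9)
            if isinstance(res, NoFit):
                # Lesion too small for a contained 9-pixel ROI: the reader
                # still places it, centred on a lesion pixel.
                r1, c1 = _nearest_mask_pixel(truth.lesion.voxels[s0], r1, c1)
                adc = _clipped_kernel_mean(vol.values, s0, r1, c1, kernel)
            else:
                s0, r1, c1 = _snap_to_valid(cache.valid_placements_9px(), s0, r1, c1)
                adc = _clipped_kernel_mean(vol.values, s0, r1, c1, kernel)
        else:
            # Free ROIs are anchored on the lesion but may overhang it.
            r1, c1 = _nearest_mask_pixel(truth.lesion.voxels[s0], r1, c1)
            adc = _clipped_kernel_mean(vol.values, s0, r1, c1, kernel)
        row.update(
            adc_value=adc,
            roi_size_mm2=n_pixels * spacing**2,
            roi_volume_cm3=np.nan,
        )
    else:
        # Soft-cap at +-CONTOUR_RADIUS_CAP voxels: contouring errors are
        # bounded in practice and unbounded draws make the study-level
        # spread heavy-tailed.
        raw = rng.normal(profile.contour_bias, profile.contour_sd)
        radius = float(CONTOUR_RADIUS_CAP * np.tanh(raw / CONTOUR_RADIUS_CAP))
        dr, dc = (int(round(v)) for v in rng.normal(0.0, profile.shift_sd_s3, size=2))
        signed = _translate_field(cache.signed_edt(), dr, dc, fill=np.inf)
        perturbed = signed <= radius
        if not perturbed.any():
            perturbed = _translate_mask(truth.lesion.voxels, dr, dc)
        pmask = LesionMask3D(voxels=perturbed)
        adc = percentile_adc(vol, pmask, 10.0)
        row.update(
            adc_value=adc,
            roi_size_mm2=np.nan,
            roi_volume_cm3=pmask.n_voxels * vol.voxel_volume_mm3 / 1000.0,
        )
    return row


def run_virtual_study(
    n_lesions: int = 40,
    n_readers: int = 10,
    profiles: list[ReaderProfile] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full three-session multi-reader study.

    Returns ``(measurements, reference)``: a tidy complete-block table of
    n_lesions x n_readers x 3 rows, and the per-lesion computer reference
    values (9-pixel minimum mean and whole-lesion 10th percentile).
    Fully reproducible from ``seed``; reader streams are independent.
    """
    if n_lesions < 2 or n_readers < 2:
        raise ValueError("need >= 2 lesions and >= 2 readers")
    if profiles is None:
        profiles = default_reader_profiles()
    if len(profiles) < n_readers:
        raise ValueError(f"{len(profiles)} profiles for {n_readers} readers")
    profiles = profiles[:n_readers]

    root = np.random.SeedSequence(seed)
    lesion_seeds = root.spawn(n_lesions)
    meas_rows: list[dict] = []
    ref_rows: list[dict] = []
    for li, lseq in enumerate(lesion_seeds):
        lesion_id = f"lesion_{li + 1:03d}"
        geom_rng = np.random.default_rng(lseq)
        config = random_lesion_config(
            geom_rng, seed=int(lseq.generate_state(1)[0] % (2**31))
        )
        truth = generate_phantom(config, compute_truth=False)
        cache = _MinAnchorCache(truth)
        ref9 = cache.get(9)
        if isinstance(ref9, NoFit):
            ref9_val = cache.get(1).value  # fallback chain bottoms out at 1 px
        else:
            ref9_val = ref9.value
        ref_rows.append(
            {
                "lesion_id": lesion_id,
                "ref_9px": ref9_val,
                "ref_p10": percentile_adc(truth.volume, truth.lesion, 10.0),
            }
        )
        reader_seqs = lseq.spawn(n_readers)
        for ri, (profile, rseq) in enumerate(zip(profiles, reader_seqs)):
            for session, sseq in zip((1, 2, 3), rseq.spawn(3)):
                rng = np.random.default_rng(sseq)
                row = simulate_reader_session(truth, profile, session, rng, cache)
                row["lesion_id"] = lesion_id
                row["reader_id"] = profile.name
                meas_rows.append(row)

    measurements = pd.DataFrame(meas_rows)[
        ["lesion_id", "reader_id", "session", "adc_value", "roi_size_mm2", "roi_volume_cm3"]
    ]
    reference = pd.DataFrame(ref_rows)
    return measurements, reference
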