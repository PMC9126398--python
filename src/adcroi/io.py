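"""File I/O: NIfTI volumes and masks, tabular ingestion, reports.

Conventions
-----------
* ADC values are 1e-6 mm^2/s in memory; NIfTI files stored in mm^2/s can
  be rescaled at load time via ``unit_scale``.
* Coordinates are 0-based (slice, row, col); NIfTI's (x, y, z) data axes
  are transposed so the slowest axis is the slice.
* Tables are tidy long format.  XLSX/CSV column names are mapped through a
  user-editable dict so schema drift in source spreadsheets never requires
  code changes.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .agreement import check_complete_block
from .reference import ADCVolume, LesionMask3D

log = logging.getLogger("adcroi")

#: Accepted values for categorical cohort fields.
COHORT_VOCABULARY = {
    "pathology_class": {"benign", "GS6", "csPCa"},
    "zone": {"PZ", "TZ"},
}

COHORT_REQUIRED = ("patient_id", "lesion_id", "pathology_class")
COHORT_OPTIONAL = (
    "scanner_model",
    "endorectal_coil",
    "zone",
    "median_pz_adc",
    "ref_9px",
    "ref_p10",
)

MEASUREMENT_REQUIRED = ("lesion_id", "reader_id", "session", "adc_value")
MEASUREMENT_OPTIONAL = ("roi_size_mm2", "roi_volume_cm3")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path} contains no data rows")
    return df


def _apply_column_map(
    df: pd.DataFrame,
    column_map: dict[str, str] | None,
    required: tuple[str, ...],
    optional: tuple[str, ...],
) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"missing required columns {missing}; available: {list(df.columns)}. "
            "Supply a column_map from canonical to source names."
        )
    keep = [c for c in required + optional if c in df.columns]
    return df[keep].copy()


def read_cohort_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    skip_invalid: bool = False,
) -> pd.DataFrame:
    """Load and validate a per-lesion cohort table (CSV or XLSX).

    Categorical fields are checked against a declared vocabulary; ADC
    fields must be positive where present.  Invalid rows abort the load
    with their row numbers unless ``skip_invalid``.
    """
    df = _apply_column_map(
        _read_table(path), column_map, COHORT_REQUIRED, COHORT_OPTIONAL
    )
    bad: list[tuple[int, str]] = []
    for field, vocab in COHORT_VOCABULARY.items():
        if field not in df.columns:
            continue
        mask = ~df[field].astype(str).isin(vocab)
        bad += [(int(i), f"{field}={df.loc[i, field]!r}") for i in df.index[mask]]
    for field in ("median_pz_adc", "ref_9px", "ref_p10"):
        if field not in df.columns:
            continue
        vals = pd.to_numeric(df[field], errors="coerce")
        mask = df[field].notna() & ~(vals > 0)
        bad += [(int(i), f"{field}={df.loc[i, field]!r}") for i in df.index[mask]]
    if bad:
        bad.sort()
        msg = "; ".join(f"row {i}: {what}" for i, what in bad[:10])
        if not skip_invalid:
            raise ValueError(f"invalid cohort rows — {msg}")
        log.warning("skipping %d invalid cohort rows — %s", len(bad), msg)
        df = df.drop(index=[i for i, _ in bad])
    return df.reset_index(drop=True)


def read_measurement_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Load a reader-measurement table and enforce complete blocks.

    Wide reader-by-lesion sheets must be pivoted to tidy long form before
    ingestion (or via the column map when one column per field exists).
    Every session present is validated as a complete lesion x reader block.
    """
    df = _apply_column_map(
        _read_table(path), column_map, MEASUREMENT_REQUIRED, MEASUREMENT_OPTIONAL
    )
    df["session"] = df["session"].astype(int)
    df["adc_value"] = pd.to_numeric(df["adc_value"])
    for session in sorted(df["session"].unique()):
        check_complete_block(df, int(session))
    return df.reset_index(drop=True)


def read_volume(path: str | Path, unit_scale: float = 1.0) -> ADCVolume:
    """Load a NIfTI ADC map as an :class:`ADCVolume`.

    ``unit_scale`` multiplies stored values (e.g. 1e6 for maps stored in
    mm^2/s).  Anisotropic in-plane spacing triggers a warning and the mean
    in-plane spacing is used.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float) * unit_scale
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    dx, dy, dz = (float(z) for z in zooms)
    if abs(dx - dy) > 1e-6:
        log.warning(
            "anisotropic in-plane spacing (%.4f, %.4f) mm; using the mean", dx, dy
        )
    spacing = (dx + dy) / 2.0
    # NIfTI stores (x, y, z); transpose so the slice axis is first.
    values = np.transpose(data, (2, 1, 0))
    return ADCVolume(values=values, pixel_spacing=spacing, slice_thickness=dz)


def read_mask(path: str | Path, volume: ADCVolume | None = None) -> LesionMask3D:
    """Load a NIfTI 0/1 mask; optionally check congruence with a volume."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    rounded = np.rint(data)
    uniq = np.unique(rounded)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"mask {path} has values other than 0/1: {uniq}")
    mask = LesionMask3D(voxels=np.transpose(rounded.astype(bool), (2, 1, 0)))
    if volume is not None and mask.shape != volume.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume shape {volume.shape}"
        )
    return mask


def write_volume(path: str | Path, volume: ADCVolume) -> None:
    """Write an :class:`ADCVolume` to NIfTI (inverse of :func:`read_volume`)."""
    data = np.transpose(volume.values, (2, 1, 0))
    affine = np.diag(
        [volume.pixel_spacing, volume.pixel_spacing, volume.slice_thickness, 1.0]
    )
    nib.save(nib.Nifti1Image(data, affine), str(path))


def write_mask(path: str | Path, mask: LesionMask3D, volume: ADCVolume) -> None:
    data = np.transpose(mask.voxels.astype(np.uint8), (2, 1, 0))
    affine = np.diag(
        [volume.pixel_spacing, volume.pixel_spacing, volume.slice_thickness, 1.0]
    )
    nib.save(nib.Nifti1Image(data, affine), str(path))


def report(results: dict, out_json: str | Path, out_markdown: str | Path | None = None) -> None:
    """Write a machine-readable JSON report and an optional Markdown summary.

    ``results`` may contain keys ``loa``, ``icc``, ``friedman``,
    ``posthoc``, ``references``, ``group_tests`` — all optional; an empty
    dict produces a valid (empty-sectioned) report.
    """
    out_json = Path(out_json)
    out_json.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    out_json.write_text(json.dumps(results, indent=2, default=_default))
    if out_markdown is not None:
        lines = ["# ADC measurement report", ""]
        for section in ("loa", "icc", "friedman", "posthoc", "references", "group_tests"):
            lines.append(f"## {section}")
            lines.append("")
            val = results.get(section)
            lines.append("_empty_" if not val else f"```\n{json.dumps(val, indent=2, default=_default)}\n```")
            lines.append("")
        Path(out_markdown).write_text("\n".join(lines))


def bland_altman_plot(result, path: str | Path) -> None:
    """Save a Bland-Altman scatter (lesion mean vs reader difference)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = result.deviations
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(d["lesion_mean"], d["diff"], s=12, alpha=0.5)
    for y, style in ((result.bias, "-"), (result.bias + result.loa_half_width, "--"),
                     (result.bias - result.loa_half_width, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("per-lesion mean ADC (1e-6 mm$^2$/s)")
    ax.set_ylabel("reader $-$ lesion mean")
    ax.set_title(f"Session {result.session}: LoA $\\pm${result.loa_half_width:.0f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
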