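"""Nuclear/cytoplasmic fluorescence-ratio quantification.

Fields are imaged in two channels (DAPI for nuclei, an antibody stain
for the protein of interest).  Nuclei are segmented from the DAPI
channel, the cell region from the stain channel, and the nuclear area is
subtracted from the cell area to obtain the cytoplasm.  Per field the
mean stain intensity over each mask is taken and their quotient is the
nuclear-to-cytoplasmic (n/c) ratio; ratios above 1 indicate nuclear
enrichment of the stained protein.

Segmentation is deterministic: Gaussian smoothing, an Otsu threshold per
channel and a minimum-area filter on connected components.  Fields are
then split into low and high cell density at the mean nucleus count over
all analyzed fields (counts strictly below the mean are "low"), compared
by Mann-Whitney, and summarized by an OLS regression of ratio on count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import filters, measure, morphology

from .stats import OLSResult, TestResult, mann_whitney, ols

__all__ = [
    "FieldMeasurement",
    "DensityAnalysis",
    "segment_nuclei",
    "segment_cytoplasm",
    "measure_field",
    "measure_synthetic_field",
    "density_split",
    "density_regression",
]


@dataclass(frozen=True)
class FieldMeasurement:
    field_id: str
    nucleus_count: int
    mean_nuclear_intensity: float
    mean_cytoplasmic_intensity: float
    nc_ratio: float
    defined: bool
    note: str = ""


@dataclass(frozen=True)
class DensityAnalysis:
    threshold: float
    groups: pd.DataFrame  # field_id, nucleus_count, nc_ratio, density
    mann_whitney: TestResult | None
    regression: OLSResult | None
    n_excluded: int


def _threshold_mask(channel: np.ndarray, sigma: float) -> np.ndarray:
    """Smooth + Otsu; an effectively constant channel yields an empty mask."""
    smoothed = filters.gaussian(channel.astype(float), sigma=sigma, preserve_range=True)
    if np.ptp(smoothed) < 1e-12:
        return np.zeros_like(smoothed, dtype=bool)
    return smoothed > filters.threshold_otsu(smoothed)


def segment_nuclei(
    dapi: np.ndarray, sigma: float = 2.0, min_area: int = 30
) -> tuple[np.ndarray, int]:
    """Binary nuclear mask and nucleus count from the DAPI channel.

    Connected components smaller than ``min_area`` pixels are removed;
    the count is the number of surviving components.  An all-background
    channel gives an empty mask and count zero.
    """
    if dapi.size == 0:
        raise ValueError("empty image")
    mask = _threshold_mask(dapi, sigma)
    if min_area > 1:
        # drop components strictly smaller than min_area
        mask = morphology.remove_small_objects(mask, max_size=min_area - 1)
    count = int(measure.label(mask).max())
    return mask, count


def segment_cytoplasm(
    stain: np.ndarray, nuclear_mask: np.ndarray, sigma: float = 0.5
) -> np.ndarray:
    """Cytoplasm mask: stain-positive cell region minus the nuclei.

    Disjointness from the nuclear mask is guaranteed by construction.
    The default smoothing is lighter than for nuclei because the
    cytoplasmic rim is only a few pixels wide and heavier smoothing
    systematically erodes its outer edge before thresholding.
    """
    if stain.shape != nuclear_mask.shape:
        raise ValueError("stain channel and nuclear mask shapes differ")
    cell = _threshold_mask(stain, sigma)
    return cell & ~nuclear_mask


def measure_field(
    field_id: str,
    stain: np.ndarray,
    nuclear_mask: np.ndarray,
    cytoplasm_mask: np.ndarray,
    nucleus_count: int,
) -> FieldMeasurement:
    """Mean stain intensities over the masks and their n/c ratio.

    A field with an empty compartment is flagged undefined rather than
    dropped, so failed fields remain visible downstream.
    """
    if nuclear_mask.shape != stain.shape or cytoplasm_mask.shape != stain.shape:
        raise ValueError("mask shapes differ from image shape")
    if (nuclear_mask & cytoplasm_mask).any():
        raise ValueError("nuclear and cytoplasm masks overlap")
    notes = []
    mean_nuc = float(stain[nuclear_mask].mean()) if nuclear_mask.any() else np.nan
    mean_cyt = float(stain[cytoplasm_mask].mean()) if cytoplasm_mask.any() else np.nan
    if not nuclear_mask.any():
        notes.append("no nuclear pixels")
    if not cytoplasm_mask.any():
        notes.append("no cytoplasmic pixels")
    defined = not notes and mean_cyt > 0
    if not notes and mean_cyt == 0:
        notes.append("zero cytoplasmic intensity")
    ratio = mean_nuc / mean_cyt if defined else np.nan
    return FieldMeasurement(
        field_id=field_id,
        nucleus_count=nucleus_count,
        mean_nuclear_intensity=mean_nuc,
        mean_cytoplasmic_intensity=mean_cyt,
        nc_ratio=ratio,
        defined=defined,
        note="; ".join(notes),
    )


def measure_synthetic_field(
    field, sigma: float = 2.0, cyto_sigma: float = 0.5, min_area: int = 30
) -> FieldMeasurement:
    """Run the full segmentation pipeline on a generated field."""
    dapi, stain = field.channels[0], field.channels[1]
    nuclear_mask, count = segment_nuclei(dapi, sigma=sigma, min_area=min_area)
    cyto_mask = segment_cytoplasm(stain, nuclear_mask, sigma=cyto_sigma)
    return measure_field(field.field_id, stain, nuclear_mask, cyto_mask, count)


def _measurements_frame(measurements) -> pd.DataFrame:
    if isinstance(measurements, pd.DataFrame):
        df = measurements.copy()
        if "defined" not in df.columns:
            df["defined"] = ~df["nc_ratio"].isna()
        return df
    return pd.DataFrame(
        {
            "field_id": [m.field_id for m in measurements],
            "nucleus_count": [m.nucleus_count for m in measurements],
            "nc_ratio": [m.nc_ratio for m in measurements],
            "defined": [m.defined for m in measurements],
        }
    )


def density_split(measurements) -> DensityAnalysis:
    """Split fields at the mean cell count and test the two groups.

    ``measurements`` is a list of :class:`FieldMeasurement` or a frame
    with ``field_id, nucleus_count, nc_ratio`` columns.  Fields with an
    undefined ratio are excluded from the threshold and the tests but
    counted in ``n_excluded``.  Counts strictly below the mean are
    "low"; counts at or above it (including exact ties) are "high".
    """
    df = _measurements_frame(measurements)
    valid = df[df["defined"]].copy()
    if len(valid) < 2:
        raise ValueError("need at least 2 fields with defined measurements")

    threshold = float(valid["nucleus_count"].mean())
    valid["density"] = np.where(valid["nucleus_count"] < threshold, "low", "high")
    if (valid["density"] == "high").all():
        warnings.warn(
            "all fields at or above the mean cell count; low-density group empty",
            stacklevel=2,
        )

    low = valid.loc[valid["density"] == "low", "nc_ratio"]
    high = valid.loc[valid["density"] == "high", "nc_ratio"]
    mw = mann_whitney(low, high) if len(low) and len(high) else None
    reg = (
        density_regression(valid)
        if len(valid) >= 3 and valid["nucleus_count"].nunique() > 1
        else None
    )
    return DensityAnalysis(
        threshold=threshold,
        groups=valid[["field_id", "nucleus_count", "nc_ratio", "density"]],
        mann_whitney=mw,
        regression=reg,
        n_excluded=int((~df["defined"]).sum()),
    )


def density_regression(measurements) -> OLSResult:
    """OLS of the n/c ratio on the nucleus count over defined fields."""
    df = _measurements_frame(measurements)
    valid = df[df["defined"]]
    return ols(valid["nucleus_count"], valid["nc_ratio"])
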