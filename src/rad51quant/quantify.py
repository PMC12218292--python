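"""Per-cell classification and background-subtracted intensity measures.

Each nucleus crop is assigned one of four categories from its skeleton and
focus content:

* ``Simple``  — a unique unbranched skeleton (one component, no junction);
* ``Complex`` — multiple or branched skeletons;
* ``Foci``    — no skeleton but at least one focus;
* ``Nothing`` — neither.

Lengths are only reported for Simple cells (length measurement is
overestimated on complex filaments, which are therefore excluded from the
length/intensity quantification).  When a cell holds several foci only the
brightest enters the record.  Intensities are summed gray values on the
raw channel after subtraction of the nuclear background, later normalized
to the mean intensity of wild-type filaments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import StructureMasks
from .skeleton import SkeletonFeatures

__all__ = [
    "BrightnessThresholds",
    "CATEGORIES",
    "classify_cell",
    "measure_intensity",
    "select_brightest_focus",
    "build_cell_records",
    "normalize_to_wt",
    "brightness_category",
    "RECORD_COLUMNS",
]

CATEGORIES = ("Simple", "Complex", "Foci", "Nothing")
RECORD_COLUMNS = [
    "cell_id", "strain", "batch", "category", "hasFilament",
    "filamentLength", "filamentLength_nm", "filamentIntensity", "spotIntensity",
]


@dataclass(frozen=True)
class BrightnessThresholds:
    """Cuts on WT-normalized mean foci intensity for the pie-chart classes.

    Bright: mean > ``bright_cut`` of the WT reference; dim: mean <
    ``dim_cut``; intermediate otherwise (both boundaries inclusive to
    intermediate).  ``reference`` names the WT statistic the means are
    normalized to — the mean WT foci intensity (``"wt_foci_mean"``) or the
    mean WT filament intensity (``"wt_filament_mean"``); both are offered
    because pie-chart and box-plot normalizations use different anchors.
    """

    bright_cut: float = 0.80
    dim_cut: float = 0.20
    reference: str = "wt_foci_mean"

    def __post_init__(self) -> None:
        if not (0 < self.dim_cut < self.bright_cut):
            raise ValueError("need 0 < dim_cut < bright_cut")
        if self.reference not in ("wt_foci_mean", "wt_filament_mean"):
            raise ValueError(f"unknown reference {self.reference!r}")


def classify_cell(features: SkeletonFeatures, foci: list) -> str:
    """Four-category call from skeleton features and the focus list.

    Categories are exhaustive and mutually exclusive: Simple iff exactly
    one skeleton component without junctions; Complex iff two or more
    components or any junction; Foci iff no skeleton but >= 1 focus;
    Nothing otherwise.
    """
    if features.n_components == 1 and features.n_junctions == 0:
        return "Simple"
    if features.n_components >= 2 or features.n_junctions > 0:
        return "Complex"
    if len(foci) >= 1:
        return "Foci"
    return "Nothing"


def measure_intensity(raw_image2d: np.ndarray, mask: np.ndarray, background: float) -> float:
    """Background-subtracted summed gray value over ``mask``.

    Negative residuals are kept (no clipping) so that noise cancels in
    expectation and the measurement is unbiased.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot measure intensity over an empty mask")
    image = np.asarray(raw_image2d, dtype=float)
    return float((image[mask] - background).sum())


def select_brightest_focus(foci_with_intensities: list) -> tuple:
    """Pick the focus with maximal background-subtracted intensity.

    ``foci_with_intensities`` is a list of ``(focus, intensity)`` pairs.
    Exact ties are broken by the lowest (row, column) of the focus center.
    """
    if not foci_with_intensities:
        raise ValueError("no foci to select from")
    return min(foci_with_intensities, key=lambda fi: (-fi[1], fi[0].center))


def dilated_mask(mask: np.ndarray, dilation_px: int) -> np.ndarray:
    """Mask grown by ``dilation_px`` to capture PSF tails when measuring."""
    if dilation_px <= 0:
        return np.asarray(mask, dtype=bool)
    return ndimage.binary_dilation(np.asarray(mask, dtype=bool), iterations=int(dilation_px))


def build_cell_records(results: list, metadata: pd.DataFrame) -> pd.DataFrame:
    """Assemble the per-cell record table from per-cell analysis results.

    ``results`` maps one dict per metadata row (matched on ``cell_id``)
    with keys ``category``, ``filament_length_px``, ``filament_length_nm``,
    ``filament_intensity``, ``spot_intensity`` (missing values allowed and
    enforced to match the category: Complex cells carry hasFilament=1 but
    no length/intensity; Foci cells carry spotIntensity only; Nothing
    cells carry nothing; cells whose analysis errored carry a missing
    category and are excluded from statistics downstream).
    """
    by_id = {r["cell_id"]: r for r in results}
    missing = [c for c in metadata["cell_id"] if c not in by_id]
    if missing:
        raise ValueError(f"missing analysis results for cells: {missing}")
    rows = []
    for _, meta in metadata.iterrows():
        res = by_id[meta["cell_id"]]
        category = res.get("category")
        row = {
            "cell_id": meta["cell_id"], "strain": meta["strain"], "batch": meta["batch"],
            "category": category,
            "hasFilament": np.nan, "filamentLength": np.nan, "filamentLength_nm": np.nan,
            "filamentIntensity": np.nan, "spotIntensity": np.nan,
        }
        if category == "Simple":
            row.update(hasFilament=1,
                       filamentLength=res.get("filament_length_px"),
                       filamentLength_nm=res.get("filament_length_nm"),
                       filamentIntensity=res.get("filament_intensity"))
        elif category == "Complex":
            row.update(hasFilament=1)
        elif category == "Foci":
            row.update(hasFilament=0, spotIntensity=res.get("spot_intensity"))
        elif category == "Nothing":
            row.update(hasFilament=0)
        rows.append(row)
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def normalize_to_wt(records: pd.DataFrame, wt_strain: str = "WT") -> pd.DataFrame:
    """Divide all intensities by the mean WT Simple-filament intensity.

    Returns a copy; the scale reference is the mean ``filamentIntensity``
    of the wild-type strain's Simple cells (the box-plot normalization).
    """
    wt = records[(records["strain"] == wt_strain) & (records["category"] == "Simple")]
    wt = wt.dropna(subset=["filamentIntensity"])
    if wt.empty:
        raise ValueError(f"no Simple cells with filament intensity for WT strain {wt_strain!r}")
    reference = float(wt["filamentIntensity"].mean())
    out = records.copy()
    out["filamentIntensity"] = out["filamentIntensity"] / reference
    out["spotIntensity"] = out["spotIntensity"] / reference
    return out


def wt_reference_value(records: pd.DataFrame, wt_strain: str, reference: str) -> float:
    """The WT statistic used as 100% for the brightness classes."""
    wt = records[records["strain"] == wt_strain]
    if reference == "wt_foci_mean":
        values = wt.loc[wt["category"] == "Foci", "spotIntensity"].dropna()
    else:
        values = wt.loc[wt["category"] == "Simple", "filamentIntensity"].dropna()
    if values.empty:
        raise ValueError(f"no WT cells available for reference {reference!r}")
    return float(values.mean())


def brightness_category(mean_normalized_foci_intensity: float,
                        thr: BrightnessThresholds | None = None) -> str:
    """Bright / intermediate / dim call for a strain's mean foci intensity.

    The input is already normalized to the WT reference (1.0 = 100% of
    WT); values above 80% are bright, below 20% dim, in between (bounds
    included) intermediate.
    """
    thr = thr if thr is not None else BrightnessThresholds()
    if mean_normalized_foci_intensity < 0:
        raise ValueError("mean normalized intensity must be >= 0")
    if mean_normalized_foci_intensity > thr.bright_cut:
        return "bright"
    if mean_normalized_foci_intensity < thr.dim_cut:
        return "dim"
    return "intermediate"
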