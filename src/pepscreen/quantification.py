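"""Per-spot median intensity readout from a scan image and its layout.

Each spot's value is the median over all pixels of its full synthesis
rectangle (no within-footprint segmentation; even pixel counts use the mean
of the two central order statistics). The global background estimate is the
median over blank-spot medians and is reported alongside, not subtracted:
empty-spot signal is the screen's reference floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .array_layout import ArrayLayout
from .constants import BLANK_ID
from .scan_simulator import ScanImage, _spot_pixels


@dataclass(frozen=True)
class SpotQuantification:
    spot_id: str
    peptide_id: str
    median_intensity: float
    pixel_count: int
    background_estimate: float


def quantify_spots(
    image: ScanImage, layout: ArrayLayout, blank_ids: frozenset[str] | None = None
) -> list[SpotQuantification]:
    """Median pixel intensity of every spot footprint in the layout.

    blank_ids: peptide ids treated as blanks for the global background
    estimate, in addition to the literal "BLANK" filler id.
    """
    spot_px = _spot_pixels(layout.grid, image.um_per_pixel)
    height, width = image.data.shape
    medians = np.empty(len(layout.spots))
    for i, s in enumerate(layout.spots):
        y0, x0 = s.row * spot_px, s.col * spot_px
        if y0 + spot_px > height or x0 + spot_px > width:
            raise ValueError(
                f"spot {s.spot_id} footprint [{y0}:{y0 + spot_px}, {x0}:{x0 + spot_px}] "
                f"exceeds image bounds {image.data.shape}"
            )
        medians[i] = np.median(image.data[y0 : y0 + spot_px, x0 : x0 + spot_px])
    blanks = blank_ids or frozenset()
    blank_medians = [
        m
        for m, s in zip(medians, layout.spots)
        if s.peptide_id == BLANK_ID or s.peptide_id in blanks
    ]
    background = float(np.median(blank_medians)) if blank_medians else float("nan")
    return [
        SpotQuantification(
            spot_id=s.spot_id,
            peptide_id=s.peptide_id,
            median_intensity=float(m),
            pixel_count=spot_px * spot_px,
            background_estimate=background,
        )
        for s, m in zip(layout.spots, medians)
    ]


def quantifications_from_table(table) -> list[SpotQuantification]:
    """Adapt a simulated spot-intensity table to the quantification record
    type, so the analysis stage is agnostic to the observation route."""
    blank_vals = table.loc[table["peptide_id"] == BLANK_ID, "intensity"]
    background = float(np.median(blank_vals)) if len(blank_vals) else float("nan")
    return [
        SpotQuantification(
            spot_id=str(row.spot_id),
            peptide_id=str(row.peptide_id),
            median_intensity=float(row.intensity),
            pixel_count=0,
            background_estimate=background,
        )
        for row in table.itertuples(index=False)
    ]
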