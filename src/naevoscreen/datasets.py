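"""Bundled reference data.

``load_reference_quantifications`` returns the published quantification
table for four naevoid-melanoma photomicrographs (1920 × 1088 px, 500 µm
scale bar) that this package's area arithmetic is validated against. Each
row's printed total area corresponds exactly to an integer scale-bar pixel
length, recorded here so the whole calibration chain can be recomputed from
first principles.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_reference_quantifications"]

_REFERENCE_ROWS = [
    # case_id, width, height, scale_bar_px, total_area_mm2, red_pixel_count, equivalent_area_mm2
    ("NM1", 1920, 1088, 280, 6.66122449, 166_689, 0.531533801),
    ("NM2", 1920, 1088, 200, 13.056, 110_438, 0.6902375),
    ("NM6", 1920, 1088, 362, 3.985226336, 140_468, 0.267978694),
    ("NM8", 1920, 1088, 392, 3.398583923, 105_898, 0.172288239),
]


def load_reference_quantifications() -> pd.DataFrame:
    """Reference per-image quantifications (500 µm scale bar).

    Columns: ``case_id``, ``width``, ``height``, ``scale_bar_px``,
    ``total_area_mm2``, ``red_pixel_count``, ``equivalent_area_mm2``.
    """
    return pd.DataFrame(
        _REFERENCE_ROWS,
        columns=[
            "case_id", "width", "height", "scale_bar_px",
            "total_area_mm2", "red_pixel_count", "equivalent_area_mm2",
        ],
    )
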