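"""Reference cohort tables bundled for examples, tests and reports.

A published dystrophinopathy cohort of 14 subjects plus pooled pediatric
controls: per-subject whole-section dystrophin mean intensity (AU, average
of 2 serial-section replicates), percent dystrophin-positive fibers, and
Western-blot percent-of-control where blotting was performed (NaN = not
done).  These are measured inputs, not values this package recomputes from
images.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_COHORT_ROWS = [
    # subject_id, phenotype, mean_intensity_au, pct_positive, wb_pct
    ("CTRL", "CTRL", 50387.0, 99.5, 100.0),
    ("P01", "mildBMD", 23228.0, 99.0, 54.0),
    ("P02", "mildBMD", 33684.0, 98.5, 54.0),
    ("P03", "mildBMD", 28519.0, 99.5, 76.0),
    ("P04", "severeBMD", 30798.0, 100.0, np.nan),
    ("P05", "severeBMD", 13657.0, 81.5, 17.0),
    ("P06", "IMD", 17064.0, 75.5, np.nan),
    ("P07", "IMD", 19168.0, 98.5, np.nan),
    ("P08", "IMD", 18726.0, 98.5, np.nan),
    ("P09", "DMD", 8694.0, 37.0, np.nan),
    ("P10", "DMD", 13551.0, 71.5, 0.0),
    ("P11", "DMD", 12572.0, 52.5, 12.0),
    ("P12", "DMD", 12168.0, 49.5, 0.0),
    ("P13", "DMD", 11539.0, 53.0, 0.0),
    ("P14", "DMD", 13161.0, 29.5, np.nan),
]

#: Mean sarcolemmal intensity (AU) of fibers in the 75-100% coverage bin,
#: for the groups where a bin-level value was reported.
BIN4_MEAN_INTENSITY_AU = {"CTRL": 50387.0, "mildBMD": 28743.0}


def load_example_cohort(include_controls: bool = True) -> pd.DataFrame:
    """Reference cohort as a DataFrame.

    Columns: subject_id, phenotype, mean_intensity_au, pct_positive, wb_pct.
    """
    df = pd.DataFrame(
        _COHORT_ROWS,
        columns=["subject_id", "phenotype", "mean_intensity_au", "pct_positive", "wb_pct"],
    )
    if not include_controls:
        df = df[df["phenotype"] != "CTRL"].reset_index(drop=True)
    return df
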