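"""Western-blot percent-of-control bookkeeping.

Input is a band-intensity table (densitometry already done): per lane a
dystrophin band and an α-actinin loading-control band.  Each lane's
dystrophin/actinin ratio is expressed as a percentage of the mean ratio of
the control lanes on the same blot; technical repeats are averaged with a
sample SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class WBError(ValueError):
    pass


@dataclass(frozen=True)
class LaneMeasurement:
    sample_id: str
    repeat_index: int
    dystrophin_band: float
    actinin_band: float

    def __post_init__(self) -> None:
        if self.dystrophin_band < 0:
            raise WBError(f"{self.sample_id}: negative dystrophin band")
        if self.actinin_band <= 0:
            raise WBError(f"{self.sample_id}: actinin band must be > 0")


@dataclass(frozen=True)
class WBResult:
    sample_id: str
    pct_of_control: float
    pct_sd: float
    n_repeats: int
    not_detected: bool = False


def control_ratio(control_lanes: list[LaneMeasurement]) -> float:
    """Mean dystrophin/actinin ratio over the control lanes of a blot."""
    if not control_lanes:
        raise WBError("no control lanes provided")
    return float(
        np.mean([l.dystrophin_band / l.actinin_band for l in control_lanes])
    )


def normalize_lane(lane: LaneMeasurement, ctrl_ratio: float) -> float:
    """100 * (dystrophin/actinin) / control ratio."""
    if ctrl_ratio <= 0:
        raise WBError("control ratio must be > 0")
    return 100.0 * (lane.dystrophin_band / lane.actinin_band) / ctrl_ratio


def summarize_wb(lanes: list[LaneMeasurement], ctrl_ratio: float) -> WBResult:
    """Mean ± sample SD of per-lane percent-of-control for one sample.

    Samples whose dystrophin band is zero in every repeat are reported as 0%
    with the ``not_detected`` flag set.
    """
    if not lanes:
        raise WBError("at least one lane required")
    sample_ids = {l.sample_id for l in lanes}
    if len(sample_ids) != 1:
        raise WBError(f"lanes from multiple samples: {sorted(sample_ids)}")
    pcts = np.array([normalize_lane(l, ctrl_ratio) for l in lanes])
    sd = float(pcts.std(ddof=1)) if pcts.size > 1 else 0.0
    return WBResult(
        sample_id=lanes[0].sample_id,
        pct_of_control=float(pcts.mean()),
        pct_sd=sd,
        n_repeats=len(lanes),
        not_detected=all(l.dystrophin_band == 0 for l in lanes),
    )


def process_blot(table: pd.DataFrame) -> pd.DataFrame:
    """Summarize a whole blot from a band-intensity table.

    Expects columns: sample_id, repeat, dys_au, actinin_au, is_control.
    Returns per-sample rows: sample_id, pct_of_control_mean, pct_sd,
    n_repeats, not_detected.
    """
    required = {"sample_id", "repeat", "dys_au", "actinin_au", "is_control"}
    missing = required - set(table.columns)
    if missing:
        raise WBError(f"band table missing columns: {sorted(missing)}")
    lanes_by_sample: dict[str, list[LaneMeasurement]] = {}
    controls: list[LaneMeasurement] = []
    for row in table.itertuples(index=False):
        lane = LaneMeasurement(
            str(row.sample_id), int(row.repeat), float(row.dys_au), float(row.actinin_au)
        )
        lanes_by_sample.setdefault(lane.sample_id, []).append(lane)
        if bool(row.is_control):
            controls.append(lane)
    ratio = control_ratio(controls)
    results = [summarize_wb(lanes, ratio) for lanes in lanes_by_sample.values()]
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "pct_of_control_mean": r.pct_of_control,
                "pct_sd": r.pct_sd,
                "n_repeats": r.n_repeats,
                "not_detected": r.not_detected,
            }
            for r in results
        ]
    )
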