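"""Per-frame feature extraction.

Six values summarize each frame for the classifiers:

* ``p_in`` / ``p_out`` — number of (residual-filtered) imprint pixels inside
  / outside the bed boundary;
* ``t_in`` / ``t_out`` — maximum raw temperature (sensor counts) over the
  imprint pixels inside / outside the bed.  When a side has no imprint the
  value falls back to the background's maximum over that side (or, without a
  background model, the frame's own maximum there), so downstream models
  always receive a number close to ambient;
* ``d`` — the ultrasonic distance reading in cm;
* ``m`` — number of pixels whose imprint membership changed since the
  previous frame (symmetric set difference; 0 for the first frame).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Union

import numpy as np

from .io import BedMask, FormatError, ThermalFrame
from .thermal import BackgroundModel, ImprintMask


@dataclass(frozen=True)
class FrameFeatures:
    index: int
    p_in: int
    p_out: int
    t_in: float
    t_out: float
    d: int
    m: int


def extract_features(
    frame: ThermalFrame,
    filtered: ImprintMask,
    bed: BedMask,
    prev_filtered: Optional[ImprintMask] = None,
    background: Optional[BackgroundModel] = None,
) -> FrameFeatures:
    """Compute the six per-frame features from a filtered imprint."""
    mask = filtered.mask
    bed_mask = bed.mask
    if mask.shape != bed_mask.shape:
        raise ValueError("imprint and bed mask shapes differ")

    in_mask = mask & bed_mask
    out_mask = mask & ~bed_mask
    fallback = background.mean_grid if background is not None else frame.grid

    def region_max(region: np.ndarray, side: np.ndarray) -> float:
        if region.any():
            return float(frame.grid[region].max())
        return float(np.asarray(fallback)[side].max())

    if prev_filtered is None:
        m = 0
    else:
        if prev_filtered.mask.shape != mask.shape:
            raise ValueError("imprint mask shapes differ")
        m = int(np.count_nonzero(mask ^ prev_filtered.mask))

    return FrameFeatures(
        index=frame.index,
        p_in=int(np.count_nonzero(in_mask)),
        p_out=int(np.count_nonzero(out_mask)),
        t_in=region_max(in_mask, bed_mask),
        t_out=region_max(out_mask, ~bed_mask),
        d=frame.distance_cm,
        m=m,
    )


def write_features(features: Iterable[FrameFeatures], path: Union[str, Path]) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "p_in", "p_out", "t_in", "t_out", "d", "m"])
        for f in features:
            writer.writerow([f.index, f.p_in, f.p_out, f.t_in, f.t_out, f.d, f.m])


def read_features(path: Union[str, Path]) -> List[FrameFeatures]:
    out: List[FrameFeatures] = []
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        for row_no, row in enumerate(csv.reader(fh), start=1):
            if not row:
                continue
            if row_no == 1 and row[0] == "index":
                continue
            if len(row) != 7:
                raise FormatError(f"row {row_no}: expected 7 feature columns")
            out.append(
                FrameFeatures(
                    index=int(row[0]),
                    p_in=int(row[1]),
                    p_out=int(row[2]),
                    t_in=float(row[3]),
                    t_out=float(row[4]),
                    d=int(row[5]),
                    m=int(row[6]),
                )
            )
    return out
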