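"""Western-blot densitometry arithmetic.

Band signals from chemiluminescence images are only comparable after two
normalisations: each lane's band signal is divided by its total-protein
loading control (Coomassie membrane stain), and each blot's lane totals are
divided by the blot's calibrator lane (a reference lysate re-run on every
blot, e.g. P10 cerebral cortex set to 1) so that values from different blots
and exposure gains live on one scale.

Bands are grouped by apparent molecular weight into long / medium / short
isoform groups; a lane's total signal is the sum of its normalised band
groups.  Cells with no detectable signal are recorded explicitly as "not
detected", distinct from cells that were never measured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import numpy as np
import pandas as pd

log = logging.getLogger("isojunct")

__all__ = [
    "BAND_GROUPS",
    "BlotMeasurement",
    "CalibratedMatrix",
    "normalize_lane",
    "normalize_lanes",
    "total_signal",
    "calibrate",
    "plot_calibrated_matrix",
]

#: band groups by apparent molecular weight: long isoforms (B and C),
#: medium isoforms (D), short isoforms (A and I)
BAND_GROUPS = ("long", "medium", "short")

_BAND_COLUMNS = [
    "blot_id",
    "sample_id",
    "tissue",
    "stage",
    "band_group",
    "raw_signal",
    "coomassie_signal",
]


@dataclass(frozen=True)
class BlotMeasurement:
    """One band-group measurement in one lane of one blot."""

    blot_id: str
    sample_id: str
    band_group: str
    raw_signal: float
    coomassie_signal: float
    tissue: str = ""
    stage: str = ""

    def __post_init__(self) -> None:
        if self.coomassie_signal <= 0:
            raise ValueError(
                f"lane {self.sample_id} on {self.blot_id}: Coomassie signal must be "
                f"positive, got {self.coomassie_signal}"
            )
        if self.raw_signal < 0:
            raise ValueError(f"lane {self.sample_id}: negative raw signal")
        if self.band_group not in BAND_GROUPS:
            raise ValueError(
                f"lane {self.sample_id}: unknown band group {self.band_group!r} "
                f"(expected one of {BAND_GROUPS})"
            )

    @property
    def normalized(self) -> float:
        return self.raw_signal / self.coomassie_signal


@dataclass
class CalibratedMatrix:
    """Calibrator-relative expression matrix (tissues x stages).

    ``values`` holds calibrator-relative totals; the calibrator cell is
    exactly 1.  ``not_detected`` marks cells measured but below the
    detection floor — distinct from cells absent from ``values`` (NaN),
    which were never measured.  ``errors`` records blots excluded for a
    missing calibrator lane.
    """

    values: pd.DataFrame
    not_detected: pd.DataFrame
    calibrator: tuple[str, str]
    errors: tuple[str, ...] = ()

    def masked(self) -> pd.DataFrame:
        """Values with not-detected cells masked to NaN (for display)."""
        return self.values.mask(self.not_detected)


def _check_bands(bands: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _BAND_COLUMNS if c not in bands.columns]
    if missing:
        raise ValueError(f"band table missing columns: {missing}")
    bad = bands[bands["coomassie_signal"] <= 0]
    if len(bad):
        lanes = sorted(set(bad["sample_id"]))[:5]
        raise ValueError(f"non-positive Coomassie signal for lane(s) {lanes}")
    if (bands["raw_signal"] < 0).any():
        raise ValueError("negative raw band signal")
    unknown = set(bands["band_group"]) - set(BAND_GROUPS)
    if unknown:
        raise ValueError(f"unknown band group(s): {sorted(unknown)}")
    return bands


def normalize_lane(m: BlotMeasurement) -> float:
    """Loading-control normalisation: raw band signal / Coomassie signal."""
    return m.normalized


def normalize_lanes(bands: pd.DataFrame) -> pd.DataFrame:
    """Vectorised lane normalisation; adds a ``normalized`` column."""
    bands = _check_bands(bands)
    out = bands.copy()
    out["normalized"] = out["raw_signal"] / out["coomassie_signal"]
    return out


def total_signal(bands: pd.DataFrame) -> pd.DataFrame:
    """Total normalised signal per lane: sum of its measured band groups."""
    normed = normalize_lanes(bands)
    keys = ["blot_id", "sample_id", "tissue", "stage"]
    out = normed.groupby(keys, sort=True)["normalized"].sum().reset_index(name="total")
    return out


def calibrate(
    bands: pd.DataFrame,
    calibrator: tuple[str, str],
    detection_floor: float = 0.0,
) -> CalibratedMatrix:
    """Calibrator-scaled tissue x stage matrix from a band table.

    Every blot must contain a calibrator lane (tissue, stage); each lane
    total on a blot is divided by that blot's calibrator total, which makes
    the result invariant to per-blot gain (exposure) factors.  Blots lacking
    the calibrator are excluded, with the affected cells listed in
    ``errors``.  Replicate lanes for one tissue/stage are averaged after
    calibration.  Totals at or below ``detection_floor`` (relative units)
    are marked not-detected.
    """
    cal_tissue, cal_stage = calibrator
    lanes = total_signal(bands)
    calibrated_parts: list[pd.DataFrame] = []
    errors: list[str] = []
    for blot_id, sub in lanes.groupby("blot_id", sort=True):
        cal = sub[(sub["tissue"] == cal_tissue) & (sub["stage"] == cal_stage)]
        if cal.empty:
            cells = sorted(set(zip(sub["tissue"], sub["stage"])))
            errors.append(
                f"blot {blot_id}: calibrator lane {cal_tissue}:{cal_stage} absent; "
                f"excluded cells {cells}"
            )
            continue
        cal_value = float(cal["total"].mean())
        if cal_value <= 0:
            errors.append(f"blot {blot_id}: calibrator signal is zero; blot excluded")
            continue
        part = sub.copy()
        part["relative"] = part["total"] / cal_value
        calibrated_parts.append(part)
    if not calibrated_parts:
        raise ValueError(
            "no blot carries the calibrator lane "
            f"{cal_tissue}:{cal_stage}: " + "; ".join(errors)
        )
    for msg in errors:
        log.warning("%s", msg)
    allp = pd.concat(calibrated_parts, ignore_index=True)
    values = (
        allp.groupby(["tissue", "stage"], sort=True)["relative"].mean().unstack("stage")
    )
    not_detected = values.notna() & (values <= detection_floor)
    # the calibrator cell is 1 by construction up to replicate averaging;
    # pin it exactly to guard against float drift
    values.loc[cal_tissue, cal_stage] = 1.0
    return CalibratedMatrix(
        values=values,
        not_detected=not_detected,
        calibrator=calibrator,
        errors=tuple(errors),
    )


def plot_calibrated_matrix(matrix: CalibratedMatrix, path=None, ax=None):
    """Heatmap of the calibrated matrix; not-detected cells are greyed out."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1 + matrix.values.shape[1], 1 + matrix.values.shape[0] / 2))
    data = np.ma.masked_array(matrix.values.values, mask=matrix.not_detected.values)
    im = ax.imshow(data, aspect="auto", cmap="coolwarm")
    im.cmap.set_bad("lightgrey")
    ax.set_xticks(range(matrix.values.shape[1]), matrix.values.columns)
    ax.set_yticks(range(matrix.values.shape[0]), matrix.values.index)
    ax.figure.colorbar(im, ax=ax, label=f"relative to {matrix.calibrator[0]}:{matrix.calibrator[1]}")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
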