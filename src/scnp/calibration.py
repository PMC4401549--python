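"""Bead-based fluorescence calibration.

Rainbow calibration particles (RCPs) carry 8 dye peaks with
manufacturer-assigned reference values in Equivalent Reference Fluorophore
(ERF) units.  Running one bead well per plate lets every fluorescent
channel be mapped from raw instrument intensity to ERF, removing
plate-to-plate and instrument gain drift: a straight line is fit through
(log10 median peak intensity, log10 reference ERF) and inverted to convert
cell events.  Scatter channels (FSC/SSC) are not fluorescence and pass
through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BeadCalibration", "CalibrationError", "fit_erf_calibration",
           "apply_calibration", "SCATTER_CHANNELS"]

SCATTER_CHANNELS = ("FSC", "SSC")
LOG_BASE = 10.0  # any fixed base is equivalent; log10 is used throughout


class CalibrationError(ValueError):
    pass


@dataclass
class ChannelFit:
    slope: float
    intercept: float
    r_squared: float
    n_peaks: int


@dataclass
class BeadCalibration:
    """Per-channel linear map in log-log space: log10(I) = a + b*log10(ERF).

    ``slope`` must be positive, making the map strictly monotone and
    invertible; ``to_erf`` applies the inverse to raw intensities.
    """

    plate_id: str
    channels: dict[str, ChannelFit] = field(default_factory=dict)

    def to_erf(self, channel: str, intensities) -> np.ndarray:
        if channel not in self.channels:
            raise CalibrationError(
                f"channel {channel!r} not calibrated on plate {self.plate_id!r}")
        fit = self.channels[channel]
        x = np.asarray(intensities, dtype=float)
        if np.any(x <= 0):
            raise CalibrationError("nonpositive intensity cannot be calibrated")
        return LOG_BASE ** ((np.log10(x) - fit.intercept) / fit.slope)

    def to_dict(self) -> dict:
        return {"plate_id": self.plate_id,
                "log_base": LOG_BASE,
                "channels": {c: vars(f) for c, f in self.channels.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "BeadCalibration":
        cal = cls(plate_id=d["plate_id"])
        for c, f in d["channels"].items():
            cal.channels[c] = ChannelFit(**f)
        return cal


def fit_erf_calibration(beads, saturation: float = 2.0 ** 18,
                        min_peaks: int = 3) -> BeadCalibration:
    """Fit the per-channel calibration line from an 8-peak bead well.

    For each channel, the median intensity of each bead peak is regressed
    (ordinary least squares) on the manufacturer-assigned reference ERF in
    log10-log10 space.  Peaks whose median is at or above ``saturation``
    (top of the detector range) are excluded; at least ``min_peaks``
    resolvable peaks must remain.

    Parameters
    ----------
    beads : BeadPlateData
        Per-channel intensity samples for the 8 peaks plus the reference
        ERF values (strictly increasing).
    """
    ref = np.asarray(beads.reference_erf, dtype=float)
    if ref.size != 8 or np.any(np.diff(ref) <= 0):
        raise CalibrationError("expected 8 strictly increasing reference ERFs")
    cal = BeadCalibration(plate_id=beads.plate_id)
    for channel, peaks in beads.peak_intensities.items():
        med = np.array([np.median(np.asarray(p, dtype=float)) for p in peaks])
        if med.size != ref.size:
            raise CalibrationError(
                f"channel {channel!r}: {med.size} peaks, expected {ref.size}")
        keep = med < saturation
        if np.any(med[keep] <= 0):
            raise CalibrationError(
                f"channel {channel!r}: zero/negative peak median")
        if keep.sum() < min_peaks:
            raise CalibrationError(
                f"channel {channel!r}: only {int(keep.sum())} resolvable peaks "
                f"(need >= {min_peaks})")
        x = np.log10(ref[keep])
        y = np.log10(med[keep])
        slope, intercept = np.polyfit(x, y, 1)
        if slope <= 0:
            raise CalibrationError(
                f"channel {channel!r}: nonpositive calibration slope")
        resid = y - (intercept + slope * x)
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
        cal.channels[channel] = ChannelFit(float(slope), float(intercept),
                                           float(r2), int(keep.sum()))
    return cal


def apply_calibration(events, cal: BeadCalibration):
    """Return a copy of an event table with fluorescent channels on the ERF
    scale.  Scatter channels pass through; the result is flagged
    ``scale="ERF"`` in its metadata.  Raises if a fluorescent channel has no
    calibration."""
    if events.meta.get("scale") == "ERF":
        return events
    data = events.data.copy()
    for channel in data.columns:
        if channel in SCATTER_CHANNELS:
            continue
        data[channel] = cal.to_erf(channel, data[channel].to_numpy())
    out = events.replace(data=data)
    out.meta = dict(events.meta, scale="ERF", calibration_plate=cal.plate_id)
    return out
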