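"""Plug and droplet QC from two-channel fluorescence traces.

Drug plugs are loaded alternately with a UV-excited dye and a green-excited
dye, so in each channel the plug train alternates between dye-positive and
dye-negative plugs.  Carryover of one plug's contents into the next shows up
as residual signal in the negative plugs: the ratio of a negative peak's
height to the preceding positive peak's height is the per-transition
contamination proxy.  Droplet mixing precision is summarized as the
coefficient of variation of per-combination median droplet intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Peak:
    index: int
    start_time: float
    end_time: float
    height: float  # plateau median between threshold crossings
    polarity: str | None = None  # "positive" / "negative" under alternation
    merged: bool = False


@dataclass
class PeakSeries:
    peaks: list[Peak]
    channel: str

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def heights(self) -> np.ndarray:
        return np.array([p.height for p in self.peaks])


def detect_peaks(
    time_s: np.ndarray,
    intensity: np.ndarray,
    threshold: float,
    min_width_s: float = 0.0,
    channel: str = "",
    merged_width_factor: float = 1.8,
) -> PeakSeries:
    """Segment a trace into above-threshold plateaus.

    A peak is a maximal run of samples above ``threshold`` lasting at least
    ``min_width_s``; its height is the median intensity of the run, which is
    robust to the brief flow-equilibration spikes at plug boundaries.
    Segments wider than ``merged_width_factor`` times the median segment
    width are flagged as possible merged plugs.  A flat trace yields an
    empty series.
    """
    time_s = np.asarray(time_s, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if np.any(np.diff(time_s) <= 0):
        raise ValueError("time stamps must be strictly increasing")
    above = intensity > threshold
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = list(np.flatnonzero(np.diff(above.astype(int)) == 1) + 1)
    ends = list(np.flatnonzero(np.diff(above.astype(int)) == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    segments = [(s, e) for s, e in zip(starts, ends) if time_s[e - 1] - time_s[s] >= min_width_s]
    widths = np.array([time_s[e - 1] - time_s[s] for s, e in segments])
    median_w = float(np.median(widths)) if len(widths) else 0.0
    peaks = [
        Peak(
            index=i,
            start_time=float(time_s[s]),
            end_time=float(time_s[e - 1]),
            height=float(np.median(intensity[s:e])),
            merged=bool(median_w > 0 and (time_s[e - 1] - time_s[s]) > merged_width_factor * median_w),
        )
        for i, (s, e) in enumerate(segments)
    ]
    return PeakSeries(peaks=peaks, channel=channel)


def assign_polarity(series: PeakSeries, first: str = "positive") -> PeakSeries:
    """Label peaks alternately from the declared loading order.

    Polarity follows the known alternating dye scheme supplied as metadata;
    it is not inferred from the signal.
    """
    if first not in ("positive", "negative"):
        raise ValueError("first must be 'positive' or 'negative'")
    other = "negative" if first == "positive" else "positive"
    labelled = [
        Peak(p.index, p.start_time, p.end_time, p.height,
             polarity=first if i % 2 == 0 else other, merged=p.merged)
        for i, p in enumerate(series.peaks)
    ]
    return PeakSeries(peaks=labelled, channel=series.channel)


def contamination_ratio(series: PeakSeries) -> tuple[pd.DataFrame, dict]:
    """Per-transition carryover ratios and their channel summary.

    For every negative peak n preceded by a positive peak n-1 the ratio
    height(n)/height(n-1) is computed; transitions with a zero positive
    height are skipped with a warning.  Invariant to global intensity
    scaling.
    """
    rows = []
    skipped = 0
    for prev, cur in zip(series.peaks, series.peaks[1:]):
        if cur.polarity != "negative" or prev.polarity != "positive":
            continue
        if prev.height <= 0:
            skipped += 1
            continue
        rows.append(
            {
                "negative_index": cur.index,
                "positive_index": prev.index,
                "ratio": cur.height / prev.height,
            }
        )
    if skipped:
        warnings.warn(f"skipped {skipped} transition(s) with zero positive height")
    if not rows:
        raise ValueError("no (positive, following negative) transitions found")
    df = pd.DataFrame(rows)
    summary = {
        "channel": series.channel,
        "mean_ratio": float(df["ratio"].mean()),
        "sd_ratio": float(df["ratio"].std(ddof=1)) if len(df) > 1 else 0.0,
        "n_transitions": int(len(df)),
        "n_skipped": skipped,
    }
    return df, summary


def droplet_cv(
    combination_intensities: dict[str, np.ndarray], channel: str = ""
) -> dict:
    """Per-combination median droplet intensities and their CV.

    ``combination_intensities`` maps each combination id to the droplet
    intensity list for one channel.  The CV (sd/mean of the per-combination
    medians) quantifies mixing stability across combinations; empty bins are
    skipped and reported.
    """
    medians = {}
    skipped = []
    for combo, values in combination_intensities.items():
        values = np.asarray(values, dtype=float)
        if values.size < 2:
            skipped.append(combo)
            continue
        medians[combo] = float(np.median(values))
    if len(medians) < 2:
        raise ValueError("need at least 2 combinations with >= 2 droplets each")
    med = np.array(list(medians.values()))
    return {
        "channel": channel,
        "medians": medians,
        "cv": float(med.std(ddof=1) / med.mean()),
        "n_combinations": len(medians),
        "skipped": skipped,
    }


def read_trace_csv(path) -> pd.DataFrame:
    """Read a trace CSV with columns time_s, uv, green."""
    df = pd.read_csv(path)
    required = {"time_s", "uv", "green"}
    if not required <= set(df.columns):
        raise ValueError(f"trace CSV must contain columns {sorted(required)}")
    return df
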