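"""Artery–vein separation via time-to-peak of the smoothed TAC.

The TAC peaks where its smoothed derivative v' crosses zero from above.  At
the first frame t_{I+1} where v' turns negative (after an uptake), the
crossing time is found by linear interpolation between (t_I, v'_I) and
(t_{I+1}, v'_{I+1}):

    a = (v'_{I+1} - v'_I) / (t_{I+1} - t_I)
    b = v'_{I+1} - a * t_{I+1}
    t_ttp = -b / a

Contrast reaches arteries before veins, so the TTP histogram over all
vessel voxels is bimodal; the valley between its two peaks (V_ttp) is the
artery/vein threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core import CTPSeries
from .vesselseg import DoGFilter, filter_tac, make_dog_filter

__all__ = [
    "TTPMap",
    "AVThreshold",
    "compute_ttp",
    "compute_ttp_map",
    "find_valley_threshold",
    "separate_arteries_veins",
]


def compute_ttp(vprime: np.ndarray, times: np.ndarray) -> float:
    """TTP (seconds) of one derivative curve; NaN when no crossing exists.

    The crossing index I+1 is the first frame with v' <= 0 after the global
    maximum of v' (the main uptake).  Anchoring the search at the uptake
    maximum makes the rule equivalent to "first negative v'" on clean
    curves while ignoring sub-noise zero crossings on the pre-bolus
    baseline.  A flat crossing (a == 0) returns t_{I+1}, the zero-slope
    limit of the interpolation.
    """
    v = np.asarray(vprime, dtype=float)
    t = np.asarray(times, dtype=float)
    imax = int(np.argmax(v))
    if v[imax] <= 0:
        return float("nan")  # no uptake at all
    for i in range(imax + 1, len(v)):
        if v[i] <= 0:
            a = (v[i] - v[i - 1]) / (t[i] - t[i - 1])
            if a == 0:
                return float(t[i])
            b = v[i] - a * t[i]
            return float(-b / a)
    return float("nan")


@dataclass
class TTPMap:
    """3D map of t_ttp seconds; NaN outside the mask or where undefined."""

    ttp: np.ndarray
    a: np.ndarray | None = None  # interpolation slope per voxel
    b: np.ndarray | None = None  # interpolation intercept per voxel


def compute_ttp_map(series: CTPSeries, vessel_mask: np.ndarray,
                    filt: DoGFilter | None = None) -> TTPMap:
    """Vectorized per-voxel TTP over the vessel mask."""
    if vessel_mask.shape != series.shape:
        raise ValueError("vessel mask does not match series grid")
    if not vessel_mask.any():
        raise ValueError("vessel mask is empty")
    filt = filt or make_dog_filter()
    tacs = series.values[:, vessel_mask].astype(float)  # (T, N)
    v = filter_tac(tacs, filt)
    t = series.times
    T, N = v.shape

    imax = v.argmax(axis=0)
    uptake = v[imax, np.arange(N)] > 0
    # candidate crossing: v' <= 0 strictly after the uptake maximum
    after = np.arange(T)[:, None] > imax[None, :]
    crossing = (v <= 0) & after & uptake[None, :]
    has = crossing.any(axis=0)
    first = np.where(has, crossing.argmax(axis=0), 1)  # dummy 1 where undefined

    cols = np.arange(N)
    vi = v[first, cols]
    vim1 = v[first - 1, cols]
    ti = t[first]
    tim1 = t[first - 1]
    a = (vi - vim1) / (ti - tim1)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = vi - a * ti
        ttp_flat = np.where(a != 0, -b / a, ti)
    ttp_flat = np.where(has, ttp_flat, np.nan)
    a = np.where(has, a, np.nan)
    b = np.where(has, b, np.nan)

    ttp = np.full(series.shape, np.nan)
    amap = np.full(series.shape, np.nan)
    bmap = np.full(series.shape, np.nan)
    ttp[vessel_mask] = ttp_flat
    amap[vessel_mask] = a
    bmap[vessel_mask] = b
    return TTPMap(ttp=ttp, a=amap, b=bmap)


@dataclass
class AVThreshold:
    v_ttp: float
    bin_edges: np.ndarray
    counts: np.ndarray
    peak_bins: tuple
    valley_bin: int


def find_valley_threshold(ttpmap: TTPMap, n_bins: int | None = None,
                          n_frame_intervals: int | None = None) -> AVThreshold:
    """V_ttp: center of the lowest-count bin between the two main TTP modes.

    Bins default to 4x the number of frame intervals, uniform over the
    observed TTP range.  The two highest-prominence histogram peaks are the
    arterial and venous modes; ties in the valley go to the lower TTP,
    which is deterministic and favors venous sensitivity.
    """
    vals = ttpmap.ttp[np.isfinite(ttpmap.ttp)]
    if vals.size == 0:
        raise ValueError("TTP map has no defined values")
    if n_bins is None:
        n_bins = 4 * (n_frame_intervals if n_frame_intervals else 19)
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        raise ValueError("all TTP values identical; unimodal histogram — "
                         "set the artery/vein threshold manually")
    counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))

    padded = np.concatenate([[0], counts, [0]])  # lets find_peaks see edge modes
    # a mode must rise well clear of counting noise; small bumps on the
    # flank of a single mode do not make the histogram bimodal
    peaks, props = find_peaks(padded, prominence=0.1 * counts.max())
    if len(peaks) < 2:
        raise ValueError("TTP histogram is unimodal; cannot find a valley — "
                         "set the artery/vein threshold manually")
    order = np.argsort(props["prominences"])[::-1][:2]
    p0, p1 = sorted(int(padded_idx) - 1 for padded_idx in peaks[order])
    if p1 - p0 < 2:
        raise ValueError("TTP histogram peaks are adjacent; no valley between them — "
                         "set the artery/vein threshold manually")
    between = counts[p0 + 1 : p1]
    valley = p0 + 1 + int(np.argmin(between))  # argmin ties -> lowest TTP bin
    centers = 0.5 * (edges[:-1] + edges[1:])
    return AVThreshold(
        v_ttp=float(centers[valley]),
        bin_edges=edges,
        counts=counts,
        peak_bins=(p0, p1),
        valley_bin=valley,
    )


def separate_arteries_veins(ttpmap: TTPMap, vessel_mask: np.ndarray, v_ttp: float):
    """Split the vessel mask: artery TTP <= V_ttp < vein TTP.

    Vessel voxels whose TAC never peaks inside the scan window (TTP NaN,
    e.g. late-filling sinuses truncated by scan end) go to the vein mask —
    the latest possible arrival.
    """
    if not np.isfinite(v_ttp):
        raise ValueError("V_ttp must be finite")
    defined = np.isfinite(ttpmap.ttp)
    artery = vessel_mask & defined & (ttpmap.ttp <= v_ttp)
    vein = vessel_mask & (~defined | (ttpmap.ttp > v_ttp))
    return artery, vein


def angiographic_volumes(series: CTPSeries, artery_mask: np.ndarray, vein_mask: np.ndarray,
                         background_hu: float = -1024.0):
    """CTA/CTV display volumes: per-voxel temporal maximum HU inside each mask."""
    tmax = series.values.max(axis=0)
    cta = np.where(artery_mask, tmax, background_hu)
    ctv = np.where(vein_mask, tmax, background_hu)
    return cta, ctv
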