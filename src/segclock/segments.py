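"""Segment calls from a simulated kymograph.

The frozen region of the tissue carries an alternating-sign profile of frozen
cell state z; each maximal constant-sign run is a band, read as one segment.
Band boundaries are the zero crossings of frozen z, located by linear
interpolation between adjacent cells of the Lagrangian freeze record (the
binned grid is too coarse for the posterior-most bands, which are only a few
bins wide).

Coordinates: bands are bounded in the *material* coordinate — the conserved
relative coordinate rho for the distributed variant (lab width = d_rho * L(t),
so established bands widen as the tissue grows) and the fixed lab coordinate x
for the age variant (no advection, constant widths).  The ``rho_lo``/``rho_hi``
columns hold whichever applies.

The anterior-most sign run abuts the tissue edge rather than a zero crossing
and spans less than half a cycle of frozen phase; it is reported by
:func:`band_labels` but flagged incomplete, and excluded from establishment
statistics.  Likewise the posterior-most run, which the freezing front is
still traversing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Kymograph, domain_length

__all__ = [
    "SegmentTable",
    "InsufficientDataError",
    "band_labels",
    "segment_table",
    "first_segment_time",
    "establishment_widths",
    "width_growth",
]


class InsufficientDataError(ValueError):
    """Raised when too few bands exist for the requested statistic."""


@dataclass
class SegmentTable:
    """Established (complete) bands of one simulation.

    ``bands`` columns: band_index (1-based from the anterior), sign,
    t_established (time the band's posterior boundary froze), rho_lo / rho_hi
    (material-coordinate bounds), width_at_establishment (lab units).
    ``width_series`` maps band_index to a (time, width) DataFrame sampled at
    the kymograph times from establishment onward.
    """

    bands: pd.DataFrame
    width_series: dict[int, pd.DataFrame]
    variant: str

    def to_csv(self, path) -> None:
        cols = ["band_index", "sign", "t_established", "rho_lo", "rho_hi",
                "width_at_establishment"]
        self.bands[cols].to_csv(path, index=False)


def _frozen_profile(kymo: Kymograph, t: float | None = None):
    """(material coordinate, z_frozen, freeze_time) of cells frozen by time t."""
    if t is None:
        t = float(kymo.times[-1])
    frozen = kymo.cell_freeze_time <= t
    if kymo.params.variant == "distributed_distance":
        m = kymo.cell_rho[frozen]
    else:
        m = kymo.cell_x[frozen]
    return m, kymo.cell_z_frozen[frozen], kymo.cell_freeze_time[frozen]


def _runs(m: np.ndarray, z: np.ndarray):
    """Sign runs of z over the ordered coordinate m.

    Returns a list of dicts with sign, lo, hi (interpolated zero-crossing
    coordinates; tissue edge / front for the outer runs) and the index range.
    """
    s = np.sign(z)
    s[s == 0] = 1  # measure-zero tie: fold exact zeros into the positive side
    change = np.nonzero(np.diff(s))[0]  # crossing between i and i+1
    cross = m[change] + (m[change + 1] - m[change]) * z[change] / (z[change] - z[change + 1])
    bounds = np.concatenate([[m[0]], cross, [m[-1]]])
    starts = np.concatenate([[0], change + 1])
    runs = []
    for k, i0 in enumerate(starts):
        runs.append(
            {
                "sign": int(s[i0]),
                "lo": float(bounds[k]),
                "hi": float(bounds[k + 1]),
                "complete": 0 < k < len(starts) - 1,
                "i0": int(i0),
            }
        )
    return runs


def band_labels(kymo: Kymograph, t: float) -> pd.DataFrame:
    """Bands of the frozen prefix at time ``t``, anterior to posterior.

    Columns: band_index, sign, rho_lo, rho_hi, width (lab units at ``t``),
    complete (both boundaries are zero crossings).  Empty when nothing has
    frozen.
    """
    if not (kymo.times[0] <= t <= kymo.times[-1]):
        raise ValueError("t outside the kymograph's time range")
    m, z, _ = _frozen_profile(kymo, t)
    cols = ["band_index", "sign", "rho_lo", "rho_hi", "width", "complete"]
    if m.size < 2:
        return pd.DataFrame(columns=cols)
    scale = domain_length(t, kymo.params) if kymo.params.variant == "distributed_distance" else 1.0
    rows = [
        (k + 1, r["sign"], r["lo"], r["hi"], (r["hi"] - r["lo"]) * scale, r["complete"])
        for k, r in enumerate(_runs(m, z))
    ]
    return pd.DataFrame(rows, columns=cols)


def segment_table(kymo: Kymograph) -> SegmentTable:
    """All complete bands with establishment times and width trajectories.

    A band is established when the freezing front passes its posterior
    boundary; that time is interpolated from the per-cell freeze times at the
    boundary coordinate.  Width at time t is ``(rho_hi - rho_lo) * L(t)`` for
    the distributed variant (material interval rescaled by growth) and the
    constant lab interval for the age variant.
    """
    p = kymo.params
    m, z, ft = _frozen_profile(kymo)
    if m.size < 2:
        return SegmentTable(
            bands=pd.DataFrame(
                columns=["band_index", "sign", "t_established", "rho_lo", "rho_hi",
                         "width_at_establishment"]
            ),
            width_series={},
            variant=p.variant,
        )
    runs = [r for r in _runs(m, z) if r["complete"]]
    distributed = p.variant == "distributed_distance"
    # freeze time as a function of the material coordinate (monotone along m:
    # increasing in x for the age variant, increasing in rho for distributed)
    rows, series = [], {}
    for k, r in enumerate(runs):
        t_est = float(np.interp(r["hi"], m, ft))
        d_m = r["hi"] - r["lo"]
        w_est = d_m * (domain_length(t_est, p) if distributed else 1.0)
        idx = k + 1
        rows.append((idx, r["sign"], t_est, r["lo"], r["hi"], w_est))
        tt = kymo.times[kymo.times >= t_est]
        ww = d_m * (domain_length(tt, p) if distributed else np.ones_like(tt))
        series[idx] = pd.DataFrame({"time": tt, "width": ww})
    bands = pd.DataFrame(
        rows,
        columns=["band_index", "sign", "t_established", "rho_lo", "rho_hi",
                 "width_at_establishment"],
    )
    return SegmentTable(bands=bands, width_series=series, variant=p.variant)


def first_segment_time(kymo: Kymograph) -> float:
    """Time at which the frozen region first spans one full oscillation cycle.

    The frozen-phase span grows as the front advances; the first segment is
    called established when that span reaches 2*pi.  Returns ``math.inf`` if
    it never does within the simulated horizon.
    """
    frozen = ~np.isnan(kymo.cell_freeze_time)
    if not np.any(frozen):
        return math.inf
    ft = kymo.cell_freeze_time[frozen]
    fp = kymo.cell_freeze_phase[frozen]
    order = np.argsort(ft)
    ft, fp = ft[order], fp[order]
    span = np.maximum.accumulate(fp) - np.minimum.accumulate(fp)
    hit = span >= 2.0 * np.pi
    if not np.any(hit):
        return math.inf
    return float(ft[np.argmax(hit)])


def establishment_widths(table: SegmentTable) -> np.ndarray:
    """Widths at establishment, ordered anterior to posterior."""
    if len(table.bands) < 2:
        raise InsufficientDataError("need at least 2 established bands")
    return table.bands.sort_values("band_index")["width_at_establishment"].to_numpy()


def width_growth(table: SegmentTable, band_index: int) -> pd.DataFrame:
    """The (time, width) trajectory of one established band."""
    if band_index not in table.width_series:
        raise KeyError(f"no established band with index {band_index}")
    return table.width_series[band_index]
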