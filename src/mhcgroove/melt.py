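"""Melting-temperature extraction from thermal-denaturation curves.

Dye-based thermal shift assays record fluorescence against a temperature
ramp; the melting temperature Tm is read from the extremum of the first
derivative of the (replicate-averaged, lightly smoothed) curve — the minimum
by default, matching a descending fluorescence transition, with the maximum
available for ascending-signal conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


class MeltError(ValueError):
    """Raised for malformed curves or absent interior transitions."""


@dataclass
class MeltCurve:
    """Temperature grid (°C, strictly increasing) and fluorescence (a.u.).

    ``fluorescence`` may be 1-D or (replicates, points); replicates are
    averaged pointwise before analysis.
    """

    temperatures: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.atleast_2d(np.asarray(self.fluorescence, dtype=float))
        if self.temperatures.size < 10:
            raise MeltError("need >= 10 temperature points")
        if not np.all(np.diff(self.temperatures) > 0):
            raise MeltError("temperature grid must be strictly increasing")
        if self.fluorescence.shape[-1] != self.temperatures.size:
            raise MeltError("fluorescence length does not match temperature grid")

    @classmethod
    def from_table(cls, path: str | Path) -> "MeltCurve":
        """Read a two-plus-column TSV/CSV: temperature, then replicate columns."""
        sep = "," if str(path).endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep, comment="#")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1:].to_numpy().T)


@dataclass(frozen=True)
class MeltResult:
    tm: float  # °C
    derivative_extremum: float  # dF/dT at Tm
    smoothing_window: int
    extremum: str
    local_extrema: tuple[float, ...] = ()  # all interior local extrema (°C)


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    # centered, truncated at the edges
    csum = np.concatenate(([0.0], np.cumsum(y)))
    half = window // 2
    n = y.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _parabolic_vertex(temps: np.ndarray, s: np.ndarray, idx: int) -> float:
    """Refine the minimum of ``s`` at index ``idx`` by parabolic interpolation.

    A least-squares parabola is fit over the contiguous neighbourhood where
    ``s`` stays below half its extremal depth — for a symmetric transition
    this region is symmetric about the true inflection, so the vertex is an
    unbiased, noise-robust refinement.  Degenerate fits fall back to the
    three-point parabola through the extremum and its neighbours.
    """
    half = s[idx] / 2.0
    lo = idx
    while lo > 0 and s[lo - 1] <= half:
        lo -= 1
    hi = idx
    while hi < s.size - 1 and s[hi + 1] <= half:
        hi += 1
    if hi - lo >= 4:
        coef = np.polyfit(temps[lo : hi + 1], s[lo : hi + 1], 2)
        if coef[0] > 0:
            vertex = -coef[1] / (2.0 * coef[0])
            if temps[lo] <= vertex <= temps[hi]:
                return float(vertex)
    x0, x1, x2 = temps[idx - 1 : idx + 2]
    y0, y1, y2 = s[idx - 1 : idx + 2]
    denom = y0 - 2 * y1 + y2
    if denom > 0:
        return float(x1 + 0.5 * (x1 - x0) * (y0 - y2) / denom)
    return float(x1)


def melting_temperature(
    curve: MeltCurve, smoothing_window: int = 11, extremum: str = "min"
) -> MeltResult:
    """Tm from the first-derivative extremum of a denaturation curve.

    Replicates are averaged pointwise; the averaged curve is smoothed by a
    centered moving average; the derivative comes from central differences;
    Tm is the temperature of the selected derivative extremum, refined by
    parabolic interpolation over the extremum and its two neighbours.  An
    extremum on the grid boundary or a flat derivative is an error.
    """
    if smoothing_window < 3 or smoothing_window % 2 == 0:
        raise MeltError("smoothing window must be odd and >= 3")
    if extremum not in ("min", "max"):
        raise MeltError("extremum must be 'min' or 'max'")
    temps = curve.temperatures
    f = curve.fluorescence.mean(axis=0)
    f_s = _moving_average(f, smoothing_window)
    # smoothing the central-difference derivative with the same window keeps
    # the extremum location unbiased for a symmetric transition while
    # suppressing grid-scale noise that would dominate the argmin
    dfdt = _moving_average(np.gradient(f_s, temps), smoothing_window)
    span = float(np.ptp(dfdt))
    scale = max(float(np.max(np.abs(dfdt))), np.finfo(float).tiny)
    if span < 1e-9 * scale or span == 0.0:
        raise MeltError("flat curve: derivative has no extremum")
    sign = 1.0 if extremum == "min" else -1.0
    s = sign * dfdt  # extremum becomes a minimum of s
    idx = int(np.argmin(s))
    if idx == 0 or idx == temps.size - 1:
        raise MeltError("no interior transition: derivative extremum at boundary")
    tm = _parabolic_vertex(temps, s, idx)
    # enumerate interior local extrema of the matching sense
    interior = np.arange(1, temps.size - 1)
    local = interior[(s[interior] <= s[interior - 1]) & (s[interior] <= s[interior + 1])]
    # collapse plateaus to single representatives
    local_temps = tuple(
        float(temps[i]) for j, i in enumerate(local) if j == 0 or local[j] > local[j - 1] + 1
    )
    return MeltResult(
        tm=tm,
        derivative_extremum=float(dfdt[idx]),
        smoothing_window=smoothing_window,
        extremum=extremum,
        local_extrema=local_temps,
    )
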