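"""Terminal-amino-group rotation analysis via the dihedral ω.

The orientation of a bound peptide's terminal amino group in the A pocket is
tracked by the torsion ω over the four atoms Cys76:CA - P7:CA - P1:CA - P1:N.
Negative ω (≈ -110°/-73° in the long-peptide crystal structures) means the
amino group points up out of the pocket; positive ω (≈ 96°/98° in the native
8mer structures) means it points down canonically.

Time series of ω from relaxation simulations are unwrapped (each step
adjusted by a multiple of 360° so consecutive changes stay below 180°),
smoothed with a centered sliding-average window (10 ns default), and scanned
for rotation events: excursions from a start band (≈ -100°) to an end band
(≈ +100°, modulo 360°, so an unwrapped -260° endpoint counts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .structure_io import PeptidePositionMap, StructureModel

logger = logging.getLogger("mhcgroove")


class RotationError(ValueError):
    """Raised for degenerate dihedral geometry or wrap-state misuse."""


@dataclass(frozen=True)
class DihedralSpec:
    """Four atom references (chain, resnum, atom name) defining a torsion."""

    atoms: tuple[tuple[str, int, str], ...]

    def __post_init__(self) -> None:
        if len(self.atoms) != 4 or len(set(self.atoms)) != 4:
            raise RotationError("a dihedral needs four distinct atoms")


@dataclass
class AngleSeries:
    """Time-stamped angle values (deg) with explicit wrap state."""

    times_ps: np.ndarray
    values_deg: np.ndarray
    wrapped: bool

    def __post_init__(self) -> None:
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        self.values_deg = np.asarray(self.values_deg, dtype=float)
        if self.times_ps.shape != self.values_deg.shape:
            raise RotationError("times and values must have equal length")
        if self.wrapped and (
            np.any(self.values_deg <= -180.0) or np.any(self.values_deg > 180.0)
        ):
            raise RotationError("wrapped values must lie in (-180, 180]")


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed torsion angle (deg) in (-180, 180], IUPAC sign convention."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    for a, b in ((p1, p2), (p2, p3), (p3, p4)):
        if np.linalg.norm(b - a) < 1e-9:
            raise RotationError("coincident consecutive points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise RotationError("collinear points: torsion undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = -float(np.degrees(np.arctan2(y, x)))  # IUPAC sign
    return 180.0 if ang <= -180.0 else ang


def omega_spec(positions: PeptidePositionMap, cys_anchor: int = 76) -> DihedralSpec:
    """The ω dihedral atoms: Cys76:CA, P7:CA, P1:CA, P1:N."""
    h, p = positions.heavy_chain, positions.peptide_chain
    return DihedralSpec(
        atoms=(
            (h, cys_anchor, "CA"),
            (p, positions.p7, "CA"),
            (p, positions.p1, "CA"),
            (p, positions.p1, "N"),
        )
    )


def omega_dihedral(model: StructureModel, positions: PeptidePositionMap) -> float:
    """Crystal-state ω (deg) of one structure."""
    spec = omega_spec(positions)
    pts = [model.atom(*ref).xyz for ref in spec.atoms]
    return dihedral(*pts)


def wrap_angles(values_deg: np.ndarray) -> np.ndarray:
    """Map angles into (-180, 180]."""
    v = np.asarray(values_deg, dtype=float)
    out = ((-v + 180.0) % 360.0)
    return -(out - 180.0)


def unwrap(series: AngleSeries) -> AngleSeries:
    """Remove 360° wrap discontinuities from a wrapped angle series.

    Each value after the first is adjusted by a multiple of 360° so that the
    change from its predecessor is below 180° in magnitude; the output equals
    the input modulo 360° at every sample.  A frame-to-frame change of
    exactly 180° is ambiguous and resolved toward no adjustment (logged).
    """
    if not series.wrapped:
        raise RotationError("series is already unwrapped")
    v = series.values_deg
    if v.size == 0:
        return AngleSeries(series.times_ps.copy(), v.copy(), wrapped=False)
    d = np.diff(v)
    if np.any(np.abs(np.abs(d) - 180.0) < 1e-12):
        logger.info("unwrap: 180° step encountered; keeping the unadjusted branch")
    # k = round(d/360) maps each step into [-180, 180]; numpy's half-to-even
    # rounding leaves an exact ±180° step unadjusted (fewest adjustments)
    k = np.round(d / 360.0)
    adj = d - 360.0 * k
    out = np.concatenate(([v[0]], v[0] + np.cumsum(adj)))
    return AngleSeries(series.times_ps.copy(), out, wrapped=False)


def smooth(series: AngleSeries, window_ns: float = 10.0) -> AngleSeries:
    """Centered sliding-average smoothing over ± window/2.

    Refuses wrapped input (averaging across a ±180° seam corrupts values;
    unwrap first).  Edge samples use the truncated window.
    """
    if series.wrapped:
        raise RotationError("unwrap first: smoothing wrapped angles is refused")
    t = series.times_ps
    if t.size > 1 and window_ns * 1000.0 > (t[-1] - t[0]):
        raise RotationError("smoothing window exceeds the series duration")
    half = window_ns * 1000.0 / 2.0  # ps
    v = series.values_deg
    left = np.searchsorted(t, t - half, side="left")
    right = np.searchsorted(t, t + half, side="right")
    csum = np.concatenate(([0.0], np.cumsum(v)))
    out = (csum[right] - csum[left]) / (right - left)
    return AngleSeries(t.copy(), out, wrapped=False)


def _circ_dist(a: np.ndarray | float, b: float) -> np.ndarray | float:
    """Smallest absolute angular separation, modulo 360°."""
    return np.abs((np.asarray(a) - b + 180.0) % 360.0 - 180.0)


def detect_rotation(
    series: AngleSeries,
    start_deg: float = -100.0,
    end_deg: float = 100.0,
    tolerance_deg: float = 45.0,
    dwell_ns: float = 1.0,
) -> list[float]:
    """Times (ps) of rotation events in a smoothed, unwrapped ω series.

    An event is registered the first time the series, having dwelt in the
    start band (start ± tolerance, modulo 360°) for at least ``dwell_ns``,
    comes within tolerance of the end value modulo 360° — so an unwrapped
    trace ending at -260° triggers the +100° end band.  After an event the
    detector re-arms only after a fresh dwell in the start band, allowing
    multiple events.
    """
    if series.wrapped:
        raise RotationError("detect_rotation needs an unwrapped (smoothed) series")
    t, v = series.times_ps, series.values_deg
    in_start = _circ_dist(v, start_deg) <= tolerance_deg
    in_end = _circ_dist(v, end_deg) <= tolerance_deg
    events: list[float] = []
    dwell_ps = dwell_ns * 1000.0
    dwell_accum = 0.0
    armed = False
    for i in range(v.size):
        dt = (t[i] - t[i - 1]) if i > 0 else 0.0
        if in_start[i]:
            dwell_accum += dt
            if dwell_accum >= dwell_ps:
                armed = True
        elif not in_end[i]:
            dwell_accum = 0.0
        if armed and in_end[i]:
            events.append(float(t[i]))
            armed = False
            dwell_accum = 0.0
    return events
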