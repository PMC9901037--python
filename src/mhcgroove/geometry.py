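"""Interaction geometry between peptide P1 and groove residues Tyr59 / Ile52.

Implements the four inter-residue distance definitions used for the
equilibrium-ensemble analysis:

* Phe P1 - Tyr59: distance between the geometric centers of the two aromatic
  rings, plus the angle between the ring normals (π-π orientation);
* Ala P1 - Tyr59: P1 Cβ to the Tyr59 ring center;
* Phe P1 - Ile52: P1 ring center to Ile52 Cδ;
* Ala P1 - Ile52: P1 Cβ to Ile52 Cδ;

together with the C-H-X angle of the CH-π criterion (Cδ, its bonded
hydrogen, and the Phe ring center X), a boolean CH-π test (distance AND
angle cutoffs), π-π stacking classification (T-shaped / parallel-like /
intermediate from the folded normal-normal angle), and histogram-based
probability distributions with peak and FWHM.

Ring normals follow the right-hand rule over the ordered ring atom sequence,
so their sign is reproducible; orientation angles are reported unfolded in
[0°, 180°] and folded to [0°, 90°] only inside classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import PeptidePositionMap
from .trajectory import Trajectory

#: Six-membered aromatic ring atoms in cyclic order (PHE and TYR).
AROMATIC_RING_ATOMS: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),
    "TYR": ("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),
}

#: Maximum tolerated out-of-plane deviation (Å) before a ring is flagged.
RING_PLANARITY_TOL = 0.5


class GeometryError(ValueError):
    """Raised for unresolvable or degenerate geometric constructions."""


@dataclass(frozen=True)
class RingSpec:
    """An aromatic ring: residue reference plus ordered ring atom names."""

    chain: str
    resnum: int
    resname: str = "PHE"
    atom_names: tuple[str, ...] = AROMATIC_RING_ATOMS["PHE"]


@dataclass(frozen=True)
class CHPiCriteria:
    """CH-π geometric criterion: ring-center distance and C-H-X angle cutoffs.

    Defaults (6.0 Å, 120°) place the reported interacting geometries
    (~5 Å, 120-150°) inside and the non-interacting ~10 Å ensembles outside.
    """

    max_distance: float = 6.0
    min_angle: float = 120.0


@dataclass
class InteractionSeries:
    """Per-frame distance (Å) and optional orientation angle (deg)."""

    times: np.ndarray
    distances: np.ndarray
    angles: np.ndarray | None
    definition: str

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.distances) <= 0):
            raise GeometryError("distances must be positive")


@dataclass
class Distribution:
    """Normalized histogram density with peak location and FWHM."""

    bin_edges: np.ndarray
    density: np.ndarray
    peak: float
    fwhm: float


def _ring_coords(atoms: dict[str, np.ndarray], ring: RingSpec) -> np.ndarray:
    present = [atoms[n] for n in ring.atom_names if n in atoms]
    if len(present) < 5:
        raise GeometryError(
            f"ring {ring.chain}/{ring.resnum}: only {len(present)} of "
            f"{len(ring.atom_names)} ring atoms present (need >= 5)"
        )
    return np.asarray(present)


def ring_center(atoms: dict[str, np.ndarray], ring: RingSpec) -> np.ndarray:
    """Unweighted mean position of the ring atoms."""
    return _ring_coords(atoms, ring).mean(axis=0)


def ring_normal(atoms: dict[str, np.ndarray], ring: RingSpec) -> np.ndarray:
    """Unit normal of the best-fit ring plane with a reproducible sign.

    The plane is fit by SVD; the sign follows the right-hand rule over the
    ordered atom sequence (Newell polygon normal), so an atom order reversal
    flips the normal.
    """
    coords = _ring_coords(atoms, ring)
    centered = coords - coords.mean(axis=0)
    u, s, vt = np.linalg.svd(centered)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise GeometryError("ring atoms are collinear; no plane defined")
    normal = vt[2]
    if s[2] > RING_PLANARITY_TOL:
        import logging

        logging.getLogger("mhcgroove").warning(
            "ring %s/%d deviates from planarity (%.2f Å)", ring.chain, ring.resnum, s[2]
        )
    newell = np.zeros(3)
    n = len(coords)
    for i in range(n):
        newell += np.cross(coords[i], coords[(i + 1) % n])
    if np.dot(normal, newell) < 0:
        normal = -normal
    return normal / np.linalg.norm(normal)


def _vec_angle(u: np.ndarray, v: np.ndarray) -> float:
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def p1_interaction_series(
    traj: Trajectory,
    positions: PeptidePositionMap,
    partner: str,
    tyr59: int = 59,
    ile52: int = 52,
) -> InteractionSeries:
    """Per-frame P1 <-> Tyr59/Ile52 distance (and orientation) series.

    The atom-pair rule is picked from the P1 residue type:

    ========  ========  =============================================
    P1        partner   distance definition
    ========  ========  =============================================
    PHE       Tyr59     ring center - ring center (+ normal-normal angle)
    ALA       Tyr59     P1 Cβ - Tyr59 ring center
    PHE       Ile52     P1 ring center - Ile52 Cδ
    ALA       Ile52     P1 Cβ - Ile52 Cδ
    ========  ========  =============================================
    """
    if partner not in ("Tyr59", "Ile52"):
        raise GeometryError(f"partner must be 'Tyr59' or 'Ile52', got {partner!r}")
    p1_num = positions.p1
    pch, hch = positions.peptide_chain, positions.heavy_chain
    p1_name = next(
        (r.resname for r in traj.topology if r.chain == pch and r.resnum == p1_num),
        None,
    )
    if p1_name not in ("PHE", "ALA"):
        raise GeometryError(
            f"unsupported P1 residue {p1_name!r}: supported types are PHE, ALA"
        )

    def res_atoms(frame: int, chain: str, resnum: int) -> dict[str, np.ndarray]:
        return {
            rec.name: traj.coordinates[frame, i]
            for i, rec in enumerate(traj.topology)
            if rec.chain == chain and rec.resnum == resnum
        }

    n = traj.n_frames
    distances = np.empty(n)
    angles: np.ndarray | None = None
    if p1_name == "PHE":
        p1_ring = RingSpec(pch, p1_num, "PHE")
    if partner == "Tyr59":
        tyr_ring = RingSpec(hch, tyr59, "TYR", AROMATIC_RING_ATOMS["TYR"])
        if p1_name == "PHE":
            angles = np.empty(n)
            definition = "ring_center(PheP1)-ring_center(Tyr59) + normal-normal angle"
        else:
            definition = "CB(AlaP1)-ring_center(Tyr59)"
        for f in range(n):
            tatoms = res_atoms(f, hch, tyr59)
            tcen = ring_center(tatoms, tyr_ring)
            patoms = res_atoms(f, pch, p1_num)
            if p1_name == "PHE":
                pcen = ring_center(patoms, p1_ring)
                distances[f] = np.linalg.norm(pcen - tcen)
                angles[f] = _vec_angle(
                    ring_normal(patoms, p1_ring), ring_normal(tatoms, tyr_ring)
                )
            else:
                if "CB" not in patoms:
                    raise GeometryError(f"P1 Ala has no CB atom in frame {f}")
                distances[f] = np.linalg.norm(patoms["CB"] - tcen)
    else:
        definition = (
            "ring_center(PheP1)-CD1(Ile52)" if p1_name == "PHE" else "CB(AlaP1)-CD1(Ile52)"
        )
        for f in range(n):
            iatoms = res_atoms(f, hch, ile52)
            if "CD1" not in iatoms:
                raise GeometryError(f"Ile52 has no CD1 atom in frame {f}")
            cd = iatoms["CD1"]
            patoms = res_atoms(f, pch, p1_num)
            if p1_name == "PHE":
                distances[f] = np.linalg.norm(ring_center(patoms, p1_ring) - cd)
            else:
                if "CB" not in patoms:
                    raise GeometryError(f"P1 Ala has no CB atom in frame {f}")
                distances[f] = np.linalg.norm(patoms["CB"] - cd)
    return InteractionSeries(
        times=traj.times.copy(), distances=distances, angles=angles, definition=definition
    )


def _ideal_methyl_hydrogens(cd: np.ndarray, cg: np.ndarray) -> list[np.ndarray]:
    # three H at ideal tetrahedral geometry on a methyl carbon: 1.09 Å bonds,
    # 109.47° from the Cγ-Cδ axis, arbitrary but deterministic azimuth
    axis = cd - cg
    axis = axis / np.linalg.norm(axis)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, axis)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    perp1 = np.cross(axis, seed)
    perp1 /= np.linalg.norm(perp1)
    perp2 = np.cross(axis, perp1)
    theta = np.radians(180.0 - 109.47)  # from +axis direction
    out = []
    for k in range(3):
        phi = 2 * np.pi * k / 3
        direction = np.cos(theta) * axis + np.sin(theta) * (
            np.cos(phi) * perp1 + np.sin(phi) * perp2
        )
        out.append(cd + 1.09 * direction)
    return out


def ch_pi_angle(
    donor_atoms: dict[str, np.ndarray],
    ring_atoms: dict[str, np.ndarray],
    ring: RingSpec,
    construct_h: bool = True,
) -> float:
    """C-H-X angle (deg): Ile52 Cδ, its bonded hydrogen, the ring center X.

    Uses an explicit hydrogen bonded to Cδ when present (the one pointing
    closest to the ring); otherwise, if ``construct_h``, builds ideal
    tetrahedral methyl hydrogens on Cδ and uses the one nearest the ring
    center (crystal structures carry no hydrogens).
    """
    if "CD1" not in donor_atoms:
        raise GeometryError("donor residue has no CD1 (Cδ) atom")
    cd = donor_atoms["CD1"]
    x = ring_center(ring_atoms, ring)
    hydrogens = [
        pos
        for name, pos in donor_atoms.items()
        if name.startswith("HD1") and np.linalg.norm(pos - cd) < 1.3
    ]
    if not hydrogens:
        if not construct_h:
            raise GeometryError("no hydrogen on Cδ and construction disabled")
        if "CG1" not in donor_atoms:
            raise GeometryError("cannot construct H: no CG1 atom to define the axis")
        hydrogens = _ideal_methyl_hydrogens(cd, donor_atoms["CG1"])
    h = min(hydrogens, key=lambda p: float(np.linalg.norm(p - x)))
    return _vec_angle(cd - h, x - h)


def ch_pi_satisfied(
    distance: float, angle: float, criteria: CHPiCriteria | None = None
) -> bool:
    """CH-π test: distance <= cutoff AND angle >= cutoff."""
    crit = criteria or CHPiCriteria()
    if not (np.isfinite(distance) and np.isfinite(angle)):
        raise GeometryError("distance and angle must be finite")
    return distance <= crit.max_distance and angle >= crit.min_angle


@dataclass
class PiPiClassification:
    label: str  # "T-shaped" | "parallel-like" | "intermediate"
    peak_deviation: float  # peak of folded stacking deviation s, degrees
    deviations: np.ndarray = field(repr=False)


def classify_pi_pi(
    angle_samples: np.ndarray,
    t_shaped_min: float = 60.0,
    parallel_max: float = 30.0,
    bin_width: float = 5.0,
) -> PiPiClassification:
    """Classify a π-π orientation ensemble from normal-normal angle samples.

    Each sample θ folds to the stacking deviation s = min(θ, 180° - θ) in
    [0°, 90°] (ring planes have no head/tail).  Classification uses the peak
    of the s distribution: s >= 60° is T-shaped (perpendicular rings),
    s <= 30° parallel-like, otherwise intermediate.
    """
    samples = np.asarray(angle_samples, dtype=float)
    if samples.size == 0:
        raise GeometryError("no angle samples")
    s = np.minimum(samples % 180.0, 180.0 - (samples % 180.0))
    if samples.size == 1:
        peak = float(s[0])
        resolution = 0.0
    else:
        dist = estimate_distribution(s, bin_width)
        peak = dist.peak
        resolution = bin_width / 2.0  # the peak is only located to half a bin
    if peak >= t_shaped_min - resolution:
        label = "T-shaped"
    elif peak <= parallel_max + resolution:
        label = "parallel-like"
    else:
        label = "intermediate"
    return PiPiClassification(label=label, peak_deviation=peak, deviations=s)


def estimate_distribution(samples: np.ndarray, bin_width: float) -> Distribution:
    """Density-normalized histogram with peak (center of maximal bin, ties to
    the lowest value) and full width at half maximum (linear interpolation
    around the peak's contiguous above-half-max region)."""
    if bin_width <= 0:
        raise GeometryError("bin width must be positive")
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise GeometryError("need >= 2 samples")
    lo, hi = samples.min(), samples.max()
    if hi == lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    if edges[-1] < hi:
        edges = np.append(edges, edges[-1] + bin_width)
    density, edges = np.histogram(samples, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    imax = int(np.argmax(density))  # argmax takes the first (lowest) max bin
    peak = float(centers[imax])
    half = density[imax] / 2.0
    # walk outward from the peak to the half-max crossings
    left = imax
    while left > 0 and density[left - 1] >= half:
        left -= 1
    right = imax
    while right < len(density) - 1 and density[right + 1] >= half:
        right += 1

    def _interp(i_in: int, i_out: int) -> float:
        d_in, d_out = density[i_in], density[i_out]
        if d_in == d_out:
            return float(centers[i_in])
        frac = (d_in - half) / (d_in - d_out)
        return float(centers[i_in] + frac * (centers[i_out] - centers[i_in]))

    x_left = _interp(left, left - 1) if left > 0 else float(edges[0])
    x_right = _interp(right, right + 1) if right < len(density) - 1 else float(edges[-1])
    return Distribution(
        bin_edges=edges, density=density, peak=peak, fwhm=float(x_right - x_left)
    )


def peak_location(distribution: Distribution) -> float:
    """Peak of a distribution (center of its maximal bin)."""
    return distribution.peak
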