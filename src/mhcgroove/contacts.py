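"""Hydrogen-bond and hydrophobic-contact networks around the A/B pockets.

Crystal structures usually carry no hydrogen positions, so hydrogen bonds are
judged donor-acceptor distance-first (<= 3.5 Å by default) with the
donor-H-acceptor angle test applied only when hydrogens exist.  Hydrophobic
contacts are carbon-carbon pairs within a distance cutoff (4.5 Å default),
reported once per residue pair at the minimum distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .structure_io import Atom, AtomSelector, StructureModel

logger = logging.getLogger("mhcgroove")

# donor / acceptor heavy atoms for the 20 standard residues; backbone handled
# separately (N donor except PRO, O/OXT acceptor)
_SIDECHAIN_DONORS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TRP": ("NE1",),
    "TYR": ("OH",),
    "CYS": ("SG",),
}
_SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "MET": ("SD",),
}
_STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


@dataclass(frozen=True)
class ContactCriteria:
    """Geometric cutoffs for contact detection."""

    hbond_max_dist: float = 3.5  # donor-acceptor, Å
    hbond_min_angle: float = 120.0  # donor-H-acceptor, degrees
    hydrophobic_max_dist: float = 4.5  # carbon-carbon, Å

    def __post_init__(self) -> None:
        if min(self.hbond_max_dist, self.hydrophobic_max_dist) <= 0:
            raise ValueError("distance cutoffs must be positive")
        if not 0 < self.hbond_min_angle <= 180:
            raise ValueError("angle cutoff must be in (0, 180]")


@dataclass(frozen=True)
class Contact:
    kind: str  # "hbond" | "hydrophobic"
    atom_a: tuple[str, int, str]  # (chain, resnum, atom name)
    atom_b: tuple[str, int, str]
    distance: float
    angle: float | None = None


def _is_donor(atom: Atom) -> bool:
    if atom.resname not in _STANDARD_RESIDUES:
        logger.warning("skipping non-standard residue %s", atom.resname)
        return False
    if atom.name == "N" and atom.resname != "PRO":
        return True
    return atom.name in _SIDECHAIN_DONORS.get(atom.resname, ())


def _is_acceptor(atom: Atom) -> bool:
    if atom.resname not in _STANDARD_RESIDUES:
        return False
    if atom.name in ("O", "OXT"):
        return True
    return atom.name in _SIDECHAIN_ACCEPTORS.get(atom.resname, ())


def _bonded_hydrogens(model: StructureModel, donor: Atom) -> list[np.ndarray]:
    out = []
    for name, pos in model.residue_atoms(donor.chain, donor.resnum).items():
        if name.startswith(("H", "1H", "2H", "3H")):
            if float(np.linalg.norm(pos - donor.xyz)) < 1.3:
                out.append(pos)
    return out


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    u, v = a - vertex, b - vertex
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _canonical(pair: tuple[Contact, ...] | Contact) -> Contact:
    c = pair
    if c.atom_b < c.atom_a:
        return Contact(c.kind, c.atom_b, c.atom_a, c.distance, c.angle)
    return c


def find_hbonds(
    model: StructureModel,
    selector_a: AtomSelector,
    selector_b: AtomSelector,
    criteria: ContactCriteria | None = None,
) -> list[Contact]:
    """Donor-acceptor pairs across two selections within the H-bond criteria.

    The angle test (donor-H-acceptor >= ``hbond_min_angle``) applies only
    when hydrogen positions are present; otherwise distance alone decides,
    which is the practical rule for crystal structures.  Sorted by distance;
    partner order is canonicalised so the result is symmetric in
    (selector_a, selector_b).
    """
    crit = criteria or ContactCriteria()
    sel_a, sel_b = selector_a.resolve(model), selector_b.resolve(model)
    found: dict[tuple, Contact] = {}
    for donors, acceptors in ((sel_a, sel_b), (sel_b, sel_a)):
        for d in donors:
            if not _is_donor(d):
                continue
            hydrogens = _bonded_hydrogens(model, d)
            for a in acceptors:
                if not _is_acceptor(a):
                    continue
                if (d.chain, d.resnum) == (a.chain, a.resnum):
                    continue
                dist = float(np.linalg.norm(d.xyz - a.xyz))
                if dist > crit.hbond_max_dist:
                    continue
                angle: float | None = None
                if hydrogens:
                    angle = max(_angle_deg(d.xyz, h, a.xyz) for h in hydrogens)
                    if angle < crit.hbond_min_angle:
                        continue
                c = _canonical(
                    Contact(
                        "hbond",
                        (d.chain, d.resnum, d.name),
                        (a.chain, a.resnum, a.name),
                        dist,
                        angle,
                    )
                )
                key = (c.atom_a, c.atom_b)
                if key not in found or found[key].distance > dist:
                    found[key] = c
    return sorted(found.values(), key=lambda c: c.distance)


def find_hydrophobic_contacts(
    model: StructureModel,
    selector_a: AtomSelector,
    selector_b: AtomSelector,
    criteria: ContactCriteria | None = None,
) -> list[Contact]:
    """Carbon-carbon contacts within the hydrophobic cutoff.

    Deduplicated per residue pair, keeping the closest atom pair.
    """
    crit = criteria or ContactCriteria()
    carbons_a = [a for a in selector_a.resolve(model) if a.name.startswith("C")]
    carbons_b = [a for a in selector_b.resolve(model) if a.name.startswith("C")]
    best: dict[tuple, Contact] = {}
    for x in carbons_a:
        for y in carbons_b:
            if (x.chain, x.resnum) == (y.chain, y.resnum):
                continue
            dist = float(np.linalg.norm(x.xyz - y.xyz))
            if dist > crit.hydrophobic_max_dist:
                continue
            c = _canonical(
                Contact(
                    "hydrophobic",
                    (x.chain, x.resnum, x.name),
                    (y.chain, y.resnum, y.name),
                    dist,
                )
            )
            key = (c.atom_a[:2], c.atom_b[:2])
            if key not in best or best[key].distance > dist:
                best[key] = c
    return sorted(best.values(), key=lambda c: c.distance)
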