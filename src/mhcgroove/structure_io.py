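"""Structure reading/writing, atom selection, and unmodeled-region detection.

The crystal structures analysed here are peptide-MHC class I complexes in
which stretches of the heavy-chain groove can be crystallographically
disordered (no interpretable electron density).  This module represents a
structure as a flat atom table plus per-chain full polymer sequences, detects
maximal runs of unmodeled residues, and maps peptide residues onto the
P-position nomenclature (P1..P8 core, P-1/P-2 N-terminal extensions) using
the engineered P7 Cys-Cys76 disulfide as the anchor.

Author residue numbering is authoritative throughout; nothing is renumbered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger("mhcgroove")

#: Sγ-Sγ distance (Å) below which two cysteines are taken as disulfide-bonded.
DISULFIDE_CUTOFF = 2.5


class StructureError(ValueError):
    """Raised for unparseable files, empty polymers, or failed lookups."""


@dataclass(frozen=True)
class Atom:
    """One atom of the coordinate record (author numbering)."""

    chain: str
    resnum: int
    resname: str
    name: str
    pos: tuple[float, float, float]
    occupancy: float = 1.0

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.pos, dtype=float)


@dataclass
class StructureModel:
    """Atom table plus per-chain full polymer sequence.

    ``chain_sequences`` holds the full construct sequence (3-letter codes)
    when a sequence record (SEQRES / entity) was present, else the observed
    residues.  ``seq_start`` maps each chain to the author number of the
    first sequence-record residue (default 1).
    """

    atoms: list[Atom]
    chain_sequences: dict[str, list[str]] = field(default_factory=dict)
    seq_start: dict[str, int] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            key = (a.chain, a.resnum, a.name)
            if key in seen:
                raise StructureError(f"duplicate atom record {key}")
            seen.add(key)
            if not np.all(np.isfinite(a.xyz)):
                raise StructureError(f"non-finite coordinates for {key}")

    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain not in out:
                out.append(a.chain)
        return out

    def residues(self, chain: str) -> list[tuple[int, str]]:
        """Modeled residues of a chain as (author number, 3-letter name), file order."""
        if chain not in self.chains():
            raise StructureError(f"chain {chain!r} not in structure")
        out: list[tuple[int, str]] = []
        for a in self.atoms:
            if a.chain == chain and (a.resnum, a.resname) not in out:
                out.append((a.resnum, a.resname))
        return out

    def atom(self, chain: str, resnum: int, name: str) -> Atom:
        for a in self.atoms:
            if a.chain == chain and a.resnum == resnum and a.name == name:
                return a
        raise StructureError(f"atom {chain}/{resnum}/{name} not found")

    def has_atom(self, chain: str, resnum: int, name: str) -> bool:
        return any(
            a.chain == chain and a.resnum == resnum and a.name == name
            for a in self.atoms
        )

    def residue_atoms(self, chain: str, resnum: int) -> dict[str, np.ndarray]:
        return {
            a.name: a.xyz
            for a in self.atoms
            if a.chain == chain and a.resnum == resnum
        }


@dataclass(frozen=True)
class ResidueRange:
    """A maximal run of consecutive unmodeled residues."""

    chain: str
    first: int
    last: int

    def __post_init__(self) -> None:
        if self.first > self.last:
            raise ValueError("first must be <= last")

    @property
    def length(self) -> int:
        return self.last - self.first + 1


@dataclass(frozen=True)
class AtomSelector:
    """Declarative atom selection: chain / residue numbers / atom names.

    ``None`` fields are wildcards.  ``residues`` may be an iterable of author
    numbers or a ``range``.  Resolution order follows the atom table, so the
    result is deterministic and order-stable.
    """

    chain: str | None = None
    residues: Iterable[int] | None = None
    atom_names: Sequence[str] | None = None
    resname: str | None = None

    @classmethod
    def parse(cls, text: str) -> "AtomSelector":
        """Parse ``CHAIN:RESSPEC:ATOMS`` (e.g. ``H:1-180:CA``, ``P:*:*``)."""
        parts = text.split(":")
        if not 1 <= len(parts) <= 3:
            raise ValueError(f"bad selector {text!r}")
        chain = None if parts[0] in ("*", "") else parts[0]
        residues: Iterable[int] | None = None
        if len(parts) > 1 and parts[1] not in ("*", ""):
            nums: list[int] = []
            for tok in parts[1].split(","):
                if "-" in tok[1:]:  # range; leading '-' means a negative number
                    cut = tok.index("-", 1)
                    nums.extend(range(int(tok[:cut]), int(tok[cut + 1:]) + 1))
                else:
                    nums.append(int(tok))
            residues = nums
        atom_names = None
        if len(parts) > 2 and parts[2] not in ("*", ""):
            atom_names = tuple(parts[2].split(","))
        return cls(chain=chain, residues=residues, atom_names=atom_names)

    def matches(self, atom: Atom) -> bool:
        if self.chain is not None and atom.chain != self.chain:
            return False
        if self.residues is not None and atom.resnum not in self.residues:
            return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        if self.resname is not None and atom.resname != self.resname:
            return False
        return True

    def resolve(self, model: StructureModel) -> list[Atom]:
        resset = None if self.residues is None else set(self.residues)
        sel = AtomSelector(self.chain, resset, self.atom_names, self.resname)
        return [a for a in model.atoms if sel.matches(a)]


@dataclass
class PeptidePositionMap:
    """P-position labels for a bound peptide, anchored on the P7 Cys.

    P7 is the peptide Cys disulfide-bonded to heavy-chain Cys76; P1 sits six
    positions N-terminal to it.  Residues N-terminal to P1 are extensions
    P-1, P-2, ... protruding out of the groove.
    """

    peptide_chain: str
    heavy_chain: str
    positions: dict[str, int]  # label -> author residue number

    def resnum(self, label: str) -> int:
        if label not in self.positions:
            raise StructureError(f"position {label} not modeled in peptide")
        return self.positions[label]

    @property
    def p1(self) -> int:
        return self.resnum("P1")

    @property
    def p7(self) -> int:
        return self.resnum("P7")

    @property
    def n_extensions(self) -> int:
        return sum(1 for k in self.positions if k.startswith("P-"))


def _pick_altloc(group: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by altloc identifier order
    return sorted(group, key=lambda a: (-a.occ, a.altloc))[0]


def read_structure(path: str | Path, fmt: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Alternate locations are resolved to the highest-occupancy conformer.
    ``chain_sequences`` comes from the sequence record (SEQRES / entity
    ``full_sequence``) when present, else from the observed residues.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    try:
        if fmt == "pdb" or (fmt is None and path.suffix.lower() in (".pdb", ".ent")):
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif" or (fmt is None and path.suffix.lower() in (".cif", ".mmcif")):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()

    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        for res in chain:
            if res.is_water():
                continue
            by_name: dict[str, list[gemmi.Atom]] = {}
            for at in res:
                by_name.setdefault(at.name, []).append(at)
            for name, group in by_name.items():
                at = _pick_altloc(group)
                atoms.append(
                    Atom(
                        chain=chain.name,
                        resnum=res.seqid.num,
                        resname=res.name,
                        name=name,
                        pos=(at.pos.x, at.pos.y, at.pos.z),
                        occupancy=at.occ,
                    )
                )
    if not atoms:
        raise StructureError(f"no polymer atoms in {path}")

    chain_sequences: dict[str, list[str]] = {}
    for ent in st.entities:
        if not ent.full_sequence:
            continue
        seq = [gemmi.Entity.first_mon(m) for m in ent.full_sequence]
        for sub in ent.subchains:
            for chain in model:
                for res in chain:
                    if res.subchain == sub:
                        chain_sequences.setdefault(chain.name, seq)
                        break
    out = StructureModel(atoms=atoms, chain_sequences=chain_sequences, name=path.stem)
    for ch in out.chains():
        if ch not in chain_sequences:
            chain_sequences[ch] = [rn for _, rn in out.residues(ch)]
    return out


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a model as PDB, including SEQRES from ``chain_sequences``."""
    st = gemmi.Structure()
    st.name = model.name or "mhcgroove"
    gm = gemmi.Model("1")
    for ch_name in model.chains():
        chain = gemmi.Chain(ch_name)
        for resnum, resname in model.residues(ch_name):
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resnum, " ")
            for a in model.atoms:
                if a.chain == ch_name and a.resnum == resnum:
                    at = gemmi.Atom()
                    at.name = a.name
                    at.pos = gemmi.Position(*a.pos)
                    at.occ = a.occupancy
                    at.element = gemmi.Element(_guess_element(a.name))
                    res.add_atom(at)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    for ent in st.entities:
        for chain in st[0]:
            if any(r.subchain in ent.subchains for r in chain):
                seq = model.chain_sequences.get(chain.name)
                if seq:
                    ent.full_sequence = list(seq)
                break
    Path(path).write_text(st.make_pdb_string())


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if name[:1].isdigit():
        name = name[1:]
    if name.startswith(("CL", "BR")):
        return name[:2]
    return name[0]


def detect_unmodeled_regions(
    model: StructureModel, chain: str, seq_start: int | None = None
) -> list[ResidueRange]:
    """Maximal runs of residues absent from the coordinate record.

    Missing residues are found from (a) gaps in author numbering between
    consecutive modeled residues and (b) sequence-record residues never
    modeled (termini included).  The sequence record is aligned to author
    numbering starting at ``seq_start`` (default: the chain's recorded start,
    else 1).  Disorder is inferred purely from coordinate absence; no
    electron-density information is consulted.
    """
    modeled = sorted(num for num, _ in model.residues(chain))
    seq = model.chain_sequences.get(chain)
    missing: set[int] = set()
    if seq is not None and len(seq) > len(modeled):
        start = seq_start if seq_start is not None else model.seq_start.get(chain, 1)
        expected = set(range(start, start + len(seq)))
        missing = expected - set(modeled)
    else:
        for lo, hi in zip(modeled, modeled[1:]):
            if hi - lo > 1:
                missing.update(range(lo + 1, hi))
    if not missing:
        return []
    runs: list[ResidueRange] = []
    nums = sorted(missing)
    first = prev = nums[0]
    for n in nums[1:]:
        if n == prev + 1:
            prev = n
            continue
        runs.append(ResidueRange(chain, first, prev))
        first = prev = n
    runs.append(ResidueRange(chain, first, prev))
    return runs


def resolve_peptide_positions(
    model: StructureModel,
    peptide_chain: str,
    heavy_chain: str,
    disulfide_cutoff: float = DISULFIDE_CUTOFF,
    cys_anchor: int = 76,
) -> PeptidePositionMap:
    """Label peptide residues with P positions via the P7 Cys-Cys76 disulfide.

    The peptide Cys whose Sγ lies within ``disulfide_cutoff`` of heavy-chain
    Cys76 Sγ is P7; P1 is six positions N-terminal along the chain; residues
    N-terminal to P1 are labelled P-1, P-2, ... outward.
    """
    try:
        anchor_sg = model.atom(heavy_chain, cys_anchor, "SG").xyz
    except StructureError as exc:
        raise StructureError(
            f"heavy chain {heavy_chain} has no Cys{cys_anchor} SG atom"
        ) from exc
    residues = model.residues(peptide_chain)
    p7_idx: int | None = None
    for i, (num, name) in enumerate(residues):
        if name != "CYS":
            continue
        if not model.has_atom(peptide_chain, num, "SG"):
            continue
        d = float(np.linalg.norm(model.atom(peptide_chain, num, "SG").xyz - anchor_sg))
        if d <= disulfide_cutoff:
            p7_idx = i
            break
    if p7_idx is None:
        raise StructureError(
            f"no peptide Cys Sγ within {disulfide_cutoff} Å of heavy-chain "
            f"Cys{cys_anchor} Sγ; specify the P7 residue manually"
        )
    positions: dict[str, int] = {}
    p1_idx = p7_idx - 6
    for i, (num, _) in enumerate(residues):
        offset = i - p1_idx
        label = f"P{offset + 1}" if offset >= 0 else f"P{offset}"
        positions[label] = num
    if "P1" not in positions:
        raise StructureError("peptide too short: no residue six positions before P7")
    return PeptidePositionMap(
        peptide_chain=peptide_chain, heavy_chain=heavy_chain, positions=positions
    )
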