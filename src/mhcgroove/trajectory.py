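"""Trajectory container, per-frame superposition, and per-residue RMSF.

A trajectory is a frames x atoms x 3 coordinate block with per-frame times
and a topology mapping every atom to (chain, residue number, residue name,
atom name).  Multi-model PDB is the required on-disk dialect (each MODEL is
a frame); binary formats readable by mdtraj are accepted behind the same
contract when mdtraj is importable.

RMSF of atom i is sqrt(mean_t |x_i(t) - <x_i>|^2) after removing global
rigid-body motion by superposing every frame on a fit selection.  Per-residue
values average constituent selected atoms (Cα only by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .structure_io import Atom, AtomSelector, StructureModel, StructureError
from .superpose import kabsch_superpose


class TrajectoryError(ValueError):
    """Raised for malformed trajectory input or undefined statistics."""


@dataclass(frozen=True)
class AtomRecord:
    chain: str
    resnum: int
    resname: str
    name: str


@dataclass
class Trajectory:
    """Coordinates (frames, atoms, 3) in Å with times (ps) and topology."""

    coordinates: np.ndarray
    times: np.ndarray
    topology: list[AtomRecord]

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise TrajectoryError("coordinates must be (frames, atoms, 3)")
        if self.coordinates.shape[1] != len(self.topology):
            raise TrajectoryError("topology length does not match atom count")
        if self.coordinates.shape[0] != len(self.times):
            raise TrajectoryError("times length does not match frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise TrajectoryError("frame times must be strictly increasing")
        if not np.all(np.isfinite(self.coordinates)):
            raise TrajectoryError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def atom_indices(self, selector: AtomSelector) -> np.ndarray:
        resset = None if selector.residues is None else set(selector.residues)
        idx = [
            i
            for i, rec in enumerate(self.topology)
            if (selector.chain is None or rec.chain == selector.chain)
            and (resset is None or rec.resnum in resset)
            and (selector.atom_names is None or rec.name in selector.atom_names)
            and (selector.resname is None or rec.resname == selector.resname)
        ]
        return np.asarray(idx, dtype=int)

    def atom_index(self, chain: str, resnum: int, name: str) -> int:
        for i, rec in enumerate(self.topology):
            if rec.chain == chain and rec.resnum == resnum and rec.name == name:
                return i
        raise TrajectoryError(f"atom {chain}/{resnum}/{name} not in topology")

    def frame_model(self, frame: int) -> StructureModel:
        """Materialise one frame as a StructureModel (for contact analyses)."""
        atoms = [
            Atom(r.chain, r.resnum, r.resname, r.name, tuple(xyz))
            for r, xyz in zip(self.topology, self.coordinates[frame])
        ]
        return StructureModel(atoms=atoms)


@dataclass
class RMSFProfile:
    """Per-residue RMSF (Å) with the selections that produced it."""

    residues: list[tuple[str, int]]
    values: np.ndarray
    fit_selection: str = ""
    measure_selection: str = ""

    def as_dict(self) -> dict[tuple[str, int], float]:
        return dict(zip(self.residues, map(float, self.values)))


def read_trajectory(
    path: str | Path,
    topology_source: str | Path | None = None,
    dt_ps: float = 20.0,
) -> Trajectory:
    """Read a multi-model PDB (or, with a topology file, a binary format).

    PDB models become frames; every model must present the same atoms in the
    same order.  PDB carries no timestamps, so times are synthesised on a
    uniform grid with spacing ``dt_ps`` (default 20 ps, a typical MD sampling
    interval).
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise TrajectoryError(f"no such file: {path}")
    if path.suffix.lower() not in (".pdb", ".ent"):
        return _read_binary_trajectory(path, topology_source, dt_ps)
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise TrajectoryError(f"no models in {path}")
    topology: list[AtomRecord] = []
    frames: list[np.ndarray] = []
    for imodel, model in enumerate(st):
        recs: list[AtomRecord] = []
        coords: list[tuple[float, float, float]] = []
        for chain in model:
            for res in chain:
                if res.is_water():
                    continue
                for at in res:
                    recs.append(AtomRecord(chain.name, res.seqid.num, res.name, at.name))
                    coords.append((at.pos.x, at.pos.y, at.pos.z))
        if imodel == 0:
            topology = recs
        elif recs != topology:
            raise TrajectoryError(
                f"frame {imodel} atom records differ from frame 0 "
                f"({len(recs)} vs {len(topology)} atoms)"
            )
        frames.append(np.asarray(coords))
    times = np.arange(len(frames)) * dt_ps
    return Trajectory(np.stack(frames), times, topology)


def _read_binary_trajectory(
    path: Path, topology_source: str | Path | None, dt_ps: float
) -> Trajectory:
    try:
        import mdtraj
    except ImportError as exc:  # pragma: no cover
        raise TrajectoryError("binary trajectory support requires mdtraj") from exc
    if topology_source is None:
        raise TrajectoryError("binary trajectories need a separate topology file")
    t = mdtraj.load(str(path), top=str(topology_source))
    topology = [
        AtomRecord(
            a.residue.chain.chain_id or chr(ord("A") + a.residue.chain.index),
            a.residue.resSeq,
            a.residue.name,
            a.name,
        )
        for a in t.topology.atoms
    ]
    times = t.time * 1.0 if t.time is not None and np.all(np.diff(t.time) > 0) else (
        np.arange(t.n_frames) * dt_ps
    )
    return Trajectory(t.xyz * 10.0, times, topology)  # nm -> Å


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write frames as a multi-model PDB."""
    lines: list[str] = []
    for f in range(traj.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        for i, (rec, xyz) in enumerate(zip(traj.topology, traj.coordinates[f]), 1):
            name = rec.name if len(rec.name) == 4 else f" {rec.name:<3s}"
            lines.append(
                f"ATOM  {i % 100000:5d} {name}{rec.resname:>4s} {rec.chain[:1]}"
                f"{rec.resnum:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"  1.00  0.00          {rec.name.strip()[0]:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def superpose_frames(
    traj: Trajectory,
    fit: AtomSelector,
    reference: str = "mean",
) -> Trajectory:
    """Remove global rigid-body motion by superposing every frame.

    ``reference`` is ``"first"`` (frame 0) or ``"mean"`` (two-pass: superpose
    on frame 0, recompute the mean structure once, then superpose on it).
    """
    idx = traj.atom_indices(fit)
    if len(idx) < 3:
        raise TrajectoryError(f"fit selection resolves to {len(idx)} atoms (< 3)")
    if reference not in ("first", "mean"):
        raise TrajectoryError(f"unknown reference {reference!r}")

    def _pass(coords: np.ndarray, ref_fit: np.ndarray) -> np.ndarray:
        out = np.empty_like(coords)
        for f in range(coords.shape[0]):
            res = kabsch_superpose(coords[f, idx], ref_fit)
            out[f] = res.apply(coords[f])
        return out

    aligned = _pass(traj.coordinates, traj.coordinates[0, idx])
    if reference == "mean":
        mean_fit = aligned[:, idx].mean(axis=0)
        aligned = _pass(aligned, mean_fit)
    return replace(traj, coordinates=aligned)


def rmsf(
    traj: Trajectory,
    fit: AtomSelector | None = None,
    measure: AtomSelector | None = None,
    reduction: str = "per-residue",
) -> RMSFProfile:
    """Per-residue (or per-atom) RMSF after optional in-call superposition.

    ``measure`` defaults to all Cα atoms.  With ``reduction="per-residue"``
    each residue gets the mean RMSF of its selected atoms; ``"per-atom"``
    keeps atoms separate (residue key repeated per atom).
    """
    if traj.n_frames < 2:
        raise TrajectoryError("RMSF undefined for a single frame")
    if fit is not None:
        traj = superpose_frames(traj, fit)
    measure = measure or AtomSelector(atom_names=("CA",))
    idx = traj.atom_indices(measure)
    if len(idx) == 0:
        raise TrajectoryError("measure selection resolves to no atoms")
    coords = traj.coordinates[:, idx]
    mean = coords.mean(axis=0)
    per_atom = np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))
    if reduction == "per-atom":
        residues = [(traj.topology[i].chain, traj.topology[i].resnum) for i in idx]
        values = per_atom
    elif reduction == "per-residue":
        groups: dict[tuple[str, int], list[float]] = {}
        order: list[tuple[str, int]] = []
        for i, v in zip(idx, per_atom):
            key = (traj.topology[i].chain, traj.topology[i].resnum)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(float(v))
        residues = order
        values = np.array([np.mean(groups[k]) for k in order])
    else:
        raise TrajectoryError(f"unknown reduction {reduction!r}")
    return RMSFProfile(
        residues=residues,
        values=values,
        fit_selection=repr(fit) if fit else "",
        measure_selection=repr(measure),
    )
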