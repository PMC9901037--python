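"""Synthetic fixtures with programmed ground truth for every pipeline stage.

Each generator is a pure function of its parameters (seed included) and
returns ``(data, ground_truth)`` where ``ground_truth`` echoes the
parameters and the quantities downstream analyses should recover:

* :func:`make_harmonic_trajectory` — rigid scaffold with per-residue
  isotropic Gaussian positional noise; expected per-residue RMSF is σ·√3.
* :func:`make_ring_pair` — two aromatic rings at a programmed center
  distance and normal-normal angle, optionally jittered per frame.
* :func:`make_rotation_trace` — wrapped dihedral time series following a
  waypoint schedule through sigmoidal transitions plus thermal noise.
* :func:`make_gapped_structure` — poly-alanine scaffold with engineered
  unmodeled residue ranges (present in the sequence record, absent from
  coordinates).
* :func:`make_melt_curve` — descending logistic fluorescence curve with a
  programmed inflection temperature.
* :func:`make_groove_complex` — a SYNTHETIC stand-in for a peptide-MHC
  crystal structure: minimal heavy chain + disulfide-anchored peptide with
  the terminal-amino-group dihedral ω engineered to a prescribed value.
  It emulates the topology the analyses need (Cys76-P7 disulfide, P1
  ring, groove residue numbering); it is not a model of the real fold.

These generators emulate the statistical structure of equilibrated MD
ensembles (stationary Gaussian fluctuations, programmed transitions), not
force-field physics.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .melt import MeltCurve
from .rotation import AngleSeries, wrap_angles
from .structure_io import Atom, StructureModel
from .trajectory import AtomRecord, Trajectory

_RING_RADIUS = 1.39  # Å, aromatic C-C ring circumradius
_RING_NAMES = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")


# ---------------------------------------------------------------- helpers

def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle_deg: float, torsion_deg: float
) -> np.ndarray:
    """Place atom D given A, B, C with |C-D|, angle B-C-D, torsion A-B-C-D (NeRF)."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def _hexagon(center: np.ndarray, normal: np.ndarray, radius: float = _RING_RADIUS) -> np.ndarray:
    """Six ring vertices ordered so the Newell normal equals ``normal``."""
    normal = normal / np.linalg.norm(normal)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, normal)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, seed)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    # counterclockwise about `normal` (right-hand rule) needs u -> -v ordering
    angles = np.radians(np.arange(0, 360, 60))
    return np.array(
        [center + radius * (np.cos(t) * u - np.sin(t) * v) for t in angles]
    )


def _helix_ca(n_res: int, radius: float = 2.3, rise: float = 1.5, twist_deg: float = 100.0) -> np.ndarray:
    i = np.arange(n_res)
    t = np.radians(twist_deg) * i
    return np.column_stack([radius * np.cos(t), radius * np.sin(t), rise * i])


# ------------------------------------------------------------- generators

def make_harmonic_trajectory(
    amplitudes: dict[int, float] | Sequence[float],
    n_frames: int,
    seed: int,
    dt_ps: float = 20.0,
    chain: str = "A",
) -> tuple[Trajectory, dict]:
    """Rigid poly-alanine Cα scaffold with per-residue Gaussian fluctuation.

    ``amplitudes`` maps residue number -> per-coordinate σ (Å), or is a
    sequence indexed from residue 1.  Every atom of residue i is displaced
    each frame by i.i.d. isotropic Gaussian noise of per-coordinate σ_i, so
    the expected RMSF of residue i is σ_i·√3.
    """
    if isinstance(amplitudes, dict):
        sigma = {int(k): float(v) for k, v in amplitudes.items()}
    else:
        sigma = {i + 1: float(v) for i, v in enumerate(amplitudes)}
    if any(v < 0 for v in sigma.values()):
        raise ValueError("amplitudes must be non-negative")
    if n_frames < 2:
        raise ValueError("need >= 2 frames")
    resnums = sorted(sigma)
    base = _helix_ca(len(resnums))
    topology = [AtomRecord(chain, r, "ALA", "CA") for r in resnums]
    rng = np.random.default_rng(seed)
    sig = np.array([sigma[r] for r in resnums])[None, :, None]
    noise = rng.normal(0.0, 1.0, size=(n_frames, len(resnums), 3)) * sig
    coords = base[None, :, :] + noise
    traj = Trajectory(coords, np.arange(n_frames) * dt_ps, topology)
    truth = {
        "sigma": {r: sigma[r] for r in resnums},
        "expected_rmsf": {r: sigma[r] * np.sqrt(3.0) for r in resnums},
        "seed": seed,
    }
    return traj, truth


def make_ring_pair(
    center_distance: float,
    normal_angle_deg: float,
    jitter: float,
    n_frames: int,
    seed: int = 0,
    dt_ps: float = 20.0,
) -> tuple[Trajectory, dict]:
    """Two PHE/TYR-like rings at a programmed center distance and tilt.

    Ring 1 (peptide chain ``P``, residue 1, PHE) lies in the xy-plane at the
    origin with normal +z; ring 2 (heavy chain ``H``, residue 59, TYR) is
    centered ``center_distance`` Å up the z-axis with its normal tilted by
    ``normal_angle_deg`` about x.  ``jitter`` is a per-atom per-frame
    Gaussian σ (Å).
    """
    if center_distance <= 0:
        raise ValueError("center distance must be positive")
    if not 0 <= normal_angle_deg <= 180:
        raise ValueError("normal angle must be in [0, 180]")
    n1 = np.array([0.0, 0.0, 1.0])
    t = np.radians(normal_angle_deg)
    n2 = np.array([0.0, -np.sin(t), np.cos(t)])
    ring1 = _hexagon(np.zeros(3), n1)
    ring2 = _hexagon(np.array([0.0, 0.0, center_distance]), n2)
    base = np.vstack([ring1, ring2])
    topology = [AtomRecord("P", 1, "PHE", n) for n in _RING_NAMES] + [
        AtomRecord("H", 59, "TYR", n) for n in _RING_NAMES
    ]
    rng = np.random.default_rng(seed)
    coords = base[None, :, :] + rng.normal(0.0, jitter, size=(n_frames, 12, 3))
    traj = Trajectory(coords, np.arange(n_frames) * dt_ps, topology)
    truth = {
        "center_distance": center_distance,
        "normal_angle_deg": normal_angle_deg,
        "jitter": jitter,
        "seed": seed,
    }
    return traj, truth


def make_rotation_trace(
    schedule: Sequence[tuple[float, float]],
    noise_sigma_deg: float,
    dt_ps: float = 20.0,
    tail_ns: float = 50.0,
    transition_ns: float = 20.0,
    seed: int = 0,
) -> tuple[AngleSeries, dict]:
    """Wrapped dihedral time series following a waypoint schedule.

    ``schedule`` is a list of (time ns, value deg) waypoints with strictly
    increasing times; the underlying smooth path holds each value and moves
    between consecutive waypoints through a sigmoidal transition of width
    ``transition_ns``.  Gaussian noise of σ ``noise_sigma_deg`` is added and
    the result wrapped into (-180°, 180°].  The ground truth records the
    number of programmed transitions (consecutive waypoints with different
    values).
    """
    if not schedule:
        raise ValueError("schedule needs at least one waypoint")
    times_ns = [t for t, _ in schedule]
    if any(b <= a for a, b in zip(times_ns, times_ns[1:])):
        raise ValueError("overlapping transitions: waypoint times must increase")
    end_ns = times_ns[-1] + tail_ns
    t = np.arange(0.0, end_ns * 1000.0 + dt_ps, dt_ps)  # ps
    t_ns = t / 1000.0
    path = np.full_like(t_ns, schedule[0][1])
    for (t0, v0), (t1, v1) in zip(schedule, schedule[1:]):
        if v1 == v0:
            continue
        mid = 0.5 * (t0 + t1)
        tau = min(transition_ns, (t1 - t0) / 4.0) / 4.0
        path = path + (v1 - v0) / (1.0 + np.exp(-(t_ns - mid) / tau))
    rng = np.random.default_rng(seed)
    noisy = path + rng.normal(0.0, noise_sigma_deg, size=path.shape)
    series = AngleSeries(times_ps=t, values_deg=wrap_angles(noisy), wrapped=True)
    n_trans = sum(1 for (t0, v0), (t1, v1) in zip(schedule, schedule[1:]) if v1 != v0)
    truth = {
        "n_transitions": n_trans,
        "schedule": list(schedule),
        "noise_sigma_deg": noise_sigma_deg,
        "unwrapped_path": path,
        "seed": seed,
    }
    return series, truth


def make_gapped_structure(
    n_residues: int,
    missing_ranges: Iterable[tuple[int, int]] = (),
    chain: str = "A",
) -> tuple[StructureModel, dict]:
    """Poly-alanine helix whose sequence record covers residues 1..n but
    whose coordinates omit the listed (first, last) ranges."""
    missing: set[int] = set()
    for lo, hi in missing_ranges:
        if not 1 <= lo <= hi <= n_residues:
            raise ValueError(f"range ({lo}, {hi}) outside 1..{n_residues}")
        missing.update(range(lo, hi + 1))
    ca = _helix_ca(n_residues)
    atoms: list[Atom] = []
    for i in range(n_residues):
        resnum = i + 1
        if resnum in missing:
            continue
        pos = ca[i]
        prev_dir = (ca[i] - ca[i - 1]) if i > 0 else np.array([1.0, 0.0, 0.0])
        prev_dir = prev_dir / np.linalg.norm(prev_dir)
        for name, offset in (
            ("N", -1.45 * prev_dir),
            ("CA", np.zeros(3)),
            ("C", 1.52 * prev_dir),
            ("O", 1.52 * prev_dir + np.array([0.0, 0.0, 1.23])),
            ("CB", np.array([0.0, 0.0, -1.53])),
        ):
            atoms.append(Atom(chain, resnum, "ALA", name, tuple(pos + offset)))
    model = StructureModel(
        atoms=atoms,
        chain_sequences={chain: ["ALA"] * n_residues},
        name="synthetic_gapped",
    )
    truth = {"missing_ranges": sorted((lo, hi) for lo, hi in missing_ranges)}
    return model, truth


def make_melt_curve(
    tm: float,
    width: float,
    noise_fraction: float,
    seed: int = 0,
    t_min: float = 25.0,
    t_max: float = 95.0,
    step: float = 0.1,
    amplitude: float = 1000.0,
    baseline: float = 100.0,
) -> tuple[MeltCurve, dict]:
    """Descending logistic fluorescence curve with inflection at ``tm``.

    F(T) = baseline + amplitude / (1 + exp((T - tm)/width)); the first
    derivative has its minimum exactly at ``tm``.  ``noise_fraction``
    scales Gaussian noise relative to the amplitude.
    """
    temps = np.arange(t_min, t_max + step / 2, step)
    f = baseline + amplitude / (1.0 + np.exp((temps - tm) / width))
    if noise_fraction:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_fraction * amplitude, size=f.shape)
    curve = MeltCurve(temperatures=temps, fluorescence=f)
    truth = {"tm": tm, "width": width, "noise_fraction": noise_fraction, "seed": seed}
    return curve, truth


# ----------------------------------------------- synthetic crystal stand-in

def make_groove_complex(
    omega_deg: float,
    p1_resname: str = "PHE",
    n_core: int = 8,
    n_ext: int = 0,
    missing_ranges: Iterable[tuple[int, int]] = (),
    heavy_chain: str = "A",
    peptide_chain: str = "C",
    n_heavy: int = 180,
    p1_offset: Sequence[float] = (0.0, 0.0, 0.0),
    p2_offset: Sequence[float] = (0.0, 0.0, 0.0),
    name: str = "synthetic_groove_complex",
) -> tuple[StructureModel, dict]:
    """SYNTHETIC stand-in for a disulfide-anchored peptide-MHC complex.

    Builds a minimal heavy chain (poly-Ala Cα helix, residues 1..``n_heavy``,
    with Ile52, Tyr59, Asn63 and Cys76 given their real identities and the
    side-chain atoms the analyses touch) plus a peptide whose P7 Cys Sγ sits
    2.04 Å from Cys76 Sγ and whose P1 amide nitrogen is placed so that the
    dihedral ω over Cys76:CA-P7:CA-P1:CA-P1:N equals ``omega_deg`` exactly.
    ``missing_ranges`` removes heavy-chain residues from the coordinates
    (sequence record retained) to emulate crystallographic disorder.
    ``p1_offset``/``p2_offset`` translate the P1/P2 residues (Å) to engineer
    known Cα displacements between stand-in pairs; ω stays exact because the
    P1 amide nitrogen is placed by torsion after the offset is applied.

    This is a geometric scaffold for exercising the analyses, not a model of
    the real fold; deposited coordinates are required for real-data numbers.
    """
    if p1_resname not in ("PHE", "ALA"):
        raise ValueError("p1_resname must be PHE or ALA")
    missing: set[int] = set()
    for lo, hi in missing_ranges:
        missing.update(range(lo, hi + 1))
    special = {52: "ILE", 59: "TYR", 63: "ASN", 76: "CYS"}
    ca = _helix_ca(n_heavy)
    atoms: list[Atom] = []
    for i in range(n_heavy):
        resnum = i + 1
        if resnum in missing:
            continue
        resname = special.get(resnum, "ALA")
        pos = ca[i]
        out_dir = pos - np.array([0.0, 0.0, pos[2]])
        out_dir /= np.linalg.norm(out_dir)
        atoms.append(Atom(heavy_chain, resnum, resname, "N", tuple(pos + np.array([-1.0, 0.5, -0.8]))))
        atoms.append(Atom(heavy_chain, resnum, resname, "CA", tuple(pos)))
        atoms.append(Atom(heavy_chain, resnum, resname, "C", tuple(pos + np.array([1.0, -0.5, 0.8]))))
        atoms.append(Atom(heavy_chain, resnum, resname, "O", tuple(pos + np.array([1.2, -0.5, 1.9]))))
        cb = pos + 1.53 * out_dir
        atoms.append(Atom(heavy_chain, resnum, resname, "CB", tuple(cb)))
        if resname == "CYS":
            atoms.append(Atom(heavy_chain, resnum, resname, "SG", tuple(cb + 1.81 * out_dir)))
        elif resname == "ILE":
            cg1 = cb + np.array([0.9, 0.9, 0.5])
            atoms.append(Atom(heavy_chain, resnum, resname, "CG1", tuple(cg1)))
            atoms.append(Atom(heavy_chain, resnum, resname, "CG2", tuple(cb + np.array([-0.9, 0.9, -0.5]))))
            atoms.append(Atom(heavy_chain, resnum, resname, "CD1", tuple(cg1 + np.array([1.0, 0.8, 0.4]))))
        elif resname == "TYR":
            ring = _hexagon(cb + 2.8 * out_dir, out_dir)
            for rn, rpos in zip(_RING_NAMES, ring):
                atoms.append(Atom(heavy_chain, resnum, resname, rn, tuple(rpos)))
            atoms.append(Atom(heavy_chain, resnum, resname, "OH", tuple(cb + (2.8 + 2 * _RING_RADIUS) * out_dir)))
        elif resname == "ASN":
            cg = cb + 1.5 * out_dir
            atoms.append(Atom(heavy_chain, resnum, resname, "CG", tuple(cg)))
            atoms.append(Atom(heavy_chain, resnum, resname, "OD1", tuple(cg + np.array([0.8, 0.8, 0.2]))))
            atoms.append(Atom(heavy_chain, resnum, resname, "ND2", tuple(cg + np.array([-0.8, 0.8, -0.2]))))

    # peptide: extensions (P-n..P-1), core P1..Pn_core; P7 Cys anchored to Cys76
    cys76_ca = ca[75]
    cys76_sg = next(
        a.xyz for a in atoms if a.chain == heavy_chain and a.resnum == 76 and a.name == "SG"
    )
    away = np.array([1.0, 1.0, 0.2])
    away /= np.linalg.norm(away)
    p7_ca = cys76_ca + 5.5 * away
    pep_dir = np.array([0.2, -0.5, 1.0])
    pep_dir -= away * np.dot(pep_dir, away) * 0.5
    pep_dir /= np.linalg.norm(pep_dir)
    p1_ca = p7_ca + 6 * 3.2 * pep_dir  # six positions N-terminal of P7

    n_pep = n_ext + n_core
    pep_ca: dict[int, np.ndarray] = {}
    for k in range(n_pep):
        idx_from_p1 = k - n_ext  # 0 at P1, -1 at P-1, 6 at P7
        pep_ca[k + 1] = p1_ca + idx_from_p1 * (p7_ca - p1_ca) / 6.0

    p1_resnum = n_ext + 1
    p7_resnum = n_ext + 7
    pep_ca[p1_resnum] = pep_ca[p1_resnum] + np.asarray(p1_offset, dtype=float)
    if p1_resnum + 1 <= n_pep:
        pep_ca[p1_resnum + 1] = pep_ca[p1_resnum + 1] + np.asarray(p2_offset, dtype=float)
    p1_ca = pep_ca[p1_resnum]  # the torsion below must see the offset position
    seq: list[str] = []
    for k in range(1, n_pep + 1):
        if k == p1_resnum:
            resname = p1_resname
        elif k == p7_resnum:
            resname = "CYS"
        else:
            resname = "ALA"
        seq.append(resname)
        capos = pep_ca[k]
        atoms.append(Atom(peptide_chain, k, resname, "CA", tuple(capos)))
        if k == p1_resnum:
            n_pos = place_atom(cys76_ca, p7_ca, p1_ca, 1.45, 109.5, omega_deg)
            atoms.append(Atom(peptide_chain, k, resname, "N", tuple(n_pos)))
        else:
            atoms.append(Atom(peptide_chain, k, resname, "N", tuple(capos + np.array([-0.9, 0.9, -0.5]))))
        atoms.append(Atom(peptide_chain, k, resname, "C", tuple(capos + np.array([0.9, -0.9, 0.5]))))
        atoms.append(Atom(peptide_chain, k, resname, "O", tuple(capos + np.array([1.1, -0.9, 1.6]))))
        side = np.cross(pep_dir, away)
        side /= np.linalg.norm(side)
        cb = capos + 1.53 * side
        if resname != "GLY":
            atoms.append(Atom(peptide_chain, k, resname, "CB", tuple(cb)))
        if k == p7_resnum:
            # place Sγ on the Cβ->Cys76 Sγ line, 2.04 Å short of the partner Sγ
            sg_dir = cys76_sg - cb
            sg_dir /= np.linalg.norm(sg_dir)
            atoms.append(Atom(peptide_chain, k, "CYS", "SG", tuple(cys76_sg - 2.04 * sg_dir)))
        if k == p1_resnum and resname == "PHE":
            ring = _hexagon(cb + 2.8 * side, side)
            for rn, rpos in zip(_RING_NAMES, ring):
                atoms.append(Atom(peptide_chain, k, resname, rn, tuple(rpos)))

    model = StructureModel(
        atoms=atoms,
        chain_sequences={
            heavy_chain: [special.get(r, "ALA") for r in range(1, n_heavy + 1)],
            peptide_chain: seq,
        },
        name=name,
    )
    truth = {
        "omega_deg": omega_deg,
        "p1_resnum": p1_resnum,
        "p7_resnum": p7_resnum,
        "missing_ranges": sorted((lo, hi) for lo, hi in missing_ranges),
        "p1_resname": p1_resname,
        "n_ext": n_ext,
        "p1_offset": tuple(float(x) for x in p1_offset),
        "p2_offset": tuple(float(x) for x in p2_offset),
    }
    return model, truth


def shift_residue(
    model: StructureModel, chain: str, resnum: int, delta: Sequence[float]
) -> StructureModel:
    """Copy of a model with every atom of one residue translated by ``delta``.

    Convenience for engineering known Cα displacements between structure
    pairs (the rest of the model, and hence any fit selection elsewhere,
    is untouched).
    """
    d = np.asarray(delta, dtype=float)
    atoms = [
        Atom(a.chain, a.resnum, a.resname, a.name, tuple(a.xyz + d), a.occupancy)
        if a.chain == chain and a.resnum == resnum
        else a
        for a in model.atoms
    ]
    return StructureModel(
        atoms=atoms,
        chain_sequences=dict(model.chain_sequences),
        seq_start=dict(model.seq_start),
        name=model.name + "_shifted",
    )
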