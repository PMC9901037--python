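"""Orchestration of the three analyses into reproducible tabular reports.

Three entry points mirror how the analyses group in practice:

* :func:`run_structure_report` — crystal-structure comparison: unmodeled
  regions, per-P-position Cα shifts between structure pairs, A/B-pocket
  contact tables, and the crystal-state ω of each complex.
* :func:`run_trajectory_report` — trajectory analysis: per-residue RMSF,
  P1-Tyr59 / P1-Ile52 interaction series with distance/orientation
  distributions, π-π classification, and the CH-π verdict fraction.
* :func:`run_rotation_report` — ω evolution per replicate: raw, unwrapped,
  smoothed series, rotation events, and a "k of n replicates rotated"
  summary.

All numeric values in the reports are computed by the stage modules; this
module only routes data and writes TSV/JSON.  Reports are deterministic
given the configuration.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contacts as _contacts
from . import geometry as _geometry
from .melt import MeltCurve, melting_temperature
from .rotation import AngleSeries, detect_rotation, omega_dihedral, smooth, unwrap
from .structure_io import (
    AtomSelector,
    StructureModel,
    detect_unmodeled_regions,
    read_structure,
    resolve_peptide_positions,
)
from .superpose import ca_displacement, default_fit_selector
from .trajectory import Trajectory, read_trajectory, rmsf, superpose_frames

logger = logging.getLogger("mhcgroove")


class ConfigError(ValueError):
    """Raised for unknown keys or missing input files."""


@dataclass
class RunConfig:
    """Declarative run configuration (YAML-loadable; unknown keys rejected)."""

    structures: dict[str, str] = field(default_factory=dict)  # name -> path
    trajectory: str | None = None
    rotation_series: list[str] = field(default_factory=list)  # TSV paths
    heavy_chain: str = "A"
    peptide_chain: str = "C"
    output_dir: str = "groove_out"
    seed: int = 0
    dt_ps: float = 20.0
    smoothing_window_ns: float = 10.0
    rotation_start_deg: float = -100.0
    rotation_end_deg: float = 100.0
    rotation_tolerance_deg: float = 45.0
    distance_bin_width: float = 0.25
    angle_bin_width: float = 5.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name, p in cfg.structures.items():
            if not Path(p).exists():
                raise ConfigError(f"structure {name!r}: no such file {p}")
        for p in ([cfg.trajectory] if cfg.trajectory else []) + list(cfg.rotation_series):
            if not Path(p).exists():
                raise ConfigError(f"no such input file {p}")
        return cfg

    def outdir(self) -> Path:
        out = Path(self.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        return out

    def echo(self) -> None:
        payload = {f.name: getattr(self, f.name) for f in fields(self)}
        (self.outdir() / "config_used.yaml").write_text(yaml.safe_dump(payload))


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s: done in %.2f s", stage, dt)
            else:
                logger.error("stage %s: failed after %.2f s: %s", stage, dt, exc)
            return False

    return _Timer()


def run_structure_report(
    config: RunConfig, models: dict[str, StructureModel] | None = None
) -> dict:
    """Crystal-structure comparison report.

    Emits ``missing_regions.tsv``, ``omega.tsv`` (crystal-state ω per
    structure), ``ca_shifts.tsv`` (per shared P position, per structure
    pair, superposed on the heavy-chain α1α2 Cα intersection), and per-
    structure contact tables for P1/P2 against the heavy chain.
    """
    out = config.outdir()
    if models is None:
        models = {}
        for name, path in config.structures.items():
            with _timed(f"read_structure[{name}]"):
                models[name] = read_structure(path)
    hch, pch = config.heavy_chain, config.peptide_chain

    with _timed("missing_regions"):
        rows = []
        for name, model in models.items():
            for rr in detect_unmodeled_regions(model, hch):
                rows.append(
                    dict(structure=name, chain=rr.chain, first=rr.first, last=rr.last, length=rr.length)
                )
        missing_df = pd.DataFrame(rows, columns=["structure", "chain", "first", "last", "length"])
        missing_df.to_csv(out / "missing_regions.tsv", sep="\t", index=False)

    with _timed("positions_and_omega"):
        posmaps = {n: resolve_peptide_positions(m, pch, hch) for n, m in models.items()}
        omega_rows = [
            dict(structure=n, omega_deg=round(omega_dihedral(models[n], posmaps[n]), 2))
            for n in models
        ]
        pd.DataFrame(omega_rows).to_csv(out / "omega.tsv", sep="\t", index=False)

    with _timed("ca_shifts"):
        shift_rows = []
        names = list(models)
        for i, na in enumerate(names):
            for nb in names[i + 1 :]:
                shared = sorted(
                    set(posmaps[na].positions) & set(posmaps[nb].positions),
                    key=lambda s: posmaps[na].positions[s],
                )
                fit = default_fit_selector(hch)
                for label in shared:
                    ra, rb = posmaps[na].positions[label], posmaps[nb].positions[label]
                    if ra != rb:
                        continue  # author numbering differs; positional pairing out of scope
                    try:
                        d = ca_displacement(models[na], models[nb], fit, (pch, ra))
                    except Exception:
                        continue
                    shift_rows.append(
                        dict(pair=f"{na}|{nb}", position=label, shift_A=round(d, 2))
                    )
        pd.DataFrame(shift_rows, columns=["pair", "position", "shift_A"]).to_csv(
            out / "ca_shifts.tsv", sep="\t", index=False
        )

    with _timed("contacts"):
        contact_rows = []
        for name, model in models.items():
            pm = posmaps[name]
            sel_pep = AtomSelector(chain=pch, residues=(pm.p1, pm.positions.get("P2", pm.p1)))
            sel_heavy = AtomSelector(chain=hch)
            for c in _contacts.find_hbonds(model, sel_pep, sel_heavy):
                contact_rows.append(_contact_row(name, c))
            for c in _contacts.find_hydrophobic_contacts(model, sel_pep, sel_heavy):
                contact_rows.append(_contact_row(name, c))
        pd.DataFrame(
            contact_rows,
            columns=["structure", "kind", "chainA", "resA", "atomA", "chainB", "resB", "atomB", "dist", "angle"],
        ).to_csv(out / "contacts.tsv", sep="\t", index=False)

    summary = {
        "structures": list(models),
        "missing_residue_counts": {
            n: int(missing_df[missing_df.structure == n].length.sum()) for n in models
        },
        "omega_deg": {r["structure"]: r["omega_deg"] for r in omega_rows},
        "n_ca_shift_rows": len(shift_rows),
        "n_contacts": len(contact_rows),
    }
    (out / "structure_summary.json").write_text(json.dumps(summary, indent=2))
    config.echo()
    return summary


def _contact_row(name: str, c) -> dict:
    return dict(
        structure=name,
        kind=c.kind,
        chainA=c.atom_a[0],
        resA=c.atom_a[1],
        atomA=c.atom_a[2],
        chainB=c.atom_b[0],
        resB=c.atom_b[1],
        atomB=c.atom_b[2],
        dist=round(c.distance, 2),
        angle=None if c.angle is None else round(c.angle, 1),
    )


def run_trajectory_report(
    config: RunConfig,
    traj: Trajectory | None = None,
    positions=None,
) -> dict:
    """Trajectory report: RMSF, interaction series/distributions, π-π, CH-π."""
    out = config.outdir()
    hch, pch = config.heavy_chain, config.peptide_chain
    if traj is None:
        with _timed("read_trajectory"):
            traj = read_trajectory(config.trajectory, dt_ps=config.dt_ps)
    summary: dict = {"n_frames": traj.n_frames}

    heavy_ca = AtomSelector(chain=hch, atom_names=("CA",))
    if len(traj.atom_indices(heavy_ca)) >= 3 and traj.n_frames >= 2:
        with _timed("rmsf"):
            aligned = superpose_frames(traj, heavy_ca)
            profile = rmsf(aligned, measure=AtomSelector(chain=hch, atom_names=("CA",)))
            pd.DataFrame(
                [
                    dict(chain=c, resnum=r, rmsf_A=round(v, 4))
                    for (c, r), v in zip(profile.residues, profile.values)
                ]
            ).to_csv(out / "rmsf.tsv", sep="\t", index=False)
            vals = profile.as_dict()
            summary["rmsf_max_residue"] = max(vals, key=vals.get)[1]
            summary["rmsf_max_A"] = round(max(vals.values()), 3)
        traj = aligned

    if positions is None:
        try:
            positions = resolve_peptide_positions(traj.frame_model(0), pch, hch)
        except Exception:
            from .structure_io import PeptidePositionMap

            pep_res = sorted({r.resnum for r in traj.topology if r.chain == pch})
            if pep_res:  # no disulfide anchor: fall back to first peptide residue as P1
                positions = PeptidePositionMap(pch, hch, {"P1": pep_res[0]})
            else:
                logger.info("no peptide chain %r: skipping interaction analysis", pch)

    for partner in ("Tyr59", "Ile52") if positions is not None else ():
        has_partner = any(
            r.chain == hch and r.resnum == (59 if partner == "Tyr59" else 52)
            for r in traj.topology
        )
        if not has_partner:
            continue
        with _timed(f"interaction[{partner}]"):
            series = _geometry.p1_interaction_series(traj, positions, partner)
            df = pd.DataFrame(dict(time_ps=series.times, distance_A=series.distances))
            if series.angles is not None:
                df["angle_deg"] = series.angles
            df.to_csv(out / f"interaction_{partner}.tsv", sep="\t", index=False)
            dist = _geometry.estimate_distribution(series.distances, config.distance_bin_width)
            summary[f"{partner}_distance_peak_A"] = round(dist.peak, 2)
            summary[f"{partner}_distance_fwhm_A"] = round(dist.fwhm, 2)
            if series.angles is not None and partner == "Tyr59":
                adist = _geometry.estimate_distribution(series.angles, config.angle_bin_width)
                summary["Tyr59_angle_peak_deg"] = round(adist.peak, 1)
                cls = _geometry.classify_pi_pi(series.angles)
                summary["pi_pi_class"] = cls.label
                summary["pi_pi_peak_deviation_deg"] = round(cls.peak_deviation, 1)
            if partner == "Ile52":
                verdicts = _chpi_verdicts(traj, positions, series)
                if verdicts is not None:
                    summary["ch_pi_fraction"] = round(float(np.mean(verdicts)), 3)

    (out / "trajectory_summary.json").write_text(json.dumps(summary, indent=2))
    config.echo()
    return summary


def _chpi_verdicts(traj: Trajectory, positions, series) -> np.ndarray | None:
    hch, pch = positions.heavy_chain, positions.peptide_chain
    p1 = positions.p1
    p1_name = next(
        (r.resname for r in traj.topology if r.chain == pch and r.resnum == p1), None
    )
    if p1_name != "PHE":
        return None
    ring = _geometry.RingSpec(pch, p1, "PHE")
    out = np.zeros(traj.n_frames, dtype=bool)
    for f in range(traj.n_frames):
        donor = {
            rec.name: traj.coordinates[f, i]
            for i, rec in enumerate(traj.topology)
            if rec.chain == hch and rec.resnum == 52
        }
        ring_atoms = {
            rec.name: traj.coordinates[f, i]
            for i, rec in enumerate(traj.topology)
            if rec.chain == pch and rec.resnum == p1
        }
        try:
            ang = _geometry.ch_pi_angle(donor, ring_atoms, ring)
        except _geometry.GeometryError:
            return None
        out[f] = _geometry.ch_pi_satisfied(float(series.distances[f]), ang)
    return out


def run_rotation_report(
    config: RunConfig, series_list: list[AngleSeries] | None = None
) -> dict:
    """ω rotation report over replicates; summary counts rotated replicates.

    Replicate inputs are TSV files (columns ``time_ps``, ``omega_deg``,
    wrapped) from ``config.rotation_series``, or in-memory series.  Each is
    unwrapped, smoothed (default 10 ns window) and scanned for start-band ->
    end-band rotation events modulo 360°.
    """
    out = config.outdir()
    if series_list is None:
        series_list = []
        for path in config.rotation_series:
            df = pd.read_csv(path, sep="\t")
            series_list.append(
                AngleSeries(
                    times_ps=df["time_ps"].to_numpy(),
                    values_deg=df["omega_deg"].to_numpy(),
                    wrapped=True,
                )
            )
    events_per_replicate: list[list[float]] = []
    for i, raw in enumerate(series_list):
        with _timed(f"rotation[replicate {i + 1}]"):
            uw = unwrap(raw) if raw.wrapped else raw
            sm = smooth(uw, config.smoothing_window_ns)
            events = detect_rotation(
                sm,
                start_deg=config.rotation_start_deg,
                end_deg=config.rotation_end_deg,
                tolerance_deg=config.rotation_tolerance_deg,
            )
            events_per_replicate.append(events)
            pd.DataFrame(
                dict(
                    time_ps=raw.times_ps,
                    omega_raw=raw.values_deg,
                    omega_unwrapped=uw.values_deg,
                    omega_smoothed=sm.values_deg,
                )
            ).to_csv(out / f"omega_replicate{i + 1}.tsv", sep="\t", index=False)
    n = len(series_list)
    k = sum(1 for ev in events_per_replicate if ev)
    summary = {
        "n_replicates": n,
        "n_rotated": k,
        "statement": f"{k} of {n} replicates rotated",
        "events_ps": events_per_replicate,
    }
    (out / "rotation_summary.json").write_text(json.dumps(summary, indent=2))
    config.echo()
    return summary


def run_melt_report(config: RunConfig, curves: dict[str, MeltCurve]) -> dict:
    """Tm per labelled melt curve (first-derivative minimum by default)."""
    out = config.outdir()
    results = {}
    for name, curve in curves.items():
        with _timed(f"tm[{name}]"):
            res = melting_temperature(curve)
            results[name] = round(res.tm, 1)
    (out / "tm_summary.json").write_text(json.dumps(results, indent=2))
    return results
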