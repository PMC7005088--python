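"""Readers/writers for the artifact formats.

GRO and XYZ for bead configurations, CSV for strain curves and tension
series, JSON for reports and RVs, HDF5 for trajectories.  GRO columns
follow the fixed-width standard (nm, 3 decimals); bead kind and species
are encoded in the atom/residue names so a configuration round-trips
through the file.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from ..axon_geometry import AxonRV
from ..axon_mechanics import LoadCase, MaterialTable, MechState, MechTrajectory
from ..cortex_strain import EnsembleCurve, StrainCurve
from ..membrane_synth import BeadConfiguration, TensionSeries

__all__ = [
    "write_gro", "read_gro", "write_xyz", "read_xyz",
    "write_curves_csv", "read_curves_csv",
    "write_tension_csv", "read_tension_csv",
    "save_rv_json", "load_rv_json",
    "save_trajectory_h5", "load_trajectory_h5",
    "config_hash",
]


class FormatError(ValueError):
    pass


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration."""
    s = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(s.encode()).hexdigest()[:12]


# ------------------------------------------------------------------ GRO / XYZ

_KIND_TO_ATOM = {"head": "HD", "tail": "TL", "water": "W",
                 "ion": "ION", "protein": "BB"}
_ATOM_TO_KIND = {v: k for k, v in _KIND_TO_ATOM.items()}


def write_gro(path, config: BeadConfiguration, title: str = "axoporate membrane"):
    """Write a bead configuration as a GRO file (nm, 3 decimals).

    The residue name is the species; the atom name encodes the bead
    kind, suffixed with ``O``/``I`` for outer/inner leaflet beads.
    """
    lines = [title, f"{config.n_beads:5d}"]
    resid_of = np.where(config.lipid_id >= 0, config.lipid_id + 1, 0)
    n_lipid_res = int(resid_of.max()) if len(resid_of) else 0
    nonlip = 0
    for i in range(config.n_beads):
        if resid_of[i] == 0:
            nonlip += 1
            resid = n_lipid_res + nonlip
        else:
            resid = int(resid_of[i])
        resid %= 100000
        atom = _KIND_TO_ATOM[str(config.kind[i])]
        leaf = str(config.leaflet[i])
        if leaf == "outer":
            atom += "O"
        elif leaf == "inner":
            atom += "I"
        x, y, z = config.coords[i]
        lines.append(f"{resid:5d}{str(config.species[i])[:5]:<5s}{atom:>5s}"
                     f"{(i + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}")
    lines.append(f"{config.box[0]:10.5f}{config.box[1]:10.5f}{config.box[2]:10.5f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gro(path) -> BeadConfiguration:
    text = Path(path).read_text().splitlines()
    if len(text) < 3:
        raise FormatError(f"{path}: truncated GRO file (fewer than 3 lines)")
    try:
        n = int(text[1])
    except ValueError as e:
        raise FormatError(f"{path}: line 2 is not an atom count") from e
    if len(text) < n + 3:
        raise FormatError(f"{path}: expected {n} atom lines, file ends at "
                          f"line {len(text)}")
    coords = np.zeros((n, 3))
    kind = np.empty(n, dtype=object)
    leaflet = np.empty(n, dtype=object)
    species = np.empty(n, dtype=object)
    lipid_id = np.full(n, -1, dtype=int)
    for i in range(n):
        ln = text[2 + i]
        try:
            resid = int(ln[0:5])
            resname = ln[5:10].strip()
            atom = ln[10:15].strip()
            coords[i] = [float(ln[20:28]), float(ln[28:36]), float(ln[36:44])]
        except (ValueError, IndexError) as e:
            raise FormatError(f"{path}: malformed atom line {3 + i}: {ln!r}") from e
        leaf = "none"
        base = atom
        if atom.endswith(("O", "I")) and atom[:-1] in _ATOM_TO_KIND:
            leaf = "outer" if atom.endswith("O") else "inner"
            base = atom[:-1]
        if base not in _ATOM_TO_KIND:
            raise FormatError(f"{path}: unknown atom name {atom!r} on line {3 + i}")
        kind[i] = _ATOM_TO_KIND[base]
        leaflet[i] = leaf
        species[i] = resname
        if kind[i] in ("head", "tail"):
            lipid_id[i] = resid - 1
    try:
        box = np.array([float(v) for v in text[2 + n].split()[:3]])
    except (ValueError, IndexError) as e:
        raise FormatError(f"{path}: malformed box line {3 + n}") from e
    return BeadConfiguration(coords=coords, kind=kind, leaflet=leaflet,
                             species=species, lipid_id=lipid_id, box=box)


def write_xyz(path, config: BeadConfiguration, comment: str = ""):
    lines = [str(config.n_beads),
             comment or f"box {config.box[0]} {config.box[1]} {config.box[2]}"]
    for i in range(config.n_beads):
        x, y, z = config.coords[i]
        lines.append(f"{str(config.species[i]):<6s} {x:12.5f} {y:12.5f} {z:12.5f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path) -> tuple[np.ndarray, np.ndarray]:
    """(labels, coords) from an XYZ file; no kind/leaflet metadata."""
    text = Path(path).read_text().splitlines()
    if len(text) < 2:
        raise FormatError(f"{path}: truncated XYZ file")
    try:
        n = int(text[0])
    except ValueError as e:
        raise FormatError(f"{path}: first line is not an atom count") from e
    if len(text) < n + 2:
        raise FormatError(f"{path}: expected {n} atom lines")
    labels = np.empty(n, dtype=object)
    coords = np.zeros((n, 3))
    for i in range(n):
        parts = text[2 + i].split()
        if len(parts) < 4:
            raise FormatError(f"{path}: malformed line {3 + i}")
        labels[i] = parts[0]
        coords[i] = [float(v) for v in parts[1:4]]
    return labels, coords


# ------------------------------------------------------------------ CSV

def write_curves_csv(path, ensembles: dict[float, EnsembleCurve]):
    rows = []
    for rate in sorted(ensembles):
        e = ensembles[rate]
        for i, ea in enumerate(e.eps_axon):
            rows.append({"rate": rate, "eps_axon": float(ea),
                         "mean_eps_x": float(e.mean_eps_x[i]),
                         "sd_eps_x": float(e.sd_eps_x[i]),
                         "mean_eps_y": float(e.mean_eps_y[i]),
                         "n_members": e.n_members})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_curves_csv(path) -> dict[float, EnsembleCurve]:
    df = pd.read_csv(path)
    out = {}
    for rate, g in df.groupby("rate"):
        g = g.sort_values("eps_axon")
        out[float(rate)] = EnsembleCurve(
            rate=float(rate), eps_axon=g["eps_axon"].to_numpy(),
            mean_eps_x=g["mean_eps_x"].to_numpy(),
            sd_eps_x=g["sd_eps_x"].to_numpy(),
            mean_eps_y=g["mean_eps_y"].to_numpy(),
            n_members=int(g["n_members"].iloc[0]))
    return out


def write_tension_csv(path, series: TensionSeries):
    df = pd.DataFrame({"step": series.steps, "gamma_mN_per_m": series.gamma})
    df.to_csv(path, index=False)


def read_tension_csv(path) -> TensionSeries:
    df = pd.read_csv(path)
    return TensionSeries(steps=df["step"].to_numpy(),
                        gamma=df["gamma_mN_per_m"].to_numpy())


# ------------------------------------------------------------------ RV JSON

def save_rv_json(path, rv: AxonRV):
    Path(path).write_text(rv.to_json())


def load_rv_json(path) -> AxonRV:
    return AxonRV.from_json(Path(path).read_text())


# ------------------------------------------------------------------ trajectory

def save_trajectory_h5(path, traj: MechTrajectory):
    with h5py.File(path, "w") as f:
        f.attrs["rv_json"] = traj.rv.to_json()
        f.attrs["materials"] = json.dumps(
            {k: getattr(traj.materials, k)
             for k in traj.materials.__dataclass_fields__})
        f.attrs["load"] = json.dumps({
            "strain_rate": traj.load.strain_rate,
            "target_axonal_strain": traj.load.target_axonal_strain,
            "eps_grid": list(traj.load.eps_grid),
            "steps_per_grid": traj.load.steps_per_grid})
        f.create_dataset("events", data=np.asarray(traj.events, dtype=np.int64)
                         .reshape(-1, 2))
        for i, st in enumerate(traj.states):
            g = f.create_group(f"state_{i:04d}")
            g.attrs["time"] = st.time
            g.attrs["eps_axon"] = st.eps_axon
            g.attrs["applied_displacement"] = st.applied_displacement
            g.attrs["kinetic_energy"] = st.kinetic_energy
            g.create_dataset("u", data=st.u)
            g.create_dataset("v", data=st.v)
            g.create_dataset("link_status", data=st.link_status)
            g.create_dataset("link_elongation", data=st.link_elongation)


def load_trajectory_h5(path) -> MechTrajectory:
    with h5py.File(path, "r") as f:
        rv = AxonRV.from_json(f.attrs["rv_json"])
        mats = MaterialTable(**json.loads(f.attrs["materials"]))
        ld = json.loads(f.attrs["load"])
        load = LoadCase(strain_rate=ld["strain_rate"],
                        target_axonal_strain=ld["target_axonal_strain"],
                        eps_grid=tuple(ld["eps_grid"]),
                        steps_per_grid=ld["steps_per_grid"])
        states = []
        names = sorted(k for k in f.keys() if k.startswith("state_"))
        for name in names:
            g = f[name]
            states.append(MechState(
                time=float(g.attrs["time"]),
                eps_axon=float(g.attrs["eps_axon"]),
                applied_displacement=float(g.attrs["applied_displacement"]),
                u=g["u"][...], v=g["v"][...],
                link_status=g["link_status"][...],
                link_elongation=g["link_elongation"][...],
                kinetic_energy=float(g.attrs["kinetic_energy"])))
        events = [tuple(int(x) for x in row) for row in f["events"][...]]
    return MechTrajectory(rv=rv, materials=mats, load=load,
                          states=states, events=events)
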