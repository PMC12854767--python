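"""Text-format plumbing: record tables, spectra, trajectories, site files.

All formats are plain delimited text so artifacts stay diffable:

* excited-state records — TSV with header
  ``snapshot  time_fs  chromophore  state  energy_eV  fosc  delta_tpa_au  delta_3pa_au``;
* spectra — two-column ``energy_eV  intensity`` TSV, comment header carrying
  process, units, gamma and snapshot count;
* trajectories — multi-frame XYZ (Å), the frame time stored in the comment
  line as ``t= <fs> fs``; single-model-per-frame PDB is read via MDAnalysis;
* topology — JSON with ``sigma_bonds`` / ``pi_bonds`` / ``dihedrals``
  (0-based indices);
* charge clouds — ``x  y  z  q`` in atomic units;
* polarizable sites — one row per site: position (bohr), charge, dipole
  (3), quadrupole (xx xy xz yy yz zz, e*bohr^2), polarizability
  (xx xy xz yy yz zz, bohr^3), fragment_id.

Every writer accepts ``header`` comment lines that are prefixed with ``#``.
"""

from __future__ import annotations

import json
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .spectra import ExcitedStateRecord, SnapshotRecord, Spectrum
from .structure import StructuralTimeline, Trajectory
from .coupling import ChargeCloud
from .polarization import PolarizableSite
from .sampling import AcfResult, TimeSeries

RECORD_COLUMNS = [
    "snapshot",
    "time_fs",
    "chromophore",
    "state",
    "energy_eV",
    "fosc",
    "delta_tpa_au",
    "delta_3pa_au",
]


def _write_header(fh, header: Iterable[str] | None) -> None:
    for line in header or ():
        fh.write(f"# {line}\n")


def records_to_frame(records: Sequence[SnapshotRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        for s in r.states:
            rows.append(
                (
                    r.snapshot_id,
                    r.time,
                    r.chromophore,
                    s.state_index,
                    s.energy,
                    s.oscillator_strength,
                    s.delta_tpa,
                    s.delta_3pa,
                )
            )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_records(path, records: Sequence[SnapshotRecord], header=None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, header)
        records_to_frame(records).to_csv(fh, sep="\t", index=False)


def read_records(path) -> list[SnapshotRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"record table missing columns: {sorted(missing)}")
    records = []
    for (snap, chromo), grp in df.groupby(["snapshot", "chromophore"], sort=True):
        grp = grp.sort_values("state")
        states = tuple(
            ExcitedStateRecord(
                state_index=int(row.state),
                energy=float(row.energy_eV),
                oscillator_strength=float(row.fosc),
                delta_tpa=float(row.delta_tpa_au),
                delta_3pa=float(row.delta_3pa_au),
            )
            for row in grp.itertuples()
        )
        records.append(
            SnapshotRecord(
                snapshot_id=int(snap),
                time=float(grp.time_fs.iloc[0]),
                chromophore=str(chromo),
                states=states,
            )
        )
    records.sort(key=lambda r: (r.time, r.chromophore))
    return records


def write_spectrum(path, spectrum: Spectrum, header=None) -> None:
    lines = list(header or ())
    lines += [
        f"process= {spectrum.process}",
        f"units= {spectrum.units}",
        f"gamma_eV= {spectrum.gamma}",
        f"n_snapshots= {spectrum.n_snapshots}",
    ]
    with open(path, "w") as fh:
        _write_header(fh, lines)
        fh.write("energy_eV\tintensity\n")
        for e, i in zip(spectrum.grid, spectrum.intensity):
            fh.write(f"{e:.6f}\t{i:.8e}\n")


def read_spectrum(path) -> Spectrum:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    return Spectrum(
        grid=df.energy_eV.to_numpy(),
        intensity=df.intensity.to_numpy(),
        process=meta.get("process", "OPA"),
        units=meta.get("units", ""),
        n_snapshots=int(meta.get("n_snapshots", 0)),
    )


def write_series(path, series: TimeSeries, header=None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, header)
        fh.write("time_fs\tvalue\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{t:.6f}\t{v:.10e}\n")


def read_series(path) -> TimeSeries:
    df = pd.read_csv(path, sep="\t", comment="#")
    return TimeSeries(times=df.time_fs.to_numpy(), values=df.value.to_numpy())


def write_acf(path, acf: AcfResult, header=None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, header)
        fh.write("lag_fs\tc\n")
        for lag, c in zip(acf.lags, acf.c):
            fh.write(f"{lag:.6f}\t{c:.10e}\n")


def write_xyz(path, traj: Trajectory, header_comment: str = "") -> None:
    """Multi-frame XYZ in Å; frame time goes in the comment line."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            extra = f" {header_comment}" if header_comment else ""
            fh.write(f"t= {traj.times[f]:.6f} fs{extra}\n")
            for el, (x, y, z) in zip(traj.elements, traj.coordinates[f]):
                fh.write(f"{el} {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path) -> Trajectory:
    frames, times, elements = [], [], None
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        n = int(lines[i].strip())
        comment = lines[i + 1]
        t = 0.0
        if "t=" in comment:
            try:
                t = float(comment.split("t=")[1].split()[0])
            except (ValueError, IndexError):
                t = 0.0
        block = lines[i + 2 : i + 2 + n]
        els = tuple(row.split()[0] for row in block)
        coords = np.array([[float(v) for v in row.split()[1:4]] for row in block])
        if elements is None:
            elements = els
        elif els != elements:
            raise ValueError("atom list changes between XYZ frames")
        frames.append(coords)
        times.append(t)
        i += 2 + n
    if not frames:
        raise ValueError(f"no frames in XYZ file {path}")
    if len(set(times)) == 1 and len(times) > 1:
        times = list(range(len(frames)))  # untimed file: frame index
    return Trajectory(elements=elements, coordinates=np.array(frames), times=np.array(times, dtype=float))


def read_pdb(path, dt: float = 1.0) -> Trajectory:
    """Single-model-per-frame PDB via MDAnalysis; frame times are index*dt fs."""
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    elements = tuple(a.element if a.element else a.name[0] for a in u.atoms)
    coords = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    times = np.arange(coords.shape[0]) * dt
    return Trajectory(elements=elements, coordinates=coords, times=times)


def write_timeline(path, tl: StructuralTimeline, header=None) -> None:
    cols = (
        ["time_fs", "bla_A"]
        + [f"sigma{i+1}_A" for i in range(5)]
        + [f"pi{i+1}_A" for i in range(5)]
        + [f"theta{i+1}_deg" for i in range(10)]
        + ["planarity"]
    )
    data = np.column_stack(
        [tl.times, tl.bla, tl.sigma_lengths, tl.pi_lengths, tl.dihedrals, tl.planarity]
    )
    with open(path, "w") as fh:
        _write_header(
            fh,
            list(header or ())
            + ["units: Å, degrees in (-180, 180], 0-based topology indices"],
        )
        fh.write("\t".join(cols) + "\n")
        np.savetxt(fh, data, delimiter="\t", fmt="%.8f")


def read_timeline(path) -> StructuralTimeline:
    df = pd.read_csv(path, sep="\t", comment="#")
    return StructuralTimeline(
        times=df.time_fs.to_numpy(),
        bla=df.bla_A.to_numpy(),
        sigma_lengths=df[[f"sigma{i+1}_A" for i in range(5)]].to_numpy(),
        pi_lengths=df[[f"pi{i+1}_A" for i in range(5)]].to_numpy(),
        dihedrals=df[[f"theta{i+1}_deg" for i in range(10)]].to_numpy(),
        planarity=df.planarity.to_numpy(),
    )


def write_charge_cloud(path, cloud: ChargeCloud, header=None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, list(header or ()) + ["columns: x y z q (a.u.)"])
        fh.write("x\ty\tz\tq\n")
        for (x, y, z), q in zip(cloud.positions, cloud.charges):
            fh.write(f"{x:.10f}\t{y:.10f}\t{z:.10f}\t{q:.10f}\n")


def read_charge_cloud(path) -> ChargeCloud:
    df = pd.read_csv(path, sep="\t", comment="#")
    return ChargeCloud(
        positions=df[["x", "y", "z"]].to_numpy(), charges=df.q.to_numpy()
    )


_SITE_COLS = (
    ["x", "y", "z", "q", "mu_x", "mu_y", "mu_z"]
    + ["theta_xx", "theta_xy", "theta_xz", "theta_yy", "theta_yz", "theta_zz"]
    + ["alpha_xx", "alpha_xy", "alpha_xz", "alpha_yy", "alpha_yz", "alpha_zz"]
    + ["fragment_id"]
)


def _sym_unpack(v) -> np.ndarray:
    xx, xy, xz, yy, yz, zz = v
    return np.array([[xx, xy, xz], [xy, yy, yz], [xz, yz, zz]])


def write_sites(path, sites: Sequence[PolarizableSite], header=None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, list(header or ()) + ["all columns in atomic units"])
        fh.write("\t".join(_SITE_COLS) + "\n")
        for s in sites:
            t, a = s.quadrupole, s.polarizability
            row = (
                list(s.position)
                + [s.charge]
                + list(s.dipole)
                + [t[0, 0], t[0, 1], t[0, 2], t[1, 1], t[1, 2], t[2, 2]]
                + [a[0, 0], a[0, 1], a[0, 2], a[1, 1], a[1, 2], a[2, 2]]
            )
            fh.write("\t".join(f"{v:.10f}" for v in row) + f"\t{s.fragment_id}\n")


def read_sites(path) -> list[PolarizableSite]:
    df = pd.read_csv(path, sep="\t", comment="#")
    sites = []
    for row in df.itertuples():
        sites.append(
            PolarizableSite(
                position=np.array([row.x, row.y, row.z]),
                charge=float(row.q),
                dipole=np.array([row.mu_x, row.mu_y, row.mu_z]),
                quadrupole=_sym_unpack(
                    [row.theta_xx, row.theta_xy, row.theta_xz, row.theta_yy, row.theta_yz, row.theta_zz]
                ),
                polarizability=_sym_unpack(
                    [row.alpha_xx, row.alpha_xy, row.alpha_xz, row.alpha_yy, row.alpha_yz, row.alpha_zz]
                ),
                fragment_id=int(row.fragment_id),
            )
        )
    return sites


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
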