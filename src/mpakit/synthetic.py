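"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate, at configurable scale, the statistical features of
the excited-state ensembles and chromophore trajectories the pipeline is
meant for:

* ``make_ensemble`` — per-state excited-state observables following a
  stationary AR(1) process (the minimal stationary process with a fast
  exponentially decaying autocorrelation), approximately Gaussian
  marginals, and a configurable correlation time;
* ``make_chain_trajectory`` — a 13-backbone-atom alternating single/double
  bond chain built from internal coordinates (bond lengths, 120 deg
  angles, prescribed dihedrals), so the exact per-frame sigma/pi bond
  lengths and dihedrals are known by construction;
* ``make_coupled_dataset`` — trajectory + records in which the first
  excitation energy is a linear function of the frame's true BLA and
  planarity plus noise (lower BLA and higher planarity give a lower E1);
* ``make_charge_cloud`` / ``make_sites`` — random charge clouds and
  water-like polarizable fragments for the electrostatics modules.

Every generator returns a machine-readable ground-truth sidecar holding
the generating parameters (and, for geometry, the prescribed descriptor
values); recovery tests read only the sidecar.  All randomness flows from
the single explicit ``seed`` in each config.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass


import numpy as np

from .polarization import PolarizableSite
from .coupling import ChargeCloud
from .spectra import ExcitedStateRecord, SnapshotRecord
from .structure import ConjugationTopology, StructuralTimeline, Trajectory

__all__ = [
    "StateParams",
    "EnsembleConfig",
    "ChainConfig",
    "make_ensemble",
    "make_chain_trajectory",
    "make_coupled_dataset",
    "make_charge_cloud",
    "make_sites",
]


@dataclass(frozen=True)
class StateParams:
    """Stationary mean/sd of one state's observables (eV for energy, a.u. else)."""

    energy_mean: float
    energy_sd: float = 0.10
    fosc_mean: float = 0.5
    fosc_sd: float = 0.05
    delta_tpa_mean: float = 5000.0
    delta_tpa_sd: float = 500.0
    delta_3pa_mean: float = 1.0e6
    delta_3pa_sd: float = 1.0e5


# Default three-state ladder: first two means at the retinal chromophore's
# QM-sampled one-photon peak energies (2.81, 4.13 eV); the third state is a
# weak higher-lying transition.
DEFAULT_STATES: tuple[StateParams, ...] = (
    StateParams(energy_mean=2.81, fosc_mean=0.90, delta_tpa_mean=6000.0),
    StateParams(energy_mean=4.13, fosc_mean=0.35, delta_tpa_mean=30000.0),
    StateParams(energy_mean=5.20, fosc_mean=0.10, delta_tpa_mean=3000.0),
)


@dataclass(frozen=True)
class EnsembleConfig:
    """Settings of the AR(1) excited-state ensemble generator."""

    n_snapshots: int = 200
    dt: float = 5.0                        # fs
    states: tuple[StateParams, ...] = DEFAULT_STATES
    correlation_time: float = 15.0         # fs
    chromophore: str = "LYR-472"
    seed: int = 0
    # E1 = c0 + c_bla * BLA + c_planarity * (10 - P) + noise  (coupled datasets)
    coupling_c0: float = 2.40              # eV
    coupling_c_bla: float = 4.0            # eV / Å
    coupling_c_planarity: float = 0.05     # eV per unit of (10 - P)
    coupling_noise_sd: float = 0.05        # eV

    def __post_init__(self) -> None:
        if self.n_snapshots < 1 or self.dt <= 0 or self.correlation_time <= 0:
            raise ValueError("invalid ensemble config")
        for s in self.states:
            if s.energy_mean <= 0:
                raise ValueError("state energy means must be positive")
            if min(s.energy_sd, s.fosc_sd, s.delta_tpa_sd, s.delta_3pa_sd) < 0:
                raise ValueError("state sds must be non-negative")


@dataclass(frozen=True)
class ChainConfig:
    """Settings of the internal-coordinate polyene chain builder."""

    n_frames: int = 200
    dt: float = 5.0                # fs
    mean_sigma: float = 1.46       # Å, single-bond length
    mean_pi: float = 1.36          # Å, double-bond length
    bond_sd: float = 0.01          # Å
    dihedral_mean: float = 180.0   # degrees
    dihedral_sd: float = 10.0      # degrees
    bond_angle: float = 120.0      # degrees
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.mean_sigma, self.mean_pi) <= 0:
            raise ValueError("bond lengths must be positive")
        if self.bond_sd < 0 or self.dihedral_sd < 0:
            raise ValueError("spreads must be non-negative")
        if not 0 < self.bond_angle < 180:
            raise ValueError("bond angle must be in (0, 180) degrees")
        if self.n_frames < 1 or self.dt <= 0:
            raise ValueError("invalid frame settings")


def _ar1(rng: np.random.Generator, n: int, mean: float, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1): lag-1 coefficient phi, stationary N(mean, sd) marginals."""
    if sd == 0.0:
        return np.full(n, mean)
    x = np.empty(n)
    x[0] = rng.normal(mean, sd)
    innov = rng.normal(0.0, sd * math.sqrt(1.0 - phi**2), size=n - 1)
    for t in range(1, n):
        x[t] = mean + phi * (x[t - 1] - mean) + innov[t - 1]
    return x


def make_ensemble(config: EnsembleConfig) -> tuple[list[SnapshotRecord], dict]:
    """Temporally correlated excited-state ensemble + ground-truth sidecar.

    Each observable of each state is an independent AR(1) series with
    lag-1 coefficient ``exp(-dt / correlation_time)``; strengths are
    truncated at zero (a negligible perturbation at the default
    signal-to-noise ratios).
    """
    rng = np.random.default_rng(config.seed)
    phi = math.exp(-config.dt / config.correlation_time)
    n = config.n_snapshots
    per_state = []
    for sp in config.states:
        per_state.append(
            {
                "energy": np.maximum(_ar1(rng, n, sp.energy_mean, sp.energy_sd, phi), 1e-6),
                "fosc": np.maximum(_ar1(rng, n, sp.fosc_mean, sp.fosc_sd, phi), 0.0),
                "delta_tpa": np.maximum(
                    _ar1(rng, n, sp.delta_tpa_mean, sp.delta_tpa_sd, phi), 0.0
                ),
                "delta_3pa": np.maximum(
                    _ar1(rng, n, sp.delta_3pa_mean, sp.delta_3pa_sd, phi), 0.0
                ),
            }
        )
    records = []
    for t in range(n):
        states = tuple(
            ExcitedStateRecord(
                state_index=i + 1,
                energy=float(obs["energy"][t]),
                oscillator_strength=float(obs["fosc"][t]),
                delta_tpa=float(obs["delta_tpa"][t]),
                delta_3pa=float(obs["delta_3pa"][t]),
            )
            for i, obs in enumerate(per_state)
        )
        records.append(
            SnapshotRecord(
                snapshot_id=t,
                time=t * config.dt,
                chromophore=config.chromophore,
                states=states,
            )
        )
    sidecar = {
        "generator": "make_ensemble",
        "config": asdict(config),
        "lag1_coefficient": phi,
    }
    return records, sidecar


def default_topology() -> ConjugationTopology:
    """Topology of the 13-atom chain: descriptor bonds between atoms 1..11.

    Bond i connects atoms (i, i+1); bonds 1, 3, 5, 7, 9 are pi (double),
    bonds 2, 4, 6, 8, 10 sigma (single); the dihedral around bond i is
    (i-1, i, i+1, i+2).  Atoms 0 and 12 only flank the terminal dihedrals.
    """
    pi_bonds = tuple((i, i + 1) for i in (1, 3, 5, 7, 9))
    sigma_bonds = tuple((i, i + 1) for i in (2, 4, 6, 8, 10))
    dihedrals = tuple((i - 1, i, i + 1, i + 2) for i in range(1, 11))
    return ConjugationTopology(
        sigma_bonds=sigma_bonds, pi_bonds=pi_bonds, dihedrals=dihedrals
    )


N_CHAIN_ATOMS = 13
_FLANK_BOND = 1.50  # Å, terminal bonds outside the conjugated segment


def _place_chain(bonds: np.ndarray, angle_deg: float, torsions_deg: np.ndarray) -> np.ndarray:
    """Cartesian embedding of a chain from internal coordinates (NeRF).

    ``bonds``: 12 bond lengths (atom i to i+1); ``torsions_deg``: 10
    dihedrals, torsion j applying to the quadruple (j, j+1, j+2, j+3).
    The supplement angle is used at every internal atom.
    """
    coords = np.zeros((N_CHAIN_ATOMS, 3))
    theta = math.radians(180.0 - angle_deg)  # deviation from straight
    coords[1] = coords[0] + [bonds[0], 0.0, 0.0]
    coords[2] = coords[1] + bonds[1] * np.array(
        [math.cos(theta), math.sin(theta), 0.0]
    )
    for k in range(3, N_CHAIN_ATOMS):
        a, b, c = coords[k - 3], coords[k - 2], coords[k - 1]
        r = bonds[k - 1]
        ang = math.radians(angle_deg)
        tor = math.radians(torsions_deg[k - 3])
        bc = c - b
        bc /= np.linalg.norm(bc)
        ab = b - a
        n = np.cross(ab, bc)
        n /= np.linalg.norm(n)
        m = np.cross(n, bc)
        d = np.array(
            [
                -r * math.cos(ang),
                r * math.sin(ang) * math.cos(tor),
                r * math.sin(ang) * math.sin(tor),
            ]
        )
        coords[k] = c + d[0] * bc + d[1] * m + d[2] * n
    return coords


def _wrap_angle(theta: np.ndarray) -> np.ndarray:
    """Wrap degrees into (-180, 180]."""
    t = (np.asarray(theta, dtype=float) + 180.0) % 360.0 - 180.0
    return np.where(t == -180.0, 180.0, t)


def make_chain_trajectory(
    config: ChainConfig,
) -> tuple[Trajectory, ConjugationTopology, StructuralTimeline, dict]:
    """Polyene-like trajectory with prescribed per-frame internal coordinates.

    Returns the Cartesian trajectory, its conjugation topology, the
    ground-truth structural timeline (computed from the sampled internal
    coordinates, not from the embedded Cartesians), and a sidecar with the
    generating parameters.
    """
    rng = np.random.default_rng(config.seed)
    topo = default_topology()
    nf = config.n_frames
    sigma_truth = rng.normal(config.mean_sigma, config.bond_sd, size=(nf, 5))
    pi_truth = rng.normal(config.mean_pi, config.bond_sd, size=(nf, 5))
    if np.min(sigma_truth) <= 0 or np.min(pi_truth) <= 0:
        raise ValueError("sampled a non-positive bond length; reduce bond_sd")
    torsions = _wrap_angle(
        rng.normal(config.dihedral_mean, config.dihedral_sd, size=(nf, 10))
    )
    coords = np.empty((nf, N_CHAIN_ATOMS, 3))
    for f in range(nf):
        bonds = np.empty(12)
        bonds[0] = bonds[11] = _FLANK_BOND
        for j, (i, _) in enumerate(topo.pi_bonds):
            bonds[i] = pi_truth[f, j]
        for j, (i, _) in enumerate(topo.sigma_bonds):
            bonds[i] = sigma_truth[f, j]
        coords[f] = _place_chain(bonds, config.bond_angle, torsions[f])
    times = np.arange(nf) * config.dt
    traj = Trajectory(
        elements=tuple(["C"] * N_CHAIN_ATOMS), coordinates=coords, times=times
    )
    from .structure import planarity_from_angles  # local to avoid cycle at import

    truth = StructuralTimeline(
        times=times.copy(),
        bla=(sigma_truth.sum(axis=1) - pi_truth.sum(axis=1)) / 5.0,
        sigma_lengths=sigma_truth,
        pi_lengths=pi_truth,
        dihedrals=torsions,
        planarity=planarity_from_angles(torsions),
    )
    sidecar = {
        "generator": "make_chain_trajectory",
        "config": asdict(config),
        "bla_mean_truth": float(np.mean(truth.bla)),
        "planarity_mean_truth": float(np.mean(truth.planarity)),
    }
    return traj, topo, truth, sidecar


def make_coupled_dataset(
    ensemble_cfg: EnsembleConfig, chain_cfg: ChainConfig
) -> tuple[Trajectory, ConjugationTopology, StructuralTimeline, list[SnapshotRecord], dict]:
    """Trajectory + records whose first excitation energy tracks the geometry.

    ``E1_t = c0 + c_bla * BLA_t + c_planarity * (10 - P_t) + noise`` with the
    coefficients from ``ensemble_cfg``; positive ``c_bla`` makes the BLA–E1
    correlation positive, positive ``c_planarity`` makes the planarity–E1
    correlation negative (more planar -> lower E1).  The remaining states
    and all strengths come from the AR(1) generator.
    """
    if ensemble_cfg.n_snapshots != chain_cfg.n_frames or ensemble_cfg.dt != chain_cfg.dt:
        raise ValueError("ensemble and chain configs disagree in n or dt")
    traj, topo, truth, chain_sidecar = make_chain_trajectory(chain_cfg)
    records, ens_sidecar = make_ensemble(ensemble_cfg)
    rng = np.random.default_rng(ensemble_cfg.seed + 1)
    noise = rng.normal(0.0, ensemble_cfg.coupling_noise_sd, size=len(records))
    e1 = (
        ensemble_cfg.coupling_c0
        + ensemble_cfg.coupling_c_bla * truth.bla
        + ensemble_cfg.coupling_c_planarity * (10.0 - truth.planarity)
        + noise
    )
    coupled = []
    for t, rec in enumerate(records):
        states = list(rec.states)
        first = states[0]
        states[0] = ExcitedStateRecord(
            state_index=first.state_index,
            energy=float(max(e1[t], 1e-6)),
            oscillator_strength=first.oscillator_strength,
            delta_tpa=first.delta_tpa,
            delta_3pa=first.delta_3pa,
        )
        coupled.append(
            SnapshotRecord(
                snapshot_id=rec.snapshot_id,
                time=rec.time,
                chromophore=rec.chromophore,
                states=tuple(states),
            )
        )
    sidecar = {
        "generator": "make_coupled_dataset",
        "coefficients": {
            "c0": ensemble_cfg.coupling_c0,
            "c_bla": ensemble_cfg.coupling_c_bla,
            "c_planarity": ensemble_cfg.coupling_c_planarity,
            "noise_sd": ensemble_cfg.coupling_noise_sd,
        },
        "chain": chain_sidecar,
        "ensemble": ens_sidecar,
    }
    return traj, topo, truth, coupled, sidecar


def make_charge_cloud(
    n: int, extent: float = 4.0, net_charge: float = 0.0, seed: int = 0
) -> tuple[ChargeCloud, dict]:
    """Uniform random charge cloud in a cube of side ``extent`` bohr.

    Charges are drawn uniformly in (-1, 1) e and shifted so the total
    charge equals ``net_charge`` exactly.
    """
    if n < 1:
        raise ValueError("need n >= 1 charges")
    rng = np.random.default_rng(seed)
    positions = rng.uniform(-extent / 2.0, extent / 2.0, size=(n, 3))
    charges = rng.uniform(-1.0, 1.0, size=n)
    charges += (net_charge - charges.sum()) / n
    cloud = ChargeCloud(positions=positions, charges=charges)
    sidecar = {
        "generator": "make_charge_cloud",
        "n": n,
        "extent_bohr": extent,
        "net_charge": net_charge,
        "seed": seed,
    }
    return cloud, sidecar


# Water-like 3-site fragment in a.u.: O at origin, O-H 1.81 bohr, 104.5 deg.
_WATER_CHARGES = (-0.66, 0.33, 0.33)
_WATER_ALPHAS = (5.7, 2.1, 2.1)  # bohr^3, LoProp-like magnitudes
_OH = 1.81
_HOH = math.radians(104.5)


def make_sites(
    n_fragments: int, seed: int = 0, spacing: float = 7.0
) -> tuple[list[PolarizableSite], dict]:
    """Randomly oriented charge-neutral water-like polarizable fragments.

    Fragments sit on a jittered cubic lattice with nearest-neighbor spacing
    ``spacing`` bohr — far enough apart at the default that the mutual
    polarization operator stays well below the catastrophe threshold.
    """
    if n_fragments < 1:
        raise ValueError("need at least one fragment")
    rng = np.random.default_rng(seed)
    local = np.array(
        [
            [0.0, 0.0, 0.0],
            [_OH * math.sin(_HOH / 2), 0.0, _OH * math.cos(_HOH / 2)],
            [-_OH * math.sin(_HOH / 2), 0.0, _OH * math.cos(_HOH / 2)],
        ]
    )
    side = math.ceil(n_fragments ** (1.0 / 3.0))
    lattice = [
        (i, j, k) for i in range(side) for j in range(side) for k in range(side)
    ][:n_fragments]
    sites: list[PolarizableSite] = []
    for frag, cell in enumerate(lattice):
        center = spacing * np.array(cell, dtype=float) + rng.uniform(-0.5, 0.5, 3)
        # random rotation from a QR decomposition of a Gaussian matrix
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        for pos, chg, alpha in zip(local @ q.T + center, _WATER_CHARGES, _WATER_ALPHAS):
            sites.append(
                PolarizableSite.isotropic(
                    position=pos, alpha=alpha, charge=chg, fragment_id=frag
                )
            )
    sidecar = {
        "generator": "make_sites",
        "n_fragments": n_fragments,
        "seed": seed,
        "spacing_bohr": spacing,
        "fragment_charges": list(_WATER_CHARGES),
        "fragment_alphas": list(_WATER_ALPHAS),
    }
    return sites, sidecar
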