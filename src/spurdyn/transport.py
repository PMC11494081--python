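"""Time-dependent Monte Carlo + MD transport of secondary electrons.

One *trial* (history) follows a single energy deposition: the initial
secondary electron starts at the origin — the centre of its parent cation's
potential well — with kinetic energy equal to the full deposition energy,
directed along +z.  Every live electron is advanced with velocity-Verlet steps
of the configured time step (1 attosecond by default) in the screened
two-body field of its own parent cation; per step, a collision fires when
1 - exp(-ds/lambda) exceeds a uniform draw, and the sampled channel is
dispatched (elastic exchange with the 300 K bath, molecular quantum
loss/gain, electronic excitation with kinematic deflection, or ionisation
which spawns an additional electron in a fresh cation well).  Trials end at
the cutoff time (500 fs default), when terminal states are classified as
relocalised (< 1 nm from the own parent) or delocalised.

The module exposes both single-collision operations on explicit electron
states (used for unit-level physics checks) and the compiled per-trial engine
used for ensembles.  Both paths share the same rate tables.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from . import _engine
from .constants import K_BOLTZMANN, K_COULOMB, M0C2, M_ELECTRON, M_WATER
from .field import (
    CORE_RADIUS_DEFAULT,
    DielectricResponse,
    CationSite,
    WELL_DEPTH_DEFAULT,
    calibrate_short_time_eps,
    eps_r,
    potential_energy,
)
from .xs import (
    ChannelSpec,
    CrossSectionBundle,
    sample_elastic_angle,
    sample_energy_transfer,
    sigma_elastic,
    sigma_momentum_transfer,
)


@dataclass
class SimulationConfig:
    """Run configuration; defaults reproduce the reference study conditions."""

    deposition_energy: float = 22.0          # eV
    n_trials: int = 1
    time_step: float = 1.0e-3                # fs (1 attosecond)
    cutoff_time: float = 500.0               # fs
    temperature: float = 300.0               # K
    seed: int = 0
    relocalisation_radius: float = 1.0       # nm
    classification_rule: str = "parent_distance"
    core_radius: float = CORE_RADIUS_DEFAULT  # nm
    well_depth: float = WELL_DEPTH_DEFAULT    # eV, calibrates eps_r(0)
    eps_static: float = 78.4
    relaxation_time: float = 300.0           # fs
    frozen_eps: bool = False
    elastic_energy_exchange: str = "kinematic"  # or "mean"
    detailed_balance: bool = True
    transfer_weight_L: bool = True
    log_all_events: bool = False
    collisions: bool = True
    max_electrons: int = 64
    event_capacity: int = 512

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        problems = []
        if not self.time_step > 0:
            problems.append("time_step must be > 0")
        if self.n_trials < 1:
            problems.append("n_trials must be >= 1")
        if not self.cutoff_time > 0:
            problems.append("cutoff_time must be > 0")
        elif self.time_step > 0:
            n = self.cutoff_time / self.time_step
            if abs(n - round(n)) > 1e-6:
                problems.append("cutoff_time must be a positive multiple of time_step")
        if self.elastic_energy_exchange not in ("kinematic", "mean"):
            problems.append("elastic_energy_exchange must be 'kinematic' or 'mean'")
        if self.classification_rule != "parent_distance":
            problems.append(f"unknown classification_rule {self.classification_rule!r}")
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))

    @property
    def n_steps(self) -> int:
        return int(round(self.cutoff_time / self.time_step))

    def dielectric_response(self) -> DielectricResponse:
        eps0 = calibrate_short_time_eps(self.core_radius, self.well_depth)
        if self.frozen_eps:
            return DielectricResponse.frozen(eps0)
        return DielectricResponse(
            eps_short=eps0,
            eps_static=self.eps_static,
            relaxation_time=self.relaxation_time,
        )


@dataclass
class ElectronState:
    """Dynamic state of one electron; kinetic energy is derived from velocity."""

    position: np.ndarray
    velocity: np.ndarray
    parent: CationSite
    generation: str = "initial"              # or "additional"
    status: str = "live"                     # or "terminated"
    birth_time: float = 0.0
    birth_kinetic_energy: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)

    @property
    def kinetic_energy(self) -> float:
        return 0.5 * M_ELECTRON * float(self.velocity @ self.velocity)

    @property
    def distance_to_parent(self) -> float:
        return float(
            np.linalg.norm(self.position - np.asarray(self.parent.position))
        )

    def with_kinetic_energy(self, energy: float) -> "ElectronState":
        """Rescale the speed to a target kinetic energy, direction unchanged."""
        if energy < 0:
            raise ValueError("kinetic energy must be >= 0")
        speed = np.linalg.norm(self.velocity)
        if speed == 0:
            raise ValueError("cannot rescale a zero velocity")
        factor = math.sqrt(2.0 * energy / M_ELECTRON) / speed
        return replace(self, velocity=self.velocity * factor)


@dataclass(frozen=True)
class CollisionEvent:
    """One recorded collision: when, where, which channel, how much energy."""

    time: float
    position: np.ndarray
    channel_id: str
    energy_transfer: float
    actor_generation: str


@dataclass
class HistoryRecord:
    """Terminal states, recorded events and per-kind counts of one trial."""

    trial_index: int
    deposition_energy: float
    cutoff_time: float
    electrons: list[ElectronState]
    cations: list[CationSite]
    events: list[CollisionEvent]
    counts: dict[str, int]
    energy_loss: float        # sum of inelastic losses, eV
    energy_gain: float        # sum of super-elastic gains, eV
    elastic_net: float        # net elastic transfer to the electrons, eV
    n_clamped: int
    ok: bool = True
    events_truncated: bool = False

    @property
    def n_ionisations(self) -> int:
        return sum(
            n for cid, n in self.counts.items() if cid.startswith("ion_")
        )

    def terminal_distances(self, generation: str | None = None) -> np.ndarray:
        states = [
            e
            for e in self.electrons
            if generation is None or e.generation == generation
        ]
        return np.array([e.distance_to_parent for e in states])

    def terminal_kinetic_energies(self) -> np.ndarray:
        return np.array([e.kinetic_energy for e in self.electrons])


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def collision_probability(delta_s, lam):
    """Per-step collision probability 1 - exp(-ds/lambda)."""
    ds = np.asarray(delta_s, dtype=float)
    if np.any(ds < 0):
        raise ValueError("delta_s must be >= 0")
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr <= 0):
        raise ValueError("mean free path must be positive")
    out = -np.expm1(-ds / lam_arr)
    return float(out) if out.ndim == 0 else out


def sample_maxwell_energy(temperature: float, rng: np.random.Generator, size=None):
    """Draw molecular kinetic energies from the 300 K-style Maxwellian.

    The kinetic-energy density is proportional to sqrt(E) exp(-E/kT), i.e.
    E = kT/2 * chi-squared(3).
    """
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    kT = K_BOLTZMANN * temperature
    n = rng.standard_normal(size=(3,) if size is None else (3,) + tuple(np.atleast_1d(size)))
    e = 0.5 * kT * np.sum(n * n, axis=0)
    return float(e) if size is None else e


def maxwell_energy_cdf(energy, temperature: float):
    """CDF of the Maxwell-Boltzmann kinetic-energy distribution."""
    from scipy.special import gammainc

    kT = K_BOLTZMANN * temperature
    return gammainc(1.5, np.asarray(energy, dtype=float) / kT)


def kinematic_angles(e1: float, e2: float) -> tuple[float, float]:
    """Deflection angles (theta_p, theta_s) of primary and secondary electron.

    From energy and momentum conservation for a binary encounter transferring
    e2 out of e1; nonrelativistically the two angles are complementary.
    """
    if not (0 < e2 < e1):
        raise ValueError("require 0 < E2 < E1")
    frac = e2 / e1
    s2p = frac / ((1.0 - frac) * e1 / (2.0 * M0C2) + 1.0)
    s2s = (1.0 - frac) / (1.0 + e2 / (2.0 * M0C2))
    return math.asin(math.sqrt(min(s2p, 1.0))), math.asin(math.sqrt(min(s2s, 1.0)))


def _rotate(velocity: np.ndarray, theta: float, phi: float) -> np.ndarray:
    vx, vy, vz = _engine._rotate_about.py_func(
        velocity[0],
        velocity[1],
        velocity[2],
        math.cos(theta),
        math.sin(theta),
        math.cos(phi),
        math.sin(phi),
    )
    return np.array([vx, vy, vz])


def apply_elastic(
    electron: ElectronState,
    bundle: CrossSectionBundle,
    rng: np.random.Generator,
    *,
    temperature: float = 300.0,
    mode: str = "kinematic",
) -> ElectronState:
    """Elastic collision: Moliere deflection plus thermal energy exchange.

    ``mode='kinematic'`` performs the full two-body exchange with a molecule
    whose velocity vector is drawn from the Maxwellian; its ensemble mean is
    the familiar (2m/M)(sigma_mom/sigma_elas)(E_e - E_mol) transfer, which is
    available verbatim as ``mode='mean'``.
    """
    new_v = elastic_bath_step(
        electron.velocity[None, :], bundle, rng, temperature=temperature, mode=mode
    )[0]
    return replace(electron, velocity=new_v)


def elastic_bath_step(
    velocities: np.ndarray,
    bundle: CrossSectionBundle,
    rng: np.random.Generator,
    *,
    temperature: float = 300.0,
    mode: str = "kinematic",
) -> np.ndarray:
    """Apply one elastic collision to every electron of an (n, 3) ensemble.

    Vectorised counterpart of :func:`apply_elastic` for bath-equilibration
    studies; same physics, same sampling formulas.
    """
    v = np.asarray(velocities, dtype=float)
    n = v.shape[0]
    energies = 0.5 * M_ELECTRON * np.einsum("ij,ij->i", v, v)
    theta = np.asarray(sample_elastic_angle(energies, bundle, rng.random(n)))
    phi = 2.0 * math.pi * rng.random(n)
    ct, st = np.cos(theta), np.sin(theta)
    cp, sp = np.cos(phi), np.sin(phi)

    def rotate(vec):
        norm = np.linalg.norm(vec, axis=1, keepdims=True)
        u = vec / np.where(norm > 0, norm, 1.0)
        h = np.where(np.abs(u[:, 2:3]) < 0.99, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
        e1 = np.cross(u, h)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(u, e1)
        newdir = (
            ct[:, None] * u + st[:, None] * (cp[:, None] * e1 + sp[:, None] * e2)
        )
        return newdir * norm

    kT = K_BOLTZMANN * temperature
    if mode == "kinematic":
        w = rng.standard_normal((n, 3)) * math.sqrt(kT / M_WATER)
        g = v - w
        g_rot = rotate(g)
        mtot = M_ELECTRON + M_WATER
        return (M_ELECTRON * v + M_WATER * w) / mtot + (M_WATER / mtot) * g_rot
    if mode != "mean":
        raise ValueError(f"unknown elastic mode {mode!r}")
    v_rot = rotate(v)
    e_mol = 0.5 * kT * np.sum(rng.standard_normal((3, n)) ** 2, axis=0)
    ratio = np.asarray(sigma_momentum_transfer(energies, bundle)) / np.asarray(
        sigma_elastic(energies, bundle)
    )
    new_e = np.maximum(
        energies - (2.0 * M_ELECTRON / M_WATER) * ratio * (energies - e_mol), 0.0
    )
    scale = np.sqrt(new_e / np.maximum(energies, 1e-300))
    return v_rot * scale[:, None]


def apply_molecular_excitation(
    electron: ElectronState, channel: ChannelSpec
) -> ElectronState:
    """Quantum loss to a molecular mode; the direction does not change."""
    if channel.kind not in ("rotation", "intra_vibration", "inter_vibration"):
        raise ValueError(f"{channel.channel_id!r} is not a molecular channel")
    energy = electron.kinetic_energy
    assert energy >= channel.transition_energy, (
        "molecular channel sampled below threshold — sampler bug"
    )
    return electron.with_kinetic_energy(energy - channel.transition_energy)


def apply_electronic_excitation(
    electron: ElectronState, channel: ChannelSpec, rng: np.random.Generator
) -> ElectronState:
    """Fixed mean-transition-energy loss with kinematic primary deflection."""
    if channel.kind != "electronic_excitation":
        raise ValueError(f"{channel.channel_id!r} is not an electronic excitation")
    energy = electron.kinetic_energy
    assert energy >= channel.transition_energy, (
        "electronic channel sampled below threshold — sampler bug"
    )
    theta_p, _ = kinematic_angles(energy, min(channel.transition_energy, energy * (1 - 1e-12)))
    new_v = _rotate(electron.velocity, theta_p, 2.0 * math.pi * rng.random())
    out = replace(electron, velocity=new_v)
    return out.with_kinetic_energy(energy - channel.transition_energy)


def apply_ionisation(
    electron: ElectronState,
    bundle: CrossSectionBundle,
    channel: ChannelSpec,
    rng: np.random.Generator,
    *,
    now: float = 0.0,
    weight_L: bool = True,
) -> tuple[ElectronState, ElectronState, CationSite]:
    """Ionisation: primary loses w', a new cation + additional electron appear.

    The new electron starts at the collision position — the minimum of its own
    parent's potential — with kinetic energy w', at theta_s off the primary's
    pre-collision direction with the azimuth offset by pi.
    """
    if channel.kind != "ionisation":
        raise ValueError(f"{channel.channel_id!r} is not an ionisation channel")
    energy = electron.kinetic_energy
    omega = float(
        sample_energy_transfer(bundle, energy, channel.channel_id, rng.random(), weight_L=weight_L)
    )
    assert omega <= energy / 2.0 + 1e-12, "sampler exceeded the E/2 transfer bound"
    theta_p, theta_s = kinematic_angles(energy, omega)
    phi = 2.0 * math.pi * rng.random()
    cation = CationSite(
        position=tuple(electron.position), birth_time=now, radius_a=electron.parent.radius_a
    )
    sec_dir = _rotate(electron.velocity, theta_s, phi + math.pi)
    sec_dir /= np.linalg.norm(sec_dir)
    secondary = ElectronState(
        position=electron.position.copy(),
        velocity=sec_dir * math.sqrt(2.0 * omega / M_ELECTRON),
        parent=cation,
        generation="additional",
        birth_time=now,
        birth_kinetic_energy=omega,
    )
    primary = replace(electron, velocity=_rotate(electron.velocity, theta_p, phi))
    primary = primary.with_kinetic_energy(energy - omega)
    return primary, secondary, cation


def classify_electron(state: ElectronState, config: SimulationConfig) -> str:
    """'relocalised' iff the terminal own-parent distance is < the radius."""
    if state.distance_to_parent < config.relocalisation_radius:
        return "relocalised"
    return "delocalised"


# ---------------------------------------------------------------------------
# engine drivers
# ---------------------------------------------------------------------------

def _trial_seed(root_seed: int, trial_index: int) -> int:
    ss = np.random.SeedSequence([int(root_seed), int(trial_index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def _eps_table(config: SimulationConfig) -> np.ndarray:
    response = config.dielectric_response()
    ages = np.arange(config.n_steps + 1) * config.time_step
    return np.asarray(eps_r(response, ages), dtype=np.float64)


def run_history(
    config: SimulationConfig,
    bundle: CrossSectionBundle,
    response: DielectricResponse | None = None,
    trial_index: int = 0,
) -> HistoryRecord:
    """Run one trial; (seed, trial_index) fully determines the outcome."""
    tables = _engine.build_engine_tables(
        bundle,
        temperature=config.temperature,
        detailed_balance=config.detailed_balance,
        transfer_weight_L=config.transfer_weight_L,
    )
    return _run_with_tables(config, bundle, tables, trial_index, response)


def _run_with_tables(
    config: SimulationConfig,
    bundle: CrossSectionBundle,
    tables: _engine.EngineTables,
    trial_index: int,
    response: DielectricResponse | None = None,
) -> HistoryRecord:
    if response is not None:
        ages = np.arange(config.n_steps + 1) * config.time_step
        eps_table = np.asarray(eps_r(response, ages), dtype=np.float64)
    else:
        eps_table = _eps_table(config)

    maxe = config.max_electrons
    ev_cap = config.event_capacity
    e_pos = np.zeros((maxe, 3))
    e_vel = np.zeros((maxe, 3))
    e_acc = np.zeros((maxe, 3))
    e_parent = np.zeros(maxe, dtype=np.int64)
    e_gen = np.zeros(maxe, dtype=np.int64)
    e_birth_step = np.zeros(maxe, dtype=np.int64)
    e_birth_ke = np.zeros(maxe)
    c_pos = np.zeros((maxe, 3))
    c_birth_step = np.zeros(maxe, dtype=np.int64)
    ev_time = np.zeros(ev_cap)
    ev_pos = np.zeros((ev_cap, 3))
    ev_channel = np.zeros(ev_cap, dtype=np.int64)
    ev_transfer = np.zeros(ev_cap)
    ev_gen = np.zeros(ev_cap, dtype=np.int64)
    counts = np.zeros(len(tables.channel_ids), dtype=np.int64)
    esums = np.zeros(4)
    out_meta = np.zeros(4, dtype=np.int64)

    imfp_tot = tables.imfp_tot
    imfp_ch = tables.imfp_ch
    if not config.collisions:
        imfp_tot = np.zeros_like(imfp_tot)
        imfp_ch = np.zeros_like(imfp_ch)

    _engine.run_trial_kernel(
        _trial_seed(config.seed, trial_index),
        config.n_steps,
        config.time_step,
        config.deposition_energy,
        config.core_radius,
        K_BOLTZMANN * config.temperature,
        eps_table,
        tables.log_e0,
        tables.dlog_e,
        imfp_tot,
        imfp_ch,
        tables.kind_code,
        tables.delta,
        tables.icdf_idx,
        tables.icdf,
        tables.eta_prefactor,
        0 if config.elastic_energy_exchange == "kinematic" else 1,
        1 if config.log_all_events else 0,
        e_pos,
        e_vel,
        e_acc,
        e_parent,
        e_gen,
        e_birth_step,
        e_birth_ke,
        c_pos,
        c_birth_step,
        ev_time,
        ev_pos,
        ev_channel,
        ev_transfer,
        ev_gen,
        counts,
        esums,
        out_meta,
    )

    n_e, n_cat, n_ev, overflow = (int(v) for v in out_meta)
    cations = [
        CationSite(
            position=tuple(c_pos[i]),
            birth_time=float(c_birth_step[i]) * config.time_step,
            radius_a=config.core_radius,
        )
        for i in range(n_cat)
    ]
    electrons = [
        ElectronState(
            position=e_pos[i].copy(),
            velocity=e_vel[i].copy(),
            parent=cations[int(e_parent[i])],
            generation="initial" if e_gen[i] == 0 else "additional",
            status="terminated",
            birth_time=float(e_birth_step[i]) * config.time_step,
            birth_kinetic_energy=float(e_birth_ke[i]),
        )
        for i in range(n_e)
    ]
    events = [
        CollisionEvent(
            time=float(ev_time[i]),
            position=ev_pos[i].copy(),
            channel_id=tables.channel_ids[int(ev_channel[i])],
            energy_transfer=float(ev_transfer[i]),
            actor_generation="initial" if ev_gen[i] == 0 else "additional",
        )
        for i in range(n_ev)
    ]
    finite = all(np.all(np.isfinite(e.position)) and np.all(np.isfinite(e.velocity)) for e in electrons)
    return HistoryRecord(
        trial_index=trial_index,
        deposition_energy=config.deposition_energy,
        cutoff_time=config.cutoff_time,
        electrons=electrons,
        cations=cations,
        events=events,
        counts={cid: int(c) for cid, c in zip(tables.channel_ids, counts)},
        energy_loss=float(esums[0]),
        energy_gain=float(esums[1]),
        elastic_net=float(esums[2]),
        n_clamped=int(esums[3]),
        ok=finite,
        events_truncated=bool(overflow),
    )


def run_ensemble(
    config: SimulationConfig,
    bundle: CrossSectionBundle,
    response: DielectricResponse | None = None,
    trial_indices: Sequence[int] | None = None,
) -> list[HistoryRecord]:
    """Run config.n_trials independent histories (per-trial RNG streams)."""
    tables = _engine.build_engine_tables(
        bundle,
        temperature=config.temperature,
        detailed_balance=config.detailed_balance,
        transfer_weight_L=config.transfer_weight_L,
    )
    indices = (
        list(trial_indices) if trial_indices is not None else list(range(config.n_trials))
    )
    return [
        _run_with_tables(config, bundle, tables, j, response) for j in indices
    ]


def history_energy_ledger(
    record: HistoryRecord, config: SimulationConfig
) -> dict[str, float]:
    """Close the per-history energy books.

    With a frozen dielectric the mechanical energy injected at each electron's
    birth (kinetic energy plus the well minimum it starts in) must equal the
    terminal mechanical energy plus net collision losses, up to integrator
    error.  With a time-varying permittivity the dielectric does work and the
    residual is reported rather than asserted.
    """
    response = config.dielectric_response()
    birth_total = 0.0
    terminal_total = 0.0
    for e in record.electrons:
        site = e.parent
        age_birth = max(e.birth_time - site.birth_time, 0.0)
        birth_total += e.birth_kinetic_energy + potential_energy(
            0.0, age_birth, site, response
        )
        age_term = max(record.cutoff_time - site.birth_time, 0.0)
        terminal_total += e.kinetic_energy + potential_energy(
            e.distance_to_parent, age_term, site, response
        )
    residual = (
        birth_total
        - record.energy_loss
        + record.energy_gain
        + record.elastic_net
        - terminal_total
    )
    return {
        "birth_total": birth_total,
        "terminal_total": terminal_total,
        "inelastic_loss": record.energy_loss,
        "superelastic_gain": record.energy_gain,
        "elastic_net": record.elastic_net,
        "residual": residual,
        "relative_residual": abs(residual) / max(record.deposition_energy, 1e-300),
    }
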