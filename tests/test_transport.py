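"""Transport engine: collision statistics, collision operators, histories."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

import spurdyn as sd
from spurdyn.constants import K_BOLTZMANN, M_ELECTRON
from spurdyn.observables import maxwellian_distance
from spurdyn.transport import (
    SimulationConfig,
    elastic_bath_step,
    history_energy_ledger,
    maxwell_energy_cdf,
    run_ensemble,
    run_history,
)


def _electron(energy, direction=(0, 0, 1.0), parent=None, generation="initial"):
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    return sd.ElectronState(
        position=np.zeros(3),
        velocity=d * math.sqrt(2 * energy / M_ELECTRON),
        parent=parent or sd.CationSite(),
        generation=generation,
        birth_kinetic_energy=energy,
    )


# ---------------------------------------------------------------------------
# collision probability and free paths
# ---------------------------------------------------------------------------

def test_collision_probability_values():
    assert sd.collision_probability(0.0, 1.0) == 0.0
    assert sd.collision_probability(1.0, 1.0) == pytest.approx(1 - math.exp(-1))
    with pytest.raises(ValueError):
        sd.collision_probability(1.0, 0.0)
    with pytest.raises(ValueError):
        sd.collision_probability(-1.0, 1.0)


def test_constant_lambda_walk_reproduces_mean_free_path(rng):
    lam = 3.0
    ds = lam / 300.0
    p = sd.collision_probability(ds, lam)
    fired = rng.random(15_000_000) < p
    gaps = np.diff(np.flatnonzero(fired)) * ds
    assert gaps.mean() == pytest.approx(lam, rel=0.01)


# ---------------------------------------------------------------------------
# Maxwellian bath sampling
# ---------------------------------------------------------------------------

def test_maxwell_energy_moments_and_cdf(rng):
    kT = K_BOLTZMANN * 300.0
    draws = sd.sample_maxwell_energy(300.0, rng, size=1_000_000)
    assert np.all(draws >= 0)
    assert draws.mean() == pytest.approx(1.5 * kT, rel=0.01)
    assert draws.mean() == pytest.approx(0.03878, rel=0.01)
    ks = stats.ks_1samp(draws, lambda e: maxwell_energy_cdf(e, 300.0))
    assert ks.statistic < 0.005


# ---------------------------------------------------------------------------
# kinematic deflection angles
# ---------------------------------------------------------------------------

def test_kinematic_angles_equal_split_gives_45_degrees():
    tp, ts = sd.kinematic_angles(20.0, 10.0)
    assert math.degrees(tp) == pytest.approx(45.0, abs=0.01)
    assert math.degrees(ts) == pytest.approx(45.0, abs=0.01)


def test_kinematic_angles_complementary_nonrelativistic():
    for e1 in (5.0, 20.0, 100.0):
        for frac in (0.05, 0.3, 0.5, 0.9):
            tp, ts = sd.kinematic_angles(e1, frac * e1)
            s2 = math.sin(tp) ** 2 + math.sin(ts) ** 2
            assert s2 == pytest.approx(1.0, abs=1e-4)


def test_kinematic_angles_limits_and_errors():
    tp, _ = sd.kinematic_angles(20.0, 1e-9)
    assert tp == pytest.approx(0.0, abs=1e-4)
    with pytest.raises(ValueError):
        sd.kinematic_angles(10.0, 10.0)
    with pytest.raises(ValueError):
        sd.kinematic_angles(10.0, 12.0)


# ---------------------------------------------------------------------------
# elastic exchange with the thermal bath
# ---------------------------------------------------------------------------

class _ScriptedRng:
    """Deterministic stand-in driving the mean-transfer elastic branch."""

    def __init__(self, u_theta, e_mol, kT):
        self._u_theta = u_theta
        self._n1 = math.sqrt(2.0 * e_mol / kT)

    def random(self, n=None):
        return np.full(n, self._u_theta) if n else self._u_theta

    def standard_normal(self, shape):
        out = np.zeros(shape)
        out.flat[0] = self._n1
        return out


def test_mean_mode_zero_transfer_when_molecule_matches_electron(bundle):
    # Eq.-5-style transfer vanishes for E_e = E_mol
    kT = K_BOLTZMANN * 300.0
    e0 = 0.5
    electron = _electron(e0)
    rng = _ScriptedRng(u_theta=0.0, e_mol=e0, kT=kT)
    out = sd.apply_elastic(electron, bundle, rng, mode="mean")
    assert out.kinetic_energy == pytest.approx(e0, rel=1e-12)


def test_mean_mode_fast_electron_loses_energy(bundle, rng):
    electron = _electron(10.0)
    for _ in range(50):
        out = sd.apply_elastic(electron, bundle, rng, mode="mean")
        assert out.kinetic_energy < electron.kinetic_energy


def test_elastic_bath_preserves_maxwellian(bundle, rng):
    """The kinematic exchange holds a 300 K ensemble stationary (detailed balance)."""
    kT = K_BOLTZMANN * 300.0
    n = 10_000
    e0 = 0.5 * kT * np.sum(rng.standard_normal((3, n)) ** 2, axis=0)
    dirs = rng.standard_normal((n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    v = dirs * np.sqrt(2 * e0 / M_ELECTRON)[:, None]
    for _ in range(300):
        v = elastic_bath_step(v, bundle, rng)
    energies = 0.5 * M_ELECTRON * np.einsum("ij,ij->i", v, v)
    assert maxwellian_distance(energies, 300.0) < 0.02


def test_elastic_bath_mean_relaxes_at_predicted_rate(bundle, rng):
    """Ensemble-mean energy relaxes as (2m/M)(sigma_mom/sigma_el) per collision."""
    n = 4000
    e0 = 0.2
    dirs = rng.standard_normal((n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    v = dirs * math.sqrt(2 * e0 / M_ELECTRON)
    n_coll = 3000
    for _ in range(n_coll):
        v = elastic_bath_step(v, bundle, rng)
    mean_e = float(np.mean(0.5 * M_ELECTRON * np.einsum("ij,ij->i", v, v)))
    kT = K_BOLTZMANN * 300.0
    ratio = sd.sigma_momentum_transfer(e0, bundle) / sd.sigma_elastic(e0, bundle)
    # analytic AR(1) prediction with the energy-dependent rate frozen at e0
    rate = 2.0 * M_ELECTRON / sd.transport.M_WATER * ratio
    predicted = 1.5 * kT + (e0 - 1.5 * kT) * (1.0 - rate) ** n_coll
    assert mean_e == pytest.approx(predicted, rel=0.05)


# ---------------------------------------------------------------------------
# inelastic collision operators
# ---------------------------------------------------------------------------

def test_molecular_excitation_bookkeeping(bundle):
    ch = bundle.channel("intra_vibration")
    spec_loss = ch.transition_energy
    electron = _electron(1.0, direction=(1, 2, 3))
    out = sd.apply_molecular_excitation(electron, ch)
    assert out.kinetic_energy == pytest.approx(1.0 - spec_loss, rel=1e-12)
    # direction identical, speed rescaled consistently
    cos = float(out.velocity @ electron.velocity) / (
        np.linalg.norm(out.velocity) * np.linalg.norm(electron.velocity)
    )
    assert cos == pytest.approx(1.0, abs=1e-12)
    v_expected = math.sqrt(2 * out.kinetic_energy / M_ELECTRON)
    assert np.linalg.norm(out.velocity) == pytest.approx(v_expected, rel=1e-12)


def test_repeated_molecular_excitations_close_the_ledger(bundle):
    ch = bundle.channel("inter_vibration")
    electron = _electron(1.0)
    n = 8
    for _ in range(n):
        electron = sd.apply_molecular_excitation(electron, ch)
    assert electron.kinetic_energy == pytest.approx(
        1.0 - n * ch.transition_energy, rel=1e-10
    )


def test_electronic_excitation_losses(bundle, rng):
    diffuse = bundle.channel("exc_diffuse")
    out = sd.apply_electronic_excitation(_electron(16.0), diffuse, rng)
    assert out.kinetic_energy == pytest.approx(16.0 - 14.1, rel=1e-9)
    collective = bundle.channel("exc_collective")
    out2 = sd.apply_electronic_excitation(_electron(30.0), collective, rng)
    assert out2.kinetic_energy == pytest.approx(30.0 - 21.4, rel=1e-9)


def test_electronic_excitation_deflects_by_kinematic_angle(bundle, rng):
    diffuse = bundle.channel("exc_diffuse")
    electron = _electron(16.0)
    out = sd.apply_electronic_excitation(electron, diffuse, rng)
    theta_p, _ = sd.kinematic_angles(16.0, 14.1)
    cos = float(out.velocity @ electron.velocity) / (
        np.linalg.norm(out.velocity) * np.linalg.norm(electron.velocity)
    )
    assert math.acos(np.clip(cos, -1, 1)) == pytest.approx(theta_p, abs=1e-6)


def test_ionisation_conserves_energy_and_spawns(bundle, rng):
    ch = bundle.channel("ion_1b1")
    electron = _electron(30.0)
    primary, secondary, cation = sd.apply_ionisation(
        electron, bundle, ch, rng, now=12.5
    )
    omega = secondary.kinetic_energy
    assert 0 < omega <= 15.0 + 1e-9
    assert primary.kinetic_energy == pytest.approx(30.0 - omega, rel=1e-9)
    assert secondary.generation == "additional"
    assert secondary.parent is cation
    assert cation.birth_time == 12.5
    assert np.allclose(np.asarray(cation.position), electron.position)
    # secondary leaves at theta_s off the pre-collision direction
    _, theta_s = sd.kinematic_angles(30.0, omega)
    cos = float(secondary.velocity @ electron.velocity) / (
        np.linalg.norm(secondary.velocity) * np.linalg.norm(electron.velocity)
    )
    assert math.acos(np.clip(cos, -1, 1)) == pytest.approx(theta_s, abs=1e-6)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "distance, expected",
    [(0.5, "relocalised"), (12.0, "delocalised"), (1.0, "delocalised")],
)
def test_classification_threshold_and_tie_policy(distance, expected):
    cfg = SimulationConfig(deposition_energy=12.0, cutoff_time=1.0)
    state = sd.ElectronState(
        position=np.array([distance, 0.0, 0.0]),
        velocity=np.array([0.0, 0.0, 0.1]),
        parent=sd.CationSite(),
    )
    assert sd.classify_electron(state, cfg) == expected


# ---------------------------------------------------------------------------
# full histories
# ---------------------------------------------------------------------------

def test_history_determinism_bit_exact(bundle, warm_engine):
    cfg = SimulationConfig(deposition_energy=25.0, n_trials=1, cutoff_time=30.0, seed=9)
    a = run_history(cfg, bundle, trial_index=4)
    b = run_history(cfg, bundle, trial_index=4)
    assert len(a.electrons) == len(b.electrons)
    for ea, eb in zip(a.electrons, b.electrons):
        assert np.array_equal(ea.position, eb.position)
        assert np.array_equal(ea.velocity, eb.velocity)
    assert a.counts == b.counts
    assert a.energy_loss == b.energy_loss


def test_per_trial_streams_independent_of_batch_size(bundle, warm_engine):
    cfg2 = SimulationConfig(deposition_energy=22.0, n_trials=2, cutoff_time=20.0, seed=5)
    cfg4 = dataclasses.replace(cfg2, n_trials=4)
    recs2 = run_ensemble(cfg2, bundle)
    recs4 = run_ensemble(cfg4, bundle)
    for a, b in zip(recs2, recs4[:2]):
        for ea, eb in zip(a.electrons, b.electrons):
            assert np.array_equal(ea.position, eb.position)


def test_electron_count_equals_one_plus_ionisations(bundle, warm_engine):
    cfg = SimulationConfig(deposition_energy=30.0, n_trials=40, cutoff_time=60.0, seed=13)
    for rec in run_ensemble(cfg, bundle):
        assert not rec.events_truncated
        assert len(rec.electrons) == 1 + rec.n_ionisations
        for e in rec.electrons:
            if e.generation == "additional":
                assert e.parent.birth_time > 0


def test_energy_ledger_closes_with_frozen_eps(bundle, warm_engine):
    cfg = SimulationConfig(
        deposition_energy=30.0, n_trials=10, cutoff_time=60.0, seed=21, frozen_eps=True
    )
    for rec in run_ensemble(cfg, bundle):
        led = history_energy_ledger(rec, cfg)
        assert led["relative_residual"] < 1e-3


def test_sub_threshold_deposition_stays_bound(bundle, warm_engine):
    # below every inelastic quantum and far below the well depth the electron
    # just orbits its parent cation
    cfg = SimulationConfig(
        deposition_energy=0.005,
        n_trials=10,
        cutoff_time=100.0,
        seed=2,
        detailed_balance=False,
    )
    recs = run_ensemble(cfg, bundle)
    dists = np.array([r.electrons[0].distance_to_parent for r in recs])
    assert np.mean(dists < 1.0) > 0.8


def test_config_validation_lists_problems():
    with pytest.raises(ValueError, match="time_step"):
        SimulationConfig(deposition_energy=10.0, time_step=0.0)
    with pytest.raises(ValueError, match="multiple"):
        SimulationConfig(deposition_energy=10.0, cutoff_time=0.0015, time_step=1e-3)
    with pytest.raises(ValueError, match="n_trials"):
        SimulationConfig(deposition_energy=10.0, n_trials=0)
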