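"""Replica-exchange engine: schedule, superposition, restraint, exchanges."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from zippersim import (ReplicaSchedule, run_hremd, superimpose,
                       restraint_energy, exchange_delta, metropolis_accept,
                       mixing_diagnostics, effective_concentration,
                       EnergyModel, PeptideSystem, build_extended_strand,
                       random_gas)
from zippersim.hremd import fit_reference


def test_lambda_schedule_endpoints_and_shape():
    sch = ReplicaSchedule()
    lam = sch.lambdas
    assert sch.n_replicas == 64
    assert lam[0] == 0.0
    assert lam[-1] == 0.032
    assert np.all(np.diff(lam) > 0)
    # quadratic form
    assert lam[32] == pytest.approx(0.032 * (32 / 63) ** 2)
    assert ReplicaSchedule(n_replicas=1).lambdas.tolist() == [0.0]


def test_effective_concentration_of_64_in_50A_sphere():
    assert effective_concentration(64, 50.0) == pytest.approx(0.20, abs=0.005)


def test_superimpose_identity_and_known_rotation(ilqins, rng):
    ref = ilqins.coords
    r, t, rmsd = superimpose(ref, ref)
    assert rmsd == pytest.approx(0.0, abs=1e-10)
    assert r == pytest.approx(np.eye(3), abs=1e-10)
    rot = Rotation.from_rotvec([0.2, 0.8, -0.5]).as_matrix()
    target = ref @ rot.T + np.array([4.0, 5.0, 6.0])
    r2, t2, rmsd2 = superimpose(ref, target)
    assert rmsd2 == pytest.approx(0.0, abs=1e-8)
    assert r2 == pytest.approx(rot, abs=1e-8)


def test_superimpose_mirror_returns_proper_rotation(ilqins):
    ref = ilqins.coords
    mirror = ref * np.array([1.0, 1.0, -1.0])
    r, _, rmsd = superimpose(ref, mirror)
    assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)
    assert rmsd > 0.1


def test_superimpose_error_cases(ilqins):
    with pytest.raises(ValueError):
        superimpose(ilqins.coords[:5], ilqins.coords)
    line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    with pytest.raises(ValueError):
        superimpose(line, line)


def test_restraint_zero_cases_and_brute_force(ilqins):
    ref = ilqins.coords
    rot = Rotation.from_rotvec([1.0, -0.3, 0.2]).as_matrix()
    moved = ref @ rot.T + np.array([10.0, -5.0, 2.0])
    assert restraint_energy(moved, ref, 0.0) == 0.0
    # rigid-motion invariance of the restraint to 1e-8
    assert restraint_energy(moved, ref, 0.032) == pytest.approx(0.0, abs=1e-8)
    # single displaced atom: 1/2 lambda |residual|^2 via explicit refit
    pert = moved.copy()
    pert[7] += np.array([0.4, 0.0, 0.0])
    lam = 0.02
    fitted = fit_reference(ref, pert)
    brute = 0.5 * lam * ((pert - fitted) ** 2).sum()
    assert restraint_energy(pert, ref, lam) == pytest.approx(brute, rel=1e-12)
    with pytest.raises(ValueError):
        restraint_energy(moved, ref, -0.1)


def test_exchange_delta_antisymmetry_and_oracle(ilqins, rng):
    ref = ilqins.coords
    slices = [slice(0, len(ref))]
    a = ref + 0.1 * rng.standard_normal(ref.shape)
    b = ref + 0.3 * rng.standard_normal(ref.shape)
    li, lj = 0.01, 0.02
    du = exchange_delta(li, lj, a, b, slices, ref)
    # swapping the restraint strengths flips the sign; swapping both the
    # strengths and the configurations is the identity relabelling
    assert exchange_delta(lj, li, a, b, slices, ref) == pytest.approx(-du)
    assert exchange_delta(lj, li, b, a, slices, ref) == pytest.approx(du)
    assert exchange_delta(li, li, a, b, slices, ref) == 0.0
    # oracle: four explicit restraint evaluations
    expected = ((restraint_energy(b, ref, li) + restraint_energy(a, ref, lj))
                - (restraint_energy(b, ref, lj) + restraint_energy(a, ref, li)))
    assert du == pytest.approx(expected, rel=1e-9)


def test_metropolis_rule():
    assert metropolis_accept(-1.0, 1.0, 0.999)
    assert metropolis_accept(0.0, 1.0, 0.999)
    assert metropolis_accept(2.0, 1.0, np.exp(-2.0) * 0.99)
    assert not metropolis_accept(2.0, 1.0, np.exp(-2.0) * 1.01)
    with pytest.raises(ValueError):
        metropolis_accept(1.0, 0.0, 0.5)


@pytest.fixture(scope="module")
def tiny_system():
    strands, base = random_gas("ILQINS", 2, 8.0, seed=4)
    return PeptideSystem(strands), base


def test_single_replica_runs_plain_dynamics(tiny_system):
    system, base = tiny_system
    sch = ReplicaSchedule(n_replicas=1)
    res = run_hremd(system, sch, base.coords, EnergyModel(), 40, seed=2,
                    stride=20)
    assert len(res.exchange_log) == 0
    assert res.frames.shape[1] == system.n_atoms


def test_two_identical_lambdas_always_exchange(tiny_system):
    system, base = tiny_system
    sch = ReplicaSchedule(n_replicas=2, lambda_max=0.0,
                          exchange_interval_ps=0.05)
    res = run_hremd(system, sch, base.coords, EnergyModel(), 50, seed=3,
                    dt_ps=0.01)
    assert len(res.exchange_log) > 0
    assert res.exchange_log["accepted"].all()
    assert (res.exchange_log["delta_u"] == 0).all()


def test_bit_identical_reproducibility(tiny_system):
    system, base = tiny_system
    sch = ReplicaSchedule(n_replicas=3, exchange_interval_ps=0.1)
    kw = dict(n_steps=60, seed=11, dt_ps=0.01, stride=30)
    a = run_hremd(system, sch, base.coords, EnergyModel(), **kw)
    b = run_hremd(system, sch, base.coords, EnergyModel(), **kw)
    assert np.array_equal(a.frames, b.frames)
    assert a.exchange_log.equals(b.exchange_log)


def test_mixing_diagnostics_on_synthetic_log():
    log = pd.DataFrame({
        "attempt": [0, 0, 1, 2, 2, 3],
        "i": [0, 2, 1, 0, 2, 1],
        "j": [1, 3, 2, 1, 3, 2],
        "delta_u": [0.0] * 6,
        "accepted": [True, False, True, True, True, False],
    })
    diag = mixing_diagnostics(log)
    assert diag["acceptance_rates"][(0, 1)] == pytest.approx(1.0)
    assert diag["acceptance_rates"][(2, 3)] == pytest.approx(0.5)
    assert diag["acceptance_rates"][(1, 2)] == pytest.approx(0.5)
    assert diag["round_trips"] >= 0
    with pytest.raises(ValueError):
        mixing_diagnostics(log.iloc[:0])


def test_all_accepted_log_rates_are_one():
    log = pd.DataFrame({"attempt": [0, 1], "i": [0, 0], "j": [1, 1],
                        "delta_u": [0.0, 0.0], "accepted": [True, True]})
    diag = mixing_diagnostics(log)
    assert diag["acceptance_rates"][(0, 1)] == 1.0
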