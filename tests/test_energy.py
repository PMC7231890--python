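"""Coarse-grained energy backend: closed forms, invariances, minimizer."""

import numpy as np
import pytest

from zippersim import (EnergyModel, PeptideSystem, total_energy, minimize,
                       bjerrum_length, build_nanocrystal,
                       build_extended_strand)
from zippersim.energy import KB, screened_coulomb, energy_and_forces


def test_bjerrum_length_values():
    assert bjerrum_length(80.0, 300.0) == pytest.approx(7.0, rel=0.03)
    assert bjerrum_length(15.0, 300.0) == pytest.approx(37.0, rel=0.02)
    # epsilon -> infinity limit
    assert bjerrum_length(1e12, 300.0) < 1e-9
    with pytest.raises(ValueError):
        bjerrum_length(-1.0, 300.0)
    with pytest.raises(ValueError):
        bjerrum_length(80.0, 0.0)


def test_opposite_charges_at_bjerrum_length_give_minus_kt():
    model = EnergyModel(epsilon_r=80.0, temperature=300.0,
                        debye_length=np.inf, w_elec=1.0)
    lb = bjerrum_length(80.0, 300.0)
    e = screened_coulomb(+1.0, -1.0, lb, model)
    assert e == pytest.approx(-KB * 300.0, rel=1e-12)


def test_terms_sum_to_total_and_per_peptide(model):
    block = build_nanocrystal("ILQINS", 5, dims=(1, 1, 3))
    system = PeptideSystem(block.strands)
    rep = total_energy(block.coords(), system, model)
    assert sum(rep.terms.values()) == pytest.approx(rep.total, rel=1e-12)
    assert rep.per_peptide.sum() == pytest.approx(rep.total, rel=1e-8)


def test_extensivity_of_noninteracting_duplicate(model, ilqins):
    far = ilqins.transform(np.eye(3), np.array([500.0, 0.0, 0.0]))
    single = PeptideSystem([ilqins])
    e1 = total_energy(single.coords0(), single, model).total
    double = PeptideSystem([ilqins, far])
    e2 = total_energy(double.coords0(), double, model).total
    assert e2 == pytest.approx(2 * e1, abs=1e-9)
    assert e1 == pytest.approx(0.0, abs=1e-9)  # isolated strand at reference


def test_rigid_motion_invariance(model, rng):
    from scipy.spatial.transform import Rotation
    block = build_nanocrystal("ILQINS", 1, dims=(1, 1, 2))
    system = PeptideSystem(block.strands)
    coords = block.coords()
    e0 = total_energy(coords, system, model).total
    rot = Rotation.from_rotvec([0.3, -0.9, 0.5]).as_matrix()
    moved = coords @ rot.T + np.array([11.0, 7.0, -40.0])
    assert total_energy(moved, system, model).total == pytest.approx(
        e0, rel=1e-10)


def test_ap_dimer_electrostatics_beats_p():
    """Charged termini favour antiparallel neighbours; oracle is the direct
    four-charge screened sum."""
    model = EnergyModel()
    terms = {}
    charge_sets = {}
    for cls in (1, 5):
        block = build_nanocrystal("ILQINS", cls, dims=(1, 1, 2))
        system = PeptideSystem(block.strands)
        terms[cls] = total_energy(block.coords(), system, model).terms[
            "electrostatic"]
        coords = block.coords()
        charge_sets[cls] = [(coords[i], q) for i, q in
                            zip(system.charges_idx, system.charges_val)]
    assert terms[5] < terms[1]
    # oracle: explicit double sum over the four terminal charges
    for cls in (1, 5):
        sites = charge_sets[cls]
        expected = 0.0
        for a in range(2):          # peptide 0 sites
            for b in range(2, 4):   # peptide 1 sites
                r = np.linalg.norm(sites[a][0] - sites[b][0])
                expected += screened_coulomb(sites[a][1], sites[b][1], r,
                                             model)
        assert terms[cls] == pytest.approx(expected, rel=1e-9)


def test_forces_match_numerical_gradient(model, rng):
    block = build_nanocrystal("ILQINS", 5, dims=(1, 1, 2))
    system = PeptideSystem(block.strands)
    x = block.coords() + 0.05 * rng.standard_normal(block.coords().shape)
    terms, forces, _ = energy_and_forces(x, system, model)
    e0 = sum(terms.values())
    for idx, comp in [(2, 0), (30, 1), (55, 2)]:
        xp = x.copy()
        xp[idx, comp] += 1e-6
        tp, _, _ = energy_and_forces(xp, system, model)
        num = (sum(tp.values()) - e0) / 1e-6
        assert -forces[idx, comp] == pytest.approx(num, rel=1e-3, abs=1e-5)


class _Quadratic:
    """Duck-typed test potential: E = 1/2 sum |x - target|^2."""

    def __init__(self, target):
        self.target = target

    def energy_and_forces(self, coords, system):
        disp = coords - self.target
        return {"quad": float(0.5 * (disp ** 2).sum())}, -disp, None


def test_minimizer_converges_to_analytic_minimum(ilqins, rng):
    system = PeptideSystem([ilqins])
    target = ilqins.coords + np.array([1.0, -2.0, 0.5])
    start = ilqins.coords + 0.3 * rng.standard_normal(ilqins.coords.shape)
    xmin, report, info = minimize(start, system, _Quadratic(target),
                                  tolerance=1e-8, max_iterations=2000,
                                  mode="cartesian")
    assert info["converged"]
    assert np.abs(xmin - target).max() < 1e-6
    assert report.total == pytest.approx(0.0, abs=1e-10)


def test_minimizer_never_increases_energy(model, rng):
    block = build_nanocrystal("ILQINS", 5, dims=(1, 1, 2))
    system = PeptideSystem(block.strands)
    start = block.coords() + 0.2 * rng.standard_normal(block.coords().shape)
    e_start = total_energy(start, system, model).total
    xmin, report, _ = minimize(start, system, model, tolerance=1e-3,
                               max_iterations=150, mode="rigid")
    assert report.total <= e_start + 1e-9


def test_already_minimal_configuration_stays_put(ilqins):
    system = PeptideSystem([ilqins])
    model = EnergyModel()
    x0 = system.coords0()
    xmin, _, info = minimize(x0, system, model, tolerance=1e-6,
                             max_iterations=50, mode="rigid")
    # an isolated rigid strand has zero inter-peptide energy everywhere
    assert np.abs(xmin - x0).max() < 1e-6
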