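"""Block cutting, interface free energies and the ddG table arithmetic."""

import numpy as np
import pandas as pd
import pytest

from zippersim import (BlockSpec, cut_block, block_free_energy, interface_dG,
                       dg_c, dg_zip, ddg_table, EnergyModel, PeptideSystem,
                       build_nanocrystal, make_ideal_assembly,
                       synth_trajectory, FixtureRecipe, total_energy)
from zippersim.thermo import FreeEnergyEstimate


def test_cut_block_identity_and_counting():
    block = build_nanocrystal("ILQINS", 1, dims=(1, 2, 14))
    strands, coords = cut_block(block, BlockSpec((1, 2, 14)))
    assert len(strands) == 28
    assert np.array_equal(coords, block.coords())
    strands, coords = cut_block(block, BlockSpec((1, 1, 14)))
    assert len(strands) == 14
    with pytest.raises(ValueError):
        cut_block(block, BlockSpec((1, 1, 15)))


def test_cut_block_matches_brute_force_membership(rng):
    block = build_nanocrystal("ILQINS", 5, dims=(2, 2, 6))
    spec = BlockSpec((1, 2, 3), origin=(1, 0, 2))
    strands, _ = cut_block(block, spec)
    got = {s.lattice_index for s in strands}
    expected = {s.lattice_index for s in block.strands
                if 1 <= s.lattice_index[0] < 2
                and 0 <= s.lattice_index[1] < 2
                and 2 <= s.lattice_index[2] < 5}
    assert got == expected


def test_block_free_energy_frozen_blocks_have_zero_stderr(model):
    block = build_nanocrystal("ILQINS", 1, dims=(1, 1, 4))
    sample = [cut_block(block, BlockSpec((1, 1, 4))) for _ in range(50)]
    est = block_free_energy(sample, model, max_iterations=5)
    assert est.stderr == 0.0
    assert est.n_samples == 50


def test_block_free_energy_refuses_undersampling(model):
    block = build_nanocrystal("ILQINS", 1, dims=(1, 1, 2))
    sample = [cut_block(block, BlockSpec((1, 1, 2))) for _ in range(5)]
    with pytest.raises(ValueError, match="50"):
        block_free_energy(sample, model)
    est = block_free_energy(sample, model, allow_undersampled=True,
                            max_iterations=2)
    assert est.undersampled_override


def test_interface_dg_zero_with_interactions_off():
    off = EnergyModel(w_pack=0.0, w_elec=0.0, w_hbond=0.0, w_solv=0.0)
    block = build_nanocrystal("ILQINS", 1, dims=(1, 1, 8))
    traj_like = synth_trajectory(block, FixtureRecipe(
        n_frames=55, sigma=0.0, burn_in_frames=5, seed=0))
    value, err, _ = dg_c(traj_like, off, n_samples=50, seed=0,
                         max_iterations=3)
    assert value == 0.0
    assert err == 0.0


def test_interface_dg_arithmetic_and_sign_convention():
    g_j = FreeEnergyEstimate(-30.0, 0.5, 50)
    g_a = FreeEnergyEstimate(-10.0, 0.3, 50)
    g_b = FreeEnergyEstimate(-12.0, 0.4, 50)
    value, err = interface_dG(g_j, g_a, g_b, n_buried=2)
    assert value == pytest.approx(-4.0)          # attractive -> negative
    assert err == pytest.approx(np.sqrt(0.25 + 0.09 + 0.16) / 2)
    with pytest.raises(ValueError):
        interface_dG(g_j, g_a, g_b, 0)


def test_dg_equals_cross_half_pairwise_oracle(model):
    """Without minimization, dG_c is exactly the cross-half interaction sum
    divided by the buried-peptide count."""
    block = build_nanocrystal("ILQINS", 1, dims=(1, 1, 8))
    traj = synth_trajectory(block, FixtureRecipe(
        n_frames=55, sigma=0.0, burn_in_frames=5, seed=0))
    value, _, _ = dg_c(traj, model, n_samples=50, seed=0, max_iterations=0)
    strands = block.strands
    coords = block.coords()
    full = total_energy(coords, PeptideSystem(strands), model).total
    halves = 0.0
    for keep in (range(4), range(4, 8)):
        sub = [strands[i] for i in keep]
        sys_half = PeptideSystem(sub)
        halves += total_energy(sys_half.coords0(), sys_half, model).total
    assert value == pytest.approx((full - halves) / 1.0, rel=1e-9)


def test_linearity_of_per_peptide_dg_c(model):
    """Per-buried-peptide dG_c from 8-strand and 12-strand sheets agrees
    within 10% (short-ranged interactions, block larger than the screening
    length)."""
    values = {}
    for n in (8, 12):
        block = build_nanocrystal("ILQINS", 1, dims=(1, 1, n))
        traj = synth_trajectory(block, FixtureRecipe(
            n_frames=55, sigma=0.0, burn_in_frames=5, seed=0))
        # converge the relaxation tightly so edge effects are consistent
        values[n], _, _ = dg_c(traj, model, n_samples=50, seed=0,
                               max_iterations=400, tolerance=5e-3)
    assert values[8] == pytest.approx(values[12], rel=0.10)


def test_ddg_table_reproduces_reference_rows():
    results = {
        ("ILQINS", 1): {"dg_c": -28.1, "dg_zip": -18.6},
        ("ILQINS", 5): {"dg_c": -28.9, "dg_zip": -16.3},
        ("TFQINS", 1): {"dg_c": -26.1, "dg_zip": -21.7},
        ("TFQINS", 5): {"dg_c": -29.5, "dg_zip": -13.1},
    }
    table = ddg_table(results).frame
    il = table[(table.sequence == "ILQINS") & (table.entry == "ddG 1-5")]
    assert il.dg_c.iloc[0] == pytest.approx(0.8)
    assert il.dg_zip.iloc[0] == pytest.approx(-2.3)
    tf = table[(table.sequence == "TFQINS") & (table.entry == "ddG 1-5")]
    assert tf.dg_zip.iloc[0] == pytest.approx(-8.6)


def test_ddg_antisymmetry_and_zero():
    same = {("X", 1): {"dg_c": -5.0, "dg_zip": -3.0},
            ("X", 5): {"dg_c": -5.0, "dg_zip": -3.0}}
    row = ddg_table(same).frame
    ddg = row[row.entry == "ddG 1-5"]
    assert ddg.dg_c.iloc[0] == 0.0 and ddg.dg_zip.iloc[0] == 0.0
    a = {("X", 1): {"dg_c": -7.0, "dg_zip": -2.0},
         ("X", 5): {"dg_c": -4.0, "dg_zip": -6.0}}
    swapped = {("X", 1): a[("X", 5)], ("X", 5): a[("X", 1)]}
    da = ddg_table(a).frame
    ds = ddg_table(swapped).frame
    assert (da[da.entry == "ddG 1-5"].dg_c.iloc[0]
            == -ds[ds.entry == "ddG 1-5"].dg_c.iloc[0])
    with pytest.raises(ValueError, match="class 5"):
        ddg_table({("Y", 1): {"dg_c": 0.0, "dg_zip": 0.0}})
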