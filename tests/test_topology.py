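"""Hydrogen-bond detection, P/AP classification and time series."""

import numpy as np
import pytest

from zippersim import (build_nanocrystal, build_extended_strand,
                       FrameTopology, detect_backbone_hbonds, count_pairings,
                       strand_direction, classify_pairing, hbond_series,
                       moving_average, synth_trajectory, FixtureRecipe,
                       make_ideal_assembly)


def _brute_force_bonds(strands, coords, dmax=2.5, amin=135.0):
    """Exhaustive oracle over all donor H / acceptor O pairs."""
    offsets = np.cumsum([0] + [s.n_atoms for s in strands])
    count = 0
    for pi, si in enumerate(strands):
        for i, nm in enumerate(si.atom_names):
            if nm != "H":
                continue
            h = coords[offsets[pi] + i]
            n = coords[offsets[pi] + si.atom_idx("N", si.res_index[i])]
            for pj, sj in enumerate(strands):
                for j, nm2 in enumerate(sj.atom_names):
                    if nm2 not in ("O", "OXT"):
                        continue
                    o = coords[offsets[pj] + j]
                    d = np.linalg.norm(o - h)
                    if d >= dmax or d < 1e-6:
                        continue
                    v1 = (h - n) / np.linalg.norm(h - n)
                    v2 = (o - h) / d
                    ang = 180 - np.degrees(
                        np.arccos(np.clip(np.dot(v1, v2), -1, 1)))
                    if ang > amin:
                        count += 1
    return count


def test_isolated_peptide_has_no_interstrand_bonds(ilqins):
    topo = FrameTopology([ilqins])
    bonds = detect_backbone_hbonds(topo, ilqins.coords)
    assert all(b.pairing == "intra" for b in bonds)
    assert count_pairings(bonds) == (0, 0)


@pytest.mark.parametrize("cls", [1, 5])
def test_dimer_count_matches_brute_force(cls):
    block = build_nanocrystal("ILQINS", cls, dims=(1, 1, 2))
    topo = FrameTopology(block.strands)
    coords = block.coords()
    bonds = detect_backbone_hbonds(topo, coords)
    assert len(bonds) == _brute_force_bonds(block.strands, coords)
    n_p, n_ap = count_pairings(bonds)
    assert (n_p > 0) == (cls == 1)
    assert (n_ap > 0) == (cls == 5)


def test_sheet_scales_with_interfaces():
    per_interface = None
    for n in (2, 3, 5):
        block = build_nanocrystal("ILQINS", 1, dims=(1, 1, n))
        bonds = detect_backbone_hbonds(FrameTopology(block.strands),
                                       block.coords())
        inter = [b for b in bonds if b.pairing != "intra"]
        if per_interface is None:
            per_interface = len(inter)
        else:
            assert len(inter) == per_interface * (n - 1)


def test_strand_direction_sign_and_oracle(ilqins, rng):
    d = strand_direction(ilqins)
    assert d == pytest.approx([1.0, 0.0, 0.0], abs=0.05)
    ca = ilqins.ca_coords()
    assert strand_direction(ca[::-1]) == pytest.approx(-d)
    # bent strand: direction equals the dominant eigenvector of the
    # second-moment (inertia-style) tensor of the CA cloud
    bent = ca + 0.3 * np.sin(np.linspace(0, 3, len(ca)))[:, None]
    dev = bent - bent.mean(0)
    w, v = np.linalg.eigh(dev.T @ dev)
    principal = v[:, -1]
    if np.dot(principal, bent[-1] - bent[0]) < 0:
        principal = -principal
    assert strand_direction(bent) == pytest.approx(principal, abs=1e-8)
    with pytest.raises(ValueError):
        strand_direction(ca[:1])


def test_classify_pairing_thresholds():
    ex = np.array([1.0, 0, 0])
    assert classify_pairing(ex, ex) == "P"
    assert classify_pairing(ex, -ex) == "AP"
    assert classify_pairing(ex, np.array([0, 1.0, 0])) == "unclassified"
    with pytest.raises(ValueError):
        classify_pairing(ex, np.array([0.5, 0, 0]))


def test_reversing_a_strand_flips_labels():
    block = build_nanocrystal("ILQINS", 1, dims=(1, 1, 2))
    topo = FrameTopology(block.strands)
    coords = block.coords()
    n_p, n_ap = count_pairings(detect_backbone_hbonds(topo, coords))
    # rotate the second strand 180 deg about the z axis through its centroid
    sl = list(block.peptide_slices())[1]
    flipped = coords.copy()
    c = coords[sl].mean(0)
    flipped[sl] = (coords[sl] - c) @ np.diag([-1.0, -1.0, 1.0]).T + c
    n_p2, n_ap2 = count_pairings(detect_backbone_hbonds(topo, flipped))
    assert n_p > 0 and n_p2 == 0
    # every surviving bond is now antiparallel
    bonds = [b for b in detect_backbone_hbonds(topo, flipped)
             if b.pairing not in ("intra",)]
    assert all(b.pairing == "AP" for b in bonds)


def test_counts_invariant_under_rigid_motion(rng):
    from scipy.spatial.transform import Rotation
    block = build_nanocrystal("ILQINS", 5, dims=(1, 1, 3))
    topo = FrameTopology(block.strands)
    coords = block.coords()
    base = count_pairings(detect_backbone_hbonds(topo, coords))
    rot = Rotation.from_rotvec([0.7, 0.2, -0.4]).as_matrix()
    moved = coords @ rot.T + np.array([30.0, -12.0, 5.0])
    assert count_pairings(detect_backbone_hbonds(topo, moved)) == base


def test_missing_amide_hydrogens_rejected(ilqins):
    bad = ilqins.copy()
    keep = [i for i, nm in enumerate(bad.atom_names) if nm != "H"]
    bad.atom_names = [bad.atom_names[i] for i in keep]
    bad.elements = [bad.elements[i] for i in keep]
    bad.res_index = bad.res_index[keep]
    bad.coords = bad.coords[keep]
    with pytest.raises(ValueError, match="amide hydrogen"):
        FrameTopology([bad])


def test_moving_average_against_brute_force(rng):
    series = rng.integers(0, 20, 31).astype(float)
    out = moving_average(series, window_ns=5.0, dt_ns=1.0)
    half = 2  # round(5)//2
    for i in range(len(series)):
        lo, hi = max(0, i - half), min(len(series), i + half + 1)
        assert out[i] == pytest.approx(series[lo:hi].mean())
    # constant series unchanged; impulse mass conserved under truncation
    assert moving_average(np.full(9, 3.0), 3.0, dt_ns=1.0) == pytest.approx(
        np.full(9, 3.0))
    impulse = np.zeros(11)
    impulse[5] = 1.0
    sm = moving_average(impulse, 3.0, dt_ns=1.0)
    assert sm.sum() == pytest.approx(1.0 / 3.0 * 3)


def test_static_ap_sheet_series_is_constant():
    block = make_ideal_assembly("ILQINS", 5, "sheet", 4)
    frames = np.stack([block.coords()] * 5)
    series = hbond_series(block.strands, frames, smooth_window_ns=1.0)
    assert np.all(series.n_p == 0)
    assert len(set(series.n_ap)) == 1 and series.n_ap[0] > 0
    assert len(series.n_ap_smooth) == len(series.n_ap)


def test_decay_trajectory_declines():
    block = make_ideal_assembly("ILQINS", 1, "sheet", 6)
    traj = synth_trajectory(block, FixtureRecipe(
        n_frames=40, sigma=0.05, decay_per_frame=0.15, seed=9))
    series = hbond_series(block.strands, traj.frames, traj.times_ns,
                          smooth_window_ns=1.0)
    sm = series.n_p_smooth
    assert sm[-1] < sm[0]
    # smoothed counts decline (weakly) monotonically within tolerance
    drops = np.diff(sm)
    assert np.all(drops <= 1e-9 + 1.0)
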