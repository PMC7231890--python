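"""Synthetic inputs: point lattices, ideal assemblies, noisy trajectories.

Everything the pipeline consumes can be generated here deterministically from
a seed; trajectories emulate the statistical structure of converged
molecular-dynamics output (per-atom Gaussian jitter around an ideal assembly,
with a labelled burn-in segment and an optional progressive hydrogen-bond
breaking schedule for decay studies).  They make no attempt to emulate
explicit hydration or force-field-specific fluctuation spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .strand import build_extended_strand, Strand
from .lattice import (LatticeParams, SymmetryClass, make_unit_cell,
                      build_block, build_nanocrystal, NanocrystalBlock)


@dataclass
class FixtureRecipe:
    """Seeded recipe for a synthetic trajectory."""

    n_frames: int = 60
    sigma: float = 0.1          # A, per-atom Gaussian jitter
    drift: float = 0.0          # A per frame, slow random-walk drift
    burn_in_frames: int = 0
    dt_ns: float = 0.1
    decay_per_frame: float = 0.0  # progressive H-bond-breaking rate
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0 or self.drift < 0 or self.decay_per_frame < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


@dataclass
class Trajectory:
    """A block plus frames (n_frames, n_atoms, 3) and a burn-in label."""

    block: NanocrystalBlock
    frames: np.ndarray
    times_ns: np.ndarray
    burn_in_frames: int = 0

    def production_frames(self):
        return self.frames[self.burn_in_frames:]


def point_lattice(spacings, dims, gamma: float = 90.0) -> np.ndarray:
    """Orthogonal (or gamma-skewed in the a-b plane) lattice of unit points."""
    d_a, d_b, d_c = spacings
    if min(d_a, d_b, d_c) <= 0:
        raise ValueError("spacings must be positive")
    n_a, n_b, n_c = dims
    g = np.deg2rad(gamma)
    a_vec = np.array([d_a, 0.0, 0.0])
    b_vec = d_b * np.array([np.cos(g), np.sin(g), 0.0])
    c_vec = np.array([0.0, 0.0, d_c])
    pts = [i * a_vec + j * b_vec + k * c_vec
           for i in range(n_a) for j in range(n_b) for k in range(n_c)]
    return np.asarray(pts)


def make_ideal_assembly(sequence: str, class_index: int, geometry: str,
                        n: int = 2, lattice: LatticeParams | None = None,
                        ) -> NanocrystalBlock:
    """Canonical small assemblies: 'dimer', 'sheet' (1x1xn), 'zipper' (1x2xn)."""
    if geometry == "dimer":
        dims = (1, 1, 2)
    elif geometry == "sheet":
        dims = (1, 1, n)
    elif geometry == "zipper":
        dims = (1, 2, n)
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    return build_nanocrystal(sequence, class_index, dims=dims, lattice=lattice)


def random_gas(sequence: str, n_peptides: int, radius: float, seed: int,
               min_separation: float = 3.0):
    """Randomly placed and oriented copies of an extended strand in a sphere.

    Returns (strands, reference strand).  Used as the starting state of
    aggregation runs.
    """
    rng = np.random.default_rng(seed)
    base = build_extended_strand(sequence)
    strands = []
    attempts = 0
    while len(strands) < n_peptides:
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("could not place peptides without overlap")
        rot = Rotation.random(random_state=rng).as_matrix()
        pos = rng.uniform(-radius, radius, 3)
        if np.linalg.norm(pos) > radius:
            continue
        s = base.transform(rot, pos)
        if all(cdist(s.coords, t.coords).min() >= min_separation
               for t in strands):
            strands.append(s)
    return strands, base


_DEMO_DEFAULTS = {
    "sequence": "ILQINS",
    "classes": (1, 5),
    "seed": 0,
    "scatter_dims": (4, 4, 16),
    "hremd_steps": 60000,
    "hremd_peptides": 8,
    "hremd_replicas": 8,
}


def demo_pipeline(config=None, out_dir=None) -> dict:
    """End-to-end desk-scale run: build, scatter, topology, HREMD, thermo.

    Returns a report dict (also written as JSON when ``out_dir`` is given).
    Unknown configuration keys are rejected by name.
    """
    import json
    import os
    import time

    from .energy import EnergyModel, PeptideSystem, bjerrum_length
    from .hremd import (ReplicaSchedule, run_hremd, effective_concentration,
                        mixing_diagnostics)
    from .scattering import block_profile, find_profile_peaks
    from .thermo import dg_c, dg_zip, ddg_table
    from .topology import (FrameTopology, detect_backbone_hbonds,
                           count_pairings, hbond_series)

    cfg = dict(_DEMO_DEFAULTS)
    for key, value in (config or {}).items():
        if key not in _DEMO_DEFAULTS:
            raise ValueError(f"unknown demo configuration key {key!r}")
        cfg[key] = value
    seq = cfg["sequence"]
    seed = int(cfg["seed"])
    model = EnergyModel()
    t_start = time.time()
    report = {"sequence": seq, "seed": seed,
              "bjerrum_water_A": bjerrum_length(80.0, 300.0),
              "effective_concentration_M": effective_concentration(64, 50.0)}

    # nanocrystal construction + scattering diagnostics
    report["classes"] = {}
    for cls in cfg["classes"]:
        block = build_nanocrystal(seq, cls, dims=cfg["scatter_dims"])
        entry = {"n_peptides": block.n_peptides}
        if block.symmetry.is_parallel:
            q = np.linspace(1.0, 1.5, 251)
            prof = block_profile(block, q, method="binned")
            peak = find_profile_peaks(prof).dominant()
            entry["waxs_peak_d_A"] = peak.d_spacing if peak else None
        else:
            q = np.linspace(0.5, 0.8, 151)
            prof = block_profile(block, q, method="binned")
            peak = find_profile_peaks(prof).dominant()
            entry["low_q_peak_d_A"] = peak.d_spacing if peak else None
            # translated-equivalent (same-sense) repeat along c
            col = [s for s in block.strands
                   if s.lattice_index[:2] == (0, 0)]
            z = {s.lattice_index[2]: s.coords.mean(axis=0)[2] for s in col}
            sen = {s.lattice_index[2]: s.sense for s in col}
            entry["same_sense_c_repeat_A"] = next(
                z[k2] - z[k] for k in sorted(z) for k2 in sorted(z)
                if k2 > k and sen[k2] == sen[k])
        report["classes"][cls] = entry

    # hydrogen-bond topology on a static ideal sheet
    sheet = make_ideal_assembly(seq, cfg["classes"][-1], "sheet", 6)
    topo = FrameTopology(sheet.strands)
    n_p, n_ap = count_pairings(detect_backbone_hbonds(topo, sheet.coords()))
    report["ideal_sheet_hbonds"] = {"n_p": n_p, "n_ap": n_ap}

    # small replica-exchange aggregation run
    strands, base = random_gas(seq, cfg["hremd_peptides"], 12.0, seed)
    system = PeptideSystem(strands)
    schedule = ReplicaSchedule(n_replicas=cfg["hremd_replicas"])
    result = run_hremd(system, schedule, base.coords, model,
                       n_steps=int(cfg["hremd_steps"]), seed=seed,
                       confinement_radius=14.0, xy_restraint=0.3,
                       stride=max(int(cfg["hremd_steps"]) // 10, 1))
    topo = FrameTopology(strands)
    series = hbond_series(topo, result.frames, result.times_ps / 1000.0)
    diag = mixing_diagnostics(result.exchange_log)
    report["hremd"] = {
        "endpoint_n_p": int(series.n_p[-1]),
        "endpoint_n_ap": int(series.n_ap[-1]),
        "mean_exchange_acceptance": float(np.nanmean(
            list(diag["acceptance_rates"].values()))),
    }

    # interface thermodynamics (frozen deterministic fixtures)
    results = {}
    for cls in (1, 5):
        sheet = make_ideal_assembly(seq, cls, "sheet", 14)
        traj = synth_trajectory(sheet, FixtureRecipe(
            n_frames=60, sigma=0.0, burn_in_frames=10, seed=seed))
        v_c, e_c, _ = dg_c(traj, model, seed=seed)
        zipb = make_ideal_assembly(seq, cls, "zipper", 14)
        trajz = synth_trajectory(zipb, FixtureRecipe(
            n_frames=60, sigma=0.0, burn_in_frames=10, seed=seed))
        v_z, e_z, _ = dg_zip(trajz, model, seed=seed)
        results[(seq, cls)] = {"dg_c": v_c, "dg_c_err": e_c,
                               "dg_zip": v_z, "dg_zip_err": e_z}
    table = ddg_table(results)
    ddg_row = table.frame[table.frame.entry == "ddG 1-5"].iloc[0]
    report["thermo"] = {
        "dg_c_class1": results[(seq, 1)]["dg_c"],
        "dg_c_class5": results[(seq, 5)]["dg_c"],
        "dg_zip_class1": results[(seq, 1)]["dg_zip"],
        "dg_zip_class5": results[(seq, 5)]["dg_zip"],
        "ddg_c_1_minus_5": float(ddg_row.dg_c),
        "ddg_zip_1_minus_5": float(ddg_row.dg_zip),
    }
    report["runtime_s"] = time.time() - t_start

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        table.to_csv(os.path.join(out_dir, "thermo_table.csv"))
    return report


def synth_trajectory(block: NanocrystalBlock, recipe: FixtureRecipe,
                     ) -> Trajectory:
    """Seeded Gaussian-jitter frames around an ideal assembly.

    With ``decay_per_frame`` > 0, a progressively growing fraction of peptides
    is additionally displaced and rotated away from the lattice, emulating the
    gradual loss of backbone hydrogen bonding seen in an unravelling sheet.
    Identical recipes give bit-identical trajectories.
    """
    rng = np.random.default_rng(recipe.seed)
    base = block.coords()
    n_atoms = len(base)
    frames = np.empty((recipe.n_frames, n_atoms, 3))
    drift = np.zeros(3)
    slices = list(block.peptide_slices())
    order = rng.permutation(len(slices))
    for k in range(recipe.n_frames):
        frame = base + rng.normal(0.0, recipe.sigma, size=(n_atoms, 3))
        if recipe.drift > 0:
            drift = drift + rng.normal(0.0, recipe.drift, size=3)
            frame = frame + drift
        if recipe.decay_per_frame > 0:
            n_broken = min(int(recipe.decay_per_frame * k), len(slices))
            for p in order[:n_broken]:
                sl = slices[p]
                rot = Rotation.random(random_state=rng).as_matrix()
                c = frame[sl].mean(axis=0)
                kick = rng.normal(0.0, 4.0, size=3)
                frame[sl] = (frame[sl] - c) @ rot.T + c + kick
        frames[k] = frame
    times = np.arange(recipe.n_frames) * recipe.dt_ns
    return Trajectory(block, frames, times, recipe.burn_in_frames)
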