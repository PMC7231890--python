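"""Block-cutting interface free-energy decomposition.

Interface formation energies are estimated by cutting rectangular sub-blocks
out of trajectory snapshots, relaxing each cut block in the continuum-solvent
energy model (rigid-per-peptide minimization), and averaging:

    dG(interface) = [ G(joined) - (G(part A) + G(part B)) ] / n_buried,

in kcal/mol per peptide buried by the interface.  The hydrogen-bonding-axis
quantity dG_c comes from splitting a single sheet (1 x 1 x 2n) in half along
c (sheet elongation precedes lateral assembly); the steric-zipper quantity
dG_zip from splitting a two-sheet block (1 x 2 x n) into its two sheets.
Estimates refuse fewer than 50 sampled blocks unless explicitly overridden
(the override is recorded in the result).  ddG(1-5) rows compare the parallel
class-1 and antiparallel class-5 values exactly as dG(class 1) - dG(class 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energy import PeptideSystem, EnergyModel, minimize, total_energy

MIN_SAMPLES = 50


@dataclass
class BlockSpec:
    """A rectangular sub-block: lattice origin plus dims, 0-based."""

    dims: tuple
    origin: tuple = (0, 0, 0)

    def __post_init__(self):
        if min(self.dims) < 1:
            raise ValueError("sub-block dims must be >= 1")
        if min(self.origin) < 0:
            raise ValueError("origin must be non-negative")

    def contains(self, index) -> bool:
        return all(o <= i < o + d
                   for i, o, d in zip(index, self.origin, self.dims))


def cut_block(block, spec: BlockSpec, frame=None):
    """Peptides of ``block`` whose lattice indices fall inside ``spec``.

    Returns (strands, coords): strand copies carrying their lattice labels and
    the corresponding coordinates taken from ``frame`` (or the block's own
    coordinates), unmodified.
    """
    for o, d, n in zip(spec.origin, spec.dims, block.dims):
        if o + d > n:
            raise ValueError("sub-block spec exceeds parent dimensions")
    frame = np.asarray(frame, dtype=float) if frame is not None else block.coords()
    keep, coords = [], []
    for sl, s in zip(block.peptide_slices(), block.strands):
        if spec.contains(s.lattice_index):
            keep.append(s)
            coords.append(frame[sl])
    return keep, np.concatenate(coords, axis=0)


@dataclass
class FreeEnergyEstimate:
    value: float
    stderr: float
    n_samples: int
    undersampled_override: bool = False


def block_free_energy(blocks, model: EnergyModel,
                      tolerance: float = 1e-2, max_iterations: int = 40,
                      allow_undersampled: bool = False) -> FreeEnergyEstimate:
    """Mean minimized block energy over sampled snapshots, with stderr.

    ``blocks`` is a sequence of (strands, coords) samples of identical
    dimensions, e.g. from :func:`cut_block` over distinct frames.
    """
    blocks = list(blocks)
    if not blocks:
        raise ValueError("no blocks supplied")
    n0 = len(blocks[0][0])
    if any(len(s) != n0 for s, _ in blocks):
        raise ValueError("heterogeneous block dimensions in sample")
    if len(blocks) < MIN_SAMPLES and not allow_undersampled:
        raise ValueError(
            f"only {len(blocks)} blocks sampled; at least {MIN_SAMPLES} "
            "required (pass allow_undersampled=True to override)")
    # frozen trajectories (zero noise) repeat one snapshot: minimize it once
    all_same = all(np.array_equal(blocks[0][1], c) for _, c in blocks[1:])
    work = blocks[:1] if all_same else blocks
    energies = []
    for strands, coords in work:
        system = PeptideSystem(strands)
        xmin, report, _ = minimize(coords, system, model, tolerance=tolerance,
                                   max_iterations=max_iterations, mode="rigid")
        energies.append(report.total)
    if all_same:
        energies = energies * len(blocks)
    energies = np.asarray(energies)
    stderr = (float(energies.std(ddof=1) / np.sqrt(len(energies)))
              if len(energies) > 1 and not all_same else 0.0)
    return FreeEnergyEstimate(float(energies.mean()), stderr, len(energies),
                              len(blocks) < MIN_SAMPLES)


def interface_dG(g_joined: FreeEnergyEstimate, g_part_a: FreeEnergyEstimate,
                 g_part_b: FreeEnergyEstimate, n_buried: int):
    """Per-buried-peptide interface free energy and propagated stderr."""
    if n_buried < 1:
        raise ValueError("n_buried must be >= 1")
    value = (g_joined.value - (g_part_a.value + g_part_b.value)) / n_buried
    err = np.sqrt(g_joined.stderr ** 2 + g_part_a.stderr ** 2
                  + g_part_b.stderr ** 2) / n_buried
    return float(value), float(err)


def _sample_frames(trajectory, n_samples, seed):
    frames = trajectory.production_frames()
    if len(frames) < n_samples:
        raise ValueError(
            f"trajectory supplies {len(frames)} production frames; "
            f"{n_samples} distinct frames required")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(frames), size=n_samples, replace=False)
    return [frames[i] for i in sorted(pick)]


def _split_dG(trajectory, model, axis: int, n_samples, seed,
              allow_undersampled=False, **min_kw):
    block = trajectory.block
    dims = block.dims
    if dims[axis] % 2:
        raise ValueError("split axis length must be even")
    half = list(dims)
    half[axis] //= 2
    origin_b = [0, 0, 0]
    origin_b[axis] = half[axis]
    spec_full = BlockSpec(tuple(dims))
    spec_a = BlockSpec(tuple(half))
    spec_b = BlockSpec(tuple(half), tuple(origin_b))

    if axis == 2:       # c split buries the sheet cross-section
        n_buried = dims[0] * dims[1]
    elif axis == 1:     # b split buries one strand column per c layer
        n_buried = dims[0] * dims[2]
    else:
        n_buried = dims[1] * dims[2]

    frames = _sample_frames(trajectory, n_samples, seed)
    parts = {}
    for key, spec in (("full", spec_full), ("a", spec_a), ("b", spec_b)):
        samples = [cut_block(block, spec, fr) for fr in frames]
        parts[key] = block_free_energy(
            samples, model, allow_undersampled=allow_undersampled, **min_kw)
    value, err = interface_dG(parts["full"], parts["a"], parts["b"], n_buried)
    return value, err, parts


def dg_c(trajectory, model: EnergyModel, n_samples: int = MIN_SAMPLES,
         seed: int = 0, allow_undersampled: bool = False, **min_kw):
    """Sheet-elongation interface energy: split a single sheet in half along c."""
    return _split_dG(trajectory, model, axis=2, n_samples=n_samples,
                     seed=seed, allow_undersampled=allow_undersampled, **min_kw)


def dg_zip(trajectory, model: EnergyModel, n_samples: int = MIN_SAMPLES,
           seed: int = 0, allow_undersampled: bool = False, **min_kw):
    """Steric-zipper interface energy: split a two-sheet block along b."""
    return _split_dG(trajectory, model, axis=1, n_samples=n_samples,
                     seed=seed, allow_undersampled=allow_undersampled, **min_kw)


@dataclass
class InterfaceEnergyTable:
    """Per-sequence, per-class dG_c / dG_zip with ddG(1-5) rows."""

    frame: pd.DataFrame

    def to_csv(self, destination):
        self.frame.to_csv(destination, index=False)


def ddg_table(results: dict) -> InterfaceEnergyTable:
    """Assemble a thermodynamics table with exact ddG(1-5) arithmetic.

    ``results`` maps (sequence, class_index) -> dict with keys
    'dg_c', 'dg_zip' and optionally 'dg_c_err', 'dg_zip_err'.
    Both class 1 and class 5 must be present for every sequence.
    """
    sequences = sorted({seq for seq, _ in results})
    rows = []
    for seq in sequences:
        for cls in (1, 5):
            if (seq, cls) not in results:
                raise ValueError(f"missing class {cls} entry for {seq}")
        r1, r5 = results[(seq, 1)], results[(seq, 5)]
        for cls, r in ((1, r1), (5, r5)):
            rows.append({
                "sequence": seq, "entry": f"class {cls}",
                "dg_c": r["dg_c"], "dg_zip": r["dg_zip"],
                "dg_c_err": r.get("dg_c_err", np.nan),
                "dg_zip_err": r.get("dg_zip_err", np.nan),
            })
        rows.append({
            "sequence": seq, "entry": "ddG 1-5",
            "dg_c": r1["dg_c"] - r5["dg_c"],
            "dg_zip": r1["dg_zip"] - r5["dg_zip"],
            "dg_c_err": np.nan, "dg_zip_err": np.nan,
        })
    return InterfaceEnergyTable(pd.DataFrame(rows))
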