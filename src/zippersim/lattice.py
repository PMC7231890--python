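"""Steric-zipper symmetry classes and nanocrystal block assembly.

The eight canonical steric-zipper symmetry classes are encoded as the three
binary choices (strand sense within a sheet, sheet face packing, relative sheet
orientation).  Only the P = classes 1-4 / AP = classes 5-8 split is fixed by
the crystallographic taxonomy; the within-group ordering used here is the
lookup table below, documented rather than derived:

====== ======= ============== ============ =================
class  sense   face packing   orientation  AP strand flip
====== ======= ============== ============ =================
1      P       face-to-face   up-up        --
2      P       face-to-back   up-up        --
3      P       face-to-face   up-down      --
4      P       face-to-back   up-down      --
5      AP      face-to-face   up-up        180 deg about c
6      AP      face-to-back   up-up        180 deg about c
7      AP      face-to-face   up-down      180 deg about b
8      AP      face-to-back   up-down      180 deg about b
====== ======= ============== ============ =================

Rotation about b (the sheet normal) reverses a strand while preserving the
side-chain face registry; rotation about c reverses it while swapping the
faces.  Classes 5-6 take the c rotation (which also yields the better
hydrogen-bonded antiparallel sheet for the pleated strand used here) and
classes 7-8 the b rotation.  Reversed strands additionally take a small
registry shift along the strand axis, found by a deterministic scan that
maximizes the number of ideal backbone hydrogen bonds to the unreversed
neighbour (the automated counterpart of building the AP sheet "by hand").

Axes: a -> x (terminus-terminus), b in the x-y plane at angle gamma from a
(side-chain stacking / zipper axis), c -> z (hydrogen bonding).  Lattice
indices are 0-based; the b index counts single sheets (spaced b/2) and the c
index counts single strands (spaced c_rise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .strand import Strand, amide_hydrogen  # noqa: F401  (re-export for topology)

CLASS_TABLE = {
    1: ("P", "face-to-face", "up-up", None),
    2: ("P", "face-to-back", "up-up", None),
    3: ("P", "face-to-face", "up-down", None),
    4: ("P", "face-to-back", "up-down", None),
    5: ("AP", "face-to-face", "up-up", "c"),
    6: ("AP", "face-to-back", "up-up", "c"),
    7: ("AP", "face-to-face", "up-down", "b"),
    8: ("AP", "face-to-back", "up-down", "b"),
}

MIN_CONTACT = 1.8  # A, hard lower bound on inter-peptide heavy-atom contacts


@dataclass(frozen=True)
class SymmetryClass:
    index: int
    strand_sense: str
    sheet_face_packing: str
    sheet_orientation: str
    ap_flip_axis: str | None = None

    @classmethod
    def from_index(cls, index: int) -> "SymmetryClass":
        if index not in CLASS_TABLE:
            raise ValueError(f"symmetry class index must be 1..8, got {index}")
        sense, packing, orient, flip = CLASS_TABLE[index]
        return cls(index, sense, packing, orient, flip)

    @property
    def is_parallel(self) -> bool:
        return self.strand_sense == "P"


@dataclass
class LatticeParams:
    """Unit-cell geometry in Angstrom / degrees.

    ``a`` is the terminus-terminus axis, ``b`` the side-chain stacking axis
    (two sheets per b repeat), ``gamma`` the a-b angle and ``c_rise`` the
    per-strand rise along the hydrogen-bonding axis.  ``c_rise`` defaults to
    4.8 for parallel classes and 4.85 for antiparallel ones, which puts the
    translated-equivalent (same-sense) repeat of an AP stack at 9.7.
    """

    a: float = 20.6
    b: float = 19.1
    gamma: float = 82.0
    c_rise: float | None = None

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("lattice lengths must be positive")
        if not 0 < self.gamma < 180:
            raise ValueError("gamma must be in (0, 180) degrees")
        if self.c_rise is not None and self.c_rise <= 0:
            raise ValueError("c_rise must be positive")

    def resolved_c_rise(self, symmetry: SymmetryClass) -> float:
        if self.c_rise is not None:
            return self.c_rise
        return 4.8 if symmetry.is_parallel else 4.85

    @property
    def a_vec(self) -> np.ndarray:
        return np.array([self.a, 0.0, 0.0])

    @property
    def b_vec(self) -> np.ndarray:
        g = np.deg2rad(self.gamma)
        return self.b * np.array([np.cos(g), np.sin(g), 0.0])


def _rot(axis: str) -> np.ndarray:
    return {
        "a": np.diag([1.0, -1.0, -1.0]),
        "b": np.diag([-1.0, 1.0, -1.0]),
        "c": np.diag([-1.0, -1.0, 1.0]),
    }[axis]


def _hbond_count(strand_a: Strand, coords_a, coords_b, dmax=2.5, amin=135.0) -> int:
    """Ideal backbone H-bond count between two copies of the same strand."""
    h_idx = [i for i, nm in enumerate(strand_a.atom_names) if nm == "H"]
    o_idx = [i for i, nm in enumerate(strand_a.atom_names) if nm in ("O", "OXT")]
    n_of_h = {i: strand_a.atom_idx("N", strand_a.res_index[i]) for i in h_idx}
    count = 0
    for cd, ca in ((coords_a, coords_b), (coords_b, coords_a)):
        for i in h_idx:
            h = cd[i]
            n = cd[n_of_h[i]]
            for j in o_idx:
                o = ca[j]
                d = np.linalg.norm(h - o)
                if d >= dmax:
                    continue
                v1 = h - n
                v2 = o - h
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                if 180.0 - np.degrees(np.arccos(np.clip(cosang, -1, 1))) > amin:
                    count += 1
    return count


def _ap_registry_shift(strand: Strand, flip_axis: str, c_rise: float) -> float:
    """Strand-axis shift of the reversed AP strand that maximizes ideal
    hydrogen bonding to its unreversed neighbour (ties -> smallest |shift|)."""
    rot = _rot(flip_axis)
    flipped = strand.coords @ rot.T
    best = (-1, np.inf, 0.0)
    for dx in np.arange(-4.0, 4.0 + 1e-9, 0.05):
        cb = flipped + np.array([dx, 0.0, c_rise])
        n = _hbond_count(strand, strand.coords, cb)
        key = (n, -abs(dx))
        if (key[0], key[1]) > (best[0], -best[1]):
            best = (n, abs(dx), dx)
    return float(best[2])


class UnitCell(list):
    """Minimal repeating motif: a list of posed strands plus lattice metadata.

    Each strand carries ``sub_b`` (which of the two sheets in the b repeat) and
    ``sub_c`` (position within the sense-alternation repeat along c; always 0
    for P classes).
    """

    def __init__(self, strands, symmetry: SymmetryClass, lattice: LatticeParams):
        super().__init__(strands)
        self.symmetry = symmetry
        self.lattice = lattice


def make_unit_cell(strand: Strand, symmetry: SymmetryClass,
                   lattice: LatticeParams | None = None) -> UnitCell:
    """Pose the minimal repeating motif: 2 strands (one per sheet) for P
    classes, 4 (two per sheet, opposite sense) for AP classes."""
    if not isinstance(symmetry, SymmetryClass):
        symmetry = SymmetryClass.from_index(int(symmetry))
    lattice = lattice or LatticeParams()
    c_rise = lattice.resolved_c_rise(symmetry)

    # sheet 0 poses as (rotation, translation) pairs
    poses = [(np.eye(3), np.zeros(3), 0)]
    if not symmetry.is_parallel:
        dx = _ap_registry_shift(strand, symmetry.ap_flip_axis, c_rise)
        poses.append((_rot(symmetry.ap_flip_axis),
                      np.array([dx, 0.0, c_rise]), 1))

    # second sheet: the same poses with the face-packing (and, for up-down
    # classes, direction-flip) operation applied about each strand's own
    # centroid, shifted by b/2.  The mating sheet is additionally staggered
    # by a/2 along the strand axis so that side chains interdigitate and the
    # charged termini of the two sheets are not juxtaposed across the dry
    # zipper interface (termini contact along a, not across the zipper).
    op = np.eye(3)
    if symmetry.sheet_face_packing == "face-to-face":
        op = _rot("a") @ op
    if symmetry.sheet_orientation == "up-down":
        op = _rot("b") @ op

    def assemble(stagger_frac, z_frac=0.0):
        shift = (0.5 * lattice.b_vec + stagger_frac * lattice.a_vec
                 + z_frac * c_rise * np.array([0.0, 0.0, 1.0]))
        strands = []
        for sub_b in (0, 1):
            for rot, trans, sub_c in poses:
                # the whole sheet is rotated by op, so the within-sheet motif
                # translation rotates with it (up to the c-lattice repeat)
                r = (op @ rot) if sub_b == 1 else rot
                t = ((op @ trans) if sub_b == 1 else trans).copy()
                if sub_b == 1:
                    if t[2] < -1e-9:   # keep the motif inside the c repeat
                        t[2] += 2.0 * c_rise
                    t += shift
                sense = 1 if (r @ np.array([1.0, 0.0, 0.0]))[0] > 0 else -1
                strands.append(_posed(strand, r, t, sense, sub_b, sub_c))
        return UnitCell(strands, symmetry, lattice)

    # preferred stagger a/2; fall back deterministically (including a half
    # c-rise interdigitation shift) if a class geometry would clash in a
    # periodic block
    candidates = [(0.5, 0.0), (-0.5, 0.0), (0.25, 0.0), (-0.25, 0.0),
                  (0.5, 0.5), (-0.5, 0.5), (0.25, 0.5), (-0.25, 0.5),
                  (0.0, 0.5), (0.0, 0.0)]
    for frac, zf in candidates:
        cell = assemble(frac, zf)
        trial = build_block(cell, 2, 2, 2 if symmetry.is_parallel else 4,
                            validate=False)
        if min_interpeptide_distance(trial) >= MIN_CONTACT:
            return cell
    raise ValueError("no clash-free sheet stagger found for this class")


def _posed(strand: Strand, rot, trans, sense, sub_b, sub_c) -> Strand:
    s = strand.transform(np.asarray(rot, dtype=float), np.asarray(trans, dtype=float))
    s.sense = sense
    s.sub_b = sub_b
    s.sub_c = sub_c
    return s


@dataclass
class NanocrystalBlock:
    """n_a x n_b x n_c peptides on the oblique steric-zipper lattice."""

    strands: list
    lattice: LatticeParams
    symmetry: SymmetryClass
    dims: tuple

    @property
    def n_peptides(self) -> int:
        return len(self.strands)

    @property
    def n_atoms_per_peptide(self) -> int:
        return self.strands[0].n_atoms

    def coords(self) -> np.ndarray:
        return np.concatenate([s.coords for s in self.strands], axis=0)

    def elements(self) -> list:
        out = []
        for s in self.strands:
            out.extend(s.elements)
        return out

    def senses(self) -> np.ndarray:
        return np.array([s.sense for s in self.strands])

    def indices(self) -> np.ndarray:
        return np.array([s.lattice_index for s in self.strands])

    def peptide_slices(self):
        start = 0
        for s in self.strands:
            yield slice(start, start + s.n_atoms)
            start += s.n_atoms

    def validate(self, check_clashes: bool = True) -> None:
        n_a, n_b, n_c = self.dims
        if self.n_peptides != n_a * n_b * n_c:
            raise ValueError("peptide count does not match dims")
        if not self.symmetry.is_parallel:
            # alternating sense along c within each (i, j) column
            idx = self.indices()
            sen = self.senses()
            for (i, j) in {(i, j) for i, j, _ in map(tuple, idx)}:
                col = sen[(idx[:, 0] == i) & (idx[:, 1] == j)]
                if not np.all(col[:-1] * col[1:] == -1):
                    raise ValueError("AP block does not alternate sense along c")
        if check_clashes:
            d = min_interpeptide_distance(self)
            if d < MIN_CONTACT:
                raise ValueError(
                    f"steric clash: inter-peptide heavy-atom distance {d:.2f} A")


def min_interpeptide_distance(block: NanocrystalBlock) -> float:
    """Smallest heavy-atom distance between different peptides."""
    heavy = block.strands[0].heavy_mask()
    pts = np.concatenate([s.coords[heavy] for s in block.strands])
    owner = np.repeat(np.arange(block.n_peptides), heavy.sum())
    tree = cKDTree(pts)
    best = np.inf
    # widen the query radius until a cross-peptide pair is found
    r = max(MIN_CONTACT, 2.0)
    while True:
        pairs = tree.query_pairs(r, output_type="ndarray")
        if len(pairs):
            cross = pairs[owner[pairs[:, 0]] != owner[pairs[:, 1]]]
            if len(cross):
                d = np.linalg.norm(pts[cross[:, 0]] - pts[cross[:, 1]], axis=1)
                best = float(d.min())
                break
        r *= 1.6
        if r > 1e3:
            break
    return best


def build_block(cell: UnitCell, n_a: int, n_b: int, n_c: int,
                validate: bool = True) -> NanocrystalBlock:
    """Replicate the unit motif into an n_a x n_b x n_c nanocrystal block.

    The b dimension counts single sheets (spacing b/2) and the c dimension
    single strands (spacing c_rise), so the peptide count is exactly
    ``n_a * n_b * n_c``.
    """
    if min(n_a, n_b, n_c) < 1:
        raise ValueError("block dimensions must be >= 1")
    lattice, symmetry = cell.lattice, cell.symmetry
    c_rise = lattice.resolved_c_rise(symmetry)
    motif = {(s.sub_b, s.sub_c): s for s in cell}
    c_period = 2 if not symmetry.is_parallel else 1

    strands = []
    for i in range(n_a):
        for j in range(n_b):
            for k in range(n_c):
                key = (j % 2, (k % c_period) if c_period == 2 else 0)
                base = motif[key]
                shift = (i * lattice.a_vec
                         + ((j - j % 2) // 2) * lattice.b_vec
                         + (k - (k % c_period if c_period == 2 else 0))
                         * c_rise * np.array([0.0, 0.0, 1.0]))
                s = base.transform(np.eye(3), shift)
                s.sense = base.sense
                s.lattice_index = (i, j, k)
                strands.append(s)
    block = NanocrystalBlock(strands, lattice, symmetry, (n_a, n_b, n_c))
    if validate:
        block.validate(check_clashes=(block.n_peptides <= 2000))
    return block


def build_nanocrystal(sequence_or_strand, class_index: int,
                      dims=(6, 12, 18), lattice: LatticeParams | None = None,
                      dihedrals=None) -> NanocrystalBlock:
    """Convenience one-call builder used by the CLI and fixtures."""
    from .strand import build_extended_strand, DEFAULT_DIHEDRALS
    if isinstance(sequence_or_strand, Strand):
        strand = sequence_or_strand
    else:
        strand = build_extended_strand(
            sequence_or_strand, dihedrals or DEFAULT_DIHEDRALS)
    symmetry = SymmetryClass.from_index(class_index)
    cell = make_unit_cell(strand, symmetry, lattice)
    return build_block(cell, *dims)
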