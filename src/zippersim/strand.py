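"""Idealized extended (pleated) beta-strand construction.

A :class:`Strand` is a single hexapeptide (or any sequence) built by forward
kinematics from standard backbone bond lengths and angles at a fixed (phi, psi)
pair in the beta basin.  Atoms kept per residue are the backbone N, H, CA, C, O
plus a CB side-chain bead (no H on proline, no CB on glycine); the C-terminus
carries an OXT oxygen.  Termini are modelled as charged (NH3+ / COO-), which is
the dominant protonation state of short unbuffered hexapeptide assemblies near
neutral pH.

After construction the strand is canonically oriented: the N->C axis lies along
+x (the terminus-terminus lattice axis), the hydrogen-bonding carbonyl
alternation along z, and the side chains along +/-y (the zipper axis), with the
CA centroid at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

# Backbone geometry (Angstrom, degrees): Engh-Huber-style ideal values.
B_N_CA = 1.458
B_CA_C = 1.525
B_C_N = 1.329
B_C_O = 1.231
B_N_H = 1.010
B_CA_CB = 1.530
A_N_CA_C = 111.0
A_CA_C_N = 116.6
A_C_N_CA = 121.9
A_CA_C_O = 120.8

#: default backbone dihedrals (phi, psi) in degrees: a pleated beta strand
#: compatible with parallel-sheet stacking, compact enough that charged
#: termini of a-axis neighbours approach without steric clash at a = 20.6 A.
DEFAULT_DIHEDRALS = (-110.0, 105.0)

# Per-residue side-chain bead parameters: (d_sc: CA-to-centroid distance A,
# LJ sigma A, LJ epsilon weight, hydrophobicity in [0, 1]).  One bead per
# residue stands in for the whole side chain; the residue-specific bead
# distance encodes side-chain length, which is what makes mixed-height sheet
# faces sterically frustrated at a zipper interface.
SIDECHAIN_PARAMS = {
    "A": (1.5, 3.8, 0.6, 0.7), "C": (2.1, 4.1, 0.7, 0.6),
    "D": (2.5, 4.2, 0.6, 0.1), "E": (3.1, 4.4, 0.6, 0.1),
    "F": (3.4, 4.8, 1.0, 1.0), "G": (1.0, 3.4, 0.3, 0.5),
    "H": (3.1, 4.6, 0.7, 0.3), "I": (2.3, 4.5, 0.9, 1.0),
    "K": (3.5, 4.4, 0.6, 0.1), "L": (2.6, 4.5, 0.9, 1.0),
    "M": (3.0, 4.5, 0.8, 0.8), "N": (2.5, 4.2, 0.6, 0.2),
    "P": (1.9, 4.2, 0.6, 0.5), "Q": (3.1, 4.4, 0.6, 0.2),
    "R": (4.1, 4.7, 0.6, 0.1), "S": (1.9, 3.7, 0.5, 0.4),
    "T": (1.9, 4.0, 0.6, 0.5), "V": (1.9, 4.3, 0.8, 0.9),
    "W": (3.9, 5.0, 1.0, 0.9), "Y": (3.8, 4.9, 0.9, 0.7),
}


@dataclass
class Strand:
    """One peptide in an idealized extended conformation.

    Attributes
    ----------
    sequence : one-letter amino-acid string.
    atom_names, elements : per-atom labels.
    res_index : 0-based residue index per atom.
    coords : (n_atoms, 3) Cartesian coordinates in Angstrom.
    direction : unit vector from the N- to the C-terminus.
    termini_charges : signed unit charges on the N- and C-terminal sites.
    sense : +1 or -1 lattice sense flag (set by the lattice builder).
    """

    sequence: str
    atom_names: list
    elements: list
    res_index: np.ndarray
    coords: np.ndarray
    direction: np.ndarray
    termini_charges: tuple = (1.0, -1.0)
    sense: int = 1
    lattice_index: tuple = field(default=(0, 0, 0))

    @property
    def n_residues(self) -> int:
        return int(self.res_index.max()) + 1

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def atom_idx(self, name: str, res: int) -> int:
        for i, (nm, ri) in enumerate(zip(self.atom_names, self.res_index)):
            if nm == name and ri == res:
                return i
        raise KeyError(f"no atom {name} in residue {res}")

    def ca_coords(self) -> np.ndarray:
        mask = [nm == "CA" for nm in self.atom_names]
        return self.coords[np.asarray(mask)]

    def copy(self) -> "Strand":
        return replace(
            self,
            coords=self.coords.copy(),
            res_index=self.res_index.copy(),
            direction=self.direction.copy(),
            atom_names=list(self.atom_names),
            elements=list(self.elements),
        )

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> "Strand":
        """Return a rigidly moved copy (rotation about the origin, then shift)."""
        out = self.copy()
        out.coords = self.coords @ rotation.T + translation
        out.direction = rotation @ self.direction
        return out

    def heavy_mask(self) -> np.ndarray:
        return np.array([el != "H" for el in self.elements])


def _place_atom(p1, p2, p3, bond, angle_deg, torsion_deg):
    """NeRF placement: new atom at given internal coordinates from p1-p2-p3."""
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    d = np.array(
        [-bond * np.cos(ang),
         bond * np.sin(ang) * np.cos(tor),
         bond * np.sin(ang) * np.sin(tor)]
    )
    bc = p3 - p2
    bc /= np.linalg.norm(bc)
    n = np.cross(p2 - p1, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("collinear reference atoms in chain build")
    n /= nn
    m = np.column_stack([bc, np.cross(n, bc), n])
    return p3 + m @ d


def amide_hydrogen(n_pos, ca_pos, c_prev_pos):
    """Planar amide H: along the bisector of the two N-neighbour bonds."""
    u1 = n_pos - c_prev_pos
    u1 /= np.linalg.norm(u1)
    u2 = n_pos - ca_pos
    u2 /= np.linalg.norm(u2)
    b = u1 + u2
    b /= np.linalg.norm(b)
    return n_pos + B_N_H * b


def _cb_position(n_pos, ca_pos, c_pos):
    u1 = n_pos - ca_pos
    u1 /= np.linalg.norm(u1)
    u2 = c_pos - ca_pos
    u2 /= np.linalg.norm(u2)
    bis = u1 + u2
    bis /= np.linalg.norm(bis)
    nrm = np.cross(u1, u2)
    nrm /= np.linalg.norm(nrm)
    # tetrahedral-ish branch: ~110.5 deg to both N and C, L-configuration
    d = -bis * 0.617 + nrm * 0.787
    return ca_pos + B_CA_CB * d / np.linalg.norm(d)


def build_extended_strand(sequence: str, dihedrals=DEFAULT_DIHEDRALS) -> Strand:
    """Build an idealized extended strand by backbone forward kinematics.

    Parameters
    ----------
    sequence : one-letter amino-acid string (must be non-empty).
    dihedrals : (phi, psi) pair in degrees applied uniformly; the default is a
        pleated beta conformation.

    Raises
    ------
    ValueError : empty sequence or unknown residue letter (position reported).
    """
    if not sequence:
        raise ValueError("empty sequence")
    for pos, letter in enumerate(sequence):
        if letter not in AMINO_ACIDS:
            raise ValueError(f"unknown residue letter {letter!r} at position {pos}")
    phi, psi = float(dihedrals[0]), float(dihedrals[1])
    omega = 180.0

    n_res = len(sequence)
    bb = {}  # (name, res) -> coords
    # seed first three atoms in a plane
    bb[("N", 0)] = np.zeros(3)
    bb[("CA", 0)] = np.array([B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(180.0 - A_N_CA_C)
    bb[("C", 0)] = bb[("CA", 0)] + B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(n_res):
        if i > 0:
            bb[("N", i)] = _place_atom(
                bb[("N", i - 1)], bb[("CA", i - 1)], bb[("C", i - 1)],
                B_C_N, A_CA_C_N, psi)
            bb[("CA", i)] = _place_atom(
                bb[("CA", i - 1)], bb[("C", i - 1)], bb[("N", i)],
                B_N_CA, A_C_N_CA, omega)
            bb[("C", i)] = _place_atom(
                bb[("C", i - 1)], bb[("N", i)], bb[("CA", i)],
                B_CA_C, A_N_CA_C, phi)
        # carbonyl O: trans to the next N, i.e. torsion psi + 180 about CA-C
        bb[("O", i)] = _place_atom(
            bb[("N", i)], bb[("CA", i)], bb[("C", i)],
            B_C_O, A_CA_C_O, psi + 180.0)

    atom_names, elements, res_index, coords = [], [], [], []

    def add(name, el, res, xyz):
        atom_names.append(name)
        elements.append(el)
        res_index.append(res)
        coords.append(np.asarray(xyz, dtype=float))

    for i, letter in enumerate(sequence):
        add("N", "N", i, bb[("N", i)])
        if letter != "P":
            if i == 0:
                # N-terminal amide proton: bisector built from CA and C
                h = amide_hydrogen(bb[("N", 0)], bb[("CA", 0)], bb[("C", 0)])
            else:
                h = amide_hydrogen(bb[("N", i)], bb[("CA", i)], bb[("C", i - 1)])
            add("H", "H", i, h)
        add("CA", "C", i, bb[("CA", i)])
        add("C", "C", i, bb[("C", i)])
        add("O", "O", i, bb[("O", i)])
        cb = _cb_position(bb[("N", i)], bb[("CA", i)], bb[("C", i)])
        if letter != "G":
            add("CB", "C", i, cb)
        # single side-chain bead at the residue's centroid distance along
        # the CA->CB direction (glycine keeps only this bead)
        d_sc = SIDECHAIN_PARAMS[letter][0]
        ca_pos = bb[("CA", i)]
        direction = (cb - ca_pos) / np.linalg.norm(cb - ca_pos)
        add("SC", "C", i, ca_pos + d_sc * direction)
    # C-terminal carboxylate: OXT opposite the carbonyl O, in the CA-C-O plane
    ca, c, o = bb[("CA", n_res - 1)], bb[("C", n_res - 1)], bb[("O", n_res - 1)]
    u1 = (ca - c) / np.linalg.norm(ca - c)
    u2 = (o - c) / np.linalg.norm(o - c)
    d = -(u1 + u2)
    add("OXT", "O", n_res - 1, c + 1.25 * d / np.linalg.norm(d))

    strand = Strand(
        sequence=sequence,
        atom_names=atom_names,
        elements=elements,
        res_index=np.asarray(res_index, dtype=int),
        coords=np.asarray(coords, dtype=float),
        direction=np.array([1.0, 0.0, 0.0]),
    )
    _canonicalize(strand)
    _validate(strand)
    return strand


def _canonicalize(strand: Strand) -> None:
    """Orient in place: N->C along +x, carbonyl alternation along z."""
    ca = strand.ca_coords()
    centroid = ca.mean(axis=0)
    # signed principal axis of the CA trace
    dev = ca - centroid
    _, _, vt = np.linalg.svd(dev)
    x_axis = vt[0]
    if np.dot(x_axis, ca[-1] - ca[0]) < 0:
        x_axis = -x_axis
    # alternating carbonyl direction defines the hydrogen-bonding (z) axis
    acc = np.zeros(3)
    for i in range(strand.n_residues):
        c = strand.coords[strand.atom_idx("C", i)]
        o = strand.coords[strand.atom_idx("O", i)]
        acc += ((-1.0) ** i) * (o - c)
    z_axis = acc - np.dot(acc, x_axis) * x_axis
    z_axis /= np.linalg.norm(z_axis)
    y_axis = np.cross(z_axis, x_axis)
    rot = np.vstack([x_axis, y_axis, z_axis])  # rows: new basis
    strand.coords = (strand.coords - centroid) @ rot.T
    strand.direction = np.array([1.0, 0.0, 0.0])
    # orient the pleat so the more hydrophobic side-chain face points +y
    # (toward the mating sheet): steric zippers bury their best face
    plus, minus = [], []
    for i, nm in enumerate(strand.atom_names):
        if nm == "SC":
            res = strand.sequence[strand.res_index[i]]
            hyd = SIDECHAIN_PARAMS[res][3]
            (plus if strand.coords[i][1] > 0 else minus).append(hyd)
    if plus and minus and np.mean(plus) < np.mean(minus):
        strand.coords = strand.coords * np.array([1.0, -1.0, -1.0])


def _validate(strand: Strand) -> None:
    ca = strand.ca_coords()
    d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    if len(d) and not np.all(np.abs(d - 3.8) <= 0.3):
        raise ValueError(f"CA-CA distances out of beta range: {d}")
    if not np.all(np.isfinite(strand.coords)):
        raise ValueError("non-finite coordinates")


def strand_span(strand: Strand) -> float:
    """End-to-end CA distance (first to last residue)."""
    ca = strand.ca_coords()
    return float(np.linalg.norm(ca[-1] - ca[0]))
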