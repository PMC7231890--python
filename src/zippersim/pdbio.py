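"""Structure and trajectory I/O.

PDB reading/writing is delegated to biotite.  Blocks can exceed the 62 chain
identifiers a PDB file allows, so the writer cycles chain IDs through
``A-Z a-z 0-9`` and restarts residue numbering at 1 for every peptide; the
reader recovers peptide boundaries wherever the residue number resets (or the
chain ID changes), which round-trips any number of peptides through plain PDB
text.  Coordinates survive the round trip to the format's 1e-3 A precision.

Multi-frame trajectories use MODEL/ENDMDL records (one model per frame).
"""

from __future__ import annotations

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.sequence import ProteinSequence

CHAIN_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


def _block_to_atom_array(block) -> struc.AtomArray:
    n_total = sum(s.n_atoms for s in block.strands)
    arr = struc.AtomArray(n_total)
    pos = 0
    for p, s in enumerate(block.strands):
        n = s.n_atoms
        arr.coord[pos:pos + n] = s.coords
        arr.chain_id[pos:pos + n] = CHAIN_ALPHABET[p % len(CHAIN_ALPHABET)]
        arr.res_id[pos:pos + n] = s.res_index + 1
        arr.atom_name[pos:pos + n] = s.atom_names
        arr.element[pos:pos + n] = s.elements
        arr.res_name[pos:pos + n] = [
            ProteinSequence.convert_letter_1to3(s.sequence[i]) for i in s.res_index
        ]
        pos += n
    arr.hetero[:] = False
    return arr


def write_structure(block, destination) -> None:
    """Write a nanocrystal block (or any object with ``.strands``) as PDB."""
    if not getattr(block, "strands", None):
        raise ValueError("cannot write an empty block")
    pdb = PDBFile()
    pdb.set_structure(_block_to_atom_array(block))
    pdb.write(destination)


def write_trajectory(block, frames, destination) -> None:
    """Write frames (n_frames, n_atoms, 3) as a multi-MODEL PDB."""
    frames = np.asarray(frames, dtype=float)
    base = _block_to_atom_array(block)
    stack = struc.stack([base] * len(frames))
    stack.coord = frames.copy()
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(destination)


def _split_peptides(arr: struc.AtomArray):
    """Peptide boundaries: residue-number reset or chain change."""
    starts = [0]
    for i in range(1, arr.array_length()):
        if (arr.res_id[i] < arr.res_id[i - 1]
                or arr.chain_id[i] != arr.chain_id[i - 1]):
            starts.append(i)
    starts.append(arr.array_length())
    return [(starts[k], starts[k + 1]) for k in range(len(starts) - 1)]


def read_structure(source):
    """Read a PDB written by :func:`write_structure` back into strands.

    Returns a list of :class:`~zippersim.strand.Strand` objects (sense and
    lattice indices are not stored in PDB and default to +1 / (0,0,0)).
    """
    from .strand import Strand

    pdb = PDBFile.read(source)
    arr = pdb.get_structure(model=1)
    strands = []
    for lo, hi in _split_peptides(arr):
        sub = arr[lo:hi]
        seq = []
        for rid in np.unique(sub.res_id):
            name3 = sub.res_name[sub.res_id == rid][0]
            seq.append(ProteinSequence.convert_letter_3to1(name3))
        ca = sub.coord[sub.atom_name == "CA"]
        direction = ca[-1] - ca[0]
        nrm = np.linalg.norm(direction)
        direction = direction / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
        strands.append(Strand(
            sequence="".join(seq),
            atom_names=list(sub.atom_name),
            elements=list(sub.element),
            res_index=np.asarray(sub.res_id, dtype=int) - 1,
            coords=np.asarray(sub.coord, dtype=float),
            direction=direction,
        ))
    return strands


def read_trajectory(source):
    """Read a multi-MODEL PDB; returns (strands of model 1, frames array)."""
    pdb = PDBFile.read(source)
    stack = pdb.get_structure()
    arr = stack[0] if isinstance(stack, struc.AtomArrayStack) else stack
    frames = (stack.coord if isinstance(stack, struc.AtomArrayStack)
              else arr.coord[None])
    import io as _io
    buf = _io.StringIO()
    single = PDBFile()
    single.set_structure(arr)
    single.write(buf)
    buf.seek(0)
    strands = read_structure(buf)
    return strands, np.asarray(frames, dtype=float)
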