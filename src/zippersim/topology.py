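"""Backbone hydrogen-bond detection and parallel/antiparallel bookkeeping.

A backbone hydrogen bond is a donor amide (N-H) and an acceptor carbonyl
oxygen (O or terminal OXT) with H...O below a distance cutoff and the N-H...O
angle above an angle cutoff (defaults 2.5 A / 135 deg; exposed because
reasonable criteria vary and absolute counts are criterion-dependent).
Bonds are labelled by the pairing of the two strands involved: the strand
direction is the signed principal axis of the CA trace, and a pair is parallel
(P) when the directions' dot product exceeds +threshold, antiparallel (AP)
below -threshold, unclassified otherwise.

Time series of (N_P, N_AP) over a trajectory, with a centered moving average
(truncated windows at the edges), reproduce the convergence observable used to
monitor sheet formation in the aggregation runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

DEFAULT_DIST_CUTOFF = 2.5    # A, H...O
DEFAULT_ANGLE_CUTOFF = 135.0  # deg, N-H...O
DEFAULT_PAIR_THRESHOLD = 0.5


@dataclass
class HBond:
    donor_peptide: int
    donor_residue: int
    acceptor_peptide: int
    acceptor_residue: int
    distance: float          # H...O, A
    angle: float             # N-H...O, deg
    pairing: str             # 'P' | 'AP' | 'intra' | 'unclassified'


@dataclass
class HBondSeries:
    time_ns: np.ndarray
    n_p: np.ndarray
    n_ap: np.ndarray
    n_p_smooth: np.ndarray | None = None
    n_ap_smooth: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"time_ns": self.time_ns, "n_p": self.n_p, "n_ap": self.n_ap}
        if self.n_p_smooth is not None:
            data["n_p_smooth"] = self.n_p_smooth
            data["n_ap_smooth"] = self.n_ap_smooth
        return pd.DataFrame(data)


class FrameTopology:
    """Donor/acceptor index bookkeeping for a fixed set of strands.

    Built once per trajectory; every frame then only supplies coordinates.
    Raises if any non-proline residue lacks its amide hydrogen (reconstruct it
    with :func:`zippersim.strand.amide_hydrogen` before analysis).
    """

    def __init__(self, strands):
        self.strands = strands
        self.n_atoms = sum(s.n_atoms for s in strands)
        donors_n, donors_h, acceptors_o = [], [], []
        donor_pep, donor_res, acc_pep, acc_res = [], [], [], []
        ca_idx, ca_pep = [], []
        offset = 0
        for p, s in enumerate(strands):
            names = s.atom_names
            for res in range(s.n_residues):
                if s.sequence[res] == "P":
                    continue
                try:
                    h = s.atom_idx("H", res)
                except KeyError:
                    raise ValueError(
                        f"peptide {p} residue {res} lacks an amide hydrogen; "
                        "add amide hydrogens before hydrogen-bond analysis"
                    ) from None
                donors_n.append(offset + s.atom_idx("N", res))
                donors_h.append(offset + h)
                donor_pep.append(p)
                donor_res.append(res)
            for i, nm in enumerate(names):
                if nm in ("O", "OXT"):
                    acceptors_o.append(offset + i)
                    acc_pep.append(p)
                    acc_res.append(int(s.res_index[i]))
                elif nm == "CA":
                    ca_idx.append(offset + i)
                    ca_pep.append(p)
            offset += s.n_atoms
        self.donors_n = np.array(donors_n)
        self.donors_h = np.array(donors_h)
        self.acceptors_o = np.array(acceptors_o)
        self.donor_pep = np.array(donor_pep)
        self.donor_res = np.array(donor_res)
        self.acc_pep = np.array(acc_pep)
        self.acc_res = np.array(acc_res)
        self.ca_idx = np.array(ca_idx)
        self.ca_pep = np.array(ca_pep)
        self.n_peptides = len(strands)


def strand_direction(peptide_or_ca) -> np.ndarray:
    """Signed N->C principal axis of a peptide's CA trace (unit norm)."""
    ca = (peptide_or_ca.ca_coords()
          if hasattr(peptide_or_ca, "ca_coords") else np.asarray(peptide_or_ca))
    if len(ca) < 2:
        raise ValueError("need at least two CA atoms for a strand direction")
    dev = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(dev)
    axis = vt[0]
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def classify_pairing(dir_i, dir_j, threshold: float = DEFAULT_PAIR_THRESHOLD) -> str:
    """'P', 'AP' or 'unclassified' from two unit direction vectors."""
    dir_i = np.asarray(dir_i, dtype=float)
    dir_j = np.asarray(dir_j, dtype=float)
    for v in (dir_i, dir_j):
        if abs(np.linalg.norm(v) - 1.0) > 1e-6:
            raise ValueError("direction vectors must be unit-normalized")
    dot = float(np.dot(dir_i, dir_j))
    if dot >= threshold:
        return "P"
    if dot <= -threshold:
        return "AP"
    return "unclassified"


def detect_backbone_hbonds(topology: FrameTopology, coords,
                           dist_cutoff: float = DEFAULT_DIST_CUTOFF,
                           angle_cutoff: float = DEFAULT_ANGLE_CUTOFF,
                           pair_threshold: float = DEFAULT_PAIR_THRESHOLD):
    """All backbone donor/acceptor pairs meeting both criteria.

    Returns a deterministically ordered list of :class:`HBond` (sorted by
    donor peptide, donor residue, acceptor peptide, acceptor residue).
    Inter-strand bonds inherit the P/AP classification of their two strands.
    """
    coords = np.asarray(coords, dtype=float)
    h = coords[topology.donors_h]
    n = coords[topology.donors_n]
    o = coords[topology.acceptors_o]

    directions = _strand_directions(topology, coords)

    tree = cKDTree(o)
    out = []
    for di, neigh in enumerate(tree.query_ball_point(h, dist_cutoff)):
        for aj in neigh:
            dvec = o[aj] - h[di]
            dist = np.linalg.norm(dvec)
            if dist >= dist_cutoff or dist < 1e-6:
                continue
            nh = h[di] - n[di]
            cosang = np.dot(nh, dvec) / (np.linalg.norm(nh) * dist)
            angle = 180.0 - np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle <= angle_cutoff:
                continue
            dp, ap = int(topology.donor_pep[di]), int(topology.acc_pep[aj])
            if dp == ap:
                pairing = "intra"
            else:
                pairing = classify_pairing(directions[dp], directions[ap],
                                           pair_threshold)
            out.append(HBond(dp, int(topology.donor_res[di]), ap,
                             int(topology.acc_res[aj]), float(dist),
                             float(angle), pairing))
    out.sort(key=lambda b: (b.donor_peptide, b.donor_residue,
                            b.acceptor_peptide, b.acceptor_residue))
    return out


def _strand_directions(topology: FrameTopology, coords):
    dirs = []
    for p in range(topology.n_peptides):
        ca = coords[topology.ca_idx[topology.ca_pep == p]]
        dirs.append(strand_direction(ca))
    return dirs


def count_pairings(bonds):
    """(N_P, N_AP) over a bond list; unclassified and intra excluded."""
    n_p = sum(1 for b in bonds if b.pairing == "P")
    n_ap = sum(1 for b in bonds if b.pairing == "AP")
    return n_p, n_ap


def moving_average(series, window_ns: float, dt_ns: float = None,
                   time_ns=None) -> np.ndarray:
    """Centered boxcar average; edge windows are truncated (shorter means).

    ``window_ns`` is converted to an odd number of frames from the time grid
    spacing (``dt_ns`` or inferred from ``time_ns``).
    """
    series = np.asarray(series, dtype=float)
    if window_ns <= 0:
        raise ValueError("window must be positive")
    if dt_ns is None:
        if time_ns is None or len(time_ns) < 2:
            dt_ns = 1.0
        else:
            dt_ns = float(time_ns[1] - time_ns[0])
    half = max(int(round(window_ns / dt_ns)) // 2, 0)
    out = np.empty_like(series)
    n = len(series)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = series[lo:hi].mean()
    return out


def hbond_series(topology_or_strands, frames, times_ns=None,
                 dist_cutoff: float = DEFAULT_DIST_CUTOFF,
                 angle_cutoff: float = DEFAULT_ANGLE_CUTOFF,
                 smooth_window_ns: float = None) -> HBondSeries:
    """Per-frame (N_P, N_AP) counts over a trajectory.

    ``frames`` is (n_frames, n_atoms, 3); ``times_ns`` defaults to the frame
    index.  With ``smooth_window_ns`` set, centered moving averages are
    attached (same length as the raw series).
    """
    topology = (topology_or_strands if isinstance(topology_or_strands, FrameTopology)
                else FrameTopology(topology_or_strands))
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or len(frames) == 0:
        raise ValueError("need at least one frame of shape (n_atoms, 3)")
    if frames.shape[1] != topology.n_atoms:
        raise ValueError("frame atom count does not match topology")
    if times_ns is None:
        times_ns = np.arange(len(frames), dtype=float)
    times_ns = np.asarray(times_ns, dtype=float)

    n_p = np.zeros(len(frames), dtype=int)
    n_ap = np.zeros(len(frames), dtype=int)
    for k, frame in enumerate(frames):
        bonds = detect_backbone_hbonds(topology, frame, dist_cutoff, angle_cutoff)
        n_p[k], n_ap[k] = count_pairings(bonds)

    series = HBondSeries(times_ns, n_p, n_ap)
    if smooth_window_ns is not None:
        series.n_p_smooth = moving_average(n_p, smooth_window_ns, time_ns=times_ns)
        series.n_ap_smooth = moving_average(n_ap, smooth_window_ns, time_ns=times_ns)
    return series
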