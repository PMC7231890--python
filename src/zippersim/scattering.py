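"""Solution X-ray scattering from explicit coordinates.

Intensities are computed with the Debye equation,

    I(q) = sum_ij f_i'(q) f_j'(q) sin(q r_ij) / (q r_ij),

which is the exact orientational average over pairwise atomic distances.
Atomic form factors are 4-Gaussian (Cromer-Mann) tabulations; solvent
contrast follows the dummy-atom convention, subtracting from each atom a
Gaussian sphere of electron density rho_s and displaced volume V:

    f'(q) = f(q) - rho_s * V * exp(-q^2 * V^(2/3) / (4 pi)).

Hydrogens are kept explicit.  Two evaluation paths exist: a reference O(N^2)
double sum and a binned-distance path (pair-distance histogram per element
pair, evaluated at per-bin mean distances) used automatically for large
systems; the two agree to well under 0.5% at the default 0.01 A bin width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks as _scipy_find_peaks
from scipy.spatial.distance import cdist

WATER_DENSITY = 0.334  # electrons per A^3

# Cromer-Mann 4-Gaussian coefficients: element -> (a[4], b[4], c)
CROMER_MANN = {
    "H": ([0.489918, 0.262003, 0.196767, 0.049879],
          [20.6593, 7.74039, 49.5519, 2.20159], 0.001305),
    "C": ([2.31000, 1.02000, 1.58860, 0.865000],
          [20.8439, 10.2075, 0.568700, 51.6512], 0.215600),
    "N": ([12.2126, 3.13220, 2.01250, 1.16630],
          [0.005700, 9.89330, 28.9975, 0.582600], -11.529),
    "O": ([3.04850, 2.28680, 1.54630, 0.867000],
          [13.2771, 5.70110, 0.323900, 32.9089], 0.250800),
    "S": ([6.90530, 5.20340, 1.43790, 1.58630],
          [1.46790, 22.2151, 0.253600, 56.1720], 0.866900),
}

# Displaced solvent volumes (A^3), Fraser-MacRae-Suzuki convention.
DISPLACED_VOLUME = {"H": 5.15, "C": 16.44, "N": 2.49, "O": 9.13, "S": 19.86}


def vacuum_form_factor(element: str, q) -> np.ndarray:
    """Cromer-Mann f(q); q in A^-1 (s = q / 4 pi)."""
    if element not in CROMER_MANN:
        raise KeyError(f"no form factor tabulated for element {element!r}")
    a, b, c = CROMER_MANN[element]
    q = np.asarray(q, dtype=float)
    s2 = (q / (4.0 * np.pi)) ** 2
    f = np.full_like(q, c, dtype=float)
    for ai, bi in zip(a, b):
        f += ai * np.exp(-bi * s2)
    return f


def contrast_form_factor(element: str, q, solvent_density: float = WATER_DENSITY):
    """Contrast-corrected form factor f'(q); at solvent_density 0, f' = f."""
    if solvent_density < 0:
        raise ValueError("solvent density must be >= 0")
    f = vacuum_form_factor(element, q)
    if solvent_density == 0:
        return f
    v = DISPLACED_VOLUME[element]
    q = np.asarray(q, dtype=float)
    g = np.exp(-(q ** 2) * v ** (2.0 / 3.0) / (4.0 * np.pi))
    return f - solvent_density * v * g


@dataclass
class ScatteringProfile:
    """I(q) on a strictly increasing q grid (A^-1), arbitrary units."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)


@dataclass
class Peak:
    q_peak: float
    d_spacing: float
    height: float
    prominence: float


@dataclass
class PeakList:
    entries: list

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def dominant(self):
        """Highest-prominence peak (ties broken toward lower q)."""
        if not self.entries:
            return None
        return max(self.entries, key=lambda p: (p.prominence, -p.q_peak))


def _sinc(x):
    # sin(x)/x with sinc(0)=1
    return np.sinc(x / np.pi)


def debye_profile(elements, coords, q_grid, solvent_density: float = 0.0,
                  method: str = "auto", bin_width: float = 0.01,
                  ) -> ScatteringProfile:
    """Orientationally averaged Debye intensity for explicit atoms.

    Parameters
    ----------
    elements : sequence of element symbols (length N).
    coords : (N, 3) coordinates in Angstrom.
    q_grid : strictly increasing q values (A^-1).
    solvent_density : continuum solvent electron density (A^-3); 0 = vacuum.
    method : 'reference' (exact O(N^2) double sum), 'binned' (pair-distance
        histogram), or 'auto' (binned above 3000 atoms).
    """
    coords = np.asarray(coords, dtype=float)
    q = np.asarray(q_grid, dtype=float)
    if coords.ndim != 2 or len(coords) == 0:
        raise ValueError("need at least one atom")
    if solvent_density < 0:
        raise ValueError("solvent density must be >= 0")
    elements = list(elements)
    if method == "auto":
        method = "binned" if len(coords) > 3000 else "reference"

    uniq = sorted(set(elements))
    groups = {e: coords[np.array([el == e for el in elements])] for e in uniq}
    ff = {e: contrast_form_factor(e, q, solvent_density) for e in uniq}

    intensity = np.zeros_like(q)
    # self terms
    for e in uniq:
        intensity += len(groups[e]) * ff[e] ** 2

    if method == "reference":
        for ia, ea in enumerate(uniq):
            for eb in uniq[ia:]:
                a, b = groups[ea], groups[eb]
                if ea == eb:
                    if len(a) < 2:
                        continue
                    iu = np.triu_indices(len(a), k=1)
                    r = cdist(a, a)[iu]
                else:
                    r = cdist(a, b).ravel()
                s = np.zeros_like(q)
                chunk = max(1, int(2e7 / max(len(q), 1)))
                for lo in range(0, len(r), chunk):
                    s += _sinc(np.outer(q, r[lo:lo + chunk])).sum(axis=1)
                intensity += 2.0 * ff[ea] * ff[eb] * s
    elif method == "binned":
        rmax = float(np.linalg.norm(coords.max(0) - coords.min(0))) + 1.0
        nbins = int(np.ceil(rmax / bin_width))
        edges = np.linspace(0.0, nbins * bin_width, nbins + 1)
        for ia, ea in enumerate(uniq):
            for eb in uniq[ia:]:
                a, b = groups[ea], groups[eb]
                counts = np.zeros(nbins)
                rsum = np.zeros(nbins)
                chunk = max(1, int(2e6 / max(len(b), 1)))
                for lo in range(0, len(a), chunk):
                    sub = a[lo:lo + chunk]
                    d = cdist(sub, b)
                    if ea == eb:
                        # drop self and double-counted pairs within the block
                        gi = np.arange(lo, lo + len(sub))
                        mask = gi[:, None] < np.arange(len(b))[None, :]
                        d = d[mask]
                    else:
                        d = d.ravel()
                    c, _ = np.histogram(d, bins=edges)
                    rs, _ = np.histogram(d, bins=edges, weights=d)
                    counts += c
                    rsum += rs
                nz = counts > 0
                rbar = rsum[nz] / counts[nz]
                s = _sinc(np.outer(q, rbar)) @ counts[nz]
                intensity += 2.0 * ff[ea] * ff[eb] * s
    else:
        raise ValueError(f"unknown method {method!r}")

    return ScatteringProfile(q, intensity, metadata={
        "solvent_density": solvent_density, "method": method,
        "n_atoms": len(coords)})


def block_profile(block, q_grid, solvent_density: float = 0.0,
                  method: str = "auto") -> ScatteringProfile:
    """Debye profile of a nanocrystal block."""
    return debye_profile(block.elements(), block.coords(), q_grid,
                         solvent_density, method=method)


def guinier_rg(profile: ScatteringProfile, q_fit_max_times_rg: float = 1.3):
    """Guinier fit: ln I = ln I0 - (Rg^2 / 3) q^2 on the admitted window.

    The window is found iteratively: fit on all points with q * Rg below the
    bound, re-estimate Rg, repeat to a fixed point.  Returns (Rg, I0).
    """
    q, i = profile.q, profile.intensity
    mask = i > 0
    if mask.sum() < 3:
        raise ValueError("too few positive-intensity points for a Guinier fit")
    q, i = q[mask], i[mask]
    window = np.ones(len(q), dtype=bool)
    rg = None
    for _ in range(100):
        if window.sum() < 3:
            raise ValueError("Guinier window shrank below 3 points")
        slope, intercept = np.polyfit(q[window] ** 2, np.log(i[window]), 1)
        rg_new = float(np.sqrt(max(-3.0 * slope, 0.0)))
        if rg is not None and abs(rg_new - rg) < 1e-9:
            break
        rg = rg_new
        if rg == 0.0:
            break
        window = q * rg <= q_fit_max_times_rg
    i0 = float(np.exp(intercept))
    return rg, i0


def find_profile_peaks(profile: ScatteringProfile, q_range=None,
                       prominence_frac: float = 0.01,
                       smooth_window: int = 1) -> PeakList:
    """Local maxima above a relative prominence threshold, with d = 2 pi / q.

    ``prominence_frac`` is relative to the intensity span inside the range;
    ``smooth_window`` (odd, in grid points) applies a centered boxcar before
    peak picking.  An empty q range yields an empty list.
    """
    q, i = profile.q, profile.intensity
    if q_range is not None:
        lo, hi = q_range
        m = (q >= lo) & (q <= hi)
        q, i = q[m], i[m]
    if len(q) < 3:
        return PeakList([])
    if smooth_window > 1:
        k = smooth_window | 1
        pad = k // 2
        kernel = np.ones(k) / k
        i = np.convolve(np.pad(i, pad, mode="edge"), kernel, mode="valid")
    span = float(i.max() - i.min())
    if span == 0:
        return PeakList([])
    idx, props = _scipy_find_peaks(i, prominence=prominence_frac * span)
    entries = [
        Peak(q_peak=float(q[k]), d_spacing=float(2.0 * np.pi / q[k]),
             height=float(i[k]), prominence=float(p))
        for k, p in zip(idx, props["prominences"])
    ]
    entries.sort(key=lambda p: p.q_peak)
    return PeakList(entries)


def compare_profiles(calculated: ScatteringProfile,
                     experimental: ScatteringProfile) -> float:
    """Reduced chi-square-style discrepancy after analytic scale fitting."""
    lo = max(calculated.q.min(), experimental.q.min())
    hi = min(calculated.q.max(), experimental.q.max())
    if lo >= hi:
        raise ValueError("profiles have disjoint q support")
    m = (experimental.q >= lo) & (experimental.q <= hi)
    qe = experimental.q[m]
    ie = experimental.intensity[m]
    se = (experimental.sigma[m] if experimental.sigma is not None
          else np.ones_like(ie))
    ic = np.interp(qe, calculated.q, calculated.intensity)
    w = 1.0 / se ** 2
    scale = float(np.sum(w * ic * ie) / np.sum(w * ic ** 2))
    chi2 = float(np.mean(((scale * ic - ie) / se) ** 2))
    return chi2


def write_dat(profile: ScatteringProfile, destination) -> None:
    """3-column whitespace q / I / sigma text (SASBDB .dat convention)."""
    sigma = (profile.sigma if profile.sigma is not None
             else np.zeros_like(profile.q))
    df = pd.DataFrame({"q": profile.q, "I": profile.intensity, "sigma": sigma})
    df.to_csv(destination, sep=" ", index=False, header=False,
              float_format="%.8g")


def read_dat(source) -> ScatteringProfile:
    df = pd.read_csv(source, sep=r"\s+", comment="#", header=None)
    if df.shape[1] < 2:
        raise ValueError("expected at least two columns (q, I)")
    sigma = df.iloc[:, 2].to_numpy() if df.shape[1] >= 3 else None
    if sigma is not None and np.all(sigma == 0):
        sigma = None
    return ScatteringProfile(df.iloc[:, 0].to_numpy(),
                             df.iloc[:, 1].to_numpy(), sigma)
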