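"""Hamiltonian replica exchange over the coarse-grained energy backend.

Replicas share one system and differ only in the strength lambda of a
harmonic restraint driving each peptide toward a rigid extended reference
conformation; the reference's position and orientation are re-fitted
(proper-rotation Kabsch superposition) onto the peptide at every evaluation,

    U(x, lambda) = 1/2 * lambda * sum_atoms |x - x_ref_fitted|^2,

so the restraint is invariant under rigid motion of the peptide and biases
only its internal conformation.  The schedule is quadratic,
lambda_i = lambda_max * (i / (M-1))^2 with lambda_0 = 0 exactly: replica 0
samples the unbiased ensemble (discontinuously, through exchanges).

Exchanges between adjacent replicas are attempted at a fixed time interval on
alternating even/odd pairs with the Metropolis rule
w = min(1, exp(-beta * dU)),
dU_ij = [U(l_i, x_j) + U(l_j, x_i)] - [U(l_j, x_j) + U(l_i, x_i)].

Dynamics is overdamped Langevin on all atoms (the molecular engine behind the
original study is replaced by this toy integrator); peptides are confined by
a half-harmonic spherical wall on their centroids (default radius 50 A, the
64-peptide setup corresponding to an effective concentration of 0.2 M).
An optional extra harmonic on the CA z-spread flattens strands into the xy
plane; it is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .energy import KB, KCAL_COULOMB, HB_R0, SOLV_RANGE

AVOGADRO = 6.02214076e23


def effective_concentration(n_molecules: int, radius_A: float) -> float:
    """Molar concentration of n molecules in a sphere of given radius (A)."""
    if n_molecules < 0 or radius_A <= 0:
        raise ValueError("need n >= 0 and radius > 0")
    volume_litre = (4.0 / 3.0) * np.pi * (radius_A * 1e-9) ** 3  # dm^3
    return n_molecules / (AVOGADRO * volume_litre)


@dataclass
class ReplicaSchedule:
    """Quadratic restraint-strength ladder."""

    n_replicas: int = 64
    lambda_max: float = 0.032   # restraint units (kcal mol^-1 A^-2)
    exchange_interval_ps: float = 5.0
    temperature: float = 300.0

    def __post_init__(self):
        if self.n_replicas < 1:
            raise ValueError("need at least one replica")
        if self.lambda_max < 0:
            raise ValueError("lambda_max must be >= 0")

    @property
    def lambdas(self) -> np.ndarray:
        m = self.n_replicas
        if m == 1:
            return np.array([0.0])
        i = np.arange(m)
        return self.lambda_max * (i / (m - 1)) ** 2

    @property
    def beta(self) -> float:
        return 1.0 / (KB * self.temperature)


def superimpose(reference, target):
    """Optimal proper-rotation superposition of reference onto target.

    Returns (rotation matrix, translation, rmsd) such that
    ``reference @ R.T + t`` best fits ``target`` in the least-squares sense;
    the rotation determinant is +1 even for mirror-image targets.
    """
    ref = np.asarray(reference, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if ref.shape != tgt.shape:
        raise ValueError("atom count mismatch between reference and target")
    if len(ref) < 3:
        raise ValueError("need at least 3 atoms for superposition")
    ref_c = ref - ref.mean(axis=0)
    tgt_c = tgt - tgt.mean(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) reference geometry")
    rot, _ = Rotation.align_vectors(tgt_c, ref_c)
    r = rot.as_matrix()
    fitted = ref_c @ r.T + tgt.mean(axis=0)
    rmsd = float(np.sqrt(((fitted - tgt) ** 2).sum(axis=1).mean()))
    t = tgt.mean(axis=0) - ref.mean(axis=0) @ r.T
    return r, t, rmsd


def fit_reference(reference, target):
    """Reference coordinates after superposition onto the target."""
    r, t, _ = superimpose(reference, target)
    return np.asarray(reference) @ r.T + t


def restraint_energy(peptide_coords, reference_coords, lam: float):
    """1/2 lambda * sum |x - fitted reference|^2 (zero iff lam=0 or congruent)."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0:
        return 0.0
    fitted = fit_reference(reference_coords, peptide_coords)
    disp = np.asarray(peptide_coords) - fitted
    return float(0.5 * lam * (disp ** 2).sum())


def _restraint_sum(coords, slices, reference):
    """Sum over peptides of the squared residual after superposition."""
    s = 0.0
    for sl in slices:
        fitted = fit_reference(reference, coords[sl])
        s += float(((coords[sl] - fitted) ** 2).sum())
    return s


def exchange_delta(lam_i, lam_j, coords_i, coords_j, slices, reference):
    """dU_ij of swapping configurations between restraint strengths i and j.

    Antisymmetric under (i <-> j); exactly zero when lam_i == lam_j.
    """
    s_i = _restraint_sum(coords_i, slices, reference)
    s_j = _restraint_sum(coords_j, slices, reference)
    return 0.5 * (lam_i - lam_j) * (s_j - s_i)


def metropolis_accept(delta_u: float, beta: float, random_draw: float) -> bool:
    """Deterministic accept for dU <= 0, else accept iff draw < exp(-beta dU)."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if delta_u <= 0:
        return True
    return random_draw < np.exp(-beta * delta_u)


@dataclass
class HremdResult:
    frames: np.ndarray          # replica-0 (unbiased) trajectory
    times_ps: np.ndarray
    exchange_log: pd.DataFrame  # attempt, i, j, delta_u, accepted
    final_coords: list          # per replica
    schedule: ReplicaSchedule


def _batch_fit(ref_centered, stacks):
    """Kabsch fit of one centered reference onto K coordinate sets at once.

    ``stacks`` is (K, n, 3); returns fitted reference copies, same shape.
    """
    mu = stacks.mean(axis=1, keepdims=True)
    xc = stacks - mu
    h = np.einsum("ni,knj->kij", ref_centered, xc)
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("kji,klj->kil", vt, u))
    d = np.ones((len(stacks), 3))
    d[:, 2] = np.sign(det)
    # R_k = V_k diag(1, 1, det) U_k^T
    rot = np.einsum("kji,kj,kmj->kim", vt, d, u)
    fitted = np.einsum("ni,kji->knj", ref_centered, rot) + mu
    return fitted


class _ReplicatedPairs:
    """System pair/index arrays tiled over replicas with per-replica offsets."""

    def __init__(self, system, m):
        n = system.n_atoms
        off = (np.arange(m) * n)[:, None]

        def tile_idx(idx):
            return (idx[None, :] + off).ravel()

        def tile_pairs(idx_a, idx_b, key):
            pa, pb = system._inter_pairs(idx_a, idx_b, key)
            a = (idx_a[pa][None, :] + off).ravel()
            b = (idx_b[pb][None, :] + off).ravel()
            return a, b

        self.qq_a, self.qq_b = tile_pairs(system.charges_idx,
                                          system.charges_idx, "qq")
        pa, pb = system._inter_pairs(system.charges_idx, system.charges_idx, "qq")
        self.qq = np.tile(system.charges_val[pa] * system.charges_val[pb], m)
        self.ho_a, self.ho_b = tile_pairs(system.hb_h, system.hb_o, "ho")
        pa, pb = system._inter_pairs(system.cb_idx, system.cb_idx, "cb")
        self.cb_a = (system.cb_idx[pa][None, :] + off).ravel()
        self.cb_b = (system.cb_idx[pb][None, :] + off).ravel()
        self.cb_sig = np.tile(0.5 * (system.cb_sigma[pa] + system.cb_sigma[pb]), m)
        self.cb_eps = np.tile(np.sqrt(system.cb_eps[pa] * system.cb_eps[pb]), m)
        self.cb_hyd = np.tile(system.cb_hyd[pa] * system.cb_hyd[pb], m)
        self.en_i = tile_idx(system.en_i)
        self.en_j = tile_idx(system.en_j)
        self.en_r0 = np.tile(system.en_r0, m)


def run_hremd(system, schedule: ReplicaSchedule, reference, model,
              n_steps: int, seed: int, dt_ps: float = 0.01,
              friction: float = 0.5, confinement_radius: float = 50.0,
              k_confine: float = 10.0, xy_restraint: float = 0.0,
              stride: int = 100, initial_coords=None,
              max_displacement: float = 0.25) -> HremdResult:
    """Run replica-exchange overdamped Langevin dynamics.

    ``system`` is a :class:`~zippersim.energy.PeptideSystem` of identical
    peptides; ``reference`` the rigid extended reference coordinates (one
    peptide).  All replicas are integrated in one vectorized sweep per step.
    The replica-0 stream is returned as the unbiased trajectory.  Fully
    reproducible: the same seed yields bit-identical trajectories and logs.
    """
    rng = np.random.default_rng(seed)
    lambdas = schedule.lambdas
    m = schedule.n_replicas
    kt = KB * schedule.temperature
    beta = schedule.beta
    reference = np.asarray(reference, dtype=float)
    ref_c = reference - reference.mean(axis=0)

    n_atoms = system.n_atoms
    n_pep = system.n_peptides
    atoms_per = system.slices[0].stop - system.slices[0].start
    if any(sl.stop - sl.start != atoms_per for sl in system.slices):
        raise ValueError("replica engine requires identical peptides")
    if len(reference) != atoms_per:
        raise ValueError("reference does not match the system's peptides")

    x0 = (np.asarray(initial_coords, dtype=float).copy()
          if initial_coords is not None else system.coords0())
    x = np.tile(x0, (m, 1, 1)).reshape(m * n_atoms, 3)  # flat over replicas
    first = system.strands[0]
    ca_local = np.array([i for i, nm in enumerate(first.atom_names)
                         if nm == "CA"])
    pairs = _ReplicatedPairs(system, m)
    lam_atom = np.repeat(lambdas, n_atoms)[:, None]

    ke = model.w_elec * KCAL_COULOMB / model.epsilon_r
    lam_d = model.debye_length
    eps_hb = model.w_hbond
    kb_en = model.w_bonded

    noise_scale = np.sqrt(2.0 * kt * dt_ps / friction)
    mob = dt_ps / friction
    steps_per_exchange = max(int(round(schedule.exchange_interval_ps / dt_ps)), 1)

    frames, times, log = [], [], []
    attempt = 0
    parity = 0

    all_a = np.concatenate([pairs.qq_a, pairs.ho_a, pairs.cb_a, pairs.en_i])
    all_b = np.concatenate([pairs.qq_b, pairs.ho_b, pairs.cb_b, pairs.en_j])
    n_qq, n_ho = len(pairs.qq_a), len(pairs.ho_a)
    n_cb, n_en = len(pairs.cb_a), len(pairs.en_i)
    sl_qq = slice(0, n_qq)
    sl_ho = slice(n_qq, n_qq + n_ho)
    sl_cb = slice(n_qq + n_ho, n_qq + n_ho + n_cb)
    sl_en = slice(n_qq + n_ho + n_cb, n_qq + n_ho + n_cb + n_en)
    n_flat = m * n_atoms

    def forces_and_restraint(xf):
        dvec = xf[all_b] - xf[all_a]
        r = np.maximum(np.sqrt(np.einsum("ij,ij->i", dvec, dvec)), 1e-9)
        dedr = np.empty_like(r)
        # screened Coulomb between terminal charges
        rq = r[sl_qq]
        e = ke * pairs.qq * np.exp(-rq / lam_d) / rq
        dedr[sl_qq] = -e * (1.0 / rq + 1.0 / lam_d)
        # hydrogen bond 10-12
        xr = HB_R0 / r[sl_ho]
        x10 = xr ** 10
        dedr[sl_ho] = eps_hb * 60.0 * (x10 - x10 * xr * xr) / r[sl_ho]
        # side-chain LJ + hydrophobic Gaussian
        rc = r[sl_cb]
        xr = pairs.cb_sig / rc
        x6 = xr ** 6
        dedr[sl_cb] = (model.w_pack * pairs.cb_eps * 12.0 * (x6 - x6 * x6) / rc
                       + model.w_solv * pairs.cb_hyd
                       * np.exp(-(rc / SOLV_RANGE) ** 2)
                       * 2.0 * rc / SOLV_RANGE ** 2)
        # intra-peptide elastic network
        dedr[sl_en] = kb_en * (r[sl_en] - pairs.en_r0)
        fv = (dedr / r)[:, None] * dvec
        f = np.empty_like(xf)
        for c in range(3):
            f[:, c] = (np.bincount(all_a, weights=fv[:, c], minlength=n_flat)
                       - np.bincount(all_b, weights=fv[:, c], minlength=n_flat))
        # conformational restraint (batched Kabsch over replicas x peptides)
        stacks = xf.reshape(m * n_pep, atoms_per, 3)
        fitted = _batch_fit(ref_c, stacks)
        disp = (stacks - fitted).reshape(m * n_atoms, 3)
        f -= lam_atom * disp
        s_pep = ((stacks - fitted) ** 2).sum(axis=(1, 2)).reshape(m, n_pep)
        restraint_sums = s_pep.sum(axis=1)  # per replica
        # spherical confinement on peptide centroids
        cent = stacks.mean(axis=1)
        rc = np.linalg.norm(cent, axis=1)
        over = rc > confinement_radius
        if np.any(over):
            push = (k_confine * (rc[over] - confinement_radius) / rc[over]
                    / atoms_per)[:, None] * cent[over]
            fr = f.reshape(m * n_pep, atoms_per, 3)
            fr[over] -= push[:, None, :]
        if xy_restraint > 0:
            # flatten each strand's CA trace into an xy plane (orientation
            # restraint only; carbonyls must stay free to point along z)
            z = stacks[:, ca_local, 2]
            fz = xy_restraint * (z - z.mean(axis=1, keepdims=True))
            fr = f.reshape(m * n_pep, atoms_per, 3)
            fr[:, ca_local, 2] -= fz
        return f, restraint_sums

    restraint_sums = None
    for step in range(n_steps):
        f, restraint_sums = forces_and_restraint(x)
        drift = mob * f
        # cap the deterministic displacement so steep repulsive walls cannot
        # destabilize the overdamped integrator
        norm = np.linalg.norm(drift, axis=1, keepdims=True)
        drift *= np.minimum(1.0, max_displacement / np.maximum(norm, 1e-12))
        x += drift + noise_scale * rng.standard_normal(x.shape)
        if (step + 1) % steps_per_exchange == 0 and m > 1:
            # re-fit on the post-move coordinates before evaluating dU
            stacks = x.reshape(m * n_pep, atoms_per, 3)
            fitted = _batch_fit(ref_c, stacks)
            restraint_sums = ((stacks - fitted) ** 2).sum(axis=(1, 2)).reshape(
                m, n_pep).sum(axis=1)
            xr = x.reshape(m, n_atoms, 3)
            for i in range(parity, m - 1, 2):
                j = i + 1
                du = 0.5 * (lambdas[i] - lambdas[j]) * (
                    restraint_sums[j] - restraint_sums[i])
                accepted = metropolis_accept(du, beta, rng.random())
                if accepted:
                    tmp = xr[i].copy()
                    xr[i] = xr[j]
                    xr[j] = tmp
                    restraint_sums[[i, j]] = restraint_sums[[j, i]]
                log.append((attempt, i, j, float(du), bool(accepted)))
            attempt += 1
            parity ^= 1
        if step % stride == 0:
            frames.append(x[:n_atoms].copy())
            times.append(step * dt_ps)

    frames.append(x[:n_atoms].copy())
    times.append(n_steps * dt_ps)
    log_df = pd.DataFrame(log, columns=["attempt", "i", "j", "delta_u",
                                        "accepted"])
    final = [x.reshape(m, n_atoms, 3)[r].copy() for r in range(m)]
    return HremdResult(np.asarray(frames), np.asarray(times), log_df,
                       final, schedule)


def mixing_diagnostics(exchange_log: pd.DataFrame):
    """Per-pair acceptance rates and configuration round-trip count.

    A round trip is one configuration label travelling from replica 0 to
    replica M-1 and back.  Pairs with no attempts are reported as NaN.
    """
    if len(exchange_log) == 0:
        raise ValueError("empty exchange log")
    m = int(max(exchange_log["i"].max(), exchange_log["j"].max())) + 1
    rates = {}
    for i in range(m - 1):
        sub = exchange_log[(exchange_log["i"] == i) & (exchange_log["j"] == i + 1)]
        rates[(i, i + 1)] = float(sub["accepted"].mean()) if len(sub) else float("nan")

    # replay label walk
    labels = list(range(m))
    state = ["bottom"] * m   # per label: last endpoint visited
    round_trips = 0
    for _, row in exchange_log.sort_values(["attempt", "i"]).iterrows():
        if row["accepted"]:
            i, j = int(row["i"]), int(row["j"])
            labels[i], labels[j] = labels[j], labels[i]
        for pos in (0, m - 1):
            lab = labels[pos]
            if pos == m - 1 and state[lab] == "bottom":
                state[lab] = "top"
            elif pos == 0 and state[lab] == "top":
                state[lab] = "bottom"
                round_trips += 1
    return {"acceptance_rates": rates, "round_trips": round_trips}
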