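"""Coarse-grained Calpha structure-based (Go-type) sampling and RMSD
clustering.

The potential is the classic Calpha Go model: the global energy minimum is
a chosen reference conformation. Harmonic bonds and angles hold the chain
geometry at native values, a periodic dihedral term biases backbone
torsions toward native, native contacts (taken from a shadow contact map)
are 12-10 Lennard-Jones wells with minima at the native distances, and all
other long-range pairs feel a truncated excluded-volume repulsion.

Units are reduced: the contact well depth epsilon defines the energy unit,
Angstrom the length unit, bead masses are 1. Sampling uses a BAOAB Langevin
integrator; with friction 0 it degenerates to plain velocity Verlet (useful
for energy-conservation checks). All randomness is seeded explicitly.

Trajectories are clustered with k-medoids over pairwise Kabsch RMSD —
medoids are actual frames, so cluster centroids are physically realisable
conformations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .interface_analysis import ContactMap
from .structures_io import ResidueKey, Structure

__all__ = [
    "GoPotential",
    "Trajectory",
    "CentroidEnsemble",
    "IntegrationError",
    "build_go_potential",
    "sample",
    "kabsch_rmsd",
    "pairwise_rmsd_matrix",
    "cluster_by_rmsd",
]


class IntegrationError(RuntimeError):
    """Raised when the integrator diverges (time step too large)."""


# --------------------------------------------------------------------------
# Potential
# --------------------------------------------------------------------------

@dataclass
class GoPotential:
    """Calpha Go potential anchored at a reference conformation.

    Energy terms (reduced units, epsilon = 1 is the contact well depth):

    - bonds:      sum  (k_bond/2) (r - r0)^2          consecutive CA pairs
    - angles:     sum  (k_angle/2) (theta - theta0)^2
    - dihedrals:  sum  k_dih [ (1 - cos(phi - phi0))
                               + 1/2 (1 - cos 3(phi - phi0)) ]
    - contacts:   sum  eps [ 5 (r0/r)^12 - 6 (r0/r)^10 ]   (minimum -eps at r0)
    - repulsion:  sum  eps_ev [ (sigma/r)^12 - 1 ]  for r < sigma, else 0

    Repulsion applies to residue pairs separated by at least 4 positions in
    sequence (or interchain) that are not native contacts; it is truncated
    and shifted to vanish at sigma, so a reference conformation whose
    non-contact pairs all exceed sigma has exactly the contact energy
    -eps * n_contacts.
    """

    reference: np.ndarray  # (n, 3) reference CA coordinates
    residue_keys: list[ResidueKey]
    bonds: np.ndarray  # (nb, 2) int
    bond_r0: np.ndarray
    angles: np.ndarray  # (na, 3) int
    angle_theta0: np.ndarray
    dihedrals: np.ndarray  # (nd, 4) int
    dihedral_phi0: np.ndarray
    contacts: np.ndarray  # (nc, 2) int
    contact_r0: np.ndarray
    ev_pairs: np.ndarray  # (ne, 2) int
    k_bond: float = 100.0
    k_angle: float = 20.0
    k_dihedral: float = 1.0
    epsilon: float = 1.0
    epsilon_ev: float = 1.0
    sigma_ev: float = 3.8

    @property
    def n_beads(self) -> int:
        return len(self.reference)

    # ---- energy ----------------------------------------------------------
    def energy(self, coords: np.ndarray) -> float:
        return self.energy_and_forces(coords, want_forces=False)[0]

    def energy_and_forces(
        self, coords: np.ndarray, want_forces: bool = True
    ) -> tuple[float, np.ndarray]:
        x = np.asarray(coords, dtype=float)
        if x.shape != (self.n_beads, 3):
            raise ValueError(f"expected coordinates of shape {(self.n_beads, 3)}")
        energy = 0.0
        forces = np.zeros_like(x)

        # bonds
        if len(self.bonds):
            rij = x[self.bonds[:, 1]] - x[self.bonds[:, 0]]
            r = np.linalg.norm(rij, axis=1)
            dr = r - self.bond_r0
            energy += 0.5 * self.k_bond * float(dr @ dr)
            if want_forces:
                f = (self.k_bond * dr / r)[:, None] * rij  # dU/d(x_j)
                np.subtract.at(forces, self.bonds[:, 1], f)
                np.add.at(forces, self.bonds[:, 0], f)

        # angles
        if len(self.angles):
            i, j, k = self.angles.T
            u = x[i] - x[j]
            v = x[k] - x[j]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            cos_t = np.clip((u * v).sum(1) / (nu * nv), -1.0, 1.0)
            theta = np.arccos(cos_t)
            dt = theta - self.angle_theta0
            energy += 0.5 * self.k_angle * float(dt @ dt)
            if want_forces:
                sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, 1e-12))
                uh = u / nu[:, None]
                vh = v / nv[:, None]
                dth_di = (cos_t[:, None] * uh - vh) / (nu * sin_t)[:, None]
                dth_dk = (cos_t[:, None] * vh - uh) / (nv * sin_t)[:, None]
                coef = (self.k_angle * dt)[:, None]
                np.subtract.at(forces, i, coef * dth_di)
                np.subtract.at(forces, k, coef * dth_dk)
                np.add.at(forces, j, coef * (dth_di + dth_dk))

        # dihedrals
        if len(self.dihedrals):
            p1, p2, p3, p4 = (x[self.dihedrals[:, c]] for c in range(4))
            b1 = p2 - p1
            b2 = p3 - p2
            b3 = p4 - p3
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            nb2 = np.linalg.norm(b2, axis=1)
            cos_p = (n1 * n2).sum(1)
            sin_p = (np.cross(n1, n2) * (b2 / nb2[:, None])).sum(1)
            phi = np.arctan2(sin_p, cos_p)
            dphi = phi - self.dihedral_phi0
            energy += self.k_dihedral * float(
                ((1.0 - np.cos(dphi)) + 0.5 * (1.0 - np.cos(3.0 * dphi))).sum()
            )
            if want_forces:
                dU = self.k_dihedral * (np.sin(dphi) + 1.5 * np.sin(3.0 * dphi))
                # collinear guard: near-degenerate dihedrals get tiny |n|
                n1_sq = np.maximum((n1 * n1).sum(1), 1e-6)
                n2_sq = np.maximum((n2 * n2).sum(1), 1e-6)
                dphi_d1 = -(nb2 / n1_sq)[:, None] * n1
                dphi_d4 = (nb2 / n2_sq)[:, None] * n2
                b1b2 = (b1 * b2).sum(1) / nb2**2
                b3b2 = (b3 * b2).sum(1) / nb2**2
                dphi_d2 = (
                    -(1.0 + b1b2)[:, None] * dphi_d1 + b3b2[:, None] * dphi_d4
                )
                dphi_d3 = (
                    b1b2[:, None] * dphi_d1 - (1.0 + b3b2)[:, None] * dphi_d4
                )
                for col, grad in zip(
                    range(4), (dphi_d1, dphi_d2, dphi_d3, dphi_d4)
                ):
                    np.subtract.at(
                        forces, self.dihedrals[:, col], dU[:, None] * grad
                    )

        # native contacts: 12-10 Lennard-Jones
        if len(self.contacts):
            rij = x[self.contacts[:, 1]] - x[self.contacts[:, 0]]
            r = np.linalg.norm(rij, axis=1)
            q = self.contact_r0 / r
            energy += self.epsilon * float((5.0 * q**12 - 6.0 * q**10).sum())
            if want_forces:
                dU_dr = self.epsilon * (-60.0 * q**12 + 60.0 * q**10) / r
                f = (dU_dr / r)[:, None] * rij
                np.subtract.at(forces, self.contacts[:, 1], f)
                np.add.at(forces, self.contacts[:, 0], f)

        # excluded volume (truncated & shifted at sigma)
        if len(self.ev_pairs):
            rij = x[self.ev_pairs[:, 1]] - x[self.ev_pairs[:, 0]]
            r = np.linalg.norm(rij, axis=1)
            inside = r < self.sigma_ev
            if inside.any():
                rr = r[inside]
                s = self.sigma_ev / rr
                energy += self.epsilon_ev * float((s**12 - 1.0).sum())
                if want_forces:
                    dU_dr = -12.0 * self.epsilon_ev * s**12 / rr
                    f = (dU_dr / rr)[:, None] * rij[inside]
                    pi = self.ev_pairs[inside]
                    np.subtract.at(forces, pi[:, 1], f)
                    np.add.at(forces, pi[:, 0], f)

        return float(energy), forces

    def native_contact_fraction(self, coords: np.ndarray, ratio: float = 1.2) -> float:
        """Fraction of native contacts formed (distance < ratio * r0)."""
        if not len(self.contacts):
            return 1.0
        x = np.asarray(coords, dtype=float)
        r = np.linalg.norm(x[self.contacts[:, 1]] - x[self.contacts[:, 0]], axis=1)
        return float((r < ratio * self.contact_r0).mean())


def _dihedral_angles(x: np.ndarray, quads: np.ndarray) -> np.ndarray:
    p1, p2, p3, p4 = (x[quads[:, c]] for c in range(4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2h = b2 / np.linalg.norm(b2, axis=1)[:, None]
    return np.arctan2((np.cross(n1, n2) * b2h).sum(1), (n1 * n2).sum(1))


def build_go_potential(
    reference: Structure,
    contacts: ContactMap | None = None,
    k_bond: float = 100.0,
    k_angle: float = 20.0,
    k_dihedral: float = 1.0,
    epsilon: float = 1.0,
    sigma_ev: float = 3.8,
) -> GoPotential:
    """Build a Calpha Go potential from a reference structure.

    Bonds, angles and dihedrals connect consecutive CA beads within each
    chain at their native values. Each residue pair of ``contacts`` (an
    interchain shadow contact map, or any residue-pair set with sequence
    separation >= 4) becomes a 12-10 well at the native CA-CA distance.
    Remaining pairs with sequence separation >= 4, or interchain, repel.
    """
    keys: list[ResidueKey] = []
    coords: list[tuple[float, float, float]] = []
    for chain in reference.chains:
        for key in reference.residues(chain):
            ca = [a for a in reference.residue_atoms(key) if a.atom_name == "CA"]
            if not ca:
                raise ValueError(
                    f"residue {key} of structure {reference.id!r} has no CA atom"
                )
            keys.append(key)
            coords.append(ca[0].coords)
    x = np.array(coords, dtype=float)
    index = {k: i for i, k in enumerate(keys)}
    chain_of = np.array([reference.chains.index(k.chain_id) for k in keys])

    bonds, angles, dihedrals = [], [], []
    n = len(keys)
    for i in range(n - 1):
        if chain_of[i] == chain_of[i + 1]:
            bonds.append((i, i + 1))
    for i in range(n - 2):
        if chain_of[i] == chain_of[i + 2]:
            angles.append((i, i + 1, i + 2))
    for i in range(n - 3):
        if chain_of[i] == chain_of[i + 3]:
            dihedrals.append((i, i + 1, i + 2, i + 3))
    bonds = np.array(bonds, dtype=int).reshape(-1, 2)
    angles = np.array(angles, dtype=int).reshape(-1, 3)
    dihedrals = np.array(dihedrals, dtype=int).reshape(-1, 4)

    contact_pairs: list[tuple[int, int]] = []
    if contacts is not None:
        for ra, rb in sorted(contacts.pairs):
            i, j = index[ra], index[rb]
            same_chain = chain_of[i] == chain_of[j]
            if same_chain and abs(i - j) < 4:
                raise ValueError(
                    f"contact {ra}-{rb} has sequence separation < 4; "
                    "not usable as a Go contact"
                )
            contact_pairs.append((min(i, j), max(i, j)))
    contact_arr = np.array(sorted(set(contact_pairs)), dtype=int).reshape(-1, 2)

    contact_set = {tuple(p) for p in contact_arr}
    ev = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if (chain_of[i] != chain_of[j] or j - i >= 4) and (i, j) not in contact_set
    ]
    ev_arr = np.array(ev, dtype=int).reshape(-1, 2)

    def _dist(pairs: np.ndarray) -> np.ndarray:
        if not len(pairs):
            return np.zeros(0)
        return np.linalg.norm(x[pairs[:, 1]] - x[pairs[:, 0]], axis=1)

    def _angle(triples: np.ndarray) -> np.ndarray:
        if not len(triples):
            return np.zeros(0)
        u = x[triples[:, 0]] - x[triples[:, 1]]
        v = x[triples[:, 2]] - x[triples[:, 1]]
        c = (u * v).sum(1) / (np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
        return np.arccos(np.clip(c, -1.0, 1.0))

    return GoPotential(
        reference=x,
        residue_keys=keys,
        bonds=bonds,
        bond_r0=_dist(bonds),
        angles=angles,
        angle_theta0=_angle(angles),
        dihedrals=dihedrals,
        dihedral_phi0=(
            _dihedral_angles(x, dihedrals) if len(dihedrals) else np.zeros(0)
        ),
        contacts=contact_arr,
        contact_r0=_dist(contact_arr),
        ev_pairs=ev_arr,
        k_bond=k_bond,
        k_angle=k_angle,
        k_dihedral=k_dihedral,
        epsilon=epsilon,
        sigma_ev=sigma_ev,
    )


# --------------------------------------------------------------------------
# Sampling
# --------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Frames of CA coordinates with per-frame energies."""

    frames: np.ndarray  # (n_frames, n_beads, 3)
    energies: np.ndarray  # potential energy per frame
    kinetic_energies: np.ndarray
    kT_sim: float
    dt: float
    seed: int
    stride: int = 1
    basin_labels: np.ndarray | None = None  # used by synthetic trajectories

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def total_energies(self) -> np.ndarray:
        return self.energies + self.kinetic_energies

    def save(self, pdb_path: str | Path, csv_path: str | Path,
             template: Structure | None = None) -> None:
        """Persist as a multi-MODEL CA-trace PDB plus an energy CSV."""
        lines = []
        for m, frame in enumerate(self.frames, start=1):
            lines.append(f"MODEL     {m:4d}")
            for i, (xc, yc, zc) in enumerate(frame):
                lines.append(
                    f"ATOM  {i + 1:5d}  CA  GLY A{i + 1:4d}    "
                    f"{xc:8.3f}{yc:8.3f}{zc:8.3f}  1.00  0.00           C"
                )
            lines.append("ENDMDL")
        lines.append("END")
        Path(pdb_path).write_text("\n".join(lines) + "\n")
        rows = ["frame_index,energy"]
        rows += [f"{i},{e!r}" for i, e in enumerate(self.energies)]
        Path(csv_path).write_text("\n".join(rows) + "\n")


def sample(
    potential: GoPotential,
    n_steps: int,
    kT_sim: float,
    dt: float = 0.002,
    seed: int = 0,
    friction: float = 1.0,
    stride: int = 10,
    start_coords: np.ndarray | None = None,
    initial_velocity_kT: float | None = None,
) -> Trajectory:
    """Langevin (BAOAB) dynamics on the Go potential.

    Starts from the reference coordinates (or ``start_coords``); frames are
    saved every ``stride`` steps. The same seed reproduces the trajectory
    bitwise. ``friction = 0`` disables the thermostat, giving plain velocity
    Verlet; in that case draw initial velocities with
    ``initial_velocity_kT`` (default 0 keeps the system at rest).
    Divergence (energy above 1e6) raises :class:`IntegrationError`.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if kT_sim < 0:
        raise ValueError("kT_sim must be non-negative")
    rng = np.random.default_rng(seed)
    x = np.array(
        potential.reference if start_coords is None else start_coords, dtype=float
    )
    v = np.zeros_like(x)
    if initial_velocity_kT:
        v = rng.normal(0.0, np.sqrt(initial_velocity_kT), size=x.shape)
    if friction > 0:
        c1 = np.exp(-friction * dt)
        c2 = np.sqrt(kT_sim * (1.0 - c1 * c1))
    else:
        c1, c2 = 1.0, 0.0

    energy, forces = potential.energy_and_forces(x)
    frames, energies, kinetics = [], [], []

    def _record() -> None:
        frames.append(x.copy())
        energies.append(energy)
        kinetics.append(0.5 * float((v * v).sum()))

    for step in range(1, n_steps + 1):
        v += 0.5 * dt * forces
        x += 0.5 * dt * v
        if friction > 0:
            v = c1 * v + c2 * rng.standard_normal(x.shape)
        x += 0.5 * dt * v
        energy, forces = potential.energy_and_forces(x)
        if not np.isfinite(energy) or energy > 1e6:
            raise IntegrationError(
                f"energy diverged at step {step} (E = {energy:.3g}); "
                "use a smaller dt"
            )
        v += 0.5 * dt * forces
        if step % stride == 0:
            _record()
    if not frames:
        _record()
    return Trajectory(
        frames=np.array(frames),
        energies=np.array(energies),
        kinetic_energies=np.array(kinetics),
        kT_sim=kT_sim,
        dt=dt,
        seed=seed,
        stride=stride,
    )


# --------------------------------------------------------------------------
# RMSD and clustering
# --------------------------------------------------------------------------

def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimal RMSD between two point sets over rigid superposition.

    Uses the Kabsch SVD solution with the determinant sign correction so
    only proper rotations are considered.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise ValueError("need at least 3 points for superposition")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    cov = a.T @ b
    u, _s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    # residuals evaluated explicitly: avoids the cancellation of the
    # trace-based closed form near rmsd = 0
    diff = a @ rot - b
    return float(np.sqrt((diff * diff).sum() / len(a)))


def pairwise_rmsd_matrix(frames: np.ndarray) -> np.ndarray:
    """All-against-all Kabsch RMSD, shape (n, n)."""
    frames = np.asarray(frames, dtype=float)
    n = len(frames)
    centered = frames - frames.mean(axis=1, keepdims=True)
    norms = (centered**2).sum(axis=(1, 2))
    npts = frames.shape[1]
    mat = np.zeros((n, n))
    for i in range(n):
        covs = np.einsum("ak,jal->jkl", centered[i], centered[i + 1 :])
        if not len(covs):
            continue
        _u, s, _vt = np.linalg.svd(covs)
        dets = np.linalg.det(covs)
        ssum = s.sum(axis=1) - 2.0 * np.where(dets < 0, s[:, -1], 0.0)
        msd = (norms[i] + norms[i + 1 :] - 2.0 * ssum) / npts
        mat[i, i + 1 :] = np.sqrt(np.maximum(msd, 0.0))
    return mat + mat.T


@dataclass
class CentroidEnsemble:
    """k-medoids clustering of a trajectory under Kabsch RMSD."""

    centroid_indices: list[int]
    centroids: np.ndarray  # (k, n_beads, 3) — actual frames
    assignments: np.ndarray  # frame -> cluster index
    member_counts: list[int]

    @property
    def k(self) -> int:
        return len(self.centroid_indices)


def cluster_by_rmsd(
    trajectory: Trajectory | np.ndarray, k: int = 1000
) -> CentroidEnsemble:
    """Deterministic k-medoids over pairwise Kabsch RMSD.

    Medoids are seeded by farthest-point traversal from frame 0 and refined
    by alternating assignment / medoid-update sweeps until stable. All ties
    break toward the lowest frame index, so the result is deterministic.
    """
    frames = trajectory.frames if isinstance(trajectory, Trajectory) else trajectory
    n = len(frames)
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    dist = pairwise_rmsd_matrix(frames)

    # farthest-point seeding from frame 0
    medoids = [0]
    while len(medoids) < k:
        dmin = dist[:, medoids].min(axis=1)
        cand = int(dmin.argmax())  # argmax takes lowest index on ties
        if cand in medoids:  # all remaining frames duplicate a medoid
            cand = min(i for i in range(n) if i not in medoids)
        medoids.append(cand)

    medoids = sorted(medoids)
    for _ in range(100):
        assign = np.argmin(dist[:, medoids], axis=1)  # ties -> lowest medoid pos
        new_medoids = []
        for c in range(k):
            members = np.flatnonzero(assign == c)
            if not len(members):
                new_medoids.append(medoids[c])
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids.append(int(members[within.argmin()]))
        new_medoids = sorted(new_medoids)
        if new_medoids == medoids:
            break
        medoids = new_medoids
    assign = np.argmin(dist[:, medoids], axis=1)
    counts = [int((assign == c).sum()) for c in range(k)]
    return CentroidEnsemble(
        centroid_indices=medoids,
        centroids=frames[medoids].copy(),
        assignments=assign,
        member_counts=counts,
    )
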