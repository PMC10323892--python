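"""Synthetic fixtures with known ground truth for every pipeline stage.

Real cyclin-CDK complexes are crystallographic inputs the pipeline accepts
from the user; these generators produce desk-scale stand-ins whose answers
are known by construction: two-chain complexes with a planted interface,
perturbed conformational ensembles, two-basin trajectories for clustering,
and multiple sequence alignments with planted conserved columns. Every
generator is a pure function of its parameters and seed.

The toy complex places two idealized Calpha/Cbeta traces (3.8 Angstrom
consecutive spacing) so that a contiguous window of residues on each chain
faces the partner at contact range — side-chain beads of planted residues
point into the interface and are strongly buried on complexation — while
the flanking residues bend steeply away from the interface plane. Planted
residues end up far above the 20% burial threshold and all others at
essentially zero burial, so interface recovery is exact by construction.
Interchain pairs of non-planted residues sit roughly 12 Angstrom or more
apart; a residue directly adjacent to the planted window is closer than
that (chain connectivity caps the step at one CA-CA spacing per residue)
but still outside SASA-occlusion and contact range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .sbm_sampler import Trajectory, kabsch_rmsd
from .structures_io import AlignmentMap, AtomRecord, ResidueKey, Structure
from .interface_analysis import InterfaceSet

__all__ = [
    "SyntheticComplexSpec",
    "SyntheticTruth",
    "make_toy_complex",
    "make_ensemble",
    "make_msa_set",
    "make_two_basin_trajectory",
    "alignment_to_fasta",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA3 = {  # one-letter -> three-letter, for emitted PDB records
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


@dataclass
class SyntheticComplexSpec:
    """Parameters of a planted-interface toy complex."""

    seed: int
    residues_per_chain: int = 20
    interface_size: int = 6
    gap_distance: float = 4.8  # CA-CA separation across the interface (A)
    noise_sigma: float = 0.05  # coordinate jitter (A)

    def __post_init__(self) -> None:
        if self.interface_size > self.residues_per_chain:
            raise ValueError(
                "interface_size cannot exceed residues_per_chain "
                f"({self.interface_size} > {self.residues_per_chain})"
            )
        if self.interface_size < 1 or self.residues_per_chain < 4:
            raise ValueError("need >= 4 residues and >= 1 interface residue per chain")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators."""

    interface_residues: dict[str, list[ResidueKey]] = field(default_factory=dict)
    contact_pairs: list[tuple[ResidueKey, ResidueKey]] = field(default_factory=list)
    conserved_columns: dict[str, list[int]] = field(default_factory=dict)
    basin_labels: np.ndarray | None = None
    parameters: dict = field(default_factory=dict)


def _chain_trace(
    n_res: int, window: range, y_interface: float, side: float,
    spacing: float = 3.8, turn_deg: float = 80.0, zigzag: float = 0.6,
) -> np.ndarray:
    """Helix-like CA trace: a zig-zag along x inside the window, bending
    away from the interface plane outside it.

    The out-of-plane zig-zag (amplitude ``zigzag`` in z, alternating per
    residue) keeps consecutive virtual bond/torsion angles away from the
    collinear degeneracy while preserving the consecutive CA spacing."""
    coords = np.zeros((n_res, 3))
    theta = np.deg2rad(turn_deg)
    planar = np.sqrt(spacing**2 - (2.0 * zigzag) ** 2)
    step_in = np.array([planar, 0.0, 0.0])
    # both bends move away from the interface plane (sign of `side` is the
    # chain's side of the plane): +x after the window, -x before it
    step_fwd = np.array([planar * np.cos(theta), side * planar * np.sin(theta), 0.0])
    step_back = np.array([-planar * np.cos(theta), side * planar * np.sin(theta), 0.0])
    w0, w1 = window.start, window.stop - 1
    coords[w0] = [planar * w0, y_interface, 0.0]
    for i in range(w0 + 1, n_res):
        coords[i] = coords[i - 1] + (step_in if i <= w1 else step_fwd)
    for i in range(w0 - 1, -1, -1):
        coords[i] = coords[i + 1] + (-step_in if i >= w0 else step_back)
    coords[:, 2] = zigzag * (-1.0) ** np.arange(n_res)
    return coords


def make_toy_complex(spec: SyntheticComplexSpec) -> tuple[Structure, SyntheticTruth]:
    """Two-chain CA/CB complex with a planted interface window.

    Chains A and B run antiparallel to the interface normal: a centred
    window of ``interface_size`` residues per chain sits at
    ``gap_distance`` (CA-CA) across the interface with CB beads pointing
    inward; all other residues head away at a steep angle, so only the
    planted residues are buried on complexation. Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.residues_per_chain
    size = spec.interface_size
    w0 = (n - size) // 2
    window = range(w0, w0 + size)
    half = spec.gap_distance / 2.0
    cb_len = 1.5

    atoms: list[AtomRecord] = []
    truth = SyntheticTruth(parameters={"spec": spec})
    serial = 0
    for chain_id, side in (("A", -1.0), ("B", +1.0)):
        ca = _chain_trace(n, window, side * half, side)
        ca = ca + rng.normal(0.0, spec.noise_sigma, size=ca.shape)
        truth.interface_residues[chain_id] = [
            ResidueKey(chain_id, i + 1) for i in window
        ]
        for i in range(n):
            resname = _AA3[_AA[int(rng.integers(len(_AA)))]]
            serial += 1
            atoms.append(
                AtomRecord(
                    serial=serial, atom_name="CA", element="C",
                    residue_name=resname, chain_id=chain_id, residue_seq=i + 1,
                    insertion_code="", coords=tuple(ca[i]), vdw_radius=1.70,
                )
            )
            # CB: into the interface for planted residues, out of plane else
            offset = (
                np.array([0.0, -side * cb_len, 0.0])
                if i in window
                else np.array([0.0, 0.0, cb_len])
            )
            cb = ca[i] + offset + rng.normal(0.0, spec.noise_sigma, size=3)
            serial += 1
            atoms.append(
                AtomRecord(
                    serial=serial, atom_name="CB", element="C",
                    residue_name=resname, chain_id=chain_id, residue_seq=i + 1,
                    insertion_code="", coords=tuple(cb), vdw_radius=1.70,
                )
            )
    truth.contact_pairs = [
        (ResidueKey("A", i + 1), ResidueKey("B", i + 1)) for i in window
    ]
    structure = Structure(f"toy_complex_seed{spec.seed}", atoms)
    return structure, truth


def make_ensemble(
    base: Structure, n: int, jitter_sigma: float, seed: int
) -> list[Structure]:
    """``n`` perturbed copies of a structure (member 0 is unperturbed).

    Coordinate noise is zero-mean isotropic Gaussian with width
    ``jitter_sigma`` Angstrom per coordinate.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if jitter_sigma < 0:
        raise ValueError("jitter_sigma must be non-negative")
    rng = np.random.default_rng(seed)
    coords = base.coords()
    members = [base.with_coords(coords, id=f"{base.id}_m0")]
    for m in range(1, n):
        noise = rng.normal(0.0, jitter_sigma, size=coords.shape) if jitter_sigma else 0.0
        members.append(base.with_coords(coords + noise, id=f"{base.id}_m{m}"))
    return members


# --------------------------------------------------------------------------
# Synthetic alignments with planted conserved interface columns
# --------------------------------------------------------------------------

def _build_alignment(
    sequences: dict[str, str]
) -> AlignmentMap:
    length = len(next(iter(sequences.values())))
    amap = AlignmentMap(length=length)
    for sid, seq in sequences.items():
        mapping: dict[int, int] = {}
        idx = 0
        for col, ch in enumerate(seq, start=1):
            if ch != "-":
                idx += 1
                mapping[idx] = col
        amap.maps[sid] = mapping
    return amap


def alignment_to_fasta(sequences: dict[str, str]) -> str:
    return "".join(f">{sid}\n{seq}\n" for sid, seq in sequences.items())


def make_msa_set(
    n_complexes: int,
    length: int,
    conserved_columns: Sequence[int],
    seed: int,
    n_decoys: int = 4,
    gap_fraction: float = 0.1,
) -> tuple[dict[str, dict[str, str]], dict[str, AlignmentMap], list[InterfaceSet], SyntheticTruth]:
    """Cyclin- and kinase-side alignments with planted conserved columns.

    For every complex, residues at the planted columns are interface
    residues; each decoy column is an interface column in all complexes but
    one, so the across-complex intersection recovers exactly the planted
    set. Gaps are inserted at random free (non-interface) columns.

    Returns (sequences per role, alignment maps per role, one
    InterfaceSet per complex with cyclin chain "A" / kinase chain "B",
    truth). Sequence ids follow the ``<complex_id>_<role>`` convention.
    """
    conserved = sorted(set(conserved_columns))
    if conserved and (conserved[0] < 1 or conserved[-1] > length):
        raise ValueError("conserved columns must lie in 1..length")
    rng = np.random.default_rng(seed)
    complex_ids = [f"cx{i}" for i in range(n_complexes)]
    free = [c for c in range(1, length + 1) if c not in conserved]
    decoys = list(rng.choice(free, size=min(n_decoys, len(free)), replace=False)) if n_complexes > 1 else []
    decoys = [int(d) for d in decoys]

    sequences: dict[str, dict[str, str]] = {"cyclin": {}, "kinase": {}}
    interface_cols: dict[str, dict[str, set[int]]] = {}
    for ci, cid in enumerate(complex_ids):
        interface_cols[cid] = {}
        for role in ("cyclin", "kinase"):
            cols = set(conserved)
            # each decoy is skipped by exactly one complex
            cols |= {d for k, d in enumerate(decoys) if k % n_complexes != ci}
            gap_candidates = [c for c in range(1, length + 1) if c not in cols]
            n_gaps = int(gap_fraction * len(gap_candidates))
            gaps = set(
                int(g)
                for g in rng.choice(gap_candidates, size=n_gaps, replace=False)
            ) if n_gaps else set()
            seq = "".join(
                "-" if c in gaps else _AA[int(rng.integers(len(_AA)))]
                for c in range(1, length + 1)
            )
            sequences[role][f"{cid}_{role}"] = seq
            interface_cols[cid][role] = cols

    maps = {role: _build_alignment(sequences[role]) for role in ("cyclin", "kinase")}

    interfaces: list[InterfaceSet] = []
    for cid in complex_ids:
        fractions: dict[ResidueKey, float] = {}
        for role, chain in (("cyclin", "A"), ("kinase", "B")):
            sid = f"{cid}_{role}"
            for col in interface_cols[cid][role]:
                idx = maps[role].column_to_index(sid, col)
                assert idx is not None  # interface columns are never gapped
                fractions[ResidueKey(chain, idx)] = 0.5
        interfaces.append(
            InterfaceSet(
                complex_id=cid, chain_pair=("A", "B"),
                burial_fractions=fractions, threshold=0.2,
            )
        )
    truth = SyntheticTruth(
        conserved_columns={"cyclin": conserved, "kinase": conserved},
        parameters={"decoys": decoys, "complex_ids": complex_ids},
    )
    return sequences, maps, interfaces, truth


# --------------------------------------------------------------------------
# Two-basin trajectory
# --------------------------------------------------------------------------

def make_two_basin_trajectory(
    n_frames: int,
    separation: float,
    spread: float,
    seed: int,
    n_beads: int = 12,
) -> tuple[Trajectory, SyntheticTruth]:
    """Frames drawn alternately around two conformations a known RMSD apart.

    Basin A is a smooth random CA trace; basin B is a deformed copy whose
    Kabsch RMSD from A is rescaled to ``separation``. Per-frame noise has
    per-atom RMS displacement ``spread`` (sigma = spread / sqrt(3) per
    coordinate). ``separation`` must exceed 4x ``spread`` or the basins are
    not separable and the construction is rejected.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames (one per basin)")
    if separation <= 4.0 * spread:
        raise ValueError(
            f"separation ({separation}) must exceed 4 x spread ({4 * spread}); "
            "basins would overlap"
        )
    rng = np.random.default_rng(seed)
    # smooth random chain: unit steps with small random turns
    direction = np.array([1.0, 0.0, 0.0])
    basin_a = [np.zeros(3)]
    for _ in range(n_beads - 1):
        direction = direction + 0.3 * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        basin_a.append(basin_a[-1] + 3.8 * direction)
    basin_a = np.array(basin_a)

    disp = rng.normal(size=basin_a.shape)
    basin_b = basin_a + disp
    for _ in range(8):  # rescale so the superposed RMSD hits the target
        r = kabsch_rmsd(basin_a, basin_b)
        if r == 0:
            disp = rng.normal(size=basin_a.shape)
            basin_b = basin_a + disp
            continue
        disp *= separation / r
        basin_b = basin_a + disp
    sigma = spread / np.sqrt(3.0)
    labels = np.arange(n_frames) % 2
    frames = np.array(
        [
            (basin_a if lab == 0 else basin_b)
            + rng.normal(0.0, sigma, size=basin_a.shape)
            for lab in labels
        ]
    )
    traj = Trajectory(
        frames=frames,
        energies=np.zeros(n_frames),
        kinetic_energies=np.zeros(n_frames),
        kT_sim=0.0,
        dt=0.0,
        seed=seed,
        stride=1,
        basin_labels=labels,
    )
    truth = SyntheticTruth(
        basin_labels=labels,
        parameters={"separation": separation, "spread": spread},
    )
    return traj, truth
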