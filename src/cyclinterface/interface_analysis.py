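"""Interface detection, interchain contact maps, conservation mapping and
distance restraints for two-chain protein complexes.

An interface residue is one that loses at least a threshold fraction
(default 20%) of its isolated-chain solvent-accessible surface area (SASA)
upon complex formation. SASA is computed with the Shrake-Rupley rolling
probe method on a deterministic Fibonacci sphere lattice, so results are
bit-reproducible for a fixed point count.

Interchain contacts use the shadow-map criterion: an atom pair within the
distance cutoff counts as a contact unless a third atom, inflated to the
shadowing radius, occludes the straight line between the two atoms.

Interface positions and contacts from several complexes are compared
through multiple sequence alignments (consumed as aligned FASTA); positions
present in every complex are "conserved" and can be turned into CA-CA
distance restraints for docking. The curated CA-CA restraint list for the
CCNI-CDK6 complex (UniProt numbering, Q14094 / Q00534) ships with the
package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structures_io import AlignmentMap, ResidueKey, Structure

__all__ = [
    "SASAProfile",
    "InterfaceSet",
    "ContactMap",
    "ConservedPositions",
    "DistanceRestraint",
    "RestraintSet",
    "compute_sasa",
    "detect_interface",
    "shadow_contact_map",
    "conserved_interface_positions",
    "conserved_contacts",
    "build_restraints",
    "load_ccni_cdk6_restraints",
    "CCNI_CDK6_RESTRAINT_PAIRS",
]


# --------------------------------------------------------------------------
# SASA
# --------------------------------------------------------------------------

@dataclass
class SASAProfile:
    """Per-residue solvent accessible surface area (Angstrom^2)."""

    areas: dict[ResidueKey, float]
    probe_radius: float
    n_points: int

    def __getitem__(self, key: ResidueKey) -> float:
        return self.areas[key]


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice, shape (n, 3)."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + 5.0**0.5) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def compute_sasa(
    structure: Structure, probe_radius: float = 1.4, n_points: int = 960
) -> SASAProfile:
    """Shrake-Rupley SASA, summed per residue.

    Each atom is expanded by the probe radius and covered with ``n_points``
    lattice points; a point is exposed if it lies outside every neighbouring
    expanded sphere. The atom's area is the exposed fraction of its expanded
    sphere; residue SASA is the sum over member atoms.
    """
    if n_points < 12:
        raise ValueError("n_points must be at least 12 for a usable quadrature")
    if probe_radius < 0:
        raise ValueError("probe_radius must be non-negative")
    coords = structure.coords()
    radii = structure.radii() + probe_radius
    n_atoms = len(coords)
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    areas: dict[ResidueKey, float] = {k: 0.0 for k in structure.residues()}
    for i in range(n_atoms):
        neigh = [
            j
            for j in tree.query_ball_point(coords[i], radii[i] + max_r)
            if j != i and np.linalg.norm(coords[j] - coords[i]) < radii[i] + radii[j]
        ]
        pts = coords[i] + radii[i] * sphere
        if neigh:
            nc = coords[neigh]
            nr2 = radii[neigh] ** 2
            d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            exposed = ~(d2 < nr2[None, :]).any(axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        areas[structure.atoms[i].residue_key] += frac * 4.0 * np.pi * radii[i] ** 2
    return SASAProfile(areas=areas, probe_radius=probe_radius, n_points=n_points)


# --------------------------------------------------------------------------
# Interface detection
# --------------------------------------------------------------------------

@dataclass
class InterfaceSet:
    """Residues buried past the threshold when two chains associate."""

    complex_id: str
    chain_pair: tuple[str, str]
    burial_fractions: dict[ResidueKey, float]
    threshold: float

    def residues(self, chain_id: str | None = None) -> list[ResidueKey]:
        keys = sorted(self.burial_fractions)
        if chain_id is None:
            return keys
        return [k for k in keys if k.chain_id == chain_id]

    def to_tsv(self, path: str | Path) -> None:
        lines = [
            f"# complex={self.complex_id} chains={self.chain_pair[0]}{self.chain_pair[1]} "
            f"threshold={self.threshold}",
            "chain_id\tresidue_seq\tinsertion_code\tburial_fraction",
        ]
        for k in self.residues():
            lines.append(
                f"{k.chain_id}\t{k.residue_seq}\t{k.insertion_code or '.'}\t"
                f"{self.burial_fractions[k]:.6f}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def detect_interface(
    complex_structure: Structure,
    chain_a: str,
    chain_b: str,
    threshold: float = 0.20,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> InterfaceSet:
    """Interface residues of a two-chain complex by SASA burial.

    For each residue of either chain, burial = (unbound - bound) / unbound
    SASA, with the unbound value computed on the residue's chain in
    isolation and the bound value on the pair. Residues with zero unbound
    SASA are excluded; burial is clamped to [0, 1]; residues at or above
    ``threshold`` are returned.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    for c in (chain_a, chain_b):
        if c not in complex_structure.chains:
            raise KeyError(f"chain {c!r} not in structure {complex_structure.id!r}")
    bound = compute_sasa(
        complex_structure.select_chains([chain_a, chain_b]), probe_radius, n_points
    )
    fractions: dict[ResidueKey, float] = {}
    for c in (chain_a, chain_b):
        unbound = compute_sasa(
            complex_structure.select_chains([c]), probe_radius, n_points
        )
        for key, area_unbound in unbound.areas.items():
            if area_unbound <= 0.0:
                continue
            burial = (area_unbound - bound.areas[key]) / area_unbound
            burial = min(1.0, max(0.0, burial))
            if burial >= threshold:
                fractions[key] = burial
    return InterfaceSet(
        complex_id=complex_structure.id,
        chain_pair=(chain_a, chain_b),
        burial_fractions=fractions,
        threshold=threshold,
    )


# --------------------------------------------------------------------------
# Shadow contact map
# --------------------------------------------------------------------------

@dataclass
class ContactMap:
    """Deduplicated interchain residue-residue contacts."""

    complex_id: str
    pairs: set[tuple[ResidueKey, ResidueKey]]
    cutoff: float
    shadow_radius: float

    def to_tsv(self, path: str | Path) -> None:
        lines = [
            f"# complex={self.complex_id} cutoff={self.cutoff} "
            f"shadow_radius={self.shadow_radius}",
            "chain_a\tres_a\tchain_b\tres_b",
        ]
        for a, b in sorted(self.pairs):
            lines.append(f"{a.chain_id}\t{a.residue_seq}\t{b.chain_id}\t{b.residue_seq}")
        Path(path).write_text("\n".join(lines) + "\n")


def _segment_distances(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance of each point to the closed segment a-b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    closest = a + t[:, None] * ab
    return np.linalg.norm(points - closest, axis=1)


def shadow_contact_map(
    complex_structure: Structure,
    cutoff: float = 6.0,
    shadow_radius: float = 1.0,
    chain_pair: tuple[str, str] | None = None,
) -> ContactMap:
    """Interchain residue contacts under the shadow criterion.

    Atom pairs across the two chains within ``cutoff`` are candidates; a
    candidate is discarded when any third atom, inflated to
    ``shadow_radius``, intersects the straight segment between the two
    atoms. ``shadow_radius = 0`` disables shadowing (cutoff-only map). A
    residue pair is a contact when at least one kept atom pair joins it.
    """
    if chain_pair is None:
        if len(complex_structure.chains) != 2:
            raise ValueError(
                f"structure {complex_structure.id!r} has "
                f"{len(complex_structure.chains)} chains; pass chain_pair to "
                "select the two chains to analyse"
            )
        chain_pair = tuple(complex_structure.chains)  # type: ignore[assignment]
    sub = complex_structure.select_chains(list(chain_pair))
    coords = sub.coords()
    chain_of = np.array([a.chain_id for a in sub.atoms])
    idx_a = np.flatnonzero(chain_of == chain_pair[0])
    idx_b = np.flatnonzero(chain_of == chain_pair[1])
    tree_b = cKDTree(coords[idx_b])
    lo, hi = sorted(chain_pair)
    pairs: set[tuple[ResidueKey, ResidueKey]] = set()
    for i in idx_a:
        for jb in tree_b.query_ball_point(coords[i], cutoff):
            j = idx_b[jb]
            if shadow_radius > 0.0:
                d = _segment_distances(coords, coords[i], coords[j])
                d[i] = np.inf
                d[j] = np.inf
                if (d < shadow_radius).any():
                    continue
            ra, rb = sub.atoms[i].residue_key, sub.atoms[j].residue_key
            if ra.chain_id != lo:
                ra, rb = rb, ra
            pairs.add((ra, rb))
    return ContactMap(
        complex_id=complex_structure.id,
        pairs=pairs,
        cutoff=cutoff,
        shadow_radius=shadow_radius,
    )


# --------------------------------------------------------------------------
# Conservation across complexes
# --------------------------------------------------------------------------

@dataclass
class ConservedPositions:
    """Alignment columns that are interface positions in every complex."""

    cyclin_columns: set[int]
    kinase_columns: set[int]
    #: per complex id, the back-mapped (cyclin residues, kinase residues)
    per_complex: dict[str, tuple[list[int], list[int]]] = field(default_factory=dict)


def _default_seq_id(complex_id: str, role: str) -> str:
    return f"{complex_id}_{role}"


def _interface_columns(
    interface: InterfaceSet,
    chain_id: str,
    alignment: AlignmentMap,
    seq_id: str,
) -> set[int]:
    if seq_id not in alignment.maps:
        raise KeyError(
            f"complex {interface.complex_id!r}: sequence {seq_id!r} missing "
            "from alignment"
        )
    cols: set[int] = set()
    for key in interface.residues(chain_id):
        cols.add(alignment.index_to_column(seq_id, key.residue_seq))
    return cols


def conserved_interface_positions(
    interfaces: Sequence[InterfaceSet],
    alignment_cyclin: AlignmentMap,
    alignment_kinase: AlignmentMap,
    cyclin_seq_ids: Mapping[str, str] | None = None,
    kinase_seq_ids: Mapping[str, str] | None = None,
) -> ConservedPositions:
    """Alignment columns whose residue is an interface residue in every
    complex, per partner role (cyclin side = first chain of each pair,
    kinase side = second chain).

    Residue numbers are interpreted as the 1-based ungapped sequence index
    of the corresponding alignment sequence; renumber with an offset table
    first if the structures use a different scheme. Sequence ids default to
    ``<complex_id>_cyclin`` / ``<complex_id>_kinase``.
    """
    if not interfaces:
        raise ValueError("need at least one interface set")
    cyc_sets: list[set[int]] = []
    kin_sets: list[set[int]] = []
    result = ConservedPositions(set(), set())
    for iface in interfaces:
        cyc_id = (cyclin_seq_ids or {}).get(
            iface.complex_id, _default_seq_id(iface.complex_id, "cyclin")
        )
        kin_id = (kinase_seq_ids or {}).get(
            iface.complex_id, _default_seq_id(iface.complex_id, "kinase")
        )
        cyc_sets.append(
            _interface_columns(iface, iface.chain_pair[0], alignment_cyclin, cyc_id)
        )
        kin_sets.append(
            _interface_columns(iface, iface.chain_pair[1], alignment_kinase, kin_id)
        )
    result.cyclin_columns = set.intersection(*cyc_sets)
    result.kinase_columns = set.intersection(*kin_sets)
    for iface in interfaces:
        cyc_id = (cyclin_seq_ids or {}).get(
            iface.complex_id, _default_seq_id(iface.complex_id, "cyclin")
        )
        kin_id = (kinase_seq_ids or {}).get(
            iface.complex_id, _default_seq_id(iface.complex_id, "kinase")
        )
        cyc_res = sorted(
            alignment_cyclin.column_to_index(cyc_id, c)
            for c in result.cyclin_columns
        )
        kin_res = sorted(
            alignment_kinase.column_to_index(kin_id, c)
            for c in result.kinase_columns
        )
        result.per_complex[iface.complex_id] = (cyc_res, kin_res)
    return result


def conserved_contacts(
    contact_maps: Sequence[ContactMap],
    alignment_cyclin: AlignmentMap,
    alignment_kinase: AlignmentMap,
    chain_pairs: Mapping[str, tuple[str, str]] | None = None,
    cyclin_seq_ids: Mapping[str, str] | None = None,
    kinase_seq_ids: Mapping[str, str] | None = None,
) -> set[tuple[int, int]]:
    """Column pairs (cyclin column, kinase column) contacted in every complex.

    ``chain_pairs`` names the (cyclin chain, kinase chain) of each complex;
    by default the lexicographically smaller chain of each contact is taken
    as the cyclin side, matching :class:`ContactMap` ordering.
    """
    if not contact_maps:
        raise ValueError("need at least one contact map")
    per_complex: list[set[tuple[int, int]]] = []
    for cmap in contact_maps:
        cyc_id = (cyclin_seq_ids or {}).get(
            cmap.complex_id, _default_seq_id(cmap.complex_id, "cyclin")
        )
        kin_id = (kinase_seq_ids or {}).get(
            cmap.complex_id, _default_seq_id(cmap.complex_id, "kinase")
        )
        if cyc_id not in alignment_cyclin.maps:
            raise KeyError(
                f"complex {cmap.complex_id!r}: sequence {cyc_id!r} missing "
                "from cyclin alignment"
            )
        if kin_id not in alignment_kinase.maps:
            raise KeyError(
                f"complex {cmap.complex_id!r}: sequence {kin_id!r} missing "
                "from kinase alignment"
            )
        cyc_chain = (chain_pairs or {}).get(cmap.complex_id, (None, None))[0]
        cols: set[tuple[int, int]] = set()
        for a, b in cmap.pairs:
            if cyc_chain is not None and a.chain_id != cyc_chain:
                a, b = b, a
            cols.add(
                (
                    alignment_cyclin.index_to_column(cyc_id, a.residue_seq),
                    alignment_kinase.index_to_column(kin_id, b.residue_seq),
                )
            )
        per_complex.append(cols)
    return set.intersection(*per_complex)


# --------------------------------------------------------------------------
# Distance restraints
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceRestraint:
    """One CA-CA interchain distance restraint in UniProt-style numbering."""

    res_a: int  # cyclin-side position
    res_b: int  # kinase-side position
    atom_name: str = "CA"
    target_distance: float | None = None
    tolerance: float = 1.0

    def __post_init__(self) -> None:
        if self.res_a <= 0 or self.res_b <= 0:
            raise ValueError("restraint positions must be positive")
        if self.atom_name != "CA":
            raise ValueError("restraints are defined between alpha carbons only")


@dataclass
class RestraintSet:
    restraints: list[DistanceRestraint]

    def __len__(self) -> int:
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)

    def pairs(self) -> set[tuple[int, int]]:
        return {(r.res_a, r.res_b) for r in self.restraints}

    def to_tsv(self, path: str | Path) -> None:
        lines = ["res_a\tatom_a\tres_b\tatom_b\ttarget_distance\ttolerance"]
        for r in self.restraints:
            target = "NA" if r.target_distance is None else f"{r.target_distance:.3f}"
            lines.append(
                f"{r.res_a}\t{r.atom_name}\t{r.res_b}\t{r.atom_name}\t"
                f"{target}\t{r.tolerance:.3f}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RestraintSet":
        restraints = []
        for line in Path(path).read_text().splitlines()[1:]:
            if not line.strip():
                continue
            ra, atom_a, rb, _atom_b, target, tol = line.split("\t")
            restraints.append(
                DistanceRestraint(
                    res_a=int(ra),
                    res_b=int(rb),
                    atom_name=atom_a,
                    target_distance=None if target == "NA" else float(target),
                    tolerance=float(tol),
                )
            )
        return cls(restraints)


def build_restraints(
    conserved_pairs: Iterable[tuple[int, int]],
    target_cyclin: str,
    target_kinase: str,
    alignment_cyclin: AlignmentMap,
    alignment_kinase: AlignmentMap,
    tolerance: float = 1.0,
    target_distances: Mapping[tuple[int, int], float] | None = None,
) -> tuple[RestraintSet, list[tuple[int, int]]]:
    """Back-map conserved column pairs onto a target complex as CA-CA
    restraints.

    Returns (restraints, unmappable column pairs); a pair is unmappable when
    either column is a gap in the corresponding target sequence. Unmappable
    pairs are reported, never silently dropped.
    """
    restraints: list[DistanceRestraint] = []
    unmappable: list[tuple[int, int]] = []
    for col_a, col_b in sorted(conserved_pairs):
        res_a = alignment_cyclin.column_to_index(target_cyclin, col_a)
        res_b = alignment_kinase.column_to_index(target_kinase, col_b)
        if res_a is None or res_b is None:
            unmappable.append((col_a, col_b))
            continue
        restraints.append(
            DistanceRestraint(
                res_a=res_a,
                res_b=res_b,
                target_distance=(target_distances or {}).get((col_a, col_b)),
                tolerance=tolerance,
            )
        )
    return RestraintSet(restraints), unmappable


#: Curated CA-CA restraint pairs for docking CCNI (UniProt Q14094, first
#: position) onto CDK6 (UniProt Q00534, second position), derived from
#: interchain contacts conserved across crystallographic cyclin-CDK
#: complexes. Tuples are (cyclin residue, cyclin aa, kinase residue,
#: kinase aa).
CCNI_CDK6_RESTRAINT_PAIRS: tuple[tuple[int, str, int, str], ...] = (
    (97, "L", 59, "I"),
    (100, "K", 52, "E"),
    (100, "K", 53, "G"),
    (100, "K", 54, "M"),
    (100, "K", 56, "L"),
    (100, "K", 59, "I"),
    (101, "T", 59, "I"),
    (101, "T", 63, "A"),
    (106, "E", 60, "R"),
    (111, "L", 52, "E"),
    (131, "E", 52, "E"),
    (131, "E", 53, "G"),
    (131, "E", 54, "M"),
    (135, "L", 54, "M"),
    (140, "W", 54, "M"),
    (140, "W", 59, "I"),
    (140, "W", 62, "V"),
    (140, "W", 94, "L"),
    (142, "L", 59, "I"),
    (142, "L", 63, "A"),
    (143, "H", 63, "A"),
)


def load_ccni_cdk6_restraints(tolerance: float = 1.0) -> RestraintSet:
    """The packaged CA-CA restraint set for the CCNI-CDK6 complex.

    21 alpha-carbon pairs in UniProt numbering (cyclin position first),
    spanning the cyclin-box interface (L97 ... H143 on CCNI against the
    CDK6 N-lobe).
    """
    return RestraintSet(
        [
            DistanceRestraint(res_a=a, res_b=b, tolerance=tolerance)
            for a, _aa, b, _bb in CCNI_CDK6_RESTRAINT_PAIRS
        ]
    )
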