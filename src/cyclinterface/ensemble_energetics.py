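"""Boltzmann-weighted ensemble binding energetics with per-residue
decomposition.

Given an ensemble of N scored conformations of a two-chain complex, each
member i carries a bound-complex score E_i and isolated-chain scores; its
interface binding energy is

    E_i^b = E_i^complex - (E_i^chainA + E_i^chainB).

Members are weighted by Boltzmann probabilities computed from the complex
scores, p_i = exp(-E_i / kT) / Q with Q = sum_j exp(-E_j / kT), and the
ensemble binding energy is the expectation E_b = sum_i p_i E_i^b. The
temperature factor kT defaults to one energy unit of the scorer in use.

Any scorer that returns a total energy plus an exact per-residue split is
accepted; the built-in surrogate (:class:`GoContactScorer`) combines
Go-type 12-10 contact wells at native CA-CA distances with a truncated
excluded-volume clash penalty, splitting every pairwise term half-and-half
between the two residues. Per-residue binding contributions are
(complex per-residue score) - (isolated-chain per-residue score), averaged
under the Boltzmann weights; residues contributing more than a fraction
(default 0.5%) of the total binding energy are "key residues".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize as _scipy_minimize
from scipy.special import logsumexp

from .structures_io import ResidueKey, Structure

__all__ = [
    "DecomposableScorer",
    "GoContactScorer",
    "ScoredMember",
    "EnsembleEnergetics",
    "ResidueContributionTable",
    "score_structure",
    "minimize",
    "boltzmann_weights",
    "interface_binding_energy",
    "ensemble_binding_energy",
    "score_member",
    "per_residue_contributions",
    "select_key_residues",
]


class DecomposableScorer(Protocol):
    """Any energy function with an exact per-residue decomposition."""

    def score(self, structure: Structure) -> tuple[float, dict[ResidueKey, float]]:
        """Total energy and per-residue split (split sums to the total)."""
        ...

    def energy_and_grad(
        self, coords: np.ndarray, keys: Sequence[ResidueKey]
    ) -> tuple[float, np.ndarray]:
        """Energy and gradient w.r.t. the given atom coordinates."""
        ...


class GoContactScorer:
    """Surrogate decomposable scorer: native-contact wells plus clash term.

    Built once from a reference complex (CA geometry). Residue pairs within
    ``contact_cutoff`` of each other (CA-CA, sequence separation >= 4 or
    interchain) become 12-10 wells of depth ``epsilon`` with minima at the
    native distance; every other long-range pair feels a clash penalty
    ``eps_clash * ((sigma/r)^12 - 1)`` for r < sigma, zero beyond. Scoring a
    sub-structure (an isolated chain) evaluates only the pairs whose two
    residues are both present, so the scorer is exactly pairwise-additive
    and the interface binding energy reduces to the interchain terms.
    """

    def __init__(
        self,
        reference: Structure,
        contact_cutoff: float = 8.0,
        epsilon: float = 1.0,
        eps_clash: float = 1.0,
        sigma_clash: float = 3.8,
    ):
        self.epsilon = epsilon
        self.eps_clash = eps_clash
        self.sigma_clash = sigma_clash
        self.contact_cutoff = contact_cutoff
        keys: list[ResidueKey] = []
        coords: list[tuple[float, float, float]] = []
        for chain in reference.chains:
            for key in reference.residues(chain):
                cas = [a for a in reference.residue_atoms(key) if a.atom_name == "CA"]
                if not cas:
                    raise ValueError(f"residue {key} has no CA atom")
                keys.append(key)
                coords.append(cas[0].coords)
        x = np.array(coords)
        chain_of = {k: k.chain_id for k in keys}
        seq_pos: dict[ResidueKey, int] = {}
        for chain in reference.chains:
            for pos, key in enumerate(reference.residues(chain)):
                seq_pos[key] = pos
        #: contact pairs -> native distance; clash pairs -> None
        self.contact_r0: dict[tuple[ResidueKey, ResidueKey], float] = {}
        self.clash_pairs: list[tuple[ResidueKey, ResidueKey]] = []
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                ki, kj = keys[i], keys[j]
                long_range = chain_of[ki] != chain_of[kj] or abs(
                    seq_pos[ki] - seq_pos[kj]
                ) >= 4
                if not long_range:
                    continue
                r = float(np.linalg.norm(x[j] - x[i]))
                if r <= contact_cutoff:
                    self.contact_r0[(ki, kj)] = r
                else:
                    self.clash_pairs.append((ki, kj))

    # -- pair energies ------------------------------------------------------
    def _pair_energy(self, kind_r0: float | None, r: float) -> float:
        if kind_r0 is not None:
            q = kind_r0 / r
            return self.epsilon * (5.0 * q**12 - 6.0 * q**10)
        if r < self.sigma_clash:
            return self.eps_clash * ((self.sigma_clash / r) ** 12 - 1.0)
        return 0.0

    def score(self, structure: Structure) -> tuple[float, dict[ResidueKey, float]]:
        ca = {
            a.residue_key: np.array(a.coords)
            for a in structure.atoms
            if a.atom_name == "CA"
        }
        per_res: dict[ResidueKey, float] = {k: 0.0 for k in ca}
        total = 0.0
        for (ki, kj), r0 in self.contact_r0.items():
            if ki in ca and kj in ca:
                e = self._pair_energy(r0, float(np.linalg.norm(ca[kj] - ca[ki])))
                total += e
                per_res[ki] += 0.5 * e
                per_res[kj] += 0.5 * e
        for ki, kj in self.clash_pairs:
            if ki in ca and kj in ca:
                e = self._pair_energy(None, float(np.linalg.norm(ca[kj] - ca[ki])))
                total += e
                per_res[ki] += 0.5 * e
                per_res[kj] += 0.5 * e
        return total, per_res

    def energy_and_grad(
        self, coords: np.ndarray, keys: Sequence[ResidueKey]
    ) -> tuple[float, np.ndarray]:
        coords = np.asarray(coords, dtype=float)
        index = {k: i for i, k in enumerate(keys)}
        energy = 0.0
        grad = np.zeros_like(coords)
        for pairs, is_contact in ((self.contact_r0, True), (self.clash_pairs, False)):
            items = pairs.items() if is_contact else ((p, None) for p in pairs)
            for (ki, kj), r0 in items:
                if ki not in index or kj not in index:
                    continue
                i, j = index[ki], index[kj]
                rij = coords[j] - coords[i]
                r = float(np.linalg.norm(rij))
                if is_contact:
                    q = r0 / r
                    energy += self.epsilon * (5.0 * q**12 - 6.0 * q**10)
                    du_dr = self.epsilon * (-60.0 * q**12 + 60.0 * q**10) / r
                elif r < self.sigma_clash:
                    s = self.sigma_clash / r
                    energy += self.eps_clash * (s**12 - 1.0)
                    du_dr = -12.0 * self.eps_clash * s**12 / r
                else:
                    continue
                g = (du_dr / r) * rij
                grad[j] += g
                grad[i] -= g
        return energy, grad


def score_structure(
    structure: Structure, scorer: DecomposableScorer
) -> tuple[float, dict[ResidueKey, float]]:
    """Score a structure, checking the per-residue split is exact."""
    try:
        total, per_res = scorer.score(structure)
    except Exception as exc:
        raise RuntimeError(f"scorer failed on structure {structure.id!r}: {exc}") from exc
    if abs(sum(per_res.values()) - total) > 1e-9 * max(1.0, abs(total)):
        raise RuntimeError(
            f"scorer decomposition does not sum to the total on {structure.id!r}"
        )
    return total, per_res


def minimize(
    structure: Structure,
    scorer: DecomposableScorer,
    n_restarts: int = 10,
    tol: float = 1e-6,
    jitter_sigma: float = 0.05,
    seed: int = 0,
    max_iter: int = 500,
) -> list[tuple[Structure, float]]:
    """Local minimizations from jittered starts (quasi-Newton descent).

    Runs ``n_restarts`` L-BFGS minimizations, each starting from the input
    coordinates plus Gaussian jitter of width ``jitter_sigma`` Angstrom
    (seeded; restart 0 onward all jittered, jitter 0 reproduces the input
    start). Returns (structure, energy) per restart; each energy is no
    larger than its starting energy.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    keys = [a.residue_key for a in structure.atoms]
    x0 = structure.coords()
    results: list[tuple[Structure, float]] = []
    for _ in range(n_restarts):
        start = x0 + (
            rng.normal(0.0, jitter_sigma, size=x0.shape) if jitter_sigma > 0 else 0.0
        )
        start_energy, _ = scorer.energy_and_grad(start, keys)

        def objective(flat: np.ndarray) -> tuple[float, np.ndarray]:
            e, g = scorer.energy_and_grad(flat.reshape(-1, 3), keys)
            if not math.isfinite(e):
                raise RuntimeError(
                    f"non-finite energy during minimization of {structure.id!r}"
                )
            return e, g.ravel()

        res = _scipy_minimize(
            objective,
            start.ravel(),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-12},
        )
        final = res.x.reshape(-1, 3)
        final_energy = float(res.fun)
        if final_energy > start_energy:  # descent guarantee
            final, final_energy = start, float(start_energy)
        results.append((structure.with_coords(final), final_energy))
    return results


# --------------------------------------------------------------------------
# Boltzmann machinery
# --------------------------------------------------------------------------

def boltzmann_weights(
    energies: Sequence[float], kT: float = 1.0
) -> tuple[np.ndarray, float]:
    """Boltzmann probabilities and partition function.

    p_i = exp(-E_i / kT) / Q with Q = sum_j exp(-E_j / kT), evaluated via a
    max-shift (log-sum-exp) so arbitrarily large energy spreads do not
    overflow. Returns (weights, Q); Q may overflow to inf for very negative
    energies while the weights stay exact.
    """
    if kT <= 0:
        raise ValueError("kT must be positive")
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise ValueError("need at least one energy")
    if not np.all(np.isfinite(e)):
        raise ValueError("energies must be finite")
    log_terms = -e / kT
    log_q = float(logsumexp(log_terms))
    weights = np.exp(log_terms - log_q)
    weights /= weights.sum()  # renormalise away the last-ulp rounding
    with np.errstate(over="ignore"):  # Q itself may round to inf; weights don't
        q = float(np.exp(log_q))
    return weights, q


def interface_binding_energy(
    e_complex: float, e_chain_a: float, e_chain_b: float
) -> float:
    """E^b = E_complex - (E_chainA + E_chainB)."""
    for v in (e_complex, e_chain_a, e_chain_b):
        if not math.isfinite(v):
            raise ValueError("energies must be finite")
    return e_complex - (e_chain_a + e_chain_b)


@dataclass
class ScoredMember:
    """One ensemble member: complex and isolated-chain scores.

    ``e_binding`` is stored as the exact difference of the stored fields.
    Per-residue vectors (complex and isolated-chain) are optional; they are
    needed only for decomposition.
    """

    member_id: str
    e_complex: float
    e_chain_cyclin: float
    e_chain_kinase: float
    e_binding: float = field(init=False)
    per_residue_complex: dict[ResidueKey, float] | None = None
    per_residue_chains: dict[ResidueKey, float] | None = None

    def __post_init__(self) -> None:
        self.e_binding = interface_binding_energy(
            self.e_complex, self.e_chain_cyclin, self.e_chain_kinase
        )


def score_member(
    member_id: str,
    complex_structure: Structure,
    chain_cyclin: str,
    chain_kinase: str,
    scorer: DecomposableScorer,
) -> ScoredMember:
    """Score one conformation: bound complex plus both chains extracted in
    their bound conformation (rigid separation, no re-minimization)."""
    e_complex, pr_complex = score_structure(complex_structure, scorer)
    e_cyc, pr_cyc = score_structure(
        complex_structure.select_chains([chain_cyclin]), scorer
    )
    e_kin, pr_kin = score_structure(
        complex_structure.select_chains([chain_kinase]), scorer
    )
    return ScoredMember(
        member_id=member_id,
        e_complex=e_complex,
        e_chain_cyclin=e_cyc,
        e_chain_kinase=e_kin,
        per_residue_complex=pr_complex,
        per_residue_chains={**pr_cyc, **pr_kin},
    )


@dataclass
class EnsembleEnergetics:
    """Boltzmann-weighted ensemble with its binding-energy expectation."""

    members: list[ScoredMember]
    kT: float
    weights: np.ndarray
    partition_function: float
    e_binding: float  # the expectation E_b

    @property
    def n(self) -> int:
        return len(self.members)


def ensemble_binding_energy(
    members: Sequence[ScoredMember], kT: float = 1.0
) -> EnsembleEnergetics:
    """E_b = sum_i p_i E_i^b with p_i from the complex scores E_i.

    The probabilities are computed from the bound-complex scores (the E_i of
    the Boltzmann formula), not from the binding energies themselves.
    """
    if not members:
        raise ValueError("need at least one member")
    weights, q = boltzmann_weights([m.e_complex for m in members], kT)
    e_b = float(weights @ np.array([m.e_binding for m in members]))
    return EnsembleEnergetics(
        members=list(members),
        kT=kT,
        weights=weights,
        partition_function=q,
        e_binding=e_b,
    )


# --------------------------------------------------------------------------
# Per-residue decomposition and key residues
# --------------------------------------------------------------------------

@dataclass
class ResidueContributionTable:
    """Boltzmann-averaged per-residue contributions to E_b."""

    contributions: dict[ResidueKey, float]
    e_binding: float

    def fraction(self, key: ResidueKey) -> float:
        """|contribution| as a fraction of |E_b|."""
        if self.e_binding == 0:
            raise ZeroDivisionError("E_b is zero; fractions are undefined")
        return abs(self.contributions[key]) / abs(self.e_binding)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chain_id": k.chain_id,
                "residue_seq": k.residue_seq,
                "insertion_code": k.insertion_code,
                "contribution": c,
                "fraction_of_total": (
                    abs(c) / abs(self.e_binding) if self.e_binding else np.nan
                ),
            }
            for k, c in sorted(self.contributions.items())
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def per_residue_contributions(
    members: Sequence[ScoredMember],
    weights: np.ndarray | Sequence[float],
) -> ResidueContributionTable:
    """Weighted per-residue binding contributions.

    Per member, a residue's binding contribution is its complex per-residue
    score minus its isolated-chain per-residue score; the table entry is the
    Boltzmann-weighted average over members. For an exactly decomposable
    scorer the entries sum to E_b.
    """
    if not members:
        raise ValueError("need at least one member")
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(members):
        raise ValueError("one weight per member required")
    first_keys: set[ResidueKey] | None = None
    contributions: dict[ResidueKey, float] = {}
    e_b = 0.0
    for w, m in zip(weights, members):
        if m.per_residue_complex is None or m.per_residue_chains is None:
            raise ValueError(f"member {m.member_id!r} lacks per-residue vectors")
        keys = set(m.per_residue_complex)
        if keys != set(m.per_residue_chains):
            raise ValueError(
                f"member {m.member_id!r}: complex and chain residue sets differ"
            )
        if first_keys is None:
            first_keys = keys
            contributions = {k: 0.0 for k in keys}
        elif keys != first_keys:
            raise ValueError(
                f"member {m.member_id!r}: residue set differs from the ensemble's"
            )
        for k in keys:
            contributions[k] += w * (
                m.per_residue_complex[k] - m.per_residue_chains[k]
            )
        e_b += w * m.e_binding
    return ResidueContributionTable(contributions=contributions, e_binding=e_b)


def select_key_residues(
    table: ResidueContributionTable, min_fraction: float = 0.005
) -> list[ResidueKey]:
    """Residues contributing more than ``min_fraction`` of the total binding
    energy, in descending order of |contribution|.

    The comparison is |contribution| / |E_b| > min_fraction (default 0.5%).
    """
    if not table.contributions:
        raise ValueError("contribution table is empty")
    if table.e_binding == 0:
        raise ZeroDivisionError("E_b is zero; key-residue fractions are undefined")
    selected = [
        k for k in table.contributions if table.fraction(k) > min_fraction
    ]
    return sorted(selected, key=lambda k: (-abs(table.contributions[k]), k))


# --------------------------------------------------------------------------
# CSV persistence
# --------------------------------------------------------------------------

def members_to_csv(
    members: Sequence[ScoredMember], path: str | Path, residues_path: str | Path | None = None
) -> None:
    """Write member energies (and optionally the long-format per-residue
    table: member_id, chain, residue_seq, score_complex, score_isolated)."""
    pd.DataFrame(
        [
            {
                "member_id": m.member_id,
                "E_complex": m.e_complex,
                "E_chain_cyclin": m.e_chain_cyclin,
                "E_chain_kinase": m.e_chain_kinase,
            }
            for m in members
        ]
    ).to_csv(path, index=False)
    if residues_path is not None:
        rows = []
        for m in members:
            if m.per_residue_complex is None:
                continue
            for k, v in sorted(m.per_residue_complex.items()):
                rows.append(
                    {
                        "member_id": m.member_id,
                        "chain_id": k.chain_id,
                        "residue_seq": k.residue_seq,
                        "score_complex": v,
                        "score_isolated": m.per_residue_chains[k],
                    }
                )
        pd.DataFrame(rows).to_csv(residues_path, index=False)


def members_from_csv(
    path: str | Path, residues_path: str | Path | None = None
) -> list[ScoredMember]:
    df = pd.read_csv(path)
    per_res: dict[str, tuple[dict, dict]] = {}
    if residues_path is not None:
        rdf = pd.read_csv(residues_path)
        for mid, grp in rdf.groupby("member_id"):
            cx, iso = {}, {}
            for row in grp.itertuples():
                key = ResidueKey(str(row.chain_id), int(row.residue_seq))
                cx[key] = float(row.score_complex)
                iso[key] = float(row.score_isolated)
            per_res[str(mid)] = (cx, iso)
    members = []
    for row in df.itertuples():
        mid = str(row.member_id)
        cx, iso = per_res.get(mid, (None, None))
        members.append(
            ScoredMember(
                member_id=mid,
                e_complex=float(row.E_complex),
                e_chain_cyclin=float(row.E_chain_cyclin),
                e_chain_kinase=float(row.E_chain_kinase),
                per_residue_complex=cx,
                per_residue_chains=iso,
            )
        )
    return members
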