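"""End-to-end orchestration: interface -> contacts -> (conservation ->
restraints) -> Go sampling -> RMSD clustering -> minimization -> ensemble
energetics -> key residues.

A run is driven by a flat key=value configuration file with strict unknown
key rejection; every stage persists its artifact under the output
directory and a run manifest records the configuration, package version,
SHA-256 digest of each artifact and per-stage wall time. All stochastic
stages are seeded, so a rerun with the same configuration and inputs
reproduces the report byte for byte (the manifest's timings differ).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

from . import __version__
from .ensemble_energetics import (
    GoContactScorer,
    ensemble_binding_energy,
    members_to_csv,
    minimize,
    per_residue_contributions,
    score_member,
    select_key_residues,
)
from .interface_analysis import (
    build_restraints,
    conserved_contacts,
    detect_interface,
    shadow_contact_map,
)
from .sbm_sampler import build_go_potential, cluster_by_rmsd, sample
from .structures_io import Structure, read_alignment, read_pdb, write_pdb

__all__ = ["PipelineConfig", "RunManifest", "ConfigError", "validate_config",
           "run_pipeline", "ca_trace"]


class ConfigError(ValueError):
    """Raised with every configuration violation collected together."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n- " + "\n- ".join(problems))


@dataclass
class PipelineConfig:
    """All pipeline parameters; numeric defaults are the analysis constants
    of the cyclin-CDK workflow (20% burial threshold, 1000 clusters, 10
    minimization restarts, kT = 1 energy unit, 0.5% key-residue rule)."""

    complex_pdb: str = ""
    output_dir: str = "run_output"
    chain_cyclin: str = "A"
    chain_kinase: str = "B"
    alignment_cyclin: str | None = None
    alignment_kinase: str | None = None
    sasa_probe: float = 1.4
    sasa_n_points: int = 960
    sasa_threshold: float = 0.20
    contact_cutoff: float = 6.0
    shadow_radius: float = 1.0
    cutoff_only: bool = False
    sample_steps: int = 2000
    sample_kt: float = 0.5
    sample_dt: float = 0.002
    sample_stride: int = 10
    seed: int = 0
    clusters: int = 1000
    min_restarts: int = 10
    min_tol: float = 1e-6
    kt: float = 1.0
    min_fraction: float = 0.005

    def validate(self) -> None:
        problems: list[str] = []
        if not self.complex_pdb:
            problems.append("complex_pdb is required")
        if not (0.0 < self.sasa_threshold <= 1.0):
            problems.append(f"sasa_threshold {self.sasa_threshold} not in (0, 1]")
        if self.sasa_n_points < 12:
            problems.append("sasa_n_points must be >= 12")
        if self.contact_cutoff <= 0:
            problems.append("contact_cutoff must be positive")
        if self.shadow_radius < 0:
            problems.append("shadow_radius must be non-negative")
        if self.cutoff_only and self.shadow_radius > 0:
            problems.append(
                "cutoff_only and a positive shadow_radius are mutually exclusive"
            )
        if self.sample_steps < 1:
            problems.append("sample_steps must be >= 1")
        if self.sample_kt < 0:
            problems.append("sample_kt must be non-negative")
        if self.clusters < 1:
            problems.append("clusters must be >= 1")
        if self.min_restarts < 1:
            problems.append("min_restarts must be >= 1")
        if self.kt <= 0:
            problems.append("kt must be positive")
        if not (0.0 < self.min_fraction < 1.0):
            problems.append(f"min_fraction {self.min_fraction} not in (0, 1)")
        if problems:
            raise ConfigError(problems)


_BOOL_KEYS = {"cutoff_only"}
_INT_KEYS = {"sasa_n_points", "sample_steps", "sample_stride", "seed", "clusters",
             "min_restarts"}
_FLOAT_KEYS = {"sasa_probe", "sasa_threshold", "contact_cutoff", "shadow_radius",
               "sample_kt", "sample_dt", "min_tol", "kt", "min_fraction"}
_OPTIONAL_STR = {"alignment_cyclin", "alignment_kinase"}


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a flat key=value configuration file.

    Unknown keys are rejected and all violations are reported together.
    """
    known = set(PipelineConfig.__dataclass_fields__)
    values: dict[str, Any] = {}
    problems: list[str] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            problems.append(f"line {lineno}: expected key=value, got {line!r}")
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in known:
            problems.append(f"line {lineno}: unknown key {key!r}")
            continue
        try:
            if key in _BOOL_KEYS:
                values[key] = value.lower() in ("1", "true", "yes")
            elif key in _INT_KEYS:
                values[key] = int(value)
            elif key in _FLOAT_KEYS:
                values[key] = float(value)
            else:
                values[key] = value
        except ValueError:
            problems.append(f"line {lineno}: cannot parse value for {key!r}")
    if problems:
        raise ConfigError(problems)
    config = PipelineConfig(**values)
    config.validate()
    return config


@dataclass
class RunManifest:
    config: dict
    package_version: str
    stage_digests: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"
        )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def ca_trace(structure: Structure) -> Structure:
    """CA-only copy of a structure, chain/residue order preserved."""
    atoms = []
    for chain in structure.chains:
        for key in structure.residues(chain):
            for a in structure.residue_atoms(key):
                if a.atom_name == "CA":
                    atoms.append(a)
    return Structure(f"{structure.id}|CA", atoms)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage in order, persisting artifacts as it goes.

    On a stage failure the error is re-raised with the stage name; partial
    artifacts are left in the output directory for inspection.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), package_version=__version__)

    def _stage(name: str):
        class _Timer:
            def __enter__(self) -> None:
                self._t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb) -> bool:
                manifest.stage_seconds[name] = time.perf_counter() - self._t0
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                return False

        return _Timer()

    def _register(name: str, path: Path) -> None:
        manifest.stage_digests[name] = _digest(path)

    shadow_radius = 0.0 if config.cutoff_only else config.shadow_radius

    with _stage("read"):
        complex_structure = read_pdb(config.complex_pdb)

    with _stage("interface"):
        interface = detect_interface(
            complex_structure,
            config.chain_cyclin,
            config.chain_kinase,
            threshold=config.sasa_threshold,
            probe_radius=config.sasa_probe,
            n_points=config.sasa_n_points,
        )
        interface.to_tsv(out / "interface.tsv")
        _register("interface", out / "interface.tsv")

    with _stage("contacts"):
        contacts = shadow_contact_map(
            complex_structure,
            cutoff=config.contact_cutoff,
            shadow_radius=shadow_radius,
            chain_pair=(config.chain_cyclin, config.chain_kinase),
        )
        contacts.to_tsv(out / "contacts.tsv")
        _register("contacts", out / "contacts.tsv")

    restraints = None
    if config.alignment_cyclin and config.alignment_kinase:
        with _stage("restraints"):
            aln_cyc = read_alignment(config.alignment_cyclin)
            aln_kin = read_alignment(config.alignment_kinase)
            cyc_id = f"{complex_structure.id}_cyclin"
            kin_id = f"{complex_structure.id}_kinase"
            conserved = conserved_contacts(
                [contacts],
                aln_cyc,
                aln_kin,
                chain_pairs={
                    complex_structure.id: (config.chain_cyclin, config.chain_kinase)
                },
                cyclin_seq_ids={complex_structure.id: cyc_id},
                kinase_seq_ids={complex_structure.id: kin_id},
            )
            restraints, _unmappable = build_restraints(
                conserved, cyc_id, kin_id, aln_cyc, aln_kin
            )
            restraints.to_tsv(out / "restraints.tsv")
            _register("restraints", out / "restraints.tsv")

    with _stage("sample"):
        potential = build_go_potential(complex_structure, contacts)
        trajectory = sample(
            potential,
            n_steps=config.sample_steps,
            kT_sim=config.sample_kt,
            dt=config.sample_dt,
            seed=config.seed,
            stride=config.sample_stride,
        )
        trajectory.save(out / "trajectory.pdb", out / "trajectory_energies.csv")
        _register("trajectory", out / "trajectory.pdb")

    with _stage("cluster"):
        ensemble = cluster_by_rmsd(trajectory, k=config.clusters)
        reference_ca = ca_trace(complex_structure)
        centroid_dir = out / "centroids"
        centroid_dir.mkdir(exist_ok=True)
        rows = ["centroid,frame_index,member_count"]
        for c, (idx, count) in enumerate(
            zip(ensemble.centroid_indices, ensemble.member_counts)
        ):
            write_pdb(
                reference_ca.with_coords(ensemble.centroids[c]),
                centroid_dir / f"centroid_{c:04d}.pdb",
            )
            rows.append(f"{c},{idx},{count}")
        (out / "clusters.csv").write_text("\n".join(rows) + "\n")
        _register("clusters", out / "clusters.csv")

    with _stage("minimize_score"):
        scorer = GoContactScorer(complex_structure)
        members = []
        for c in range(ensemble.k):
            centroid = reference_ca.with_coords(
                ensemble.centroids[c], id=f"centroid{c}"
            )
            minimized = minimize(
                centroid,
                scorer,
                n_restarts=config.min_restarts,
                tol=config.min_tol,
                seed=config.seed + c,
            )
            for r, (structure, _energy) in enumerate(minimized):
                members.append(
                    score_member(
                        f"c{c}_r{r}",
                        structure,
                        config.chain_cyclin,
                        config.chain_kinase,
                        scorer,
                    )
                )
        members_to_csv(members, out / "ensemble_energies.csv",
                       out / "ensemble_residue_scores.csv")
        _register("ensemble_energies", out / "ensemble_energies.csv")

    with _stage("report"):
        energetics = ensemble_binding_energy(members, kT=config.kt)
        table = per_residue_contributions(members, energetics.weights)
        key_residues = select_key_residues(table, config.min_fraction)
        table.to_tsv(out / "residue_contributions.tsv")
        report = {
            "schema_version": 1,
            "n_members": energetics.n,
            "kT": config.kt,
            "partition_function": energetics.partition_function,
            "E_b": energetics.e_binding,
            "weights": {
                m.member_id: float(w)
                for m, w in zip(energetics.members, energetics.weights)
            },
            "residue_contributions": {
                str(k): v for k, v in sorted(table.contributions.items())
            },
            "key_residues": [str(k) for k in key_residues],
            "n_restraints": len(restraints) if restraints is not None else None,
        }
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        _register("report", out / "report.json")

    manifest.save(out / "manifest.json")
    return manifest
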