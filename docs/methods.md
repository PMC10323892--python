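# Methods

This note documents the models, algorithms, numerical choices and
limitations of `cyclinterface`, in the spirit of the methods documentation
of packages like msprime or statsmodels: what is computed, under which
assumptions, with which defaults, and what passing the test suite does and
does not establish.

## Coordinate model and I/O

Structures are a minimal chains → residues → atoms hierarchy with Å
coordinates. PDB reading keeps heavy-atom `ATOM` records of the first
MODEL only; waters, HETATM records and hydrogens are dropped (the SASA and
contact analyses operate on crystal structures, where hydrogens are
usually absent anyway). For alternate locations only the first-listed
conformer of each atom is kept. Van der Waals radii come from a table
pinned inside the package (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å,
default 1.70) so results are identical across installs. Author residue
numbering is authoritative; a 3-column offset table
(`chain_id, pdb_seq_start, uniprot_seq_start`) converts to UniProt
numbering, the convention used for the packaged CCNI–CDK6 restraints.
Writing uses the 8.3 coordinate format, so a write/read round trip is
exact for coordinates quantized to 3 decimals and within 5·10⁻⁴ Å
otherwise.

Alignments are consumed as aligned FASTA (via Biopython); the package
never computes an alignment. Conservation mapping treats a residue's
`residue_seq` as its 1-based ungapped index in the corresponding alignment
sequence — renumber first if the structure numbering differs.

## SASA and interface definition

SASA is Shrake–Rupley: each atom inflated by the probe radius (default
1.4 Å), covered with `n_points` quadrature points (default 960) on a
*deterministic Fibonacci lattice* — chosen over random sphere sampling so
results are bit-reproducible and over external SASA binaries so the
package is self-contained. A point is exposed if outside every
neighbouring inflated sphere; atom areas sum per residue. The
single-atom quadrature error is < 10⁻¹³ relative (the lattice covers the
sphere uniformly) and doubling the point count moves buried-residue areas
by well under 2%. An independent cross-check against Biopython's
Shrake–Rupley with identical radii agrees to ~3%, the expected
point-distribution difference.

An interface residue loses ≥ 20% (configurable threshold, inclusive
comparison) of its isolated-chain SASA upon complexation. Burial is
computed residue-level (areas summed before the ratio), clamped to [0, 1];
residues with zero unbound SASA are excluded rather than divided by zero.
The isolated-chain ("unbound") state is the chain extracted rigidly from
the complex, not re-minimized.

## Shadow contact maps

Interchain atom pairs within the cutoff (default 6 Å) are contact
candidates; a candidate is discarded when any third atom's center lies
within the shadowing radius (default 1 Å) of the closed segment between
the two atoms. Setting the radius to 0 disables shadowing (cutoff-only
map), and by construction the shadow map is always a subset of the
cutoff-only map. Residue pairs are contacts when any kept atom pair joins
them, ordered with the lexicographically smaller chain first.

## Conservation and restraints

Interface positions (or contact pairs) of several complexes are mapped to
alignment columns; columns present in *every* complex — strict
intersection, no majority vote — are conserved, and back-map to each
complex's numbering. Conserved column pairs become Cα–Cα distance
restraints in the numbering of a chosen target sequence; pairs falling on
a gap in the target are returned in an explicit unmappable list, never
silently dropped. Restraint target distances, when built from structures,
default to the observed Cα–Cα distance with a 1 Å tolerance.

The package ships the curated 21-pair Cα–Cα restraint list for docking
CCNI onto CDK6 (UniProt numbering), spanning ten distinct cyclin-box
positions (97–143) against the CDK6 N-lobe.

## The Cα Gō potential and sampler

Resolution is one bead per residue at the Cα position. Terms and defaults
(reduced units; the contact depth ε = 1 is the energy unit, Å the length
unit, masses 1):

| term | form | default |
|---|---|---|
| bond | ½ k_b (r − r₀)² | k_b = 100 ε/Å² |
| angle | ½ k_a (θ − θ₀)² | k_a = 20 ε/rad² |
| dihedral | k_d [(1 − cos Δφ) + ½(1 − cos 3Δφ)] | k_d = 1 ε |
| native contact | ε [5 (r₀/r)¹² − 6 (r₀/r)¹⁰] | ε = 1 |
| excluded volume | ε_ev [(σ/r)¹² − 1] for r < σ, else 0 | σ = 3.8 Å |

Native values (r₀, θ₀, φ₀) come from the reference structure; contacts
come from a shadow contact map (sequence separation ≥ 4 or interchain).
The repulsion is truncated and shifted to vanish at σ, so a reference pose
whose non-contact pairs all exceed σ has energy exactly −ε·n_contacts — a
convenient exactness check. Dihedral forces use the standard
torsion-gradient formulas with denominators floored at 10⁻⁶ to keep
near-collinear geometries finite; all force routines are verified against
central differences in the tests.

Sampling is BAOAB Langevin with friction 1/time-unit and explicit seeds
(identical seed ⇒ bitwise-identical trajectory). With friction 0 the
integrator reduces to velocity Verlet; over 10⁴ NVE steps at dt = 0.001
total energy drifts by ~3·10⁻⁵ relative. Energies above 10⁶ abort with an
integration error suggesting a smaller time step. The default sampling
temperature kT_sim = 0.5 ε sits below the folding temperature of these
toy complexes: poses fluctuate 1–2 Å RMSD around the reference while
keeping ≥ 90% of native contacts, which is the regime in which alternative
*binding* poses (rather than unfolding) are explored.

## RMSD and clustering

Kabsch superposition (SVD with the determinant sign correction, proper
rotations only); the RMSD is evaluated from explicit residuals after
applying the optimal rotation, which avoids the catastrophic cancellation
of the trace-based closed form near zero (identical sets return < 10⁻¹²).
Clustering is k-medoids on the pairwise RMSD matrix: deterministic
farthest-point seeding from frame 0, alternating assignment and medoid
update until stable, every tie broken toward the lowest frame index.
Medoids are real frames, so centroids are physically realisable. The
nominal production setting is k = 1000 clusters over long trajectories;
tests and the acceptance script run k ≤ 10 over ≤ 500 frames, which
exercises the identical code path at desk scale.

## Ensemble energetics

Probabilities are computed from the *bound-complex* scores E_i (not from
the binding energies), via log-sum-exp so arbitrary energy spreads neither
overflow nor underflow; kT defaults to 1 energy unit. The partition
function is reported as exp(log Q) and may round to infinity for very
negative energy scales while the weights remain exact. Isolated-chain
scores use the chains extracted in their bound conformation (rigid
separation, no re-relaxation) — with an exactly pairwise scorer this makes
E_i^b the sum of interchain terms, which is the quantity of interest.

The built-in surrogate scorer is a native-contact (12-10) energy plus a
truncated clash penalty over Cα pairs (contact cutoff 8 Å on the
reference), with every pairwise term split half-and-half between its two
residues. The half-split convention is pinned and documented because any
exact decomposition of pairwise energies onto residues is a convention.
Per-residue binding contributions (complex minus isolated-chain score,
Boltzmann-averaged) therefore sum to E_b to ≤ 10⁻⁹. Key residues are
those with |contribution| > 0.5% of |E_b| (both quantities in absolute
value, since the sign convention of "total binding energy" is otherwise
ambiguous), ordered by contribution magnitude.

Local minimization is L-BFGS with analytic gradients from seeded
Gaussian-jittered starts (σ = 0.05 Å, 10 restarts by default); a result
is never accepted with higher energy than its start.

## Synthetic data: what it emulates, and what it does not

The generators provide every input with planted ground truth:

- **Toy complexes** — two helix-like Cα/CB traces (3.8 Å spacing with an
  out-of-plane zig-zag that keeps torsions non-degenerate). A centred
  window of residues per chain (default 6 of 20) faces the partner at
  contact range (default 4.8 Å Cα–Cα, inside the 4–6 Å contact band) with
  side-chain beads pointing inward; flanking residues bend steeply away.
  Planted residues bury ≥ 30% of their SASA on complexation and
  non-planted residues essentially 0%, so planted-interface recovery is
  exact with wide margins. Note one geometric impossibility deliberately
  not attempted: a residue chain-adjacent to the interface window cannot
  be arbitrarily far from the partner (consecutive Cα are one bond apart),
  so "all other pairs far apart" holds for pairs of non-planted residues
  and functionally (zero burial, no contacts) for mixed pairs.
- **Ensembles** — seeded isotropic Gaussian perturbations of a base
  structure, member 0 unperturbed.
- **Alignment sets** — cyclin- and kinase-side alignments where the
  planted columns are interface-positive in every complex and each decoy
  column is missed by exactly one complex, so strict intersection recovers
  the planted set exactly; gaps land only on free columns.
- **Two-basin trajectories** — frames alternating around two
  conformations whose superposed RMSD is rescaled to a target separation;
  generation is refused unless separation > 4× spread, the regime where
  perfect clustering purity is guaranteed.

Everything is a pure function of parameters and seed. These fixtures
validate the *machinery* — burial arithmetic, intersection semantics,
weight normalization, clustering optima — with known answers. They do not
emulate real side-chain packing, sequence statistics, crystallographic
noise or the ruggedness of an all-atom energy landscape, so green tests
certify correctness of the computation, not predictive accuracy on real
cyclin–CDK complexes.

## Pipeline determinism and problem sizes

Every stochastic stage takes an explicit seed; rerunning a configuration
reproduces `report.json` byte for byte (the run manifest's wall-clock
timings are the only non-reproducible output). The defaults pinned in the
configuration are the analysis constants of the workflow: burial threshold
0.20, 1000 clusters, 10 minimization restarts, kT = 1, key-residue
fraction 0.005. Tests and the acceptance script use reduced problem sizes
chosen to exercise every code path while keeping a full run in seconds:
2000 sampling steps (200 frames at stride 10), 5 clusters, 10 restarts →
a 50-member ensemble.

## Known limitations

- The sampler and scorer are Cα-resolution surrogates; absolute energies
  are in model units, not kcal/mol, and are not comparable across scorers.
- Interface detection needs both chains in one file with distinct chain
  identifiers; mmCIF, NMR multi-model ensembles, ligands and waters are
  out of scope.
- Conservation mapping requires structure numbering to match alignment
  indexing (use the offset-table helper first).
- The shadow criterion is applied with a single shadowing radius for all
  atoms; no bonded-neighbour exemption is made beyond excluding the two
  endpoint atoms themselves.
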