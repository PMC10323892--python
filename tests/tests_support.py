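"""Small shared helpers for the test suite."""

from __future__ import annotations

import numpy as np

from cyclinterface.sbm_sampler import GoPotential


def bond_only_potential(k_bond: float = 100.0, r0: float = 3.8) -> GoPotential:
    """A two-bead potential with a single harmonic bond (for statistical-
    mechanics checks against the equipartition closed form)."""
    empty2 = np.zeros((0, 2), dtype=int)
    empty3 = np.zeros((0, 3), dtype=int)
    empty4 = np.zeros((0, 4), dtype=int)
    z = np.zeros(0)
    return GoPotential(
        reference=np.array([[0.0, 0.0, 0.0], [r0, 0.0, 0.0]]),
        residue_keys=[None, None],
        bonds=np.array([[0, 1]]), bond_r0=np.array([r0]),
        angles=empty3, angle_theta0=z, dihedrals=empty4, dihedral_phi0=z,
        contacts=empty2, contact_r0=z, ev_pairs=empty2, k_bond=k_bond,
    )
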