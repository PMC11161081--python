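"""Shared builders for hand-constructed bead systems.

Analyses only ever resolve the beads they need (site constraint residues,
residue 13, C3A tails, ...), so test systems carry exactly the beads a given
metric reads, placed at hand-chosen coordinates.
"""

from __future__ import annotations

import numpy as np
import pytest

from discbind.trajectory import BeadMeta, BeadTrajectory, MolType


def _per_frame(pos, n_frames):
    pos = np.asarray(pos, dtype=float)
    if pos.ndim == 1:
        return np.broadcast_to(pos, (n_frames, 3)).copy()
    assert pos.shape == (n_frames, 3)
    return pos


def build_system(times, lcat=None, peptides=None, lipids_c3a=None, extra=None):
    """Assemble a BeadTrajectory from per-bead position specs.

    Parameters
    ----------
    times : array-like of frame times (ns)
    lcat : dict {res_index: xyz or (F, 3)} of LCAT BB beads (mol_id 0)
    peptides : dict {mol_id: {(res_index, bead_name) or res_index: xyz}}
        plain int keys mean the BB bead of that residue
    lipids_c3a : list of xyz or (F, 3), one C3A bead per lipid molecule
    extra : list of (BeadMeta, xyz or (F, 3)) appended verbatim
    """
    times = np.asarray(times, dtype=float)
    F = len(times)
    beads, cols = [], []
    for res, pos in sorted((lcat or {}).items()):
        beads.append(BeadMeta(0, MolType.LCAT, res, "BB"))
        cols.append(_per_frame(pos, F))
    for pid in sorted(peptides or {}):
        for key, pos in sorted(
            peptides[pid].items(),
            key=lambda kv: kv[0] if isinstance(kv[0], tuple) else (kv[0], "BB"),
        ):
            res, name = key if isinstance(key, tuple) else (key, "BB")
            beads.append(BeadMeta(pid, MolType.PEPTIDE, res, name))
            cols.append(_per_frame(pos, F))
    first_lipid = 1 + max(peptides or {0: 0}, default=0)
    for li, pos in enumerate(lipids_c3a or []):
        beads.append(BeadMeta(first_lipid + li + 1000, MolType.LIPID, 1, "C3A"))
        cols.append(_per_frame(pos, F))
    for meta, pos in extra or []:
        beads.append(meta)
        cols.append(_per_frame(pos, F))
    coords = np.stack(cols, axis=1)
    return BeadTrajectory(times, coords, beads)


def standard_anchors():
    """LCAT anchor beads spread so the three site anchor points are distinct."""
    return {
        48: (10.0, 0.0, 0.0),
        226: (0.0, 0.0, 0.0),
        229: (0.5, 0.5, 0.0),
        237: (10.0, 2.0, 0.0),
        239: (9.5, -0.5, 0.0),
    }
    # midpoint(48, 237) = (10, 1, 0)


def random_rotation(rng):
    """A uniformly random proper rotation matrix (QR with sign fix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture
def rng():
    return np.random.default_rng(20240528)
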