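"""Bead-trajectory data model and readers/writers.

A :class:`BeadTrajectory` is the in-memory container every analysis in this
package consumes: ``n_frames`` snapshots of ``n_beads`` coarse-grained beads,
coordinates in nanometres, times in nanoseconds.  Per-bead metadata (which
molecule a bead belongs to, whether that molecule is the enzyme, a peptide or
a lipid, the 1-based residue index within the molecule, and the Martini bead
name such as ``BB``/``SC1``/``C3A``) is trajectory-constant.

Internal units are nm and ns throughout; microsecond inputs are converted at
the boundary so the core never mixes scales.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MolType",
    "BeadMeta",
    "BeadTrajectory",
    "AnchorPoint",
    "SiteDefinition",
    "AnalysisWindow",
    "TopologyMap",
    "NANODISC_SITE",
    "FULLLENGTH_SITE",
    "read_tabular",
    "write_tabular",
    "read_gro",
    "read_xtc",
    "select_beads",
]

TABULAR_COLUMNS = [
    "frame",
    "time_ns",
    "mol_id",
    "mol_type",
    "res_index",
    "bead_name",
    "x_nm",
    "y_nm",
    "z_nm",
]


class MolType(str, Enum):
    LCAT = "LCAT"
    PEPTIDE = "PEPTIDE"
    LIPID = "LIPID"
    OTHER = "OTHER"


@dataclass(frozen=True)
class BeadMeta:
    """Identity of one bead: molecule, residue and bead name."""

    mol_id: int
    mol_type: MolType
    res_index: int
    bead_name: str

    def __post_init__(self) -> None:
        if self.mol_id < 0:
            raise ValueError(f"mol_id must be >= 0, got {self.mol_id}")
        if self.res_index < 1:
            raise ValueError(f"res_index is 1-based, got {self.res_index}")


class TrajectoryError(ValueError):
    """A trajectory violating the data-model invariants."""


@dataclass
class BeadTrajectory:
    """Frames x beads coordinate array with per-bead metadata.

    Parameters
    ----------
    times : array of shape (n_frames,)
        Frame times in ns, strictly increasing.
    coords : array of shape (n_frames, n_beads, 3)
        Coordinates in nm; all finite.
    beads : sequence of BeadMeta
        One entry per bead, constant over frames.
    box : optional array (n_frames, 3) or (n_frames, 3, 3)
        Box vectors in nm, if known.
    """

    times: np.ndarray
    coords: np.ndarray
    beads: list
    box: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.beads = list(self.beads)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError(
                f"coords must have shape (n_frames, n_beads, 3), got {self.coords.shape}"
            )
        if len(self.times) != self.coords.shape[0]:
            raise TrajectoryError(
                f"{len(self.times)} times for {self.coords.shape[0]} coordinate frames"
            )
        if self.coords.shape[1] != len(self.beads):
            raise TrajectoryError(
                f"{len(self.beads)} bead metadata entries for "
                f"{self.coords.shape[1]} coordinate columns"
            )
        if len(self.times) == 0:
            raise TrajectoryError("trajectory must contain at least one frame")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise TrajectoryError("frame times must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise TrajectoryError("coordinates contain non-finite values")
        keys = [(b.mol_id, b.res_index, b.bead_name) for b in self.beads]
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise TrajectoryError(
                f"duplicate bead (mol_id, res_index, bead_name) = {dup}"
            )
        self._index = {k: i for i, k in enumerate(keys)}

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    def bead_index(self, mol_id: int, res_index: int, bead_name: str) -> int:
        """Storage index of one bead; KeyError naming the reference if absent."""
        try:
            return self._index[(mol_id, res_index, bead_name)]
        except KeyError:
            raise KeyError(
                f"no bead (mol_id={mol_id}, res_index={res_index}, "
                f"bead_name={bead_name!r}) in trajectory"
            ) from None

    def mol_ids(self, mol_type: MolType) -> list:
        """Sorted molecule ids of the given type."""
        return sorted({b.mol_id for b in self.beads if b.mol_type == mol_type})

    def transformed(self, rotation: np.ndarray = None, translation=None) -> "BeadTrajectory":
        """Copy with every frame rigidly moved (same motion for all frames)."""
        coords = self.coords
        if rotation is not None:
            coords = coords @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            coords = coords + np.asarray(translation, dtype=float)
        return BeadTrajectory(self.times.copy(), coords, list(self.beads), self.box)


def select_beads(
    traj: BeadTrajectory,
    mol_type: Optional[MolType] = None,
    mol_id: Optional[int] = None,
    res_index: Optional[int] = None,
    bead_name: Optional[str] = None,
) -> np.ndarray:
    """Indices of beads matching all given fields (conjunctive); empty is valid."""
    if isinstance(mol_type, str) and not isinstance(mol_type, MolType):
        mol_type = MolType(mol_type)
    out = []
    for i, b in enumerate(traj.beads):
        if mol_type is not None and b.mol_type != mol_type:
            continue
        if mol_id is not None and b.mol_id != mol_id:
            continue
        if res_index is not None and b.res_index != res_index:
            continue
        if bead_name is not None and b.bead_name != bead_name:
            continue
        out.append(i)
    return np.asarray(out, dtype=int)


# ---------------------------------------------------------------------------
# Site definitions


class AnchorKind(str, Enum):
    SINGLE = "SINGLE"
    MIDPOINT = "MIDPOINT"


@dataclass(frozen=True)
class AnchorPoint:
    """A point on the enzyme: one backbone bead, or the midpoint of two.

    The nanodisc-site second constraint anchors at the middle point between
    two residues (W48 and I237 of LCAT); the others use single beads.
    """

    kind: AnchorKind
    residues: tuple  # of (res_index, bead_name)

    def __post_init__(self) -> None:
        n = {AnchorKind.SINGLE: 1, AnchorKind.MIDPOINT: 2}[self.kind]
        if len(self.residues) != n:
            raise ValueError(f"{self.kind.value} anchor needs {n} residue refs")

    @classmethod
    def single(cls, res_index: int, bead_name: str = "BB") -> "AnchorPoint":
        return cls(AnchorKind.SINGLE, ((res_index, bead_name),))

    @classmethod
    def midpoint(cls, ref_a, ref_b) -> "AnchorPoint":
        return cls(AnchorKind.MIDPOINT, (tuple(ref_a), tuple(ref_b)))

    def positions(self, traj: BeadTrajectory, mol_id: int) -> np.ndarray:
        """Anchor position per frame, shape (n_frames, 3)."""
        try:
            idx = [traj.bead_index(mol_id, r, b) for r, b in self.residues]
        except KeyError as exc:
            raise KeyError(f"anchor {self.residues} unresolvable: {exc}") from None
        pts = traj.coords[:, idx, :]
        return pts.mean(axis=1)


@dataclass(frozen=True)
class SiteDefinition:
    """Ordered distance constraints defining "occupied".

    Each constraint pairs a peptide residue (its backbone bead) with an
    anchor point on the enzyme and a cutoff in nm.  The nearest peptide is
    ranked by the unweighted sum of the per-constraint distances.
    """

    constraints: tuple  # of (peptide_res_index, AnchorPoint, cutoff_nm)
    peptide_bead_name: str = "BB"

    def __post_init__(self) -> None:
        if len(self.constraints) < 1:
            raise ValueError("a site needs at least one constraint")
        for res, anchor, cutoff in self.constraints:
            if cutoff <= 0:
                raise ValueError(f"cutoff must be > 0, got {cutoff}")

    @property
    def cutoffs(self) -> np.ndarray:
        return np.array([c for _, _, c in self.constraints], dtype=float)


#: Peptide-on-nanodisc occupancy site: residue 2 to LCAT G226 within 1 nm,
#: residue 11 to the W48/I237 midpoint within 1 nm, residue 20 to W48 within 2 nm.
NANODISC_SITE = SiteDefinition(
    (
        (2, AnchorPoint.single(226, "BB"), 1.0),
        (11, AnchorPoint.midpoint((48, "BB"), (237, "BB")), 1.0),
        (20, AnchorPoint.single(48, "BB"), 2.0),
    )
)

#: Full-length apoA1 variant: helix residue 2 to LCAT Q229 and helix residue 20
#: to L239, both within 1.2 nm.
FULLLENGTH_SITE = SiteDefinition(
    (
        (2, AnchorPoint.single(229, "BB"), 1.2),
        (20, AnchorPoint.single(239, "BB"), 1.2),
    )
)


@dataclass(frozen=True)
class AnalysisWindow:
    """Equilibration cut and block count for uncertainty estimation.

    Frames with time < ``t_start_ns`` are excluded; the remaining series is
    split into ``n_blocks`` consecutive blocks whose means give the reported
    standard deviation.  The production default discards the first 1 us.
    """

    t_start_ns: float = 1000.0
    n_blocks: int = 3

    def __post_init__(self) -> None:
        if self.t_start_ns < 0:
            raise ValueError("t_start_ns must be >= 0")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")

    def frame_mask(self, times: np.ndarray) -> np.ndarray:
        return np.asarray(times) >= self.t_start_ns


# ---------------------------------------------------------------------------
# Tabular reference format


class TabularFormatError(ValueError):
    pass


def read_tabular(path) -> BeadTrajectory:
    """Read the TSV fallback trajectory format.

    Columns (exactly): frame, time_ns, mol_id, mol_type, res_index,
    bead_name, x_nm, y_nm, z_nm.  Frames must share an identical bead set and
    times must be strictly increasing.
    """
    df = pd.read_csv(path, sep="\t", dtype={"bead_name": str, "mol_type": str})
    if list(df.columns) != TABULAR_COLUMNS:
        missing = [c for c in TABULAR_COLUMNS if c not in df.columns]
        extra = [c for c in df.columns if c not in TABULAR_COLUMNS]
        raise TabularFormatError(
            f"bad header: missing columns {missing}, unexpected {extra}"
        )
    if df.empty:
        raise TabularFormatError("empty trajectory table")
    frames = sorted(df["frame"].unique())
    key_cols = ["mol_id", "mol_type", "res_index", "bead_name"]
    ref = None
    times, per_frame = [], []
    for f in frames:
        sub = df[df["frame"] == f]
        keys = list(map(tuple, sub[key_cols].itertuples(index=False, name=None)))
        if ref is None:
            ref = keys
        elif keys != ref:
            raise TabularFormatError(
                f"frame {f} bead set differs from frame {frames[0]}"
            )
        t = sub["time_ns"].unique()
        if len(t) != 1:
            raise TabularFormatError(f"frame {f} has multiple time_ns values")
        times.append(float(t[0]))
        per_frame.append(sub[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float))
    times = np.array(times)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise TabularFormatError("non-monotone frame times")
    beads = [
        BeadMeta(int(m), MolType(str(mt)), int(r), str(b)) for m, mt, r, b in ref
    ]
    return BeadTrajectory(times, np.stack(per_frame), beads)


def write_tabular(traj: BeadTrajectory, path) -> None:
    """Write the canonical TSV form (6-decimal fixed point; round-trip stable)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(TABULAR_COLUMNS) + "\n")
        for f in range(traj.n_frames):
            t = traj.times[f]
            for i, b in enumerate(traj.beads):
                x, y, z = traj.coords[f, i]
                fh.write(
                    f"{f}\t{t:.6f}\t{b.mol_id}\t{b.mol_type.value}\t"
                    f"{b.res_index}\t{b.bead_name}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n"
                )


# ---------------------------------------------------------------------------
# Topology map


@dataclass
class TopologyMap:
    """Molecule annotation table mapping file bead order to BeadMeta.

    ``molecules`` lists, in file order, entries of the form
    ``(mol_type, count, beads)`` where ``beads`` is the per-molecule list of
    (res_index, bead_name) pairs and ``count`` repeats the molecule.
    """

    molecules: list  # of (MolType, count, [(res_index, bead_name), ...])

    def expand(self) -> list:
        out, mol_id = [], 0
        for mol_type, count, beads in self.molecules:
            mt = MolType(mol_type)
            for _ in range(int(count)):
                for res_index, bead_name in beads:
                    out.append(BeadMeta(mol_id, mt, int(res_index), str(bead_name)))
                mol_id += 1
        return out

    @classmethod
    def from_yaml(cls, path) -> "TopologyMap":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict) or "molecules" not in doc:
            raise ValueError(f"{path}: topology map must have a 'molecules' list")
        mols = []
        for entry in doc["molecules"]:
            beads = [(int(r), str(b)) for r, b in entry["beads"]]
            mols.append((MolType(entry["mol_type"]), int(entry.get("count", 1)), beads))
        return cls(mols)

    def to_yaml(self, path) -> None:
        doc = {
            "molecules": [
                {
                    "mol_type": mt.value if isinstance(mt, MolType) else str(mt),
                    "count": int(count),
                    "beads": [[int(r), str(b)] for r, b in beads],
                }
                for mt, count, beads in self.molecules
            ]
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# GRO (single-frame) and XTC (delegated)


class GroParseError(ValueError):
    pass


def read_gro(path, topology_map: TopologyMap) -> BeadTrajectory:
    """Read one fixed-column GRO frame; the topology map supplies bead identity.

    GRO stores positions in nm in 8.3f columns; they are kept as stored, in
    file order.  A malformed line raises :class:`GroParseError` naming it.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if len(lines) < 3:
        raise GroParseError(f"{path}: file too short to be a GRO frame")
    try:
        n_atoms = int(lines[1].strip())
    except ValueError:
        raise GroParseError(f"{path}, line 2: atom count {lines[1]!r} not an integer")
    if n_atoms < 1:
        raise GroParseError(f"{path}: empty atom section (count {n_atoms})")
    if len(lines) < 2 + n_atoms + 1:
        raise GroParseError(
            f"{path}: {n_atoms} atoms declared but only {len(lines) - 3} atom lines"
        )
    coords = np.empty((n_atoms, 3), dtype=float)
    for i in range(n_atoms):
        ln = lines[2 + i]
        if len(ln) < 44:
            raise GroParseError(f"{path}, line {3 + i}: too short for fixed columns")
        try:
            coords[i, 0] = float(ln[20:28])
            coords[i, 1] = float(ln[28:36])
            coords[i, 2] = float(ln[36:44])
        except ValueError:
            raise GroParseError(
                f"{path}, line {3 + i}: malformed coordinate columns {ln[20:44]!r}"
            )
    box_fields = lines[2 + n_atoms].split()
    box = None
    if len(box_fields) >= 3:
        try:
            box = np.array([[float(v) for v in box_fields[:3]]])
        except ValueError:
            box = None
    beads = topology_map.expand()
    if len(beads) != n_atoms:
        raise ValueError(
            f"topology map covers {len(beads)} beads but GRO has {n_atoms} atoms"
        )
    return BeadTrajectory(np.array([0.0]), coords[None, :, :], beads, box)


def write_gro(traj: BeadTrajectory, path, frame: int = 0, title: str = "discbind") -> None:
    """Write one frame as GRO (8.3f nm columns)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(title + "\n")
        fh.write(f"{traj.n_beads:5d}\n")
        for i, b in enumerate(traj.beads):
            x, y, z = traj.coords[frame, i]
            resname = b.mol_type.value[:5]
            fh.write(
                f"{b.res_index % 100000:5d}{resname:<5s}{b.bead_name[:5]:>5s}"
                f"{(i + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
            )
        if traj.box is not None and traj.box.ndim == 2:
            bx = traj.box[min(frame, len(traj.box) - 1)]
            fh.write(f"{bx[0]:10.5f}{bx[1]:10.5f}{bx[2]:10.5f}\n")
        else:
            fh.write(f"{0.0:10.5f}{0.0:10.5f}{0.0:10.5f}\n")


def read_xtc(gro_path, xtc_path, topology_map: TopologyMap) -> BeadTrajectory:
    """Read a compressed trajectory via MDAnalysis behind the same contract.

    Requires the optional MDAnalysis dependency; coordinates are converted
    A -> nm and times ps -> ns.
    """
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "XTC ingestion needs MDAnalysis (install the 'traj' extra); "
            "the tabular format needs no extra dependency"
        ) from exc
    u = mda.Universe(str(gro_path), str(xtc_path))
    beads = topology_map.expand()
    if len(beads) != len(u.atoms):
        raise ValueError(
            f"topology map covers {len(beads)} beads but trajectory has "
            f"{len(u.atoms)} atoms"
        )
    coords, times = [], []
    for ts in u.trajectory:
        coords.append(u.atoms.positions / 10.0)
        times.append(ts.time / 1000.0)
    return BeadTrajectory(np.array(times), np.array(coords), beads)
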