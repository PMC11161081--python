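"""Synthetic bead trajectories and sequence sets with planted ground truth.

These generators emulate the geometry of a Martini-like nanodisc system —
one enzyme at the disc rim, ~28 amphipathic 22-residue peptides, ~200 lipids
— at the level the analysis layer consumes: coordinates, bead identities,
times.  The geometry is schematic (no excluded volume, no dynamics); what it
guarantees instead is *machine-checkable truth*: every planted condition
(which frames are occupied, which peptides are dissociated, where dimer
samples land) holds with explicit margins, is re-validated numerically
before a trajectory is emitted, and is returned as a
:class:`GroundTruth` object the analysis results can be compared against
exactly.

Layout in brief: lipids on a sunflower disc in the z=0 plane (three beads
per lipid, C3A tails included); enzyme anchor beads fixed just off the rim;
background peptides as compact bead clusters whose residue-13 positions sit
on a hexagonal grid with >= 2.25 nm separation (so no unplanted pair ever
enters the 0-2 nm dimer range); planted dimer pairs realised exactly by
residue-13 separation and 1->21 direction rotation; dissociated peptides
lifted to a high layer; in scheduled frames the designated occupant's
residues 2/11/20 are placed 0.5/0.5/1.0 nm from their anchors.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .seqscreen import DE4_QR7, STANDARD_AA, MoietyPattern
from .trajectory import BeadMeta, BeadTrajectory, MolType

__all__ = [
    "DiscPlantSpec",
    "GroundTruth",
    "LayoutError",
    "make_disc_trajectory",
    "make_sequence_set",
    "sequence_truth_regex",
    "make_hbond_frames",
    "HBondPlant",
]


class LayoutError(ValueError):
    """A plant specification that cannot be realised with the required margins."""


# geometry constants (nm)
R_DISC = 6.5          # lipid disc radius
GRID_Z = 0.9          # height of attached peptide centres above the disc
DISSOC_Z = 4.5        # height of the dissociated layer
GRID_SPACING = 2.25   # min residue-13 separation of non-planted peptides
GRID_RMAX = 7.8       # attached centres stay within 1.8 nm of a tail bead
ANCHOR_BASE = np.array([7.5, 0.0, 0.8])
ANCHOR_EXCLUSION = 4.5  # keep background clusters this far (xy) from the rim site
PEP_SPACING = 0.07    # backbone spacing inside a compact peptide cluster
PEP_NRES = 22

# default dimer histogram the ground truth refers to
DIMER_NX, DIMER_NY = 40, 36
DIMER_XRANGE, DIMER_YRANGE = (0.0, 2.0), (0.0, 180.0)

ANCHORS = {
    (48, "BB"): ANCHOR_BASE + np.array([0.3, 1.0, 0.2]),
    (226, "BB"): ANCHOR_BASE,
    (229, "BB"): ANCHOR_BASE + np.array([-0.1, 0.4, 0.1]),
    (237, "BB"): ANCHOR_BASE + np.array([0.3, -1.0, 0.2]),
    (239, "BB"): ANCHOR_BASE + np.array([0.1, -0.4, 0.3]),
}
LCAT_FILLER_RES = (1, 100, 150, 300)


@dataclass(frozen=True)
class DiscPlantSpec:
    """Recipe for one planted nanodisc trajectory.

    Peptide mol_ids run 1..n_peptides (the enzyme is molecule 0, lipids
    follow the peptides).  ``occupancy_schedule`` lists the frame indices in
    which the designated peptide — the lowest peptide id that is neither
    dissociated nor part of a dimer plant — satisfies the nanodisc site at
    distances (0.5, 0.5, 1.0) nm; in all other frames every peptide misses
    every cutoff by at least 0.2 nm.  ``dimer_plants`` are
    (id_i, id_j, distance_nm, angle_deg) with distance in (0, 2) and angle
    in [0, 180], realised exactly in every frame.  ``jitter_sigma`` is
    Gaussian positional noise (clipped to +-0.1 nm) applied only to beads
    that no planted condition reads.
    """

    n_peptides: int = 28
    n_lipids: int = 200
    n_frames: int = 100
    dt_ns: float = 10.0
    seed: int = 0
    occupancy_schedule: frozenset = frozenset()
    dissociated_ids: frozenset = frozenset()
    dimer_plants: tuple = ()
    jitter_sigma: float = 0.02

    def validate(self) -> None:
        if self.n_peptides < 1 or self.n_lipids < 3 or self.n_frames < 1:
            raise LayoutError("need >= 1 peptide, >= 3 lipids, >= 1 frame")
        if self.dt_ns <= 0:
            raise LayoutError("dt_ns must be > 0")
        pep_ids = set(range(1, self.n_peptides + 1))
        if not set(self.occupancy_schedule) <= set(range(self.n_frames)):
            raise LayoutError("occupancy_schedule outside [0, n_frames)")
        if not set(self.dissociated_ids) <= pep_ids:
            raise LayoutError("dissociated_ids outside peptide id range")
        seen = set()
        for i, j, d, a in self.dimer_plants:
            if i == j or not ({i, j} <= pep_ids):
                raise LayoutError(f"bad dimer plant ids ({i}, {j})")
            if {i, j} & seen:
                raise LayoutError("a peptide appears in two dimer plants")
            seen |= {i, j}
            if {i, j} & set(self.dissociated_ids):
                raise LayoutError(
                    f"dimer plant ({i}, {j}) involves a dissociated peptide"
                )
            if not (0.0 < d < 2.0):
                raise LayoutError(f"dimer distance {d} outside (0, 2) nm")
            if not (0.0 <= a <= 180.0):
                raise LayoutError(f"dimer angle {a} outside [0, 180] deg")
            # a plant sitting on an interior bin edge of the default grid
            # would make its truth bin float-ambiguous
            x_step = (DIMER_XRANGE[1] - DIMER_XRANGE[0]) / DIMER_NX
            y_step = (DIMER_YRANGE[1] - DIMER_YRANGE[0]) / DIMER_NY
            if abs(d / x_step - round(d / x_step)) * x_step < 1e-6:
                raise LayoutError(
                    f"dimer distance {d} lies on a default histogram bin edge"
                )
            if a not in (0.0, 180.0) and (
                abs(a / y_step - round(a / y_step)) * y_step < 1e-6
            ):
                raise LayoutError(
                    f"dimer angle {a} lies on a default histogram bin edge"
                )
        if self.occupancy_schedule and self.designated_id() is None:
            raise LayoutError(
                "occupancy scheduled but no peptide is free to occupy the "
                "site (all dissociated or in dimer plants)"
            )

    def designated_id(self) -> Optional[int]:
        in_dimers = {p for plant in self.dimer_plants for p in plant[:2]}
        for pid in range(1, self.n_peptides + 1):
            if pid not in self.dissociated_ids and pid not in in_dimers:
                return pid
        return None


@dataclass
class GroundTruth:
    """Machine-readable expectations derivable from a DiscPlantSpec."""

    occupied: np.ndarray          # per-frame booleans, all frames
    occupant_id: int              # designated peptide mol_id, -1 if none
    occupancy_pct: float          # over all frames (t_start = 0)
    dissociated_pct: float
    dissociated_ids: tuple
    dimer_bins: tuple             # of (ix, iy, count_per_all_frames)
    dimer_x_edges: np.ndarray
    dimer_y_edges: np.ndarray
    times: np.ndarray

    def expected_occupancy(self, t_start_ns: float = 0.0) -> float:
        mask = self.times >= t_start_ns
        if not mask.any():
            raise ValueError("no frames in window")
        return 100.0 * float(self.occupied[mask].mean())


def _hex_grid(spacing: float, r_max: float) -> np.ndarray:
    dy = spacing * math.sqrt(3.0) / 2.0
    ny = int(r_max / dy) + 1
    nx = int(r_max / spacing) + 1
    pts = []
    for row in range(-ny, ny + 1):
        y = row * dy
        off = 0.5 * spacing if row % 2 else 0.0
        for col in range(-nx, nx + 1):
            x = col * spacing + off
            if x * x + y * y <= r_max * r_max:
                pts.append((x, y))
    pts.sort(key=lambda p: (round(math.hypot(*p), 9), round(math.atan2(p[1], p[0]), 9)))
    return np.array(pts)


def _cluster_coords(center: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """22 backbone beads in a compact line; residue 13 exactly at ``center``."""
    k = np.arange(1, PEP_NRES + 1, dtype=float)
    return center[None, :] + (k - 13.0)[:, None] * PEP_SPACING * direction[None, :]


def _bound_coords() -> np.ndarray:
    """Designated-occupant geometry satisfying the nanodisc site with margin."""
    res2 = ANCHORS[(226, "BB")] + np.array([-0.5, 0.0, 0.0])
    mid = 0.5 * (ANCHORS[(48, "BB")] + ANCHORS[(237, "BB")])
    res11 = mid + np.array([-0.5, 0.0, 0.0])
    res20 = ANCHORS[(48, "BB")] + np.array([-1.0, 0.0, 0.0])
    k = np.arange(1, PEP_NRES + 1, dtype=float)
    out = np.empty((PEP_NRES, 3))
    for c in range(3):
        out[:, c] = np.interp(k, [2.0, 11.0, 20.0],
                              [res2[c], res11[c], res20[c]])
    return out


def _rot_z(deg: float) -> np.ndarray:
    t = math.radians(deg)
    return np.array([[math.cos(t), -math.sin(t), 0.0],
                     [math.sin(t), math.cos(t), 0.0],
                     [0.0, 0.0, 1.0]])


def _lipid_layout(n_lipids: int) -> np.ndarray:
    """Lipid centres (xy): a dense rim ring at R_DISC plus a sunflower interior.

    The explicit ring keeps the disc edge smooth so the attachment bound
    (residue 13 within 2 nm of a tail bead) holds with margin for peptide
    centres out to GRID_RMAX.
    """
    n_ring = min(n_lipids // 2, int(2.0 * math.pi * R_DISC / 0.8) + 1)
    th_ring = 2.0 * math.pi * np.arange(n_ring) / max(n_ring, 1)
    ring = np.stack([R_DISC * np.cos(th_ring), R_DISC * np.sin(th_ring)], axis=1)
    n_in = n_lipids - n_ring
    k = np.arange(1, n_in + 1)
    r = (R_DISC - 0.4) * np.sqrt((k - 0.5) / max(n_in, 1))
    golden = math.pi * (3.0 - math.sqrt(5.0))
    th = k * golden
    inner = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
    return np.concatenate([ring, inner]) if n_in > 0 else ring


def make_disc_trajectory(spec: DiscPlantSpec):
    """Build a planted nanodisc trajectory and its ground truth.

    Raises :class:`LayoutError` if the spec is internally inconsistent or
    cannot be laid out with the required safety margins (every planted
    condition must hold with >= 0.2 nm slack so floating-point noise cannot
    flip an outcome).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pep_ids = list(range(1, spec.n_peptides + 1))
    designated = spec.designated_id() if spec.occupancy_schedule else None
    in_dimers = {p for plant in spec.dimer_plants for p in plant[:2]}
    dissociated = sorted(spec.dissociated_ids)

    # --- choose residue-13 centres -------------------------------------
    anchor_xy = ANCHOR_BASE[:2]
    cand = [
        p for p in _hex_grid(GRID_SPACING, GRID_RMAX)
        if np.linalg.norm(p - anchor_xy) >= ANCHOR_EXCLUSION
    ]
    placed: list = []  # xy centres already used (attached layer)

    def far_enough(pt, min_sep):
        return all(np.linalg.norm(pt - q) >= min_sep - 1e-6 for q in placed)

    centers: dict = {}
    directions: dict = {}

    # pairs go to the rim first: their off-grid points fragment the grid
    # least there, leaving the dense interior for single placements
    for (i, j, d_star, theta_star) in spec.dimer_plants:
        ok = False
        for g in reversed(cand):
            rg = np.linalg.norm(g)
            v = (np.array([-g[1], g[0]]) / rg) if rg > 1e-9 else np.array([0.0, 1.0])
            ci, cj = g + 0.5 * d_star * v, g - 0.5 * d_star * v
            if any(np.linalg.norm(c) > GRID_RMAX for c in (ci, cj)):
                continue
            if any(np.linalg.norm(c - anchor_xy) < ANCHOR_EXCLUSION for c in (ci, cj)):
                continue
            if not (far_enough(ci, GRID_SPACING) and far_enough(cj, GRID_SPACING)):
                continue
            u = (g / rg) if rg > 1e-9 else np.array([1.0, 0.0])
            u3 = np.array([u[0], u[1], 0.0])
            centers[i] = np.array([ci[0], ci[1], GRID_Z])
            centers[j] = np.array([cj[0], cj[1], GRID_Z])
            directions[i] = u3
            directions[j] = _rot_z(theta_star) @ u3
            placed.extend([ci, cj])
            ok = True
            break
        if not ok:
            raise LayoutError(f"cannot place dimer plant ({i}, {j}) with margins")

    attached_singles = [
        p for p in pep_ids if p not in in_dimers and p not in spec.dissociated_ids
    ]
    for pid in attached_singles:
        spot = next((g for g in cand if far_enough(g, GRID_SPACING)), None)
        if spot is None:
            raise LayoutError(
                f"hex grid exhausted placing peptide {pid}; too many attached "
                "peptides for the disc layout"
            )
        centers[pid] = np.array([spot[0], spot[1], GRID_Z])
        r = np.linalg.norm(spot)
        u = (np.array([-spot[1], spot[0]]) / r) if r > 1e-9 else np.array([1.0, 0.0])
        directions[pid] = np.array([u[0], u[1], 0.0])
        placed.append(np.asarray(spot))

    diss_grid = _hex_grid(2.4, 9.0)
    if len(diss_grid) < len(dissociated):
        raise LayoutError("too many dissociated peptides for the high layer")
    for k, pid in enumerate(dissociated):
        g = diss_grid[k]
        centers[pid] = np.array([g[0], g[1], DISSOC_Z])
        directions[pid] = np.array([1.0, 0.0, 0.0])

    # --- assemble beads -------------------------------------------------
    beads: list = []
    base: list = []
    for res in sorted(set(r for r, _b in ANCHORS) | set(LCAT_FILLER_RES)):
        beads.append(BeadMeta(0, MolType.LCAT, res, "BB"))
        if (res, "BB") in ANCHORS:
            base.append(ANCHORS[(res, "BB")])
        else:
            base.append(ANCHOR_BASE + np.array([0.5, 0.0, 0.4])
                        + 0.1 * np.array([res % 3, res % 5, res % 7]))
    lcat_filler_idx = [
        i for i, b in enumerate(beads) if b.res_index in LCAT_FILLER_RES
        and (b.res_index, "BB") not in ANCHORS
    ]

    pep_bead_rows: dict = {}
    jitterable_pep_rows: list = []
    metric_res = {1, 2, 11, 13, 20, 21}
    for pid in pep_ids:
        rows = []
        for res in range(1, PEP_NRES + 1):
            rows.append(len(beads))
            beads.append(BeadMeta(pid, MolType.PEPTIDE, res, "BB"))
            if res not in metric_res and pid != designated:
                jitterable_pep_rows.append(rows[-1])
        pep_bead_rows[pid] = rows
        base.extend(_cluster_coords(centers[pid], directions[pid]))

    lipid_xy = _lipid_layout(spec.n_lipids)
    lipid_bead_z = {"PO4": 0.2, "GL1": 0.0, "C3A": -0.1}
    lipid_jitter_rows = []
    first_lipid_mol = spec.n_peptides + 1
    for li in range(spec.n_lipids):
        for name, z in lipid_bead_z.items():
            if name != "C3A":
                lipid_jitter_rows.append(len(beads))
            beads.append(BeadMeta(first_lipid_mol + li, MolType.LIPID, 1, name))
            base.append(np.array([lipid_xy[li, 0], lipid_xy[li, 1], z]))
    base = np.asarray(base)

    # --- frames ----------------------------------------------------------
    bound = _bound_coords()
    jit_rows = np.array(lipid_jitter_rows + jitterable_pep_rows + lcat_filler_idx,
                        dtype=int)
    coords = np.empty((spec.n_frames, len(beads), 3))
    sched = set(spec.occupancy_schedule)
    for f in range(spec.n_frames):
        frame = base.copy()
        if designated is not None and f in sched:
            frame[pep_bead_rows[designated]] = bound
        if spec.jitter_sigma > 0 and len(jit_rows):
            noise = rng.normal(0.0, spec.jitter_sigma, size=(len(jit_rows), 3))
            frame[jit_rows] += np.clip(noise, -0.1, 0.1)
        coords[f] = frame
    times = np.arange(spec.n_frames, dtype=float) * spec.dt_ns
    traj = BeadTrajectory(times, coords, beads)

    # --- ground truth ----------------------------------------------------
    occupied = np.zeros(spec.n_frames, dtype=bool)
    if designated is not None:
        occupied[sorted(sched)] = True
    x_edges = np.linspace(*DIMER_XRANGE, DIMER_NX + 1)
    y_edges = np.linspace(*DIMER_YRANGE, DIMER_NY + 1)
    bin_counts: dict = {}
    for (_i, _j, d_star, theta_star) in spec.dimer_plants:
        ix = min(int(np.searchsorted(x_edges, d_star, side="right")) - 1, DIMER_NX - 1)
        iy = min(int(np.searchsorted(y_edges, theta_star, side="right")) - 1, DIMER_NY - 1)
        bin_counts[(ix, iy)] = bin_counts.get((ix, iy), 0) + spec.n_frames
    truth = GroundTruth(
        occupied=occupied,
        occupant_id=designated if designated is not None else -1,
        occupancy_pct=100.0 * float(occupied.mean()),
        dissociated_pct=100.0 * len(dissociated) / spec.n_peptides,
        dissociated_ids=tuple(dissociated),
        dimer_bins=tuple((ix, iy, c) for (ix, iy), c in sorted(bin_counts.items())),
        dimer_x_edges=x_edges,
        dimer_y_edges=y_edges,
        times=times,
    )
    _validate_layout(traj, spec, centers, directions, designated)
    return traj, truth


def _validate_layout(traj, spec, centers, directions, designated) -> None:
    """Numerically confirm every planted condition holds with margin."""
    from .trajectory import NANODISC_SITE

    margin = 0.2
    site = NANODISC_SITE
    # representative frames: one scheduled (if any), one not (if any);
    # metric beads are frame-constant apart from the designated toggle

    sched = sorted(spec.occupancy_schedule)
    reps = []
    if sched:
        reps.append((sched[0], True))
    unsched = next((f for f in range(spec.n_frames) if f not in set(sched)), None)
    if unsched is not None:
        reps.append((unsched, False))
    for f, is_sched in reps:
        for (res, anchor, cutoff) in site.constraints:
            apos = anchor.positions(traj, 0)[f]
            for pid in range(1, spec.n_peptides + 1):
                p = traj.coords[f, traj.bead_index(pid, res, "BB")]
                d = float(np.linalg.norm(p - apos))
                if pid == designated and is_sched:
                    if d > cutoff - margin:
                        raise LayoutError(
                            f"occupant residue {res} misses its margin ({d:.3f} nm)"
                        )
                elif d < cutoff + margin:
                    raise LayoutError(
                        f"peptide {pid} residue {res} too close to an anchor "
                        f"({d:.3f} nm vs cutoff {cutoff})"
                    )
    # dissociation margins (residue 13 vs C3A tails; static beads: frame 0
    # suffices, plus a scheduled frame for the designated peptide)
    c3a = [i for i, b in enumerate(traj.beads)
           if b.mol_type == MolType.LIPID and b.bead_name == "C3A"]
    check_frames = {0} | ({sched[0]} if sched else set())
    for f in check_frames:
        tails = traj.coords[f, c3a]
        for pid in range(1, spec.n_peptides + 1):
            r13 = traj.coords[f, traj.bead_index(pid, 13, "BB")]
            mind = float(np.linalg.norm(tails - r13, axis=1).min())
            if pid in spec.dissociated_ids:
                if mind < 2.0 + margin:
                    raise LayoutError(f"dissociated peptide {pid} margin ({mind:.3f})")
            elif mind > 2.0 - margin:
                raise LayoutError(f"attached peptide {pid} margin ({mind:.3f})")
    # dimer exactness and pairwise separation
    planted = {frozenset((i, j)): (d, a) for i, j, d, a in spec.dimer_plants}
    for f in check_frames:
        for i in range(1, spec.n_peptides + 1):
            for j in range(i + 1, spec.n_peptides + 1):
                ri = traj.coords[f, traj.bead_index(i, 13, "BB")]
                rj = traj.coords[f, traj.bead_index(j, 13, "BB")]
                d = float(np.linalg.norm(ri - rj))
                key = frozenset((i, j))
                if key in planted:
                    d_star, a_star = planted[key]
                    ui = (traj.coords[f, traj.bead_index(i, 21, "BB")]
                          - traj.coords[f, traj.bead_index(i, 1, "BB")])
                    uj = (traj.coords[f, traj.bead_index(j, 21, "BB")]
                          - traj.coords[f, traj.bead_index(j, 1, "BB")])
                    cosang = np.clip(
                        np.dot(ui, uj) / (np.linalg.norm(ui) * np.linalg.norm(uj)),
                        -1.0, 1.0)
                    ang = math.degrees(math.acos(cosang))
                    if abs(d - d_star) > 1e-9 or abs(ang - a_star) > 1e-6:
                        raise LayoutError(
                            f"dimer plant ({i}, {j}) realised at ({d:.6f} nm, "
                            f"{ang:.4f} deg) instead of ({d_star}, {a_star})"
                        )
                elif d < 2.0 + margin:
                    raise LayoutError(
                        f"unplanted pair ({i}, {j}) at {d:.3f} nm enters the "
                        "dimer histogram range"
                    )


# ---------------------------------------------------------------------------
# Sequence sets


def sequence_truth_regex(pattern: MoietyPattern) -> str:
    """Overlapping-match regex equivalent of a MoietyPattern (oracle form)."""
    def body(constraints):
        cells = ["."] * pattern.window
        for pos, allowed in constraints:
            cells[pos - 1] = "[" + "".join(sorted(allowed)) + "]"
        return "".join(cells)

    if pattern.any_of:
        alts = [
            body(tuple(pattern.constraints) + (grp,)) for grp in pattern.any_of
        ]
        return "(?=(" + "|".join(alts) + "))"
    return "(?=(" + body(pattern.constraints) + "))"


def make_sequence_set(
    n: int,
    length: int = 60,
    planted: Sequence = (),
    background_composition: Optional[dict] = None,
    seed: int = 0,
    pattern: MoietyPattern = DE4_QR7,
):
    """Random protein sequences with moiety plants and oracle-computed truth.

    ``planted`` lists (record_index, start) insertions: the pattern's
    constrained positions inside the window starting there are set to
    admissible residues.  The truth table is NOT the plant list: it is a
    brute-force regular-expression scan of the emitted sequences, so
    background coincidences are part of the truth.

    Returns ``(records, truth)`` with records as (id, sequence) pairs and
    truth as a list of (record_id, start) hits in scan order.
    """
    rng = np.random.default_rng(seed)
    letters = sorted(STANDARD_AA)
    if background_composition:
        probs = np.array([background_composition.get(a, 0.0) for a in letters])
        if probs.sum() <= 0:
            raise ValueError("background composition sums to zero")
        probs = probs / probs.sum()
    else:
        probs = np.full(len(letters), 1.0 / len(letters))
    seqs = [
        "".join(rng.choice(letters, size=length, p=probs)) for _ in range(n)
    ]
    assignment: dict = {}
    for rec, start in planted:
        if not (0 <= rec < n):
            raise ValueError(f"plant record {rec} out of range")
        if not (1 <= start and start + pattern.window - 1 <= length):
            raise ValueError(f"plant start {start} leaves no full window")
        groups = list(pattern.constraints)
        if pattern.any_of:
            groups.append(pattern.any_of[0])
        for pos, allowed in groups:
            abspos = start + pos - 1
            letter = str(rng.choice(sorted(allowed)))
            prev = assignment.get((rec, abspos))
            if prev is not None and prev not in allowed:
                raise ValueError(
                    f"overlapping plants conflict at record {rec} "
                    f"position {abspos}"
                )
            if prev is None:
                assignment[(rec, abspos)] = letter
    for (rec, abspos), letter in assignment.items():
        s = seqs[rec]
        seqs[rec] = s[: abspos - 1] + letter + s[abspos:]
    records = [(f"synth_{i:04d}", seqs[i]) for i in range(n)]
    rx = re.compile(sequence_truth_regex(pattern))
    truth = [
        (rid, m.start() + 1)
        for rid, seq in records
        for m in rx.finditer(seq)
    ]
    return records, truth


def write_fasta(records, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Hydrogen-bond frames


@dataclass
class HBondPlant:
    trajectory: BeadTrajectory
    spec: "object"  # HBondSpec
    on_frames: np.ndarray
    rate: float  # realised planted occupancy fraction


def make_hbond_frames(p: float, n_frames: int, seed: int = 0,
                      dt_ns: float = 0.1) -> HBondPlant:
    """Donor/hydrogen/acceptor triples toggling a geometric hydrogen bond.

    Bond-on frames satisfy the 0.35 nm / 30 degree rule with >= 0.1 nm /
    30 degree slack; bond-off frames violate the distance by >= 0.2 nm.  The
    realised Bernoulli(p) rate is recorded as truth.
    """
    from .structure import HBondSpec

    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be in [0, 1]")
    rng = np.random.default_rng(seed)
    on = rng.random(n_frames) < p
    beads = [
        BeadMeta(0, MolType.OTHER, 1, "N"),
        BeadMeta(0, MolType.OTHER, 1, "HN"),
        BeadMeta(0, MolType.OTHER, 2, "O"),
    ]
    coords = np.zeros((n_frames, 3, 3))
    coords[:, 1, 0] = 0.10  # hydrogen on the donor-acceptor axis
    coords[:, 2, 0] = np.where(on, 0.25, 0.60)
    times = np.arange(n_frames, dtype=float) * dt_ns
    traj = BeadTrajectory(times, coords, beads)
    spec = HBondSpec(donor=(0, 1, "N"), hydrogen=(0, 1, "HN"),
                     acceptor=(0, 2, "O"))
    return HBondPlant(traj, spec, on, float(on.mean()))
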