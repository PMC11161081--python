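"""Nanodisc packing metrics: dimerization profiles, dissociation, plane fits.

Dimerization is characterised by 2D angle-distance histograms over all
peptide pairs: the residue-13 backbone distance (0-2 nm) against the angle
between the residue 1 -> 21 direction vectors (0-180 degrees).  A peptide is
dissociated from the bilayer when its residue-13 backbone bead is strictly
more than 2 nm from every lipid C3A tail bead.  Position densities express a
reference point in disc-frame cylindrical coordinates after least-squares
fitting a plane to all lipid beads each frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Optional, Sequence

import numpy as np

from .binding import block_stats
from .trajectory import AnalysisWindow, BeadTrajectory, MolType, select_beads

__all__ = [
    "Histogram2D",
    "DiscPlane",
    "DissociationResult",
    "pair_angle_distance",
    "dimerization_histogram",
    "dissociated_fraction",
    "fit_disc_plane",
    "position_density",
    "lcat_position_density",
    "peptide_position_density",
]


@dataclass
class Histogram2D:
    """Binned 2D counts with explicit edges and mass bookkeeping.

    ``sum(counts) + n_out_of_range == n_samples_total`` always holds; samples
    outside the x-range are part of the metric's definition (the axis range)
    and are tracked, not silently dropped.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    n_samples_total: int
    n_out_of_range: int

    def __post_init__(self) -> None:
        self.x_edges = np.asarray(self.x_edges, dtype=float)
        self.y_edges = np.asarray(self.y_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.x_edges) - 1, len(self.y_edges) - 1):
            raise ValueError("counts grid does not match bin edges")
        if (self.counts < 0).any():
            raise ValueError("negative bin count")
        if int(self.counts.sum()) + self.n_out_of_range != self.n_samples_total:
            raise ValueError(
                "histogram mass not conserved: "
                f"{int(self.counts.sum())} + {self.n_out_of_range} != "
                f"{self.n_samples_total}"
            )

    def bin_of(self, x: float, y: float):
        """(ix, iy) of the bin containing (x, y); None if out of range."""
        if not (self.x_edges[0] <= x <= self.x_edges[-1]):
            return None
        if not (self.y_edges[0] <= y <= self.y_edges[-1]):
            return None
        ix = min(int(np.searchsorted(self.x_edges, x, side="right")) - 1,
                 len(self.x_edges) - 2)
        iy = min(int(np.searchsorted(self.y_edges, y, side="right")) - 1,
                 len(self.y_edges) - 2)
        return ix, iy

    def normalized(self, reference_max: float) -> np.ndarray:
        """Counts scaled by an externally supplied reference maximum."""
        if reference_max <= 0:
            raise ValueError("reference_max must be > 0")
        return self.counts / float(reference_max)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("x_lo\tx_hi\ty_lo\ty_hi\tcount\n")
            for i in range(self.counts.shape[0]):
                for j in range(self.counts.shape[1]):
                    fh.write(
                        f"{self.x_edges[i]:.6f}\t{self.x_edges[i + 1]:.6f}\t"
                        f"{self.y_edges[j]:.6f}\t{self.y_edges[j + 1]:.6f}\t"
                        f"{int(self.counts[i, j])}\n"
                    )


@dataclass(frozen=True)
class DiscPlane:
    centroid: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-12:
            raise ValueError("plane normal must be unit length")

    def height(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.centroid) @ self.normal

    def radial(self, points: np.ndarray) -> np.ndarray:
        rel = np.atleast_2d(points) - self.centroid
        h = rel @ self.normal
        return np.linalg.norm(rel - np.outer(h, self.normal), axis=1)


def _pep_bead_matrix(traj: BeadTrajectory, res_index: int, bead_name: str = "BB"):
    """Coordinates (n_frames, n_peptides, 3) of one residue's bead per peptide."""
    pids = traj.mol_ids(MolType.PEPTIDE)
    idx = [traj.bead_index(p, res_index, bead_name) for p in pids]
    return traj.coords[:, idx, :], pids


def pair_angle_distance(traj: BeadTrajectory, frame: int, mol_i: int, mol_j: int):
    """Residue-13 distance (nm) and 1->21 direction angle (deg) for one pair.

    Symmetric in (i, j); the angle is the arccos of the normalised dot
    product clipped to [-1, 1], in [0, 180].
    """
    r13_i = traj.coords[frame, traj.bead_index(mol_i, 13, "BB")]
    r13_j = traj.coords[frame, traj.bead_index(mol_j, 13, "BB")]
    d = float(np.linalg.norm(r13_i - r13_j))
    u = (traj.coords[frame, traj.bead_index(mol_i, 21, "BB")]
         - traj.coords[frame, traj.bead_index(mol_i, 1, "BB")])
    v = (traj.coords[frame, traj.bead_index(mol_j, 21, "BB")]
         - traj.coords[frame, traj.bead_index(mol_j, 1, "BB")])
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError(
            f"zero-length 1->21 direction vector (peptides {mol_i}, {mol_j})"
        )
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return d, float(np.degrees(np.arccos(cosang)))


def dimerization_histogram(
    traj: BeadTrajectory,
    window: AnalysisWindow,
    x_range=(0.0, 2.0),
    y_range=(0.0, 180.0),
    nx: int = 40,
    ny: int = 36,
) -> Histogram2D:
    """Angle-distance histogram over all unordered peptide pairs per frame.

    Samples whose distance falls outside ``x_range`` are excluded from the
    grid and counted in ``n_out_of_range``.
    """
    mask = window.frame_mask(traj.times)
    if not mask.any():
        raise ValueError(f"no frames at or after t_start = {window.t_start_ns} ns")
    r13, pids = _pep_bead_matrix(traj, 13)
    if len(pids) < 2:
        raise ValueError(f"need at least 2 peptides, found {len(pids)}")
    r1, _ = _pep_bead_matrix(traj, 1)
    r21, _ = _pep_bead_matrix(traj, 21)
    dirs = r21 - r1
    norms = np.linalg.norm(dirs, axis=2)
    if np.any(norms == 0.0):
        raise ValueError("zero-length 1->21 direction vector in trajectory")
    iu, ju = np.triu_indices(len(pids), k=1)
    r13, dirs, norms = r13[mask], dirs[mask], norms[mask]
    dist = np.linalg.norm(r13[:, iu, :] - r13[:, ju, :], axis=2)  # (F, n_pairs)
    dots = np.einsum("fpc,fpc->fp", dirs[:, iu, :], dirs[:, ju, :])
    cosang = np.clip(dots / (norms[:, iu] * norms[:, ju]), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    dist, ang = dist.ravel(), ang.ravel()
    in_range = (dist >= x_range[0]) & (dist <= x_range[1])
    x_edges = np.linspace(x_range[0], x_range[1], nx + 1)
    y_edges = np.linspace(y_range[0], y_range[1], ny + 1)
    counts, _, _ = np.histogram2d(dist[in_range], ang[in_range],
                                  bins=[x_edges, y_edges])
    return Histogram2D(
        x_edges,
        y_edges,
        counts.astype(int),
        n_samples_total=dist.size,
        n_out_of_range=int((~in_range).sum()),
    )


@dataclass
class DissociationResult:
    percentage: float
    block_std: float
    block_means: tuple
    per_frame_counts: np.ndarray
    times: np.ndarray
    n_peptides: int


def dissociated_fraction(
    traj: BeadTrajectory,
    window: AnalysisWindow,
    cutoff: float = 2.0,
) -> DissociationResult:
    """Percentage of peptides detached from the bilayer.

    A peptide is dissociated in a frame iff the minimum distance from its
    residue-13 backbone bead to every lipid C3A tail bead is strictly greater
    than ``cutoff``.  The percentage averages the per-frame dissociated
    fraction over the analysis window.
    """
    mask = window.frame_mask(traj.times)
    if not mask.any():
        raise ValueError(f"no frames at or after t_start = {window.t_start_ns} ns")
    r13, pids = _pep_bead_matrix(traj, 13)
    if not pids:
        raise ValueError("no peptides in trajectory")
    c3a = select_beads(traj, mol_type=MolType.LIPID, bead_name="C3A")
    if len(c3a) == 0:
        raise ValueError("no lipid C3A beads in trajectory")
    tails = traj.coords[:, c3a, :][mask]  # (F, L, 3)
    r13 = r13[mask]
    diff = r13[:, :, None, :] - tails[:, None, :, :]
    mind = np.sqrt((diff ** 2).sum(axis=3)).min(axis=2)  # (F, P)
    dissoc = mind > cutoff
    counts = dissoc.sum(axis=1)
    frac_pct = 100.0 * counts / len(pids)
    bs = block_stats(frac_pct, window.n_blocks)
    return DissociationResult(
        percentage=float(frac_pct.mean()),
        block_std=bs.std,
        block_means=bs.block_means,
        per_frame_counts=counts,
        times=traj.times[mask],
        n_peptides=len(pids),
    )


def fit_disc_plane(points: np.ndarray, orient_toward: Optional[np.ndarray] = None) -> DiscPlane:
    """Least-squares plane through a point set.

    The normal is the smallest principal axis of the centred covariance
    (total least squares).  Its sign is chosen so ``orient_toward`` (e.g. the
    enzyme centroid) has non-negative height; without a reference the normal
    points toward +z.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValueError("plane fit needs >= 3 points of shape (n, 3)")
    centroid = pts.mean(axis=0)
    _u, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    if s[1] <= 1e-10 * max(s[0], 1e-30):
        raise ValueError("degenerate (collinear) point set: plane undefined")
    normal = vt[2]
    normal = normal / np.linalg.norm(normal)
    if orient_toward is not None:
        if np.dot(np.asarray(orient_toward) - centroid, normal) < 0:
            normal = -normal
    elif normal[2] < 0:
        normal = -normal
    return DiscPlane(centroid, normal)


def position_density(
    traj: BeadTrajectory,
    window: AnalysisWindow,
    reference_points: Callable[[BeadTrajectory, int], np.ndarray],
    r_max: float,
    h_range,
    nr: int = 40,
    nh: int = 40,
    signed: bool = True,
) -> Histogram2D:
    """Radial-height density of reference points in the disc frame.

    Per analysed frame the plane is refit to all lipid beads (the disc
    tumbles) and oriented toward the enzyme centroid; each reference point
    contributes one (in-plane radial distance, height along normal) sample.
    With ``signed=False`` the absolute height is used.
    """
    mask = window.frame_mask(traj.times)
    if not mask.any():
        raise ValueError(f"no frames at or after t_start = {window.t_start_ns} ns")
    lipid_idx = select_beads(traj, mol_type=MolType.LIPID)
    if len(lipid_idx) < 3:
        raise ValueError("plane fit needs lipid beads")
    lcat_idx = select_beads(traj, mol_type=MolType.LCAT, bead_name="BB")
    x_edges = np.linspace(0.0, r_max, nr + 1)
    y_edges = np.linspace(h_range[0], h_range[1], nh + 1)
    counts = np.zeros((nr, nh), dtype=int)
    total = 0
    oob = 0
    for f in np.flatnonzero(mask):
        orient = (traj.coords[f, lcat_idx].mean(axis=0)
                  if len(lcat_idx) else None)
        plane = fit_disc_plane(traj.coords[f, lipid_idx], orient_toward=orient)
        refs = np.atleast_2d(reference_points(traj, f))
        r = plane.radial(refs)
        h = plane.height(refs)
        if not signed:
            h = np.abs(h)
        total += len(refs)
        ok = (r >= 0) & (r <= r_max) & (h >= y_edges[0]) & (h <= y_edges[-1])
        oob += int((~ok).sum())
        c, _, _ = np.histogram2d(r[ok], h[ok], bins=[x_edges, y_edges])
        counts += c.astype(int)
    return Histogram2D(x_edges, y_edges, counts, total, oob)


def lcat_position_density(
    traj: BeadTrajectory,
    window: AnalysisWindow,
    r_max: float = 10.0,
    h_range=(-5.0, 5.0),
    nr: int = 40,
    nh: int = 40,
) -> Histogram2D:
    """Density of the enzyme's backbone centroid: signed height over [-5, 5] nm."""
    lcat_idx = select_beads(traj, mol_type=MolType.LCAT, bead_name="BB")
    if len(lcat_idx) == 0:
        raise ValueError("no LCAT BB beads in trajectory")

    def ref(t: BeadTrajectory, f: int) -> np.ndarray:
        return t.coords[f, lcat_idx].mean(axis=0)

    return position_density(traj, window, ref, r_max, h_range, nr, nh, signed=True)


def peptide_position_density(
    traj: BeadTrajectory,
    window: AnalysisWindow,
    r_max: float = 7.0,
    h_range=(0.0, 3.5),
    nr: int = 40,
    nh: int = 40,
    signed: bool = False,
) -> Histogram2D:
    """Density of peptide residue-13 backbone beads: absolute height 0-3.5 nm."""
    pids = traj.mol_ids(MolType.PEPTIDE)
    if not pids:
        raise ValueError("no peptides in trajectory")
    idx = [traj.bead_index(p, 13, "BB") for p in pids]

    def ref(t: BeadTrajectory, f: int) -> np.ndarray:
        return t.coords[f, idx]

    return position_density(traj, window, ref, r_max, h_range, nr, nh, signed=signed)
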