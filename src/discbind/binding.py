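"""Binding-site occupancy: nearest-peptide selection, block statistics, events.

The occupancy metric asks, frame by frame, whether the peptide nearest to the
enzyme's lid/MBD cavity satisfies every distance constraint of a
:class:`~discbind.trajectory.SiteDefinition`.  "Nearest" means smallest
unweighted sum of the per-constraint Euclidean distances; occupancy is the
percentage of analysed frames in which that nearest peptide passes every
cutoff (strict ``<``).  Uncertainty comes from block averaging: the analysed
series is split into equal consecutive blocks and the sample standard
deviation of the block means is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .trajectory import (
    AnalysisWindow,
    BeadTrajectory,
    FULLLENGTH_SITE,
    MolType,
    SiteDefinition,
)

__all__ = [
    "BindingEvent",
    "BlockStats",
    "OccupancyResult",
    "nearest_peptide",
    "frame_occupied",
    "occupancy",
    "block_stats",
    "longest_event",
    "helix_occupancy",
]


@dataclass(frozen=True)
class BindingEvent:
    """A maximal run of occupied frames with a constant occupant."""

    start_ns: float
    end_ns: float
    occupant: int
    duration_ns: float


@dataclass(frozen=True)
class BlockStats:
    mean: float
    std: float
    block_means: tuple
    single_block: bool = False


@dataclass
class OccupancyResult:
    """Per-frame occupancy series and its summary statistics.

    ``occupant`` records the nearest peptide every analysed frame, whether or
    not the frame is occupied; ``occupied`` is true only when that peptide
    passes every cutoff.  ``events`` are maximal occupied runs with constant
    occupant; an occupant switch ends an event.
    """

    times: np.ndarray
    occupied: np.ndarray
    occupant: np.ndarray
    distances: np.ndarray  # (frames_analyzed, n_constraints) of nearest peptide
    occupancy_pct: float
    block_means: tuple
    block_std: float
    events: list
    single_block_warning: bool = False

    @property
    def frames_analyzed(self) -> int:
        return len(self.times)


def _resolve_lcat(traj: BeadTrajectory, lcat_mol_id: Optional[int]) -> int:
    if lcat_mol_id is not None:
        return lcat_mol_id
    ids = traj.mol_ids(MolType.LCAT)
    if len(ids) != 1:
        raise ValueError(
            f"expected exactly one LCAT molecule, found {len(ids)}; "
            "pass lcat_mol_id explicitly"
        )
    return ids[0]


def _site_distance_tensor(
    traj: BeadTrajectory,
    site: SiteDefinition,
    lcat_mol_id: Optional[int] = None,
    peptide_ids: Optional[Sequence[int]] = None,
):
    """Distances (n_frames, n_peptides, n_constraints) plus sorted peptide ids."""
    lcat = _resolve_lcat(traj, lcat_mol_id)
    if peptide_ids is None:
        peptide_ids = traj.mol_ids(MolType.PEPTIDE)
    peptide_ids = sorted(peptide_ids)
    if not peptide_ids:
        raise ValueError("no peptide molecules in trajectory")
    n_c = len(site.constraints)
    dists = np.empty((traj.n_frames, len(peptide_ids), n_c))
    for c, (res, anchor, _cut) in enumerate(site.constraints):
        anchor_pos = anchor.positions(traj, lcat)  # (F, 3)
        idx = []
        for pid in peptide_ids:
            try:
                idx.append(traj.bead_index(pid, res, site.peptide_bead_name))
            except KeyError:
                raise KeyError(
                    f"peptide {pid} has no residue {res} bead "
                    f"{site.peptide_bead_name!r} required by the site"
                ) from None
        pep = traj.coords[:, idx, :]  # (F, P, 3)
        dists[:, :, c] = np.linalg.norm(pep - anchor_pos[:, None, :], axis=2)
    return dists, np.asarray(peptide_ids)


def nearest_peptide(
    traj: BeadTrajectory,
    frame: int,
    site: SiteDefinition,
    lcat_mol_id: Optional[int] = None,
):
    """Nearest peptide in one frame.

    Returns ``(mol_id, per_constraint_distances, combined_distance)`` where
    the combined distance is the unweighted sum; ties go to the lowest
    mol_id.
    """
    dists, pids = _site_distance_tensor(traj, site, lcat_mol_id)
    combined = dists[frame].sum(axis=1)
    k = int(np.argmin(combined))  # first minimum = lowest mol_id (pids sorted)
    return int(pids[k]), dists[frame, k].copy(), float(combined[k])


def frame_occupied(
    traj: BeadTrajectory,
    frame: int,
    site: SiteDefinition,
    lcat_mol_id: Optional[int] = None,
) -> bool:
    """True iff every constraint distance of the nearest peptide is < its cutoff."""
    _pid, d, _comb = nearest_peptide(traj, frame, site, lcat_mol_id)
    return bool(np.all(d < site.cutoffs))


def block_stats(series, n_blocks: int) -> BlockStats:
    """Mean of a series and the sample std of its consecutive block means.

    The series is split into ``n_blocks`` blocks of ``floor(n/n_blocks)``
    entries; remainder entries are appended to the last block.  The std uses
    the n-1 denominator.  With a single block the std is reported as 0 and
    flagged.
    """
    series = np.asarray(series, dtype=float)
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    n = len(series)
    if n < n_blocks:
        raise ValueError(f"series of length {n} cannot form {n_blocks} blocks")
    size = n // n_blocks
    means = []
    for b in range(n_blocks):
        lo = b * size
        hi = (b + 1) * size if b < n_blocks - 1 else n
        means.append(float(series[lo:hi].mean()))
    if n_blocks == 1:
        warnings.warn("single block: block std is not meaningful", stacklevel=2)
        return BlockStats(means[0], 0.0, tuple(means), single_block=True)
    return BlockStats(
        float(series.mean()), float(np.std(means, ddof=1)), tuple(means)
    )


def _events_from_series(times, occupied, occupant) -> list:
    if len(times) == 0 or not occupied.any():
        return []
    dt = float(np.median(np.diff(times))) if len(times) > 1 else 0.0
    events = []
    start = None
    for i in range(len(times)):
        if occupied[i]:
            if start is None or occupant[i] != occupant[start]:
                if start is not None:
                    events.append((start, i - 1))
                start = i
        else:
            if start is not None:
                events.append((start, i - 1))
                start = None
    if start is not None:
        events.append((start, len(times) - 1))
    out = []
    for a, b in events:
        t0, t1 = float(times[a]), float(times[b])
        out.append(BindingEvent(t0, t1, int(occupant[a]), (t1 - t0) + dt))
    return out


def occupancy(
    traj: BeadTrajectory,
    site: SiteDefinition,
    window: AnalysisWindow,
    lcat_mol_id: Optional[int] = None,
) -> OccupancyResult:
    """Occupancy over the analysis window, with block statistics and events."""
    mask = window.frame_mask(traj.times)
    if not mask.any():
        raise ValueError(
            f"no frames at or after t_start = {window.t_start_ns} ns"
        )
    dists, pids = _site_distance_tensor(traj, site, lcat_mol_id)
    dists = dists[mask]
    times = traj.times[mask]
    combined = dists.sum(axis=2)  # (F, P)
    nearest = np.argmin(combined, axis=1)  # first min = lowest mol_id
    rows = np.arange(dists.shape[0])
    nearest_d = dists[rows, nearest, :]  # (F, C)
    occupied = np.all(nearest_d < site.cutoffs[None, :], axis=1)
    occupant = pids[nearest]
    pct = 100.0 * float(occupied.mean())
    bs = block_stats(occupied.astype(float) * 100.0, window.n_blocks)
    events = _events_from_series(times, occupied, occupant)
    return OccupancyResult(
        times=times,
        occupied=occupied,
        occupant=occupant,
        distances=nearest_d,
        occupancy_pct=pct,
        block_means=bs.block_means,
        block_std=bs.std,
        events=events,
        single_block_warning=bs.single_block,
    )


def longest_event(result: OccupancyResult) -> float:
    """Longest binding-event duration in ns; 0 with no events."""
    if not result.events:
        return 0.0
    return max(e.duration_ns for e in result.events)


def helix_occupancy(
    traj: BeadTrajectory,
    helix_ranges: Sequence,
    site: SiteDefinition = FULLLENGTH_SITE,
    window: Optional[AnalysisWindow] = None,
    lcat_mol_id: Optional[int] = None,
    chain_mol_type: MolType = MolType.PEPTIDE,
) -> pd.DataFrame:
    """Per-helix per-frame occupancy table for full-length chains.

    Each helix ``(label, first_res, last_res)`` is tested independently: the
    helix is occupied in a frame if ANY chain has its residue ``first+1``
    within the first cutoff of its anchor and residue ``first+19`` within the
    second (both strict).  Multiple helices may be simultaneously true.
    """
    if window is None:
        window = AnalysisWindow(t_start_ns=0.0)
    lcat = _resolve_lcat(traj, lcat_mol_id)
    chains = traj.mol_ids(chain_mol_type)
    if not chains:
        raise ValueError(f"no {chain_mol_type.value} chains in trajectory")
    mask = window.frame_mask(traj.times)
    if not mask.any():
        raise ValueError(f"no frames at or after t_start = {window.t_start_ns} ns")
    anchors = [a.positions(traj, lcat)[mask] for _r, a, _c in site.constraints]
    cutoffs = site.cutoffs
    # site constraint residues are defined relative to the helix start:
    # constraint k at helix residue (first + res_k - 1)
    rel = [res for res, _a, _c in site.constraints]
    data = {}
    for label, first, last in helix_ranges:
        if last - first + 1 < 20:
            raise ValueError(
                f"helix {label!r} spans {last - first + 1} residues; "
                "at least 20 required to place residues 2 and 20"
            )
        ok = np.zeros(int(mask.sum()), dtype=bool)
        for chain in chains:
            chain_ok = np.ones_like(ok)
            for k, res_rel in enumerate(rel):
                res = first + res_rel - 1
                try:
                    bi = traj.bead_index(chain, res, site.peptide_bead_name)
                except KeyError:
                    chain_ok[:] = False
                    break
                d = np.linalg.norm(traj.coords[mask, bi, :] - anchors[k], axis=1)
                chain_ok &= d < cutoffs[k]
            ok |= chain_ok
        data[label] = ok
    return pd.DataFrame(data, index=pd.Index(traj.times[mask], name="time_ns"))
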