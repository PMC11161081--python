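"""Atomistic-side metrics: geometric hydrogen bonds, SASA differencing,
bead-bead distance series.

Hydrogen bonds use the geometric criterion of the classic VMD plugin:
donor-acceptor distance < 0.35 nm and the angle at the donor between the
D->H and D->A vectors < 30 degrees.  Because only the plugin is named by
convention, the alternative criterion (deviation of the D-H-A angle from
linearity) is selectable.

Per-residue solvent-accessible surface areas are consumed as input tables
(computed upstream with a standard tool); this module only differences them.
Under the default sign convention a NEGATIVE difference marks a residue
protected from water when the enzyme sits on the nanodisc.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .trajectory import AnalysisWindow, BeadTrajectory

__all__ = [
    "HBondSpec",
    "hbond_geometry",
    "hbond_present",
    "hbond_occupancy",
    "sasa_difference",
    "read_sasa_table",
    "xvg_frames_to_sasa_table",
    "distance_timeseries",
]


@dataclass(frozen=True)
class HBondSpec:
    """Donor/hydrogen/acceptor bead references with geometric cutoffs.

    Each reference is a (mol_id, res_index, bead_name) triple.  Which atoms
    can donate or accept is the caller's declaration; no topology-based
    perception is attempted.
    """

    donor: tuple
    hydrogen: tuple
    acceptor: tuple
    d_cut: float = 0.35
    angle_cut: float = 30.0
    angle_at: str = "donor"  # or "hydrogen" (D-H-A deviation from 180)

    def __post_init__(self) -> None:
        if self.d_cut <= 0:
            raise ValueError("d_cut must be > 0")
        if not (0 < self.angle_cut < 180):
            raise ValueError("angle_cut must be in (0, 180)")
        if self.angle_at not in ("donor", "hydrogen"):
            raise ValueError("angle_at must be 'donor' or 'hydrogen'")


def hbond_geometry(
    donor: np.ndarray,
    hydrogen: np.ndarray,
    acceptor: np.ndarray,
    d_cut: float = 0.35,
    angle_cut: float = 30.0,
    angle_at: str = "donor",
) -> bool:
    """Geometric hydrogen-bond test on raw coordinates (nm).

    ``angle_at='donor'``: true iff |D-A| < d_cut and the angle between D->H
    and D->A is < angle_cut.  ``angle_at='hydrogen'``: the deviation of the
    D-H-A angle from 180 degrees replaces the donor angle.
    """
    d = np.asarray(donor, float)
    h = np.asarray(hydrogen, float)
    a = np.asarray(acceptor, float)
    da = a - d
    dist = np.linalg.norm(da)
    if dist == 0.0:
        raise ValueError("coincident donor and acceptor")
    if dist >= d_cut:
        return False
    if angle_at == "donor":
        dh = h - d
        ndh = np.linalg.norm(dh)
        if ndh == 0.0:
            raise ValueError("coincident donor and hydrogen")
        cosang = np.clip(np.dot(dh, da) / (ndh * dist), -1.0, 1.0)
        ang = np.degrees(np.arccos(cosang))
    else:
        hd = d - h
        ha = a - h
        nhd, nha = np.linalg.norm(hd), np.linalg.norm(ha)
        if nhd == 0.0 or nha == 0.0:
            raise ValueError("coincident hydrogen with donor or acceptor")
        cosang = np.clip(np.dot(hd, ha) / (nhd * nha), -1.0, 1.0)
        ang = 180.0 - np.degrees(np.arccos(cosang))
    return bool(ang < angle_cut)


def _ref_index(traj: BeadTrajectory, ref) -> int:
    return traj.bead_index(*ref)


def hbond_present(traj: BeadTrajectory, frame: int, spec: HBondSpec) -> bool:
    """Evaluate one HBondSpec in one frame."""
    d = traj.coords[frame, _ref_index(traj, spec.donor)]
    h = traj.coords[frame, _ref_index(traj, spec.hydrogen)]
    a = traj.coords[frame, _ref_index(traj, spec.acceptor)]
    return hbond_geometry(d, h, a, spec.d_cut, spec.angle_cut, spec.angle_at)


def hbond_occupancy(
    traj: BeadTrajectory,
    specs: Sequence[HBondSpec],
    window: Optional[AnalysisWindow] = None,
    threshold_pct: Optional[float] = None,
) -> pd.DataFrame:
    """Percentage of analysed frames each bond is present.

    ``threshold_pct`` (the reporting convention is 40%) filters the table at
    output only; pass None for all bonds.
    """
    if window is None:
        window = AnalysisWindow(t_start_ns=0.0)
    mask = window.frame_mask(traj.times)
    if not mask.any():
        raise ValueError(f"no frames at or after t_start = {window.t_start_ns} ns")
    frames = np.flatnonzero(mask)
    rows = []
    for spec in specs:
        hits = sum(hbond_present(traj, f, spec) for f in frames)
        rows.append(
            {
                "donor": spec.donor,
                "hydrogen": spec.hydrogen,
                "acceptor": spec.acceptor,
                "occupancy_pct": 100.0 * hits / len(frames),
            }
        )
    df = pd.DataFrame(rows, columns=["donor", "hydrogen", "acceptor", "occupancy_pct"])
    if threshold_pct is not None:
        df = df[df["occupancy_pct"] > threshold_pct].reset_index(drop=True)
    return df


def read_sasa_table(path) -> pd.DataFrame:
    """Read a per-residue per-frame SASA table (TSV: residue_index, frame, sasa_nm2)."""
    df = pd.read_csv(path, sep="\t")
    need = ["residue_index", "frame", "sasa_nm2"]
    if list(df.columns) != need:
        raise ValueError(f"SASA table must have columns {need}, got {list(df.columns)}")
    return df


def xvg_frames_to_sasa_table(paths: Sequence) -> pd.DataFrame:
    """Convert per-frame two-column xvg dumps (residue, sasa) to the tidy table.

    Each path is one frame, in order; lines starting with '#' or '@' are xvg
    metadata and are skipped.
    """
    rows = []
    for frame, path in enumerate(paths):
        with open(path, "r", encoding="utf-8") as fh:
            for ln in fh:
                ln = ln.strip()
                if not ln or ln.startswith(("#", "@")):
                    continue
                res, sasa = ln.split()[:2]
                rows.append((int(float(res)), frame, float(sasa)))
    return pd.DataFrame(rows, columns=["residue_index", "frame", "sasa_nm2"])


def sasa_difference(
    open_table: pd.DataFrame,
    closed_table: pd.DataFrame,
    negative_means_protected: bool = True,
) -> pd.DataFrame:
    """Per-residue mean SASA difference between two simulations.

    Default: delta_i = mean(open_i) - mean(closed_i), so residues buried by
    nanodisc binding come out negative ("protected").  Setting
    ``negative_means_protected=False`` flips the subtraction order; the
    convention used is recorded in ``DataFrame.attrs['sign_convention']``.
    """
    mo = open_table.groupby("residue_index")["sasa_nm2"].mean()
    mc = closed_table.groupby("residue_index")["sasa_nm2"].mean()
    if set(mo.index) != set(mc.index):
        diff = sorted(set(mo.index) ^ set(mc.index))
        raise ValueError(f"residue sets differ; symmetric difference: {diff}")
    if negative_means_protected:
        delta = mo - mc
        convention = "open_minus_closed (negative = protected on nanodisc)"
    else:
        delta = mc - mo
        convention = "closed_minus_open (positive = protected on nanodisc)"
    out = delta.rename("delta_sasa_nm2").reset_index().sort_values("residue_index")
    out = out.reset_index(drop=True)
    out.attrs["sign_convention"] = convention
    return out


def distance_timeseries(
    traj: BeadTrajectory,
    bead_a,
    bead_b,
    window: Optional[AnalysisWindow] = None,
):
    """Per-frame Euclidean distance between two beads and its window mean.

    Beads are (mol_id, res_index, bead_name) references; returns
    (times, series, mean).  Side-chain conventions (SC1 for residues 1 and 4,
    SC2 for residue 7) are the caller's choice of reference.
    """
    if window is None:
        window = AnalysisWindow(t_start_ns=0.0)
    mask = window.frame_mask(traj.times)
    if not mask.any():
        raise ValueError(f"no frames at or after t_start = {window.t_start_ns} ns")
    ia = _ref_index(traj, bead_a)
    ib = _ref_index(traj, bead_b)
    series = np.linalg.norm(traj.coords[mask, ia, :] - traj.coords[mask, ib, :], axis=1)
    return traj.times[mask], series, float(series.mean())
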