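"""Config-driven end-to-end runs with provenance and machine-readable reports.

A run executes whichever stages its inputs allow: trajectory metrics
(occupancy, dissociation, dimerization histogram, position densities) when a
trajectory is configured, and the sequence screen when a FASTA is.  Besides
the final summary an interim checkpoint report is written at a configurable
time, mirroring the screening practice of triaging candidate systems early;
the go/no-go decision is left to the user, as no numeric criterion defines
"poor binding".
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .binding import longest_event, occupancy
from .disc import dimerization_histogram, dissociated_fraction
from .seqscreen import PATTERN_PRESETS, screen_proteome
from .trajectory import (
    AnalysisWindow,
    AnchorPoint,
    FULLLENGTH_SITE,
    NANODISC_SITE,
    SiteDefinition,
    TopologyMap,
    read_gro,
    read_tabular,
)

logger = logging.getLogger("discbind")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "site_from_name"]


class PipelineError(RuntimeError):
    """A stage failure, named after the stage that raised it."""


def site_from_name(site) -> SiteDefinition:
    """Resolve 'nanodisc', 'fulllength' or a JSON site file to a SiteDefinition."""
    if isinstance(site, SiteDefinition):
        return site
    if site == "nanodisc":
        return NANODISC_SITE
    if site == "fulllength":
        return FULLLENGTH_SITE
    path = Path(site)
    if not path.exists():
        raise ValueError(f"unknown site preset or missing file: {site}")
    doc = json.loads(path.read_text(encoding="utf-8"))
    constraints = []
    for c in doc["constraints"]:
        refs = [tuple(r) for r in c["anchor"]]
        anchor = (AnchorPoint.single(*refs[0]) if len(refs) == 1
                  else AnchorPoint.midpoint(*refs))
        constraints.append((int(c["peptide_res"]), anchor, float(c["cutoff_nm"])))
    return SiteDefinition(tuple(constraints))


@dataclass
class RunConfig:
    """Inputs, window, metric settings and outputs for one pipeline run."""

    outdir: str
    trajectory: Optional[str] = None      # tabular TSV
    gro: Optional[str] = None             # single-frame alternative
    topology: Optional[str] = None        # topology map YAML (for gro)
    fasta: Optional[str] = None
    site: str = "nanodisc"
    t_start_ns: float = 0.0
    t_start_us: Optional[float] = None    # convenience; converted to ns
    n_blocks: int = 3
    checkpoint_ns: Optional[float] = None
    pattern: str = "de4qr7"
    dimer_bins: tuple = (40, 36)
    ref_max: Optional[float] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.t_start_us is not None:
            self.t_start_ns = float(self.t_start_us) * 1000.0
            self.t_start_us = None
        for name in ("trajectory", "gro", "topology", "fasta"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config {name}: no such file {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if "dimer_bins" in doc:
            doc["dimer_bins"] = tuple(doc["dimer_bins"])
        return cls(**doc)

    def canonical(self) -> str:
        doc = asdict(self)
        doc["dimer_bins"] = list(doc["dimer_bins"])
        return json.dumps(doc, sort_keys=True)


def _sig6(x):
    """Round floats to 6 significant digits for the human-facing summary."""
    if isinstance(x, dict):
        return {k: _sig6(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_sig6(v) for v in x]
    if isinstance(x, float):
        return float(f"{x:.6g}")
    return x


def _full_precision(x):
    """repr-precision decimal strings for bit-stable diffing."""
    if isinstance(x, dict):
        return {k: _full_precision(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_full_precision(v) for v in x]
    if isinstance(x, float):
        return repr(x)
    return x


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("load_trajectory")
def _load_traj(config: RunConfig):
    if config.trajectory:
        logger.info("loading tabular trajectory %s", config.trajectory)
        return read_tabular(config.trajectory)
    if config.gro:
        if not config.topology:
            raise ValueError("a GRO input needs a topology map")
        logger.info("loading GRO frame %s", config.gro)
        return read_gro(config.gro, TopologyMap.from_yaml(config.topology))
    return None


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns and writes the report bundle.

    Outputs in ``outdir``: ``summary.json`` (6 significant digits),
    ``summary_full.json`` (repr-precision strings), ``dimers.tsv`` (histogram),
    ``screen.tsv`` (sequence screen) and, if a checkpoint time is set,
    ``checkpoint.json`` with the interim occupancy.
    """
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "provenance": {
            "config_sha256": hashlib.sha256(config.canonical().encode()).hexdigest(),
            "seed": config.seed,
            "discbind_version": __version__,
        }
    }
    traj = _load_traj(config)
    window = AnalysisWindow(config.t_start_ns, config.n_blocks)
    if traj is not None and traj.n_frames >= config.n_blocks:
        site = site_from_name(config.site)

        @_stage("occupancy")
        def run_occ():
            occ = occupancy(traj, site, window)
            return {
                "occupancy_pct": occ.occupancy_pct,
                "block_std": occ.block_std,
                "block_means": list(occ.block_means),
                "n_events": len(occ.events),
                "longest_event_ns": longest_event(occ),
                "events": [
                    {"start_ns": e.start_ns, "end_ns": e.end_ns,
                     "occupant": e.occupant, "duration_ns": e.duration_ns}
                    for e in occ.events
                ],
            }

        summary["occupancy"] = run_occ()

        @_stage("dissociation")
        def run_diss():
            d = dissociated_fraction(traj, window)
            return {"dissociated_pct": d.percentage, "block_std": d.block_std}

        summary["dissociation"] = run_diss()

        @_stage("dimerization")
        def run_dimers():
            nx, ny = config.dimer_bins
            hist = dimerization_histogram(traj, window, nx=nx, ny=ny)
            hist.to_tsv(outdir / "dimers.tsv")
            out = {
                "n_samples_total": hist.n_samples_total,
                "n_out_of_range": hist.n_out_of_range,
                "max_bin_count": int(hist.counts.max()),
            }
            if config.ref_max:
                out["normalized_max"] = float(hist.counts.max() / config.ref_max)
            return out

        try:
            summary["dimerization"] = run_dimers()
        except PipelineError as exc:
            # fewer than two peptides is a legitimate single-chain system
            logger.warning("%s (skipping dimerization)", exc)

        if config.checkpoint_ns is not None:
            @_stage("checkpoint")
            def run_checkpoint():
                keep = traj.times <= config.checkpoint_ns
                if keep.sum() < 1:
                    raise ValueError("checkpoint before first frame")
                sub = traj.__class__(traj.times[keep], traj.coords[keep],
                                     traj.beads, traj.box)
                occ = occupancy(sub, site,
                                AnalysisWindow(config.t_start_ns, 1))
                return {
                    "checkpoint_ns": config.checkpoint_ns,
                    "occupancy_pct": occ.occupancy_pct,
                    "note": "interim triage report; continuation is the user's decision",
                }
            cp = run_checkpoint()
            (outdir / "checkpoint.json").write_text(
                json.dumps(_sig6(cp), indent=2) + "\n", encoding="utf-8")
            summary["checkpoint"] = cp

    if config.fasta:
        @_stage("seqscreen")
        def run_screen():
            pattern = PATTERN_PRESETS.get(config.pattern)
            if pattern is None:
                raise ValueError(
                    f"unknown pattern {config.pattern!r}; "
                    f"presets: {sorted(PATTERN_PRESETS)}"
                )
            report = screen_proteome(config.fasta, pattern)
            report.to_tsv(outdir / "screen.tsv")
            return {"n_hits": len(report.hits), "pattern": pattern.name}

        summary["seqscreen"] = run_screen()

    (outdir / "summary.json").write_text(
        json.dumps(_sig6(summary), indent=2) + "\n", encoding="utf-8")
    (outdir / "summary_full.json").write_text(
        json.dumps(_full_precision(summary), indent=2) + "\n", encoding="utf-8")
    return summary
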