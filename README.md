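# discbind

Analysis toolkit for coarse-grained simulations of lecithin:cholesterol
acyltransferase (LCAT) binding to peptide-based nanodiscs, and for screening
protein sequences for the amphipathic-helix charge moiety that predicts LCAT
binding.

## Who this is for

LCAT esterifies cholesterol on HDL particles; its activation depends on
apolipoprotein helices docking into the cavity between its lid and membrane
binding domain. Researchers studying this interaction with Martini-style
coarse-grained MD need a reproducible way to turn bead trajectories into
binding statistics, and a fast sequence-level pre-screen to nominate
candidate helices. `discbind` provides both, plus synthetic planted-truth
generators so every metric can be validated without running MD.

## The metrics

**Binding-site occupancy.** Per frame, the nearest peptide to the site is the
one minimising the unweighted sum of three backbone distances: peptide
residue 2 to LCAT G226, residue 11 to the midpoint of W48/I237, and residue
20 to W48. The frame is *occupied* iff that nearest peptide's distances are
strictly below 1, 1 and 2 nm. Occupancy is the percentage of occupied frames
among analysed frames (analysis starts after an equilibration cut, 1 μs by
default); uncertainty is the sample standard deviation of three
consecutive-block means. A variant for full-length apoA1 tests each helix
against Q229/L239 anchors at 1.2 nm. Maximal runs of occupied frames with a
constant occupant give binding-event durations.

**Disc packing.** Dimerization profiles histogram, over all peptide pairs
per frame, the residue-13 backbone distance (0–2 nm) against the angle
between residue 1→21 direction vectors (0–180°). A peptide is *dissociated*
when its residue-13 bead is more than 2 nm from every lipid C3A tail bead.
Position densities express the enzyme centroid or peptide positions in
cylindrical coordinates of a plane least-squares-fitted to all lipid beads.

**Sequence screen.** 22-mer fragments with Asp/Glu at position 4 and Gln/Arg
at position 7 (the "DE4-QR7" moiety; generalised form: R7 or K/R at 10–11)
are enumerated and triaged by mean Hopp–Woods hydrophilicity, mean
Pace–Scholtz helical penalty, and the HELIQUEST-style hydrophobic moment

```
μH = (1/N) · |Σₙ Hₙ exp(i·n·δ)|,   δ = 100° per residue.
```

**Structural metrics.** Geometric hydrogen bonds (donor–acceptor < 0.35 nm,
donor-vertex angle < 30°), per-residue SASA differencing between open
(on-nanodisc) and closed (in-water) enzyme states, and bead–bead distance
time series.

## Worked example

```python
from discbind import (AnalysisWindow, NANODISC_SITE, DiscPlantSpec,
                      make_disc_trajectory, occupancy, dissociated_fraction,
                      scan_pairs, load_packaged_sequence)

spec = DiscPlantSpec(
    n_frames=120, dt_ns=10.0, seed=7,
    occupancy_schedule=frozenset(f for f in range(120) if f % 8 < 3),
    dissociated_ids=frozenset({20, 21, 22}),
)
traj, truth = make_disc_trajectory(spec)
window = AnalysisWindow(t_start_ns=0.0, n_blocks=3)
occ = occupancy(traj, NANODISC_SITE, window)
print(f"occupancy: {occ.occupancy_pct:.1f}% +/- {occ.block_std:.1f}%")
diss = dissociated_fraction(traj, window)
print(f"dissociated: {diss.percentage:.1f}% +/- {diss.block_std:.1f}%")
apo = load_packaged_sequence("apoa1_mature")
print("helix-6 charge pairs:", scan_pairs(apo, region=(143, 164)))
```

prints

```
occupancy: 37.5% +/- 0.0%
dissociated: 10.7% +/- 0.0%
helix-6 charge pairs: [146, 150, 157]
```

The occupancy equals the planted schedule density exactly (45 of 120 frames
occupied by the designated peptide), the dissociation equals 3/28 peptides,
and the pair scan of mature apoA1 residues 143–164 recovers the three
i, i+3 acid/arginine pairs of helix 6 — E146-R149, D150-R153 and D157-R160.
The 22-mer window that places the most C-terminal of these at fragment
positions 4/7 starts at residue 154.

A CLI mirrors the library: `discbind simulate | occupancy | dissociation |
dimers | density | seqscreen | run` (see `discbind --help`).

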