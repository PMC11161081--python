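# Methods

This note documents the definitions, conventions and design choices behind
`discbind`, and what the synthetic-data validation does and does not show.

## Data model and units

All coordinates are nanometres and all times nanoseconds, everywhere in the
core; microseconds are accepted at configuration boundaries and converted
once (`t_start_us`). A `BeadTrajectory` is a dense `(n_frames, n_beads, 3)`
array with trajectory-constant per-bead metadata: molecule id, molecule type
(LCAT / PEPTIDE / LIPID / OTHER), 1-based residue index within the molecule,
and bead name following Martini conventions (`BB` backbone, `SC1`/`SC2`
side chains, `C3A` lipid tail). Readers reject, rather than repair, any
input violating the invariants (strictly increasing times, finite
coordinates, unique bead identities, frame-consistent bead sets).

Residue numbering is per-molecule and 1-based. LCAT residue indices follow
whatever numbering the topology map supplies; the map owner is responsible
for aligning G226, W48, etc. Peptide sequences are taken in mature-protein
numbering; callers supply signal-peptide-free sequences when absolute
positions matter.

Formats: a TSV tabular trajectory (reference path, 6-decimal fixed point,
byte-stable round trip), single-frame GRO (strict fixed-column parsing with
line-numbered errors), and XTC via MDAnalysis behind the same contract
(optional dependency). Distances are plain Euclidean with no
minimum-image convention: prepared systems keep the complex whole, and the
synthetic generator builds unwrapped geometry by construction.

## Occupancy

The binding site is an ordered list of constraints, each pairing a peptide
residue's backbone bead with an anchor point on the enzyme (a single bead or
the midpoint of two) and a cutoff. Presets:

- nanodisc site: residue 2 ↔ G226 (1.0 nm), residue 11 ↔ midpoint(W48,
  I237) (1.0 nm), residue 20 ↔ W48 (2.0 nm);
- full-length variant: helix residue 2 ↔ Q229 and helix residue 20 ↔ L239,
  both 1.2 nm, each helix tested independently (several may be occupied
  simultaneously).

Conventions adopted where the definition leaves room:

- **Nearest peptide** = smallest unweighted sum of the per-constraint
  distances; ties break to the lowest molecule id, making results
  independent of storage order. The nearest peptide is recorded every frame
  whether or not it passes the cutoffs.
- **Strict inequalities.** "Less than" is taken literally (`<`); a frame
  with a constraint distance exactly at its cutoff is unoccupied. On real
  trajectories this is a measure-zero distinction; on synthetic boundary
  cases it is testable and tested.
- **Analysis window.** Frames with time < `t_start_ns` (default 1000 ns) are
  excluded. Rim-attachment detection is not automated — no geometric
  criterion defines it — so an earlier or later start is a manual override.
  A window with zero frames is an error, never silently 0%.
- **Block statistics.** The analysed series is split into `n_blocks`
  (default 3) consecutive blocks of `floor(n/n_blocks)` frames, remainder
  appended to the last block; the reported spread is the sample (n−1)
  standard deviation of the block means. With one block the spread is
  reported as 0 and flagged, since a single block carries no spread
  information.
- **Events.** Maximal runs of occupied frames with a constant occupant; an
  occupant switch ends the event even without an unoccupied gap. Duration is
  (t_last − t_first) + the median frame spacing, so a single-frame event has
  one frame's worth of duration rather than zero.
- Peptides longer than 22 residues use the same constraint residues 2/11/20
  unchanged; one condition set applies to every system.

## Disc packing

- **Dimerization histograms**: one sample per unordered peptide pair per
  analysed frame; x = residue-13 backbone distance, y = angle between
  residue 1→21 vectors (arccos of the clipped normalised dot product, hence
  exactly symmetric in the pair). The 0–2 nm axis range is part of the
  metric: samples beyond it are excluded and counted in `n_out_of_range`, so
  total mass is always conserved. Default 40 × 36 bins (0.05 nm × 5°),
  matching typical plot granularity; normalisation is by an externally
  supplied reference maximum (cross-system colour scales), never internal.
- **Dissociation**: a peptide is off the bilayer when its residue-13 bead is
  strictly more than 2 nm from every C3A tail bead. The percentage averages
  the per-frame dissociated fraction; for a constant peptide count this
  equals per-peptide time averaging.
- **Disc plane**: total-least-squares plane through all lipid beads
  (smallest principal axis of the centred covariance), refit every frame
  because the disc tumbles; the normal's sign is fixed by the enzyme
  centroid when available, else +z. Collinear point sets are an error.
- **Position densities**: enzyme density uses the centroid of LCAT backbone
  beads as reference, signed height over [−5, 5] nm, radius 0–10 nm;
  peptide density uses residue-13 beads, absolute height 0–3.5 nm, radius
  0–7 nm. The absolute-height convention for peptides is inferred from the
  non-negative axis and is configurable (`signed=`). The enzyme reference
  point (backbone-bead centroid) is this package's documented choice; other
  reductions (e.g. domain-specific centroids) can be passed as custom
  reference callables.

## Sequence screen

`MoietyPattern` holds conjunctive positional constraints over a fragment
window (default 22, the repeat length of apolipoprotein amphipathic
helices), plus an optional disjunctive `any_of` group used by the
generalised preset (D/E at 4 with R at 7 *or* K/R at 10 *or* K/R at 11 —
the substitute salt-bridge positions seen for apoE helix 1 and apoB100
helix AS). Fragment positions are 1-based; `X` and other non-standard
letters never satisfy a constraint, and score functions raise on them
rather than impute values.

Scores: arithmetic-mean Hopp–Woods hydrophilicity; arithmetic-mean
Pace–Scholtz helix-propensity penalty (kcal/mol, Ala = 0); hydrophobic
moment μH = (1/N)|Σ Hᵢ e^(i·δ·i)| with δ = 100°, index starting at 0, mean
normalisation and the Fauchère–Pliška table — the published HELIQUEST
definition (Hopp–Woods and Eisenberg tables are also shipped; all tables
are JSON data files with citations). No hard score cut-offs are applied:
no defensible thresholds exist, so the report ranks and the user decides.

The packaged mature apoA1 sequence (UniProt P02647, residues 25–267,
numbered D1–Q243) was cross-checked against the helix landmarks it must
reproduce (D102/D103, the three helix-6 pairs E146-R149 / D150-R153 /
D157-R160, D168/R171) before being frozen as a data file. The 22A mimetic
sequence is included likewise.

## Structural metrics

Hydrogen bonds use the VMD-plugin geometric criterion: donor–acceptor
distance < 0.35 nm and the angle at the donor between D→H and D→A < 30°.
Because conventions differ between tools, the alternative criterion
(deviation of the D–H–A angle from linearity, vertex at the hydrogen) is
selectable per spec. Donor/acceptor chemistry is caller-declared; there is
no topology-based perception. The 40% reporting threshold filters output
only, never the computation.

SASA values are consumed, not computed (they come from standard tools
upstream). The per-residue difference defaults to mean(open) − mean(closed),
so a residue buried by nanodisc binding is negative ("protected"); the
convention is configurable and recorded in the output's metadata because
the two natural subtraction orders are both in circulation.

## Synthetic data: what it emulates and what it does not

The generator emulates the *interface* of a Martini nanodisc system — 28
peptides of 22 backbone beads, 200 three-bead lipids with C3A tails, one
enzyme with the five anchor residues, nm/ns units — with schematic geometry:
lipids on a rim-ring-plus-sunflower disc, background peptides as compact
bead clusters on a hexagonal grid (2.25 nm spacing), dissociated peptides on
a high layer, the designated occupant placed at 0.5/0.5/1.0 nm from its
anchors in scheduled frames and parked far away otherwise, and planted dimer
pairs realised exactly by residue-13 separation and 1→21 rotation. Gaussian
jitter (σ = 0.02 nm, clipped at ±0.1 nm) is applied only to beads no planted
condition reads.

Every planted condition must hold with ≥ 0.2 nm slack and is re-validated
numerically before a trajectory is emitted (`LayoutError` otherwise); plants
whose distance or angle falls on a default histogram bin edge are rejected
as float-ambiguous, and the grid layout guarantees that no unplanted pair
ever enters the 0–2 nm dimer range. Consistency rules: a dimer member may
not be dissociated, no peptide joins two plants, and scheduling occupancy
requires at least one peptide free of both roles.

There is no excluded volume, no dynamics, no force field: passing the
planted-truth suite demonstrates that the *analysis* layer computes its
definitions exactly, not that the geometry is physical. Conclusions about
real systems still require real trajectories; what the suite rules out is
bookkeeping error in the metrics themselves. Sequence sets likewise compute
their truth by an independent regular-expression scan of the emitted
sequences, so background coincidences count as hits. Test and validation
problem sizes (tens of frames, 20 randomized plants, ~10³ oracle instances)
were chosen as the smallest sizes that exercise every branch of the layout
logic.

## Pipeline

`run_pipeline` executes whichever stages its inputs allow, aborts with a
stage-named error otherwise, and writes: a 6-significant-digit
`summary.json`, a full-precision sidecar (`repr` decimal strings, for
bit-stable diffing), histogram and screen TSVs, a provenance block (config
hash, seed, package version), and an optional interim checkpoint report
with the occupancy up to a chosen time — mirroring the practice of triaging
candidate systems early. No automatic kill criterion is applied; "poor
binding" has no numeric definition, so the decision stays with the user.

## Known limitations

- No periodic-boundary handling; inputs must be whole-molecule.
- GRO reading is single-frame; multi-frame trajectories use the tabular
  format or XTC (optional MDAnalysis).
- The sequence screen models the moiety and three bulk scores only; it does
  not predict secondary structure, kinks, or lipid affinity, all of which
  gate real binding.
- Block standard deviations understate uncertainty when the correlation
  time approaches the block length; choose the window and block count
  accordingly.
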