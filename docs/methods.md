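# Methods

## What the package computes

`ribocar` measures the geometry of the CAR surface — the stacked
C1054·A1196·R146 column of the small ribosomal subunit head — against the
+1 mRNA codon, in trajectories represented as multi-model PDB files over a
fixed topology.  The package does not run molecular dynamics: it builds the
restrained subsystem, emits the staged simulation protocol as
configuration, and analyzes coordinate frames produced elsewhere (or by
its own synthetic generator).

## Hydrogen-bond criterion

A hydrogen bond is recorded when the donor-to-acceptor *heavy-atom*
distance is strictly below 3.0 Å **and** the donor–hydrogen–acceptor angle
(hydrogen at the vertex) is at least 135°, for at least one hydrogen
attached to the donor.  This is the cpptraj-style convention; the vertex
choice is fixed as the hydrogen because that is what the reference tool
evaluates.  Both cutoffs are arguments of `detect_hbonds`.  Detection
requires explicit hydrogens: donors whose hydrogens are missing from the
file are skipped individually (a phosphodiester O5′ legitimately has no
hydroxyl proton), but if *no* donor in the requested set carries a
hydrogen the call raises `MissingHydrogenError` instead of silently
reporting zero bonds.  Intra-residue pairs are excluded.

## Base-pair edges

Edge atom sets follow the Leontis–Westhof faces, restricted to the
polar donors/acceptors actually scored:

| residue | Watson–Crick edge | Hoogsteen edge |
|---|---|---|
| A | N6 (d), N1 (a) | N6 (d), N7 (a) |
| C | N4 (d), N3 (a), O2 (a) | — |
| G | O6 (a), N1 (d), N2 (d) | O6 (a), N7 (a) |
| U | N3 (d), O2 (a), O4 (a) | — |

The arginine guanidinium group is treated as an additional "edge" with
donors NE, NH1, NH2 (the backbone amide N is a separate donor).  Adenine
N6 belongs to both faces; `classify_edge` disambiguates per residue pair:
if one edge explains every bonded atom of that residue within the pair it
is chosen (so N6+N7 engagement reads as Hoogsteen, N6+N1 as Watson–Crick);
when only shared atoms are engaged the tie breaks toward Watson–Crick.
Atoms on no face (O2′, phosphate oxygens, backbone) classify as
*off-edge*; unknown residue types are kept as *unclassified* rather than
dropped.

## Distances

* **Edge distance** — distance between the mass-weighted centers of the
  donor+acceptor heavy atoms of each edge (standard atomic masses,
  hydrogens excluded).
* **Guanidinium minimum-edge rule** — centers of mass of {NE, NH1} and of
  {NE, NH2} are computed each frame and the smaller distance to the
  partner edge is reported; exact ties resolve deterministically to the
  NE,NH1 branch and the winning branch is recorded.
* **Stacking distance** — distance between mass centers of the base-ring
  heavy atoms only (purine: N1…N9 nine-ring; pyrimidine: N1…C6 six-ring;
  exocyclic substituents excluded).  For arginine the planar CZ/NE/NH1/NH2
  group stands in as the ring.  A pair is *reported* stacked below 4.5 Å
  by default: observed stacked readings sit between 3 and 4 Å and
  unstacked ones above 5 Å, so the boundary lies in an empirically empty
  band and is exposed as a parameter rather than hard-coded knowledge.
* **Backbone RMSD** — least-squares (Kabsch) superposition per frame over
  backbone atoms (protein N/CA/C/O; nucleic P/O5′/C5′/C4′/C3′/O3′), with
  `superpose=False` available for raw coordinate RMSD (that variant is
  what closed-form single-atom checks apply to, since optimal fitting
  strictly reduces the value).

Time courses support frame striding (the sampling rate metadata is
rescaled so time stays in ns) and pooling into consecutive non-overlapping
bins (default 1 ns).  Bin means are plain means over member frames; the
trailing partial bin is kept and flagged, and the bin-size-weighted mean
of bin means reproduces the global mean exactly.

## Subsystem construction

Shell membership is by *any-atom* distance: a residue is kept iff any of
its atoms lies within `radius_A` (default 40 Å) of any atom of the anchor
residue (default landmark number 530, the decoding-center loop
nucleotide).  Any-atom membership maximizes retention of partially
overlapping residues.  Gaps of at most `gap_fill_max` residues (default
10) between kept segments of a chain are merged in; the published
curation of chain breaks was judgment-based, so the rule is a parameter,
not a guess at the original procedure.  Every remaining segment terminus
that is not a native chain terminus is recorded as a break point with a
matching cap record; capping is bookkeeping (terminal-residue flagging),
no cap groups are built.  Restraint masks partition the selection into an
unrestrained core and a restrained "onion shell" at a default weight of
20 kcal mol⁻¹ Å⁻², serialize to JSON and to an AMBER-style
`restraintmask` string over serial positions, and offer a buffer check
verifying that at least one unrestrained residue separates the shell from
protected residues (C1054, A1196, R146).

Nucleotide substitution keeps the coordinates of every atom shared by the
old and new base (by name) plus the entire sugar–phosphate backbone, and
grows atoms unique to the new base from an idealized template superposed
on three anchors: the glycosidic nitrogen (N9 purine / N1 pyrimidine),
C1′, and the ring atom adjacent to the glycosidic nitrogen (C4 purine /
C2 pyrimidine).  The base-plane normal may rotate at most 5° or the
operation fails.  Atoms outside the target residue are never touched.

## Staged protocol

`default_schedule()` returns the full optimized protocol as a frozen
constant: eleven minimization rounds — (20000 steps/2500 steepest
descent/100 kcal mol⁻¹ Å⁻²), (10000/2500/75), (5000/2500/65),
(3000/2500/55), (3000/2500/45), then (2000/2000/w) for w = 30, 20, 15,
10, 5, 1 — followed by 20 ps heating at a 2 fs timestep with all residues
restrained at 20 kcal mol⁻¹ Å⁻², 3 ns equilibration at 1 fs with
inherited velocities, and production at 300 K sampled at 100 frames/ns
with only the onion shell restrained.  Environment parameters (truncated
octahedral box, 12 Å solvent margin, TIP3P water, Na⁺ counter-ions) are
recorded for the renderer.  Production duration is deliberately a free
parameter.  The between-round energy-drop rule that shaped the ramp needs
engine energies, so it travels as a documentation field and is not
evaluated; an optional stabilization variant (0, 10 or 100 ps of
unrestrained MD before fixing the shell) is a schedule flag.  Rendering
to `generic_json` round-trips exactly; `amber_mdin` emits mdin-style text
with ntr/restraint_wt/restraintmask lines.

## Multi-run statistics

The replication unit is the MD run: frames within a run are strongly
autocorrelated, so run-level means are computed first and group means,
standard errors (SD of run means / √n_runs) and t-tests operate on them.
Group comparison uses the two-sided Welch (unequal-variance) t-test; the
pooled-variance alternative was rejected because run variances are not
exchangeable across substitutions.  A single-run group reports SE 0 with
an explicit flag.  Two exactly identical zero-variance groups return
statistic 0 and p = 1 (the limit scipy reports as NaN).  Contact
frequencies are pooled frame-weighted across runs — frequency = frames
with ≥ 1 bond over total frames — with a per-run-average alternative
behind `pooling="runs"`.  Display categories: strong for f ≥ 0.10
(boundary inclusive), weak for 0.025 < f < 0.10 (strict lower bound),
none otherwise.  No multiple-testing correction is applied across pairs.

## Synthetic fixtures: what they emulate, and what they do not

The generator produces idealized planar bases with explicit hydrogens
(templates from the chemical component dictionary bundled with biotite)
and composes them rigidly:

* **pairs** (`make_pair`) are built by a deterministic multi-start least
  squares over the in-plane placement of the second base, targeting
  2.9 Å for every defining donor–acceptor distance (the center of the
  2.5–3.5 Å formed-pair band) with near-linear donor hydrogens and a
  steric-clearance term that keeps non-bonded heavy atoms ≥ 2.7 Å apart
  (this excludes mis-registered minima).  Formed constructions are
  verified against `detect_hbonds` at default cutoffs before being
  returned.  Supported: Watson–Crick G:C and A:U, trans
  Watson–Crick/Hoogsteen A:C and A:U, wobble G:U.
* **the decoding-center fixture** (`make_car_fixture`) stacks, at a
  default rise of 3.8 Å (inside the observed 3.5–4.0 Å band), a
  codon–anticodon duplex (A-site codon CCU against a GGG anticodon with a
  G:U wobble; the wobble base identity is the generator's choice and the
  fixture layout is this package's own construction, not a replica of any
  deposited subsystem), C1054 above the wobble base, A1196 above C1054,
  and the arginine guanidinium above A1196.  The +1 codon is
  configurable: position 1 pairs C1054 only when it is G; position 2
  pairs the A1196 Hoogsteen edge when pyrimidine, while purines are
  parked with their edge ≥ 4 Å away — the steric clash of the larger base
  is modelled as increased separation, not simulated.
* **trajectories** (`make_trajectory`) script per-frame bond state: pairs
  scheduled broken have their second residue rigidly displaced beyond
  6 Å (outside both the detection cutoff and the stacked/unstacked
  ambiguity band), then i.i.d. Gaussian noise of σ Å is added to every
  coordinate.  Identical seeds give identical trajectories, and the seed,
  noise level and schedule are recorded in the trajectory metadata.

These fixtures validate the *measurement* code: thresholds, edge
assignment, center-of-mass arithmetic, schedule recovery, aggregation.
They do not emulate force-field energetics, solvent, temporal
autocorrelation, correlated breathing motions, or realistic backbone
continuity between stacked planes — so passing tests demonstrate that the
analysis measures what it claims on known geometry, not that any MD
observable (bond counts per frame, stage differences) is reproduced at
published magnitudes.  Those observables require the full restrained
subsystem (hundreds of residues, explicit solvent) simulated at GPU
scale, which is out of scope here.

## Problem sizes and numerical choices

The test suite and acceptance script run entirely on generated fixtures:
two-residue pairs (~65 atoms), the 12-residue decoding-center fixture
(~390 atoms), 10-residue strands, trajectories of 20–200 frames at
σ = 0–0.6 Å, 2000-replicate null simulations for test calibration.  These
sizes keep full runs under a few minutes on one CPU while leaving every
statistic well-determined (schedule recovery and type-I rates are stable
to well within their asserted bands across seeds).  Threshold location
uses bisection on synthetic collinear probes to 10⁻⁴ Å / 10⁻³ degrees.
PDB round trips are exact to the format's fixed 3-decimal coordinate
columns (0.001 Å/0.0005 Å rounding).  Distance comparisons against
independent center-of-mass oracles are asserted to 10⁻⁹ Å.

## Known limitations

* Trajectories are multi-model PDB only; binary formats (DCD/XTC) would
  slot behind the same `Trajectory` contract but are not implemented.
* Edge tables cover the four standard ribonucleotides and arginine;
  modified bases classify as *unclassified*.
* The numbering map ships only the decoding-center landmarks; it is a
  lookup table, not an alignment.
* `substitute_nucleotide` assumes the target sugar is intact (glycosidic
  N, C1′ and the adjacent ring atom present).
* Contact-map pooling weights runs by frame count; runs of very unequal
  length therefore contribute unequally unless `pooling="runs"` is used.
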