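# Methods

## Scope and model system

`ptmdimer` analyses two-chain peptide trajectories for the signatures of
association: heavy-atom close contacts, residue-pair interaction
persistence, salt-bridge classes, and buried solvent-accessible surface
area.  The reference system is the histone H3 tail fragment (residues
1–12) in four modification states — unmodified with a free or acetylated
N-terminus (P0M0 ala/ace, charges +5/+4), carrying the mitotic
phospho-T3 + trimethyl-K4 + dimethyl-R8 mark set (P1M2, +3), and fully
modified and charge-neutral (P2M4, 0) — but every component is generic
over annotated peptides.

Producing the trajectories themselves (force fields, solvent, ensemble
protocols) is out of scope; the package consumes multi-model PDB files
from any source and ships a synthetic generator for testing.

## Formal charge model

The charge of an annotated peptide is the sum of fixed group
contributions at neutral pH: +1 for a free N-terminal amine (0 for an
acetyl cap), −1 for a free C-terminal acid (0 for an N-methyl amide cap),
+1 for Arg and Lys side chains in any methylation state, 0 for
acetyl-lysine, −1 for Asp/Glu, 0 for His, and −2 per phosphate on
Ser/Thr/Tyr.  The phosphate is treated as fully deprotonated (−2); no
pKa/titration model is attempted, which is the convention needed for the
integer charges above.  His = 0 and Asp/Glu = −1 are defined so the model
is total over the twenty amino acids even though the four study peptides
contain none of them.  Masses and pH-dependent charge curves are
non-goals.

## Trajectory format and views

The native format is multi-model PDB (one MODEL block per frame, two
chains, fixed-column ATOM records, %8.3f Å).  At the hundreds-of-frames
scale analysed here a human-readable text format is preferable to binary
MD formats, and round-trips to half-ULP coordinate precision (5×10⁻⁴ Å).
The reader enforces a frame-invariant atom roster (diagnostics name the
first offending atom), requires exactly two chains, drops solvent/ion
records with a logged count, and infers elements from columns 77–78 or,
failing that, from the first alphabetic character of the atom name
(two-character elements restricted to those occurring in peptides).
Modified residues are written as TPO/SEP/M3L/DA2 etc.; standard names
with the PTM declared in the YAML topology sidecar are accepted equally.
Periodic-boundary imaging is assumed done upstream; no minimum-image
convention is applied.

All contact and SASA analysis operates on the hydrogen-free view of the
trajectory.

## Close contacts and N_cc

A close contact is a pair of heavy atoms on different chains at distance
strictly less than the cutoff (default 4 Å).  `N_cc` counts each
unordered inter-chain atom pair once per frame; its arithmetic mean over
frames is the association statistic reported per dimer.  Counting atom
pairs (not residue pairs) is what makes double-digit N_cc values possible
for 12-residue peptides.  At residue granularity, a pair is in contact
when at least one of its heavy-atom pairs is within the cutoff (the
standard any-atom contact-map convention).  The fast path is a k-d tree
neighbour query; the test suite validates it against an explicit O(n²)
double loop, and a strictness check at exactly 4.0 Å confirms the open
boundary.

Residue-pair interactions are typed from residue identity and PTM state:
(possibly methylated) Arg or Lys against phospho-Ser/Thr gives the four
salt-bridge classes R/K × pS/pT (with a `donor_modified` flag);
acetyl-lysine is excluded (its amine is neutralised); everything else is
`other_contact`.  Classification is deliberately not geometric
(no phosphate-O–guanidinium-N distance criterion): it types *which
residues* interact, which is the information the persistence maps carry.

## Persistence maps

Persistence is frames-in-contact divided by total frames, kept as an
exact rational.  Thresholds supplied as floats are interpreted at their
printed decimal value (`0.10` means 1/10) because the binary double
nearest 0.1 is slightly *above* 1/10 and would silently exclude a pair in
contact in exactly 10% of frames — the reporting boundary itself.  The
threshold comparison is inclusive (≥ 10%).  Intramolecular pairs with
|i−j| ≤ 2 are excluded by default as trivially persistent consequences of
backbone connectivity (the window is configurable); intermolecular pairs
are never excluded.  Maps are sorted by descending persistence and export
to TSV and to a JSON document in which `line_width` maps persistence
linearly from 0.10 (thinnest) to 0.98 (thickest) for the linear-diagram
renderer in `examples/plot_interaction_map.py`.

No burn-in trimming is applied: persistence is computed over the frames
supplied, and callers emulate equilibration removal by slicing input.
Contact kinetics (on/off rates, lifetimes) are out of scope.

## SASA and the buried-area statistic

SASA uses the Shrake–Rupley sphere-point method with a deterministic
golden-section spiral lattice (default 960 points, probe 1.4 Å water,
Bondi-derived heavy-atom radii C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å).
Determinism makes the result bit-reproducible across runs; accuracy is
anchored by analytic oracles: an isolated atom reproduces 4π(r+probe)² to
better than 0.5% at 960 points, a two-atom configuration matches the
closed-form two-sphere spherical-cap area within 2%, and the lattice
converges monotonically below 1% error at 3840 points.

The association statistic is ΔA = ⟨A₁ + A₂ − A₁₂⟩.  Monomer areas A₁ and
A₂ are computed on the dimer-frame coordinates with the partner deleted
(the standard buried-surface convention), which makes ΔA a per-frame
observable of the same trajectory, as the time-average requires; the
alternative reading — independently simulated monomers — would decouple
ΔA from the dimer ensemble.  Per frame A₁ + A₂ ≥ A₁₂ up to lattice
resolution (tolerance 0.1 Å²), and ΔA vanishes for chains that never
approach.  Hydrogens are excluded throughout; no united-atom radius
inflation, molecular (Connolly) surfaces or per-residue normalisation.

## Synthetic trajectories and ground truth

The generator emulates what the analysis needs from MD output — two
12-residue chains whose inter-chain residue contacts follow a known
schedule — without pretending to be physics.  Chains are rigid
ideal-geometry copies: backbone N/CA/C/O placed by internal-coordinate
(NeRF) chain building at (φ,ψ) = (−57°,−47°) for α-helical or
(−135°,135°) for extended starts, plus CB (except Gly) and one
charged-group tip pseudo-atom per residue (N for Arg/Lys, P for
phospho-Ser/Thr, C otherwise; Gly and Ala carry none).  The reduced side
chain keeps the generator simple while exercising contacts, persistence
and SASA; full-atom input arrives through the PDB reader.

A schedule is a list of episodes (residue pair, fraction, contact
distance ≤ 3.2 Å) over n frames with an apart distance ≥ 6 Å.  Fractions
times n must be integers so recovery can be exact.  Frames are assigned
by a seeded permutation — disjoint blocks when the fractions fit within
the trajectory, independent draws otherwise — and chain B is rigidly
placed per frame: head-on tip-to-tip docking for single contacts (chain
axes made perpendicular, with a small set of candidate spin angles about
the contact axis), a least-squares rigid fit with an outward body anchor
for simultaneous multi-pair sets, and a pure translation past the apart
distance when no episode is on.  Every distinct pose is verified
noise-free: scheduled pairs must sit below 3.6 Å and all other
inter-chain residue pairs above 4.8 Å.  If no candidate pose passes —
as happens for geometrically contradictory simultaneous episode sets on
straight rigid chains — an `InfeasibleScheduleError` names the
conflicting episodes.  Persistence ladders whose fractions sum past 1
(e.g. 19/64/94/98%) are therefore realised as a suite of schedules,
mirroring how per-dimer ensembles are analysed separately.

Gaussian positional noise (default σ = 0.3 Å) is then added from the
same seeded generator.  A per-atom noise draw can, with small but
non-zero probability, push a contact pair across the 4 Å classification
boundary; to keep the schedule exactly true the generator redraws a
frame's noise (bounded attempts) whenever it would flip any inter-chain
residue-pair classification.  The docking margins make redraws rare, and
the schedule invariant `apart − contact > 6σ + (4 − contact)` keeps the
rejection region small by construction.  Identical seeds produce
byte-identical trajectories (NumPy `default_rng`).

What passing on synthetic data does *not* show: the generator has no
conformational flexibility, solvent, energetics or realistic side-chain
packing, so agreement here demonstrates correctness of the bookkeeping
(counting, thresholding, averaging, geometry), not fidelity of any MD
force field.  Observables that depend on interface detail — e.g. the
absolute magnitude of N_cc or ΔA for a real dimer — cannot be compared
against published MD tables, which summarise long explicit-solvent
trajectories that are not deposited.

## Pipeline and reports

`run_analysis` chains read → heavy-atom filter → contacts → persistence →
SASA → reports under a single `RunConfig` (cutoff 4 Å, threshold 0.10,
probe 1.4 Å, 960 lattice points, stride 1 by default; stride s analyses
⌈n/s⌉ frames and the log says so).  Reports are single-header TSV plus
full-precision JSON; the summary prints N_cc with one decimal and ΔA with
none, matching the conventional display precision.  The run log carries
parameters, frame counts and per-chain formal charges, and is
timestamp-free so reruns are byte-identical.  Stage failures re-raise
with the stage named.  `compare_runs` assembles the per-dimer,
per-conformation long table (duplicate keys rejected).

## Default problem sizes

Bundled fixtures use 2 × 12-residue chains and 100–200 frames, with the
persistence ladder {19%, 64%, 94%, 98%} drawn from the range observed
for real modified H3 dimers; these sizes exercise every code path while
keeping the full test suite in the low minutes.  Larger inputs are
handled by the same code paths (the contact stage is near-linear via the
k-d tree; SASA is the O(n·points) term).

## Known limitations

- No PBC/minimum-image handling; trajectories must be pre-imaged.
- Salt-bridge typing is identity-based, not geometric.
- The generator cannot realise arbitrary overlapping episode sets
  (rigid-chain geometry); infeasibility is detected and reported rather
  than silently approximated.
- Binary trajectory formats (DCD/XTC) are not read; convert to
  multi-model PDB upstream.
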