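# Methods

This note documents the models, conventions and numerical choices behind
lidtraj, and what its tests do and do not demonstrate.

## Containers and conventions

Coordinates are Å (float64), times ps, masses amu.  Author (source-file)
residue numbering is preserved everywhere; there is no internal
renumbering, so analyses and outputs speak the same residue language as
the crystallographic literature on the system (e.g. Ser595, Asn1).
Element masses come from a standard periodic table; an unknown element
symbol is an error, never a guess.  Alternate locations resolve to the
highest-occupancy conformer (ties: first listed).  Hydrogens are retained
when present; waters and ions are parsed and flagged but excluded from
protein selections.

Distance calculations default to **heavy atoms**.  Crystal structures at
typical resolution carry no hydrogens, so heavy-atom distances are the
only convention under which crystal-state and simulation analyses are
commensurable.  `all` and `backbone` subsets are available everywhere.

No periodic-boundary imaging is performed; inputs are assumed to be whole
molecules.  A continuity guard warns when consecutive residues are
implausibly far apart (C–N peptide bond > 3 Å, or pseudo-atom spacing
> 4.5 Å for one-atom-per-residue models), which is the signature of a
molecule broken across a periodic box.

## Superposition

The least-squares rigid fit minimises the (optionally mass-weighted)
squared deviation over a selection, via the SVD-based Kabsch solution
(scipy's `Rotation.align_vectors`).  Reflections are never returned; a
selection of fewer than three atoms, or a collinear one, is rejected as
degenerate rather than silently resolved.  For deviation analyses the
recommended fit group is the backbone of the rigid sub-domain (the
β-sandwich in the DnaK system), so that deviations measure internal
motion of the mobile parts rather than tumbling.  The fit group is
configurable and recorded in the MSD profile.

## Domain-additive MSD

MSD is defined in Å² with mass weights normalised by the **whole**
selection's mass, which makes the per-domain terms additive exactly (to
floating point): the sum over any disjoint partition equals the whole at
every frame, asserted at construction.  Because additivity holds only
before the square root, the Å² series is the primary quantity; an
RMSD-style √MSD column is emitted for display alongside.  The reference
is the first trajectory frame by default, but any frame (or pair of
times) can be used.  Superposition, when requested, happens once per
frame over the profile's fit selection — never per domain, which would
break additivity.

## Nearest-contact trace

Bin boundaries are half-open with the boundary assigned upward: [0, 3) Å
close, [3, 6) mid, [6, ∞) far.  The published description of the scheme
("less than 3", "more than 6") leaves boundary membership unstated; the
half-open convention is fixed here so that every distance has exactly one
bin.  Ties between lid residues break toward the lower residue number.
The probe defaults to the whole peptide; restricting it to the N-terminal
residue is a one-line region change.

"A contact has formed" is operationalised as a **persistence criterion**:
the earliest time from which the binned trace stays at or below the
threshold bin for at least K consecutive records (default K = 10).  A
single-frame excursion is noise, not a formed contact; a trailing run
shorter than K does not qualify.

## Proximity factor and networks

The geometric mean is evaluated in log space; per-frame distances are
clamped below at 1e-6 Å before the logarithm.  A raw product over
thousands of frames would under- or overflow, and a coincidentally zero
distance would annihilate the product.  Single-frame windows degenerate
to the plain minimal distance; by the AM–GM inequality the proximity
factor never exceeds the arithmetic mean of the distances (equality iff
constant), both of which are asserted as properties.

Networks connect pairs with P at or below the cutoff.  Two cutoffs are
first-class configuration: 4.0 Å for display networks and 3.5 Å for
report tables.  A minimum sequence separation (default 4) drops
trivially adjacent backbone contacts, which are always "close" and carry
no structural information.  Analysis windows follow the
early-versus-late convention (first/last fraction of the run, default
`last:0.2`), expressed as time fractions so scaled-down runs use the same
configuration as long ones.

Common contacts across conditions default to "present in all but one
network" (k = n−1), with strict intersection (k = n) available.  The
packaged reference file `lid_contact_reference_sets.tsv` carries the
published per-condition contact distances for the DnaK SBD lid (crystal,
wild type, N1R, R2A, K577E); it is transcribed input data for
intersection analysis, stored at a 3.6 Å cutoff because the two-decimal
published values include entries rounded just above the nominal 3.5 Å.

## Synthetic trajectories and ground truth

The generator builds a one-pseudo-atom-per-residue complex: a compact
serpentine-lattice core (chain A), an extended lid arm whose last residue
is the tip (chain B), and a peptide in a groove under the core (chain P)
carrying the NRLLLTG residue names.  The lid tip is placed **exactly** at
the construction separation from the peptide tip — 22 Å by default, the
crystal-state lid-to-peptide separation of the reference system — and the
arm points away from the peptide so the tip is always the nearest lid
atom.

Motion has three independent parts, all reproducible bit-for-bit from one
seed:

* **Region amplitude**: a rigid random translation of the whole region,
  i.i.d. per frame, drawn so the RMS displacement equals the configured
  amplitude (per-coordinate σ = a/√3).
* **Per-atom noise**: i.i.d. Gaussian per atom, per coordinate, per
  frame (σ in Å).
* **Approach**: a deterministic translation of the mobile region along
  the tip-to-tip line, scaled by a profile s(t) ∈ [0, 1] that reaches 1
  exactly at the formation time t_c, so the programmed tip separation is
  d(t) = d₀ − s(t)(d₀ − d_final).  Profiles: `linear`, or `sigmoid`
  (logistic with time constant τ, centred 4τ before t_c and normalised to
  hit 1 at t_c).

Frame 0 is the base structure exactly, giving analyses a clean reference.

Ground truth emitted with every trajectory: the per-region expected MSD
contribution (mass fraction × (a² + 3σ² + mean squared approach offset)),
expected fractional contributions, the noise-free programmed distance
curve, the realized tip-pair distances, and the **true formation time**,
defined as the first sampled frame whose noise-free programmed distance
enters the close (< 3 Å) bin.

The default sigmoid time constant is **half a frame interval** (τ =
dt/2).  A formation time is only well defined at frame resolution when
the transition is fast against the sampling grid: with τ = dt the
noise-free distance one frame before the crossing sits around 3.3 Å,
close enough to the bin boundary that typical noise levels trigger
detection one sampling interval early in several percent of runs, whereas
with τ = dt/2 the pre-crossing frame sits near 6.6 Å and the crossing is
unambiguous.  τ is configurable (`approach_tau_ps`) for studying slower
approaches, where formation-time recovery degrades gracefully and by
design.

Study presets (chosen once as the package's reference conditions):

| preset | amplitudes (core/lid/peptide, Å) | noise σ (Å) | event |
|---|---|---|---|
| `approach` | 0.05 / 0.15 / 0.05 | 0.15 | sigmoid to 2.3 Å at t_c = 60 % of the run |
| `no-approach` | 0.05 / 0.15 / 0.05 | 0.15 | none (separation stays at 22 Å) |
| `rigid` | 0.02 / 0.02 / 0.02 | 0.02 | none |

Defaults: 250 frames × 10 ps.  The 2.3 Å final distance matches the
formed-contact scale of the reference system (2.31 ± 0.95 Å); the noise
level is a realistic per-atom jitter well inside the ≤ 0.3 Å regime in
which frame-accurate recovery is expected; the no-approach preset mirrors
the uncharged-peptide negative control, in which the lid never reorients
and the separation stays far above the contact bins.

**What the generator does not emulate**: force-field physics, solvent,
temporal autocorrelation (displacements are independent between frames),
internal deformation of regions (amplitude motion is rigid per region),
and hydrogens.  Passing parameter-recovery tests therefore demonstrates
that the estimators are correct and noise-robust under the stated
statistical model — not that any molecular-dynamics observable is
reproduced.  Real-trajectory behaviour (autocorrelated motion, slow
drift, conformational substates) can make the persistence criterion and
window choices matter more than they do here.

## Problem sizes

Tests and the acceptance script run on the 47-atom toy complex with
30–250-frame trajectories and 100-replicate recovery studies; these sizes
give sub-second analyses and standard errors comfortably inside the
stated recovery tolerances (the lid-fraction estimator's sampling error
at 250 frames is ≈ 0.3 %, against a 5 % tolerance).  All analyses scale
to real all-atom trajectories; the proximity matrix is the most expensive
stage (per frame, one atom-pair distance matrix over the selected
residues).

## Crystal-structure checks

The distance checks against the experimental DnaK SBD–peptide crystal
structure (lid Ser595 to peptide Asn1 ≈ 22 Å; lid pair proximity factors
531–581 ≈ 2.23 Å, 536–576 ≈ 2.68 Å, 547–573 ≈ 2.22 Å) require the PDB
entry 1DKX, which is not redistributable with this package.  The test
suite downloads it when the network allows, or uses a copy placed at
`data/1DKX.pdb`; in fully offline environments those tests fail with an
explanatory message while everything else remains self-contained.  A
0.3 Å tolerance covers atom-subset ambiguity (which atoms enter the
minimal distance is not fully specified in the published analyses), and
whether the published values were computed on the deposited coordinates
or on a minimised first frame is unknown — the checks here use the
deposited coordinates.
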