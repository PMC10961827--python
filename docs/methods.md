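# Methods

## Scope and model of the system

The package analyzes parallel-stranded, monomeric DNA G-quadruplexes with
four G-tracts contributing one guanine per tetrad layer, all-*anti*
glycosidic conformations, and single-nucleotide resolution. Antiparallel
and hybrid topologies are outside the classification taxonomy (a tetrad is
still detected wherever the Hoogsteen 4-cycle forms). Coordinates are
Angstrom internally; channel radius of gyration and surface areas are
converted to nm / nm² only when reported, matching the units in which the
corresponding thresholds are conventionally quoted.

## Tetrad detection

Hydrogen bonds are accepted on geometry alone: donor–acceptor distance
≤ 3.5 Å and D–H–A angle ≥ 135° (both configurable). These values are
common practice for nucleic-acid analysis; nothing in the package is
sensitive to modest changes. When the structure carries no hydrogens, an
idealized H is placed 1.01 Å from the donor: along the sp² bisector for
ring N–H, and at ±60° from the extended C–N bond, in the aromatic plane,
for amino groups. A tetrad is a directed 4-cycle of guanines where each
edge carries *both* Hoogsteen bonds (N1→O6 and N2→N7); the strict
both-bond rule favours precision over recall and can be relaxed to
either-bond. Cycles must pass an RMS planarity check (≤ 0.5 Å over the
guanine ring atoms). Cycles are reported once, rotated to start at the
lowest residue.

## Fold classification

* **Stack axis** — centroid difference for two tetrads, first principal
  component of centroids for more, oriented from the 5′-side tetrad
  (identified by residue order within the tracts) to the 3′ side.
* **Twist** — for each pair of azimuthally adjacent strands, the C1′→C1′
  edge vector is projected perpendicular to the axis in both tetrads and
  the signed angle between the projections is measured; θ is the circular
  mean of the four edges. Positive θ = right-handed screw about the 5′→3′
  axis. Strand correspondence between stacked tetrads requires
  sequence-adjacent residues on the same chain, so block-stacking
  interfaces (where no strand continues) are skipped automatically.
* **Helicity** — RH above +5°, LH below −5°, indeterminate inside the
  dead zone; the dead zone exists so that thermal noise around 0° is not
  assigned a handedness.
* **Progression** — tract C1′-centroid azimuths are measured in a
  right-handed frame (e₁, e₂, axis); "+" when the azimuth decrements by
  ≈90° (±45°) from tract i to i+1, "−" when it increments. Which physical
  sense of rotation this labels was fixed so that the builder/classifier
  pair reproduces the established pairing of left-handed folds with (+)
  and right-handed folds with (−) progression.
* **Polarity** — sign of axis·Σ rᵢ×rᵢ₊₁ over the donor cycle positions
  about the tetrad centroid: +1 when the Hoogsteen donor cycle circulates
  counterclockwise about the axis.

## The idealized builder

Single-nucleotide internal geometry comes from the standard chemical
component definitions bundled with biotite. Two corrections are applied
before use: the deoxyribose is rebuilt at the C2′-endo (South) pucker
(pseudorotation phase 162°, amplitude 38°) typical of B-form and parallel
G4 tracts — the as-shipped ideal conformer sits in a non-helical pucker —
and the glycosidic torsion is set explicitly.

The tetrad is solved by placing the base in the stack plane with C1′ at a
prescribed radius and rotating it in-plane until the two Hoogsteen
contacts to the 90°-rotated copy both reach 2.90 Å, with a steric guard
against the spurious interpenetrating solution branch. Minimizing the
residual over the radius as well defines the canonical C1′ radius,
8.13 Å, used by default (the O6 channel radius then comes out 2.24 Å,
in the range seen in solved parallel G4s).

Stacking applies the screw (twist θ, rise 3.4 Å per step; 3.4 Å is the
canonical base-stacking distance). The G-tract backbone conformation
(χ within the anti window [−170°, −90°], γ, β) is then solved once per
twist by driving the inter-residue P···O3′ virtual bond to 1.60 Å with a
plausible O3′–P–O5′ angle; weak priors toward canonical B-form torsions
(χ −117°, γ 54°, β 171°) select among degenerate solutions. Both strand
directions relative to the stack are tried, and only one closes for a
given twist sign: right-handed twists close with the 5′ tetrad at the
bottom of the screw, left-handed twists with it on top. Consequently the
relaxed RH and LH cores carry opposite tetrad polarity, as the deposited
RH/LH structure pair does. χ is refined per twist rather than pinned at
−120° because backbone closure is geometrically impossible for
right-handed twists with a rigid sugar at fixed χ; the refined values
stay inside the anti window, and `build_tetrad` (no stacking context)
keeps χ = −120°.

Strand progression is realized as the threading order of the tracts —
which stack end the sequence enters from ("+" = 5′ on top). Reversing the
progression at fixed helicity therefore flips tetrad polarity, and the
two stable fold types, RH(−) and LH(+), are exactly the ones whose
threading matches the closure direction of their core; the prohibited
folds LH(−) and RH(+) are built with an unclosed (strained) intra-tract
backbone, mirroring their kinetic instability. The 5′-terminal guanine of
each tract has no upstream tract neighbour, so its phosphate arm is set
to the relaxed canonical conformation (γ⁺/β-trans) instead of the
closure solution.

Loops are geometric placeholders: rigid thymidines placed along a
quadratic Bézier arc between the attachment atoms, bases swung outward.
No torsional realism is claimed for them; clashes with the core trigger a
warning, not an error. Loop-span analysis needs only the attachment
geometry, which is why this is sufficient.

With these choices the idealized two-layer builds give attachment-span
differences of 6.9 Å (LH−RH at (−) progression) and 4.9 Å (RH−LH at (+)),
which `scripts/acceptance.py` recomputes end-to-end; the conventional
reference values are 7 Å and 6 Å, measured on fully relaxed simulated
structures, so the idealization is expected to land within ~1.5 Å rather
than exactly.

## Collective variables

Channel RoG uses the O6 atoms of all detected tetrad guanines
(mass-unweighted; the folded boundary 0.37 nm is applied strictly, folded
= RoG < 0.37 nm). ΔRMSD superposes the probe independently onto each
reference with proper-rotation Kabsch (scipy) on the same heavy-atom
selection. Loop spans are O3′(3′-terminal G of tract i) to
P(5′-terminal G of tract i+1), the atoms that bracket the loop's covalent
ends; C1′–C1′ is available as an option. SASA is Shrake–Rupley with Bondi
radii, probe 1.4 Å and a 960-point golden-spiral sphere, which makes
results reproducible bit-for-bit; the S/E thymine classifier applies
1.63 nm² strictly (< is S), per loop-terminal thymine, with a
molecule-level aggregate left to the caller. Hydrogen-bond occupancy
reports the fraction of frames with ≥1 bond matching a donor/acceptor
selector pair; when a state series is supplied, the total is defined as
the sum of the S- and E-frame fractions so the decomposition is additive
by construction. The "O4 of deoxyribose" acceptor named in the LH
hydrogen-bonding literature is mapped to the sugar ring oxygen O4′
(deoxyribose has no O4).

QM fragment preparation severs the two glycosidic C1′–N9 bonds of a
stacked guanine dinucleotide and caps them with hydrogens at 1.09 Å
(backbone side, C–H) and 1.01 Å (base side, N–H) along the bond
directions; heavy atoms partition exactly between the sugar–phosphate
fragment and the base-stack fragment and no original coordinate moves,
so external single-point energies decompose the total into backbone and
stacking contributions.

## Kinetics and free energies

State series are built by strict thresholding, with an optional
minimum-dwell filter that absorbs sub-threshold flickers into the
surrounding state (shortest interior run first). Dwells are maximal runs;
the final run is censored by the observation window, while the initial
run counts as complete because unfolding runs start in-state by
construction (both toggles are exposed). The mean lifetime is the
censored-exponential MLE (total observed time over number of completed
dwells), which stays unbiased when long dwells are cut; the naive mean of
completed dwells is also reported for transparency, and a dwell-resampling
bootstrap provides intervals. Grid reporting merges dwells shorter than
one frame into their neighbours, so lifetime validation keeps both state
lifetimes well above the frame spacing.

Boltzmann inversion uses 100 bins by default over the sampled range, with
empty bins masked rather than pseudo-counted, and profiles min-shifted to
zero. WHAM is the standard histogram self-consistent iteration over the
window free energies (tolerance 10⁻¹⁰ on max |Δf|), reduces exactly to
Boltzmann inversion for a single unbiased window, is invariant to window
order and duplication, and refuses window sets whose histograms do not
overlap. Basin statistics take the two basin minima on either side of a
stated boundary and the highest sampled point between them as the
barrier, flagged absent for monotonic profiles.

## Synthetic dynamics

The telegraph generator draws dwell times exactly from the exponential
distributions (the reporting grid only discretizes labels), starts in the
folded state, flags the final truncated dwell censored, and exposes its
internal event log so estimator tests can compare against ground truth.
The Langevin generator is Euler–Maruyama on
U(x) = a(x²−b²)² + cx + ½k(x−x₀)², with an optional harmonic umbrella for
WHAM window generation, one seeded RNG per call, and an explicit
divergence error naming the time step. Validation sizes were chosen so
statistical error sits comfortably inside the stated tolerances: ~10⁴
dwells for the 3-standard-error lifetime check, 6×10⁶ steps for the 3 %
Ornstein–Uhlenbeck variance check (the Euler discretization bias at
θ·dt ≈ 8×10⁻³ is an order of magnitude below it), 4×10⁶ unbiased steps
and 12 umbrella windows of 1.5×10⁵ steps for the double-well recoveries.

## What the synthetic data do and do not show

Idealized builds and parameter-jittered "ensembles" exercise the full
analysis chain with known ground truth, but they are exactly C4-symmetric,
carry no ions, no thermal backbone disorder and no loop physics; passing
tests demonstrate correctness of the geometry and estimators, not
force-field-level realism. The telegraph/Langevin generators match the
estimators' model assumptions by construction; real trajectories break
those assumptions (non-exponential dwells, position-dependent diffusion),
which is precisely why the estimators are validated where the truth is
known. Absolute folding free energies and lifetimes of real G4s require
microsecond-scale simulation and are out of scope.

## Known limitations

PDB is the only structure dialect (no mmCIF, no binary trajectory
formats); multi-model PDB stands in for trajectories. Bulged or
discontinuous G-tracts are found only if their Hoogsteen 4-cycle forms,
and strand correspondence (hence twist) requires sequence-adjacent
guanines. The builder's strained folds carry an open intra-tract P···O3′
virtual bond rather than a distorted closed one. SASA thresholds are
applied with the stated radii/probe; a different radius set shifts
absolute areas by a few percent.
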