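# Methods

## Scope and philosophy

`ringmotor` is a desk-scale re-implementation of a potential-switching
coarse-grained simulation of a hexameric ring motor (a CMG/Mcm2-7 proxy)
on DNA. The published full-scale calculations use cryo-EM-derived
structure-based force fields (an AICG2+-class protein model and a
3SPN-class three-site DNA model) on systems of thousands of beads with
10⁷ steps per state dwell; none of that is desk-reproducible. This
package therefore replaces the structural inputs with synthetic toy
geometry whose *registry* is constrained by the printed step sizes, and
replaces the published force fields with simple stand-ins that keep the
same functional roles. What is preserved — and what the tests probe — is
the mechanism: directional translocation from asymmetric switching among
four DNA-binding states, its failure modes (idling, backstepping,
reversed-cycle null), sequence-dependent duplex unwinding coupled 1:1 to
translocation, lagging-strand clogging, nucleosome unwrapping, and the
accessory-factor effects.

## The switching model

Four reference states engage four of six subunits each ({2,3,5,6},
{2,3,5,7}, {3,4,6,7}, {7,4,6,2}); each engaged subunit's pore loop grips
~2 nt of the tracked strand in a right-handed staircase. The registry
offsets Δ = {0, 1, 7, 9} nt are derived from the printed per-transition
steps (1, 6, 2, 3 nt) and close a 12-nt cycle exactly; the per-subunit
height table (see `synthetic_topology`) is one consistent solution — the
individual nucleotide registers are not uniquely determined by the step
sizes, and the generator assumes the same staircase polarity for state 4
as for states 1–3. Subunits engaged across a transition drop by the step
size and drag the DNA; the released subunit's well is switched off and
the newly engaged subunit's well forms on whatever phosphate arrives at
its site. At the ambiguous 3→1 transition of the three-state cycle the
height table makes anchor-6 retention a +5 nt step and anchor-3 retention
a −7 nt backstep, which is what produces the bimodal forward/idling
outcome.

A potential switch is abrupt, but two relaxation processes accompany it,
both essential for the mechanism to function (see "Design choices"):

* **Conformational relaxation.** The loop-target restraints move linearly
  from the old to the new staircase over `loop_move_steps` (4 000 steps).
  An instantaneous target jump of several nt tears every anchor free of
  its phosphate before the DNA can follow; the interpolated motion lets
  anchors drag quasi-statically, standing in for the continuous
  conformational relaxation a full elastic-network protein model would
  provide.
* **Grip formation.** A newly engaged subunit's hydrogen-bond well deepens
  linearly from zero over `hb_form_steps` (12 000 steps) after the
  switch; retained subunits keep mature wells. Hydrogen-bond networks
  form progressively on contact, and without this asymmetry freshly
  engaging subunits pin the *old* registry and block the anchors' drag.
  The ramp is keyed strictly to the switch time: in a steady dwell and in
  the no-switch null the potential set is time-independent, so there is
  no ratchet pathway (history-dependent formation kinetics were tried and
  rejected for exactly that reason — they rectify thermal noise).

The grip well itself is a Gaussian from the loop bead to the *nearest*
eligible phosphate, restricted to an axial window (`hb_axial_window`,
2.5 nt) around the loop's structural position — a stand-in for the
orientational specificity of coarse-grained hydrogen-bond potentials.
Sliding eligibility is what lets registry choice, idling and backstepping
emerge instead of being scripted; the window keeps a displaced loop from
raking the strand as it travels.

The conformation-only control switches the loop targets but retains the
hydrogen-bond contact set; the frozen mode switches nothing (a diffusion
null).

## Force field

All values in reduced units: length 1 ≈ 6 Å (one nt of ssDNA rise),
energy 1 = k_BT at 300 K, bead mass 5, charge in e.

| term | form | defaults |
|------|------|----------|
| bonds / angles | harmonic, zero at built geometry | k_bond 120, k_angle 8 |
| scaffold | position restraints on ring body & histone core | k 50 |
| loop targets | per-state restraints on the six pore loops | k_loop 14 |
| excluded volume | ½·ε(σ−r)² for r < σ = r_i+r_j | ε_ev 100 |
| electrostatics | Debye–Hückel, shifted cutoff at 5 λ_D | 300 mM, 300 K, ε 72.2 |
| base pairing | Morse well per pair, broken beyond 5%-depth distance | ε_AT 5, ε_GC 8, a 4 |
| stacking | Gaussian between consecutive bases | ε 3, r₀ 1, σ 0.35 |
| motor grip | Gaussian to nearest windowed phosphate | ε_HB 30, σ 0.25, r₀ 0.15 |
| nucleosome sites | Gaussian, reference separation from assembly | outer 2.5, inner 10 |
| RPA wells | fixed Gaussian bead–phosphate pairs | ε 8 |

Charge rules follow the published convention: phosphates −0.6 e toward
other DNA (counterion condensation), −1.0 e toward protein (counterion
release), ±1 e on charged protein beads (factor patches, disordered
tails, the exposed histone-dimer surface). Turning the fork-protection
complex's electrostatics off zeroes its patch charges and nothing else.

Integration is BAOAB underdamped Langevin with friction 0.843 and
timestep 0.1 (the source model's nominal 0.2 presumes its own mass and
stiffness scales; at ours, 0.1 keeps dt·ω < 1.2 for the stiffest mode).
Velocities are Maxwell–Boltzmann at assembly only; switches leave
coordinates and velocities untouched. The timestep halves automatically
on force overflow (logged); neighbor lists rebuild every 25 steps with a
1-unit skin.

The excluded volume is a harmonic overlap repulsion rather than a power
law: a hard r⁻¹² wall has unbounded curvature and is linearly unstable
under this integrator at any workable mass, while the harmonic wall keeps
the same contract (purely repulsive, zero beyond contact, monotone in
overlap).

## Toy geometry

* **Ring**: 6 subunits × 20 body beads + 1 loop bead each. Fourteen
  pore-lining beads per subunit at exactly 1-nt axial spacing form a snug
  wall (channel proper z ≤ 9.5; the wall continues to the fork mouth so a
  duplex cannot slip between columns, with collar beads closing the
  upper-wall gaps). Pore radius 1.25 passes ssDNA and excludes duplex.
  The dense commensurate wall is load-bearing: a sparse or twisted-lining
  channel lets the chain buckle and turns the sliding wells into a
  compression ratchet that translocates without switching.
* **DNA**: 3 beads/nt; 1 unit rise for both ssDNA and the toy (untwisted,
  ladder-form) duplex; duplex backbones ±1 from the axis, paired bases
  0.8 apart. The in-pore lateral direction is constant — a twist against
  the discrete wall tilts the registry landscape.
* **ssDNA scenario**: 60 nt with the motor at nt 30 (full-scale 495 nt /
  position 157 remains constructible).
* **Fork**: parental 20 bp, lagging arm 6 bp, leading arm 6 bp, lagging
  ssDNA 8 nt, leading ssDNA 18 nt by default (full-scale dimensions
  constructible). The subunit-3 loop starts 7 nt from the junction; the
  distal parental terminus is anchored through the lagging strand only,
  so motor pull loads the junction base pairs rather than an anchor on
  the tracked strand.
* **Nucleosome**: 27-bead rigid core; 14 half-integer-SHL contact sites
  at 5 bp per half-SHL on a 70-bp wrap (dyad at SHL 0); the fork junction
  sits 22 bp upstream of the chosen start position (−7, −5, −4 or −3),
  and sites outward of the start are detached by construction. The
  exposed H2A/H2B dimer surface is a positively charged core patch whose
  exposure requires detachment of the entry sites −6.5…−3.5.
* **Factors**: RPA = 4-bead bodies tiling the lagging ssDNA (toy
  footprint 8 nt; 25 nt at full scale) bound by fixed strong wells (the
  published protocol likewise strengthens this interaction so occupancy
  persists); FPC = 8-bead body tethered at the ring front with a +1 e
  patch facing the parental duplex; Ctf4/Mrc1 = inert tethered bodies;
  FACT = 6-bead domain at the dyad plus an 8-bead acidic tail (the
  Spt16-CTD proxy) that competes with the lagging strand for the exposed
  dimer surface. Placement retries with seeded jitter until clash-free.

Assemblies are validated clash-free (minimum inter-body separation ≥ 0.8
of summed radii) and are bitwise reproducible from scenario + seed.

## Protocols and measurement

The toy switching interval is 16 000 steps — the smallest dwell at which
the post-switch energy plateaus (slope test over the last 20% of a
segment) and the conformational + grip-formation relaxations complete;
one protocol run therefore costs (n_states + 1) × 16 000 steps. Each
experiment runs 20 replicates at seeds seed0 + i with non-overlapping
seed blocks per experiment.

Displacement is the index of the nucleotide whose phosphate is nearest
the *channel-frame site* of subunit 3's loop (its engaged position in
state 1), positive toward 5′, with hysteretic tie-breaking. The fixed
reference site (rather than the instantaneous loop bead) matters in the
toy because the loop itself travels several nt during a conformational
change, which would hide the intra-cycle steps; in the full-scale model
the loop moves negligibly and the two definitions coincide. Steps are
differences of segment-tail means (last 10% of each dwell, configurable),
so they telescope to the net displacement exactly; outcomes classify as
forward (> +3 nt), backward (< −3 nt) or idling. Unwinding is the
contiguous run of broken pairs from the junction (distal fraying is not
unwinding); clogging uses the 10-Å-equivalent lagging-strand-to-pore
distance; unwrapping is the innermost detached entry-side SHL of the
contiguous detached run from the entry end; lagging-strand capture
requires the exposure rule plus persistent contact with the dimer patch.
Condition comparisons use the one-tailed Wilcoxon–Mann–Whitney test
(exact permutation for n ≤ 10 without ties) with Cohen's d.

## What the generator emulates — and what it does not

The synthetic structures encode the facts that constrain the mechanism:
the four engaged-subunit sets, ~2 nt per subunit in a right-handed
staircase, the printed fork-arm proportions, the 7-nt loop-to-junction
offset, the 22-bp junction-to-nucleosome offset, and half-integer SHL
contact sites with graded strengths (outer sites breathe, sites inward of
SHL(−5) stay formed ≥ 99% of an equilibrium run). It does not emulate
real protein elasticity (rigid scaffolds with one grip bead per subunit),
helical DNA geometry, sequence-specific nucleosome positioning, or the
published force-field parameterizations. Passing tests therefore
demonstrate that the *switching geometry* suffices for directional
translocation and its couplings in a minimal physical setting — not that
the stand-in force field is quantitatively transferable to real
replisomes.

## Numerical and design choices

* Registry table: the cycle-closure invariant (steps summing to 12 nt on
  both pathways) holds exactly; the particular height assignment is one
  consistent solution chosen so every printed anchor narrative holds
  (e.g. the 3′-side release by subunit 6 at 1→2, subunit 3's release and
  5′ re-engagement around state 4).
* One grip bead and one sliding well per engaged subunit; the ~2
  nt/subunit engagement lives in the registry metadata. Grip beads are
  excluded from nonbonded terms so the well alone sets the grip geometry.
* Base-pair break distance = where the Morse well retains 5% depth;
  electrostatic cutoff = 5 Debye lengths with energy shift; contact
  capture radius = r₀ + 2σ of the grip well; clogging threshold fixed at
  the 10-Å equivalent.
* Degenerate inputs raise: pores that cannot pass ssDNA (or would pass
  duplex), ring positions without staircase clearance, unthreadable
  forks, unknown states/modes/keys.
* Tie-breaks: nearest-phosphate selection is hysteretic in the metrics;
  in the energetics the argmin is exact (energy is continuous across
  eligibility changes).

## Known limitations

* **Three-state 3→1 completion.** The tug-of-war between subunits 3
  and 6 resolves, but the winner often cannot finish its full drag
  against the loser's re-formed grip within one dwell: forward-classified
  three-state runs average ~+9–12 nt rather than a tight 12 ± 1, the
  forward 3→1 step reads low, and idling backsteps are shallower than
  −7. The single-bead grip lacks the multi-contact cooperativity that
  lets the full structure-based model's winning anchor displace the
  re-binding loser. The four-state cycle — the mechanism's main result —
  does not suffer from this (all transitions are anchor-cooperative) and
  reproduces all four step sizes, the ~11–12 nt total, and 20/20 forward
  outcomes.
* Fork displacements carry ~1–2 nt of elastic slack relative to unwound
  base pairs, which lowers the toy displacement/unwinding correlation
  (~0.75–0.9) relative to the full-scale value (0.94).
* Nucleosome-condition statistics (unwrapping distributions, capture
  frequencies, the chaperone rescue at SHL(−3)) are implemented and
  runnable through the experiment registry, but at 20 replicates they
  exceed a test-suite time budget; the suite checks these effects as
  orderings at reduced replicate counts and trusts the metrics' unit
  tests for their definitions.
* Physical time is not mapped: the toy reports steps, not nanoseconds
  (the source model's own step-to-time mapping is ambiguous, and dwell
  times between states are experimentally undetermined).
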