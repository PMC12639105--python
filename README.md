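# ringmotor

Coarse-grained, potential-switching Langevin simulations of a hexameric
ring motor — a toy Cdc45–Mcm2-7–GINS (CMG) replicative-helicase model —
translocating 3′→5′ along single-stranded DNA, unwinding duplex DNA at a
replication-fork junction, and colliding with a nucleosome, together with
every trajectory metric needed to quantify its stepping, unwinding,
lagging-strand clogging, nucleosome unwrapping and histone-surface capture.

The package is aimed at molecular-motor modellers who want a desk-scale,
fully seeded re-implementation of the asymmetric hand-over-hand switching
mechanism: all structures are generated synthetically (no external data),
one switching cycle runs in seconds, and every reported quantity is
recomputed from trajectories.

## The model

The Mcm2–7-like motor is a ring of six subunits (adjacency 5-3-7-4-6-2),
each carrying one DNA-binding pore-loop bead (a ps1β proxy). ATP-driven
conformational changes are modelled as *potential switching* among four
DNA-binding reference states; state *s* engages four subunits whose loops
grip the tracked strand at a right-handed staircase of axial positions
*z*(*i*) (≈2 nt of ssDNA per subunit), with registry offset Δ_s:

| state | engaged subunits | loop heights (nt) | Δ_s (nt) |
|-------|------------------|-------------------|----------|
| 1 | 2, 3, 5, 6 | 6:1 5:3 2:5 3:7 | 0 |
| 2 | 2, 3, 5, 7 | 5:2 2:4 3:6 7:9 | 1 |
| 3 | 3, 4, 6, 7 | 3:0 7:3 6:6 4:8 | 7 |
| 4 | 7, 4, 6, 2 | 7:1 6:4 4:6 2:8 | 9 |

Subunits engaged in two consecutive states keep their grip and drag the
DNA by the registry difference, giving heterogeneous steps of 1, 6, 2 and
3 nt over the 1→2→3→4→1 cycle (12 nt per cycle, closure exact). In the
three-state cycle 1→2→3→1 the final transition is ambiguous — subunits 3
and 6 are engaged on both sides — so a run either advances (+5, anchor 6)
or backsteps (−7, anchor 3), reproducing the idling branch.

The grip is a switchable Gaussian "hydrogen-bond" well from each engaged
loop to its *nearest* tracked-strand phosphate (within an axial window
around the loop's structural position), so the registry, idling and
backstepping emerge from the dynamics rather than being scripted. DNA is
three beads per nucleotide (phosphate–sugar–base) with Morse base pairing
(GC deeper than AT), stacking, Debye–Hückel electrostatics (300 mM, 300 K,
ε = 72.2; phosphates −0.6 e toward DNA, −1.0 e toward protein) and soft
excluded volume; integration is BAOAB Langevin with friction 0.843.

## Worked example

Twenty seeded replicates of one four-state switching cycle on a 60-nt
single strand:

```
$ ringmotor experiment ss_4state --replicates 20 --seed 1000 --outdir out_4state
{
 "experiment": "ss_4state",
 "n_replicates": 20,
 "n_completed": 20,
 "net_mean": 11.26,
 "net_std": 2.21,
 "counts": {
  "forward": 20,
  "idling": 0,
  "backward": 0
 }
}
```

Every replicate translocates forward, advancing 11.3 ± 2.2 nt per cycle —
near the ideal 12 nt expected from six subunits engaging ~2 nt each. The
per-transition step table (`out_4state/steps.csv`) resolves the
heterogeneous stepping pattern, with means near 1, 6, 2 and 3 nt for the
1→2, 2→3, 3→4 and 4→1 transitions. A single run with trajectory output:

```
$ ringmotor run --seed 5 --outdir out_run --pdb
net displacement +11.2 nt (forward); outputs in out_run
```

which writes a multi-model PDB, a bit-exact coordinate CSV, per-frame
metrics, and a manifest (config hash + seeds) that reproduces the run.
The default protocol is the three-state cycle, whose runs split between
forward translocation and idling, so another seed may finish near 0 nt.

From Python, the same machinery:

```python
from ringmotor import synthetic_topology, engine, metrics

asm = synthetic_topology.build_fork_scenario(sequence_mode="polyAT", seed=0)
traj = engine.run_protocol(asm, engine.SwitchProtocol(sequence=(1, 2, 3, 4)),
                           seed=0)
summary = metrics.summarize_run(traj)
summary.net_displacement    # nt translocated in one cycle
summary.unwound_bp_final    # base pairs unwound at the junction
summary.clogged_fraction    # frames with lagging strand inside the pore
```

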