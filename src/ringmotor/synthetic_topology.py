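"""Toy structures for the ring-motor simulations.

This module generates every structure the simulations run on: a six-subunit
ring motor with one DNA-binding pore loop per subunit, single-stranded DNA,
a Y-fork (parental / lagging / leading arms), a nucleosome with 14
half-integer superhelical-location (SHL) contact sites, and simplified
accessory-factor bodies (RPA, Csm3/Tof1 fork-protection complex, Ctf4/Mrc1,
FACT).  It also defines the four DNA-binding reference states of the motor
and their registry geometry.

Geometry conventions
--------------------
* The motor channel axis is +z; the ring occupies z in [0, ~9.5].
* Nucleotide indices on the tracked (leading-template) strand increase
  toward the 5' end, so forward 3'->5' translocation of the motor reads as
  a positive index displacement.  DNA on the 5' side feeds into the channel
  from the top (+z).
* One nucleotide of ssDNA rise equals one reduced length unit.

Reference-state registry
------------------------
Four DNA-binding states engage four of the six subunits each:

=====  ================  ======================  ================
state  engaged subunits  loop height (z) per     registry offset
       (ring labels)     engaged subunit, nt     Delta_s, nt
=====  ================  ======================  ================
1      2, 3, 5, 6        6:1  5:3  2:5  3:7      0
2      2, 3, 5, 7        5:2  2:4  3:6  7:9      1
3      3, 4, 6, 7        3:0  7:3  6:6  4:8      7
4      7, 4, 6, 2        7:1  6:4  4:6  2:8      9
=====  ================  ======================  ================

Subunits engaged in consecutive states whose loop height drops by delta
drag the DNA forward by delta nucleotides, giving per-transition steps of
1 (1->2), 6 (2->3), 2 (3->4) and 3 (4->1), closing a 12-nt cycle.  In the
three-state cycle the 3->1 transition is ambiguous: if subunit 6 keeps its
grip the step is +5; if subunit 3 does, it is -7 (a backstep that cancels
the cycle).  The height table is one consistent solution to the printed
step sizes; the per-subunit nucleotide registers themselves are not
uniquely determined.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# constants

KIND_PROTEIN = 0
KIND_PHOSPHATE = 1
KIND_SUGAR = 2
KIND_BASE = 3
KIND_NAMES = {
    KIND_PROTEIN: "protein",
    KIND_PHOSPHATE: "phosphate",
    KIND_SUGAR: "sugar",
    KIND_BASE: "base",
}

#: ring adjacency order (azimuthal placement); standard architecture of the
#: Mcm2-7 hetero-hexamer.  Only adjacency matters, not absolute orientation.
RING_ORDER = (5, 3, 7, 4, 6, 2)

STATE_IDS = (1, 2, 3, 4)
STATE_ENGAGED = {
    1: frozenset({2, 3, 5, 6}),
    2: frozenset({2, 3, 5, 7}),
    3: frozenset({3, 4, 6, 7}),
    4: frozenset({7, 4, 6, 2}),
}
STATE_HEIGHTS = {
    1: {6: 1.0, 5: 3.0, 2: 5.0, 3: 7.0},
    2: {5: 2.0, 2: 4.0, 3: 6.0, 7: 9.0},
    4: {7: 1.0, 6: 4.0, 4: 6.0, 2: 8.0},
    3: {3: 0.0, 7: 3.0, 6: 6.0, 4: 8.0},
}
REGISTRY_OFFSETS = {1: 0, 2: 1, 3: 7, 4: 9}
CYCLE_NT = 12

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

# bead radii (reduced length)
R_PROTEIN = 0.40
R_PHOSPHATE = 0.30
R_SUGAR = 0.28
R_BASE = 0.25

# per-nucleotide local geometry: offsets of S and B from P along the
# lateral unit vector pointing toward the pairing partner
OFF_SUGAR = 0.35
OFF_BASE = 0.60
#: distance between paired base beads at the duplex reference geometry
BP_DISTANCE = 0.80
#: half-separation of the two phosphate backbones in a duplex
DUPLEX_HALF_WIDTH = 1.0
#: rise per nucleotide along a strand (ss and toy duplex alike)
RISE = 1.0

SHL_LABELS = tuple(s / 2.0 for s in range(-13, 14, 2))  # -6.5 .. +6.5
BP_PER_SHL = 5  # toy compression: 5 bp between half-integer SHL sites
NUC_ENTRY_OFFSET_BP = 22  # fork junction sits 22 bp upstream of the target SHL


class AssemblyError(ValueError):
    """Raised when a scenario cannot be assembled (geometry or clashes)."""


# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class BeadSpec:
    """One coarse-grained bead.

    ``residue_index`` is the nucleotide index for DNA beads (increasing
    toward the 5' end of the tracked strand) and a residue counter for
    protein beads.
    """

    bead_id: int
    kind: str
    chain_id: str
    residue_index: int
    mass: float
    radius: float
    charge: float


@dataclass
class RingTopology:
    subunit_labels: tuple
    body_beads: dict  # label -> list of bead ids
    loop_bead: dict  # label -> bead id
    channel_axis: np.ndarray
    pore_bead_set: np.ndarray  # bead ids lining the channel
    azimuth: dict  # label -> radians
    loop_radius: float
    park_radius: float
    park_z: float
    loop_rise_per_nt: float
    pore_radius: float
    z_top: float


@dataclass
class ReferenceState:
    state_id: int
    engaged_set: frozenset
    registry_offset: int
    loop_heights: dict  # engaged label -> axial coordinate (nt units)
    per_subunit_registry: dict  # engaged label -> (rank, rank+1)
    loop_targets: dict  # label (all 6) -> xyz target for the loop bead
    native_pair_list: tuple  # ((loop_bead_id, target_xyz), ...) realization


@dataclass
class DNATopology:
    strands: list  # [(chain_id, sequence)]
    pairing_table: pd.DataFrame  # columns: nt_i, nt_j, chain_i, chain_j, cls
    fork_junction_index: Optional[int]
    tracked_strand: str
    tracked_phosphates: np.ndarray  # bead ids ordered by nt index
    tracked_nt_index: np.ndarray  # nt index per entry of tracked_phosphates


@dataclass
class NucleosomeTopology:
    core_beads: np.ndarray
    contact_sites: pd.DataFrame  # columns: shl, anchor_bead, dna_bead, nt, eps
    dyad_index: int
    h2ab_patch: np.ndarray
    exposure_rule: tuple  # SHL labels whose detachment exposes the patch


@dataclass
class FactorSet:
    rpa_bodies: list = field(default_factory=list)  # [(bead ids, (nt0, nt1))]
    fpc_body: Optional[np.ndarray] = None
    fpc_patch: Optional[np.ndarray] = None
    inert_bodies: list = field(default_factory=list)
    fact_body: Optional[np.ndarray] = None
    fact_tail: Optional[np.ndarray] = None
    fpc_electrostatics_on: bool = True


@dataclass
class ScenarioSpec:
    name: str
    kind: str  # "ssdna" | "fork" | "nucleosome"
    seed: int
    n_nt: int = 0
    ring_position_nt: int = 0
    parental_bp: int = 0
    lagging_bp: int = 0
    leading_bp: int = 0
    lagging_ss_nt: int = 0
    leading_ss_nt: int = 0
    sequence_mode: str = "random"
    lagging_arm_mode: str = "ssDNA"  # or "duplex-occluded"
    shl_start: float = -7.0
    factors: tuple = ()
    fpc_electrostatics_on: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# --------------------------------------------------------------------------
# assembly container


@dataclass
class Assembly:
    """A complete, simulation-ready system: packed arrays plus metadata."""

    pos: np.ndarray  # (N, 3)
    kind: np.ndarray  # int8
    chain_code: np.ndarray  # int16
    chain_ids: list
    resindex: np.ndarray  # int32
    mass: np.ndarray
    radius: np.ndarray
    q_intra: np.ndarray  # charge used between DNA beads
    q_cross: np.ndarray  # charge used when a protein bead is involved
    is_dna: np.ndarray  # bool
    group: np.ndarray  # int32 exclusion group (-1: chain-distance rule)
    mobile: np.ndarray  # bool
    bonds: np.ndarray  # (B, 2) int32
    bond_k: np.ndarray
    bond_r0: np.ndarray
    angles: np.ndarray  # (A, 3) int32
    angle_k: np.ndarray
    angle_t0: np.ndarray
    scaffold_idx: np.ndarray  # position-restrained beads
    scaffold_k: np.ndarray
    scaffold_pos: np.ndarray  # (R, 3)
    pair_i: np.ndarray  # base bead ids (tracked side)
    pair_j: np.ndarray  # base bead ids (partner side)
    pair_cls: np.ndarray  # int8: 0 = AT, 1 = GC
    stack_i: np.ndarray
    stack_j: np.ndarray
    site_anchor: np.ndarray
    site_dna: np.ndarray
    site_eps: np.ndarray
    site_shl: np.ndarray
    site_r0: np.ndarray
    fixedwell_i: np.ndarray
    fixedwell_j: np.ndarray
    fixedwell_eps: np.ndarray
    ring: RingTopology
    dna: DNATopology
    scenario: ScenarioSpec
    states: list
    nucleosome: Optional[NucleosomeTopology] = None
    factors: Optional[FactorSet] = None

    @property
    def n_beads(self) -> int:
        return self.pos.shape[0]

    def bead_table(self) -> pd.DataFrame:
        """Per-bead table (one row per :class:`BeadSpec`)."""
        return pd.DataFrame(
            {
                "bead_id": np.arange(self.n_beads),
                "kind": [KIND_NAMES[int(k)] for k in self.kind],
                "chain_id": [self.chain_ids[c] for c in self.chain_code],
                "residue_index": self.resindex,
                "mass": self.mass,
                "radius": self.radius,
                "charge": np.where(self.is_dna, self.q_intra, self.q_cross),
                "x": self.pos[:, 0],
                "y": self.pos[:, 1],
                "z": self.pos[:, 2],
            }
        )

    def min_separation_ratio(self) -> float:
        """min over inter-group bead pairs of distance / (r_i + r_j).

        Brute-force; used to validate the clash-free invariant at assembly.
        """
        return _min_separation_ratio(
            self.pos, self.radius, self.group, self.chain_code, self.resindex
        )

    def copy(self) -> "Assembly":
        out = dataclasses.replace(self)
        out.pos = self.pos.copy()
        return out


def _min_separation_ratio(pos, radius, group, chain_code, resindex) -> float:
    n = pos.shape[0]
    best = np.inf
    for i in range(n):
        d = np.linalg.norm(pos[i + 1 :] - pos[i], axis=1)
        ratio = d / (radius[i + 1 :] + radius[i])
        # ignore pairs in the same exclusion group, close-in-chain pairs,
        # and nonbonded-silent beads (group -2)
        same_group = (group[i + 1 :] == group[i]) & (group[i] >= 0)
        near_chain = (chain_code[i + 1 :] == chain_code[i]) & (
            np.abs(np.arange(i + 1, n) - i) <= 8
        )
        silent = (group[i + 1 :] == -2) | (group[i] == -2)
        ratio = np.where(same_group | near_chain | silent, np.inf, ratio)
        m = ratio.min() if ratio.size else np.inf
        if m < best:
            best = float(m)
    return best


# --------------------------------------------------------------------------
# incremental builder


class _Builder:
    def __init__(self) -> None:
        self.pos: list = []
        self.kind: list = []
        self.chain_code: list = []
        self.chain_ids: list = []
        self.resindex: list = []
        self.mass: list = []
        self.radius: list = []
        self.q_intra: list = []
        self.q_cross: list = []
        self.is_dna: list = []
        self.group: list = []
        self.mobile: list = []
        self.bonds: list = []
        self.bond_k: list = []
        self.bond_r0: list = []
        self.angles: list = []
        self.angle_k: list = []
        self.angle_t0: list = []
        self.scaffold: list = []  # (idx, k, xyz)
        self.pairs: list = []  # (bead_i, bead_j, cls)
        self.stacks: list = []
        self.sites: list = []  # (anchor, dna_bead, eps, shl, r0)
        self.fixedwells: list = []  # (i, j, eps)

    # -- beads ------------------------------------------------------------
    def chain(self, chain_id: str) -> int:
        self.chain_ids.append(chain_id)
        return len(self.chain_ids) - 1

    def bead(
        self,
        xyz,
        kind: int,
        chain: int,
        res: int,
        mass: float = 5.0,
        radius: float = R_PROTEIN,
        q_intra: float = 0.0,
        q_cross: float = 0.0,
        group: int = -1,
        mobile: bool = True,
    ) -> int:
        self.pos.append(np.asarray(xyz, dtype=float))
        self.kind.append(kind)
        self.chain_code.append(chain)
        self.resindex.append(res)
        self.mass.append(mass)
        self.radius.append(radius)
        self.q_intra.append(q_intra)
        self.q_cross.append(q_cross)
        self.is_dna.append(kind != KIND_PROTEIN)
        self.group.append(group)
        self.mobile.append(mobile)
        return len(self.pos) - 1

    def bond(self, i: int, j: int, k: float, r0: Optional[float] = None) -> None:
        if r0 is None:
            r0 = float(np.linalg.norm(self.pos[i] - self.pos[j]))
        self.bonds.append((i, j))
        self.bond_k.append(k)
        self.bond_r0.append(r0)

    def angle(self, i: int, j: int, k: int, kang: float, t0: Optional[float] = None) -> None:
        if t0 is None:
            a = self.pos[i] - self.pos[j]
            b = self.pos[k] - self.pos[j]
            c = float(
                np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
            )
            t0 = math.acos(max(-1.0, min(1.0, c)))
        self.angles.append((i, j, k))
        self.angle_k.append(kang)
        self.angle_t0.append(t0)

    def restrain(self, i: int, k: float, xyz=None) -> None:
        if xyz is None:
            xyz = self.pos[i]
        self.scaffold.append((i, k, np.asarray(xyz, dtype=float)))

    # -- DNA --------------------------------------------------------------
    def add_strand(
        self,
        chain_id: str,
        sequence: str,
        p_positions: np.ndarray,
        lateral: np.ndarray,
        k_bond: float,
        k_angle: float,
        q_phos_intra: float,
        q_phos_cross: float,
    ) -> dict:
        """Lay down one strand: P, S, B per nucleotide.

        ``p_positions`` are the phosphate positions (n, 3); ``lateral`` the
        per-nt unit vectors from P toward the base side (n, 3).
        """
        ch = self.chain(chain_id)
        n = len(sequence)
        pb, sb, bb = [], [], []
        for i in range(n):
            p = p_positions[i]
            lat = lateral[i]
            pb.append(
                self.bead(p, KIND_PHOSPHATE, ch, i, 5.0, R_PHOSPHATE,
                          q_intra=q_phos_intra, q_cross=q_phos_cross)
            )
            sb.append(self.bead(p + OFF_SUGAR * lat, KIND_SUGAR, ch, i, 5.0, R_SUGAR))
            bb.append(self.bead(p + OFF_BASE * lat, KIND_BASE, ch, i, 5.0, R_BASE))
        for i in range(n):
            self.bond(pb[i], sb[i], k_bond)
            self.bond(sb[i], bb[i], k_bond)
            if i + 1 < n:
                self.bond(sb[i], pb[i + 1], k_bond)
                self.angle(pb[i], sb[i], pb[i + 1], k_angle)
                self.stacks.append((bb[i], bb[i + 1]))
            if i + 2 < n:
                self.angle(sb[i], pb[i + 1], sb[i + 1], k_angle)
        return {"chain": ch, "P": pb, "S": sb, "B": bb, "seq": sequence}

    def finish(self, ring, dna, scenario, states, nucleosome=None, factors=None) -> Assembly:
        scaffold = self.scaffold or []
        return Assembly(
            pos=np.asarray(self.pos, dtype=float).reshape(-1, 3),
            kind=np.asarray(self.kind, dtype=np.int8),
            chain_code=np.asarray(self.chain_code, dtype=np.int16),
            chain_ids=list(self.chain_ids),
            resindex=np.asarray(self.resindex, dtype=np.int32),
            mass=np.asarray(self.mass, dtype=float),
            radius=np.asarray(self.radius, dtype=float),
            q_intra=np.asarray(self.q_intra, dtype=float),
            q_cross=np.asarray(self.q_cross, dtype=float),
            is_dna=np.asarray(self.is_dna, dtype=bool),
            group=np.asarray(self.group, dtype=np.int32),
            mobile=np.asarray(self.mobile, dtype=bool),
            bonds=np.asarray(self.bonds, dtype=np.int32).reshape(-1, 2),
            bond_k=np.asarray(self.bond_k, dtype=float),
            bond_r0=np.asarray(self.bond_r0, dtype=float),
            angles=np.asarray(self.angles, dtype=np.int32).reshape(-1, 3),
            angle_k=np.asarray(self.angle_k, dtype=float),
            angle_t0=np.asarray(self.angle_t0, dtype=float),
            scaffold_idx=np.asarray([s[0] for s in scaffold], dtype=np.int32),
            scaffold_k=np.asarray([s[1] for s in scaffold], dtype=float),
            scaffold_pos=np.asarray(
                [s[2] for s in scaffold], dtype=float
            ).reshape(-1, 3),
            pair_i=np.asarray([p[0] for p in self.pairs], dtype=np.int32),
            pair_j=np.asarray([p[1] for p in self.pairs], dtype=np.int32),
            pair_cls=np.asarray([p[2] for p in self.pairs], dtype=np.int8),
            stack_i=np.asarray([s[0] for s in self.stacks], dtype=np.int32),
            stack_j=np.asarray([s[1] for s in self.stacks], dtype=np.int32),
            site_anchor=np.asarray([s[0] for s in self.sites], dtype=np.int32),
            site_dna=np.asarray([s[1] for s in self.sites], dtype=np.int32),
            site_eps=np.asarray([s[2] for s in self.sites], dtype=float),
            site_shl=np.asarray([s[3] for s in self.sites], dtype=float),
            site_r0=np.asarray([s[4] for s in self.sites], dtype=float),
            fixedwell_i=np.asarray([w[0] for w in self.fixedwells], dtype=np.int32),
            fixedwell_j=np.asarray([w[1] for w in self.fixedwells], dtype=np.int32),
            fixedwell_eps=np.asarray([w[2] for w in self.fixedwells], dtype=float),
            ring=ring,
            dna=dna,
            scenario=scenario,
            states=states,
            nucleosome=nucleosome,
            factors=factors,
        )


# --------------------------------------------------------------------------
# sequences


def make_sequence(n: int, mode: str, rng: np.random.Generator) -> str:
    """Generate a sequence of length ``n``.

    ``random`` draws i.i.d. uniform over {A, C, G, T}; ``polyAT`` and
    ``polyGC`` alternate the two bases of the named pair so every base pair
    built on the sequence is AT- or GC-class respectively.
    """
    if mode == "random":
        return "".join(rng.choice(list("ACGT"), size=n))
    if mode == "polyAT":
        return ("AT" * (n // 2 + 1))[:n]
    if mode == "polyGC":
        return ("GC" * (n // 2 + 1))[:n]
    raise ValueError(f"unknown sequence mode: {mode!r}")


def complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in seq)


def pair_class(base: str) -> int:
    return 1 if base in "GC" else 0


# --------------------------------------------------------------------------
# ring


def build_ring(
    beads_per_subunit: int = 20,
    pore_radius: float = 1.25,
    loop_rise_per_nt: float = 1.0,
) -> RingTopology:
    """Build the six-subunit toy ring (geometry only; beads are added to an
    assembly by the scenario builders).

    The pore must pass single-stranded but not duplex DNA: ssDNA base beads
    reach ``OFF_BASE`` from the axis while a duplex backbone sits at
    ``DUPLEX_HALF_WIDTH``.
    """
    if beads_per_subunit < 4:
        raise AssemblyError("beads_per_subunit must be >= 4")
    ss_clearance = OFF_BASE + R_BASE + R_PROTEIN  # 1.25 at defaults
    duplex_block = DUPLEX_HALF_WIDTH + R_PHOSPHATE + R_PROTEIN  # 1.70
    if pore_radius < ss_clearance:
        raise AssemblyError(
            f"pore_radius {pore_radius} too small to pass ssDNA "
            f"(needs >= {ss_clearance})"
        )
    if pore_radius >= duplex_block:
        raise AssemblyError(
            f"pore_radius {pore_radius} would pass duplex DNA "
            f"(must be < {duplex_block})"
        )
    azimuth = {
        lab: 2.0 * math.pi * k / 6.0 for k, lab in enumerate(RING_ORDER)
    }
    return RingTopology(
        subunit_labels=RING_ORDER,
        body_beads={},
        loop_bead={},
        channel_axis=np.array([0.0, 0.0, 1.0]),
        pore_bead_set=np.empty(0, dtype=np.int32),
        azimuth=azimuth,
        loop_radius=0.2,
        park_radius=2.0,
        park_z=4.5,
        loop_rise_per_nt=loop_rise_per_nt,
        pore_radius=pore_radius,
        z_top=9.5,
    )


def _emit_ring_beads(b: _Builder, ring: RingTopology, beads_per_subunit: int,
                     k_scaffold: float, z_offset: float = 0.0) -> None:
    """Add ring beads to a builder: per subunit, 4 pore-lining beads plus a
    body grid at larger radius, all position-restrained, and one mobile
    pore-loop bead."""
    # dense pore lining at exactly 1-nt axial spacing: a taut wall that the
    # threaded strand cannot buckle into, with no long-wavelength mismatch
    # against the 1-nt backbone lattice
    n_pore = min(14, beads_per_subunit - 6)
    n_collar = 4
    n_body = beads_per_subunit - n_pore - n_collar
    pore_ids = []
    for gi, lab in enumerate(ring.subunit_labels):
        ch = b.chain(f"M{lab}")
        az = ring.azimuth[lab]
        ids = []
        # pore-lining beads; the channel proper reaches z ~ 9.5 and the
        # wall continues up to the fork mouth so a duplex cannot slip in
        for zi, z in enumerate(0.25 + 1.0 * np.arange(n_pore)):
            xyz = (
                ring.pore_radius * math.cos(az),
                ring.pore_radius * math.sin(az),
                z + z_offset,
            )
            i = b.bead(xyz, KIND_PROTEIN, ch, zi, group=gi, mobile=True)
            b.restrain(i, k_scaffold)
            ids.append(i)
            if z <= ring.z_top:
                pore_ids.append(i)
        # collar beads at the intermediate azimuths close the upper-wall
        # gaps that a base pair could otherwise straddle
        for ci, z in enumerate(10.25 + 1.0 * np.arange(n_collar)):
            xyz = (
                ring.pore_radius * math.cos(az + math.pi / 6.0),
                ring.pore_radius * math.sin(az + math.pi / 6.0),
                z + z_offset,
            )
            i = b.bead(xyz, KIND_PROTEIN, ch, n_pore + ci, group=gi,
                       mobile=True)
            b.restrain(i, k_scaffold)
            ids.append(i)
        # outer body grid
        n_cols = 2
        n_rows = max(1, int(math.ceil(n_body / n_cols)))
        count = 0
        for r in range(n_rows):
            for c in range(n_cols):
                if count >= n_body:
                    break
                daz = (c - (n_cols - 1) / 2.0) * 0.30
                z = 0.5 + r * (9.0 / max(1, n_rows - 1)) if n_rows > 1 else 4.5
                xyz = (
                    2.2 * math.cos(az + daz),
                    2.2 * math.sin(az + daz),
                    z + z_offset,
                )
                i = b.bead(xyz, KIND_PROTEIN, ch,
                           n_pore + n_collar + count, group=gi)
                b.restrain(i, k_scaffold)
                ids.append(i)
                count += 1
        ring.body_beads[lab] = ids
        # pore loop bead (the ps1beta proxy): mobile, restrained to
        # state-dependent targets by the engine
        loop_xyz = (
            ring.loop_radius * math.cos(az),
            ring.loop_radius * math.sin(az),
            4.5 + z_offset,
        )
        # grip beads are nonbonded-silent (group -2): the hydrogen-bond
        # well alone sets the grip geometry, free of excluded volume
        li = b.bead(loop_xyz, KIND_PROTEIN, ch, beads_per_subunit, group=-2,
                    radius=0.01)
        ring.loop_bead[lab] = li
    ring.pore_bead_set = np.asarray(pore_ids, dtype=np.int32)


# --------------------------------------------------------------------------
# reference states


def build_reference_states(ring: RingTopology) -> list:
    """Construct the four DNA-binding reference states for a built ring.

    Engaged loops target ``loop_radius`` from the channel axis at their
    state height; disengaged loops park at ``park_radius``.  The registry
    rank pair of an engaged subunit is ``(Delta_s + h, Delta_s + h + 1)``
    so that loop heights satisfy ``z = (rank - Delta_s) * loop_rise_per_nt``.
    """
    states = []
    for sid in STATE_IDS:
        eng = STATE_ENGAGED[sid]
        heights = dict(STATE_HEIGHTS[sid])
        delta = REGISTRY_OFFSETS[sid]
        registry = {
            lab: (int(delta + h), int(delta + h) + 1) for lab, h in heights.items()
        }
        targets = {}
        pairs = []
        for lab in ring.subunit_labels:
            az = ring.azimuth[lab]
            if lab in eng:
                z = heights[lab] * ring.loop_rise_per_nt
                xyz = np.array(
                    [ring.loop_radius * math.cos(az),
                     ring.loop_radius * math.sin(az), z]
                )
            else:
                xyz = np.array(
                    [ring.park_radius * math.cos(az),
                     ring.park_radius * math.sin(az), ring.park_z]
                )
            targets[lab] = xyz
            if lab in ring.loop_bead:
                pairs.append((ring.loop_bead[lab], xyz))
        states.append(
            ReferenceState(
                state_id=sid,
                engaged_set=eng,
                registry_offset=delta,
                loop_heights=heights,
                per_subunit_registry=registry,
                loop_targets=targets,
                native_pair_list=tuple(pairs),
            )
        )
    return states


def registry_step(from_state: int, to_state: int) -> int:
    """Ideal step size (nt) for a transition, from the registry offsets.

    Forward transitions advance by ``(Delta_to - Delta_from) mod 12``.
    """
    return (REGISTRY_OFFSETS[to_state] - REGISTRY_OFFSETS[from_state]) % CYCLE_NT


# --------------------------------------------------------------------------
# scenario builders


_DEF_KBOND = 120.0
_DEF_KANGLE = 8.0
_DEF_KSCAFF = 50.0
_Q_INTRA = -0.6
_Q_CROSS = -1.0


def _helix_lateral(n: int, phase: float = 0.262, turn: float = 0.0) -> np.ndarray:
    """Lateral unit vectors for a strand.

    The default is a constant direction (phase 15 degrees, between the
    wall and collar bead columns): a twist inside the discrete pore would make the
    chain's steric energy aperiodic in the registry and tilt the
    translocation landscape; with a constant lateral the in-pore energy is
    exactly periodic under a 1-nt shift.
    """
    ang = phase + turn * np.arange(n)
    return np.stack([np.cos(ang), np.sin(ang), np.zeros(n)], axis=1)


def _seat_loops(b: _Builder, ring: RingTopology, state: ReferenceState) -> None:
    """Place the pore-loop beads at their state targets before relaxation
    (otherwise they drag the DNA while settling into the first state)."""
    for lab, xyz in state.loop_targets.items():
        b.pos[ring.loop_bead[lab]] = np.asarray(xyz, dtype=float).copy()


def build_ssdna_scenario(
    n_nt: int = 60,
    ring_position_nt: int = 30,
    seed: int = 0,
    sequence_mode: str = "random",
    beads_per_subunit: int = 20,
) -> Assembly:
    """Motor threaded on ssDNA (the translocation scenario).

    The tracked strand runs along the channel axis; nucleotide
    ``ring_position_nt`` starts at the subunit-3 loop height of state 1.
    """
    # the state-1 staircase grips nucleotides ring_position_nt-7 ..
    # ring_position_nt+1 and one full cycle advances 12 nt toward 5'
    if not (8 <= ring_position_nt <= n_nt - CYCLE_NT - 3):
        raise AssemblyError(
            f"ring_position_nt {ring_position_nt} must lie in "
            f"[8, {n_nt - CYCLE_NT - 3}]"
        )
    rng = np.random.default_rng(seed)
    scenario = ScenarioSpec(
        name="ssdna", kind="ssdna", seed=seed, n_nt=n_nt,
        ring_position_nt=ring_position_nt, sequence_mode=sequence_mode,
    )
    b = _Builder()
    ring = build_ring(beads_per_subunit=beads_per_subunit)
    _emit_ring_beads(b, ring, beads_per_subunit, _DEF_KSCAFF)

    seq = make_sequence(n_nt, sequence_mode, rng)
    h3 = STATE_HEIGHTS[1][3]  # subunit-3 loop height in state 1
    z = (np.arange(n_nt) - ring_position_nt) * RISE + h3
    p_pos = np.stack([np.zeros(n_nt), np.zeros(n_nt), z], axis=1)
    lat = _helix_lateral(n_nt)
    strand = b.add_strand(
        "T", seq, p_pos, lat, _DEF_KBOND, _DEF_KANGLE, _Q_INTRA, _Q_CROSS
    )
    dna = DNATopology(
        strands=[("T", seq)],
        pairing_table=pd.DataFrame(
            columns=["nt_i", "nt_j", "chain_i", "chain_j", "cls"]
        ),
        fork_junction_index=None,
        tracked_strand="T",
        tracked_phosphates=np.asarray(strand["P"], dtype=np.int32),
        tracked_nt_index=np.arange(n_nt, dtype=np.int32),
    )
    states = build_reference_states(ring)
    _seat_loops(b, ring, states[0])
    asm = b.finish(ring, dna, scenario, states)
    _validate_clash_free(asm)
    return asm


def _duplex_positions(axis_points: np.ndarray, normal: np.ndarray):
    """Phosphate tracks and lateral vectors for the two strands of a duplex
    laid along ``axis_points`` (per-bp centers).  ``normal`` is the unit
    vector (one shared, or one per bp for curved axes) from the
    tracked-strand backbone toward the partner backbone."""
    nrm = np.asarray(normal, dtype=float)
    if nrm.ndim == 1:
        nrm = np.tile(nrm / np.linalg.norm(nrm), (len(axis_points), 1))
    else:
        nrm = nrm / np.linalg.norm(nrm, axis=1, keepdims=True)
    p_a = axis_points - DUPLEX_HALF_WIDTH * nrm
    p_b = axis_points + DUPLEX_HALF_WIDTH * nrm
    lat_a = nrm.copy()
    lat_b = -nrm
    return p_a, lat_a, p_b, lat_b


def build_fork_scenario(
    parental_bp: int = 20,
    lagging_bp: int = 6,
    leading_bp: int = 6,
    lagging_ss_nt: int = 8,
    leading_ss_nt: int = 18,
    sequence_mode: str = "random",
    seed: int = 0,
    lagging_arm_mode: str = "ssDNA",
    beads_per_subunit: int = 20,
    _parental_axis=None,
    _parental_normals=None,
    _nuc: Optional[dict] = None,
) -> Assembly:
    """Y-forked DNA with the motor on the leading-strand template.

    The subunit-3 loop starts 7 nt from the fork junction.  The parental
    duplex rises along +z above the ring; the lagging strand (ssDNA then
    duplex arm) exits laterally; the leading-strand duplex trails below.
    ``lagging_arm_mode="duplex-occluded"`` pairs the lagging single-stranded
    region with an extra complementary strand so no unpaired lagging
    nucleotides exist at assembly.
    """
    if min(parental_bp, lagging_bp, leading_bp, lagging_ss_nt, leading_ss_nt) < 0:
        raise AssemblyError("all fork lengths must be >= 0")
    if leading_ss_nt < 14:
        raise AssemblyError(
            "leading ssDNA too short to thread the pore (needs >= 14 nt)"
        )
    rng = np.random.default_rng(seed)
    scenario = ScenarioSpec(
        name="fork", kind="fork", seed=seed,
        parental_bp=parental_bp, lagging_bp=lagging_bp, leading_bp=leading_bp,
        lagging_ss_nt=lagging_ss_nt, leading_ss_nt=leading_ss_nt,
        sequence_mode=sequence_mode, lagging_arm_mode=lagging_arm_mode,
    )
    b = _Builder()
    ring = build_ring(beads_per_subunit=beads_per_subunit)
    _emit_ring_beads(b, ring, beads_per_subunit, _DEF_KSCAFF)

    # tracked strand: [leading arm | leading ss | parental], indices toward 5'
    n_tracked = leading_bp + leading_ss_nt + parental_bp
    junction = leading_bp + leading_ss_nt  # first paired parental nt
    h3 = STATE_HEIGHTS[1][3]
    z_of = lambda n: (n - (junction - 7)) * RISE + h3  # noqa: E731
    seq_tracked = make_sequence(n_tracked, sequence_mode, rng)

    # tracked phosphate path: straight up the channel axis, shifting to the
    # parental duplex backbone position above the ring
    p_pos = np.zeros((n_tracked, 3))
    lat = _helix_lateral(n_tracked)
    parental_normal = np.array([-1.0, 0.0, 0.0])  # tracked backbone at -x
    if _parental_axis is None:
        axis_pts = np.stack(
            [np.ones(parental_bp), np.zeros(parental_bp),
             z_of(junction) + RISE * np.arange(parental_bp)], axis=1
        )
    else:
        axis_pts = _parental_axis
        assert len(axis_pts) == parental_bp
    if _parental_normals is not None:
        parental_normal = _parental_normals
    p_par, lat_par, p_lag_dup, lat_lag_dup = _duplex_positions(
        axis_pts, parental_normal
    )
    for n in range(n_tracked):
        if n < junction:
            p_pos[n] = (0.0, 0.0, z_of(n))
        else:
            p_pos[n] = p_par[n - junction]
            lat[n] = lat_par[n - junction]
    strand_t = b.add_strand(
        "T", seq_tracked, p_pos, lat, _DEF_KBOND, _DEF_KANGLE, _Q_INTRA, _Q_CROSS
    )

    # lagging strand: pairs parental region of tracked, then ss, then arm
    n_lag = parental_bp + lagging_ss_nt + lagging_bp
    seq_lag_par = complement(seq_tracked[junction:][::-1])[::-1]
    seq_lag_rest = make_sequence(lagging_ss_nt + lagging_bp, sequence_mode, rng)
    # lagging indices run antiparallel: entry 0 = paired with last parental nt
    p_lag = np.zeros((n_lag, 3))
    lat_lag = np.zeros((n_lag, 3))
    # paired region (reverse order along the parental axis)
    for k in range(parental_bp):
        p_lag[k] = p_lag_dup[parental_bp - 1 - k]
        lat_lag[k] = lat_lag_dup[parental_bp - 1 - k]
    # ss region exits laterally from the junction toward +x, sloping down
    exit_dir = np.array([1.0, 0.6, -0.35])
    exit_dir /= np.linalg.norm(exit_dir)
    j_xyz = np.array([2.0, 0.0, z_of(junction)])  # lagging backbone at fork
    for k in range(lagging_ss_nt):
        p_lag[parental_bp + k] = j_xyz + (k + 1) * RISE * exit_dir
        lat_lag[parental_bp + k] = _helix_lateral(1)[0]
    # lagging arm duplex continues along the exit direction
    arm_axis = np.stack(
        [j_xyz + (lagging_ss_nt + 1 + k) * RISE * exit_dir
         for k in range(lagging_bp)], axis=0
    ) + np.array([0.0, 0.0, 0.0])
    arm_normal = np.cross(exit_dir, [0.0, 0.0, 1.0])
    arm_normal /= np.linalg.norm(arm_normal)
    p_arm_a, lat_arm_a, p_arm_b, lat_arm_b = _duplex_positions(arm_axis, arm_normal)
    for k in range(lagging_bp):
        p_lag[parental_bp + lagging_ss_nt + k] = p_arm_a[k]
        lat_lag[parental_bp + lagging_ss_nt + k] = lat_arm_a[k]
    seq_lag = seq_lag_par[::-1] + seq_lag_rest
    strand_l = b.add_strand(
        "L", seq_lag, p_lag, lat_lag, _DEF_KBOND, _DEF_KANGLE, _Q_INTRA, _Q_CROSS
    )

    pairs_rows = []
    # parental base pairs (tracked nt j+k <-> lagging nt parental_bp-1-k)
    for k in range(parental_bp):
        nt_t = junction + k
        nt_l = parental_bp - 1 - k
        cls = pair_class(seq_tracked[nt_t])
        b.pairs.append((strand_t["B"][nt_t], strand_l["B"][nt_l], cls))
        pairs_rows.append((nt_t, nt_l, "T", "L", cls))

    # lagging arm complement strand
    if lagging_bp > 0:
        seq_arm_c = complement(seq_lag[parental_bp + lagging_ss_nt :][::-1])[::-1]
        lat_c = np.stack([lat_arm_b[lagging_bp - 1 - k] for k in range(lagging_bp)])
        p_c = np.stack([p_arm_b[lagging_bp - 1 - k] for k in range(lagging_bp)])
        strand_lc = b.add_strand(
            "l", seq_arm_c[::-1], p_c, lat_c, _DEF_KBOND, _DEF_KANGLE,
            _Q_INTRA, _Q_CROSS,
        )
        for k in range(lagging_bp):
            nt_l = parental_bp + lagging_ss_nt + k
            nt_c = lagging_bp - 1 - k
            cls = pair_class(seq_lag[nt_l])
            b.pairs.append((strand_l["B"][nt_l], strand_lc["B"][nt_c], cls))
            pairs_rows.append((nt_l, nt_c, "L", "l", cls))

    # occlude the lagging ss region with a complementary strand if requested
    if lagging_arm_mode == "duplex-occluded" and lagging_ss_nt > 0:
        occ_axis = np.stack(
            [j_xyz + (1 + k) * RISE * exit_dir for k in range(lagging_ss_nt)]
        )
        occ_normal = arm_normal
        _, _, p_occ, lat_occ = _duplex_positions(occ_axis, occ_normal)
        # move the lagging ss backbone onto the duplex track
        for k in range(lagging_ss_nt):
            i = parental_bp + k
            newp = occ_axis[k] - DUPLEX_HALF_WIDTH * occ_normal
            shift = newp - b.pos[strand_l["P"][i]]
            for key in ("P", "S", "B"):
                b.pos[strand_l[key][i]] = b.pos[strand_l[key][i]] + shift
            b.pos[strand_l["S"][i]] = b.pos[strand_l["P"][i]] + OFF_SUGAR * occ_normal
            b.pos[strand_l["B"][i]] = b.pos[strand_l["P"][i]] + OFF_BASE * occ_normal
        seq_occ = complement(seq_lag[parental_bp : parental_bp + lagging_ss_nt])
        strand_o = b.add_strand(
            "o", seq_occ, p_occ, -lat_occ * 0 - np.array([occ_normal]),
            _DEF_KBOND, _DEF_KANGLE, _Q_INTRA, _Q_CROSS,
        )
        for k in range(lagging_ss_nt):
            nt_l = parental_bp + k
            cls = pair_class(seq_lag[nt_l])
            b.pairs.append((strand_l["B"][nt_l], strand_o["B"][k], cls))
            pairs_rows.append((nt_l, k, "L", "o", cls))

    # leading-arm duplex (already-synthesized product behind the motor)
    if leading_bp > 0:
        lead_axis = np.stack(
            [np.ones(leading_bp), np.zeros(leading_bp),
             z_of(0) + RISE * np.arange(leading_bp)], axis=1
        )
        # tracked nts 0..leading_bp-1 sit on the channel axis; shift them
        # onto the duplex backbone
        p_ta, lat_ta, p_tb, lat_tb = _duplex_positions(
            lead_axis, np.array([-1.0, 0.0, 0.0])
        )
        for k in range(leading_bp):
            shift = p_ta[k] - b.pos[strand_t["P"][k]]
            b.pos[strand_t["P"][k]] = p_ta[k]
            b.pos[strand_t["S"][k]] = p_ta[k] + OFF_SUGAR * lat_ta[k]
            b.pos[strand_t["B"][k]] = p_ta[k] + OFF_BASE * lat_ta[k]
        seq_lead_c = complement(seq_tracked[:leading_bp][::-1])[::-1]
        p_cb = np.stack([p_tb[leading_bp - 1 - k] for k in range(leading_bp)])
        lat_cb = np.stack([lat_tb[leading_bp - 1 - k] for k in range(leading_bp)])
        strand_tc = b.add_strand(
            "d", seq_lead_c[::-1], p_cb, lat_cb, _DEF_KBOND, _DEF_KANGLE,
            _Q_INTRA, _Q_CROSS,
        )
        for k in range(leading_bp):
            cls = pair_class(seq_tracked[k])
            b.pairs.append(
                (strand_t["B"][k], strand_tc["B"][leading_bp - 1 - k], cls)
            )
            pairs_rows.append((k, leading_bp - 1 - k, "T", "d", cls))

    # anchor the distal parental terminus via the lagging strand only: the
    # motor's pull on the tracked strand then loads the junction base
    # pairs (which must unwind for it to advance) rather than an anchor on
    # the tracked strand itself, and the fork cannot be dragged through
    # the ring wholesale
    b.restrain(strand_l["P"][0], 15.0)

    strands = [("T", seq_tracked), ("L", seq_lag)]
    dna = DNATopology(
        strands=strands,
        pairing_table=pd.DataFrame(
            pairs_rows, columns=["nt_i", "nt_j", "chain_i", "chain_j", "cls"]
        ),
        fork_junction_index=junction,
        tracked_strand="T",
        tracked_phosphates=np.asarray(strand_t["P"], dtype=np.int32),
        tracked_nt_index=np.arange(n_tracked, dtype=np.int32),
    )
    states = build_reference_states(ring)
    _seat_loops(b, ring, states[0])
    nucleosome = None
    if _nuc is not None:
        nucleosome = _emit_nucleosome(b, strand_t, strand_l, junction, _nuc)
    asm = b.finish(ring, dna, scenario, states, nucleosome=nucleosome)
    _validate_clash_free(asm)
    return asm


# --------------------------------------------------------------------------
# nucleosome


def _emit_nucleosome(b: _Builder, strand_t, strand_l, junction, nuc: dict):
    """Add the histone-core beads and SHL contact sites.

    ``nuc`` carries: shl_start, entry_nt (tracked nt at the wrap entry),
    axis points already laid out by the caller for the wrapped region,
    core_center, eps_outer, eps_inner.
    """
    shl_start = nuc["shl_start"]
    entry_nt = nuc["entry_nt"]
    core_center = nuc["core_center"]
    ch = b.chain("H")
    core_ids = []
    rng = np.random.default_rng(12345)
    # core: a compact ball of beads (rigid, position-restrained)
    shells = [(0.0, 1), (1.4, 8), (2.4, 18)]
    for rad, cnt in shells:
        for k in range(cnt):
            phi = math.pi * (3 - math.sqrt(5)) * k
            ct = 1 - 2 * (k + 0.5) / cnt
            st = math.sqrt(max(0.0, 1 - ct * ct))
            xyz = core_center + rad * np.array(
                [st * math.cos(phi), st * math.sin(phi), ct]
            )
            i = b.bead(xyz, KIND_PROTEIN, ch, len(core_ids), radius=0.45,
                       group=900)
            b.restrain(i, _DEF_KSCAFF)
            core_ids.append(i)
    core_ids = np.asarray(core_ids, dtype=np.int32)

    # contact sites at half-integer SHLs; DNA nt index per SHL
    site_rows = []
    eps_outer, eps_inner = nuc["eps_outer"], nuc["eps_inner"]
    for shl in SHL_LABELS:
        nt = entry_nt + int(round(BP_PER_SHL * (shl - shl_start)))
        if nt < junction or nt >= len(strand_t["P"]):
            continue
        dna_bead = strand_t["P"][nt]
        # anchor: core bead nearest the site's phosphate reference position
        p = b.pos[dna_bead]
        d = [np.linalg.norm(b.pos[i] - p) for i in core_ids]
        anchor = int(core_ids[int(np.argmin(d))])
        eps = eps_inner if abs(shl) < 5.0 else eps_outer
        # reference separation for wrapped sites; detached-at-assembly sites
        # (outward of shl_start, on the straight segment) use a nominal 1.2
        r0_site = float(np.linalg.norm(b.pos[anchor] - p))
        if shl < shl_start:
            r0_site = 1.2
        b.sites.append((anchor, dna_bead, eps, shl, r0_site))
        site_rows.append((shl, anchor, dna_bead, nt, eps))
    sites = pd.DataFrame(
        site_rows, columns=["shl", "anchor_bead", "dna_bead", "nt", "eps"]
    )
    # H2A/H2B surface proxy: positively charged core-surface beads on the
    # entry-side face around SHL(-4); exposed when entry sites -6.5..-3.5
    # are detached
    patch = []
    target_shls = [-4.5, -3.5]
    for shl in target_shls:
        row = sites[sites.shl == shl]
        if len(row) == 0:
            continue
        p = b.pos[int(row.dna_bead.iloc[0])]
        d = [np.linalg.norm(b.pos[i] - p) for i in core_ids]
        k = int(core_ids[int(np.argmin(d))])
        b.q_cross[k] = 1.0
        patch.append(k)
    dyad_row = sites[sites.shl == 0.5]
    dyad_index = int(dyad_row.nt.iloc[0]) if len(dyad_row) else entry_nt
    return NucleosomeTopology(
        core_beads=core_ids,
        contact_sites=sites,
        dyad_index=dyad_index,
        h2ab_patch=np.asarray(patch, dtype=np.int32),
        exposure_rule=(-6.5, -5.5, -4.5, -3.5),
    )


def build_nucleosome_scenario(
    shl_start: float = -7.0,
    factors: Sequence[str] = (),
    seed: int = 0,
    sequence_mode: str = "random",
    fpc_electrostatics_on: bool = True,
    eps_site_outer: float = 2.5,
    eps_site_inner: float = 10.0,
) -> Assembly:
    """Y-fork whose parental arm is wrapped onto a toy nucleosome.

    The fork junction is placed ``NUC_ENTRY_OFFSET_BP`` (22) bp upstream of
    ``shl_start``; contact sites outward of ``shl_start`` are detached at
    assembly by construction (their DNA lies on the straight segment toward
    the fork).
    """
    if shl_start not in (-7.0, -5.0, -4.0, -3.0):
        raise AssemblyError("shl_start must be one of -7, -5, -4, -3")
    # wrapped portion: from max(shl_start, -6.5) to +6.5 plus a short stub
    first_site = max(shl_start, -6.5)
    wrap_bp = int(round(BP_PER_SHL * (6.5 - first_site))) + 4
    straight_bp = NUC_ENTRY_OFFSET_BP
    parental_bp = straight_bp + wrap_bp

    # lay out the parental axis: straight up, then a superhelix
    z_j = 14.0  # junction height (junction nt at z_of(junction))
    axis_pts = np.zeros((parental_bp, 3))
    for k in range(straight_bp):
        axis_pts[k] = (1.0, 0.0, z_j + RISE * k)
    r_w = 4.5
    theta_bp = RISE / r_w  # arc length per bp = rise
    z_entry = z_j + RISE * (straight_bp - 1)
    core_center = np.array([1.0 + r_w, 0.0, z_entry + 2.0])
    normals = np.tile(np.array([-1.0, 0.0, 0.0]), (parental_bp, 1))
    for k in range(wrap_bp):
        th = math.pi + theta_bp * (k + 1)  # start at the entry tangent point
        axis_pts[straight_bp + k] = core_center + np.array(
            [r_w * math.cos(th), r_w * math.sin(th), 0.08 * (k + 1)]
        )
        # tracked backbone faces the histone core (radially inward side)
        normals[straight_bp + k] = (math.cos(th), math.sin(th), 0.0)
    junction = 8 + 18  # leading_bp + leading_ss_nt below
    entry_nt = junction + straight_bp
    asm = build_fork_scenario(
        parental_bp=parental_bp,
        lagging_bp=8,
        leading_bp=8,
        lagging_ss_nt=10,
        leading_ss_nt=18,
        sequence_mode=sequence_mode,
        seed=seed,
        _parental_axis=axis_pts,
        _parental_normals=normals,
        _nuc={
            "shl_start": shl_start,
            "entry_nt": entry_nt,
            "core_center": core_center,
            "eps_outer": eps_site_outer,
            "eps_inner": eps_site_inner,
        },
    )
    asm.scenario = dataclasses.replace(
        asm.scenario, name="nucleosome", kind="nucleosome", shl_start=shl_start,
        factors=tuple(factors), fpc_electrostatics_on=fpc_electrostatics_on,
        seed=seed, sequence_mode=sequence_mode,
    )
    if factors:
        asm = place_factors(
            asm, make_factors(asm, factors,
                              fpc_electrostatics_on=fpc_electrostatics_on,
                              seed=seed)
        )
    return asm


# --------------------------------------------------------------------------
# factors


def make_factors(
    assembly: Assembly,
    names: Iterable[str],
    rpa_footprint_nt: int = 8,
    fpc_electrostatics_on: bool = True,
    seed: int = 0,
) -> FactorSet:
    """Describe the requested accessory factors for :func:`place_factors`.

    ``names`` may contain: ``rpa``, ``fpc``, ``ctf4``, ``mrc1``, ``fact``.
    """
    names = set(names)
    unknown = names - {"rpa", "fpc", "ctf4", "mrc1", "fact"}
    if unknown:
        raise ValueError(f"unknown factors: {sorted(unknown)}")
    fs = FactorSet(fpc_electrostatics_on=fpc_electrostatics_on)
    fs._names = tuple(sorted(names))  # type: ignore[attr-defined]
    fs._rpa_footprint = rpa_footprint_nt  # type: ignore[attr-defined]
    fs._seed = seed  # type: ignore[attr-defined]
    return fs


def _blob_positions(center, n, spacing=0.95):
    pts = []
    k = 0
    for dz in (0, 1):
        for dx in (0, 1):
            for dy in (0, 1):
                if k >= n:
                    break
                pts.append(center + spacing * np.array([dx, dy, dz]))
                k += 1
    return pts[:n]


def place_factors(assembly: Assembly, factors: FactorSet,
                  max_retries: int = 20) -> Assembly:
    """Add factor beads to an assembled scenario.

    RPA bodies tile the lagging single-stranded region (one body per
    footprint, bound by fixed attractive wells); the fork-protection complex
    (FPC) is tethered at the ring front next to the parental duplex with a
    positively charged patch; Ctf4/Mrc1 are inert tethered bodies; FACT sits
    at the nucleosome dyad with an acidic flexible tail.  Placement retries
    with seeded jitter on steric clashes; :class:`AssemblyError` is raised
    if no clash-free placement is found within the retry budget.
    """
    names = getattr(factors, "_names", ())
    if not names:
        return assembly
    rng = np.random.default_rng(getattr(factors, "_seed", 0) + 77)
    last_exc: Optional[Exception] = None
    for attempt in range(max_retries):
        jitter = (0.0 if attempt == 0
                  else 0.25 * attempt * rng.standard_normal(3))
        factors.rpa_bodies = []
        factors.inert_bodies = []
        try:
            return _place_factors_once(assembly, factors, names, jitter)
        except AssemblyError as exc:
            last_exc = exc
    raise AssemblyError(
        f"no clash-free factor placement within {max_retries} retries: "
        f"{last_exc}"
    )


def _place_factors_once(assembly: Assembly, factors: FactorSet, names,
                        jitter) -> Assembly:
    b = _rebuilder_from(assembly)
    ring = assembly.ring
    sc = assembly.scenario
    junction = assembly.dna.fork_junction_index

    if "rpa" in names:
        if sc.kind == "ssdna" or junction is None:
            raise AssemblyError("RPA requires a fork scenario")
        footprint = getattr(factors, "_rpa_footprint", 8)
        lag_par = sc.parental_bp
        n_ss = sc.lagging_ss_nt
        n_bodies = max(0, n_ss // footprint) if footprint > 0 else 0
        lag_chain = assembly.chain_ids.index("L")
        lag_p = np.where(
            (assembly.chain_code == lag_chain)
            & (assembly.kind == KIND_PHOSPHATE)
        )[0]
        for m in range(n_bodies):
            nt0 = lag_par + m * footprint
            nts = list(range(nt0, nt0 + footprint))
            anchor_p = lag_p[nts[footprint // 2]]
            center = assembly.pos[anchor_p] + np.array([0.0, 1.6, 0.6]) + jitter
            ch = b.chain(f"R{m}")
            ids = []
            for kk, xyz in enumerate(_blob_positions(center, 4)):
                i = b.bead(xyz, KIND_PROTEIN, ch, kk, radius=0.45,
                           group=700 + m)
                ids.append(i)
            for a, c in zip(ids[:-1], ids[1:]):
                b.bond(a, c, 20.0)
            # fixed attractive wells onto the footprint phosphates
            for t, nt in enumerate(nts):
                b.fixedwells.append((ids[t % len(ids)], int(lag_p[nt]), 8.0))
            factors.rpa_bodies.append((np.asarray(ids), (nts[0], nts[-1])))

    if "fpc" in names:
        # body beside the parental duplex just above the ring
        ch = b.chain("F")
        center = np.array([3.0, 0.8, 10.8]) + jitter
        ids = []
        for kk, xyz in enumerate(_blob_positions(center, 8)):
            i = b.bead(xyz, KIND_PROTEIN, ch, kk, radius=0.45, group=800)
            ids.append(i)
        for a, c in zip(ids[:-1], ids[1:]):
            b.bond(a, c, 20.0)
        # positive patch: the three beads nearest the duplex axis
        d = [np.linalg.norm(np.asarray(b.pos[i])[:2] - np.array([1.0, 0.0]))
             for i in ids]
        patch = [ids[k] for k in np.argsort(d)[:3]]
        qp = 1.0 if factors.fpc_electrostatics_on else 0.0
        for i in patch:
            b.q_cross[i] = qp
        # tether to ring-top body beads
        top_beads = []
        for lab in ring.subunit_labels:
            bb = ring.body_beads[lab]
            top_beads.append(max(bb, key=lambda i: assembly.pos[i][2]))
        top_beads.sort(key=lambda i: np.linalg.norm(assembly.pos[i] - center))
        for t in top_beads[:2]:
            b.bond(ids[0], t, 3.0)
            b.bond(ids[1], t, 3.0)
        factors.fpc_body = np.asarray(ids)
        factors.fpc_patch = np.asarray(patch)

    for nm, off in (("ctf4", np.array([-3.2, 1.2, 9.5]) + jitter),
                    ("mrc1", np.array([-1.2, -3.2, 9.5]) + jitter)):
        if nm not in names:
            continue
        ch = b.chain(nm[0].upper() + "x")
        ids = []
        for kk, xyz in enumerate(_blob_positions(off, 5)):
            i = b.bead(xyz, KIND_PROTEIN, ch, kk, radius=0.45,
                       group=810 + (0 if nm == "ctf4" else 1))
            ids.append(i)
        for a, c in zip(ids[:-1], ids[1:]):
            b.bond(a, c, 20.0)
        side = []
        for lab in ring.subunit_labels:
            side.extend(ring.body_beads[lab])
        side.sort(key=lambda i: np.linalg.norm(assembly.pos[i] - off))
        b.bond(ids[0], side[0], 3.0)
        factors.inert_bodies.append(np.asarray(ids))

    if "fact" in names:
        if assembly.nucleosome is None:
            raise AssemblyError("FACT requires a nucleosome scenario")
        nuc = assembly.nucleosome
        dyad_bead = int(
            nuc.contact_sites.dna_bead.iloc[len(nuc.contact_sites) // 2]
        )
        core_center = assembly.pos[nuc.core_beads].mean(axis=0)
        dyad_pos = assembly.pos[dyad_bead]
        outward = dyad_pos - core_center
        outward /= np.linalg.norm(outward)
        center = dyad_pos + 1.8 * outward + jitter
        ch = b.chain("Q")
        dom = []
        for kk, xyz in enumerate(_blob_positions(center, 6)):
            i = b.bead(xyz, KIND_PROTEIN, ch, kk, radius=0.45, group=820)
            dom.append(i)
        for a, c in zip(dom[:-1], dom[1:]):
            b.bond(a, c, 20.0)
        near_core = sorted(
            (int(i) for i in nuc.core_beads),
            key=lambda i: np.linalg.norm(assembly.pos[i] - center),
        )[:2]
        for t in near_core:
            b.bond(dom[0], t, 4.0)
        # acidic flexible tail (Spt16-CTD proxy)
        tail = []
        prev = dom[-1]
        tdir = outward + np.array([0.0, 0.0, -0.4])
        tdir /= np.linalg.norm(tdir)
        for kk in range(8):
            xyz = np.asarray(b.pos[dom[-1]]) + (kk + 1) * 0.8 * tdir
            i = b.bead(xyz, KIND_PROTEIN, ch, 6 + kk, radius=0.30,
                       q_cross=-1.0, group=-1)
            b.bond(prev, i, 20.0)
            prev = i
            tail.append(i)
        factors.fact_body = np.asarray(dom)
        factors.fact_tail = np.asarray(tail)

    new_asm = b.finish(
        assembly.ring, assembly.dna, assembly.scenario, assembly.states,
        nucleosome=assembly.nucleosome, factors=factors,
    )
    new_asm.scenario = dataclasses.replace(
        new_asm.scenario, factors=tuple(names),
        fpc_electrostatics_on=factors.fpc_electrostatics_on,
    )
    _validate_clash_free(new_asm)
    return new_asm


def _rebuilder_from(assembly: Assembly) -> _Builder:
    """Re-open an assembly for appending beads."""
    b = _Builder()
    b.pos = [p.copy() for p in assembly.pos]
    b.kind = list(assembly.kind)
    b.chain_code = list(assembly.chain_code)
    b.chain_ids = list(assembly.chain_ids)
    b.resindex = list(assembly.resindex)
    b.mass = list(assembly.mass)
    b.radius = list(assembly.radius)
    b.q_intra = list(assembly.q_intra)
    b.q_cross = list(assembly.q_cross)
    b.is_dna = list(assembly.is_dna)
    b.group = list(assembly.group)
    b.mobile = list(assembly.mobile)
    b.bonds = [tuple(x) for x in assembly.bonds]
    b.bond_k = list(assembly.bond_k)
    b.bond_r0 = list(assembly.bond_r0)
    b.angles = [tuple(x) for x in assembly.angles]
    b.angle_k = list(assembly.angle_k)
    b.angle_t0 = list(assembly.angle_t0)
    b.scaffold = [
        (int(i), float(k), p.copy())
        for i, k, p in zip(
            assembly.scaffold_idx, assembly.scaffold_k, assembly.scaffold_pos
        )
    ]
    b.pairs = [
        (int(i), int(j), int(c))
        for i, j, c in zip(assembly.pair_i, assembly.pair_j, assembly.pair_cls)
    ]
    b.stacks = [
        (int(i), int(j)) for i, j in zip(assembly.stack_i, assembly.stack_j)
    ]
    b.sites = [
        (int(a), int(d), float(e), float(s), float(r))
        for a, d, e, s, r in zip(
            assembly.site_anchor, assembly.site_dna,
            assembly.site_eps, assembly.site_shl, assembly.site_r0,
        )
    ]
    b.fixedwells = [
        (int(i), int(j), float(e))
        for i, j, e in zip(
            assembly.fixedwell_i, assembly.fixedwell_j, assembly.fixedwell_eps
        )
    ]
    return b


def build_minimal_system(
    n_beads: int = 1,
    k_restraint: float = 1.0,
    spacing: float = 3.0,
    bond_k: float = 0.0,
) -> Assembly:
    """A bare system of restrained beads (no ring, no DNA).

    Used for integrator calibration (harmonic-oscillator equipartition,
    overdamped relaxation) where the full scenario machinery would only
    obscure the check.
    """
    b = _Builder()
    prev = None
    for i in range(n_beads):
        # one chain per bead: nonbonded terms act between all beads
        ch = b.chain(f"X{i}")
        bead = b.bead((spacing * i, 0.0, 0.0), KIND_PROTEIN, ch, 0,
                      radius=0.4, group=-1)
        if k_restraint > 0:
            b.restrain(bead, k_restraint)
        if bond_k > 0 and prev is not None:
            b.bond(prev, bead, bond_k)
        prev = bead
    ring = RingTopology(
        subunit_labels=(), body_beads={}, loop_bead={},
        channel_axis=np.array([0.0, 0.0, 1.0]),
        pore_bead_set=np.empty(0, dtype=np.int32), azimuth={},
        loop_radius=0.5, park_radius=2.0, park_z=4.5,
        loop_rise_per_nt=1.0, pore_radius=1.45, z_top=9.5,
    )
    dna = DNATopology(
        strands=[], pairing_table=pd.DataFrame(
            columns=["nt_i", "nt_j", "chain_i", "chain_j", "cls"]
        ),
        fork_junction_index=None, tracked_strand="",
        tracked_phosphates=np.empty(0, dtype=np.int32),
        tracked_nt_index=np.empty(0, dtype=np.int32),
    )
    state = ReferenceState(
        state_id=1, engaged_set=frozenset(), registry_offset=0,
        loop_heights={}, per_subunit_registry={}, loop_targets={},
        native_pair_list=(),
    )
    scenario = ScenarioSpec(name="minimal", kind="ssdna", seed=0)
    return b.finish(ring, dna, scenario, [state])


def _validate_clash_free(asm: Assembly, factor: float = 0.8) -> None:
    ratio = asm.min_separation_ratio()
    if ratio < factor:
        raise AssemblyError(
            f"assembly has steric clashes: min separation ratio "
            f"{ratio:.3f} < {factor}"
        )
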