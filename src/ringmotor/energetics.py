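"""Potential-energy terms and the switchable active-potential set.

The force field is a deliberately simple stand-in for structure-based
protein and three-site-per-nucleotide DNA models: harmonic local terms plus
scaffold restraints stabilize the reference geometry, a Morse well per base
pair (deeper for GC than AT) plus base stacking stabilizes the duplex, and
Debye-Hueckel electrostatics with excluded volume act between everything
else.  The motor's grip on DNA is a set of switchable Gaussian
"hydrogen-bond" wells between each engaged subunit's pore-loop bead and its
*nearest* tracked-strand phosphate: the sliding eligibility is what lets
registry choice, idling, and backstepping emerge instead of being scripted.

Only the state-dependent terms (the hydrogen-bond contact set and the
state's loop-target restraints) change at a potential switch; bonded terms,
excluded volume, electrostatics, base pairing, stacking, nucleosome site
wells and factor wells stay on throughout.

Charge rules: DNA phosphates carry -0.6e toward other DNA beads
(counterion condensation) and -1.0e toward protein beads (counterion
release on binding); charged protein beads (factor patches, disordered
tails, the exposed histone-dimer surface) carry +/-1e.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ringmotor import _kernels as K
from ringmotor import units
from ringmotor.synthetic_topology import Assembly, ReferenceState

__all__ = [
    "ForceFieldParams",
    "ContactSet",
    "ActivePotentials",
    "bonded_energy",
    "hbond_energy",
    "basepair_energy",
    "electrostatic_energy",
    "excluded_volume_energy",
    "nucleosome_site_energy",
    "make_active_potentials",
    "total_force",
]


@dataclass
class ForceFieldParams:
    """All force-field constants, in reduced units (see :mod:`ringmotor.units`).

    Every field has a config key of the same name in the ``forcefield``
    section of the run configuration.
    """

    k_bond: float = 120.0         #: harmonic bond stiffness
    k_angle: float = 8.0          #: harmonic angle stiffness (ss chains)
    k_scaffold: float = 50.0      #: ring-body / core position restraints
    k_loop: float = 14.0          #: pore-loop target restraints (per state)
    eps_ev: float = 100.0         #: excluded-volume overlap stiffness
    eps_hb: float = 30.0          #: motor hydrogen-bond well depth
    sigma_hb: float = 0.25        #: motor hydrogen-bond well width
    r0_hb: float = 0.15           #: motor hydrogen-bond well center
    hb_form_steps: int = 12000    #: post-switch steps to full depth of new wells
    loop_move_steps: int = 4000   #: conformational relaxation time of loop targets
    hb_axial_window: float = 2.5  #: axial binding window of a loop around its target
    eps_at: float = 5.0           #: AT base-pair well depth
    eps_gc: float = 8.0           #: GC base-pair well depth (> AT)
    morse_a: float = 4.0          #: Morse well steepness for base pairs
    r0_bp: float = 0.8            #: base-pair equilibrium separation
    eps_stack: float = 3.0        #: stacking well depth
    r0_stack: float = 1.0         #: stacking equilibrium separation
    sigma_stack: float = 0.35     #: stacking well width
    sigma_site: float = 0.4       #: nucleosome site well width
    eps_fixedwell_sigma: float = 0.5  #: width of factor (RPA) wells
    r0_fixedwell: float = 0.7     #: center of factor (RPA) wells
    temperature: float = 1.0      #: reduced temperature (multiples of 300 K)
    salt: float = 0.3             #: monovalent salt, mol/L
    dielectric: float = 72.2      #: solvent dielectric constant
    q_phosphate_intra: float = -0.6
    q_phosphate_protein: float = -1.0
    q_idr_pos: float = 1.0
    q_idr_neg: float = -1.0
    elec_cutoff_debye: float = 5.0  #: electrostatic cutoff, Debye lengths
    gamma: float = 0.843          #: Langevin friction coefficient
    dt: float = 0.1               #: integration timestep

    def __post_init__(self) -> None:
        if not (self.eps_gc > self.eps_at > 0):
            raise ValueError("require eps_gc > eps_at > 0")
        if min(self.k_bond, self.k_angle, self.k_scaffold, self.k_loop) <= 0:
            raise ValueError("all stiffnesses must be > 0")
        if self.sigma_hb <= 0 or self.r0_hb < 0:
            raise ValueError("require sigma_hb > 0 and r0_hb >= 0")

    # ---- derived quantities -------------------------------------------
    @property
    def kappa(self) -> float:
        """Inverse Debye length (reduced units)."""
        return units.debye_kappa(self.salt, self.dielectric, self.temperature)

    @property
    def bjerrum(self) -> float:
        return units.bjerrum_length(self.dielectric, self.temperature)

    @property
    def elec_cutoff(self) -> float:
        return self.elec_cutoff_debye / self.kappa

    @property
    def r_break(self) -> float:
        """Base-pair break distance: where the Morse well keeps 5% depth."""
        return self.r0_bp + math.log(1.0 / (1.0 - math.sqrt(0.95))) / self.morse_a

    @property
    def capture_radius(self) -> float:
        """Contact-capture radius used by the metrics: r0_hb + 2 sigma_hb."""
        return self.r0_hb + 2.0 * self.sigma_hb

    @property
    def clog_threshold(self) -> float:
        """Lagging-strand-in-pore threshold, the 10-Angstrom equivalent."""
        return units.angstrom_to_reduced(10.0)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ForceFieldParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown forcefield keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class ContactSet:
    """The switchable hydrogen-bond wells realizing one DNA-binding state.

    ``wells`` is a list of ``(loop_bead_id, eligible_phosphates, eps,
    sigma, r0)``; each well binds the nearest eligible phosphate.
    """

    wells: list
    state_id: int

    def loop_beads(self) -> np.ndarray:
        return np.asarray([w[0] for w in self.wells], dtype=np.int32)


# --------------------------------------------------------------------------
# public per-term energies (NumPy reference implementations)


def bonded_energy(coords: np.ndarray, assembly: Assembly) -> float:
    """Harmonic bond + angle energy; zero at the reference geometry."""
    e = 0.0
    if len(assembly.bonds):
        d = coords[assembly.bonds[:, 0]] - coords[assembly.bonds[:, 1]]
        r = np.linalg.norm(d, axis=1)
        e += float(np.sum(0.5 * assembly.bond_k * (r - assembly.bond_r0) ** 2))
    if len(assembly.angles):
        a = coords[assembly.angles[:, 0]] - coords[assembly.angles[:, 1]]
        b = coords[assembly.angles[:, 2]] - coords[assembly.angles[:, 1]]
        ct = np.sum(a * b, axis=1) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
        )
        th = np.arccos(np.clip(ct, -1.0, 1.0))
        e += float(np.sum(0.5 * assembly.angle_k * (th - assembly.angle_t0) ** 2))
    return e


def hbond_energy(coords: np.ndarray, contact_set: ContactSet) -> float:
    """Sum over wells of the Gaussian evaluated at the nearest eligible
    phosphate.  Bounded below by -(sum of well depths)."""
    e = 0.0
    for loop, elig, eps, sigma, r0 in contact_set.wells:
        d = np.linalg.norm(coords[np.asarray(elig)] - coords[loop], axis=1)
        r = float(d.min())
        e += -eps * math.exp(-((r - r0) ** 2) / (2.0 * sigma**2))
    return e


def basepair_energy(
    coords: np.ndarray, assembly: Assembly, params: ForceFieldParams
):
    """Morse energy over the pairing table plus per-pair formed flags.

    A pair is flagged broken when the base-base distance exceeds the break
    distance (where the well retains 5% of its depth).
    """
    if len(assembly.pair_i) == 0:
        return 0.0, np.zeros(0, dtype=bool)
    d = np.linalg.norm(
        coords[assembly.pair_i] - coords[assembly.pair_j], axis=1
    )
    depth = np.where(assembly.pair_cls == 1, params.eps_gc, params.eps_at)
    om = 1.0 - np.exp(-params.morse_a * (d - params.r0_bp))
    e = float(np.sum(depth * (om * om - 1.0)))
    formed = d <= params.r_break
    return e, formed


def electrostatic_energy(
    coords: np.ndarray, assembly: Assembly, params: ForceFieldParams
) -> float:
    """Debye-Hueckel energy over all non-excluded charged pairs (brute
    force; the integrator uses the equivalent pair-list kernel).

    The pair class picks the charge: DNA-DNA pairs use the intra-DNA
    phosphate charge, pairs involving a protein bead use the protein-DNA
    phosphate charge and the protein bead's own charge.
    """
    q_i, q_c = assembly.q_intra, assembly.q_cross
    charged = np.where((q_i != 0) | (q_c != 0))[0]
    lb, kap, rcut = params.bjerrum, params.kappa, params.elec_cutoff
    shift = math.exp(-kap * rcut) / rcut
    e = 0.0
    for a in range(len(charged)):
        i = charged[a]
        for b in range(a + 1, len(charged)):
            j = charged[b]
            if _excluded(assembly, i, j):
                continue
            qq = (
                q_i[i] * q_i[j]
                if assembly.is_dna[i] and assembly.is_dna[j]
                else q_c[i] * q_c[j]
            )
            if qq == 0.0:
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            if r < rcut:
                e += qq * lb * (math.exp(-kap * r) / r - shift)
    return e


def excluded_volume_energy(
    coords: np.ndarray, assembly: Assembly, params: ForceFieldParams
) -> float:
    """Purely repulsive harmonic-overlap energy; zero beyond contact
    (brute force reference path)."""
    partner = _pair_partner(assembly)
    n = assembly.n_beads
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if _excluded(assembly, i, j) or partner[i] == j:
                continue
            sig = assembly.radius[i] + assembly.radius[j]
            r = float(np.linalg.norm(coords[i] - coords[j]))
            if 0 < r < sig:
                e += 0.5 * params.eps_ev * (sig - r) ** 2
    return e


def nucleosome_site_energy(
    coords: np.ndarray, assembly: Assembly, params: ForceFieldParams
):
    """Histone-DNA site wells (Gaussian per SHL site) plus formed flags.

    A site is broken when its DNA nucleotide is displaced beyond 6 sigma
    from the reference separation to its core anchor.
    """
    if len(assembly.site_anchor) == 0:
        return 0.0, np.zeros(0, dtype=bool)
    d = np.linalg.norm(
        coords[assembly.site_anchor] - coords[assembly.site_dna], axis=1
    )
    e = float(
        np.sum(
            -assembly.site_eps
            * np.exp(-((d - assembly.site_r0) ** 2) / (2 * params.sigma_site**2))
        )
    )
    formed = np.abs(d - assembly.site_r0) <= 6.0 * params.sigma_site
    return e, formed


def _excluded(assembly: Assembly, i: int, j: int) -> bool:
    if assembly.group[i] == -2 or assembly.group[j] == -2:
        return True
    if assembly.group[i] == assembly.group[j] and assembly.group[i] >= 0:
        return True
    if assembly.chain_code[i] == assembly.chain_code[j] and abs(i - j) <= 3:
        return True
    return False


def _pair_partner(assembly: Assembly) -> np.ndarray:
    partner = np.full(assembly.n_beads, -1, dtype=np.int32)
    partner[assembly.pair_i] = assembly.pair_j
    partner[assembly.pair_j] = assembly.pair_i
    return partner


# --------------------------------------------------------------------------
# active potentials


class ActivePotentials:
    """Packed, switchable potential set for one assembly and one state.

    Always-on terms never change across switches; :meth:`set_state`
    replaces the hydrogen-bond contact set and/or the loop-target
    restraints depending on the switching mode.
    """

    EXCL_SEP = 3  # chain-separation exclusion for nonbonded terms
    SKIN = 1.0   # neighbor-list skin

    def __init__(
        self,
        assembly: Assembly,
        params: ForceFieldParams,
        state: ReferenceState,
        contact_set: Optional[ContactSet] = None,
    ) -> None:
        self.assembly = assembly
        self.params = params
        a = assembly
        self._pos_dtype = float
        self.radius = a.radius
        self.partner = _pair_partner(a)
        self.is_dna_u8 = a.is_dna.astype(np.uint8)
        # nonbonded subsets
        self.ev_sub = np.arange(a.n_beads, dtype=np.int32)
        self.el_sub = np.where((a.q_intra != 0) | (a.q_cross != 0))[0].astype(
            np.int32
        )
        self.ev_cut = float(2.0 * a.radius.max())
        self.el_cut = params.elec_cutoff
        cap_ev = max(64, 80 * a.n_beads)
        cap_el = max(64, 120 * max(1, len(self.el_sub)))
        self.ev_i = np.zeros(cap_ev, dtype=np.int32)
        self.ev_j = np.zeros(cap_ev, dtype=np.int32)
        self.el_i = np.zeros(cap_el, dtype=np.int32)
        self.el_j = np.zeros(cap_el, dtype=np.int32)
        self.n_ev = 0
        self.n_el = 0
        # base pairing
        self.pair_depth = np.where(
            a.pair_cls == 1, params.eps_gc, params.eps_at
        ).astype(float)
        # generic Gaussian wells: stacking + nucleosome sites + factor wells
        gi = [a.stack_i, a.site_anchor, a.fixedwell_i]
        gj = [a.stack_j, a.site_dna, a.fixedwell_j]
        geps = [
            np.full(len(a.stack_i), params.eps_stack),
            a.site_eps,
            a.fixedwell_eps,
        ]
        gr0 = [
            np.full(len(a.stack_i), params.r0_stack),
            a.site_r0,
            np.full(len(a.fixedwell_i), params.r0_fixedwell),
        ]
        gsig = [
            np.full(len(a.stack_i), params.sigma_stack),
            np.full(len(a.site_anchor), params.sigma_site),
            np.full(len(a.fixedwell_i), params.eps_fixedwell_sigma),
        ]
        self.gw_i = np.concatenate(gi).astype(np.int32)
        self.gw_j = np.concatenate(gj).astype(np.int32)
        self.gw_eps = np.concatenate(geps).astype(float)
        self.gw_r0 = np.concatenate(gr0).astype(float)
        self.gw_sig = np.concatenate(gsig).astype(float)
        # loop restraints (all six loops, state targets)
        self.loop_idx = np.asarray(
            [a.ring.loop_bead[lab] for lab in a.ring.subunit_labels],
            dtype=np.int32,
        )
        self.loop_k = np.full(len(self.loop_idx), params.k_loop)
        self.loop_target = np.zeros((len(self.loop_idx), 3))
        # state-dependent pieces
        self.state = state
        self.contact = (
            contact_set
            if contact_set is not None
            else self._build_contact(state)
        )
        self._apply_targets(state)
        self.loop_target[:] = self.loop_target_goal
        self.loop_target_start[:] = self.loop_target_goal
        self._pack_wells()
        self.chosen = np.full(len(self.well_loop), -1, dtype=np.int64)

    # -- state switching -------------------------------------------------
    def _build_contact(self, state: ReferenceState) -> ContactSet:
        a = self.assembly
        elig = a.dna.tracked_phosphates
        wells = [
            (
                int(a.ring.loop_bead[lab]),
                elig,
                self.params.eps_hb,
                self.params.sigma_hb,
                self.params.r0_hb,
            )
            for lab in sorted(state.engaged_set)
        ]
        return ContactSet(wells=wells, state_id=state.state_id)

    def _apply_targets(self, state: ReferenceState) -> None:
        """Set the loop-target endpoints for ``state``.

        The targets themselves move smoothly from their current positions
        to the new state's positions over ``loop_move_steps``
        (:meth:`update_loop_targets`): the potential switch is abrupt but
        the ring's conformational relaxation is continuous, which is what
        lets anchoring subunits drag the DNA quasi-statically instead of
        tearing free.
        """
        self.loop_target_start = self.loop_target.copy()
        self.loop_target_goal = self.loop_target.copy()
        for m, lab in enumerate(self.assembly.ring.subunit_labels):
            self.loop_target_goal[m] = state.loop_targets[lab]

    def update_loop_targets(self, t_since_switch: int) -> None:
        if t_since_switch > self.params.loop_move_steps + 100 and np.array_equal(
            self.loop_target, self.loop_target_goal
        ):
            return
        frac = min(1.0, max(0.0, t_since_switch
                            / max(1, self.params.loop_move_steps)))
        self.loop_target[:] = (
            self.loop_target_start
            + frac * (self.loop_target_goal - self.loop_target_start)
        )
        self._sync_well_targets()

    def _sync_well_targets(self) -> None:
        """Axial positions of each grip well's binding window (the loop's
        current structural target): a loop can only bind phosphates within
        ``hb_axial_window`` of it, the stand-in for the orientational
        specificity of coarse-grained hydrogen bonds."""
        loop_z = {
            int(self.loop_idx[m]): float(self.loop_target[m, 2])
            for m in range(len(self.loop_idx))
        }
        for w in range(len(self.well_loop)):
            self.well_tgt_z[w] = loop_z.get(int(self.well_loop[w]), 0.0)

    def _pack_wells(self, levels=None) -> None:
        self.well_loop = np.asarray(
            [w[0] for w in self.contact.wells], dtype=np.int32
        )
        self.well_depth_full = np.asarray(
            [w[2] for w in self.contact.wells], dtype=float
        )
        n = len(self.well_loop)
        ramp = float(max(1, self.params.hb_form_steps))
        if levels is None:
            # fully formed grips (initial assembly)
            self.well_t0 = np.full(n, -ramp)
            self.well_grip = np.full(n, -1, dtype=np.int64)
        else:
            # retained subunits keep mature grips on their phosphate; new
            # subunits ramp from the switch instant
            self.well_t0 = np.asarray(
                [-ramp if int(lb) in levels else 0.0
                 for lb in self.well_loop], float
            )
            self.well_grip = np.asarray(
                [levels.get(int(lb), (-1,))[-1] if isinstance(
                    levels.get(int(lb)), tuple) else -1
                 for lb in self.well_loop], dtype=np.int64
            )
        self.well_level = np.ones(n)
        self.well_depth = self.well_depth_full.copy()
        self.well_tgt_z = np.zeros(n)
        self._sync_well_targets()
        self.elig = np.asarray(
            self.contact.wells[0][1] if self.contact.wells else [],
            dtype=np.int32,
        )

    def update_well_levels(self, pos: np.ndarray, t_since_switch: int) -> None:
        """Advance the formation ramp of newly engaged grip wells.

        The hydrogen-bond network of a subunit that (re)engages DNA after
        a potential switch forms progressively, reaching full depth
        ``hb_form_steps`` after the switch; subunits engaged in both the
        previous and the current state keep a mature grip throughout (they
        are the potential anchors).  Outside the formation window the
        potential set is time-independent, so a steady dwell and the
        no-switch null are strictly conservative.
        """
        if len(self.well_loop) == 0:
            return
        if t_since_switch - self.well_t0.min() > self.params.hb_form_steps:
            if self.well_level.min() >= 1.0:
                return  # all grips mature; nothing to update
        ramp = max(1, self.params.hb_form_steps)
        lvl = np.clip((t_since_switch - self.well_t0) / ramp, 0.0, 1.0)
        self.well_level[:] = lvl
        self.well_depth[:] = self.well_depth_full * lvl

    def update_well_levels_t0(self) -> None:
        """Apply depths for the switch instant (t_since_switch = 0)."""
        ramp = max(1, self.params.hb_form_steps)
        lvl = np.clip((0.0 - self.well_t0) / ramp, 0.0, 1.0)
        self.well_level[:] = lvl
        self.well_depth[:] = self.well_depth_full * lvl

    def set_state(self, state: ReferenceState, mode: str = "full") -> None:
        """Switch the state-dependent terms.

        ``full`` replaces the contact set and the loop targets;
        ``conformation_only`` replaces the loop targets but keeps the
        hydrogen-bond contact set; ``frozen`` changes nothing.
        """
        if mode not in ("full", "conformation_only", "frozen"):
            raise ValueError(f"unknown switching mode: {mode!r}")
        if mode == "frozen":
            return
        prev_levels = {
            int(lb): (float(lv), int(gr))
            for lb, lv, gr in zip(
                self.well_loop, self.well_level, self.well_grip
            )
        }
        self.state = state
        self._apply_targets(state)
        if mode == "full":
            self.contact = self._build_contact(state)
            # retained subunits keep their formed grip; newly engaged
            # subunits start with an unformed (zero-depth) well
            self._pack_wells(levels=prev_levels)
            self.update_well_levels_t0()
            self.chosen = np.full(len(self.well_loop), -1, dtype=np.int64)

    # -- evaluation --------------------------------------------------------
    def rebuild_neighbors(self, pos: np.ndarray) -> None:
        a = self.assembly
        n = K.build_pairs(
            pos, self.ev_sub, self.ev_cut + self.SKIN, a.group,
            a.chain_code.astype(np.int32), a.resindex, self.EXCL_SEP,
            self.ev_i, self.ev_j,
        )
        if n < 0:
            raise RuntimeError("excluded-volume pair list overflow")
        self.n_ev = n
        n = K.build_pairs(
            pos, self.el_sub, self.el_cut + self.SKIN, a.group,
            a.chain_code.astype(np.int32), a.resindex, self.EXCL_SEP,
            self.el_i, self.el_j,
        )
        if n < 0:
            raise RuntimeError("electrostatic pair list overflow")
        self.n_el = n

    def _kernel_args(self, pos, f):
        a = self.assembly
        p = self.params
        return (
            pos, f,
            a.bonds, a.bond_k, a.bond_r0,
            a.angles, a.angle_k, a.angle_t0,
            a.scaffold_idx, a.scaffold_k, a.scaffold_pos,
            self.loop_idx, self.loop_k, self.loop_target,
            self.ev_i, self.ev_j, self.n_ev, a.radius, p.eps_ev, self.partner,
            self.el_i, self.el_j, self.n_el, a.q_intra, a.q_cross,
            self.is_dna_u8, p.bjerrum, p.kappa, p.elec_cutoff,
            a.pair_i, a.pair_j, self.pair_depth, p.morse_a, p.r0_bp,
            self.gw_i, self.gw_j, self.gw_eps, self.gw_r0, self.gw_sig,
            self.well_loop, self.well_depth, p.sigma_hb, p.r0_hb, self.elig,
            self.well_tgt_z, p.hb_axial_window, self.chosen,
        )

    def forces(self, pos: np.ndarray, rebuild: bool = True):
        """Analytic force on every bead plus the total energy."""
        if not np.all(np.isfinite(pos)):
            raise FloatingPointError("non-finite coordinates")
        if rebuild:
            self.rebuild_neighbors(pos)
        f = np.zeros_like(pos)
        e = K.total_forces(*self._kernel_args(pos, f))
        return f, float(e)

    def energy(self, pos: np.ndarray) -> float:
        return self.forces(pos)[1]

    def energy_terms(self, pos: np.ndarray) -> dict:
        """Per-term energies (brute-force reference path; for diagnostics
        and the switch-invariance checks)."""
        a, p = self.assembly, self.params
        ebp, _ = basepair_energy(pos, a, p)
        esite, _ = nucleosome_site_energy(pos, a, p)
        # stacking + factor wells from the generic Gaussian set minus sites
        nstack = len(a.stack_i)
        d = np.linalg.norm(pos[self.gw_i] - pos[self.gw_j], axis=1)
        egw = -self.gw_eps * np.exp(
            -((d - self.gw_r0) ** 2) / (2 * self.gw_sig**2)
        )
        nsites = len(a.site_anchor)
        estack = float(egw[:nstack].sum())
        efact = float(egw[nstack + nsites :].sum())
        rest = pos[a.scaffold_idx] - a.scaffold_pos
        loops = pos[self.loop_idx] - self.loop_target
        return {
            "bonded": bonded_energy(pos, a),
            "scaffold": float(np.sum(0.5 * a.scaffold_k * np.sum(rest**2, 1))),
            "loop_restraints": float(
                np.sum(0.5 * self.loop_k * np.sum(loops**2, 1))
            ),
            "excluded_volume": excluded_volume_energy(pos, a, p),
            "electrostatics": electrostatic_energy(pos, a, p),
            "basepair": ebp,
            "stacking": estack,
            "nucleosome_sites": esite,
            "factor_wells": efact,
            "hbond": self._hbond_current(pos),
        }

    def _hbond_current(self, pos: np.ndarray) -> float:
        """Hydrogen-bond energy at the *current* well depths (which may be
        mid-ramp and hence differ from the contact set's full depths)."""
        e = 0.0
        if len(self.elig) == 0:
            return e
        p = self.params
        for w in range(len(self.well_loop)):
            inwin = np.abs(
                pos[self.elig, 2] - self.well_tgt_z[w]
            ) <= p.hb_axial_window
            if not inwin.any():
                continue
            d = np.linalg.norm(
                pos[self.elig[inwin]] - pos[self.well_loop[w]], axis=1
            )
            r = float(d.min())
            e += -self.well_depth[w] * math.exp(
                -((r - p.r0_hb) ** 2) / (2.0 * p.sigma_hb**2)
            )
        return e


def make_active_potentials(
    state: ReferenceState,
    params: ForceFieldParams,
    assembly: Assembly,
    contact_set: Optional[ContactSet] = None,
) -> ActivePotentials:
    """Assemble the active potential set for ``state``.

    Hydrogen-bond wells exist only for the engaged subunits of ``state``
    (unless an explicit ``contact_set`` is carried over, as in the
    conformation-only control); all always-on terms are taken from the
    assembly unchanged.
    """
    if state.state_id not in {s.state_id for s in assembly.states}:
        raise ValueError(f"unknown state id {state.state_id}")
    return ActivePotentials(assembly, params, state, contact_set=contact_set)


def total_force(coords: np.ndarray, active: ActivePotentials) -> np.ndarray:
    """Analytic gradient of the total energy; finite everywhere."""
    f, _ = active.forces(coords)
    if not np.all(np.isfinite(f)):
        bad = int(np.where(~np.isfinite(f).all(axis=1))[0][0])
        raise FloatingPointError(f"non-finite force on bead {bad}")
    return f
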