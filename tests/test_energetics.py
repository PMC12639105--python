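"""Energy terms, forces, and switch invariance."""

import math

import numpy as np
import pytest

from ringmotor import synthetic_topology as topo
from ringmotor.energetics import (
    ActivePotentials,
    ContactSet,
    ForceFieldParams,
    basepair_energy,
    bonded_energy,
    electrostatic_energy,
    excluded_volume_energy,
    hbond_energy,
    make_active_potentials,
    nucleosome_site_energy,
    total_force,
)


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ForceFieldParams(eps_gc=2.0, eps_at=3.0)
        with pytest.raises(ValueError):
            ForceFieldParams(k_bond=-1.0)

    def test_debye_screening_scales_with_salt(self, params):
        saltier = ForceFieldParams(salt=1.2)
        assert saltier.kappa == pytest.approx(2.0 * params.kappa)

    def test_round_trip_dict(self, params):
        again = ForceFieldParams.from_dict(params.to_dict())
        assert again == params
        with pytest.raises(ValueError, match="frictoin"):
            ForceFieldParams.from_dict({"frictoin": 1.0})


class TestBonded:
    def test_zero_at_reference(self, ss_assembly):
        assert bonded_energy(ss_assembly.pos, ss_assembly) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_single_bond_closed_form(self, ss_assembly):
        asm = ss_assembly
        i, j = asm.bonds[0]
        k, r0 = asm.bond_k[0], asm.bond_r0[0]
        pos = asm.pos.copy()
        direction = pos[i] - pos[j]
        direction /= np.linalg.norm(direction)
        delta = 0.07
        pos[i] += delta * direction
        # only this bond is perturbed appreciably; angle terms touching the
        # pair change too, so compare against the brute-force sum
        expected = 0.5 * k * delta**2
        got = float(
            np.sum(
                0.5 * asm.bond_k
                * (np.linalg.norm(pos[asm.bonds[:, 0]] - pos[asm.bonds[:, 1]],
                                  axis=1) - asm.bond_r0) ** 2
            )
        )
        assert got == pytest.approx(expected, rel=1e-9)

    def test_matches_term_by_term_oracle(self, ss_assembly, rng):
        """Randomly perturbed coordinates: the packaged bond+angle energy
        equals an explicit per-term summation."""
        asm = ss_assembly
        pos = asm.pos + 0.03 * rng.standard_normal(asm.pos.shape)
        e_bonds = 0.0
        for (i, j), k, r0 in zip(asm.bonds, asm.bond_k, asm.bond_r0):
            e_bonds += 0.5 * k * (np.linalg.norm(pos[i] - pos[j]) - r0) ** 2
        e_angles = 0.0
        for (i, j, l), k, t0 in zip(asm.angles, asm.angle_k, asm.angle_t0):
            a, b = pos[i] - pos[j], pos[l] - pos[j]
            ct = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
            e_angles += 0.5 * k * (math.acos(np.clip(ct, -1, 1)) - t0) ** 2
        assert bonded_energy(pos, asm) == pytest.approx(
            e_bonds + e_angles, rel=1e-9
        )


class TestHbond:
    def _contact(self, asm, params, loop_lab=3):
        loop = asm.ring.loop_bead[loop_lab]
        return ContactSet(
            wells=[(loop, asm.dna.tracked_phosphates, params.eps_hb,
                    params.sigma_hb, params.r0_hb)],
            state_id=1,
        )

    def test_minimum_at_r0(self, ss_assembly, params):
        asm = ss_assembly
        cs = self._contact(asm, params)
        pos = asm.pos.copy()
        loop = cs.wells[0][0]
        target = asm.pos[asm.dna.tracked_phosphates[30]] + np.array(
            [params.r0_hb, 0, 0]
        )
        pos[loop] = target
        assert hbond_energy(pos, cs) == pytest.approx(-params.eps_hb,
                                                      rel=1e-6)

    def test_tail_negligible(self, ss_assembly, params):
        asm = ss_assembly
        cs = self._contact(asm, params)
        pos = asm.pos.copy()
        pos[cs.wells[0][0]] = np.array([50.0, 50.0, 50.0])
        assert abs(hbond_energy(pos, cs)) < 1e-6 * params.eps_hb

    def test_nearest_eligible_selected(self, ss_assembly, params, rng):
        """The well binds the nearest eligible phosphate: matches an
        explicit minimum over the eligible set."""
        asm = ss_assembly
        cs = self._contact(asm, params)
        loop, elig, eps, sigma, r0 = cs.wells[0]
        for _ in range(10):
            pos = asm.pos.copy()
            pos[loop] = asm.pos[loop] + rng.uniform(-1.5, 1.5, 3)
            d = np.linalg.norm(pos[elig] - pos[loop], axis=1).min()
            expected = -eps * math.exp(-((d - r0) ** 2) / (2 * sigma**2))
            assert hbond_energy(pos, cs) == pytest.approx(expected, rel=1e-9)

    def test_bounded_below(self, ss_assembly, params):
        state = ss_assembly.states[0]
        ap = make_active_potentials(state, params, ss_assembly)
        assert hbond_energy(ss_assembly.pos, ap.contact) >= -4 * params.eps_hb


class TestBasePair:
    def test_all_formed_at_reference(self, fork_assembly, params):
        e, formed = basepair_energy(fork_assembly.pos, fork_assembly, params)
        depth = np.where(fork_assembly.pair_cls == 1, params.eps_gc,
                         params.eps_at)
        assert formed.all()
        assert e == pytest.approx(-float(depth.sum()), rel=1e-4)

    def test_separated_pair_broken_and_weightless(self, fork_assembly,
                                                  params):
        asm = fork_assembly
        pos = asm.pos.copy()
        pos[asm.pair_i[0]] += np.array([0.0, 8.0, 0.0])
        e, formed = basepair_energy(pos, asm, params)
        assert not formed[0]
        assert formed[1:].all()
        e_ref, _ = basepair_energy(asm.pos, asm, params)
        depth0 = params.eps_gc if asm.pair_cls[0] == 1 else params.eps_at
        assert e == pytest.approx(e_ref + depth0, abs=0.05 * depth0)

    def test_quasistatic_pulling_breaks_at_before_gc(self, params):
        """Slow symmetric separation of matched AT and GC pairs: the AT
        pair loses its well (drops below 5% depth) at a smaller distance
        penalty - verified on the closed-form Morse profile."""
        r = np.linspace(params.r0_bp, params.r0_bp + 2.5, 400)

        def depth_frac(eps):
            u = eps * ((1 - np.exp(-params.morse_a * (r - params.r0_bp))) ** 2
                       - 1.0)
            return -u / eps

        at, gc = depth_frac(params.eps_at), depth_frac(params.eps_gc)
        # same fractional profile but absolute retention differs
        u_at = -params.eps_at * at
        u_gc = -params.eps_gc * gc
        cross_at = r[np.argmax(u_at > -1.0)]  # distance where < 1 kBT held
        cross_gc = r[np.argmax(u_gc > -1.0)]
        assert cross_at < cross_gc


class TestElectrostatics:
    def test_neutral_pair_contributes_zero(self, params):
        asm = topo.build_minimal_system(n_beads=2, k_restraint=1.0)
        assert electrostatic_energy(asm.pos, asm, params) == 0.0

    def test_screened_coulomb_closed_form(self, params):
        """Two protein-class unit charges at one Debye length."""
        asm = topo.build_minimal_system(n_beads=2, k_restraint=1.0,
                                        spacing=1.0 / params.kappa)
        asm.q_cross[:] = 1.0
        expected = params.bjerrum * params.kappa * (
            math.exp(-1.0)
            - math.exp(-params.elec_cutoff_debye) / params.elec_cutoff_debye
        )
        got = electrostatic_energy(asm.pos, asm, params)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_charge_class_ratio(self, params):
        """Same geometry classed intra-DNA vs protein-DNA: energies in the
        ratio (0.6 * 0.6) : (1.0 * 0.6) per the phosphate charge rules."""
        asm = topo.build_minimal_system(n_beads=2, k_restraint=1.0,
                                        spacing=2.0)
        asm.q_intra[:] = params.q_phosphate_intra
        asm.q_cross[:] = params.q_phosphate_protein
        asm.is_dna[:] = True
        e_dna = electrostatic_energy(asm.pos, asm, params)
        asm.is_dna[1] = False  # one bead now protein-class
        asm.q_cross[0] = params.q_phosphate_protein
        asm.q_cross[1] = 0.6
        e_cross = electrostatic_energy(asm.pos, asm, params)
        assert abs(e_cross) / abs(e_dna) == pytest.approx(
            (1.0 * 0.6) / (0.6 * 0.6), rel=1e-9
        )


class TestExcludedVolume:
    def test_zero_beyond_contact(self, params):
        asm = topo.build_minimal_system(n_beads=2, k_restraint=1.0,
                                        spacing=3.0)
        assert excluded_volume_energy(asm.pos, asm, params) == 0.0

    def test_monotone_in_overlap(self, params):
        asm = topo.build_minimal_system(n_beads=2, k_restraint=1.0,
                                        spacing=3.0)
        energies = []
        for r in (0.7, 0.5, 0.3, 0.1):
            pos = asm.pos.copy()
            pos[1] = pos[0] + np.array([r, 0, 0])
            energies.append(excluded_volume_energy(pos, asm, params))
        assert energies[0] > 0
        assert all(b > a for a, b in zip(energies, energies[1:]))

    def test_matches_bruteforce_pair_loop(self, ss_assembly, params, rng):
        asm = ss_assembly
        pos = asm.pos + 0.05 * rng.standard_normal(asm.pos.shape)
        ap = make_active_potentials(asm.states[0], params, asm)
        ap.rebuild_neighbors(pos)
        terms = ap.energy_terms(pos)
        # kernel total equals the brute-force per-term sum
        _, e_kernel = ap.forces(pos, rebuild=False)
        assert e_kernel == pytest.approx(sum(terms.values()), rel=1e-6,
                                         abs=1e-6)


class TestNucleosomeSites:
    def test_fully_wrapped_reference(self, nuc_assembly, params):
        e, formed = nucleosome_site_energy(nuc_assembly.pos, nuc_assembly,
                                           params)
        assert formed.all()
        assert e == pytest.approx(-float(nuc_assembly.site_eps.sum()),
                                  rel=1e-2)

    def test_displaced_site_broken(self, nuc_assembly, params):
        asm = nuc_assembly
        pos = asm.pos.copy()
        pos[asm.site_dna[0]] += np.array([0.0, 0.0, 6.1 * params.sigma_site
                                          + asm.site_r0[0]])
        _, formed = nucleosome_site_energy(pos, asm, params)
        assert not formed[0]


class TestActivePotentials:
    def test_state1_wells_on_engaged_loops_only(self, ss_active,
                                                ss_assembly):
        wells = set(ss_active.contact.loop_beads())
        expected = {ss_assembly.ring.loop_bead[lab] for lab in (2, 3, 5, 6)}
        assert wells == expected

    def test_conformation_only_keeps_contact_set(self, ss_assembly, params):
        ap = make_active_potentials(ss_assembly.states[0], params,
                                    ss_assembly)
        before = list(ap.contact.loop_beads())
        ap.set_state(ss_assembly.states[1], mode="conformation_only")
        assert list(ap.contact.loop_beads()) == before
        # but the conformation (loop targets) did switch
        assert not np.array_equal(ap.loop_target_goal, ap.loop_target_start)

    def test_unknown_state_rejected(self, ss_assembly, params):
        import dataclasses

        bogus = dataclasses.replace(ss_assembly.states[0], state_id=9)
        with pytest.raises(ValueError, match="unknown state"):
            make_active_potentials(bogus, params, ss_assembly)

    def test_switch_invariance_of_always_on_terms(self, ss_assembly,
                                                  params, rng):
        """Electrostatics, excluded volume, base pairing, stacking and
        bonded energies are identical immediately before and after a state
        switch at frozen coordinates."""
        asm = ss_assembly
        pos = asm.pos + 0.02 * rng.standard_normal(asm.pos.shape)
        ap = make_active_potentials(asm.states[0], params, asm)
        before = ap.energy_terms(pos)
        ap.set_state(asm.states[1], mode="full")
        after = ap.energy_terms(pos)
        for key in ("bonded", "scaffold", "excluded_volume",
                    "electrostatics", "basepair", "stacking",
                    "nucleosome_sites", "factor_wells"):
            assert after[key] == pytest.approx(before[key], rel=1e-12), key

    def test_force_matches_numerical_gradient(self, ss_assembly, params,
                                              rng):
        """Central-difference check of the analytic gradient on a random
        configuration: max relative deviation < 1e-4."""
        asm = ss_assembly
        ap = make_active_potentials(asm.states[0], params, asm)
        pos = asm.pos + 0.02 * rng.standard_normal(asm.pos.shape)
        ap.rebuild_neighbors(pos)
        f, _ = ap.forces(pos, rebuild=False)
        h = 1e-6
        worst = 0.0
        for _ in range(40):
            i = int(rng.integers(asm.n_beads))
            d = int(rng.integers(3))
            pp, pm = pos.copy(), pos.copy()
            pp[i, d] += h
            pm[i, d] -= h
            fnum = -(ap.forces(pp, rebuild=False)[1]
                     - ap.forces(pm, rebuild=False)[1]) / (2 * h)
            scale = max(1.0, abs(fnum))
            worst = max(worst, abs(fnum - f[i, d]) / scale)
        assert worst < 1e-4

    def test_force_finite_and_errors_on_nan(self, ss_active, ss_assembly):
        f = total_force(ss_assembly.pos, ss_active)
        assert np.isfinite(f).all()
        bad = ss_assembly.pos.copy()
        bad[3, 0] = np.nan
        with pytest.raises(FloatingPointError):
            total_force(bad, ss_active)

    def test_hbond_force_linear_in_depth(self, ss_assembly, rng):
        """Doubling the well depth doubles the hydrogen-bond force
        contribution exactly."""
        pos = ss_assembly.pos + 0.02 * rng.standard_normal(
            ss_assembly.pos.shape
        )
        p1 = ForceFieldParams()
        p2 = ForceFieldParams(eps_hb=2 * p1.eps_hb)
        ap1 = make_active_potentials(ss_assembly.states[0], p1, ss_assembly)
        ap2 = make_active_potentials(ss_assembly.states[0], p2, ss_assembly)
        ap1.rebuild_neighbors(pos)
        ap2.rebuild_neighbors(pos)
        # isolate the well term by zeroing depths
        f1, _ = ap1.forces(pos, rebuild=False)
        ap1.well_depth[:] = 0
        f1_off, _ = ap1.forces(pos, rebuild=False)
        f2, _ = ap2.forces(pos, rebuild=False)
        ap2.well_depth[:] = 0
        f2_off, _ = ap2.forces(pos, rebuild=False)
        np.testing.assert_allclose(f2 - f2_off, 2 * (f1 - f1_off),
                                   rtol=1e-9, atol=1e-9)
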