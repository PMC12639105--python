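"""Trajectory metrics on constructed inputs with independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from ringmotor import metrics as M
from ringmotor import synthetic_topology as topo
from ringmotor.energetics import ForceFieldParams
from ringmotor.engine import Trajectory


def _traj_from_frames(asm, frames, events=(), params=None, step_stride=100):
    frames = np.asarray(frames, dtype=np.float32)
    return Trajectory(
        frames=frames,
        frame_step=np.arange(1, len(frames) + 1) * step_stride,
        frame_state=np.ones(len(frames), dtype=np.int16),
        switch_events=list(events),
        seed=0,
        scenario=asm.scenario,
        interval=step_stride,
        dt=0.1,
        assembly=asm,
        params=params or ForceFieldParams(),
    )


def _shift_dna(asm, nt_shift):
    """Rigidly translate every DNA bead down the axis by ``nt_shift``
    nucleotides (the geometry of forward translocation)."""
    pos = asm.pos.copy()
    pos[asm.is_dna] -= np.array([0.0, 0.0, float(nt_shift)])
    return pos


def _piecewise_traj(asm, levels, frames_per_level=10):
    """Displacement-profile trajectory: each level is a rigid DNA shift,
    with switch events at the level boundaries."""
    frames, events = [], []
    step = 0
    seq = [1, 2, 3, 4, 1, 2, 3, 4]
    for li, lvl in enumerate(levels):
        for _ in range(frames_per_level):
            step += 100
            frames.append(_shift_dna(asm, lvl))
        if li + 1 < len(levels):
            events.append((step + 50, seq[li], seq[li + 1]))
    traj = _traj_from_frames(asm, frames)
    traj.frame_step = np.arange(1, len(frames) + 1) * 100
    traj.switch_events = events
    return traj


class TestTrackedDisplacement:
    def test_static_trajectory_all_zero(self, ss_assembly):
        traj = _traj_from_frames(ss_assembly, [ss_assembly.pos] * 5)
        assert (M.tracked_displacement(traj) == 0).all()

    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_rigid_shift_reads_k(self, ss_assembly, k):
        traj = _traj_from_frames(
            ss_assembly, [ss_assembly.pos, _shift_dna(ss_assembly, k)]
        )
        disp = M.tracked_displacement(traj)
        assert disp[0] == 0
        assert disp[1] == k

    def test_sign_convention_5prime_positive(self, ss_assembly):
        """DNA sliding so higher (5'-ward) indices reach the reference site
        reads as positive displacement."""
        traj = _traj_from_frames(
            ss_assembly, [ss_assembly.pos, _shift_dna(ss_assembly, 2)]
        )
        assert M.tracked_displacement(traj)[1] > 0


class TestSteps:
    def test_piecewise_profile_steps(self, ss_assembly):
        """Displacement plateaus (0, 1, 7, 12) yield steps (1, 6, 5): the
        3-state registry pattern."""
        traj = _piecewise_traj(ss_assembly, [0, 1, 7, 12])
        table = M.per_transition_steps(traj)
        assert table.transitions.step_size.tolist() == [1.0, 6.0, 5.0]
        assert table.net_displacement == 12.0
        assert table.outcome == "forward"

    def test_no_switches_empty_table(self, ss_assembly):
        traj = _traj_from_frames(
            ss_assembly, [ss_assembly.pos, _shift_dna(ss_assembly, 2)]
        )
        table = M.per_transition_steps(traj)
        assert table.transitions.empty
        assert table.net_displacement == 2.0

    @given(
        levels=hst.lists(hst.integers(min_value=-10, max_value=12),
                         min_size=2, max_size=6)
    )
    @settings(max_examples=15, deadline=None)
    def test_telescoping_identity(self, levels):
        """Per-transition steps always sum exactly to the net
        displacement, for arbitrary plateau profiles."""
        asm = _TELESCOPE_ASM
        traj = _piecewise_traj(asm, levels, frames_per_level=5)
        table = M.per_transition_steps(traj)
        assert table.transitions.step_size.sum() == pytest.approx(
            table.net_displacement, abs=1e-9
        )


_TELESCOPE_ASM = topo.build_ssdna_scenario(seed=99)


class TestClassification:
    @pytest.mark.parametrize(
        "net,label",
        [(4, "forward"), (3.2, "forward"), (0, "idling"), (3, "idling"),
         (-3, "idling"), (-4, "backward")],
    )
    def test_thresholds(self, net, label):
        assert M.classify_outcome(net) == label

    @given(hst.integers(min_value=-40, max_value=40))
    @settings(max_examples=50, deadline=None)
    def test_partition_exhaustive_exclusive(self, n):
        assert M.classify_outcome(n) in {"forward", "idling", "backward"}

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            M.classify_outcome(float("nan"))


class TestAnchorIdentity:
    def test_persisting_subunit_wins(self, ss_assembly):
        """Across a 3->1 switch, only subunit 6's loop stays on its
        phosphate; the anchor is 6."""
        asm = ss_assembly
        frames = [asm.pos.copy() for _ in range(8)]
        loop3 = asm.ring.loop_bead[3]
        tp = asm.dna.tracked_phosphates
        # after the switch, park subunit-3's loop far from the strand
        for fr in frames[4:]:
            fr[loop3] = np.array([5.0, 5.0, 5.0])
        # keep subunit 6 exactly on a phosphate throughout
        loop6 = asm.ring.loop_bead[6]
        for fr in frames:
            fr[loop6] = asm.pos[tp[24]]
        traj = _traj_from_frames(asm, frames, events=[(450, 3, 1)])
        assert M.anchor_identity(traj, 0) == 6

    def test_shared_domain_of_1_to_2(self, short_ss_traj):
        anchor = M.anchor_identity(short_ss_traj, 0)  # the 1->2 switch
        assert anchor in {2, 3, 5, None}

    def test_no_persistent_contact_returns_none(self, ss_assembly):
        asm = ss_assembly
        frames = [asm.pos.copy() for _ in range(4)]
        for lab in (3, 6):
            for fr in frames:
                fr[asm.ring.loop_bead[lab]] = np.array([9.0, 9.0, 9.0])
        traj = _traj_from_frames(asm, frames, events=[(250, 3, 1)])
        assert M.anchor_identity(traj, 0) is None


class TestUnwinding:
    def test_assembly_frame_zero(self, fork_assembly):
        traj = _traj_from_frames(fork_assembly, [fork_assembly.pos] * 3)
        assert (M.count_unwound_bp(traj) == 0).all()

    def test_synthetic_melt_of_five_junction_bp(self, fork_assembly):
        asm = fork_assembly
        pos = asm.pos.copy()
        j = asm.dna.fork_junction_index
        table = asm.dna.pairing_table
        sel = np.where(
            (table.chain_i == "T") & (table.nt_i < j + 5)
            & (table.chain_j == "L")
        )[0]
        pos[asm.pair_j[sel]] += np.array([0.0, 6.0, 0.0])
        traj = _traj_from_frames(asm, [asm.pos, pos])
        counts = M.count_unwound_bp(traj)
        assert counts[0] == 0 and counts[1] == 5

    def test_distal_fraying_not_counted(self, fork_assembly):
        """A broken pair away from the junction does not count: unwinding
        is the contiguous run from the junction."""
        asm = fork_assembly
        pos = asm.pos.copy()
        table = asm.dna.pairing_table
        j = asm.dna.fork_junction_index
        sel = np.where(
            (table.chain_i == "T") & (table.nt_i == j + 10)
        )[0]
        pos[asm.pair_j[sel]] += np.array([0.0, 6.0, 0.0])
        traj = _traj_from_frames(asm, [asm.pos, pos])
        assert M.count_unwound_bp(traj)[1] == 0

    def test_reannealing_events_counted(self, fork_assembly):
        asm = fork_assembly
        melted = asm.pos.copy()
        table = asm.dna.pairing_table
        j = asm.dna.fork_junction_index
        sel = np.where((table.chain_i == "T") & (table.nt_i == j))[0]
        melted[asm.pair_j[sel]] += np.array([0.0, 6.0, 0.0])
        traj = _traj_from_frames(asm, [asm.pos, melted, asm.pos])
        _, events = M.count_unwound_bp(traj, return_events=True)
        assert events == 1


class TestClogging:
    def test_distant_lagging_strand_fraction_zero(self, fork_assembly,
                                                  params):
        asm = fork_assembly
        pos = asm.pos.copy()
        lag = np.where(asm.chain_code == asm.chain_ids.index("L"))[0]
        pos[lag] += np.array([30.0, 0.0, 0.0])
        traj = _traj_from_frames(asm, [pos] * 4)
        mind, frac = M.clogging_stats(traj)
        assert frac == 0.0
        assert (mind > params.clog_threshold).all()

    def test_planted_bead_inside_pore_clogs(self, fork_assembly, params):
        asm = fork_assembly
        pos = asm.pos.copy()
        lag = np.where(asm.chain_code == asm.chain_ids.index("L"))[0]
        pos[lag] += np.array([30.0, 0.0, 0.0])
        pore_bead = int(asm.ring.pore_bead_set[0])
        # plant one lagging bead at the 5-Angstrom equivalent from the pore
        pos[lag[0]] = asm.pos[pore_bead] + np.array(
            [0.5 * params.clog_threshold, 0, 0]
        )
        traj = _traj_from_frames(asm, [pos])
        _, frac = M.clogging_stats(traj)
        assert frac == 1.0


class TestUnwrap:
    def _break_sites(self, asm, shls_to_break):
        pos = asm.pos.copy()
        for shl in shls_to_break:
            k = int(np.where(asm.site_shl == shl)[0][0])
            pos[asm.site_dna[k]] += np.array([0.0, 0.0, 8.0])
        return pos

    def test_all_formed_sentinel(self, nuc_assembly):
        traj = _traj_from_frames(nuc_assembly, [nuc_assembly.pos])
        assert M.unwrap_extent(traj)[0] == M.FULLY_WRAPPED

    def test_contiguous_run_reports_innermost(self, nuc_assembly):
        pos = self._break_sites(nuc_assembly, [-6.5, -5.5, -4.5])
        traj = _traj_from_frames(nuc_assembly, [pos])
        assert M.unwrap_extent(traj)[0] == -4.5

    def test_inner_island_ignored(self, nuc_assembly):
        pos = self._break_sites(nuc_assembly, [-4.5])
        traj = _traj_from_frames(nuc_assembly, [pos])
        assert M.unwrap_extent(traj)[0] == M.FULLY_WRAPPED


class TestLaggingCapture:
    def test_patch_never_exposed_false(self, nuc_assembly):
        traj = _traj_from_frames(nuc_assembly, [nuc_assembly.pos] * 6)
        flag, frame = M.lagging_capture(traj)
        assert flag is False and frame is None

    def test_exposed_plus_contact_true(self, nuc_assembly, params):
        asm = nuc_assembly
        pos = asm.pos.copy()
        for shl in asm.nucleosome.exposure_rule:
            k = int(np.where(asm.site_shl == shl)[0][0])
            pos[asm.site_dna[k]] += np.array([0.0, 0.0, 8.0])
        lag = np.where(asm.chain_code == asm.chain_ids.index("L"))[0]
        patch = asm.nucleosome.h2ab_patch
        pos[lag[-1]] = asm.pos[patch[0]] + np.array(
            [0.5 * params.capture_radius, 0, 0]
        )
        traj = _traj_from_frames(asm, [pos] * 6)
        flag, frame = M.lagging_capture(traj, persistence_frames=3)
        assert flag is True and frame == 0

    def test_contact_without_exposure_false(self, nuc_assembly, params):
        asm = nuc_assembly
        pos = asm.pos.copy()
        lag = np.where(asm.chain_code == asm.chain_ids.index("L"))[0]
        patch = asm.nucleosome.h2ab_patch
        pos[lag[-1]] = asm.pos[patch[0]] + np.array(
            [0.5 * params.capture_radius, 0, 0]
        )
        traj = _traj_from_frames(asm, [pos] * 6)
        flag, _ = M.lagging_capture(traj, persistence_frames=3)
        assert flag is False


class TestContactProbability:
    def test_disjoint_static_groups_zero(self, ss_assembly):
        traj = _traj_from_frames(ss_assembly, [ss_assembly.pos] * 3)
        probs = M.contact_probability(traj, [0, 1], [200, 201], cutoff=0.2)
        assert (probs == 0).all()

    def test_permanent_contact_one(self, ss_assembly):
        asm = ss_assembly
        pos = asm.pos.copy()
        pos[1] = pos[200]
        traj = _traj_from_frames(asm, [pos] * 3)
        probs = M.contact_probability(traj, [0, 1], [200], cutoff=0.5)
        assert probs[1] == 1.0

    def test_empty_group_rejected(self, short_ss_traj):
        with pytest.raises(ValueError):
            M.contact_probability(short_ss_traj, [], [1])


class TestOccupancyDensity:
    def test_single_static_bead_one_voxel(self, ss_assembly):
        traj = _traj_from_frames(ss_assembly, [ss_assembly.pos] * 4)
        dens, edges = M.occupancy_density(traj, [5], grid_spacing=0.5)
        assert (dens > 0).sum() == 1

    def test_normalization(self, short_ss_traj, ss_assembly):
        beads = ss_assembly.dna.tracked_phosphates[:10]
        dens, _ = M.occupancy_density(short_ss_traj, beads,
                                      grid_spacing=0.5)
        assert dens.sum() * 0.5**3 == pytest.approx(1.0, abs=1e-6)

    def test_two_frame_hand_computed(self, ss_assembly):
        asm = ss_assembly
        a, b = asm.pos.copy(), asm.pos.copy()
        b[7] = a[7] + np.array([5.0, 0.0, 0.0])
        traj = _traj_from_frames(asm, [a, b])
        dens, _ = M.occupancy_density(traj, [7], grid_spacing=1.0)
        nonzero = np.sort(dens[dens > 0].ravel())
        assert np.allclose(nonzero, [0.5, 0.5])

    def test_empty_bead_set_rejected(self, short_ss_traj):
        with pytest.raises(ValueError):
            M.occupancy_density(short_ss_traj, [])


class TestCorrelationAndStats:
    def test_perfect_and_anti_coupling(self):
        pts = [(i, i) for i in range(5)]
        assert M.coupling_correlation(pts) == pytest.approx(1.0)
        pts = [(i, -i) for i in range(5)]
        assert M.coupling_correlation(pts) == pytest.approx(-1.0)

    def test_four_point_textbook_formula(self):
        xs = np.array([1.0, 2.0, 4.0, 7.0])
        ys = np.array([2.0, 1.0, 5.0, 6.0])
        r_hand = (
            np.sum((xs - xs.mean()) * (ys - ys.mean()))
            / math.sqrt(np.sum((xs - xs.mean()) ** 2)
                        * np.sum((ys - ys.mean()) ** 2))
        )
        assert M.coupling_correlation(list(zip(xs, ys))) == pytest.approx(
            r_hand
        )

    def test_zero_variance_flagged_nan(self):
        with pytest.warns(UserWarning, match="zero variance"):
            out = M.coupling_correlation([(1, 2), (1, 3), (1, 4)])
        assert math.isnan(out)

    def test_wmw_exact_disjoint_5v5(self):
        """Disjoint-support groups, n = 5 vs 5: the exact one-tailed
        p-value equals 1/C(10,5) = 1/252, verified against brute-force
        enumeration of all rank arrangements."""
        a = [10.0, 11.0, 12.0, 13.0, 14.0]
        b = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = M.compare_conditions(a, b)
        assert res["p_value"] == pytest.approx(1.0 / 252.0, rel=1e-12)
        # independent enumeration oracle: count arrangements with a rank
        # sum at least as extreme
        pooled = sorted(a + b)
        u_obs = sum(
            sum(1 for y in b if x > y) for x in a
        )
        count = 0
        total = 0
        for combo in itertools.combinations(range(10), 5):
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in range(10) if i not in combo]
            u = sum(sum(1 for y in ys if x > y) for x in xs)
            total += 1
            count += u >= u_obs
        assert res["p_value"] == pytest.approx(count / total, rel=1e-12)

    def test_identical_groups_d_zero(self):
        res = M.compare_conditions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["cohens_d"] == 0.0

    def test_constant_shift_d_one(self, rng):
        a = rng.normal(size=30)
        sd = np.std(a, ddof=1)
        res = M.compare_conditions(a + sd, a)
        assert res["cohens_d"] == pytest.approx(1.0, abs=1e-9)

    def test_all_tied_convention(self):
        res = M.compare_conditions([2.0] * 5, [2.0] * 5)
        assert res["p_value"] == 0.5
        assert res["cohens_d"] == 0.0
        assert res["flagged"]

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            M.compare_conditions([1.0], [2.0, 3.0, 4.0])


def test_metric_determinism(short_ss_traj):
    """Identical trajectory bytes give identical summaries."""
    s1 = M.summarize_run(short_ss_traj)
    s2 = M.summarize_run(short_ss_traj)
    assert np.array_equal(s1.displacement, s2.displacement)
    assert s1.net_displacement == s2.net_displacement
    assert s1.step_table.transitions.equals(s2.step_table.transitions)
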