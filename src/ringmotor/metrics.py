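"""Trajectory metrics: every quantity the analyses report.

Displacement convention: the tracked nucleotide is the one whose phosphate
is nearest the channel-frame site of subunit 3's pore loop (the loop's
engaged position in state 1).  The site is fixed in the ring frame because
the toy loop bead itself travels several nucleotides during a
conformational change, which would hide intra-cycle steps; displacement is
positive toward the 5' end (forward 3'->5' translocation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ringmotor.energetics import ForceFieldParams
from ringmotor.engine import Trajectory
from ringmotor.synthetic_topology import STATE_ENGAGED, STATE_HEIGHTS

__all__ = [
    "StepTable",
    "RunSummary",
    "tracked_displacement",
    "per_transition_steps",
    "classify_outcome",
    "anchor_identity",
    "count_unwound_bp",
    "clogging_stats",
    "unwrap_extent",
    "lagging_capture",
    "contact_probability",
    "occupancy_density",
    "coupling_correlation",
    "compare_conditions",
    "summarize_run",
    "FULLY_WRAPPED",
]

#: sentinel reported by :func:`unwrap_extent` for a fully wrapped
#: nucleosome ("wrapped beyond SHL(-6.5)")
FULLY_WRAPPED = -7.0


@dataclass
class StepTable:
    """Per-transition step sizes for one run.

    ``transitions`` has columns ``from_state, to_state, step_size`` (nt);
    the telescoping identity ``sum(step_size) == net_displacement`` holds
    exactly by construction (steps are differences of segment-tail means).
    """

    transitions: pd.DataFrame
    net_displacement: float
    outcome: str
    anchor_subunit: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = self.transitions.copy()
        df["net_displacement"] = self.net_displacement
        df["outcome"] = self.outcome
        return df


@dataclass
class RunSummary:
    """All metrics of one replicate."""

    step_table: StepTable
    displacement: np.ndarray
    unwound_bp: Optional[np.ndarray] = None
    reannealing_events: int = 0
    min_pore_distance: Optional[np.ndarray] = None
    clogged_fraction: Optional[float] = None
    unwrap_series: Optional[np.ndarray] = None
    lagging_capture_flag: Optional[bool] = None
    lagging_capture_frame: Optional[int] = None
    seed: int = 0

    @property
    def net_displacement(self) -> float:
        return self.step_table.net_displacement

    @property
    def outcome(self) -> str:
        return self.step_table.outcome

    @property
    def unwound_bp_final(self) -> Optional[float]:
        if self.unwound_bp is None:
            return None
        return float(self.unwound_bp[-1])

    def to_frame(self) -> pd.DataFrame:
        """Per-frame scalar table (CSV-ready)."""
        data = {"displacement_nt": self.displacement}
        if self.unwound_bp is not None:
            data["unwound_bp"] = self.unwound_bp
        if self.min_pore_distance is not None:
            data["min_pore_distance"] = self.min_pore_distance
        if self.unwrap_series is not None:
            data["unwrap_extent_shl"] = self.unwrap_series
        return pd.DataFrame(data)


# --------------------------------------------------------------------------
# displacement and steps


def _reference_site(assembly) -> np.ndarray:
    az = assembly.ring.azimuth[3]
    z = STATE_HEIGHTS[1][3] * assembly.ring.loop_rise_per_nt
    return np.array(
        [assembly.ring.loop_radius * math.cos(az),
         assembly.ring.loop_radius * math.sin(az), z]
    )


def tracked_displacement(
    traj: Trajectory,
    return_flags: bool = False,
    tie_tolerance: float = 0.3,
):
    """Per-frame displacement (nt) of the tracked strand through the motor.

    For each frame: the index of the nucleotide whose phosphate is nearest
    the subunit-3 reference site, minus the index at frame 0.  Ties within
    ``tie_tolerance`` are broken toward the previous frame's index
    (hysteresis suppresses chatter at half-integer crossings); frames
    where even the nearest phosphate lies far beyond the contact-capture
    radius carry the previous value forward and are flagged.
    """
    asm = traj.assembly
    params = traj.params or ForceFieldParams()
    ref = _reference_site(asm)
    tp = asm.dna.tracked_phosphates
    capture = params.capture_radius
    out = np.zeros(traj.n_frames, dtype=float)
    flags = np.zeros(traj.n_frames, dtype=bool)
    prev = None
    for k in range(traj.n_frames):
        d = np.linalg.norm(traj.frames[k][tp].astype(float) - ref, axis=1)
        j = int(np.argmin(d))
        if prev is not None:
            if d[prev] - d[j] < tie_tolerance:
                j = prev
            if d[j] > capture + 1.0:
                # reference site transiently unoccupied: carry forward
                j = prev
                flags[k] = True
        prev = j
        out[k] = asm.dna.tracked_nt_index[j]
    out -= out[0]
    if return_flags:
        return out, flags
    return out


def _segment_slices(traj: Trajectory):
    """Frame index ranges of the dwell segments between switch events."""
    bounds = [0]
    for step, _, _ in traj.switch_events:
        bounds.append(int(np.searchsorted(traj.frame_step, step, "right")))
    bounds.append(traj.n_frames)
    return [slice(bounds[k], bounds[k + 1]) for k in range(len(bounds) - 1)]


def _tail_mean(x: np.ndarray, frac: float) -> float:
    n = max(1, int(math.ceil(frac * len(x))))
    return float(np.mean(x[-n:]))


def per_transition_steps(traj: Trajectory, tail_frac: float = 0.1) -> StepTable:
    """Step sizes from segment-tail means.

    The step of transition k is the mean displacement over the last
    ``tail_frac`` of segment k+1 minus the same for segment k (the tail
    window suppresses post-switch relaxation transients).  Steps telescope
    to the net displacement exactly.
    """
    disp = tracked_displacement(traj)
    segs = _segment_slices(traj)
    if any((s.stop - s.start) < 2 for s in segs):
        raise ValueError("too few frames per segment for step analysis")
    tails = [_tail_mean(disp[s], tail_frac) for s in segs]
    rows = []
    for k, (step, frm, to) in enumerate(traj.switch_events):
        rows.append((frm, to, tails[k + 1] - tails[k]))
    if rows:
        table = pd.DataFrame(rows, columns=["from_state", "to_state",
                                            "step_size"])
        net = tails[-1] - tails[0]
    else:
        table = pd.DataFrame(columns=["from_state", "to_state", "step_size"])
        net = float(disp[-1])
    outcome = classify_outcome(net)
    anchors = {}
    for k, (_, frm, to) in enumerate(traj.switch_events):
        shared = STATE_ENGAGED.get(frm, set()) & STATE_ENGAGED.get(to, set())
        if len(shared) >= 1 and frm != to:
            anchors[(frm, to)] = anchor_identity(traj, k)
    return StepTable(
        transitions=table, net_displacement=net, outcome=outcome,
        anchor_subunit=anchors,
    )


def classify_outcome(net_displacement: float) -> str:
    """Forward if > +3 nt, backward if < -3 nt, idling in [-3, +3]."""
    if not np.isfinite(net_displacement):
        raise ValueError("net displacement must be finite")
    if net_displacement > 3:
        return "forward"
    if net_displacement < -3:
        return "backward"
    return "idling"


def anchor_identity(traj: Trajectory, transition_index: int):
    """The shared engaged subunit whose grip persisted longest across a
    switch (the anchor deciding forward vs backward at ambiguous
    transitions); ``None`` if no shared contact persists."""
    step, frm, to = traj.switch_events[transition_index]
    shared = STATE_ENGAGED.get(frm, set()) & STATE_ENGAGED.get(to, set())
    if not shared:
        return None
    asm = traj.assembly
    params = traj.params or ForceFieldParams()
    capture = params.capture_radius
    tp = asm.dna.tracked_phosphates
    k0 = max(0, int(np.searchsorted(traj.frame_step, step, "right")) - 1)
    best_lab, best_run = None, 0
    for lab in sorted(shared):
        lb = asm.ring.loop_bead[lab]
        d0 = np.linalg.norm(
            traj.frames[k0][tp].astype(float) - traj.frames[k0][lb], axis=1
        )
        j = int(np.argmin(d0))
        if d0[j] > capture:
            continue
        run = 0
        for k in range(k0 + 1, traj.n_frames):
            d = float(np.linalg.norm(
                traj.frames[k][tp[j]].astype(float) - traj.frames[k][lb]
            ))
            if d > capture:
                break
            run += 1
        if run > best_run:
            best_lab, best_run = lab, run
    return best_lab


# --------------------------------------------------------------------------
# fork metrics


def _parental_pairs(asm) -> np.ndarray:
    """Indices (into the pairing arrays) of junction-side base pairs."""
    table = asm.dna.pairing_table
    mask = (
        (table.chain_i == asm.dna.tracked_strand) & (table.chain_j == "L")
    ).to_numpy()
    return np.where(mask)[0]


def count_unwound_bp(traj: Trajectory, return_events: bool = False):
    """Per-frame count of initially-formed parental base pairs currently
    broken, plus the number of reannealing events (formed -> broken ->
    formed on the same pair)."""
    asm = traj.assembly
    params = traj.params or ForceFieldParams()
    sel = _parental_pairs(asm)
    pi = asm.pair_i[sel]
    pj = asm.pair_j[sel]
    order = np.argsort(asm.dna.pairing_table.nt_i.to_numpy()[sel])
    pi, pj = pi[order], pj[order]
    d = np.linalg.norm(
        traj.frames[:, pi, :].astype(float) - traj.frames[:, pj, :], axis=2
    )
    broken = d > params.r_break
    init_formed = ~broken[0]
    # unwound = maximal contiguous broken run starting at the junction
    # (transient fraying of the distal duplex end is not unwinding)
    counts = np.zeros(traj.n_frames)
    for k in range(traj.n_frames):
        c = 0
        for m in range(broken.shape[1]):
            if not init_formed[m]:
                continue
            if broken[k, m]:
                c += 1
            else:
                break
        counts[k] = c
    b = broken[:, init_formed]
    reanneal = int(np.sum(b[:-1] & ~b[1:]))
    if return_events:
        return counts, reanneal
    return counts


def clogging_stats(
    traj: Trajectory,
    pore_bead_set: Optional[np.ndarray] = None,
    threshold: Optional[float] = None,
):
    """Minimum lagging-strand-to-pore distance per frame and the clogged
    fraction (fraction of frames below the 10-Angstrom-equivalent
    threshold)."""
    asm = traj.assembly
    params = traj.params or ForceFieldParams()
    if pore_bead_set is None:
        pore_bead_set = asm.ring.pore_bead_set
    if threshold is None:
        threshold = params.clog_threshold
    lag_chain = asm.chain_ids.index("L")
    lag = np.where(asm.chain_code == lag_chain)[0]
    mind = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        fr = traj.frames[k].astype(float)
        d = np.linalg.norm(
            fr[lag][:, None, :] - fr[pore_bead_set][None, :, :], axis=2
        )
        mind[k] = d.min()
    return mind, float(np.mean(mind < threshold))


# --------------------------------------------------------------------------
# nucleosome metrics


def _site_formed(traj: Trajectory) -> np.ndarray:
    asm = traj.assembly
    params = traj.params or ForceFieldParams()
    d = np.linalg.norm(
        traj.frames[:, asm.site_anchor, :].astype(float)
        - traj.frames[:, asm.site_dna, :], axis=2
    )
    return np.abs(d - asm.site_r0[None, :]) <= 6.0 * params.sigma_site


def unwrap_extent(traj: Trajectory) -> np.ndarray:
    """Per-frame unwrapping extent (SHL label).

    The innermost entry-side contact site in the maximal contiguous
    detached run starting from SHL(-6.5); a fully wrapped nucleosome is
    reported as the sentinel ``FULLY_WRAPPED`` (-7.0).  Detached islands
    not connected to the entry end are ignored.
    """
    asm = traj.assembly
    if asm.nucleosome is None:
        raise ValueError("not a nucleosome scenario")
    order = np.argsort(asm.site_shl)
    shls = asm.site_shl[order]
    formed = _site_formed(traj)[:, order]
    out = np.full(traj.n_frames, FULLY_WRAPPED)
    for k in range(traj.n_frames):
        extent = FULLY_WRAPPED
        for m in range(len(shls)):
            if formed[k, m]:
                break
            extent = shls[m]
        out[k] = extent
    return out


def lagging_capture(
    traj: Trajectory,
    capture_cutoff: Optional[float] = None,
    persistence_frames: int = 5,
):
    """Whether the lagging strand binds the exposed histone-dimer surface.

    True iff the exposure rule holds (all entry-side sites named in the
    rule detached) while the minimum lagging-strand distance to the
    surface patch stays below the capture cutoff for at least
    ``persistence_frames`` consecutive frames.  Returns ``(flag,
    first-contact frame or None)``.
    """
    asm = traj.assembly
    nuc = asm.nucleosome
    if nuc is None:
        raise ValueError("not a nucleosome scenario")
    params = traj.params or ForceFieldParams()
    if capture_cutoff is None:
        capture_cutoff = params.capture_radius
    rule = set(nuc.exposure_rule)
    order = np.argsort(asm.site_shl)
    shls = asm.site_shl[order]
    formed = _site_formed(traj)[:, order]
    rule_idx = [m for m in range(len(shls)) if shls[m] in rule]
    lag_chain = asm.chain_ids.index("L")
    lag = np.where(asm.chain_code == lag_chain)[0]
    patch = nuc.h2ab_patch
    if len(patch) == 0:
        return False, None
    run = 0
    for k in range(traj.n_frames):
        exposed = not formed[k, rule_idx].any() if rule_idx else False
        fr = traj.frames[k].astype(float)
        d = np.linalg.norm(
            fr[lag][:, None, :] - fr[patch][None, :, :], axis=2
        ).min()
        if exposed and d < capture_cutoff:
            run += 1
            if run >= persistence_frames:
                return True, k - persistence_frames + 1
        else:
            run = 0
    return False, None


# --------------------------------------------------------------------------
# generic metrics


def contact_probability(
    traj: Trajectory,
    query_beads: Sequence[int],
    target_beads: Sequence[int],
    cutoff: Optional[float] = None,
) -> np.ndarray:
    """Per-query-bead fraction of frames with min distance to the target
    set below the cutoff (defaults to the contact-capture radius)."""
    q = np.asarray(query_beads, dtype=int)
    t = np.asarray(target_beads, dtype=int)
    if len(q) == 0 or len(t) == 0:
        raise ValueError("bead groups must be nonempty")
    params = traj.params or ForceFieldParams()
    if cutoff is None:
        cutoff = params.capture_radius
    hits = np.zeros(len(q))
    for k in range(traj.n_frames):
        fr = traj.frames[k].astype(float)
        d = np.linalg.norm(fr[q][:, None, :] - fr[t][None, :, :], axis=2)
        hits += d.min(axis=1) < cutoff
    return hits / traj.n_frames


def occupancy_density(
    traj: Trajectory,
    bead_set: Sequence[int],
    grid_spacing: float = 0.5,
):
    """Normalized 3-D density of bead positions on a regular grid.

    Returns ``(density, edges)``; the density integrates to 1
    (``sum * voxel_volume == 1``).  Frames are used in the lab frame,
    which is the nucleosome-core frame because cores are
    position-restrained.
    """
    beads = np.asarray(bead_set, dtype=int)
    if len(beads) == 0:
        raise ValueError("empty bead set")
    pts = traj.frames[:, beads, :].astype(float).reshape(-1, 3)
    lo = pts.min(axis=0) - grid_spacing
    hi = pts.max(axis=0) + grid_spacing
    nbins = [max(1, int(math.ceil((hi[d] - lo[d]) / grid_spacing)))
             for d in range(3)]
    hist, edges = np.histogramdd(
        pts, bins=nbins,
        range=[(lo[d], lo[d] + nbins[d] * grid_spacing) for d in range(3)],
    )
    vol = grid_spacing**3
    total = hist.sum()
    if total == 0:
        raise ValueError("no samples in grid")
    return hist / (total * vol), edges


def coupling_correlation(run_summaries: Sequence) -> float:
    """Pearson correlation of (net displacement, final unwound bp) across
    runs.  Accepts RunSummary objects or (net, unwound) pairs."""
    xs, ys = [], []
    for r in run_summaries:
        if isinstance(r, RunSummary):
            xs.append(r.net_displacement)
            ys.append(r.unwound_bp_final)
        else:
            xs.append(r[0])
            ys.append(r[1])
    if len(xs) < 3:
        raise ValueError("need at least 3 runs")
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    if xs.std() == 0 or ys.std() == 0:
        import warnings

        warnings.warn("zero variance: correlation undefined")
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])


def compare_conditions(values_a, values_b) -> dict:
    """One-tailed Wilcoxon-Mann-Whitney test (H1: a > b) plus Cohen's d.

    Exact-permutation p-value for group sizes <= 10 without ties; normal
    approximation with tie correction otherwise.  All-tied input returns
    the p = 0.5 convention with d = 0 (flagged).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need n >= 3 per group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return {"p_value": 0.5, "cohens_d": 0.0,
                "statistic": len(a) * len(b) / 2, "flagged": True}
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = (
        "exact" if (len(a) <= 10 and len(b) <= 10 and not has_ties)
        else "asymptotic"
    )
    res = sps.mannwhitneyu(a, b, alternative="greater", method=method)
    sd_p = math.sqrt(
        ((len(a) - 1) * a.std(ddof=1) ** 2
         + (len(b) - 1) * b.std(ddof=1) ** 2)
        / (len(a) + len(b) - 2)
    )
    d = 0.0 if sd_p == 0 else float((a.mean() - b.mean()) / sd_p)
    return {"p_value": float(res.pvalue), "cohens_d": d,
            "statistic": float(res.statistic), "flagged": False}


# --------------------------------------------------------------------------


def summarize_run(traj: Trajectory, seed: int = 0) -> RunSummary:
    """Compute every metric applicable to the trajectory's scenario."""
    disp = tracked_displacement(traj)
    if traj.switch_events:
        table = per_transition_steps(traj)
    else:
        net = float(disp[-1])
        table = StepTable(
            transitions=pd.DataFrame(
                columns=["from_state", "to_state", "step_size"]
            ),
            net_displacement=net,
            outcome=classify_outcome(net),
        )
    summary = RunSummary(step_table=table, displacement=disp, seed=seed)
    asm = traj.assembly
    if asm.scenario.kind in ("fork", "nucleosome"):
        counts, reanneal = count_unwound_bp(traj, return_events=True)
        summary.unwound_bp = counts
        summary.reannealing_events = reanneal
        mind, frac = clogging_stats(traj)
        summary.min_pore_distance = mind
        summary.clogged_fraction = frac
    if asm.nucleosome is not None:
        summary.unwrap_series = unwrap_extent(traj)
        flag, frame = lagging_capture(traj)
        summary.lagging_capture_flag = flag
        summary.lagging_capture_frame = frame
    return summary
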