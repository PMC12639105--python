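"""Named, seeded scenario registry with replicate aggregation.

Each experiment reproduces one of the study's computational conditions at
toy scale: single-stranded translocation under the 3-state, 4-state,
reversed, two-state, and conformation-only switching schemes; Y-fork
unwinding under three sequence compositions with accessory-factor
combinations; and nucleosome collisions from four start positions with and
without the histone chaperone.  Replicate ``i`` of an experiment uses seed
``seed0 + i``; everything downstream is deterministic given the spec.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from ringmotor import metrics as M
from ringmotor import synthetic_topology as topo
from ringmotor.energetics import ForceFieldParams
from ringmotor.engine import SwitchProtocol, run_protocol

__all__ = [
    "ExperimentSpec",
    "ExperimentResult",
    "registry",
    "get_experiment",
    "run_experiment",
    "compare_experiments",
]

#: default replicate count (independent seeded runs per condition)
N_REPLICATES = 20

#: seed spacing between experiments so replicate streams never overlap
SEED_STRIDE = 1000


@dataclass
class ExperimentSpec:
    """One named, seeded computational experiment."""

    name: str
    scenario_kind: str  # "ssdna" | "fork" | "nucleosome"
    protocol: SwitchProtocol
    n_replicates: int = N_REPLICATES
    seed0: int = 0
    scenario_kwargs: dict = field(default_factory=dict)
    factors: tuple = ()
    fpc_electrostatics_on: bool = True
    toy_scale: bool = True

    def build_assembly(self, seed: int):
        if self.scenario_kind == "ssdna":
            return topo.build_ssdna_scenario(seed=seed, **self.scenario_kwargs)
        if self.scenario_kind == "fork":
            asm = topo.build_fork_scenario(seed=seed, **self.scenario_kwargs)
            if self.factors:
                fs = topo.make_factors(
                    asm, self.factors,
                    fpc_electrostatics_on=self.fpc_electrostatics_on,
                    seed=seed,
                )
                asm = topo.place_factors(asm, fs)
            return asm
        if self.scenario_kind == "nucleosome":
            return topo.build_nucleosome_scenario(
                seed=seed, factors=self.factors,
                fpc_electrostatics_on=self.fpc_electrostatics_on,
                **self.scenario_kwargs,
            )
        raise ValueError(f"unknown scenario kind {self.scenario_kind!r}")


@dataclass
class ExperimentResult:
    """Replicate summaries plus the aggregate table."""

    spec: ExperimentSpec
    summaries: list  # RunSummary per replicate (None for failures)
    failures: list  # [(seed, message)]

    @property
    def complete(self) -> bool:
        return not self.failures

    def _ok(self):
        return [s for s in self.summaries if s is not None]

    def net_displacements(self) -> np.ndarray:
        return np.asarray([s.net_displacement for s in self._ok()])

    def outcome_counts(self) -> dict:
        out = {"forward": 0, "idling": 0, "backward": 0}
        for s in self._ok():
            out[s.outcome] += 1
        return out

    def step_table(self) -> pd.DataFrame:
        """Per-replicate per-transition steps (long format)."""
        rows = []
        for s in self._ok():
            df = s.step_table.transitions.copy()
            df["seed"] = s.seed
            df["outcome"] = s.outcome
            rows.append(df)
        if not rows:
            return pd.DataFrame(
                columns=["from_state", "to_state", "step_size", "seed",
                         "outcome"]
            )
        return pd.concat(rows, ignore_index=True)

    def mean_steps(self, outcome: Optional[str] = None) -> pd.DataFrame:
        df = self.step_table()
        if outcome is not None:
            df = df[df.outcome == outcome]
        if df.empty:
            return df
        return (
            df.groupby(["from_state", "to_state"], sort=False)
            .step_size.agg(["mean", "std", "count"])
            .reset_index()
        )

    def aggregate(self) -> dict:
        """Headline aggregate (JSON-ready)."""
        nets = self.net_displacements()
        counts = self.outcome_counts()
        agg = {
            "experiment": self.spec.name,
            "n_replicates": self.spec.n_replicates,
            "n_completed": len(self._ok()),
            "net_mean": float(nets.mean()) if len(nets) else float("nan"),
            "net_std": float(nets.std(ddof=1)) if len(nets) > 1 else 0.0,
            "counts": counts,
        }
        unwound = [
            s.unwound_bp_final for s in self._ok()
            if s.unwound_bp_final is not None
        ]
        if unwound:
            agg["unwound_bp_mean"] = float(np.mean(unwound))
        clogged = [
            s.clogged_fraction for s in self._ok()
            if s.clogged_fraction is not None
        ]
        if clogged:
            agg["clogged_fraction_mean"] = float(np.mean(clogged))
        captures = [
            s.lagging_capture_flag for s in self._ok()
            if s.lagging_capture_flag is not None
        ]
        if captures:
            agg["lagging_capture_count"] = int(sum(captures))
        return agg


# --------------------------------------------------------------------------
# registry


def _specs() -> list:
    fwd3 = (1, 2, 3)
    fwd4 = (1, 2, 3, 4)
    specs = [
        ExperimentSpec("ss_3state", "ssdna", SwitchProtocol(sequence=fwd3)),
        ExperimentSpec("ss_4state", "ssdna", SwitchProtocol(sequence=fwd4)),
        ExperimentSpec(
            "ss_reversed", "ssdna", SwitchProtocol(sequence=(1, 3, 2))
        ),
        ExperimentSpec(
            "ss_control_conformation_only", "ssdna",
            SwitchProtocol(sequence=fwd3, mode="conformation_only"),
        ),
        ExperimentSpec("ss_no_switch", "ssdna", SwitchProtocol(sequence=(1,))),
    ]
    # two-state scan: all 6 unordered pairs among states 1-4
    for a, b in itertools.combinations((1, 2, 3, 4), 2):
        specs.append(
            ExperimentSpec(
                f"ss_two_state_{a}{b}", "ssdna",
                SwitchProtocol(sequence=(a, b), n_cycles=2),
            )
        )
    # fork experiments
    for mode in ("random", "polyAT", "polyGC"):
        specs.append(
            ExperimentSpec(
                f"fork_{mode}", "fork", SwitchProtocol(sequence=fwd4),
                scenario_kwargs={"sequence_mode": mode},
            )
        )
    for combo, factors in (
        ("rpa", ("rpa",)),
        ("fpc_ctf4", ("fpc", "ctf4", "mrc1")),
        ("rpa_fpc_ctf4", ("rpa", "fpc", "ctf4", "mrc1")),
    ):
        for mode in ("polyAT", "polyGC"):
            specs.append(
                ExperimentSpec(
                    f"fork_{mode}_{combo}", "fork",
                    SwitchProtocol(sequence=fwd4),
                    scenario_kwargs={"sequence_mode": mode},
                    factors=factors,
                )
            )
    specs.append(
        ExperimentSpec(
            "fork_polyGC_rpa_fpc_ctf4_noelec", "fork",
            SwitchProtocol(sequence=fwd4),
            scenario_kwargs={"sequence_mode": "polyGC"},
            factors=("rpa", "fpc", "ctf4", "mrc1"),
            fpc_electrostatics_on=False,
        )
    )
    specs.append(
        ExperimentSpec(
            "fork_polyGC_lagging_duplex", "fork",
            SwitchProtocol(sequence=fwd4),
            scenario_kwargs={
                "sequence_mode": "polyGC",
                "lagging_arm_mode": "duplex-occluded",
            },
        )
    )
    # nucleosome experiments: start positions named by the target SHL
    for shl in (7, 5, 4, 3):
        specs.append(
            ExperimentSpec(
                f"nuc_shl{shl}_fpc_rpa", "nucleosome",
                SwitchProtocol(sequence=fwd4),
                scenario_kwargs={"shl_start": -float(shl)},
                factors=("rpa", "fpc", "ctf4", "mrc1"),
            )
        )
        specs.append(
            ExperimentSpec(
                f"nuc_shl{shl}_fact", "nucleosome",
                SwitchProtocol(sequence=fwd4),
                scenario_kwargs={"shl_start": -float(shl)},
                factors=("rpa", "fpc", "ctf4", "mrc1", "fact"),
            )
        )
    specs.append(
        ExperimentSpec(
            "nuc_shl7_noelec", "nucleosome",
            SwitchProtocol(sequence=fwd4),
            scenario_kwargs={"shl_start": -7.0},
            factors=("rpa", "fpc", "ctf4", "mrc1"),
            fpc_electrostatics_on=False,
        )
    )
    # seed policy: non-overlapping replicate streams per experiment
    for idx, spec in enumerate(specs):
        spec.seed0 = SEED_STRIDE * idx
    return specs


def registry() -> list:
    """All named experiments (fresh spec objects)."""
    return _specs()


def get_experiment(name: str) -> ExperimentSpec:
    for spec in _specs():
        if spec.name == name:
            return spec
    known = ", ".join(s.name for s in _specs())
    raise KeyError(f"unknown experiment {name!r}; known: {known}")


# --------------------------------------------------------------------------
# running


def run_experiment(
    spec: ExperimentSpec,
    params: Optional[ForceFieldParams] = None,
    subsample: int = 100,
    keep_trajectories: bool = False,
    progress: Optional[Callable[[int, int], None]] = None,
) -> ExperimentResult:
    """Run all replicates of an experiment and aggregate.

    Replicate ``i`` uses seed ``spec.seed0 + i``.  A replicate failure is
    recorded (not fatal) and the result is flagged incomplete.
    """
    params = params or ForceFieldParams()
    summaries, failures = [], []
    trajectories = []
    for i in range(spec.n_replicates):
        seed = spec.seed0 + i
        try:
            asm = spec.build_assembly(seed)
            traj = run_protocol(
                asm, spec.protocol, seed=seed, params=params,
                subsample=subsample,
            )
            summaries.append(M.summarize_run(traj, seed=seed))
            if keep_trajectories:
                trajectories.append(traj)
        except Exception as exc:  # noqa: BLE001 - record, don't abort
            summaries.append(None)
            failures.append((seed, str(exc)))
        if progress is not None:
            progress(i + 1, spec.n_replicates)
    result = ExperimentResult(spec=spec, summaries=summaries,
                              failures=failures)
    if keep_trajectories:
        result.trajectories = trajectories  # type: ignore[attr-defined]
    return result


def compare_experiments(
    result_a: ExperimentResult,
    result_b: ExperimentResult,
    metric_key: str = "net_displacement",
) -> dict:
    """One-tailed Wilcoxon-Mann-Whitney comparison of a per-replicate
    metric between two conditions (H1: a > b), with Cohen's d."""

    def values(res):
        vals = []
        for s in res._ok():
            v = getattr(s, metric_key, None)
            if v is None:
                raise ValueError(
                    f"metric {metric_key!r} undefined for {res.spec.name}"
                )
            vals.append(float(v))
        return vals

    va, vb = values(result_a), values(result_b)
    if len(va) != len(vb):
        raise ValueError("mismatched replicate structure")
    stats = M.compare_conditions(va, vb)
    stats.update(
        {
            "experiment_a": result_a.spec.name,
            "experiment_b": result_b.spec.name,
            "metric": metric_key,
            "direction": "a_greater",
            "mean_a": float(np.mean(va)),
            "mean_b": float(np.mean(vb)),
        }
    )
    return stats
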