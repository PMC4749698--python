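"""Metabolic-demand summaries of circuit activity per cortical region.

The attentional hierarchy is read as three cortical "regions" laid out
posterior to anterior: F0, F1 (including its gain node G1) and F2
(including G2).  Two proxies for metabolic demand / blood flow are
computed per region: the space-time average of supra-threshold output, and
the space-time average of the absolute membrane potential.  No hemodynamic
convolution is applied — the proxy is exactly the stated average.

Four task conditions:

- *passive perception*: a hue drives F0, but extra drive onto G1 suppresses
  the F1 output pathway, so nothing is classified; F0 and the F1 region
  (via G1 itself) light up while F2 stays silent.
- *active perception*: the hue is classified; all three regions engage.
- *passive cognition*: word-driven expectation reaches F2 through the
  associative map while G1's drive is suppressed; only the F2 region (the
  weakly primed categories plus the tonically active G2) lights up.
- *active cognition*: the same expectation with normal gain operation; G1
  is driven by the primed categories, so F1 and F2 regions light up and
  the F2 activity spreads over the full associative fan-out.

Contrasting the passive pair yields disjoint activation (the anterior
shift); the active pair overlaps in F1 and F2 (the overlap effect).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .dynamics import TraceRecorder
from .system import ModelSystem

__all__ = [
    "REGIONS",
    "METRICS",
    "TaskCondition",
    "MetabolicSummary",
    "run_condition",
    "activation_pattern",
    "contrast",
    "run_battery",
    "battery_floors",
]

REGIONS = ("F0", "F1", "F2")
METRICS = ("supra_output_mean", "abs_potential_mean")

#: Fraction of the trailing window used to count settled F2 spread.
_SPREAD_TAIL = 0.25


@dataclass(frozen=True)
class TaskCondition:
    """One cell of the engagement x mode design."""

    mode: str  # "perception" | "cognition"
    engagement: str  # "passive" | "active"
    color: str = "red"

    def __post_init__(self) -> None:
        if self.mode not in ("perception", "cognition"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.engagement not in ("passive", "active"):
            raise ValueError(f"unknown engagement {self.engagement!r}")

    @property
    def label(self) -> str:
        return f"{self.engagement}_{self.mode}"


@dataclass
class MetabolicSummary:
    """Per-region values of both metabolic metrics for one condition."""

    condition: TaskCondition
    supra_output_mean: Dict[str, float]
    abs_potential_mean: Dict[str, float]
    f2_spread: int = 0

    def metric(self, name: str) -> Dict[str, float]:
        if name not in METRICS:
            raise ValueError(f"unknown metric {name!r}")
        return getattr(self, name)


_REGION_LAYERS = {
    # G1 is counted with the F1 region, G2 with the F2 region.
    "F0": ("f0",),
    "F1": ("f1", "g1"),
    "F2": ("f2", "g2"),
}


def _region_means(trace, module: str) -> Dict[str, Dict[str, float]]:
    supra: Dict[str, float] = {}
    absv: Dict[str, float] = {}
    for region, layers in _REGION_LAYERS.items():
        out_sum = pot_sum = 0.0
        n_nodes = 0
        for layer in layers:
            out = trace.outputs[(module, layer)]
            pot = trace.potentials[(module, layer)]
            out_sum += out.sum()
            pot_sum += np.abs(pot).sum()
            n_nodes += out.shape[1]
        n_samples = trace.times.size * n_nodes
        supra[region] = float(out_sum / n_samples)
        absv[region] = float(pot_sum / n_samples)
    return {"supra_output_mean": supra, "abs_potential_mean": absv}


def run_condition(
    cond: TaskCondition,
    system: ModelSystem,
    duration: Optional[float] = None,
) -> MetabolicSummary:
    """Simulate one condition and summarize both metrics per region."""
    cfg = system.config
    duration = duration if duration is not None else cfg.timing.fmri_duration
    dt = cfg.timing.dt
    mod = system.color
    mod.reset_state()
    mod.register_input(np.array([]))
    mod.set_priming(np.array([]))
    mod.g1_drive_scale, mod.g1_extra_drive, mod.g2_drive_scale = 1.0, 0.0, 1.0

    if cond.mode == "perception":
        mod.register_input(system.hue_pattern(cond.color).activations)
        if cond.engagement == "passive":
            # extra drive onto the gain node blocks the F1 output pathway,
            # suppressing classification while G1 itself stays active
            mod.g1_extra_drive = cfg.fmri.passive_g1_extra
    else:
        mod.set_priming(system.priming_from_word(cond.color))
        if cond.engagement == "passive":
            mod.g1_drive_scale = 0.0  # silences the F1 region

    rec = TraceRecorder()
    mod.run(duration, dt, recorder=rec)
    trace = rec.build()
    mod.g1_drive_scale, mod.g1_extra_drive, mod.g2_drive_scale = 1.0, 0.0, 1.0
    mod.reset_state()
    mod.register_input(np.array([]))
    mod.set_priming(np.array([]))

    means = _region_means(trace, mod.name)
    tail = trace.window(duration * (1.0 - _SPREAD_TAIL), duration)
    f2_out = tail.outputs[(mod.name, "f2")]
    spread = int(np.sum(f2_out.mean(axis=0) > 0.0))
    return MetabolicSummary(
        condition=cond,
        supra_output_mean=means["supra_output_mean"],
        abs_potential_mean=means["abs_potential_mean"],
        f2_spread=spread,
    )


def activation_pattern(
    summary: MetabolicSummary, floor: Dict[str, float]
) -> Dict[str, Dict[str, bool]]:
    """Boolean activation per region, computed separately for each metric.

    ``floor`` maps metric name -> activation floor (> 0).
    """
    result = {}
    for metric in METRICS:
        f = floor[metric]
        if not f > 0:
            raise ValueError("activation floor must be positive")
        result[metric] = {
            region: summary.metric(metric)[region] > f for region in REGIONS
        }
    return result


def battery_floors(
    summaries: Dict[str, MetabolicSummary], fraction: float = 0.05
) -> Dict[str, float]:
    """Per-metric floor: ``fraction`` of the maximum region value across
    all supplied conditions."""
    return {
        metric: fraction
        * max(s.metric(metric)[r] for s in summaries.values() for r in REGIONS)
        for metric in METRICS
    }


@dataclass
class ContrastReport:
    engagement: str
    overlap: tuple
    perception_only: tuple
    cognition_only: tuple
    f2_spread: Dict[str, int] = field(default_factory=dict)


def contrast(
    perception: MetabolicSummary,
    cognition: MetabolicSummary,
    floor: Dict[str, float],
) -> ContrastReport:
    """Overlap / disjointness of perception vs. cognition activation.

    Both summaries must come from the same engagement level.  The report
    uses the activation maps of both metrics (which must agree) and counts
    the settled F2 spread of each condition.
    """
    if perception.condition.engagement != cognition.condition.engagement:
        raise ValueError("contrast requires summaries at one engagement level")
    maps_p = activation_pattern(perception, floor)
    maps_c = activation_pattern(cognition, floor)
    for maps in (maps_p, maps_c):
        if maps["supra_output_mean"] != maps["abs_potential_mean"]:
            raise RuntimeError(
                "metabolic metrics disagree on the activation pattern"
            )
    act_p = {r for r in REGIONS if maps_p["supra_output_mean"][r]}
    act_c = {r for r in REGIONS if maps_c["supra_output_mean"][r]}
    order = {r: i for i, r in enumerate(REGIONS)}
    return ContrastReport(
        engagement=perception.condition.engagement,
        overlap=tuple(sorted(act_p & act_c, key=order.get)),
        perception_only=tuple(sorted(act_p - act_c, key=order.get)),
        cognition_only=tuple(sorted(act_c - act_p, key=order.get)),
        f2_spread={
            "perception": perception.f2_spread,
            "cognition": cognition.f2_spread,
        },
    )


def run_battery(
    system: ModelSystem, duration: Optional[float] = None
) -> Dict[str, MetabolicSummary]:
    """All four engagement x mode conditions."""
    out = {}
    for engagement in ("passive", "active"):
        for mode in ("perception", "cognition"):
            cond = TaskCondition(mode=mode, engagement=engagement)
            out[cond.label] = run_condition(cond, system, duration)
    return out
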