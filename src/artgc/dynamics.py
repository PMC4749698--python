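"""Shunting (membrane-style) node layers and explicit-Euler network integration.

Every node in the model obeys the same bounded additive-shunting equation

    tau * dx/dt = -A*x + (B - x)*E - (x - D)*I

where ``E`` and ``I`` are non-negative excitatory and inhibitory drives,
``A`` is a passive decay rate and ``B``/``D`` are the upper/lower saturation
bounds.  Multiplicative gating by ``(B - x)`` and ``(x - D)`` keeps every
potential inside ``[D, B]`` for any admissible drive, which is what makes
the circuit's winner-take-all and matching stages well behaved without any
explicit clipping.

Layers communicate through *thresholded output signals*, never through raw
potentials.  Three signal families are supported: threshold-linear
(rectification), faster-than-linear (squared rectification, used by
recurrent competitive fields to sharpen winners) and a rectified steep
sigmoid ("step") used by gating nodes.

Integration is synchronous explicit Euler: every layer reads the previous
step's outputs, so results do not depend on the order in which layers are
declared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ShuntingParams",
    "LayerState",
    "SimulationTrace",
    "TraceRecorder",
    "output_signal",
    "shunting_step",
    "layer_sum",
    "Layer",
    "Network",
    "ScheduleEvent",
    "integrate",
    "DivergenceError",
]

SIGNAL_KINDS = ("threshold-linear", "faster-than-linear", "step")

#: Half-width of the rectified sigmoid used by the "step" signal family.
STEP_STEEPNESS = 0.02

#: How far a potential may leave [lower_bound, upper_bound] before the
#: integrator treats the run as numerically divergent.
DIVERGENCE_TOL = 1e-6


class DivergenceError(RuntimeError):
    """Raised when a potential leaves its shunting bounds during integration."""


@dataclass(frozen=True)
class ShuntingParams:
    """Constants of one layer's membrane equation.

    Parameters
    ----------
    decay_rate:
        Passive decay ``A`` (1/time). Must be positive.
    upper_bound:
        Excitatory saturation ``B`` (> 0).
    lower_bound:
        Hyperpolarization floor ``D`` (<= 0). A strictly negative floor
        makes inhibition effectively subtractive near rest, which the
        matching layer uses to cancel top-down excitation exactly.
    output_threshold:
        Signal threshold; outputs are exactly zero at and below it.
    time_constant:
        Membrane time constant ``tau`` (> 0).
    """

    decay_rate: float = 1.0
    upper_bound: float = 1.0
    lower_bound: float = 0.0
    output_threshold: float = 0.0
    time_constant: float = 1.0

    def __post_init__(self) -> None:
        if not self.decay_rate > 0:
            raise ValueError(f"decay_rate must be > 0, got {self.decay_rate}")
        if not self.upper_bound > 0:
            raise ValueError(f"upper_bound must be > 0, got {self.upper_bound}")
        if self.lower_bound > 0:
            raise ValueError(f"lower_bound must be <= 0, got {self.lower_bound}")
        if not self.time_constant > 0:
            raise ValueError(
                f"time_constant must be > 0, got {self.time_constant}"
            )


@dataclass
class LayerState:
    """Membrane potentials and thresholded outputs of one layer at one instant."""

    potentials: np.ndarray
    outputs: np.ndarray

    @classmethod
    def zeros(cls, size: int) -> "LayerState":
        return cls(np.zeros(size), np.zeros(size))

    @property
    def size(self) -> int:
        return self.potentials.shape[0]

    def copy(self) -> "LayerState":
        return LayerState(self.potentials.copy(), self.outputs.copy())


def output_signal(
    potential,
    params: ShuntingParams,
    kind: str = "threshold-linear",
    gain: float = 1.0,
):
    """Map membrane potential(s) to a non-negative output signal.

    All families are non-decreasing in the potential and are exactly zero at
    and below ``params.output_threshold``.

    - ``threshold-linear``: ``gain * max(x - theta, 0)``
    - ``faster-than-linear``: ``gain * max(x - theta, 0)**2`` (sharpens
      recurrent competition into a choice)
    - ``step``: rectified steep sigmoid saturating at ``gain``
    """
    x = np.asarray(potential, dtype=float)
    above = np.maximum(x - params.output_threshold, 0.0)
    if kind == "threshold-linear":
        out = gain * above
    elif kind == "faster-than-linear":
        out = gain * above * above
    elif kind == "step":
        out = gain * np.maximum(2.0 / (1.0 + np.exp(-above / STEP_STEEPNESS)) - 1.0, 0.0)
    else:
        raise ValueError(
            f"unknown signal kind {kind!r}; expected one of {SIGNAL_KINDS}"
        )
    if np.ndim(potential) == 0:
        return float(out)
    return out


def shunting_step(
    state: LayerState,
    excitation: np.ndarray,
    inhibition: np.ndarray,
    params: ShuntingParams,
    dt: float,
    signal_kind: str = "threshold-linear",
    signal_gain: float = 1.0,
) -> LayerState:
    """One explicit-Euler update of a shunting layer.

    The update is contractive toward ``[lower_bound, upper_bound]`` whenever
    ``dt * (A + E + I) / tau <= 1``, so potentials never leave the bounds
    under the step sizes used in this package.
    """
    if not dt > 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    x = state.potentials
    e = np.asarray(excitation, dtype=float)
    i = np.asarray(inhibition, dtype=float)
    if e.shape != x.shape or i.shape != x.shape:
        raise ValueError(
            f"drive shapes {e.shape}/{i.shape} do not match layer size {x.shape}"
        )
    for name, v in (("excitation", e), ("inhibition", i)):
        if not np.all(np.isfinite(v)):
            bad = int(np.flatnonzero(~np.isfinite(v))[0])
            raise ValueError(f"non-finite {name} at node {bad}")
    p = params
    dx = (
        -p.decay_rate * x
        + (p.upper_bound - x) * e
        - (x - p.lower_bound) * i
    ) / p.time_constant
    new_x = x + dt * dx
    return LayerState(new_x, output_signal(new_x, p, signal_kind, signal_gain))


def layer_sum(state: LayerState) -> float:
    """Total thresholded output of a layer (the Sigma nodes of the circuit)."""
    return float(np.sum(state.outputs))


# ---------------------------------------------------------------------------
# Generic coupled-network integration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Layer:
    """Declaration of one named layer in a generic network."""

    name: str
    size: int
    params: ShuntingParams = field(default_factory=ShuntingParams)
    signal_kind: str = "threshold-linear"
    signal_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValueError(
                f"unknown signal kind {self.signal_kind!r} for layer {self.name}"
            )


@dataclass(frozen=True)
class ScheduleEvent:
    """External excitatory drive applied to one layer over a time window."""

    layer: str
    start: float
    stop: float
    drive: np.ndarray


# A connection function maps (previous outputs by layer name, time) to the
# (excitation, inhibition) drive pair of its target layer.
ConnectionFn = Callable[[Mapping[str, np.ndarray], float], tuple]


@dataclass
class Network:
    """A set of coupled shunting layers with arbitrary connection functions."""

    layers: list
    connections: dict

    def __post_init__(self) -> None:
        names = [lay.name for lay in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate layer names")
        for target in self.connections:
            if target not in names:
                raise ValueError(f"connection target {target!r} is not a layer")


class TraceRecorder:
    """Accumulates per-layer time series and assembles a SimulationTrace."""

    def __init__(self) -> None:
        self._times: list = []
        self._pot: dict = {}
        self._out: dict = {}

    def record(self, t: float, states: Mapping) -> None:
        """states maps (module, layer) -> LayerState.

        Re-recording the current end time replaces the last sample, so
        chained integration phases can share their boundary point.
        """
        if self._times and t <= self._times[-1] + 1e-12:
            self._times.pop()
            for key in self._pot:
                self._pot[key].pop()
                self._out[key].pop()
        self._times.append(t)
        for key, st in states.items():
            self._pot.setdefault(key, []).append(st.potentials.copy())
            self._out.setdefault(key, []).append(st.outputs.copy())

    def build(self) -> "SimulationTrace":
        return SimulationTrace(
            times=np.asarray(self._times, dtype=float),
            potentials={k: np.asarray(v) for k, v in self._pot.items()},
            outputs={k: np.asarray(v) for k, v in self._out.items()},
        )


@dataclass
class SimulationTrace:
    """Time-indexed record of all node potentials and outputs of a run.

    ``potentials[(module, layer)]`` is a ``(T, n)`` array aligned with
    ``times``; ``outputs`` likewise.
    """

    times: np.ndarray
    potentials: dict
    outputs: dict

    def __post_init__(self) -> None:
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("trace times must be strictly increasing")
        for key, arr in self.potentials.items():
            if arr.shape[0] != self.times.size:
                raise ValueError(f"series length mismatch for {key}")

    def keys(self) -> Iterable:
        return self.potentials.keys()

    def series(self, module: str, layer: str, node: int, what: str = "potentials"):
        data = self.potentials if what == "potentials" else self.outputs
        return data[(module, layer)][:, node]

    def window(self, t0: float, t1: float) -> "SimulationTrace":
        mask = (self.times >= t0) & (self.times <= t1)
        return SimulationTrace(
            times=self.times[mask],
            potentials={k: v[mask] for k, v in self.potentials.items()},
            outputs={k: v[mask] for k, v in self.outputs.items()},
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view: time, module, layer, node, potential, output."""
        rows = []
        for (module, layer), pot in self.potentials.items():
            out = self.outputs[(module, layer)]
            n = pot.shape[1]
            for node in range(n):
                rows.append(
                    pd.DataFrame(
                        {
                            "time": self.times,
                            "module": module,
                            "layer": layer,
                            "node": node,
                            "potential": pot[:, node],
                            "output": out[:, node],
                        }
                    )
                )
        if not rows:
            return pd.DataFrame(
                columns=["time", "module", "layer", "node", "potential", "output"]
            )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> dict:
        """Compact JSON-ready run summary (peaks and final values per layer)."""
        out = {}
        for key, pot in self.potentials.items():
            module, layer = key
            out[f"{module}/{layer}"] = {
                "n_nodes": int(pot.shape[1]),
                "peak_potential": float(pot.max()) if pot.size else 0.0,
                "final_max_output": float(self.outputs[key][-1].max())
                if pot.size
                else 0.0,
            }
        return {
            "duration": float(self.times[-1]) if self.times.size else 0.0,
            "n_steps": int(self.times.size),
            "layers": out,
        }


def integrate(
    network: Network,
    schedule: Iterable[ScheduleEvent],
    duration: float,
    dt: float,
    record_every: int = 1,
    module: str = "net",
) -> SimulationTrace:
    """Integrate a coupled network with synchronous explicit-Euler updates.

    Every layer's drives are computed from the *previous* step's outputs, so
    the result is independent of layer iteration order.  Raises
    :class:`DivergenceError` (naming the offending time) if any potential
    leaves its shunting bounds.
    """
    if not duration > 0:
        raise ValueError("duration must be > 0")
    events = list(schedule)
    for ev in events:
        if ev.start < 0 or ev.stop > duration + 1e-12:
            raise ValueError(
                f"schedule event for {ev.layer!r} outside [0, {duration}]"
            )
    states = {lay.name: LayerState.zeros(lay.size) for lay in network.layers}
    by_name = {lay.name: lay for lay in network.layers}
    rec = TraceRecorder()
    n_steps = int(round(duration / dt))
    for step in range(n_steps + 1):
        t = step * dt
        if step % record_every == 0:
            rec.record(t, {(module, n): s for n, s in states.items()})
        if step == n_steps:
            break
        outputs = {name: s.outputs for name, s in states.items()}
        new_states = {}
        for name, lay in by_name.items():
            conn = network.connections.get(name)
            if conn is None:
                e = np.zeros(lay.size)
                i = np.zeros(lay.size)
            else:
                e, i = conn(outputs, t)
                e = np.broadcast_to(np.asarray(e, dtype=float), (lay.size,)).copy()
                i = np.broadcast_to(np.asarray(i, dtype=float), (lay.size,)).copy()
            for ev in events:
                if ev.layer == name and ev.start <= t < ev.stop:
                    e += ev.drive
            new_states[name] = shunting_step(
                states[name], e, i, lay.params, dt, lay.signal_kind, lay.signal_gain
            )
            p = lay.params
            x = new_states[name].potentials
            if np.any(x > p.upper_bound + DIVERGENCE_TOL) or np.any(
                x < p.lower_bound - DIVERGENCE_TOL
            ):
                raise DivergenceError(
                    f"layer {name!r} left [{p.lower_bound}, {p.upper_bound}] "
                    f"at t={t + dt:.4f}"
                )
        states = new_states
    return rec.build()
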