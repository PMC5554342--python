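"""Wilson-Cowan rate dynamics for networks of neural populations.

Every element of the sentence blackboard (concept assemblies, main and sub
assemblies, gating-circuit relays and working-memory units) is a single
excitatory or inhibitory population obeying

    tau * dA/dt = -(A - baseline) + (1 - A) * F(input),

where ``F`` is a logistic sigmoid shifted so that ``F(0) = 0`` (a resting
population receives no drive from the transfer function, so the rest state
is a true fixed point).  Inhibition is carried on negative link weights;
``F`` may go negative for net-inhibitory input, which pulls activity down,
and activity is clamped to [0, 1] after every explicit Euler step.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Population",
    "Link",
    "StimulusSchedule",
    "ActivityTrace",
    "Network",
    "WiringError",
    "WM_PARAMS",
    "fixed_point_rhs",
]


class WiringError(Exception):
    """A link or stimulus refers to a population that does not exist."""


#: Parameter set for working-memory populations.  The steep gain and high
#: threshold give bistability: a stable rest state at 0 and a stable
#: persistent state near 0.46 sustained by recurrent excitation alone
#: (reverberating activity).  Verified by the bistability tests.
WM_PARAMS = {"tau": 10.0, "gain": 8.0, "threshold": 0.7, "self_weight": 2.0}


@dataclass
class Population:
    """One neural population (a Wilson-Cowan rate unit).

    Parameters
    ----------
    id : str
        Opaque identifier, unique within a network.
    tau : float
        Time constant in ms.
    gain, threshold : float
        Slope and midpoint of the logistic transfer function.
    baseline : float
        Resting rate the population relaxes to with no input.
    self_weight : float
        Recurrent excitation (>= 0); large values make the unit bistable.
    drive : float
        Tonic external input, present at every step (used e.g. for the
        inhibitory population of a gating circuit, which must be active
        by default so that the gate rests closed).
    """

    id: str
    tau: float = 10.0
    gain: float = 4.0
    threshold: float = 0.5
    baseline: float = 0.0
    self_weight: float = 0.0
    drive: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.self_weight < 0:
            raise ValueError("self_weight must be >= 0")
        if not (0.0 <= self.baseline <= 1.0):
            raise ValueError("baseline must lie in [0, 1]")


@dataclass
class Link:
    """Directed connection between two populations.

    ``kind='plain'`` delivers ``weight * A_source`` at every step.
    ``kind='gated'`` delivers ``weight * A_source * A_gate``: a shunting
    connection that only transmits while its gate population is active.
    The blackboard realizes its conditional connections with explicit
    three-population gating circuits made of plain links; gated links are
    the lighter-weight alternative for ad-hoc circuits.
    """

    source: str
    target: str
    weight: float
    kind: str = "plain"
    gate: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.weight):
            raise ValueError("link weight must be finite")
        if self.kind not in ("plain", "gated"):
            raise ValueError(f"unknown link kind {self.kind!r}")
        if self.kind == "gated" and self.gate is None:
            raise ValueError("gated link requires a gate population id")


@dataclass
class StimulusSchedule:
    """External input pulses: (population id, onset ms, offset ms, amplitude)."""

    pulses: list[tuple[str, float, float, float]] = field(default_factory=list)

    def add(self, pid: str, onset: float, offset: float, amplitude: float) -> None:
        if onset >= offset:
            raise ValueError(f"pulse onset {onset} must precede offset {offset}")
        if amplitude < 0:
            raise ValueError("pulse amplitude must be >= 0")
        self.pulses.append((pid, onset, offset, amplitude))

    @property
    def max_offset(self) -> float:
        return max((p[2] for p in self.pulses), default=0.0)

    def population_ids(self) -> set[str]:
        return {p[0] for p in self.pulses}


class ActivityTrace:
    """Sampled activity of every population over a run."""

    def __init__(self, times: np.ndarray, ids: Sequence[str], data: np.ndarray):
        self.times = np.asarray(times, dtype=float)
        self.ids = list(ids)
        self.data = np.asarray(data, dtype=float)  # shape (T, N)
        self._index = {pid: i for i, pid in enumerate(self.ids)}

    def population(self, pid: str) -> np.ndarray:
        return self.data[:, self._index[pid]]

    def total(self) -> np.ndarray:
        """Pointwise sum of all population activities."""
        if self.data.size == 0:
            return np.zeros_like(self.times)
        return self.data.sum(axis=1)

    def to_csv(self, path) -> None:
        """Long-format CSV with header ``time_ms,population_id,activity``."""
        with open(path, "w") as fh:
            fh.write("time_ms,population_id,activity\n")
            for i, t in enumerate(self.times):
                for j, pid in enumerate(self.ids):
                    fh.write(f"{t:.3f},{pid},{self.data[i, j]:.6f}\n")


def total_activity(trace: ActivityTrace) -> np.ndarray:
    """Sum of the activation of all neural populations at each sample."""
    if len(trace.times) == 0:
        raise ValueError("empty trace")
    return trace.total()


def fixed_point_rhs(a: float, inp: float, gain: float = 4.0, threshold: float = 0.5) -> float:
    """Stationarity residual ``-a + (1 - a) * F(inp)`` for a single unit.

    Exposed so that fixed points can be located independently of the
    integrator (e.g. by bisection).
    """
    f = 1.0 / (1.0 + math.exp(-gain * (inp - threshold))) - 1.0 / (
        1.0 + math.exp(gain * threshold)
    )
    return -a + (1.0 - a) * f


class Network:
    """A collection of populations and links, integrated with explicit Euler.

    State (activities and runtime control drives) lives on the network; the
    parameter arrays are compiled lazily and invalidated whenever topology
    changes.
    """

    def __init__(self) -> None:
        self.populations: dict[str, Population] = {}
        self.links: list[Link] = []
        self._dirty = True
        self._ids: list[str] = []
        self._idx: dict[str, int] = {}
        self._A: np.ndarray = np.zeros(0)
        self._control: np.ndarray = np.zeros(0)

    # -- construction -------------------------------------------------

    def add_population(self, pop: Population) -> Population:
        if pop.id in self.populations:
            raise WiringError(f"duplicate population id {pop.id!r}")
        self.populations[pop.id] = pop
        self._dirty = True
        return pop

    def add_link(self, link: Link) -> Link:
        for endpoint in (link.source, link.target):
            if endpoint not in self.populations:
                raise WiringError(f"link endpoint {endpoint!r} is not a population")
        if link.gate is not None and link.gate not in self.populations:
            raise WiringError(f"gate {link.gate!r} is not a population")
        if link.source == link.target and link.kind == "plain":
            raise WiringError(
                "self-links are not allowed; use Population.self_weight"
            )
        self.links.append(link)
        self._dirty = True
        return link

    def __len__(self) -> int:
        return len(self.populations)

    def __contains__(self, pid: str) -> bool:
        return pid in self.populations

    # -- compiled state ------------------------------------------------

    def _compile(self) -> None:
        old_A = dict(zip(self._ids, self._A)) if len(self._ids) else {}
        old_ctrl = dict(zip(self._ids, self._control)) if len(self._ids) else {}
        self._ids = list(self.populations)
        self._idx = {pid: i for i, pid in enumerate(self._ids)}
        n = len(self._ids)
        pops = [self.populations[pid] for pid in self._ids]
        self._tau = np.array([p.tau for p in pops])
        self._gain = np.array([p.gain for p in pops])
        self._threshold = np.array([p.threshold for p in pops])
        self._baseline = np.array([p.baseline for p in pops])
        self._self_w = np.array([p.self_weight for p in pops])
        self._drive = np.array([p.drive for p in pops])
        # F offset so F(0) = 0 per population
        self._f0 = 1.0 / (1.0 + np.exp(self._gain * self._threshold))
        self._W = np.zeros((n, n))
        gated: list[tuple[int, int, int, float]] = []
        for link in self.links:
            s, t = self._idx[link.source], self._idx[link.target]
            if link.kind == "plain":
                self._W[t, s] += link.weight
            else:
                gated.append((t, s, self._idx[link.gate], link.weight))
        self._gated = gated
        self._A = np.array([old_A.get(pid, self.populations[pid].baseline) for pid in self._ids])
        self._control = np.array([old_ctrl.get(pid, 0.0) for pid in self._ids])
        self._dirty = False

    def _ensure(self) -> None:
        if self._dirty:
            self._compile()

    # -- state access --------------------------------------------------

    def activity(self, pid: str) -> float:
        self._ensure()
        return float(self._A[self._idx[pid]])

    def activities(self) -> dict[str, float]:
        self._ensure()
        return dict(zip(self._ids, self._A))

    def set_activity(self, pid: str, value: float) -> None:
        self._ensure()
        self._A[self._idx[pid]] = float(np.clip(value, 0.0, 1.0))

    def set_control(self, pid: str, value: float) -> None:
        """Set a persistent control drive (e.g. a di population held open)."""
        self._ensure()
        if pid not in self._idx:
            raise WiringError(f"unknown population {pid!r}")
        self._control[self._idx[pid]] = value

    def reset(self) -> None:
        self._ensure()
        self._A = np.array([self.populations[pid].baseline for pid in self._ids])
        self._control[:] = 0.0

    # -- integration ---------------------------------------------------

    def step(
        self,
        external: Mapping[str, float] | np.ndarray | None = None,
        dt: float = 1.0,
    ) -> "Network":
        """Advance every population by one Euler step of size ``dt`` ms."""
        if dt <= 0:
            raise ValueError(f"dt must be positive, got {dt}")
        self._ensure()
        n = len(self._ids)
        if n == 0:
            return self
        if external is None:
            ext = 0.0
        elif isinstance(external, np.ndarray):
            ext = external
        else:
            ext = np.zeros(n)
            for pid, amp in external.items():
                if pid not in self._idx:
                    raise WiringError(f"unknown population {pid!r} in input")
                ext[self._idx[pid]] += amp
        inp = self._W @ self._A + self._self_w * self._A + self._drive + self._control + ext
        for t, s, g, w in self._gated:
            inp[t] += w * self._A[s] * self._A[g]
        f = 1.0 / (1.0 + np.exp(-self._gain * (inp - self._threshold))) - self._f0
        dA = (-(self._A - self._baseline) + (1.0 - self._A) * f) * (dt / self._tau)
        self._A = np.clip(self._A + dA, 0.0, 1.0)
        return self

    def run(
        self,
        schedule: StimulusSchedule,
        duration: float,
        dt: float = 1.0,
        record_every: int = 1,
    ) -> ActivityTrace:
        """Integrate for ``duration`` ms under a stimulus schedule.

        Deterministic: there is no randomness anywhere in the dynamics.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        if duration < schedule.max_offset:
            raise ValueError("duration shorter than the last scheduled offset")
        self._ensure()
        missing = schedule.population_ids() - set(self._idx)
        if missing:
            raise WiringError(f"schedule references unknown populations {sorted(missing)}")
        nsteps = int(round(duration / dt))
        times = [0.0]
        frames = [self._A.copy()]
        n = len(self._ids)
        for k in range(nsteps):
            t = k * dt
            ext = np.zeros(n)
            for pid, onset, offset, amp in schedule.pulses:
                if onset <= t < offset:
                    ext[self._idx[pid]] += amp
            self.step(ext if n else None, dt)
            if (k + 1) % record_every == 0:
                times.append((k + 1) * dt)
                frames.append(self._A.copy())
        data = np.vstack(frames) if frames else np.zeros((0, n))
        return ActivityTrace(np.array(times), self._ids, data)

    # -- serialization -------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "populations": [asdict(p) for p in self.populations.values()],
                "links": [asdict(l) for l in self.links],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "Network":
        doc = json.loads(text)
        net = cls()
        for p in doc["populations"]:
            net.add_population(Population(**p))
        for l in doc["links"]:
            net.add_link(Link(**l))
        return net
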