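"""Discrete event simulation core.

A minimal heap-based event scheduler drives three kinds of activity:

* **arrivals** — specimens are generated by a Poisson process (exponential
  inter-arrival times) and flagged growth-positive by a Bernoulli draw;
* **pure delays** — transport to the laboratory, incubation and the
  post-Gram reporting cascade elapse without consuming staff;
* **staff tasks** — each staff agent runs the OnHold loop: at each wake
  it claims *all* specimens queued for its earliest pending step and
  processes them (one duration draw for a per-batch step; concurrent
  per-specimen draws otherwise, busy until the last finishes), then
  re-enters the OnHold dormancy for exactly its configured wait before
  the next claim; a wake that finds no queued work simply starts another
  OnHold period.  Off-shift agents claim nothing and queued work waits;
  a task in progress at shift end is allowed to complete.

Randomness is split into independent named streams (arrivals, positivity,
time-to-positivity, one per pathway step) derived from a single master
seed, so that perturbing one staff parameter does not reshuffle unrelated
draws — the common-random-numbers structure the sensitivity and
calibration analyses rely on.

Event timestamps are recorded at completion: ``collection`` is the
arrival instant, ``receipt`` the end of transport, ``load_analyzer`` the
incubator load, ``flag_positive`` (growth) or ``incubation_complete``
(no growth) the end of incubation, and ``final_report`` the terminal
event.  Task start times are kept separately for shift diagnostics.
"""

from __future__ import annotations

import heapq
import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np

from . import distributions as dist
from .errors import ConfigError, ParameterDomainError
from .lab_model import SimulationConfig, validate_config

__all__ = ["Specimen", "SimulationResult", "generate_arrivals", "run_simulation",
           "replicate", "rng_stream"]


def rng_stream(seed: int, name: str) -> np.random.Generator:
    """An independent, reproducible generator for one named purpose."""
    tag = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


@dataclass
class Specimen:
    """One simulated blood culture and its event history."""

    id: int
    is_positive: bool
    collection: float
    events: dict[str, float] = field(default_factory=dict)
    starts: dict[str, float] = field(default_factory=dict)
    completed: bool = False


@dataclass
class SimulationResult:
    specimens: list[Specimen]
    config: SimulationConfig
    seed: int
    n_generated: int = 0
    n_completed: int = 0
    n_positive: int = 0

    def __post_init__(self):
        self.n_generated = len(self.specimens)
        self.n_completed = sum(s.completed for s in self.specimens)
        self.n_positive = sum(s.is_positive for s in self.specimens)


def generate_arrivals(rate: float, horizon: float, rng: np.random.Generator,
                      positivity: float = 0.0,
                      positivity_rng: np.random.Generator | None = None):
    """Poisson-process arrival times in [0, horizon) with positivity flags.

    Inter-arrival times are exponential with the given per-minute rate; each
    arrival is flagged positive with probability ``positivity`` using an
    independent stream (``positivity_rng``, defaulting to ``rng``).
    """
    if rate <= 0:
        raise ParameterDomainError("rate", "must be > 0")
    if horizon < 0:
        raise ParameterDomainError("horizon", "must be >= 0")
    if positivity_rng is None:
        positivity_rng = rng
    out = []
    t = float(rng.exponential(1.0 / rate))
    while t < horizon:
        out.append((t, bool(positivity_rng.random() < positivity)))
        t += float(rng.exponential(1.0 / rate))
    return out


def _duration_minutes(spec, k: int, rng) -> np.ndarray:
    d = dist.sample(spec, k, rng)
    return d / 60.0 if spec.unit == "seconds" else d


class _Agent:
    """Staff agent state: queues for its steps, OnHold/off-shift schedule."""

    def __init__(self, staff_cfg, step_indices):
        self.cfg = staff_cfg
        self.step_indices = step_indices  # pathway indices this role performs
        self.queues = {i: [] for i in step_indices}

    def pending_step(self):
        # deepest pending step first: pipeline order preserves arrival
        # order, so this serves the longest-waiting specimens and keeps
        # new arrivals from starving downstream work
        for i in reversed(self.step_indices):
            if self.queues[i]:
                return i
        return None


class _Simulation:
    def __init__(self, config: SimulationConfig, seed: int):
        violations = validate_config(config)
        if violations:
            raise ConfigError("invalid configuration: " + "; ".join(violations))
        if config.run_length <= 0:
            raise ParameterDomainError("run_length", "must be > 0")
        self.cfg = config
        self.seed = int(seed)
        self.heap: list = []
        self._seq = itertools.count()
        self.steps = config.pathway
        self.step_rngs = [rng_stream(seed, f"step:{s.name}") for s in self.steps]
        self.ttp_rng = rng_stream(seed, "ttp")
        self.agents: dict[str, _Agent] = {}
        for staff in config.staff:
            indices = [i for i, s in enumerate(self.steps)
                       if s.kind == "staff_task" and s.performer == staff.role]
            self.agents[staff.role] = _Agent(staff, indices)
        self.specimens: list[Specimen] = []

    def schedule(self, t: float, fn) -> None:
        heapq.heappush(self.heap, (t, next(self._seq), fn))

    def run(self, arrivals=None) -> SimulationResult:
        cfg = self.cfg
        if arrivals is None:
            arrivals = generate_arrivals(cfg.arrival_rate, cfg.run_length,
                                         rng_stream(self.seed, "arrivals"),
                                         cfg.positivity,
                                         rng_stream(self.seed, "positivity"))
        for sid, (t, pos) in enumerate(arrivals):
            sp = Specimen(id=sid, is_positive=pos, collection=t)
            sp.events["collection"] = t
            self.specimens.append(sp)
            self.schedule(t, lambda at=t, s=sp: self._advance(s, 0, at))
        for agent in self.agents.values():
            self.schedule(0.0, lambda a=agent: self._wake(a, 0.0))
        horizon = cfg.run_length
        while self.heap:
            t, _, fn = heapq.heappop(self.heap)
            if t > horizon:
                continue  # beyond the run: drop, do not reschedule
            fn()
        return SimulationResult(self.specimens, cfg, self.seed)

    # -- specimen progression -------------------------------------------

    def _applies(self, step, specimen) -> bool:
        return (step.applies_to == "all"
                or (step.applies_to == "positive_only" and specimen.is_positive)
                or (step.applies_to == "negative_only" and not specimen.is_positive))

    def _advance(self, specimen: Specimen, index: int, t: float) -> None:
        """Move a specimen to its next applicable step from pathway[index]."""
        while index < len(self.steps) and not self._applies(self.steps[index], specimen):
            index += 1
        if index >= len(self.steps):
            specimen.events.setdefault("final_report", t)
            specimen.completed = True
            return
        step = self.steps[index]
        if step.kind == "staff_task":
            self.agents[step.performer].queues[index].append(specimen)
            return
        if step.kind == "incubation":
            if specimen.is_positive:
                dur = float(_duration_minutes(self.cfg.incubation_ttp, 1, self.ttp_rng)[0])
                name = "flag_positive"
            else:
                dur = float(self.cfg.incubation_negative)
                name = "incubation_complete"
        else:  # pure_delay
            dur = float(_duration_minutes(step.duration, 1, self.step_rngs[index])[0])
            name = step.name
        end = t + dur
        self.schedule(end, lambda s=specimen, i=index, e=end, nm=name: self._finish(s, i, e, nm))

    def _finish(self, specimen: Specimen, index: int, t: float, name: str) -> None:
        specimen.events[name] = t
        self._advance(specimen, index + 1, t)

    # -- staff agents -----------------------------------------------------

    def _wake(self, agent: _Agent, t: float) -> None:
        shift = agent.cfg.shift
        if shift.is_off(t):
            on = shift.next_on(t)
            self.schedule(on, lambda: self._wake(agent, on))
            return
        index = agent.pending_step()
        if index is None:
            nxt = t + agent.cfg.onhold_wait  # OnHold dormancy
            self.schedule(nxt, lambda: self._wake(agent, nxt))
            return
        step = self.steps[index]
        batch = agent.queues[index]
        agent.queues[index] = []
        rng = self.step_rngs[index]
        if step.batch_mode == "per_batch":
            dur = float(_duration_minutes(step.duration, 1, rng)[0])
            ends = [t + dur] * len(batch)
        else:
            ends = list(t + _duration_minutes(step.duration, len(batch), rng))
        busy_until = max(ends)
        for sp, end in zip(batch, ends):
            sp.starts[step.name] = t
            self.schedule(end, lambda s=sp, i=index, e=end: self._finish(s, i, e, step.name))
        # having finished a batch of jobs, the agent re-enters OnHold for
        # exactly its wait before the next claim opportunity
        nxt = busy_until + agent.cfg.onhold_wait
        self.schedule(nxt, lambda: self._wake(agent, nxt))


def run_simulation(config: SimulationConfig, seed: int | None = None,
                   arrivals=None) -> SimulationResult:
    """Run one seeded simulation of the configured laboratory.

    ``arrivals`` may inject an explicit list of (time, is_positive) pairs
    in place of the Poisson stream — useful for deterministic scenario
    runs and trace-level verification.
    """
    if seed is None:
        seed = config.seed
    return _Simulation(config, seed).run(arrivals=arrivals)


def replicate(config: SimulationConfig, n_reps: int) -> list[SimulationResult]:
    """``n_reps`` independent replicates seeded ``config.seed + i``."""
    if n_reps < 1:
        raise ParameterDomainError("n_reps", "must be >= 1")
    return [run_simulation(config, seed=config.seed + i) for i in range(n_reps)]
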