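"""Domain model of the blood-culture laboratory.

Three staff agents process specimens along a fixed pathway:

* a **reception technician** (off shift 20:00-08:00) books specimens in and
  loads them onto the automated incubator,
* a **bench technician** (always available) unloads flagged bottles and
  prepares Gram-stain smears,
* a **scientist** (always available) reads and reports the Gram stain.

Each staff agent alternates between working on queued specimens and a fixed
"OnHold" dormancy that stands in for all activity outside blood-culture
processing (other specimen types, admin, breaks).  The OnHold wait, in
minutes, is the model's surrogate for staff availability.

The default configuration encodes the study laboratory: ~35,000 blood
cultures per year arriving as a Poisson process, an 11.1% positivity rate,
directly observed task-duration distributions (stored in seconds), a
Weibull time-to-positivity for growth-positive bottles and a fixed 5-day
incubation for no-growth bottles, and lognormal delays from Gram report to
the final/AST report.

Canonical internal time unit: minutes since simulation start, with t = 0
at midnight of day 0 (clock-of-day = t mod 1440).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .distributions import DistributionSpec
from .errors import ConfigError

RECEPTION = "reception_technician"
BENCH = "bench_technician"
SCIENTIST = "scientist"
ROLES = (RECEPTION, BENCH, SCIENTIST)

#: Seed used when a config file omits one.
DEFAULT_SEED = 42

MINUTES_PER_DAY = 1440
MINUTES_PER_YEAR = 525_600


def _parse_clock(value) -> int:
    """Accept minutes past midnight or an 'HH:MM' string."""
    if isinstance(value, str):
        h, m = value.split(":")
        value = int(h) * 60 + int(m)
    value = int(value)
    if not 0 <= value < MINUTES_PER_DAY:
        raise ConfigError(f"clock time {value} outside [0, 1440)")
    return value


def _format_clock(minutes: int) -> str:
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


@dataclass(frozen=True)
class ShiftSchedule:
    """An off-shift window on the 24 h clock; may wrap midnight."""

    off_start: int | None = None
    off_end: int | None = None
    always_on: bool = False

    def is_off(self, t: float) -> bool:
        if self.always_on:
            return False
        clock = t % MINUTES_PER_DAY
        if self.off_start <= self.off_end:
            return self.off_start <= clock < self.off_end
        return clock >= self.off_start or clock < self.off_end

    def next_on(self, t: float) -> float:
        """Earliest time >= t at which the agent is on shift."""
        if not self.is_off(t):
            return t
        clock = t % MINUTES_PER_DAY
        day_start = t - clock
        if self.off_start <= self.off_end or clock >= self.off_start:
            # off window ends at off_end, possibly on the next day
            end = day_start + self.off_end
            if end <= t:
                end += MINUTES_PER_DAY
            return end
        return day_start + self.off_end

    def to_dict(self) -> dict:
        if self.always_on:
            return {"always_on": True}
        return {"off_start": _format_clock(self.off_start), "off_end": _format_clock(self.off_end)}

    @classmethod
    def from_dict(cls, d: dict) -> "ShiftSchedule":
        if d.get("always_on"):
            return cls(always_on=True)
        return cls(off_start=_parse_clock(d["off_start"]), off_end=_parse_clock(d["off_end"]))


ALWAYS_ON = ShiftSchedule(always_on=True)


@dataclass(frozen=True)
class StaffConfig:
    role: str
    onhold_wait: float  # minutes, > 0
    shift: ShiftSchedule = ALWAYS_ON


@dataclass(frozen=True)
class ProcessStep:
    """One pathway step.

    ``kind`` is ``staff_task`` (performed by a role, with a batching mode),
    ``pure_delay`` (an elapsing interval with no resource), or
    ``incubation`` (duration taken from the config's time-to-positivity or
    fixed negative-incubation length rather than from ``duration``).
    """

    name: str
    kind: str  # staff_task | pure_delay | incubation
    duration: DistributionSpec | None = None
    performer: str | None = None
    batch_mode: str | None = None  # per_batch | per_specimen
    applies_to: str = "all"  # all | positive_only | negative_only


@dataclass
class SimulationConfig:
    arrival_rate: float  # specimens per minute
    positivity: float
    staff: list[StaffConfig]
    pathway: list[ProcessStep]
    incubation_ttp: DistributionSpec
    incubation_negative: float  # minutes
    run_length: float  # minutes
    warmup: float = 0.0
    seed: int = DEFAULT_SEED

    def staff_by_role(self) -> dict[str, StaffConfig]:
        return {s.role: s for s in self.staff}

    def with_onhold(self, waits: dict[str, float]) -> "SimulationConfig":
        """Copy with some roles' OnHold waits replaced."""
        staff = [replace(s, onhold_wait=waits.get(s.role, s.onhold_wait)) for s in self.staff]
        return replace(self, staff=staff)


def _sec(family, **params):
    return DistributionSpec(family, params, "seconds")


def _minutes(family, **params):
    return DistributionSpec(family, params, "minutes")


def default_pathway() -> list[ProcessStep]:
    lk = dict(kind="staff_task", performer=RECEPTION, batch_mode="per_batch")
    bk = dict(kind="staff_task", performer=BENCH, batch_mode="per_specimen")
    pos = dict(applies_to="positive_only")
    return [
        # collection -> receipt in the laboratory (porter transport etc.)
        ProcessStep("receipt", "pure_delay", _minutes("gamma", shape=0.99, rate=0.003)),
        # specimen reception (booking in), batched
        ProcessStep("label", duration=_sec("uniform", a=22, b=700), **lk),
        ProcessStep("lims", duration=_sec("uniform", a=21, b=548), **lk),
        ProcessStep("combine_labels", duration=_sec("uniform", a=31, b=838), **lk),
        ProcessStep("scan_request_form", duration=_sec("uniform", a=37, b=109), **lk),
        ProcessStep("move_location", duration=_sec("lognormal", mu=3.736, sigma=0.385), **lk),
        ProcessStep("load_analyzer", duration=_sec("gamma", shape=1.493, rate=0.017), **lk),
        # automated incubation: Weibull TTP if growth, fixed 5 days if not
        ProcessStep("incubation", "incubation"),
        # blood culture bench, per specimen; unload applies to both outcomes
        ProcessStep("unload", duration=_sec("lognormal", mu=4.219, sigma=0.785), **bk),
        ProcessStep("hazard_check", duration=_sec("lognormal", mu=4.482, sigma=0.639), **bk, **pos),
        ProcessStep("vent", duration=_sec("lognormal", mu=5.452, sigma=0.499), **bk, **pos),
        ProcessStep("prepare_culture_smear", duration=_sec("lognormal", mu=5.467, sigma=0.499), **bk, **pos),
        ProcessStep("gram_stain_smear", duration=_sec("lognormal", mu=5.595, sigma=0.416), **bk, **pos),
        ProcessStep("dry_smear", duration=_sec("lognormal", mu=5.37, sigma=0.785), **bk, **pos),
        ProcessStep("read_report_gram", kind="staff_task", performer=SCIENTIST,
                    batch_mode="per_specimen",
                    duration=_sec("lognormal", mu=5.185, sigma=0.758), **pos),
        # reporting cascade after the Gram stain (positives only); the final
        # report doubles as the AST report
        ProcessStep("gram_to_24h_report", "pure_delay",
                    _minutes("lognormal", mu=7.228, sigma=0.221), **pos),
        ProcessStep("report_24h_to_48h", "pure_delay",
                    _minutes("lognormal", mu=7.282, sigma=0.109), **pos),
        ProcessStep("report_48h_to_final", "pure_delay",
                    _minutes("lognormal", mu=7.859, sigma=0.772), **pos),
    ]


#: Retrospective interval distributions that the simulator must reproduce
#: *emergently* (they arise from staff availability, so they are never
#: sampled during a run); kept as references for fixtures and calibration.
RETROSPECTIVE_REFERENCE = {
    "receipt_to_load": _minutes("gamma", shape=0.542, rate=0.015),
    "load_to_flag": _minutes("weibull", shape=1.383, scale=1417),
    "flag_to_unload": _minutes("weibull", shape=0.59, scale=23.796),
    "unload_to_gram": _minutes("gamma", shape=1.665, rate=0.017),
}


def default_config() -> SimulationConfig:
    """The study laboratory's parameterization.

    35,000 specimens/year (exponential inter-arrivals, mean ~15.02 min),
    positivity 11.1%, all OnHold waits 23 min, reception technician off
    shift 20:00-08:00, 28-day run with a 2-day warmup.
    """
    return SimulationConfig(
        arrival_rate=35_000 / MINUTES_PER_YEAR,
        positivity=0.111,
        staff=[
            StaffConfig(RECEPTION, onhold_wait=23.0,
                        shift=ShiftSchedule(off_start=20 * 60, off_end=8 * 60)),
            StaffConfig(BENCH, onhold_wait=23.0),
            StaffConfig(SCIENTIST, onhold_wait=23.0),
        ],
        pathway=default_pathway(),
        incubation_ttp=_minutes("weibull", shape=1.383, scale=1417),
        incubation_negative=5 * MINUTES_PER_DAY,
        run_length=28 * MINUTES_PER_DAY,
        warmup=2 * MINUTES_PER_DAY,
        seed=DEFAULT_SEED,
    )


def validate_config(config: SimulationConfig) -> list[str]:
    """Check every structural invariant; return violations (empty = valid)."""
    v: list[str] = []
    if not config.arrival_rate > 0:
        v.append("arrival_rate: must be > 0")
    if not 0 <= config.positivity <= 1:
        v.append("positivity: must be in [0, 1]")
    if not config.run_length > config.warmup >= 0:
        v.append("run_length/warmup: require run_length > warmup >= 0")
    if config.incubation_negative < 0:
        v.append("incubation_negative: must be >= 0")
    roles = [s.role for s in config.staff]
    if sorted(roles) != sorted(set(roles)):
        v.append("staff: duplicate roles")
    for s in config.staff:
        if s.role not in ROLES:
            v.append(f"staff[{s.role}].role: unknown role")
        if not s.onhold_wait > 0:
            v.append(f"staff[{s.role}].onhold_wait: must be > 0")
    names = set()
    for i, step in enumerate(config.pathway):
        loc = f"pathway[{i}]({step.name})"
        if step.name in names:
            v.append(f"{loc}: duplicate step name")
        names.add(step.name)
        if step.kind not in ("staff_task", "pure_delay", "incubation"):
            v.append(f"{loc}.kind: unknown kind {step.kind!r}")
        if step.applies_to not in ("all", "positive_only", "negative_only"):
            v.append(f"{loc}.applies_to: unknown value {step.applies_to!r}")
        if step.kind == "staff_task":
            if step.performer not in roles:
                v.append(f"{loc}.performer: role {step.performer!r} not in staff")
            if step.batch_mode not in ("per_batch", "per_specimen"):
                v.append(f"{loc}.batch_mode: must be per_batch or per_specimen")
            if step.duration is None:
                v.append(f"{loc}.duration: staff task needs a duration")
        else:
            if step.performer is not None or step.batch_mode is not None:
                v.append(f"{loc}: {step.kind} steps have no performer/batch_mode")
            if step.kind == "pure_delay" and step.duration is None:
                v.append(f"{loc}.duration: pure delay needs a duration")
    if sum(s.kind == "incubation" for s in config.pathway) != 1:
        v.append("pathway: exactly one incubation step required")
    return v


# ---------------------------------------------------------------------------
# serialization

def _step_to_dict(step: ProcessStep) -> dict:
    d: dict = {"name": step.name, "kind": step.kind, "applies_to": step.applies_to}
    if step.duration is not None:
        d["duration"] = step.duration.to_dict()
    if step.kind == "staff_task":
        d["performer"] = step.performer
        d["batch_mode"] = step.batch_mode
    return d


def config_to_dict(config: SimulationConfig) -> dict:
    return {
        "arrival_rate": config.arrival_rate,
        "positivity": config.positivity,
        "staff": [{"role": s.role, "onhold_wait": s.onhold_wait, "shift": s.shift.to_dict()}
                  for s in config.staff],
        "pathway": [_step_to_dict(s) for s in config.pathway],
        "incubation_ttp": config.incubation_ttp.to_dict(),
        "incubation_negative": config.incubation_negative,
        "run_length": config.run_length,
        "warmup": config.warmup,
        "seed": config.seed,
    }


def _spec_from_dict(d: dict, loc: str) -> DistributionSpec:
    try:
        return DistributionSpec.from_dict(d)
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"{loc}: {exc}") from exc


def config_from_dict(d: dict) -> SimulationConfig:
    try:
        staff = [StaffConfig(role=s["role"], onhold_wait=float(s["onhold_wait"]),
                             shift=ShiftSchedule.from_dict(s.get("shift", {"always_on": True})))
                 for s in d["staff"]]
        steps = []
        for i, sd in enumerate(d["pathway"]):
            dur = None
            if "duration" in sd:
                dur = _spec_from_dict(sd["duration"], f"pathway[{i}].duration")
            steps.append(ProcessStep(
                name=sd["name"], kind=sd["kind"], duration=dur,
                performer=sd.get("performer"), batch_mode=sd.get("batch_mode"),
                applies_to=sd.get("applies_to", "all")))
        return SimulationConfig(
            arrival_rate=float(d["arrival_rate"]),
            positivity=float(d["positivity"]),
            staff=staff,
            pathway=steps,
            incubation_ttp=_spec_from_dict(d["incubation_ttp"], "incubation_ttp"),
            incubation_negative=float(d["incubation_negative"]),
            run_length=float(d["run_length"]),
            warmup=float(d.get("warmup", 0.0)),
            seed=int(d.get("seed", DEFAULT_SEED)),
        )
    except ConfigError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed configuration: {exc!r}") from exc


def write_config(config: SimulationConfig, path) -> None:
    path = Path(path)
    d = config_to_dict(config)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def read_config(path) -> SimulationConfig:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        d = json.loads(text)
    else:
        d = yaml.safe_load(text)
    return config_from_dict(d)
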