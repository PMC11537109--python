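"""Simulation engine: arrivals, staff semantics, determinism, invariants.

The single-specimen trace test re-implements the staff wake rules in
miniature (an independent hand-stepped oracle) and checks the engine's
event log against it timestamp by timestamp.
"""

import math
from dataclasses import replace

import numpy as np
import pytest

from bcsim import distributions as dist
from bcsim.engine import generate_arrivals, replicate, rng_stream, run_simulation
from bcsim.errors import ConfigError, ParameterDomainError
from bcsim.lab_model import RECEPTION, DistributionSpec, ProcessStep

# pathway order of recorded events (positives)
POSITIVE_EVENT_ORDER = [
    "collection", "receipt", "label", "lims", "combine_labels", "scan_request_form",
    "move_location", "load_analyzer", "flag_positive", "unload", "hazard_check",
    "vent", "prepare_culture_smear", "gram_stain_smear", "dry_smear",
    "read_report_gram", "gram_to_24h_report", "report_24h_to_48h",
    "report_48h_to_final", "final_report"]

RECEPTION_STEPS = ["label", "lims", "combine_labels", "scan_request_form",
                   "move_location", "load_analyzer"]


class TestGenerateArrivals:
    def test_annual_volume(self, config):
        arr = generate_arrivals(config.arrival_rate, 525_600, np.random.default_rng(3))
        assert abs(len(arr) - 35_000) < 3 * math.sqrt(35_000)

    def test_zero_horizon(self, rng):
        assert generate_arrivals(1.0, 0, rng) == []

    def test_zero_positivity(self, rng):
        arr = generate_arrivals(1.0, 10_000, rng, positivity=0.0)
        assert not any(pos for _, pos in arr)

    def test_strictly_increasing_within_horizon(self, rng):
        arr = generate_arrivals(0.5, 1_000, rng)
        times = [t for t, _ in arr]
        assert all(b > a for a, b in zip(times, times[1:]))
        assert times[-1] < 1_000

    def test_positivity_convergence(self, config):
        n_target = 50_000
        horizon = n_target / config.arrival_rate
        arr = generate_arrivals(config.arrival_rate, horizon, np.random.default_rng(5),
                                positivity=config.positivity,
                                positivity_rng=np.random.default_rng(6))
        frac = sum(pos for _, pos in arr) / len(arr)
        se = math.sqrt(0.111 * 0.889 / len(arr))
        assert abs(frac - 0.111) < 3 * se

    def test_invalid_rate(self, rng):
        with pytest.raises(ParameterDomainError):
            generate_arrivals(0.0, 100, rng)


class TestDeterminism:
    def test_same_seed_same_trace(self, short_config):
        a = run_simulation(short_config, seed=11)
        b = run_simulation(short_config, seed=11)
        assert len(a.specimens) == len(b.specimens)
        for sa, sb in zip(a.specimens, b.specimens):
            assert sa.events == sb.events and sa.is_positive == sb.is_positive

    def test_replicates_distinct_and_reproducible(self, short_config):
        reps = replicate(short_config, 3)
        assert len({r.seed for r in reps}) == 3
        again = replicate(short_config, 3)
        assert reps[1].specimens[0].events == again[1].specimens[0].events
        assert reps[0].specimens[0].events != reps[1].specimens[0].events

    def test_zero_replicates_rejected(self, short_config):
        with pytest.raises(ParameterDomainError):
            replicate(short_config, 0)


@pytest.fixture(scope="module")
def result():
    from bcsim import default_config
    cfg = replace(default_config(), run_length=7 * 1440.0, warmup=1440.0)
    return run_simulation(cfg, seed=21)


class TestPathwayInvariants:

    def test_conservation(self, result):
        ids = [sp.id for sp in result.specimens]
        assert len(ids) == len(set(ids)) == result.n_generated

    def test_monotone_event_order(self, result):
        for sp in result.specimens:
            ts = [sp.events[e] for e in POSITIVE_EVENT_ORDER if e in sp.events]
            assert all(b >= a for a, b in zip(ts, ts[1:])), sp.events

    def test_positive_only_events_absent_for_negatives(self, result):
        for sp in result.specimens:
            if not sp.is_positive:
                assert "flag_positive" not in sp.events
                assert "read_report_gram" not in sp.events

    def test_negative_incubation_exact(self, result):
        negs = [sp for sp in result.specimens
                if not sp.is_positive and "incubation_complete" in sp.events]
        assert negs
        for sp in negs:
            assert sp.events["incubation_complete"] - sp.events["load_analyzer"] == \
                pytest.approx(7_200, abs=1e-9)

    def test_no_reception_start_off_shift(self, result):
        for sp in result.specimens:
            for step in RECEPTION_STEPS:
                if step in sp.starts:
                    clock = sp.starts[step] % 1440
                    assert not (clock >= 1200 or clock < 480), (step, clock)

    def test_completed_have_final_report(self, result):
        for sp in result.specimens:
            assert sp.completed == ("final_report" in sp.events)


def _constant_transport(config, minutes):
    """Replace the transport delay by a degenerate constant (in minutes)."""
    pathway = [replace(s, duration=DistributionSpec("uniform",
                                                    {"a": minutes, "b": minutes},
                                                    "minutes"))
               if s.name == "receipt" else s for s in config.pathway]
    return replace(config, pathway=pathway, warmup=0.0)


class TestShiftAndLatency:
    def test_late_receipt_waits_for_morning(self, config):
        # receipt at 22:00 -> first reception task start at/after 08:00 next day
        cfg = _constant_transport(config, 1320.0)
        res = run_simulation(cfg, seed=3, arrivals=[(0.0, False)])
        sp = res.specimens[0]
        assert sp.events["receipt"] == 1320.0
        assert sp.starts["label"] >= 1920.0

    def test_onhold_latency_bound(self, config):
        # daytime receipt in an empty system: first-task wait <= onhold_wait
        cfg = _constant_transport(config, 540.0)
        cfg = cfg.with_onhold({s.role: 30.0 for s in cfg.staff})
        res = run_simulation(cfg, seed=3, arrivals=[(0.0, False)])
        sp = res.specimens[0]
        wait = sp.starts["label"] - sp.events["receipt"]
        assert 0 <= wait <= 30.0


class TestSingleSpecimenTrace:
    """Hand-stepped oracle for one positive specimen in an empty system."""

    EPS = 0.5  # dyadic OnHold wait so wake grids are exact in floats
    SEED = 77
    ARRIVAL = 541.25

    def _oracle(self, config):
        """Recompute every event time from the seeded streams and the
        staff wake rules, independently of the event loop."""
        draws = {}
        for step in config.pathway:
            if step.duration is not None:
                d = dist.sample(step.duration, 1, rng_stream(self.SEED, f"step:{step.name}"))[0]
                draws[step.name] = d / 60.0 if step.duration.unit == "seconds" else d
        ttp = dist.sample(config.incubation_ttp, 1, rng_stream(self.SEED, "ttp"))[0]

        def first_claim(grid_anchor, ready, shift=None):
            # idle agent polls every EPS from its anchor; off-shift wakes
            # are pushed to shift end
            k = math.ceil((ready - grid_anchor) / self.EPS)
            t = grid_anchor + max(k, 0) * self.EPS
            if shift is not None and shift.is_off(t):
                t = shift.next_on(t)
            return t

        ev = {"collection": self.ARRIVAL}
        ev["receipt"] = self.ARRIVAL + draws["receipt"]
        shift = config.staff_by_role()[RECEPTION].shift
        # reception agent wakes from 08:00, polling every EPS while idle
        t = first_claim(480.0, ev["receipt"], shift)
        for name in RECEPTION_STEPS:
            end = t + draws[name]
            ev[name] = end
            t = end + self.EPS  # OnHold after the batch, work ready at wake
        ev["flag_positive"] = ev["load_analyzer"] + ttp
        t = first_claim(0.0, ev["flag_positive"])  # bench idle since t=0
        for name in ["unload", "hazard_check", "vent", "prepare_culture_smear",
                     "gram_stain_smear", "dry_smear"]:
            end = t + draws[name]
            ev[name] = end
            t = end + self.EPS
        t = first_claim(0.0, ev["dry_smear"])  # scientist idle since t=0
        ev["read_report_gram"] = t + draws["read_report_gram"]
        t = ev["read_report_gram"]
        for name in ["gram_to_24h_report", "report_24h_to_48h", "report_48h_to_final"]:
            t = t + draws[name]
            ev[name] = t
        ev["final_report"] = t
        return ev, draws

    def test_trace_equals_oracle(self, config):
        cfg = replace(config, run_length=40 * 1440.0, warmup=0.0)
        cfg = cfg.with_onhold({s.role: self.EPS for s in cfg.staff})
        expected, draws = self._oracle(cfg)
        # preconditions for the hand trace: receipt mid-shift, chain done by 20:00
        assert 481 < expected["receipt"] < 1100
        assert expected["load_analyzer"] < 1200
        res = run_simulation(cfg, seed=self.SEED, arrivals=[(self.ARRIVAL, True)])
        sp = res.specimens[0]
        assert sp.completed
        assert set(sp.events) == set(expected)
        for name, t in expected.items():
            assert sp.events[name] == pytest.approx(t, abs=1e-9), name

    def test_receipt_to_load_is_sum_of_task_draws(self, config):
        # with a vanishing OnHold wait the six reception draws are the
        # whole receipt-to-load interval (no contention)
        expected, draws = self._oracle(
            replace(config, run_length=40 * 1440.0, warmup=0.0)
            .with_onhold({s.role: self.EPS for s in config.staff}))
        task_sum = sum(draws[n] for n in RECEPTION_STEPS)
        interval = expected["load_analyzer"] - expected["receipt"]
        assert interval == pytest.approx(task_sum, abs=7 * self.EPS)


class TestErrors:
    def test_invalid_config_rejected(self, config):
        with pytest.raises(ConfigError):
            run_simulation(replace(config, positivity=2.0))
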