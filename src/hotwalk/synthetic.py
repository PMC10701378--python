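"""Synthetic cohort generator: phenotype-parameterized walks and responses.

The generator emulates the behavioral structure of a three-group study
(AD / aMCI / NC) on the place-item matching phase of the Hidden Objects
Test: nine excursions from the central box to a hiding place and back,
tracked at 13 Hz inside a 3 x 4 m arena.

Movement model
--------------
A waypoint-seeking walker, not a gait model.  Each tick the walker turns
toward the current waypoint at a bounded turn rate, then steps
``base_speed * dt`` along a heading perturbed by zero-mean Gaussian noise.
Three phenotype-dependent disturbances produce the mined signatures:

* wrong-target excursions — with probability ``wrong_target_prob`` an item
  leg first visits the centroid of a wrong hiding section (misremembered
  place), inflating distance and duration;
* detour loops — with probability ``detour_prob`` per leg an extra waypoint
  about ``detour_length_m / 2`` off the straight leg is inserted (wandering);
* pauses — a Poisson process (rate ``pause_rate_per_s`` of walking time)
  freezes the walker in place for an exponentially distributed duration
  (hesitation), ramping speed down and back up over a few samples so that
  stopping itself is kinematically smooth.

Pauses longer than the stay-point time threshold become stay points; heading
noise drives the Kalman innovation gate, so noisier (more impaired)
phenotypes accrue more trajectory outliers.  Every draw flows from the
explicit integer seed; cohorts derive per-participant seeds as
``base_seed + participant_index`` so earlier participants never reshuffle
when a cohort is extended.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .errors import ValidationError
from .layout import RoomLayout, default_layout
from .scoring import SUBTESTS, ResponseRecord
from .trajectory import ArenaConfig, Trajectory

#: Maximum turn rate of the walker (rad/s).  Bounded turning keeps the
#: constant-velocity filter's innovations small on noise-free paths, so that
#: outliers reflect erratic movement rather than route geometry.
MAX_TURN_RATE = 15.0

#: Samples used to ramp speed down/up around a pause.
PAUSE_RAMP_SAMPLES = 4

#: While heading to a detour waypoint the walker moves hurriedly and
#: erratically: heading noise and speed are boosted by these factors.  This
#: is what turns detours into innovation bursts (outlier runs) for the
#: noisier phenotypes; both vanish when the phenotype's noise or detour
#: probability is zero.
DETOUR_NOISE_BOOST = 2.0
DETOUR_SPEED_BOOST = 1.4

#: Hard cap on trajectory length (one hour at 13 Hz) to guarantee termination.
MAX_SAMPLES = 13 * 3600

#: Offset of the response-record seed from the participant seed.
RESPONSE_SEED_OFFSET = 2 ** 24


@dataclass(frozen=True)
class PhenotypeParams:
    """Per-group simulator knobs encoding behavioral impairment."""

    base_speed_mps: float
    heading_noise_sd_rad: float
    detour_prob: float
    detour_length_m: float
    pause_rate_per_s: float
    pause_duration_mean_s: float
    wrong_target_prob: float
    subtest_accuracies: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.base_speed_mps <= 0:
            raise ValidationError("base_speed_mps must be positive")
        if self.heading_noise_sd_rad < 0 or self.detour_length_m < 0:
            raise ValidationError("noise and detour length must be >= 0")
        if self.pause_rate_per_s < 0 or self.pause_duration_mean_s <= 0:
            raise ValidationError("pause rate must be >= 0 and mean duration > 0")
        for name, p in (("detour_prob", self.detour_prob),
                        ("wrong_target_prob", self.wrong_target_prob)):
            if not 0 <= p <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if set(self.subtest_accuracies) != set(SUBTESTS):
            raise ValidationError(
                f"subtest_accuracies must have keys {sorted(SUBTESTS)}")
        for name, p in self.subtest_accuracies.items():
            if not 0 <= p <= 1:
                raise ValidationError(f"accuracy {name} must lie in [0, 1]")


@dataclass
class CohortBundle:
    """Everything one simulated study produces."""

    trajectories: dict[str, Trajectory]
    responses: dict[str, ResponseRecord]
    layout: RoomLayout
    seed: int


def load_phenotypes(path=None) -> dict[str, PhenotypeParams]:
    """Load phenotype parameters from YAML (packaged calibration by default)."""
    if path is None:
        text = resources.files("hotwalk").joinpath("data/phenotypes.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {group: PhenotypeParams(**params) for group, params in raw.items()}


def default_phenotypes() -> dict[str, PhenotypeParams]:
    """The packaged parameter sets calibrated to the published group means.

    Simulated cohorts reproduce, in expectation, the published ordering of
    duration (AD > aMCI > NC), stay points (AD > aMCI > NC), mean speed
    (aMCI highest) and outlier burden (AD > NC).
    """
    return load_phenotypes()


def generate_task_sequence(layout: RoomLayout, seed: int = 0) -> list[tuple[float, float]]:
    """The 18 task waypoints: each item's hiding-section centroid, then the
    central box, in the fixed presentation order of the items."""
    center = layout.arena.center
    wps = []
    for name, _ in layout.items:
        wps.append(layout.section_centroid(layout.item_assignments[name]))
        wps.append(center)
    return wps


def _plan_route(params, layout, arena, rng):
    """Expand the task sequence with wrong-target excursions and detours."""
    center = arena.center
    route = []
    hiding = list(layout.hiding_sections)
    for name, _ in layout.items:
        sec = layout.item_assignments[name]
        if rng.random() < params.wrong_target_prob:
            others = [s for s in hiding if s != sec]
            wrong = others[rng.integers(len(others))]
            route.append(layout.section_centroid(wrong))
        route.append(layout.section_centroid(sec))
        route.append(center)

    margin = 0.2
    out = []  # (x, y, is_detour)
    prev = center
    for wp in route:
        if rng.random() < params.detour_prob:
            u = rng.uniform(0.25, 0.75)
            phi = rng.uniform(0.0, 2.0 * math.pi)
            bx = prev[0] + u * (wp[0] - prev[0])
            by = prev[1] + u * (wp[1] - prev[1])
            half = params.detour_length_m / 2.0
            dx = min(max(bx + half * math.cos(phi), margin), arena.width_m - margin)
            dy = min(max(by + half * math.sin(phi), margin), arena.depth_m - margin)
            out.append((dx, dy, True))
        out.append((wp[0], wp[1], False))
        prev = wp
    return out


def generate_trajectory(
    params: PhenotypeParams,
    layout: RoomLayout | None = None,
    arena: ArenaConfig | None = None,
    seed: int = 0,
    participant_id: str = "sim",
    group: str = "NC",
) -> Trajectory:
    """Simulate one tracked walk through the full nine-item task."""
    layout = layout or default_layout()
    arena = arena or layout.arena
    rng = np.random.default_rng(seed)
    route = _plan_route(params, layout, arena, rng)

    dt = arena.dt
    v = params.base_speed_mps
    sigma = params.heading_noise_sd_rad
    p_pause = params.pause_rate_per_s * dt
    mu = params.pause_duration_mean_s
    w, d = arena.width_m, arena.depth_m
    # arrival radius: just above the bounded-turn circle so the walker can
    # neither orbit a waypoint nor cut legs short by more than ~a step
    arrive = max(0.05, 1.1 * v / MAX_TURN_RATE)
    arrive_burst = max(arrive, 1.1 * v * DETOUR_SPEED_BOOST / MAX_TURN_RATE)
    max_turn = MAX_TURN_RATE * dt
    ramp = PAUSE_RAMP_SAMPLES

    x, y = arena.center
    wi = 0
    wx, wy, burst = route[0]
    heading = math.atan2(wy - y, wx - x)
    xs = [x]
    ys = [y]

    # pre-drawn randomness consumed sequentially (chunked for speed)
    CHUNK = 4096
    normals: list = []
    uniforms: list = []

    # pause state machine: >0 -> frozen ticks left; ramp counters
    freeze_left = 0
    pending_freeze = 0
    ramp_down = 0
    ramp_up = 0

    while len(xs) < MAX_SAMPLES:
        if freeze_left > 0:
            freeze_left -= 1
            if freeze_left == 0:
                ramp_up = ramp
            xs.append(x)
            ys.append(y)
            continue

        if ramp_down > 0:
            factor = ramp_down / (ramp + 1.0)
            ramp_down -= 1
            if ramp_down == 0:
                freeze_left = max(1, pending_freeze)
        elif ramp_up > 0:
            factor = (ramp + 1.0 - ramp_up) / (ramp + 1.0)
            ramp_up -= 1
        else:
            factor = 1.0
            if p_pause > 0:
                if not uniforms:
                    uniforms = rng.random(CHUNK).tolist()
                if uniforms.pop() < p_pause:
                    pending_freeze = int(round(rng.exponential(mu) / dt))
                    ramp_down = ramp

        desired = math.atan2(wy - y, wx - x)
        delta = (desired - heading + math.pi) % (2.0 * math.pi) - math.pi
        if delta > max_turn:
            delta = max_turn
        elif delta < -max_turn:
            delta = -max_turn
        heading += delta

        if sigma > 0:
            if not normals:
                normals = rng.standard_normal(CHUNK).tolist()
            noise_sd = sigma * DETOUR_NOISE_BOOST if burst else sigma
            step_dir = heading + noise_sd * normals.pop()
        else:
            step_dir = heading

        s = v * dt * factor * (DETOUR_SPEED_BOOST if burst else 1.0)
        x += s * math.cos(step_dir)
        y += s * math.sin(step_dir)
        # boundary reflection keeps samples inside the arena
        if x < 0.0:
            x = -x
        elif x > w:
            x = 2.0 * w - x
        if y < 0.0:
            y = -y
        elif y > d:
            y = 2.0 * d - y

        xs.append(x)
        ys.append(y)

        rad = arrive_burst if burst else arrive
        if (x - wx) * (x - wx) + (y - wy) * (y - wy) <= rad * rad:
            wi += 1
            if wi >= len(route):
                break
            wx, wy, burst = route[wi]

    t = np.arange(len(xs)) * dt
    return Trajectory(participant_id, group, t, np.column_stack([xs, ys]),
                      nominal_rate_hz=arena.rate_hz)


def generate_response_record(
    params: PhenotypeParams, layout: RoomLayout | None = None, seed: int = 0
) -> ResponseRecord:
    """Draw one participant's subtest answers at the phenotype's accuracies."""
    layout = layout or default_layout()
    rng = np.random.default_rng(seed)
    acc = params.subtest_accuracies

    prospective = tuple(bool(rng.random() < acc["prospective"]) for _ in range(3))

    recalled = tuple(name for name, _ in layout.items
                     if rng.random() < acc["item_recall"])

    non_hiding = [s for s in layout.sections if s not in layout.hiding_sections]
    marked = []
    for name, _ in layout.items:
        if rng.random() < acc["place_recall"]:
            marked.append(layout.item_assignments[name])
        elif rng.random() < 0.5:  # commission error: sticker on an empty section
            marked.append(non_hiding[rng.integers(len(non_hiding))])

    choices = []
    for k, (name, _) in enumerate(layout.items):
        if rng.random() < acc["recognition"]:
            choices.append(name)
        else:
            distractors = [o for o in layout.recognition_options[k] if o != name]
            choices.append(distractors[rng.integers(len(distractors))])

    matching = tuple(bool(rng.random() < acc["matching"]) for _ in range(9))

    return ResponseRecord(
        prospective_actions=prospective,
        recalled_items=recalled,
        marked_sections=tuple(marked),
        recognition_choices=tuple(choices),
        matching_reached=matching,
    )


def generate_cohort(
    n_ad: int,
    n_amci: int,
    n_nc: int,
    seed: int = 0,
    layout: RoomLayout | None = None,
    phenotypes: dict[str, PhenotypeParams] | None = None,
) -> CohortBundle:
    """Simulate a full cohort: one trajectory + response record per participant.

    Participant ``i`` (counting AD first, then aMCI, then NC) uses trajectory
    seed ``seed + i`` and response seed ``seed + i + RESPONSE_SEED_OFFSET``,
    so extending a cohort never reshuffles earlier participants.
    """
    if min(n_ad, n_amci, n_nc) < 0:
        raise ValidationError("group sizes must be >= 0")
    if n_ad + n_amci + n_nc == 0:
        raise ValidationError("cannot generate an empty cohort")
    layout = layout or default_layout()
    phenotypes = phenotypes or default_phenotypes()

    trajectories: dict[str, Trajectory] = {}
    responses: dict[str, ResponseRecord] = {}
    i = 0
    for group, n in (("AD", n_ad), ("aMCI", n_amci), ("NC", n_nc)):
        params = phenotypes[group]
        for k in range(n):
            pid = f"{group}{k + 1:03d}"
            trajectories[pid] = generate_trajectory(
                params, layout, layout.arena, seed=seed + i,
                participant_id=pid, group=group)
            responses[pid] = generate_response_record(
                params, layout, seed=seed + i + RESPONSE_SEED_OFFSET)
            i += 1
    return CohortBundle(trajectories, responses, layout, seed)
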