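"""Synthetic cohorts, behaviour, masks and z-stacks with known ground truth.

Every downstream stage of the pipeline (trial coding, affected/unaffected
classification, masked-intensity quantification, box-counting morphometry,
the statistical battery) is exercised against data produced here, so each
generator carries its ground truth alongside its output: the latent
affected state of every rat, the planted per-compartment median intensity
of every z-stack, and the construction parameters of every cell mask.

Behavioural measures use over-dispersed positive families — negative
binomial for counts, log-normal for dwell times — which is the simplest
structure matching foraging behaviour on the maze. The latent *affected*
phenotype multiplies atrium dwell, end-of-arm dwell and stretch-attend
rates; the multiplier tapers linearly from its day-1 value back to baseline
at day 21, so that rats meeting the classification criterion early may stop
meeting it in the third week.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage import draw as _draw
from skimage import morphology as _morph

from .maze import BehaviouralEvent, MazeConfig, TrialRecord

__all__ = [
    "GROUPS",
    "CohortConfig",
    "EffectProfile",
    "RatTimeline",
    "simulate_cohort",
    "simulate_sensory_motor",
    "MorphParams",
    "generate_microglia_mask",
    "generate_fractal_fixture",
    "PlantedCell",
    "ZStackPlan",
    "SyntheticZStack",
    "generate_zstack",
]

GROUPS = ("sham_vehicle", "sham_minocycline", "cci_vehicle", "cci_minocycline")


class ConfigurationError(ValueError):
    """Raised for non-finite or out-of-range generator parameters."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort structure: four surgery × treatment groups.

    Default sizes 9 / 7 / 37 / 21 and a 22 % latent affected prevalence in
    the vehicle-treated nerve-injured group reflect the study design this
    pipeline re-implements; minocycline-treated and sham rats default to a
    zero prevalence.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: {
        "sham_vehicle": 9, "sham_minocycline": 7,
        "cci_vehicle": 37, "cci_minocycline": 21,
    })
    p_affected: dict[str, float] = field(default_factory=lambda: {
        "sham_vehicle": 0.0, "sham_minocycline": 0.0,
        "cci_vehicle": 0.22, "cci_minocycline": 0.0,
    })
    n_days_post: int = 21
    seed: int = 0

    def __post_init__(self) -> None:
        _check(set(self.group_sizes) <= set(GROUPS), f"groups must be among {GROUPS}")
        for g, n in self.group_sizes.items():
            _check(isinstance(n, (int, np.integer)) and n >= 0,
                   f"group size for {g} must be a non-negative integer")
        for g, p in self.p_affected.items():
            _check(g in GROUPS and math.isfinite(p) and 0.0 <= p <= 1.0,
                   f"p_affected[{g}] must be in [0, 1]")
        _check(self.n_days_post >= 1, "n_days_post must be >= 1")


@dataclass(frozen=True)
class EffectProfile:
    """Generative parameters for one rat-day maze trial.

    Rates are per arm entry unless stated; durations are seconds. Log-normal
    distributions are parameterised by their median and log-space sigma.
    ``affected_multiplier`` is the day-1 factor applied to atrium dwell,
    end-of-arm dwell and the stretch-attend rate of latently affected rats;
    it decays linearly to 1 at ``affected_baseline_day``.
    """

    entries_mean: float = 16.0
    entries_dispersion: float = 8.0
    atrium_dwell_median_s: float = 6.0
    atrium_dwell_sigma: float = 0.35
    arm_time_median_s: float = 6.0
    arm_time_sigma: float = 0.30
    end_of_arm_prob: float = 0.7
    end_of_arm_median_s: float = 3.0
    end_of_arm_sigma: float = 0.40
    nose_poke_rate: float = 0.3
    sap_rate: float = 0.15
    groom_rate_per_trial: float = 2.0
    groom_median_s: float = 5.0
    rear_rate_per_trial: float = 2.0
    rear_median_s: float = 4.0
    climb_rate_per_trial: float = 0.5
    climb_median_s: float = 4.0
    unbaited_choice_rate: float = 0.45
    revisit_rate: float = 0.25
    pellet_omission_prob: float = 0.10
    rat_trait_sigma: float = 0.12
    affected_multiplier: float = 6.0
    affected_baseline_day: int = 21
    #: emit one sham-minocycline rat with no pellet seeking (exclusion path)
    include_non_forager: bool = False

    def __post_init__(self) -> None:
        for name in ("end_of_arm_prob", "unbaited_choice_rate", "revisit_rate",
                     "pellet_omission_prob"):
            v = getattr(self, name)
            _check(math.isfinite(v) and 0.0 <= v <= 1.0, f"{name} must be in [0, 1]")
        for name in ("entries_mean", "entries_dispersion", "atrium_dwell_median_s",
                     "atrium_dwell_sigma", "arm_time_median_s", "arm_time_sigma",
                     "end_of_arm_median_s", "end_of_arm_sigma", "groom_median_s",
                     "rear_median_s", "climb_median_s"):
            v = getattr(self, name)
            _check(math.isfinite(v) and v > 0, f"{name} must be > 0")
        for name in ("nose_poke_rate", "sap_rate", "groom_rate_per_trial",
                     "rear_rate_per_trial", "climb_rate_per_trial", "rat_trait_sigma"):
            v = getattr(self, name)
            _check(math.isfinite(v) and v >= 0, f"{name} must be >= 0")
        _check(self.affected_multiplier >= 1.0, "affected_multiplier must be >= 1")
        _check(self.affected_baseline_day > 1, "affected_baseline_day must be > 1")

    def multiplier_on_day(self, day: int) -> float:
        """Affected-effect multiplier on a post-surgery day (linear taper)."""
        frac = max(0.0, (self.affected_baseline_day - day)
                   / (self.affected_baseline_day - 1))
        return 1.0 + (self.affected_multiplier - 1.0) * frac


@dataclass(frozen=True)
class RatTimeline:
    rat_id: str
    group: str
    affected: bool
    trials: tuple[TrialRecord, ...]


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(median * math.exp(sigma * rng.standard_normal()))


def _simulate_trial(
    rng: np.random.Generator,
    rat_id: str,
    group: str,
    day: int,
    effects: EffectProfile,
    maze: MazeConfig,
    trait: float,
    mult: float,
    forager: bool = True,
) -> TrialRecord:
    events: list[BehaviouralEvent] = []
    t = 0.0
    budget = maze.trial_duration_s

    def emit(event_type: str, duration: float, arm: int | None = None,
             pellet_eaten: bool = False) -> bool:
        nonlocal t
        if t >= budget:
            return False
        duration = min(duration, budget - t)
        events.append(BehaviouralEvent(event_type=event_type, t_start_s=t,
                                       duration_s=duration, arm=arm,
                                       pellet_eaten=pellet_eaten))
        t += duration
        return True

    if not forager:
        # sits in the atrium for the whole trial, never enters an arm
        emit("atrium_dwell", budget)
        return TrialRecord(rat_id=rat_id, group=group, day=day,
                           events=tuple(events))

    n_entries = int(rng.negative_binomial(
        effects.entries_dispersion,
        effects.entries_dispersion / (effects.entries_dispersion + effects.entries_mean),
    ))
    n_entries = max(1, n_entries)

    # per-trial comfort behaviours, interleaved before randomly chosen entries
    extras: list[tuple[int, str, float]] = []
    for etype, rate, med in (("groom", effects.groom_rate_per_trial, effects.groom_median_s),
                             ("rear", effects.rear_rate_per_trial, effects.rear_median_s),
                             ("climb", effects.climb_rate_per_trial, effects.climb_median_s)):
        for _ in range(rng.poisson(rate)):
            extras.append((int(rng.integers(0, n_entries)), etype,
                           _lognormal(rng, med, 0.4)))
    extras.sort(key=lambda x: x[0])

    visited: set[int] = set()
    arms = list(range(1, maze.n_arms + 1))
    baited = set(maze.baited_arms)
    for i in range(n_entries):
        while extras and extras[0][0] <= i:
            _, etype, dur = extras.pop(0)
            if not emit(etype, dur):
                break
        dwell = _lognormal(rng, effects.atrium_dwell_median_s * trait * mult,
                           effects.atrium_dwell_sigma)
        if not emit("atrium_dwell", dwell):
            break
        # risk-assessment behaviours performed from the atrium
        probe_arm = int(rng.choice(arms))
        for _ in range(rng.poisson(effects.nose_poke_rate)):
            if not emit("nose_poke", _lognormal(rng, 1.0, 0.3), arm=probe_arm):
                break
        for _ in range(rng.poisson(effects.sap_rate * mult)):
            if not emit("stretch_attend", _lognormal(rng, 1.5, 0.3), arm=probe_arm):
                break
        if t >= budget:
            break
        # arm choice: revisit vs novel pool, then unbaited-vs-baited bias
        pool = list(visited) if (visited and rng.random() < effects.revisit_rate) \
            else [a for a in arms if a not in visited] or arms
        unbaited_pool = [a for a in pool if a not in baited]
        baited_pool = [a for a in pool if a in baited]
        if unbaited_pool and (not baited_pool or rng.random() < effects.unbaited_choice_rate):
            arm = int(rng.choice(unbaited_pool))
        else:
            arm = int(rng.choice(baited_pool or pool))
        first = arm not in visited
        ate = (arm in baited and first
               and rng.random() >= effects.pellet_omission_prob)
        visited.add(arm)
        if not emit("arm_entry", _lognormal(rng, effects.arm_time_median_s,
                                            effects.arm_time_sigma),
                    arm=arm, pellet_eaten=ate):
            break
        if rng.random() < effects.end_of_arm_prob:
            if not emit("end_of_arm_dwell",
                        _lognormal(rng, effects.end_of_arm_median_s * mult,
                                   effects.end_of_arm_sigma), arm=arm):
                break
    return TrialRecord(rat_id=rat_id, group=group, day=day, events=tuple(events))


def simulate_cohort(
    config: CohortConfig,
    effects: EffectProfile | None = None,
    maze: MazeConfig | None = None,
) -> list[RatTimeline]:
    """Simulate one maze trial per rat per post-surgery day.

    Latent affected states are drawn i.i.d. with each group's ``p_affected``;
    the returned timelines carry the state so classifier recovery can be
    scored against ground truth. Reproducible given ``config.seed``.
    """
    effects = effects or EffectProfile()
    maze = maze or MazeConfig()
    rng = np.random.default_rng(config.seed)
    timelines: list[RatTimeline] = []
    non_forager_assigned = False
    for group in GROUPS:
        n = config.group_sizes.get(group, 0)
        p_aff = config.p_affected.get(group, 0.0)
        for i in range(n):
            rat_id = f"{group}_{i + 1:02d}"
            affected = bool(rng.random() < p_aff)
            trait = math.exp(effects.rat_trait_sigma * rng.standard_normal())
            forager = True
            if (effects.include_non_forager and group == "sham_minocycline"
                    and not non_forager_assigned):
                forager, non_forager_assigned = False, True
            trials = tuple(
                _simulate_trial(
                    rng, rat_id, group, day, effects, maze, trait,
                    effects.multiplier_on_day(day) if affected else 1.0,
                    forager=forager,
                )
                for day in range(1, config.n_days_post + 1)
            )
            timelines.append(RatTimeline(rat_id=rat_id, group=group,
                                         affected=affected, trials=trials))
    return timelines


# ---------------------------------------------------------------------------
# sensory / motor tables

#: default test days: 0 = pre-surgery baseline, then five post-surgery days
SENSORY_TEST_DAYS = (0, 3, 7, 11, 15, 19)

AESTHESIOMETER_CEILING_G = 50.0
ROTAROD_CEILING_S = 180.0


def simulate_sensory_motor(
    config: CohortConfig,
    test_days: tuple[int, ...] = SENSORY_TEST_DAYS,
    withdrawal_baseline_g: float = 35.0,
    withdrawal_cci_g: float = 12.0,
    withdrawal_cci_minocycline_g: float = 22.0,
    withdrawal_sd_g: float = 4.0,
    rotarod_baseline_s: float = 110.0,
    rotarod_cci_s: float = 70.0,
    rotarod_sd_s: float = 15.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-rat withdrawal thresholds (mean of 5 replicates, both paws) and
    rotarod latencies (mean of 3 trials).

    Nerve-injured groups drop on the ipsilateral paw after day 0; oral
    minocycline partially attenuates the drop; the contralateral paw and
    sham groups are stable. Thresholds are clipped to (0, 50] g, the ramp
    ceiling of the aesthesiometer; latencies to (0, 180] s.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 101)))
    sens_rows, motor_rows = [], []
    for group in GROUPS:
        injured = group.startswith("cci")
        ipsi_post = (withdrawal_cci_minocycline_g if group == "cci_minocycline"
                     else withdrawal_cci_g) if injured else withdrawal_baseline_g
        rota_post = rotarod_cci_s if injured else rotarod_baseline_s
        for i in range(config.group_sizes.get(group, 0)):
            rat_id = f"{group}_{i + 1:02d}"
            for day in test_days:
                post = day > 0
                for side, mean in (("ipsilateral", ipsi_post if post else withdrawal_baseline_g),
                                   ("contralateral", withdrawal_baseline_g)):
                    reps = mean + withdrawal_sd_g * rng.standard_normal(5)
                    reps = np.clip(reps, 0.5, AESTHESIOMETER_CEILING_G)
                    sens_rows.append({"rat_id": rat_id, "group": group, "day": day,
                                      "side": side,
                                      "threshold_g": float(reps.mean())})
                trials = (rota_post if post else rotarod_baseline_s) \
                    + rotarod_sd_s * rng.standard_normal(3)
                trials = np.clip(trials, 1.0, ROTAROD_CEILING_S)
                motor_rows.append({"rat_id": rat_id, "group": group, "day": day,
                                   "latency_s": float(trials.mean())})
    return pd.DataFrame(sens_rows), pd.DataFrame(motor_rows)


# ---------------------------------------------------------------------------
# microglia masks

class GenerationError(RuntimeError):
    """Raised when a requested cell cannot fit its canvas."""


@dataclass(frozen=True)
class MorphParams:
    """Construction parameters for one synthetic microglial silhouette.

    ``branch_depth`` controls the number of bifurcation levels; the radial
    reach of the arbor is held fixed so that deeper trees subdivide into
    more, finer branches and generated geometric complexity (box-counting
    dimension) increases monotonically with depth.
    """

    cell_kind: str = "ramified"
    branch_depth: int = 3
    branch_length: float = 90.0  # total radial reach of the arbor, px
    branch_thickness: int = 1
    soma_radius: float = 6.0
    canvas: tuple[int, int] = (256, 256)
    n_primary: tuple[int, int] = (4, 7)  # inclusive-exclusive range
    length_decay: float = 0.7
    branch_angle: float = 0.7

    def __post_init__(self) -> None:
        _check(self.cell_kind in ("ramified", "amoeboid"),
               "cell_kind must be 'ramified' or 'amoeboid'")
        _check(self.branch_depth >= 0, "branch_depth must be >= 0")
        _check(self.branch_length >= 0, "branch_length must be >= 0")
        _check(self.branch_thickness >= 0, "branch_thickness must be >= 0")
        _check(self.soma_radius > 0, "soma_radius must be > 0")
        _check(0 < self.length_decay < 1, "length_decay must be in (0, 1)")
        reach = self.soma_radius + (self.branch_length if self.branch_depth else 0)
        if 2 * reach + 4 > min(self.canvas):
            raise GenerationError(
                f"cell reach {reach:.0f}px exceeds canvas {self.canvas}")


def generate_microglia_mask(
    params: MorphParams, rng: np.random.Generator | int | None = None
) -> tuple[np.ndarray, dict]:
    """Draw one cell as a single 8-connected boolean component.

    Returns the mask and a ground-truth descriptor ``{kind, branch_depth}``.
    """
    rng = np.random.default_rng(rng)
    h, w = params.canvas
    img = np.zeros((h, w), dtype=bool)
    cy, cx = h // 2, w // 2
    rr, cc = _draw.disk((cy, cx), params.soma_radius, shape=img.shape)
    img[rr, cc] = True

    if params.cell_kind == "amoeboid":
        # compact blob: soma plus a few short lobes
        for _ in range(params.branch_depth):
            ang = rng.uniform(0, 2 * math.pi)
            r = params.soma_radius * 0.5
            oy = cy + (params.soma_radius * 0.7) * math.sin(ang)
            ox = cx + (params.soma_radius * 0.7) * math.cos(ang)
            rr, cc = _draw.disk((oy, ox), r, shape=img.shape)
            img[rr, cc] = True
        return img, {"kind": "amoeboid", "branch_depth": params.branch_depth}

    depth = params.branch_depth
    if depth > 0 and params.branch_thickness > 0:
        f = params.length_decay
        level0 = params.branch_length * (1 - f) / (1 - f ** depth)
        selem = (_morph.disk(params.branch_thickness // 2)
                 if params.branch_thickness > 1 else None)

        def grow(y: float, x: float, ang: float, length: float, d: int) -> None:
            if d == 0 or length < 2:
                return
            y2, x2 = y + length * math.sin(ang), x + length * math.cos(ang)
            rr, cc = _draw.line(round(y), round(x), round(y2), round(x2))
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            if selem is not None:
                seg = np.zeros_like(img)
                seg[rr[ok], cc[ok]] = True
                img[:] |= _morph.dilation(seg, selem)
            else:
                img[rr[ok], cc[ok]] = True
            for k in (0, 1):
                da = rng.normal(0, 0.35) + (params.branch_angle if k else -params.branch_angle)
                grow(y2, x2, ang + da, length * f, d - 1)

        n_primary = int(rng.integers(*params.n_primary))
        for i in range(n_primary):
            ang = 2 * math.pi * i / n_primary + rng.normal(0, 0.2)
            grow(cy, cx, ang, level0 * (1 + rng.normal(0, 0.08)), depth)
    return img, {"kind": "ramified", "branch_depth": depth}


# ---------------------------------------------------------------------------
# analytic fractal fixtures (oracle inputs for box counting)

def generate_fractal_fixture(kind: str, size: int = 256, depth: int | None = None
                             ) -> np.ndarray:
    """Deterministic binary constructions with known fractal dimension.

    ``line`` (D=1), ``filled_square`` (D=2), ``disc`` (D=2),
    ``sierpinski_triangle`` (D=log3/log2, recursive midpoint removal on a
    right-triangle lattice; at depth d the mask is 2^d wide with 3^d
    foreground pixels) and ``koch_curve`` (D=log4/log3, segment
    substitution).
    """
    if kind in ("line", "filled_square", "disc") and size < 2:
        raise ValueError("size must be >= 2")
    if kind == "line":
        m = np.zeros((3, size + 4), dtype=bool)
        m[1, 2:2 + size] = True
        return m
    if kind == "filled_square":
        m = np.zeros((size + 4, size + 4), dtype=bool)
        m[2:2 + size, 2:2 + size] = True
        return m
    if kind == "disc":
        r = size // 2
        m = np.zeros((2 * r + 5, 2 * r + 5), dtype=bool)
        rr, cc = _draw.disk((r + 2, r + 2), r, shape=m.shape)
        m[rr, cc] = True
        return m
    if kind == "sierpinski_triangle":
        d = 7 if depth is None else depth
        if d < 0:
            raise ValueError("depth must be >= 0")
        m = np.ones((1, 1), dtype=bool)
        for _ in range(d):
            z = np.zeros_like(m)
            m = np.block([[m, z], [m, m]])
        return m
    if kind == "koch_curve":
        d = 4 if depth is None else depth
        pts = [(0.0, 0.0), (1.0, 0.0)]
        for _ in range(d):
            new = [pts[0]]
            for (x1, y1), (x2, y2) in zip(pts[:-1], pts[1:]):
                dx, dy = (x2 - x1) / 3, (y2 - y1) / 3
                ax, ay = x1 + dx, y1 + dy
                bx, by = x1 + 2 * dx, y1 + 2 * dy
                # apex of the replaced middle third
                mx = (ax + bx) / 2 - (by - ay) * math.sqrt(3) / 2
                my = (ay + by) / 2 + (bx - ax) * math.sqrt(3) / 2
                new.extend([(ax, ay), (mx, my), (bx, by), (x2, y2)])
            pts = new
        arr = np.asarray(pts)
        arr -= arr.min(axis=0)
        scale = (size - 1) / arr[:, 0].max()
        arr *= scale
        h = int(arr[:, 1].max()) + 3
        m = np.zeros((h, size + 2), dtype=bool)
        for (x1, y1), (x2, y2) in zip(arr[:-1], arr[1:]):
            rr, cc = _draw.line(round(y1) + 1, round(x1) + 1,
                                round(y2) + 1, round(x2) + 1)
            m[rr, cc] = True
        return m
    raise ValueError(f"unsupported fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# synthetic multi-channel z-stacks

MASK_ROLES = ("NeuN", "IBA1", "GFAP", "DAPI")


@dataclass(frozen=True)
class PlantedCell:
    """One planted cell: a disc in a mask channel with a known target level."""

    center: tuple[int, int]
    radius: float
    compartment: str  # which mask role the cell belongs to, e.g. "IBA1"
    target_intensity: float
    nucleus_radius: float | None = None  # adds a DAPI disc when set


@dataclass(frozen=True)
class ZStackPlan:
    shape: tuple[int, int] = (128, 128)
    n_planes: int = 3
    channel_roles: tuple[str, ...] = ("IBA1", "DAPI", "target")
    cells: tuple[PlantedCell, ...] = ()
    mask_level: float = 200.0
    background: float = 0.0
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        _check(self.n_planes >= 2, "z-stack needs >= 2 planes so projection is exercised")
        roles = list(self.channel_roles)
        _check(roles.count("target") == 1, "exactly one target channel required")
        _check(any(r in MASK_ROLES for r in roles),
               "at least one mask-role channel (NeuN/IBA1/GFAP/DAPI) required")
        _check(len(set(roles)) == len(roles), "duplicate channel roles")
        for c in self.cells:
            _check(c.compartment in roles, f"cell compartment {c.compartment!r} "
                                           "has no matching channel")


@dataclass(frozen=True)
class SyntheticZStack:
    """Planes ``(z, channel, h, w)`` plus construction ground truth."""

    planes: np.ndarray
    channel_roles: dict[int, str]
    truth_masks: dict[str, np.ndarray]      # per mask role, 2-D boolean
    truth_medians: dict[str, float]         # per compartment, target median


def generate_zstack(plan: ZStackPlan,
                    rng: np.random.Generator | int | None = None) -> SyntheticZStack:
    """Materialise a plan into a stack with known per-compartment medians.

    The full target intensity of each cell is placed on one z-plane and half
    on the others, so a maximum projection is required to recover it. With
    zero planted cells the mask channels are empty and downstream
    quantification must flag the empty mask.
    """
    rng = np.random.default_rng(rng)
    h, w = plan.shape
    n_ch = len(plan.channel_roles)
    roles = {i: r for i, r in enumerate(plan.channel_roles)}
    ch_index = {r: i for i, r in roles.items()}

    masks = {r: np.zeros((h, w), dtype=bool) for r in plan.channel_roles
             if r in MASK_ROLES}
    target2d = np.full((h, w), plan.background, dtype=float)
    for cell in plan.cells:
        if not plan.cells:
            break
        rr, cc = _draw.disk(cell.center, cell.radius, shape=(h, w))
        masks[cell.compartment][rr, cc] = True
        target2d[rr, cc] = cell.target_intensity
        if cell.nucleus_radius and "DAPI" in masks:
            rr, cc = _draw.disk(cell.center, cell.nucleus_radius, shape=(h, w))
            masks["DAPI"][rr, cc] = True

    planes = np.zeros((plan.n_planes, n_ch, h, w), dtype=float)
    bright_z = 0
    for z in range(plan.n_planes):
        frac = 1.0 if z == bright_z else 0.5
        for r, idx in ch_index.items():
            if r == "target":
                planes[z, idx] = target2d * frac
            else:
                planes[z, idx] = np.where(masks[r], plan.mask_level * frac, 0.0)
        if plan.noise_sigma > 0:
            planes[z] += rng.normal(0, plan.noise_sigma, size=(n_ch, h, w))
    planes = np.clip(planes, 0, None)

    truth_medians = {}
    for r, m in masks.items():
        if r == "DAPI":
            continue
        if m.any():
            truth_medians[r] = float(np.median(target2d[m]))
    if not plan.cells:
        warnings.warn("z-stack plan has zero planted cells; masks are empty",
                      stacklevel=2)
    return SyntheticZStack(planes=planes, channel_roles=roles,
                           truth_masks=masks, truth_medians=truth_medians)


def cohort_effects_null() -> EffectProfile:
    """An effect profile with no latent phenotype effect (multiplier 1)."""
    return replace(EffectProfile(), affected_multiplier=1.0)
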