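"""Synthetic study generator.

Emulates a within-subjects object-lifting experiment: every participant
lifts four cylinders (2 sizes x 2 masses) in a *real* and a *virtual*
(head-mounted-display) condition, rates felt heaviness on an open magnitude
scale after each lift, has wrist and object positions tracked at 90 Hz, and
answers a six-item presence questionnaire after the virtual block.

The generative rating model is deliberately the same linear form the
analysis fits — ``rating = b0 + bW * mass + bV * volume + noise`` with
participant-level coefficient heterogeneity — so slope recovery is exact in
the noise-free limit and calibrated effect sizes can be injected through
the ``bV`` condition offsets.  Reaches and lifts follow minimum-jerk
displacement profiles, the standard smooth-movement model for point-to-point
reaching, with Gaussian tracker jitter added per axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .objects import (
    ObjectSpec,
    TEST_OBJECT_LABELS,
    WASHOUT_LABEL,
    make_object_set,
)

CONDITIONS = ("real", "virtual")
N_WASHOUT = 5
N_TEST = 32

# Four fixed pseudo-random test orders (indices into TEST_OBJECT_LABELS);
# each object appears 8 times and never more than twice in a row.
TRIAL_ORDERS: tuple[tuple[int, ...], ...] = (
    (1, 0, 3, 1, 0, 3, 3, 1, 1, 2, 3, 2, 3, 2, 1, 1,
     0, 0, 1, 2, 2, 3, 0, 0, 1, 3, 0, 2, 2, 3, 0, 2),
    (0, 1, 2, 2, 3, 3, 2, 3, 0, 1, 3, 2, 1, 3, 2, 3,
     0, 3, 0, 1, 1, 0, 1, 1, 0, 2, 0, 1, 2, 0, 2, 3),
    (0, 2, 3, 2, 2, 1, 3, 3, 0, 3, 0, 1, 0, 0, 2, 3,
     1, 1, 0, 1, 3, 2, 3, 1, 3, 0, 2, 1, 2, 1, 2, 0),
    (3, 3, 2, 1, 0, 1, 0, 0, 2, 0, 2, 0, 2, 3, 1, 1,
     3, 3, 1, 2, 2, 1, 2, 3, 3, 0, 3, 0, 1, 1, 2, 0),
)

RATING_FLOOR = 1e-6


@dataclass
class RatingModel:
    """Linear heaviness-rating generator, participant-heterogeneous.

    Coefficient units: ``beta0`` in rating units, ``betaW`` in rating units
    per gram of lifted mass, ``betaV`` in rating units per cm^3 of volume.
    The implied illusion strength is ``-betaV/betaW`` grams per cm^3
    (0.20 g/cm^3 at the defaults).  ``condition_deltas`` shifts the betaV
    mean per condition and is the hook for injecting a real-vs-virtual
    difference; ``betaV_condition_sd`` is participant-by-condition scatter
    of betaV, the main source of between-participant spread in the
    per-condition illusion scores.
    """

    beta0_mean: float = 20.0
    betaW_mean: float = 0.1
    betaV_mean: float = -0.02
    beta0_sd: float = 5.0
    betaW_sd: float = 0.005
    betaV_sd: float = 0.002
    betaV_condition_sd: float = 0.0079
    residual_sd: float = 3.0
    condition_deltas: dict[str, float] = field(
        default_factory=lambda: {"real": 0.0, "virtual": 0.0}
    )

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")
        for sd in (self.beta0_sd, self.betaW_sd, self.betaV_sd, self.betaV_condition_sd):
            if sd < 0:
                raise ValueError("coefficient SDs must be non-negative")


@dataclass
class KinematicModel:
    """Minimum-jerk reach/lift trajectory generator.

    ``reach_duration_s`` is per condition: the virtual default is slower so
    that peak reach velocity (1.875 * amplitude / duration) differs by about
    100 mm/s between conditions, the size of difference typical of guarded
    reaching under a head-mounted display.
    """

    reach_amplitude_mm: float = 300.0
    reach_duration_s: dict[str, float] = field(
        default_factory=lambda: {"real": 0.75, "virtual": 0.865}
    )
    reach_duration_between_sd_s: float = 0.05
    reach_duration_cond_sd_s: float = 0.067
    reach_duration_trial_sd_s: float = 0.03
    lift_height_mm: float = 100.0
    lift_duration_s: float = 0.5
    lower_duration_s: float = 0.5
    pre_delay_s: float = 0.3
    grasp_dwell_s: float = 0.4
    post_delay_s: float = 0.3
    position_noise_sd_mm: float = 0.3

    def __post_init__(self) -> None:
        if self.reach_amplitude_mm <= 0:
            raise ValueError("reach amplitude must be positive")
        if any(d <= 0 for d in self.reach_duration_s.values()):
            raise ValueError("reach durations must be positive")
        if self.lift_duration_s <= 0 or self.lift_height_mm <= 0:
            raise ValueError("lift parameters must be positive")
        if self.position_noise_sd_mm < 0:
            raise ValueError("position noise SD must be non-negative")


@dataclass
class PresenceModel:
    """Latent-normal presence questionnaire generator.

    Each participant has a latent presence level on the 1-7 item scale;
    the six items are the latent level plus item noise, cut into the
    integer categories.  ``association_slope`` (latent units per SD of the
    participant's virtual-condition volume slope betaV) couples presence to
    illusion strength: a positive slope means higher presence goes with a
    *less* negative betaV, i.e. a smaller illusion.
    """

    latent_mean: float = 5.0
    latent_sd: float = 1.0
    item_sd: float = 0.8
    association_slope: float = 0.55

    def __post_init__(self) -> None:
        if self.latent_sd < 0 or self.item_sd < 0:
            raise ValueError("presence SDs must be non-negative")


@dataclass
class StudyConfig:
    """Full configuration of one synthetic study."""

    n_participants: int = 25
    seed: int = 0
    sampling_rate_hz: float = 90.0
    hold_duration_s: float = 2.0
    counterbalance: bool = True
    rating_model: RatingModel = field(default_factory=RatingModel)
    kinematic_model: KinematicModel = field(default_factory=KinematicModel)
    presence_model: PresenceModel = field(default_factory=PresenceModel)

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.hold_duration_s <= 0:
            raise ValueError("hold duration must be positive")


# stage offsets for sub-generators so stages can be regenerated independently
_STAGE_SEEDS = {"coefs": 1, "ratings": 2, "streams": 3, "presence": 4}


def _stage_rng(config: StudyConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([_STAGE_SEEDS[stage], int(config.seed)])


def make_schedule(config: StudyConfig) -> pd.DataFrame:
    """Build trial slots for every participant.

    Per participant: two condition blocks (order counterbalanced, odd
    participant ids real-first), each with 5 washout lifts of the medium
    cylinder followed by 32 test lifts in one of the four fixed
    pseudo-random orders, assigned cyclically by participant index.
    """
    rows = []
    for p in range(1, config.n_participants + 1):
        real_first = (p % 2 == 1) if config.counterbalance else True
        conds = ("real", "virtual") if real_first else ("virtual", "real")
        order = TRIAL_ORDERS[(p - 1) % len(TRIAL_ORDERS)]
        for cond in conds:
            for i in range(N_WASHOUT):
                rows.append((p, cond, i + 1, "washout", WASHOUT_LABEL))
            for i, obj_idx in enumerate(order):
                rows.append(
                    (p, cond, N_WASHOUT + i + 1, "test", TEST_OBJECT_LABELS[obj_idx])
                )
    return pd.DataFrame(
        rows, columns=["participant_id", "condition", "trial_index", "phase", "object"]
    )


def draw_participant_coefficients(config: StudyConfig) -> pd.DataFrame:
    """Draw per-participant, per-condition rating coefficients.

    Returns one row per participant x condition with columns
    ``beta0``, ``betaW``, ``betaV`` (the realised condition-specific volume
    slope) and the implied ``true_swi`` = -betaV/betaW.
    """
    rm = config.rating_model
    rng = _stage_rng(config, "coefs")
    n = config.n_participants
    beta0 = rng.normal(rm.beta0_mean, rm.beta0_sd, n)
    betaW = rng.normal(rm.betaW_mean, rm.betaW_sd, n)
    betaV = rng.normal(rm.betaV_mean, rm.betaV_sd, n)
    rows = []
    for i, p in enumerate(range(1, n + 1)):
        for cond in CONDITIONS:
            bv = (
                betaV[i]
                + rm.condition_deltas.get(cond, 0.0)
                + rng.normal(0.0, rm.betaV_condition_sd)
            )
            rows.append((p, cond, beta0[i], betaW[i], bv, -bv / betaW[i]))
    return pd.DataFrame(
        rows,
        columns=["participant_id", "condition", "beta0", "betaW", "betaV", "true_swi"],
    )


def simulate_ratings(
    config: StudyConfig,
    schedule: pd.DataFrame | None = None,
    objects: Iterable[ObjectSpec] | None = None,
    coefficients: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Generate the heaviness-rating table.

    rating = beta0 + betaW * total_mass + betaV * volume + N(0, residual_sd),
    floored at a small positive value to respect the open positive scale.
    """
    rm = config.rating_model
    if schedule is None:
        schedule = make_schedule(config)
    if objects is None:
        objects = make_object_set()
    if coefficients is None:
        coefficients = draw_participant_coefficients(config)
    omap = {o.label: o for o in objects}
    rng = _stage_rng(config, "ratings")

    coef = coefficients.set_index(["participant_id", "condition"])
    mass = schedule["object"].map(lambda l: omap[l].total_mass_g).to_numpy()
    vol = schedule["object"].map(lambda l: omap[l].volume_cm3).to_numpy()
    idx = pd.MultiIndex.from_frame(schedule[["participant_id", "condition"]])
    b0 = coef["beta0"].reindex(idx).to_numpy()
    bw = coef["betaW"].reindex(idx).to_numpy()
    bv = coef["betaV"].reindex(idx).to_numpy()
    noise = rng.normal(0.0, rm.residual_sd, len(schedule)) if rm.residual_sd > 0 else 0.0
    rating = np.maximum(b0 + bw * mass + bv * vol + noise, RATING_FLOOR)

    out = schedule.copy()
    out["rating"] = rating
    return out


def minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Normalised minimum-jerk displacement 10*tau^3 - 15*tau^4 + 6*tau^5."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def simulate_stream(
    config: StudyConfig,
    trial_id: str,
    condition: str,
    rng: np.random.Generator | None = None,
    reach_duration_s: float | None = None,
) -> pd.DataFrame:
    """Generate one trial's 90 Hz wrist/object position stream.

    Timeline: still hand at the start position; minimum-jerk reach (x axis)
    to the object; grasp dwell; minimum-jerk lift (z axis) of wrist and
    object together; 2 s hold; minimum-jerk lower; final still period.
    The object is stationary until lift onset.  Independent Gaussian noise
    is added per axis to both trackers.
    """
    km = config.kinematic_model
    if rng is None:
        rng = _stage_rng(config, "streams")
    reach_T = (
        km.reach_duration_s[condition] if reach_duration_s is None else reach_duration_s
    )
    if reach_T <= 0:
        raise ValueError("reach duration must be positive")

    dt = 1.0 / config.sampling_rate_hz
    segs = [
        ("still", km.pre_delay_s),
        ("reach", reach_T),
        ("dwell", km.grasp_dwell_s),
        ("lift", km.lift_duration_s),
        ("hold", config.hold_duration_s),
        ("lower", km.lower_duration_s),
        ("still2", km.post_delay_s),
    ]
    total = sum(d for _, d in segs)
    n = int(round(total * config.sampling_rate_hz))
    t = np.arange(n) * dt

    wrist = np.zeros((n, 3))
    obj = np.zeros((n, 3))
    obj[:, 0] = km.reach_amplitude_mm  # object sits at the reach target

    t0 = 0.0
    for name, dur in segs:
        sel = (t >= t0) & (t < t0 + dur)
        tau = (t[sel] - t0) / dur
        if name == "reach":
            wrist[sel, 0] = km.reach_amplitude_mm * minimum_jerk(tau)
        elif name == "lift":
            z = km.lift_height_mm * minimum_jerk(tau)
            wrist[sel, 2] = z
            obj[sel, 2] = z
        elif name == "hold":
            wrist[sel, 2] = km.lift_height_mm
            obj[sel, 2] = km.lift_height_mm
        elif name == "lower":
            z = km.lift_height_mm * (1.0 - minimum_jerk(tau))
            wrist[sel, 2] = z
            obj[sel, 2] = z
        if name in ("dwell", "lift", "hold", "lower", "still2"):
            wrist[sel, 0] = km.reach_amplitude_mm
        t0 += dur

    if km.position_noise_sd_mm > 0:
        wrist = wrist + rng.normal(0.0, km.position_noise_sd_mm, wrist.shape)
        obj = obj + rng.normal(0.0, km.position_noise_sd_mm, obj.shape)

    return pd.DataFrame(
        {
            "trial_id": trial_id,
            "time_s": t,
            "wrist_x_mm": wrist[:, 0],
            "wrist_y_mm": wrist[:, 1],
            "wrist_z_mm": wrist[:, 2],
            "obj_x_mm": obj[:, 0],
            "obj_y_mm": obj[:, 1],
            "obj_z_mm": obj[:, 2],
        }
    )


def trial_id_for(participant_id: int, condition: str, trial_index: int) -> str:
    return f"p{participant_id:02d}_{condition}_{trial_index:02d}"


def parse_trial_id(trial_id: str) -> tuple[int, str, int]:
    """Inverse of :func:`trial_id_for`."""
    p, cond, idx = trial_id.split("_")
    return int(p[1:]), cond, int(idx)


def simulate_streams(
    config: StudyConfig, schedule: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Generate position streams for every scheduled trial (long format)."""
    km = config.kinematic_model
    if schedule is None:
        schedule = make_schedule(config)
    rng = _stage_rng(config, "streams")
    # participant-level and participant-by-condition tempo offsets; the
    # latter is what carries between-participant spread of the paired
    # real-virtual velocity differences
    n = config.n_participants
    part_offsets = {
        p: rng.normal(0.0, km.reach_duration_between_sd_s)
        for p in range(1, n + 1)
    }
    cond_offsets = {
        (p, c): rng.normal(0.0, km.reach_duration_cond_sd_s)
        for p in range(1, n + 1)
        for c in CONDITIONS
    }
    frames = []
    for row in schedule.itertuples(index=False):
        base = km.reach_duration_s[row.condition]
        dur = base + part_offsets[row.participant_id]
        dur += cond_offsets[(row.participant_id, row.condition)]
        dur += rng.normal(0.0, km.reach_duration_trial_sd_s)
        dur = max(dur, 0.2)
        tid = trial_id_for(row.participant_id, row.condition, row.trial_index)
        frames.append(
            simulate_stream(config, tid, row.condition, rng=rng, reach_duration_s=dur)
        )
    return pd.concat(frames, ignore_index=True)


def simulate_presence(
    config: StudyConfig, coefficients: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Generate the six-item presence questionnaire responses.

    The participant's latent presence is tied (via ``association_slope``)
    to their virtual-condition volume slope betaV, standardised by the
    total betaV scatter, then each item is the latent value plus noise cut
    into the 1..7 categories at half-integer cutpoints.
    """
    pm = config.presence_model
    rm = config.rating_model
    if coefficients is None:
        coefficients = draw_participant_coefficients(config)
    rng = _stage_rng(config, "presence")
    virt = (
        coefficients[coefficients["condition"] == "virtual"]
        .set_index("participant_id")["betaV"]
    )
    bv_sd = float(np.hypot(rm.betaV_sd, rm.betaV_condition_sd))
    rows = []
    for p in range(1, config.n_participants + 1):
        dev = (virt.loc[p] - rm.betaV_mean) / bv_sd if bv_sd > 0 else 0.0
        latent = (
            pm.latent_mean
            + pm.association_slope * dev
            + (rng.normal(0.0, pm.latent_sd) if pm.latent_sd > 0 else 0.0)
        )
        items = latent + (
            rng.normal(0.0, pm.item_sd, 6) if pm.item_sd > 0 else np.zeros(6)
        )
        items = np.clip(np.rint(items), 1, 7).astype(int)
        rows.append([p, *items])
    return pd.DataFrame(
        rows, columns=["participant_id"] + [f"item{i}" for i in range(1, 7)]
    )


@dataclass
class SyntheticStudy:
    """Bundle of one simulated study plus its generative ground truth."""

    config: StudyConfig
    ratings: pd.DataFrame
    presence: pd.DataFrame
    coefficients: pd.DataFrame
    streams: pd.DataFrame | None = None


def simulate_study(config: StudyConfig, include_streams: bool = True) -> SyntheticStudy:
    """Run the full generator: schedule, coefficients, ratings, presence, streams."""
    schedule = make_schedule(config)
    coefs = draw_participant_coefficients(config)
    ratings = simulate_ratings(config, schedule, coefficients=coefs)
    presence = simulate_presence(config, coefs)
    streams = simulate_streams(config, schedule) if include_streams else None
    return SyntheticStudy(config, ratings, presence, coefs, streams)


def config_to_dict(config: StudyConfig) -> dict:
    return asdict(config)


def config_from_dict(d: dict) -> StudyConfig:
    d = dict(d)
    if "rating_model" in d and isinstance(d["rating_model"], dict):
        d["rating_model"] = RatingModel(**d["rating_model"])
    if "kinematic_model" in d and isinstance(d["kinematic_model"], dict):
        d["kinematic_model"] = KinematicModel(**d["kinematic_model"])
    if "presence_model" in d and isinstance(d["presence_model"], dict):
        d["presence_model"] = PresenceModel(**d["presence_model"])
    return StudyConfig(**d)
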