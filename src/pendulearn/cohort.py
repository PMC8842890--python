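"""Synthetic participants, the study design, and cohort generation.

The study protocol is a 4-modality between-subjects factorial (haptic
rendering x arm weight support) with 36 blocks of 30 s per participant:

* 2 baseline (BL) and 2 transfer-baseline (TBL) blocks,
* 24 training-phase blocks: 20 training blocks (T) in the group's modality
  and 4 catch-trial blocks (CT, positions 5/9/13/17) in the test modality,
* 2 short-term retention (STR) + 2 transfer retention (TSTR) blocks,
* 2 long-term retention (LTR) + 2 transfer retention (TLTR) blocks.

All test blocks (BL/CT/STR/LTR and their transfer variants) use the
visuo-haptic test modality (haptics on, support off); transfer blocks use the
short 0.25 m rod instead of 0.35 m.

Human behaviour is stood in for by a closed-loop energy-pumping /
stabilising controller (see :mod:`pendulearn._controller`) whose
imperfection knobs — command noise, feedback delay, drive amplitude — are
tied to a scalar skill level.  Skill grows linearly with the number of
training-phase blocks experienced; configurable group effects add to the
per-block skill gain, to the acquired phase lead, and to block-level vertical
exploration, mirroring the directions a haptic-rendering / weight-support
study would probe.  With all effects zero, the four groups are exchangeable,
which is what makes null-calibration studies possible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import arm as arm_mod
from ._controller import simulate_block_kernel
from .exceptions import DesignError
from .metrics import block_metrics, movement_phase_difference, movement_variability, physical_effort
from .pendulum import (PendulumParams, PendulumState, PendulumTrace,
                       PivotTrajectory, compute_score, decompose_rod_force,
                       rod_force)
from .records import BlockRecording, Modality, TEST_MODALITY

__all__ = [
    "GROUPS",
    "BlockSpec",
    "StudyDesign",
    "make_design",
    "ParticipantProfile",
    "GroupEffects",
    "PopulationConfig",
    "ControllerConfig",
    "swingup_controller",
    "simulate_participant",
    "generate_study",
    "CohortDataset",
    "ALL_METRICS",
]

GROUPS = {
    "Visual": Modality(hr=False, ws=False),
    "SupportedVisual": Modality(hr=False, ws=True),
    "VisuoHaptic": Modality(hr=True, ws=False),
    "SupportedVisuoHaptic": Modality(hr=True, ws=True),
}

MAIN_ROD_LENGTH = 0.35
TRANSFER_ROD_LENGTH = 0.25
CATCH_TRIAL_POSITIONS = (5, 9, 13, 17)
N_TRAINING_BLOCKS = 24
BLOCK_DURATION_S = 30.0
REST_DURATION_S = 30.0

ALL_METRICS = ("score", "phase_diff", "var_y", "var_z", "effort")

#: Shoulder-frame offset of the neutral hand position (m); pivot excursions
#: are expressed about this point when converting to arm poses.
HAND_BASE = (0.30, -0.25)


@dataclass(frozen=True)
class BlockSpec:
    """One block of the protocol."""

    index: int                      # 1-based position in the session order
    phase_label: str                # BL, TBL, T, CT, STR, TSTR, LTR, TLTR
    modality: Modality
    rod_length: float
    duration: float = BLOCK_DURATION_S
    training_position: Optional[int] = None  # 1..24 within the training phase

    @property
    def is_training_phase(self) -> bool:
        return self.phase_label in ("T", "CT")

    @property
    def is_transfer(self) -> bool:
        return self.phase_label in ("TBL", "TSTR", "TLTR")


@dataclass(frozen=True)
class StudyDesign:
    """Ordered block list of one participant's protocol."""

    group: str
    blocks: tuple
    rest_duration: float = REST_DURATION_S

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise DesignError(f"unknown group {self.group!r}")
        if len(self.blocks) != 36:
            raise DesignError("protocol must have exactly 36 blocks")
        labels = [b.phase_label for b in self.blocks]
        if labels.count("T") != 20 or labels.count("CT") != 4:
            raise DesignError("training phase must contain 20 T and 4 CT blocks")
        for b in self.blocks:
            test_block = b.phase_label != "T"
            if test_block and b.modality != TEST_MODALITY:
                raise DesignError(
                    f"block {b.index} ({b.phase_label}) must use the test modality")
            expected_rod = TRANSFER_ROD_LENGTH if b.is_transfer else MAIN_ROD_LENGTH
            if not math.isclose(b.rod_length, expected_rod):
                raise DesignError(f"block {b.index} has wrong rod length")

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)


def make_design(group: str, block_duration: float = BLOCK_DURATION_S) -> StudyDesign:
    """Build the 36-block protocol for one training group."""
    if group not in GROUPS:
        raise DesignError(f"unknown group {group!r}; one of {sorted(GROUPS)}")
    train_modality = GROUPS[group]
    blocks = []
    idx = 0

    def add(label, modality, rod, training_position=None):
        nonlocal idx
        idx += 1
        blocks.append(BlockSpec(index=idx, phase_label=label, modality=modality,
                                rod_length=rod, duration=block_duration,
                                training_position=training_position))

    for _ in range(2):
        add("BL", TEST_MODALITY, MAIN_ROD_LENGTH)
    for _ in range(2):
        add("TBL", TEST_MODALITY, TRANSFER_ROD_LENGTH)
    for pos in range(1, N_TRAINING_BLOCKS + 1):
        if pos in CATCH_TRIAL_POSITIONS:
            add("CT", TEST_MODALITY, MAIN_ROD_LENGTH, training_position=pos)
        else:
            add("T", train_modality, MAIN_ROD_LENGTH, training_position=pos)
    for _ in range(2):
        add("STR", TEST_MODALITY, MAIN_ROD_LENGTH)
    for _ in range(2):
        add("TSTR", TEST_MODALITY, TRANSFER_ROD_LENGTH)
    for _ in range(2):
        add("LTR", TEST_MODALITY, MAIN_ROD_LENGTH)
    for _ in range(2):
        add("TLTR", TEST_MODALITY, TRANSFER_ROD_LENGTH)
    return StudyDesign(group=group, blocks=tuple(blocks))


@dataclass(frozen=True)
class ParticipantProfile:
    """Latent parameters of one synthetic participant."""

    participant_id: str
    group: str
    skill0: float = 0.35            # initial skill in [0, 1]
    learning_rate: float = 0.012    # skill gain per training-phase block
    phase_lead: float = 0.3         # target pivot lead (rad)
    motor_noise_sd: float = 2.0     # command accel noise at zero skill (m/s^2)
    feedback_delay: float = 0.15    # sensorimotor delay (s)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.skill0 <= 1.0:
            raise ValueError("skill0 must lie in [0, 1]")
        if self.learning_rate < 0 or self.motor_noise_sd < 0:
            raise ValueError("learning_rate and motor_noise_sd must be >= 0")
        if self.feedback_delay < 0:
            raise ValueError("feedback_delay must be >= 0")


@dataclass(frozen=True)
class GroupEffects:
    """Per-block modality effects injected during training.

    The default values are the demonstration configuration: haptic rendering
    speeds up learning and builds phase lead; weight support slows learning,
    erodes phase lead, and (like haptics) boosts vertical exploration during
    the blocks in which it is active.  Effort differences need no knob — they
    follow mechanically from the support torques.  ``null()`` zeroes
    everything, making the four groups statistically exchangeable.
    """

    learning_rate_hr: float = 0.005     # extra skill gain per HR block
    learning_rate_ws: float = -0.003    # skill gain change per WS block
    phase_lead_hr: float = 0.005        # acquired lead per HR block (rad)
    phase_lead_ws: float = -0.004       # acquired lead per WS block (rad)
    vertical_noise_hr: float = 0.6      # z-noise multiplier increment, HR on
    vertical_noise_ws: float = 0.8      # z-noise multiplier increment, WS on

    @classmethod
    def null(cls) -> "GroupEffects":
        return cls(learning_rate_hr=0.0, learning_rate_ws=0.0,
                   phase_lead_hr=0.0, phase_lead_ws=0.0,
                   vertical_noise_hr=0.0, vertical_noise_ws=0.0)


@dataclass(frozen=True)
class PopulationConfig:
    """Sampling distributions of the participant profiles."""

    skill0_mean: float = 0.30
    skill0_sd: float = 0.08
    skill0_range: tuple = (0.10, 0.55)
    learning_rate_mean: float = 0.006
    learning_rate_sd: float = 0.002
    learning_rate_max: float = 0.012
    phase_lead_mean: float = 0.30
    phase_lead_sd: float = 0.10
    motor_noise_mean: float = 2.0
    motor_noise_sd: float = 0.5
    delay_mean: float = 0.15
    delay_sd: float = 0.03
    delay_range: tuple = (0.05, 0.25)


@dataclass(frozen=True)
class ControllerConfig:
    """Tuning of the synthetic-participant controller (accelerations m/s^2)."""

    drive_gain: float = 6.0      # saturation of the energy-pumping drive
    drive_floor: float = 0.5     # fraction of drive available at zero skill
    energy_gain: float = 8.0     # k_e of the energy-shaping law (1/(J*s))
    kp: float = 40.0             # inverted-pose stiffness (1/s^2)
    kd: float = 12.0             # inverted-pose damping (1/s)
    stab_floor: float = 0.1      # fraction of kp/kd available at zero skill
    capture_angle: float = 0.7   # stabiliser engagement window (rad)
    capture_speed: float = 4.0   # stabiliser speed window (rad/s)
    y_spring: float = 3.0        # workspace-centering stiffness (1/s^2)
    y_damp: float = 1.5
    z_spring: float = 20.0
    z_damp: float = 6.0
    z_noise_sd: float = 1.0      # baseline vertical exploration noise
    workspace: float = 0.4       # hard pivot clip (m)
    u_max: float = 25.0          # overall pivot-acceleration clip
    noise_ref_rate: float = 600.0  # rate at which noise SDs are quoted (Hz)


DEFAULT_CONTROLLER = ControllerConfig()
DEFAULT_SUPPORT_FRACTION = 1.0


def _run_block(params: PendulumParams, duration: float, sample_rate: float,
               skill: float, motor_noise_sd: float, delay_s: float,
               lead: float, z_noise_scale: float, rng: np.random.Generator,
               ctrl: ControllerConfig = DEFAULT_CONTROLLER):
    """Closed-loop simulation of one block; returns (pivot, trace)."""
    n = int(round(duration * sample_rate)) + 1
    dt = 1.0 / sample_rate
    # noise SDs are quoted at the reference rate; scale so the induced
    # velocity diffusion is sampling-rate invariant
    rate_scale = math.sqrt(sample_rate / ctrl.noise_ref_rate)
    sd_y = motor_noise_sd * max(0.0, 1.0 - skill) * rate_scale
    sd_z = ctrl.z_noise_sd * z_noise_scale * rate_scale
    noise_y = rng.standard_normal(n) * sd_y
    noise_z = rng.standard_normal(n) * sd_z
    # a positive lead advances the sensed swing timing by lead/omega_n
    # seconds; anticipation can cancel the sensorimotor delay but not act
    # ahead of the movement itself
    net_delay = max(0.0, delay_s - lead / params.natural_frequency)
    delay_steps = int(round(net_delay * sample_rate))
    drive = ctrl.drive_gain * (ctrl.drive_floor + (1.0 - ctrl.drive_floor) * skill)
    # hold quality also grows with skill: the stabiliser gains scale up
    stab = ctrl.stab_floor + (1.0 - ctrl.stab_floor) * skill
    cml2 = params.c / (params.m * params.l**2)
    out = simulate_block_kernel(
        0.0, 0.0, n, dt, params.m, params.l, params.g, cml2,
        drive, ctrl.energy_gain, ctrl.kp * stab, ctrl.kd * stab,
        ctrl.capture_angle, ctrl.capture_speed,
        delay_steps, noise_y, noise_z,
        ctrl.y_spring, ctrl.y_damp, ctrl.z_spring, ctrl.z_damp,
        ctrl.workspace, ctrl.u_max)
    theta, thetadot, y, z, ydot, zdot, yddot, zddot = out
    t = np.arange(n) * dt
    pivot = PivotTrajectory(t, y, z, ydot, zdot, yddot, zddot)
    trace = PendulumTrace(t, theta, thetadot)
    return pivot, trace


def swingup_controller(profile: ParticipantProfile, params: PendulumParams,
                       duration: float, seed: Optional[int] = None,
                       sample_rate: float = 600.0,
                       ctrl: ControllerConfig = DEFAULT_CONTROLLER) -> PivotTrajectory:
    """Generate one pivot trajectory from the synthetic participant.

    The participant's ``skill0`` sets the controller imperfection; the same
    (profile, seed) pair always yields the same trajectory.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if seed is None:
        seed = profile.rng_seed
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    pivot, _ = _run_block(params, duration, sample_rate, profile.skill0,
                          profile.motor_noise_sd, profile.feedback_delay,
                          profile.phase_lead, 1.0, rng, ctrl)
    return pivot


def _block_torques(pivot: PivotTrajectory, trace: PendulumTrace,
                   params: PendulumParams, arm: arm_mod.ArmParams,
                   hr: bool, ws: bool, support_fraction: float) -> np.ndarray:
    """Participant-generated joint torques of one block (n, 2)."""
    q_s, q_e = arm_mod.inverse_kinematics(pivot.y + HAND_BASE[0],
                                          pivot.z + HAND_BASE[1], arm)
    interaction = np.zeros((len(pivot), 2))
    if hr:
        f = rod_force((trace.theta, trace.theta_dot),
                      (pivot.y_ddot, pivot.z_ddot), params)
        f_y, f_z = decompose_rod_force(f, trace.theta)
        # the participant reacts to the rendered force on the hand, so the
        # torque they generate is J^T of the opposing force
        interaction += arm_mod.hand_force_to_joint_torques((-f_y, -f_z),
                                                           (q_s, q_e), arm)
    if ws:
        interaction += arm_mod.weight_support_torques((q_s, q_e), arm,
                                                      support_fraction)
    return arm_mod.generated_torques(interaction, (q_s, q_e), arm)


def simulate_participant(profile: ParticipantProfile, design: StudyDesign,
                         effects: GroupEffects,
                         sample_rate: float = 600.0,
                         arm: Optional[arm_mod.ArmParams] = None,
                         support_fraction: float = DEFAULT_SUPPORT_FRACTION,
                         metrics: tuple = ALL_METRICS,
                         keep_recordings: bool = False,
                         phases: Optional[tuple] = None,
                         ctrl: ControllerConfig = DEFAULT_CONTROLLER):
    """Simulate every block of one participant's protocol.

    Skill and acquired phase lead evolve linearly with training-phase blocks;
    the per-block increments depend on the modality experienced in that block
    through ``effects``.  Returns ``(rows, recordings)`` where ``rows`` is a
    list of per-block metric dicts and ``recordings`` maps block index to
    :class:`~pendulearn.records.BlockRecording` (``None`` unless requested).

    ``phases`` restricts which phase labels are actually simulated; skipped
    blocks still advance the skill state.  Because every block draws from its
    own counter-based seed, the simulated blocks are identical to what a full
    run would produce.
    """
    if arm is None:
        arm = arm_mod.ArmParams()
    skill = profile.skill0
    acquired_lead = 0.0
    rows = []
    recordings = {} if keep_recordings else None
    need_torques = keep_recordings or "effort" in metrics

    def advance_learning(block):
        nonlocal skill, acquired_lead
        if block.is_training_phase:
            hr, ws = block.modality.hr, block.modality.ws
            skill += (profile.learning_rate
                      + effects.learning_rate_hr * hr
                      + effects.learning_rate_ws * ws)
            skill = min(1.0, max(0.0, skill))
            acquired_lead += (effects.phase_lead_hr * hr
                              + effects.phase_lead_ws * ws)

    for block in design:
        if phases is not None and block.phase_label not in phases:
            advance_learning(block)
            continue
        params = PendulumParams(l=block.rod_length)
        rng = np.random.Generator(np.random.PCG64(
            np.random.SeedSequence(entropy=profile.rng_seed,
                                   spawn_key=(block.index,))))
        hr, ws = block.modality.hr, block.modality.ws
        # exploration effects are a training-modality behaviour: they apply
        # to the T blocks, not to the common-modality test/catch blocks
        if block.phase_label == "T":
            z_scale = (1.0 + effects.vertical_noise_hr * hr
                       + effects.vertical_noise_ws * ws)
        else:
            z_scale = 1.0
        pivot, trace = _run_block(
            params, block.duration, sample_rate,
            skill=min(1.0, max(0.0, skill)),
            motor_noise_sd=profile.motor_noise_sd,
            delay_s=profile.feedback_delay,
            lead=profile.phase_lead + acquired_lead,
            z_noise_scale=z_scale, rng=rng, ctrl=ctrl)
        torques = (_block_torques(pivot, trace, params, arm, hr, ws,
                                  support_fraction) if need_torques else None)
        rec = BlockRecording(modality=block.modality,
                             phase_label=block.phase_label,
                             rod_length=block.rod_length, pivot=pivot,
                             states=trace, torques=torques,
                             block_index=block.index,
                             training_position=block.training_position)
        row = {
            "participant": profile.participant_id,
            "group": profile.group,
            "hr_train": GROUPS[profile.group].hr,
            "ws_train": GROUPS[profile.group].ws,
            "block_index": block.index,
            "phase": block.phase_label,
            "training_position": block.training_position,
            "rod_length": block.rod_length,
            "block_hr": hr,
            "block_ws": ws,
        }
        if metrics == ALL_METRICS:
            m = block_metrics(rec, params)
            row.update(score=m.score, phase_diff=m.phase_diff,
                       var_y=m.var_y, var_z=m.var_z, effort=m.effort,
                       hand_speed=float(np.mean(np.hypot(pivot.y_dot,
                                                         pivot.z_dot))))
        else:
            if "score" in metrics:
                row["score"] = compute_score(trace, params).score
            if "phase_diff" in metrics:
                try:
                    row["phase_diff"] = movement_phase_difference(rec, params)
                except Exception:
                    row["phase_diff"] = None
            if "var_y" in metrics or "var_z" in metrics:
                var_y, var_z = movement_variability(pivot)
                if "var_y" in metrics:
                    row["var_y"] = var_y
                if "var_z" in metrics:
                    row["var_z"] = var_z
                row["hand_speed"] = float(np.mean(np.hypot(pivot.y_dot,
                                                           pivot.z_dot)))
            if "effort" in metrics:
                row["effort"] = physical_effort(torques)
        rec.score = row.get("score")
        rows.append(row)
        if keep_recordings:
            recordings[block.index] = rec
        advance_learning(block)
    return rows, recordings


#: Questionnaire subscales: (scale_min, scale_max, default mean response).
QUESTIONNAIRE_SUBSCALES = {
    "agency": (-3, 3, 1.7),
    "imi_interest_enjoyment": (1, 7, 5.6),
    "imi_effort_importance": (1, 7, 5.5),
    "imi_pressure_tension": (1, 7, 2.5),
    "imi_perceived_competence": (1, 7, 4.5),
}
QUESTIONNAIRE_TIME_POINTS = ("BL", "T", "LTR")
N_ITEMS_PER_SUBSCALE = 3


def _sample_questionnaires(profile: ParticipantProfile,
                           rng: np.random.Generator,
                           item_sd: float = 1.0,
                           missing_item_rate: float = 0.02) -> list:
    rows = []
    for time_point in QUESTIONNAIRE_TIME_POINTS:
        for subscale, (lo, hi, mean) in QUESTIONNAIRE_SUBSCALES.items():
            # at most one item per subscale may go unanswered, matching the
            # missing-item rule the scoring applies
            missing_item = 0
            if rng.random() < missing_item_rate:
                missing_item = int(rng.integers(1, N_ITEMS_PER_SUBSCALE + 1))
            for item in range(1, N_ITEMS_PER_SUBSCALE + 1):
                if item == missing_item:
                    response = np.nan
                else:
                    response = float(np.clip(
                        np.round(rng.normal(mean, item_sd)), lo, hi))
                rows.append({
                    "participant": profile.participant_id,
                    "group": profile.group,
                    "time_point": time_point,
                    "subscale": subscale,
                    "item": item,
                    "response": response,
                })
    return rows


@dataclass
class CohortDataset:
    """A full synthetic study: profiles, per-block metrics, questionnaires."""

    profiles: list
    metrics: pd.DataFrame
    questionnaires: pd.DataFrame
    seed: int
    config: dict = field(default_factory=dict)
    recordings: Optional[dict] = None

    @property
    def n_participants(self) -> int:
        return len(self.profiles)

    @property
    def n_blocks(self) -> int:
        return len(self.metrics)


def _sample_profile(pid: str, group: str, ss: np.random.SeedSequence,
                    pop: PopulationConfig) -> ParticipantProfile:
    rng = np.random.Generator(np.random.PCG64(ss))
    skill0 = float(np.clip(rng.normal(pop.skill0_mean, pop.skill0_sd),
                           *pop.skill0_range))
    lr = float(np.clip(rng.normal(pop.learning_rate_mean, pop.learning_rate_sd),
                       0.0, pop.learning_rate_max))
    lead = float(rng.normal(pop.phase_lead_mean, pop.phase_lead_sd))
    noise = float(abs(rng.normal(pop.motor_noise_mean, pop.motor_noise_sd)))
    delay = float(np.clip(rng.normal(pop.delay_mean, pop.delay_sd),
                          *pop.delay_range))
    seed = int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
    return ParticipantProfile(participant_id=pid, group=group, skill0=skill0,
                              learning_rate=lr, phase_lead=lead,
                              motor_noise_sd=noise, feedback_delay=delay,
                              rng_seed=seed)


def generate_study(n_per_group: int = 10,
                   effects: Optional[GroupEffects] = None,
                   seed: int = 0,
                   block_duration: float = BLOCK_DURATION_S,
                   sample_rate: float = 600.0,
                   population: Optional[PopulationConfig] = None,
                   metrics: tuple = ALL_METRICS,
                   keep_recordings: bool = False,
                   missing_item_rate: float = 0.02,
                   arm: Optional[arm_mod.ArmParams] = None,
                   support_fraction: float = DEFAULT_SUPPORT_FRACTION,
                   phases: Optional[tuple] = None,
                   ctrl: ControllerConfig = DEFAULT_CONTROLLER) -> CohortDataset:
    """Generate a balanced 4-group cohort.

    Per-participant seeds are derived from the master seed with a
    counter-based scheme (participant index as spawn key), so each
    participant's data is invariant to cohort size or ordering.  The whole
    dataset is a pure function of the arguments.
    """
    if n_per_group < 2:
        raise DesignError("need at least 2 participants per group")
    if effects is None:
        effects = GroupEffects()
    if population is None:
        population = PopulationConfig()
    metric_rows = []
    quest_rows = []
    profiles = []
    all_recordings = {} if keep_recordings else None
    p_index = 0
    for group in GROUPS:
        design = make_design(group, block_duration=block_duration)
        for k in range(n_per_group):
            pid = f"P{p_index + 1:03d}"
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(p_index,))
            profile = _sample_profile(pid, group, ss, population)
            profiles.append(profile)
            rows, recs = simulate_participant(
                profile, design, effects, sample_rate=sample_rate, arm=arm,
                support_fraction=support_fraction, metrics=metrics,
                keep_recordings=keep_recordings, phases=phases, ctrl=ctrl)
            metric_rows.extend(rows)
            if keep_recordings:
                all_recordings[pid] = recs
            q_rng = np.random.Generator(np.random.PCG64(
                np.random.SeedSequence(entropy=seed,
                                       spawn_key=(p_index, 1))))
            quest_rows.extend(_sample_questionnaires(
                profile, q_rng, missing_item_rate=missing_item_rate))
            p_index += 1
    config = {
        "n_per_group": n_per_group,
        "seed": seed,
        "block_duration": block_duration,
        "sample_rate": sample_rate,
        "effects": vars(effects).copy() if hasattr(effects, "__dict__")
        else {k: getattr(effects, k) for k in effects.__dataclass_fields__},
        "metrics": list(metrics),
    }
    return CohortDataset(profiles=profiles,
                         metrics=pd.DataFrame(metric_rows),
                         questionnaires=pd.DataFrame(quest_rows),
                         seed=seed, config=config,
                         recordings=all_recordings)
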