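"""Synthetic penalty scenes and coded datasets with known ground truth.

Two generators stand in for broadcast video and the coded study table:

``simulate_scene``
    Builds kicker and goalkeeper skeleton tracks analytically in field
    coordinates -- so the planted orientation angles, anticipation angle and
    foot displacements are exact by construction -- then pushes every
    landmark through a field-to-image camera homography, adds isotropic
    Gaussian pixel noise, and draws per-landmark confidence scores.  The
    emitted artefacts use the exact same dialects the real pipeline reads
    (per-frame keypoint JSON, corner CSV, annotation CSV).

``simulate_ospaf_dataset``
    Draws a binary strategy label at a configurable prevalence, each
    categorical variable from a strategy-conditional level distribution, and
    the numeric pose variables as Gaussians with strategy-dependent means.
    The population 2x2 association (phi) implied by each binary variable's
    conditionals is returned alongside the sample, serving as the oracle for
    association-recovery tests.

All randomness flows from a single integer seed; equal configurations give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import body25
from .errors import ConfigError
from .field_geometry import (
    PITCH_LENGTH,
    PITCH_WIDTH,
    Correspondence,
    Homography,
    project_point,
    write_corner_file,
)
from .keypoint_io import (
    Landmark,
    MomentAnnotation,
    PersonFrame,
    Track,
    write_annotations,
    write_openpose_frames,
)
from .ospaf_coding import OSPAF_LEVELS, OSPAF_VARIABLES
from .pose_metrics import side_of_angle
from .strategy_stats import NEGATIVE_LEVEL, POSITIVE_LEVEL


def default_camera() -> Homography:
    """A plausible behind-the-kicker broadcast camera (field -> image px).

    Maps the penalty area of the field frame (goal at x = 0) into a
    1280 x 720 image with mild perspective; roughly 50 px/m across the goal
    and 30 px/m in depth near the goal line.
    """
    return Homography(
        np.array(
            [
                [0.0, -50.0, 640.0],
                [-30.0, 0.0, 200.0],
                [-0.02, 0.0, 1.0],
            ]
        )
    )


def pitch_corner_correspondences(
    camera: Homography,
    pitch_length: float = PITCH_LENGTH,
    pitch_width: float = PITCH_WIDTH,
) -> list[Correspondence]:
    """The four pitch corners and their (possibly off-image) pixel positions."""
    corners = [
        (0.0, -pitch_width / 2),
        (0.0, pitch_width / 2),
        (-pitch_length, pitch_width / 2),
        (-pitch_length, -pitch_width / 2),
    ]
    return [
        Correspondence(image_xy=project_point(camera, c), field_xy=c)
        for c in corners
    ]


@dataclass(frozen=True)
class SceneConfig:
    """Ground-truth parameters of one synthetic penalty scene.

    Angles are degrees in the field frame (0 = facing the attacked goal,
    counter-clockwise positive); distances are metres; noise is pixels.
    ``confidence_law`` is (mean, sd, lower clip) of the per-landmark
    confidence draws, matching the broadcast-footage regime of roughly
    0.80 +/- 0.14.
    """

    penalty_id: str = "p001"
    true_alpha_gk: float = 30.0
    true_orientations: Mapping[str, float] = field(
        default_factory=lambda: {"shoulders": 10.0, "hips": 20.0, "support_foot": 5.0}
    )
    gk_foot_moves: tuple[float, float] = (0.4, 1.2)  # (left, right) metres
    kicking_foot: str = "right"
    camera_homography: Homography = field(default_factory=default_camera)
    pixel_noise_sd: float = 1.0
    confidence_law: tuple[float, float, float] = (0.80, 0.14, 0.05)
    fps: float = 25.0
    n_frames: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_noise_sd < 0:
            raise ConfigError("pixel_noise_sd must be >= 0")
        if not 0.0 <= self.true_alpha_gk <= 180.0:
            raise ConfigError("true_alpha_gk must lie in [0, 180]")
        if self.n_frames < 12:
            raise ConfigError("need n_frames >= 12 for the two analysed moments")
        if self.kicking_foot not in ("right", "left"):
            raise ConfigError(f"bad kicking_foot {self.kicking_foot!r}")
        if any(m < 0 for m in self.gk_foot_moves):
            raise ConfigError("gk_foot_moves must be >= 0")
        missing = {"shoulders", "hips", "support_foot"} - set(self.true_orientations)
        if missing:
            raise ConfigError(f"true_orientations lacks {sorted(missing)}")


@dataclass(frozen=True)
class SceneBundle:
    kicker: Track
    goalkeeper: Track
    correspondences: list[Correspondence]
    annotation: MomentAnnotation
    ground_truth: dict


def _rot(deg: float) -> np.ndarray:
    r = math.radians(deg)
    return np.array([[math.cos(r), -math.sin(r)], [math.sin(r), math.cos(r)]])


def _lr_pair(center: np.ndarray, angle_deg: float, separation: float):
    """(left_point, right_point) of an LR pair facing ``angle_deg``."""
    r = math.radians(angle_deg)
    u = np.array([math.sin(r), -math.cos(r)])  # unit left -> right
    return center - 0.5 * separation * u, center + 0.5 * separation * u


def _kicker_skeleton(
    center: np.ndarray, orientations: Mapping[str, float], kicking_foot: str
) -> dict[int, np.ndarray]:
    """Field-plane positions of all 25 kicker landmarks.

    Only the measured pairs (shoulders, hips, support-foot toes) carry exact
    semantics; the rest are plausible filler so files are fully populated.
    """
    theta = orientations["shoulders"]
    facing = np.array([math.cos(math.radians(theta)), math.sin(math.radians(theta))])
    left_dir = _rot(90.0) @ facing  # subject's left in the field plane

    sh_l, sh_r = _lr_pair(center, orientations["shoulders"], 0.38)
    hip_l, hip_r = _lr_pair(center, orientations["hips"], 0.30)

    sf_theta = orientations["support_foot"]
    sf_facing = np.array(
        [math.cos(math.radians(sf_theta)), math.sin(math.radians(sf_theta))]
    )
    support_side = 1.0 if kicking_foot == "right" else -1.0  # +1 = subject's left
    sf_center = center + 0.18 * support_side * left_dir + 0.1 * facing
    toe_l, toe_r = _lr_pair(sf_center, sf_theta, 0.12)
    kick_center = center - 0.18 * support_side * left_dir - 0.35 * facing

    pts: dict[int, np.ndarray] = {
        body25.NOSE: center + 0.15 * facing,
        body25.NECK: center + 0.05 * facing,
        body25.R_SHOULDER: sh_r,
        3: sh_r - 0.25 * facing,            # RElbow
        4: sh_r - 0.45 * facing,            # RWrist
        body25.L_SHOULDER: sh_l,
        6: sh_l - 0.25 * facing,            # LElbow
        7: sh_l - 0.45 * facing,            # LWrist
        body25.MID_HIP: center.copy(),
        body25.R_HIP: hip_r,
        10: hip_r - 0.1 * facing,           # RKnee
        body25.L_HIP: hip_l,
        13: hip_l - 0.1 * facing,           # LKnee
        15: center + 0.17 * facing - 0.03 * left_dir,   # REye
        16: center + 0.17 * facing + 0.03 * left_dir,   # LEye
        17: center + 0.12 * facing - 0.07 * left_dir,   # REar
        18: center + 0.12 * facing + 0.07 * left_dir,   # LEar
    }
    # the hallux is the medial element of the toe pair
    if kicking_foot == "right":  # left support foot: big toe = right-side point
        pts[body25.L_BIG_TOE] = toe_r
        pts[body25.L_SMALL_TOE] = toe_l
        pts[body25.L_HEEL] = sf_center - 0.2 * sf_facing
        pts[body25.L_ANKLE] = sf_center - 0.14 * sf_facing
        pts[body25.R_BIG_TOE] = kick_center + 0.1 * facing
        pts[body25.R_SMALL_TOE] = kick_center + 0.08 * facing - 0.05 * left_dir
        pts[body25.R_HEEL] = kick_center - 0.1 * facing
        pts[body25.R_ANKLE] = kick_center
    else:  # right support foot: big toe = left-side point
        pts[body25.R_BIG_TOE] = toe_l
        pts[body25.R_SMALL_TOE] = toe_r
        pts[body25.R_HEEL] = sf_center - 0.2 * sf_facing
        pts[body25.R_ANKLE] = sf_center - 0.14 * sf_facing
        pts[body25.L_BIG_TOE] = kick_center + 0.1 * facing
        pts[body25.L_SMALL_TOE] = kick_center + 0.08 * facing + 0.05 * left_dir
        pts[body25.L_HEEL] = kick_center - 0.1 * facing
        pts[body25.L_ANKLE] = kick_center
    return pts


def _goalkeeper_skeleton(
    center: np.ndarray,
    axis_angle_deg: float,
    ankle_left: np.ndarray,
    ankle_right: np.ndarray,
) -> dict[int, np.ndarray]:
    """Field-plane goalkeeper landmarks; ``axis_angle_deg`` is the direction
    of the mid-hip -> neck body-axis projection."""
    r = math.radians(axis_angle_deg)
    axis = np.array([math.cos(r), math.sin(r)])
    neck = center + 0.30 * axis
    midhip = center - 0.30 * axis
    facing = np.array([-1.0, 0.0])  # toward the kicker
    left_dir = _rot(90.0) @ facing
    sh_l, sh_r = _lr_pair(neck, 180.0, 0.45)
    hip_l, hip_r = _lr_pair(midhip, 180.0, 0.32)
    pts: dict[int, np.ndarray] = {
        body25.NOSE: neck + 0.12 * axis,
        body25.NECK: neck,
        body25.R_SHOULDER: sh_r,
        3: sh_r + 0.3 * left_dir * -1 + 0.1 * facing,
        4: sh_r + 0.5 * left_dir * -1 + 0.15 * facing,
        body25.L_SHOULDER: sh_l,
        6: sh_l + 0.3 * left_dir + 0.1 * facing,
        7: sh_l + 0.5 * left_dir + 0.15 * facing,
        body25.MID_HIP: midhip,
        body25.R_HIP: hip_r,
        10: (hip_r + ankle_right) / 2,
        body25.R_ANKLE: ankle_right,
        body25.L_HIP: hip_l,
        13: (hip_l + ankle_left) / 2,
        body25.L_ANKLE: ankle_left,
        15: neck + 0.13 * axis - 0.03 * left_dir,
        16: neck + 0.13 * axis + 0.03 * left_dir,
        17: neck + 0.1 * axis - 0.07 * left_dir,
        18: neck + 0.1 * axis + 0.07 * left_dir,
        body25.L_BIG_TOE: ankle_left + 0.15 * facing,
        body25.L_SMALL_TOE: ankle_left + 0.13 * facing + 0.05 * left_dir,
        body25.L_HEEL: ankle_left - 0.08 * facing,
        body25.R_BIG_TOE: ankle_right + 0.15 * facing,
        body25.R_SMALL_TOE: ankle_right + 0.13 * facing - 0.05 * left_dir,
        body25.R_HEEL: ankle_right - 0.08 * facing,
    }
    return pts


def _interp(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    return a + (b - a) * t


def simulate_scene(config: SceneConfig) -> SceneBundle:
    """Generate one penalty scene with exact planted ground truth.

    With ``pixel_noise_sd = 0`` the full pipeline (homography estimation
    from the corner correspondences, projection, metric computation)
    recovers every planted quantity to numerical precision.
    """
    rng = np.random.default_rng(config.seed)
    camera = config.camera_homography
    runup_start = 5
    contact = config.n_frames - 6
    annotation = MomentAnnotation(
        penalty_id=config.penalty_id,
        runup_start_frame=runup_start,
        ball_contact_frame=contact,
        fps=config.fps,
        kicking_foot=config.kicking_foot,
    )

    kicker_start = np.array([-14.0, -1.8])
    kicker_contact = np.array([-11.35, 0.1])
    gk_center = np.array([-0.6, 0.0])
    axis_start = 100.0
    axis_contact = axis_start - config.true_alpha_gk
    d_left, d_right = config.gk_foot_moves
    ankle_l_1 = gk_center + np.array([0.05, -0.22])
    ankle_r_1 = gk_center + np.array([0.05, 0.22])
    dir_l = np.array([-0.3, -0.95])
    dir_l = dir_l / np.linalg.norm(dir_l)
    dir_r = np.array([-0.2, 0.97])
    dir_r = dir_r / np.linalg.norm(dir_r)
    ankle_l_2 = ankle_l_1 + d_left * dir_l
    ankle_r_2 = ankle_r_1 + d_right * dir_r

    mean_c, sd_c, floor_c = config.confidence_law

    def to_person(pts: dict[int, np.ndarray], frame_index: int, person_index: int) -> PersonFrame:
        landmarks = []
        for part in range(body25.N_PARTS):
            u, v = project_point(camera, pts[part])
            if config.pixel_noise_sd > 0:
                u += rng.normal(0.0, config.pixel_noise_sd)
                v += rng.normal(0.0, config.pixel_noise_sd)
            conf = float(np.clip(rng.normal(mean_c, sd_c), floor_c, 1.0))
            landmarks.append(Landmark(float(u), float(v), conf))
        return PersonFrame(frame_index, person_index, tuple(landmarks))

    kicker_frames, gk_frames = [], []
    for f in range(config.n_frames):
        if f <= runup_start:
            t = 0.0
        elif f >= contact:
            t = 1.0
        else:
            t = (f - runup_start) / (contact - runup_start)
        k_center = _interp(kicker_start, kicker_contact, t)
        k_pts = _kicker_skeleton(k_center, config.true_orientations, config.kicking_foot)
        axis = axis_start + (axis_contact - axis_start) * t
        g_pts = _goalkeeper_skeleton(
            gk_center,
            axis,
            _interp(ankle_l_1, ankle_l_2, t),
            _interp(ankle_r_1, ankle_r_2, t),
        )
        kicker_frames.append(to_person(k_pts, f, 0))
        gk_frames.append(to_person(g_pts, f, 1))

    ground_truth = {
        "penalty_id": config.penalty_id,
        "alpha_gk": config.true_alpha_gk,
        "alpha_sh": config.true_orientations["shoulders"] % 360.0,
        "alpha_hi": config.true_orientations["hips"] % 360.0,
        "alpha_sf": config.true_orientations["support_foot"] % 360.0,
        "lr_sh": side_of_angle(config.true_orientations["shoulders"]),
        "lr_hi": side_of_angle(config.true_orientations["hips"]),
        "lr_sf": side_of_angle(config.true_orientations["support_foot"]),
        "d_gk_left": d_left,
        "d_gk_right": d_right,
    }
    return SceneBundle(
        kicker=Track(role="kicker", frames=kicker_frames),
        goalkeeper=Track(role="goalkeeper", frames=gk_frames),
        correspondences=pitch_corner_correspondences(camera),
        annotation=annotation,
        ground_truth=ground_truth,
    )


def write_scene_bundle(bundle: SceneBundle, out_dir: str | Path) -> None:
    """Write one scene in the dialects the real pipeline reads:
    ``keypoints/<penalty_id>/`` JSON files, ``corners.csv``,
    ``annotations.csv``."""
    out_dir = Path(out_dir)
    pid = bundle.annotation.penalty_id
    write_openpose_frames(
        list(bundle.kicker.frames) + list(bundle.goalkeeper.frames),
        out_dir / "keypoints" / pid,
        prefix=pid,
    )
    write_corner_file(bundle.correspondences, out_dir / "corners.csv")
    write_annotations([bundle.annotation], out_dir / "annotations.csv")


# ---------------------------------------------------------------------------
# coded-dataset simulation
# ---------------------------------------------------------------------------

#: strategy-independent base level probabilities (same under either label)
_BASE_PROBS: dict[str, tuple[float, ...]] = {
    "run_up_speed": (0.5, 0.5),
    "run_up_fluency": (0.7, 0.3),
    "run_up_angle": (0.35, 0.65),
    "number_of_steps": (0.2, 0.5, 0.3),
    "kicking_technique": (0.7, 0.3),
    "foot_used": (0.75, 0.25),
    "kicker_gaze": (0.7, 0.3),
    "gk_initial_posture": (0.25, 0.55, 0.2),
    "deception": (0.3, 0.7),
    "gk_tactical_action": (0.5, 0.5),
    "gk_performance": (0.05, 0.1, 0.2, 0.25, 0.2, 0.2),
    "match_moment": (0.4, 0.5, 0.1),
    "location": (0.45, 0.1, 0.45),
    "momentary_result_kicker": (0.3, 0.45, 0.25),
    "momentary_result_gk": (0.3, 0.45, 0.25),
    "match_importance": (0.08, 0.17, 0.3, 0.2, 0.25),
    "kick_direction": (0.4, 0.2, 0.4),
    "kick_height": (0.25, 0.25, 0.5),
    "outcome": (0.72, 0.2, 0.08),
    "taker_strategy": (0.4, 0.12, 0.48),
    "gk_strategy": (0.44, 0.12, 0.44),
}


@dataclass(frozen=True)
class SimStudyConfig:
    """Population of a synthetic coded study.

    ``conditional_level_probabilities`` maps an OSPAF variable to
    ``{"positive": probs, "negative": probs}`` over its canonical levels,
    conditioning on the binary strategy label; unlisted variables use the
    strategy-independent base distribution.  ``numeric_effects`` maps a
    numeric variable to ``(mean_positive, mean_negative, sd)``.
    """

    n_penalties: int = 34
    outcome: str = "gk_strategy"
    strategy_prevalence: float = 0.5
    conditional_level_probabilities: Mapping[str, Mapping[str, Sequence[float]]] = field(
        default_factory=dict
    )
    numeric_effects: Mapping[str, tuple[float, float, float]] = field(
        default_factory=dict
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_penalties < 1:
            raise ConfigError("n_penalties must be >= 1")
        if not 0.0 < self.strategy_prevalence < 1.0:
            raise ConfigError("strategy_prevalence must lie in (0, 1)")
        if self.outcome not in POSITIVE_LEVEL:
            raise ConfigError(f"outcome must be one of {tuple(POSITIVE_LEVEL)}")
        for var, cond in self.conditional_level_probabilities.items():
            if var not in OSPAF_LEVELS:
                raise ConfigError(f"unknown OSPAF variable {var!r}")
            for arm in ("positive", "negative"):
                probs = np.asarray(cond[arm], dtype=float)
                if len(probs) != len(OSPAF_LEVELS[var]):
                    raise ConfigError(
                        f"{var}: {arm} probabilities must cover "
                        f"{len(OSPAF_LEVELS[var])} levels"
                    )
                if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
                    raise ConfigError(f"{var}: {arm} probabilities must sum to 1")


def default_study_config(
    outcome: str = "gk_strategy", n_penalties: int = 34, seed: int = 0
) -> SimStudyConfig:
    """Study conditions emulating the reported association pattern.

    For the goalkeeper outcome, tactical action is strongly associated
    (population phi 0.8) and run-up speed moderately (phi 0.35), with
    goalkeeper anticipation the single strongly separating numeric.  For the
    taker outcome, the four run-up/gaze/deception variables carry phi 0.24
    to 0.76 and ball speed is the separating numeric.
    """
    def symmetric(var: str, phi: float, flip: bool = False) -> dict:
        hi, lo = 0.5 + phi / 2, 0.5 - phi / 2
        pos = (lo, hi) if not flip else (hi, lo)
        neg = (hi, lo) if not flip else (lo, hi)
        return {var: {"positive": pos, "negative": neg}}

    if outcome == "gk_strategy":
        conditionals = {}
        # kicker-dependent keeper: awaits (level 2) and faces a slow run-up
        conditionals.update(symmetric("gk_tactical_action", 0.8))
        conditionals.update(symmetric("run_up_speed", 0.35))
        numeric = {
            "alpha_gk": (18.0, 72.0, 8.0),
            "d_gk_left": (0.8, 0.8, 0.3),
            "d_gk_right": (0.8, 0.8, 0.3),
            "alpha_sh": (55.0, 55.0, 15.0),
            "alpha_hi": (50.0, 50.0, 15.0),
            "alpha_sf": (40.0, 40.0, 20.0),
            "ball_speed": (25.0, 25.0, 2.5),
        }
    elif outcome == "taker_strategy":
        conditionals = {}
        conditionals.update(symmetric("run_up_speed", 0.24))
        conditionals.update(symmetric("run_up_fluency", 0.38))
        conditionals.update(symmetric("kicker_gaze", 0.76))
        conditionals.update(symmetric("deception", 0.47, flip=True))
        numeric = {
            "alpha_gk": (45.0, 45.0, 20.0),
            "d_gk_left": (0.8, 0.8, 0.3),
            "d_gk_right": (0.8, 0.8, 0.3),
            "alpha_sh": (55.0, 55.0, 15.0),
            "alpha_hi": (50.0, 50.0, 15.0),
            "alpha_sf": (40.0, 40.0, 20.0),
            "ball_speed": (19.5, 26.5, 1.4),
        }
    else:
        raise ConfigError(f"outcome must be one of {tuple(POSITIVE_LEVEL)}")
    return SimStudyConfig(
        n_penalties=n_penalties,
        outcome=outcome,
        strategy_prevalence=0.5,
        conditional_level_probabilities=conditionals,
        numeric_effects=numeric,
        seed=seed,
    )


def zero_effect_study_config(
    outcome: str = "gk_strategy", n_penalties: int = 200, seed: int = 0
) -> SimStudyConfig:
    """All variables independent of the strategy (type-I error conditions)."""
    return SimStudyConfig(
        n_penalties=n_penalties,
        outcome=outcome,
        strategy_prevalence=0.5,
        conditional_level_probabilities={},
        numeric_effects={
            "alpha_gk": (45.0, 45.0, 20.0),
            "ball_speed": (24.0, 24.0, 2.5),
            "alpha_sh": (55.0, 55.0, 15.0),
            "d_gk_left": (0.8, 0.8, 0.3),
            "d_gk_right": (0.8, 0.8, 0.3),
        },
        seed=seed,
    )


def population_phi(joint_probabilities: Sequence[Sequence[float]]) -> float:
    """phi of a 2x2 joint probability table:
    |p11*p22 - p12*p21| / sqrt(p1. * p2. * p.1 * p.2)."""
    t = np.asarray(joint_probabilities, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ConfigError("joint table must be 2x2 with entries >= 0")
    if abs(t.sum() - 1.0) > 1e-9:
        raise ConfigError("joint probabilities must sum to 1")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows <= 0) or np.any(cols <= 0):
        raise ConfigError("degenerate margin in joint table")
    return float(
        abs(t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0])
        / math.sqrt(rows[0] * rows[1] * cols[0] * cols[1])
    )


def _conditional_probs(config: SimStudyConfig, var: str, positive: bool):
    cond = config.conditional_level_probabilities.get(var)
    if cond is None:
        return np.asarray(_BASE_PROBS[var], dtype=float)
    return np.asarray(cond["positive" if positive else "negative"], dtype=float)


def simulate_ospaf_dataset(
    config: SimStudyConfig,
) -> tuple[pd.DataFrame, dict]:
    """Draw a coded penalty table with known population associations.

    Returns ``(table, params)`` where the table holds ``penalty_id``, all 21
    categorical variables (the outcome column carries the binary strategy
    labels) and the configured numeric columns, and ``params`` records the
    population phi of every 2-level categorical and the standardized mean
    difference of every numeric variable.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_penalties
    prevalence = config.strategy_prevalence
    positive = rng.random(n) < prevalence

    data: dict[str, list] = {
        "penalty_id": [f"p{i + 1:03d}" for i in range(n)],
    }
    pos_level = POSITIVE_LEVEL[config.outcome]
    neg_level = NEGATIVE_LEVEL[config.outcome]
    for var in OSPAF_VARIABLES:
        if var == config.outcome:
            data[var] = [pos_level if b else neg_level for b in positive]
            continue
        levels = OSPAF_LEVELS[var]
        p_pos = _conditional_probs(config, var, True)
        p_neg = _conditional_probs(config, var, False)
        draws = []
        for b in positive:
            draws.append(levels[rng.choice(len(levels), p=p_pos if b else p_neg)])
        data[var] = draws
    for var, (mean_pos, mean_neg, sd) in config.numeric_effects.items():
        vals = rng.normal(np.where(positive, mean_pos, mean_neg), sd)
        if var.startswith("alpha"):
            vals = np.clip(vals, 0.0, 180.0 if var == "alpha_gk" else 359.999)
        if var.startswith("d_") or var == "ball_speed":
            vals = np.clip(vals, 0.0, None)
        data[var] = vals.tolist()

    table = pd.DataFrame(data)

    phi: dict[str, float] = {}
    for var, cond in config.conditional_level_probabilities.items():
        if len(OSPAF_LEVELS[var]) != 2:
            continue
        p_pos = np.asarray(cond["positive"], dtype=float)
        p_neg = np.asarray(cond["negative"], dtype=float)
        joint = np.vstack([prevalence * p_pos, (1 - prevalence) * p_neg])
        phi[var] = population_phi(joint)
    numeric_d = {
        var: (mp - mn) / sd
        for var, (mp, mn, sd) in config.numeric_effects.items()
    }
    params = {
        "prevalence": prevalence,
        "phi": phi,
        "numeric_d": numeric_d,
        "n_positive": int(positive.sum()),
    }
    return table, params


def simulate_study_scenes(
    study_config: SimStudyConfig,
    scene_template: SceneConfig | None = None,
) -> tuple[pd.DataFrame, list[SceneBundle], dict]:
    """A full synthetic study: one coded table plus one scene per penalty.

    Each penalty's scene plants the numeric pose values drawn for it
    (anticipation angle, foot displacements, orientations), so running the
    extraction pipeline over the scenes reproduces the table's numeric
    columns up to pixel noise.  Scene seeds derive deterministically from
    the study seed.
    """
    template = scene_template or SceneConfig()
    table, params = simulate_ospaf_dataset(study_config)
    bundles = []
    for i, row in table.iterrows():
        orientations = {
            "shoulders": float(row.get("alpha_sh", 10.0)) % 360.0,
            "hips": float(row.get("alpha_hi", 20.0)) % 360.0,
            "support_foot": float(row.get("alpha_sf", 5.0)) % 360.0,
        }
        cfg = replace(
            template,
            penalty_id=str(row["penalty_id"]),
            true_alpha_gk=float(np.clip(row.get("alpha_gk", 30.0), 0.0, 180.0)),
            true_orientations=orientations,
            gk_foot_moves=(
                float(row.get("d_gk_left", 0.8)),
                float(row.get("d_gk_right", 0.8)),
            ),
            kicking_foot=str(row.get("foot_used", "right")),
            seed=int(study_config.seed * 100_003 + i) % (2**31),
        )
        bundles.append(simulate_scene(cfg))
    return table, bundles, params


def write_study(
    table: pd.DataFrame, bundles: Sequence[SceneBundle], out_dir: str | Path
) -> None:
    """Write a whole study: ospaf.csv (with ball_speed), per-penalty keypoint
    directories, one shared corners.csv and annotations.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # pose-truth columns stay out of the coded table on disk: the pipeline
    # re-derives them from the keypoints
    drop = [c for c in table.columns if c.startswith(("alpha_", "d_gk_"))]
    table.drop(columns=drop).to_csv(out_dir / "ospaf.csv", index=False)
    annotations = []
    for bundle in bundles:
        pid = bundle.annotation.penalty_id
        write_openpose_frames(
            list(bundle.kicker.frames) + list(bundle.goalkeeper.frames),
            out_dir / "keypoints" / pid,
            prefix=pid,
        )
        annotations.append(bundle.annotation)
    if bundles:
        write_corner_file(bundles[0].correspondences, out_dir / "corners.csv")
    write_annotations(annotations, out_dir / "annotations.csv")
    truth = pd.DataFrame([b.ground_truth for b in bundles])
    truth.to_csv(out_dir / "ground_truth.csv", index=False)
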