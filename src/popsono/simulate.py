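"""Synthetic midsagittal Valsalva scene simulator.

Generates, per virtual patient, the same artefacts a segmentation network
would produce on a real dynamic transperineal ultrasound video: one soft
confidence map per organ and frame, values in [0, 1].  Alongside the maps it
keeps the underlying organ trajectories and derives ground-truth prolapse
labels from the standard mm-threshold sonographic criteria, so that every
downstream stage (feature engineering, modelling, evaluation) can be
exercised and audited without access to clinical data.

Diagnostic criteria (descent measured during Valsalva relative to the
posterior-inferior edge of the pubic symphysis, along the image vertical):

* cystocele          — bladder descends >= 10 mm below the landmark;
* cystourethrocele   — cystocele with urethral involvement (urethra also
                       descends >= 10 mm below the landmark);
* uterine prolapse   — the pubis-to-uterine-fundus distance shrinks by
                       >= 15 mm between rest and maximal Valsalva;
* cervical elongation— that shrinkage stays < 15 mm while the cervix
                       descends >= 15 mm below the landmark;
* rectocele          — rectum descends >= 15 mm with anterior rectal wall
                       herniation (flag);
* enterocele         — the enterocele region descends >= 15 mm with
                       abdominal content anterior to the anorectal angle
                       (flag);
* any prolapse       — logical OR of the six.

The simulated network was "trained on healthy anatomy": its confidence in an
organ degrades as the organ departs from the healthy reference position,
which is the anomaly signal the downstream classifier exploits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from popsono.organs import ENTEROCELE_REGION, HEALTHY_LAYOUT_MM, ORGANS

# mm thresholds of the sonographic diagnostic criteria
CYSTOCELE_THRESHOLD_MM = 10.0
URETHRA_THRESHOLD_MM = 10.0
UTERINE_THRESHOLD_MM = 15.0
CERVIX_THRESHOLD_MM = 15.0
RECTOCELE_THRESHOLD_MM = 15.0
ENTEROCELE_THRESHOLD_MM = 15.0

DESCENT_KEYS = (
    "bladder_descent_mm",
    "urethra_descent_mm",
    "fundus_distance_reduction_mm",
    "cervix_descent_mm",
    "rectum_descent_mm",
    "enterocele_descent_mm",
)

TARGET_NAMES = (
    "cystocele",
    "cystourethrocele",
    "uterine_prolapse",
    "cervical_elongation",
    "rectocele",
    "enterocele",
    "any_prolapse",
)


@dataclass(frozen=True)
class SceneConfig:
    """Rendering and acquisition parameters for one synthetic video.

    ``n_frames`` may be a fixed count or an inclusive (low, high) range from
    which each patient's video length is drawn, mirroring the variable
    duration of real Valsalva clips (typically 100-200 frames).
    """

    frame_height: int = 128
    frame_width: int = 128
    mm_per_pixel: float = 0.5
    n_frames: int | tuple[int, int] = (100, 200)
    organ_set: tuple[str, ...] = ORGANS
    seed: int = 0
    healthy_peak: float = 0.95
    edge_softness_px: float = 1.5
    anomaly_degradation: float = 0.5
    degradation_scale_mm: float = 30.0
    center_jitter_px: float = 1.0
    speckle_sd: float = 0.02
    # extra caudal shift of every organ in a prolapse patient, as a fraction
    # of the largest pathological descent (generalised pelvic floor laxity)
    co_descent_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")
        if self.frame_height < 1 or self.frame_width < 1:
            raise ValueError("frame dimensions must be positive")
        lo, hi = self.n_frames_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid n_frames specification: {self.n_frames!r}")
        if len(set(self.organ_set)) != 8:
            raise ValueError("organ_set must contain exactly 8 distinct organs")
        if not 0.0 <= self.anomaly_degradation <= 1.0:
            raise ValueError("anomaly_degradation must lie in [0, 1]")

    @property
    def n_frames_range(self) -> tuple[int, int]:
        if isinstance(self.n_frames, int):
            return (self.n_frames, self.n_frames)
        lo, hi = self.n_frames
        return (int(lo), int(hi))

    def draw_n_frames(self, rng: np.random.Generator) -> int:
        lo, hi = self.n_frames_range
        if lo == hi:
            return lo
        return int(rng.integers(lo, hi + 1))


@dataclass(frozen=True)
class PathologyProfile:
    """Intended pathology content of one simulated patient.

    Descent magnitudes are the *target measured values* of the corresponding
    diagnostic quantity (mm below the pubic landmark, or mm of
    pubis-fundus distance reduction for uterine prolapse).  They are only
    honoured for pathologies whose flag is set; healthy organs move by a
    small physiological amount instead.
    """

    cystocele: bool = False
    cystourethrocele: bool = False
    uterine_prolapse: bool = False
    cervical_elongation: bool = False
    rectocele: bool = False
    enterocele: bool = False
    bladder_descent_mm: float = 0.0
    urethra_descent_mm: float = 0.0
    fundus_descent_mm: float = 0.0
    cervix_descent_mm: float = 0.0
    rectum_descent_mm: float = 0.0
    enterocele_descent_mm: float = 0.0
    herniation_flag: bool = False
    abdominal_content_flag: bool = False

    def __post_init__(self) -> None:
        for name in (
            "bladder_descent_mm",
            "urethra_descent_mm",
            "fundus_descent_mm",
            "cervix_descent_mm",
            "rectum_descent_mm",
            "enterocele_descent_mm",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.uterine_prolapse and self.cervical_elongation:
            raise ValueError(
                "cervical elongation is defined in the absence of uterine "
                "prolapse; the two flags are mutually exclusive"
            )

    @property
    def any_prolapse(self) -> bool:
        return any(
            (
                self.cystocele,
                self.cystourethrocele,
                self.uterine_prolapse,
                self.cervical_elongation,
                self.rectocele,
                self.enterocele,
            )
        )

    @classmethod
    def healthy(cls) -> "PathologyProfile":
        return cls()


@dataclass
class OrganTrajectory:
    """Per-frame geometry of one (elliptical) organ in pixel coordinates."""

    organ: str
    center_row: np.ndarray
    center_col: np.ndarray
    a_row: np.ndarray
    a_col: np.ndarray
    rotation: np.ndarray
    visible: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.center_row)

    def bottom_row(self) -> np.ndarray:
        """Most caudal extent (row) of the ellipse per frame."""
        return self.center_row + self.a_row

    def top_row(self) -> np.ndarray:
        """Most cranial extent (row) of the ellipse per frame."""
        return self.center_row - self.a_row


@dataclass(frozen=True)
class GroundTruth:
    labels: dict[str, int]
    descents: dict[str, float]


@dataclass
class SyntheticVideo:
    patient_id: str
    config: SceneConfig
    profile: PathologyProfile
    trajectories: dict[str, OrganTrajectory]
    maps: dict[str, np.ndarray]
    ground_truth: GroundTruth

    @property
    def n_frames(self) -> int:
        return next(iter(self.trajectories.values())).n_frames


# ---------------------------------------------------------------------------
# landmark and descent measurement
# ---------------------------------------------------------------------------


def landmark_row(pubis: OrganTrajectory) -> float:
    """Row coordinate (px) of the posterior-inferior pubic symphysis edge.

    Taken as the point of the rest-frame pubis ellipse that extends furthest
    in the caudal-posterior direction (unit vector (1, 1)/sqrt(2) in
    row/col space); for an axis-aligned ellipse this support point is
    analytic.  The pubis is probe-fixed, so the landmark is constant over
    the video.
    """
    u = 1.0 / math.sqrt(2.0)
    ar = float(pubis.a_row[0])
    ac = float(pubis.a_col[0])
    s = math.hypot(ar * u, ac * u)
    return float(pubis.center_row[0]) + ar * ar * u / s


def measure_descents(
    trajectories: dict[str, OrganTrajectory], mm_per_pixel: float
) -> dict[str, float]:
    """Measure the diagnostic descent quantities (mm) from trajectories.

    Descents are signed vertical offsets of the organ's most caudal point
    below the pubic landmark, maximised over frames; the pubis-fundus
    distance is the vertical separation between landmark and uterine fundus
    (most cranial uterine point), and its reduction is rest minus the
    minimum over the video.
    """
    if mm_per_pixel <= 0:
        raise ValueError("mm_per_pixel must be positive")
    if "pubis" not in trajectories:
        raise ValueError("pubis trajectory missing: it is the landmark reference")
    lrow = landmark_row(trajectories["pubis"])
    scale = mm_per_pixel

    def max_descent(organ: str) -> float:
        traj = trajectories[organ]
        return float(np.max(traj.bottom_row() - lrow)) * scale

    out: dict[str, float] = {}
    out["bladder_descent_mm"] = max_descent("bladder")
    out["urethra_descent_mm"] = max_descent("urethra")
    uterus = trajectories["uterus"]
    fundus_dist = (lrow - uterus.top_row()) * scale  # per-frame, mm
    out["fundus_distance_reduction_mm"] = float(fundus_dist[0] - np.min(fundus_dist))
    out["cervix_descent_mm"] = max_descent("uterus")
    out["rectum_descent_mm"] = max_descent("rectum")
    if ENTEROCELE_REGION in trajectories:
        out["enterocele_descent_mm"] = max_descent(ENTEROCELE_REGION)
    else:
        out["enterocele_descent_mm"] = float("-inf")
    return out


def labels_from_descents(
    d: dict[str, float], herniation_flag: bool, abdominal_content_flag: bool
) -> dict[str, int]:
    """Apply the mm diagnostic thresholds to measured descent quantities.

    Thresholds are inclusive: a descent exactly at 10 mm (bladder/urethra)
    or 15 mm (uterus/cervix/rectum/enterocele region) is positive.
    """
    cystocele = d["bladder_descent_mm"] >= CYSTOCELE_THRESHOLD_MM
    cystourethrocele = cystocele and d["urethra_descent_mm"] >= URETHRA_THRESHOLD_MM
    uterine = d["fundus_distance_reduction_mm"] >= UTERINE_THRESHOLD_MM
    cervical = (
        d["fundus_distance_reduction_mm"] < UTERINE_THRESHOLD_MM
        and d["cervix_descent_mm"] >= CERVIX_THRESHOLD_MM
    )
    rectocele = d["rectum_descent_mm"] >= RECTOCELE_THRESHOLD_MM and herniation_flag
    enterocele = (
        d["enterocele_descent_mm"] >= ENTEROCELE_THRESHOLD_MM and abdominal_content_flag
    )
    labels = {
        "cystocele": int(cystocele),
        "cystourethrocele": int(cystourethrocele),
        "uterine_prolapse": int(uterine),
        "cervical_elongation": int(cervical),
        "rectocele": int(rectocele),
        "enterocele": int(enterocele),
    }
    labels["any_prolapse"] = int(any(labels.values()))
    return labels


def apply_diagnostic_rules(
    trajectories: dict[str, OrganTrajectory],
    herniation_flag: bool,
    abdominal_content_flag: bool,
    mm_per_pixel: float,
) -> GroundTruth:
    """Measure descents from trajectories and apply the mm criteria."""
    d = measure_descents(trajectories, mm_per_pixel)
    labels = labels_from_descents(d, herniation_flag, abdominal_content_flag)
    return GroundTruth(labels=labels, descents=d)


# ---------------------------------------------------------------------------
# trajectory synthesis
# ---------------------------------------------------------------------------


def _smoothstep(s: np.ndarray) -> np.ndarray:
    s = np.clip(s, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


def _rest_layout_px(config: SceneConfig) -> dict[str, tuple[float, float, float, float]]:
    scale = config.mm_per_pixel
    return {
        organ: tuple(v / scale for v in geom)
        for organ, geom in HEALTHY_LAYOUT_MM.items()
    }


def _landmark_row_rest_px(config: SceneConfig) -> float:
    cr, _cc, ar, ac = _rest_layout_px(config)["pubis"]
    u = 1.0 / math.sqrt(2.0)
    s = math.hypot(ar * u, ac * u)
    return cr + ar * ar * u / s


def _plan_displacements(
    config: SceneConfig, profile: PathologyProfile, rng: np.random.Generator
) -> dict[str, dict[str, float]]:
    """Target caudal displacement (px) and final caudal semi-axis per organ.

    For flagged pathologies the displacement is solved so that the measured
    diagnostic quantity lands on the profile's target value (before jitter);
    healthy organs receive a small physiological descent, plus — in prolapse
    patients — a co-descent proportional to the largest pathological
    descent, reflecting generalised pelvic floor laxity.
    """
    scale = config.mm_per_pixel
    layout = _rest_layout_px(config)
    lrow = _landmark_row_rest_px(config)

    active_mm = [0.0]
    if profile.cystocele or profile.cystourethrocele:
        active_mm.append(profile.bladder_descent_mm)
    if profile.cystourethrocele:
        active_mm.append(profile.urethra_descent_mm)
    if profile.uterine_prolapse:
        active_mm.append(profile.fundus_descent_mm)
    if profile.cervical_elongation:
        active_mm.append(profile.cervix_descent_mm)
    if profile.rectocele:
        active_mm.append(profile.rectum_descent_mm)
    if profile.enterocele:
        active_mm.append(profile.enterocele_descent_mm)
    co_px = config.co_descent_fraction * max(active_mm) / scale

    plan: dict[str, dict[str, float]] = {}
    for organ, (cr, _cc, ar, _ac) in layout.items():
        if organ == "pubis":
            plan[organ] = {"disp": 0.0, "a_row_final": ar}
            continue
        phys = rng.uniform(1.0, 3.0) / scale
        # the urethra is held by the pubourethral ligaments and does not
        # share the generalised co-descent unless itself involved
        co = 0.0 if organ == "urethra" else co_px
        plan[organ] = {"disp": phys + co, "a_row_final": ar}

    def bottom_rest(organ: str) -> float:
        cr, _cc, ar, _ac = layout[organ]
        return cr + ar

    if profile.cystocele or profile.cystourethrocele:
        target = lrow + profile.bladder_descent_mm / scale
        plan["bladder"]["disp"] = target - bottom_rest("bladder")
    if profile.cystourethrocele:
        target = lrow + profile.urethra_descent_mm / scale
        plan["urethra"]["disp"] = target - bottom_rest("urethra")
    if profile.uterine_prolapse:
        # vertical reference: fundus descent == pubis-fundus distance loss
        plan["uterus"]["disp"] = profile.fundus_descent_mm / scale
    if profile.cervical_elongation:
        # fundus stays put (small physiological drift only); the cervix
        # reaches its target by elongation of the caudal uterine axis
        cr, _cc, ar, _ac = layout["uterus"]
        fundus_final = (cr - ar) + plan["uterus"]["disp"]
        cervix_final = lrow + profile.cervix_descent_mm / scale
        a_final = max(ar, (cervix_final - fundus_final) / 2.0)
        plan["uterus"]["a_row_final"] = a_final
        # center displacement keeps the fundus (top) at fundus_final
        plan["uterus"]["disp"] = (fundus_final + a_final) - cr
    if profile.rectocele:
        target = lrow + profile.rectum_descent_mm / scale
        plan["rectum"]["disp"] = target - bottom_rest("rectum")
    if profile.enterocele:
        target = lrow + profile.enterocele_descent_mm / scale
        plan[ENTEROCELE_REGION]["disp"] = target - bottom_rest(ENTEROCELE_REGION)

    for organ, p in plan.items():
        p["disp"] = max(p["disp"], 0.0)
    return plan


def _build_trajectories(
    config: SceneConfig,
    profile: PathologyProfile,
    n_frames: int,
    rng: np.random.Generator,
) -> dict[str, OrganTrajectory]:
    layout = _rest_layout_px(config)
    plan = _plan_displacements(config, profile, rng)
    t = np.arange(n_frames, dtype=float)
    s = _smoothstep(t / max(n_frames - 1, 1))
    H, W = config.frame_height, config.frame_width

    trajectories: dict[str, OrganTrajectory] = {}
    for organ, (cr, cc, ar, ac) in layout.items():
        disp = plan[organ]["disp"]
        a_final = plan[organ]["a_row_final"]
        if organ == "pubis":
            # probe-fixed landmark: constant, jitter-free
            row = np.full(n_frames, cr)
            col = np.full(n_frames, cc)
        else:
            jr = rng.normal(0.0, config.center_jitter_px, n_frames)
            jc = rng.normal(0.0, config.center_jitter_px, n_frames)
            jr[0] = 0.0  # frame 0 is the rest reference
            jc[0] = 0.0
            row = cr + disp * s + jr
            col = cc + 0.1 * disp * s + jc
        a_row = ar + (a_final - ar) * s
        a_col = np.full(n_frames, ac)
        visible = (row >= 0) & (row < H) & (col >= 0) & (col < W)
        trajectories[organ] = OrganTrajectory(
            organ=organ,
            center_row=row,
            center_col=col,
            a_row=a_row,
            a_col=a_col,
            rotation=np.zeros(n_frames),
            visible=visible,
        )
    return trajectories


# ---------------------------------------------------------------------------
# confidence-map rendering
# ---------------------------------------------------------------------------


def render_confidence_maps(
    trajectories: dict[str, OrganTrajectory],
    config: SceneConfig,
    rng: np.random.Generator | None = None,
    anomaly_degradation: float | None = None,
) -> dict[str, np.ndarray]:
    """Render per-organ per-frame confidence maps in [0, 1].

    The map follows a smooth sigmoid ramp of the (approximate) signed
    distance to the ellipse boundary, saturating at a peak confidence that
    is scaled down with the organ's displacement from its healthy reference
    position:

        peak(t) = healthy_peak * (1 - degradation * min(1, disp_mm / D))

    with D = ``degradation_scale_mm``.  This emulates a segmentation network
    trained exclusively on healthy anatomy, which becomes less certain the
    further an organ strays from where it learned to expect it.  Optional
    speckle noise (clipped additive Gaussian) is applied when ``rng`` is
    given and ``speckle_sd`` > 0.  Only the eight segmentable organs are
    rendered; virtual measurement regions are skipped.
    """
    deg = config.anomaly_degradation if anomaly_degradation is None else anomaly_degradation
    if not 0.0 <= deg <= 1.0:
        raise ValueError("anomaly degradation must lie in [0, 1]")
    H, W = config.frame_height, config.frame_width
    w = config.edge_softness_px
    scale = config.mm_per_pixel
    layout = _rest_layout_px(config)
    rows = np.arange(H, dtype=np.float32)[None, :, None]
    cols = np.arange(W, dtype=np.float32)[None, None, :]

    maps: dict[str, np.ndarray] = {}
    for organ in config.organ_set:
        traj = trajectories[organ]
        T = traj.n_frames
        cr = traj.center_row.astype(np.float32)[:, None, None]
        cc = traj.center_col.astype(np.float32)[:, None, None]
        ar = traj.a_row.astype(np.float32)[:, None, None]
        ac = traj.a_col.astype(np.float32)[:, None, None]
        theta = traj.rotation.astype(np.float32)[:, None, None]

        dr = rows - cr
        dc = cols - cc
        if np.any(traj.rotation):
            ct, st = np.cos(theta), np.sin(theta)
            r_loc = dr * ct + dc * st
            c_loc = -dr * st + dc * ct
        else:
            r_loc, c_loc = dr, dc
        rho = np.sqrt((r_loc / ar) ** 2 + (c_loc / ac) ** 2)
        # signed distance (px) to the boundary, positive inside
        d = (1.0 - rho) * np.minimum(ar, ac)
        x = np.clip((d + w) / (2.0 * w), 0.0, 1.0)
        ramp = x * x * (3.0 - 2.0 * x)

        rest_r, rest_c = layout[organ][0], layout[organ][1]
        disp_mm = (
            np.hypot(traj.center_row - rest_r, traj.center_col - rest_c) * scale
        )
        peak = config.healthy_peak * (
            1.0 - deg * np.minimum(1.0, disp_mm / config.degradation_scale_mm)
        )
        conf = peak.astype(np.float32)[:, None, None] * ramp
        conf[~traj.visible] = 0.0
        if rng is not None and config.speckle_sd > 0:
            conf = conf + rng.normal(0.0, config.speckle_sd, conf.shape).astype(
                np.float32
            )
        maps[organ] = np.clip(conf, 0.0, 1.0, out=conf).astype(np.float32, copy=False)
    return maps


# ---------------------------------------------------------------------------
# patient- and cohort-level generation
# ---------------------------------------------------------------------------


def simulate_patient(
    config: SceneConfig,
    profile: PathologyProfile,
    seed: int,
    patient_id: str | None = None,
) -> SyntheticVideo:
    """Simulate one patient's Valsalva video.

    Deterministic for a fixed (config, profile, seed) triple.  Trajectories
    start at the healthy rest layout in frame 0 and ease monotonically (plus
    per-frame jitter) toward the Valsalva configuration dictated by the
    pathology profile; confidence maps are rendered with anomaly-dependent
    peak degradation and speckle noise.
    """
    rng = np.random.default_rng(seed)
    n_frames = config.draw_n_frames(rng)
    trajectories = _build_trajectories(config, profile, n_frames, rng)
    truth = apply_diagnostic_rules(
        trajectories,
        profile.herniation_flag,
        profile.abdominal_content_flag,
        config.mm_per_pixel,
    )
    maps = render_confidence_maps(trajectories, config, rng=rng)
    return SyntheticVideo(
        patient_id=patient_id if patient_id is not None else f"P{seed:06d}",
        config=config,
        profile=profile,
        trajectories=trajectories,
        maps=maps,
        ground_truth=truth,
    )


# Default pathology mix, expressed as conditional frequencies over a cohort
# in which roughly half the patients have some prolapse.  Within prolapse
# patients the individual pathology rates follow the composition of a
# typical urogynaecology referral population (cystocele the most common,
# enterocele rare); cystourethrocele is sampled as a subset of cystocele and
# cervical elongation only among patients without uterine prolapse, matching
# the clinical definitions.
DEFAULT_PREVALENCE: dict[str, float] = {
    "pop": 99 / 188,
    "cystocele": 67 / 99,
    "cystourethrocele_given_cystocele": 13 / 67,
    "uterine_prolapse": 41 / 99,
    "cervical_elongation_given_no_uterine": 36 / 58,
    "rectocele": 24 / 99,
    "enterocele": 9 / 99,
}

# pathological descents are drawn well clear of the diagnostic threshold
PATHOLOGICAL_DESCENT_RANGE = (1.5, 2.0)  # multiples of the mm threshold


def sample_profile(
    rng: np.random.Generator, prevalence: dict[str, float] | None = None
) -> PathologyProfile:
    """Draw one patient's pathology profile from cohort prevalences."""
    prev = dict(DEFAULT_PREVALENCE)
    if prevalence:
        unknown = set(prevalence) - set(prev)
        if unknown:
            raise ValueError(f"unknown prevalence keys: {sorted(unknown)}")
        prev.update(prevalence)
    for key, p in prev.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"prevalence {key}={p} outside [0, 1]")

    if rng.random() >= prev["pop"]:
        return PathologyProfile.healthy()

    lo, hi = PATHOLOGICAL_DESCENT_RANGE
    for _ in range(1000):
        cysto = rng.random() < prev["cystocele"]
        cystoure = cysto and rng.random() < prev["cystourethrocele_given_cystocele"]
        uterine = rng.random() < prev["uterine_prolapse"]
        cervical = (not uterine) and rng.random() < prev[
            "cervical_elongation_given_no_uterine"
        ]
        rectocele = rng.random() < prev["rectocele"]
        enterocele = rng.random() < prev["enterocele"]
        if any((cysto, cystoure, uterine, cervical, rectocele, enterocele)):
            break
    else:  # pragma: no cover - requires pathological prevalence config
        raise RuntimeError("failed to sample a prolapse profile")

    def draw(threshold: float) -> float:
        return float(rng.uniform(lo, hi) * threshold)

    return PathologyProfile(
        cystocele=cysto,
        cystourethrocele=cystoure,
        uterine_prolapse=uterine,
        cervical_elongation=cervical,
        rectocele=rectocele,
        enterocele=enterocele,
        bladder_descent_mm=draw(CYSTOCELE_THRESHOLD_MM) if cysto else 0.0,
        urethra_descent_mm=draw(URETHRA_THRESHOLD_MM) if cystoure else 0.0,
        fundus_descent_mm=draw(UTERINE_THRESHOLD_MM) if uterine else 0.0,
        cervix_descent_mm=draw(CERVIX_THRESHOLD_MM) if cervical else 0.0,
        rectum_descent_mm=draw(RECTOCELE_THRESHOLD_MM) if rectocele else 0.0,
        enterocele_descent_mm=draw(ENTEROCELE_THRESHOLD_MM) if enterocele else 0.0,
        herniation_flag=rectocele,
        abdominal_content_flag=enterocele,
    )


def iter_cohort(
    n_patients: int,
    prevalence: dict[str, float] | None = None,
    config: SceneConfig | None = None,
    seed: int = 0,
):
    """Yield ``n_patients`` simulated videos one at a time (memory-light)."""
    if n_patients < 2:
        raise ValueError("a cohort needs at least 2 patients to be splittable")
    cfg = config if config is not None else SceneConfig()
    master = np.random.default_rng(seed)
    profile_rng = np.random.default_rng(master.integers(0, 2**31))
    patient_seeds = master.integers(0, 2**31, size=n_patients)
    for i in range(n_patients):
        profile = sample_profile(profile_rng, prevalence)
        yield simulate_patient(
            cfg, profile, int(patient_seeds[i]), patient_id=f"P{i:04d}"
        )


def cohort_label_table(videos) -> pd.DataFrame:
    """Assemble the per-patient label + measured-descent table."""
    rows = []
    for v in videos:
        row: dict[str, object] = {"patient_id": v.patient_id}
        row.update(v.ground_truth.labels)
        row.update(v.ground_truth.descents)
        rows.append(row)
    cols = ["patient_id", *TARGET_NAMES, *DESCENT_KEYS]
    return pd.DataFrame(rows, columns=cols)


def generate_cohort(
    n_patients: int,
    prevalence: dict[str, float] | None = None,
    config: SceneConfig | None = None,
    seed: int = 0,
) -> tuple[list[SyntheticVideo], pd.DataFrame]:
    """Materialise a full cohort and its label table.

    Convenient for small cohorts; for large ones prefer :func:`iter_cohort`
    and stream videos through feature extraction to bound memory.
    """
    videos = list(iter_cohort(n_patients, prevalence, config, seed))
    return videos, cohort_label_table(videos)
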