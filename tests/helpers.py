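"""Independent naive oracles and scene-building helpers for the tests.

Everything here is deliberately written the dumb way (explicit loops,
closed-form arithmetic) and stays independent of the package code paths it
is used to check.
"""

from __future__ import annotations

import math

import numpy as np

from popsono.organs import ENTEROCELE_REGION, HEALTHY_LAYOUT_MM
from popsono.simulate import OrganTrajectory

MM_PER_PX = 0.5


# ---------------------------------------------------------------------------
# naive per-frame feature oracle
# ---------------------------------------------------------------------------


def naive_frame_features(m: np.ndarray) -> tuple[np.ndarray, bool]:
    """Brute-force loop implementation of the 17 per-frame descriptors."""
    H, W = m.shape
    all_vals = [float(m[i, j]) for i in range(H) for j in range(W)]
    region = [(i, j) for i in range(H) for j in range(W) if m[i, j] > 0.5]

    def stats(vals):
        n = len(vals)
        mean = sum(vals) / n
        var = sum((v - mean) ** 2 for v in vals) / n
        return mean, math.sqrt(var), max(vals), min(vals)

    out = np.full(17, np.nan)
    out[0:4] = stats(all_vals)
    present = bool(region)
    if present:
        out[4:8] = stats([float(m[i, j]) for i, j in region])
        rr = [i for i, _ in region]
        cc = [j for _, j in region]
        out[8] = sum(rr) / len(rr)
        out[9] = sum(cc) / len(cc)
        out[10] = len(region)
        out[11] = max(cc) - min(cc) + 1
        out[12] = max(rr) - min(rr) + 1
        out[13] = min(rr)
        out[14] = min(cc)
        out[15] = max(rr)
        out[16] = max(cc)
    return out, present


def naive_aggregate(feats: np.ndarray, present: np.ndarray) -> np.ndarray:
    """Brute-force (mean, population std, max, min) over present frames."""
    out = np.full(68, np.nan)
    rows = [feats[t] for t in range(len(feats)) if present[t]]
    if not rows:
        return out
    for f in range(17):
        vals = [float(r[f]) for r in rows]
        n = len(vals)
        mean = sum(vals) / n
        var = sum((v - mean) ** 2 for v in vals) / n
        out[4 * f + 0] = mean
        out[4 * f + 1] = math.sqrt(var)
        out[4 * f + 2] = max(vals)
        out[4 * f + 3] = min(vals)
    return out


# ---------------------------------------------------------------------------
# naive average precision (threshold sweep over distinct scores)
# ---------------------------------------------------------------------------


def naive_average_precision(scores, labels) -> float:
    """AP = sum_n (R_n - R_{n-1}) * P_n over score-descending thresholds."""
    scores = list(map(float, scores))
    labels = list(map(int, labels))
    n_pos = sum(labels)
    assert n_pos > 0
    thresholds = sorted(set(scores), reverse=True)
    ap = 0.0
    prev_recall = 0.0
    for th in thresholds:
        tp = sum(1 for s, y in zip(scores, labels) if s >= th and y == 1)
        fp = sum(1 for s, y in zip(scores, labels) if s >= th and y == 0)
        precision = tp / (tp + fp)
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


# ---------------------------------------------------------------------------
# independent re-implementation of the mm diagnostic thresholds
# ---------------------------------------------------------------------------


def independent_labels(
    descents: dict[str, float], herniation: bool, abdominal: bool
) -> dict[str, int]:
    """Re-derive labels from measured descents (mm) with the clinical rules."""
    cysto = descents["bladder_descent_mm"] >= 10.0
    labels = {
        "cystocele": int(cysto),
        "cystourethrocele": int(cysto and descents["urethra_descent_mm"] >= 10.0),
        "uterine_prolapse": int(descents["fundus_distance_reduction_mm"] >= 15.0),
        "cervical_elongation": int(
            descents["fundus_distance_reduction_mm"] < 15.0
            and descents["cervix_descent_mm"] >= 15.0
        ),
        "rectocele": int(descents["rectum_descent_mm"] >= 15.0 and herniation),
        "enterocele": int(descents["enterocele_descent_mm"] >= 15.0 and abdominal),
    }
    labels["any_prolapse"] = int(any(labels.values()))
    return labels


# ---------------------------------------------------------------------------
# hand-built trajectory scenes (no noise) for rule edge cases
# ---------------------------------------------------------------------------


def _static_traj(organ: str, geom_mm, n_frames: int = 2) -> OrganTrajectory:
    cr, cc, ar, ac = (v / MM_PER_PX for v in geom_mm)
    return OrganTrajectory(
        organ=organ,
        center_row=np.full(n_frames, cr),
        center_col=np.full(n_frames, cc),
        a_row=np.full(n_frames, ar),
        a_col=np.full(n_frames, ac),
        rotation=np.zeros(n_frames),
        visible=np.ones(n_frames, dtype=bool),
    )


def landmark_row_px() -> float:
    cr, _cc, ar, ac = (v / MM_PER_PX for v in HEALTHY_LAYOUT_MM["pubis"])
    u = 1.0 / math.sqrt(2.0)
    s = math.hypot(ar * u, ac * u)
    return cr + ar * ar * u / s


def scene_with_descents(
    bladder_mm: float = -4.5,
    urethra_mm: float = 3.0,
    fundus_reduction_mm: float = 0.0,
    cervix_mm: float = -6.0,
    rectum_mm: float = 4.5,
    enterocele_mm: float = -1.5,
    n_frames: int = 3,
) -> dict[str, OrganTrajectory]:
    """Noise-free scene whose measured descents hit the given values exactly.

    Each organ descends linearly so that its most caudal point ends
    ``*_mm`` below the pubic landmark in the final frame (fundus reduction
    is applied to the uterine fundus directly).
    """
    lrow = landmark_row_px()
    trajs = {"pubis": _static_traj("pubis", HEALTHY_LAYOUT_MM["pubis"], n_frames)}
    s = np.linspace(0.0, 1.0, n_frames)

    def moving(organ: str, target_bottom_mm: float) -> OrganTrajectory:
        cr, cc, ar, ac = (v / MM_PER_PX for v in HEALTHY_LAYOUT_MM[organ])
        target_center = lrow + target_bottom_mm / MM_PER_PX - ar
        row = cr + (target_center - cr) * s
        return OrganTrajectory(
            organ=organ,
            center_row=row,
            center_col=np.full(n_frames, cc),
            a_row=np.full(n_frames, ar),
            a_col=np.full(n_frames, ac),
            rotation=np.zeros(n_frames),
            visible=np.ones(n_frames, dtype=bool),
        )

    trajs["bladder"] = moving("bladder", bladder_mm)
    trajs["urethra"] = moving("urethra", urethra_mm)
    trajs["rectum"] = moving("rectum", rectum_mm)
    trajs[ENTEROCELE_REGION] = moving(ENTEROCELE_REGION, enterocele_mm)

    # uterus: move the whole ellipse down by the fundus reduction, but also
    # honour the cervix target by elongating the caudal semi-axis if needed
    cr, cc, ar, ac = (v / MM_PER_PX for v in HEALTHY_LAYOUT_MM["uterus"])
    fundus_final = (cr - ar) + fundus_reduction_mm / MM_PER_PX
    cervix_final = max(lrow + cervix_mm / MM_PER_PX, fundus_final + 2 * ar)
    a_final = (cervix_final - fundus_final) / 2.0
    center_final = fundus_final + a_final
    trajs["uterus"] = OrganTrajectory(
        organ="uterus",
        center_row=cr + (center_final - cr) * s,
        center_col=np.full(n_frames, cc),
        a_row=ar + (a_final - ar) * s,
        a_col=np.full(n_frames, ac),
        rotation=np.zeros(n_frames),
        visible=np.ones(n_frames, dtype=bool),
    )
    for organ in ("vagina", "anus", "levator_ani"):
        trajs[organ] = _static_traj(organ, HEALTHY_LAYOUT_MM[organ], n_frames)
    return trajs
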