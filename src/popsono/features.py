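"""Confidence-map feature engineering.

Turns per-organ confidence-map stacks into a flat learning table.  For each
frame and organ, 17 descriptors are computed: 4 confidence statistics over
all pixels, 4 over the organ region (pixels with confidence strictly above
0.5), and 9 geometry descriptors of that region (centroid, pixel area,
bounding-box width/height and the 4 bounding-box corner coordinates).
Videos are cut into 60-frame windows with 30-frame overlap, and each
descriptor is aggregated over the window with (mean, std, max, min),
yielding 68 variables per (organ, window) record; together with the organ
indicator this gives the 69-column dataset the classifiers are trained on.

An organ absent from a frame (empty region) contributes NaN for the 13
region-dependent descriptors; window aggregates are computed over the
frames where the organ is present, and a record for an organ never present
in the window is all-NaN.  The downstream gradient-boosted learner handles
missing values natively.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd

from popsono.organs import ORGANS
from popsono.simulate import TARGET_NAMES, SyntheticVideo

logger = logging.getLogger(__name__)

REGION_THRESHOLD = 0.5  # strict: a pixel belongs to the region iff conf > 0.5
WINDOW_LENGTH = 60
WINDOW_STEP = 30

FRAME_FEATURE_NAMES: tuple[str, ...] = (
    "conf_mean",
    "conf_std",
    "conf_max",
    "conf_min",
    "region_conf_mean",
    "region_conf_std",
    "region_conf_max",
    "region_conf_min",
    "centroid_row",
    "centroid_col",
    "region_area",
    "bbox_width",
    "bbox_height",
    "bbox_min_row",
    "bbox_min_col",
    "bbox_max_row",
    "bbox_max_col",
)
# indices of descriptors that are undefined when the organ region is empty
_REGION_DEPENDENT = tuple(range(4, 17))

AGG_STATS: tuple[str, ...] = ("mean", "std", "max", "min")

FEATURE_COLUMNS: tuple[str, ...] = tuple(
    f"{feat}_{stat}" for feat in FRAME_FEATURE_NAMES for stat in AGG_STATS
)  # 68 columns

PROVENANCE_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "video_id",
    "window_index",
    "window_start",
    "window_end",
)


class FrameWindow(NamedTuple):
    """Half-open frame interval [start, end)."""

    start: int
    end: int


def organ_region(confidence: np.ndarray) -> np.ndarray:
    """Boolean mask of the organ region: confidence strictly greater than 0.5."""
    confidence = np.asarray(confidence)
    return confidence > REGION_THRESHOLD


def confidence_features(
    confidence: np.ndarray, region: np.ndarray | None = None
) -> np.ndarray:
    """The 8 confidence statistics: (mean, std, max, min) over all pixels,
    then over region pixels (NaN when the region is empty).

    std uses the population convention (divide by n).
    """
    confidence = np.asarray(confidence, dtype=float)
    if region is None:
        region = organ_region(confidence)
    out = np.empty(8)
    out[0] = confidence.mean()
    out[1] = confidence.std()
    out[2] = confidence.max()
    out[3] = confidence.min()
    vals = confidence[region]
    if vals.size:
        out[4] = vals.mean()
        out[5] = vals.std()
        out[6] = vals.max()
        out[7] = vals.min()
    else:
        out[4:] = np.nan
    return out


def geometry_features(region: np.ndarray) -> np.ndarray:
    """The 9 region-geometry descriptors, all NaN for an empty region.

    Centroid is the unweighted mean of member pixel coordinates; area is
    the member-pixel count; bounding-box width/height use the inclusive
    pixel extent (max - min + 1).
    """
    region = np.asarray(region, dtype=bool)
    if not region.any():
        return np.full(9, np.nan)
    rr, cc = np.nonzero(region)
    min_r, max_r = rr.min(), rr.max()
    min_c, max_c = cc.min(), cc.max()
    return np.array(
        [
            rr.mean(),
            cc.mean(),
            float(rr.size),
            float(max_c - min_c + 1),
            float(max_r - min_r + 1),
            float(min_r),
            float(min_c),
            float(max_r),
            float(max_c),
        ]
    )


def frame_features(confidence: np.ndarray) -> tuple[np.ndarray, bool]:
    """All 17 per-frame descriptors for one confidence map.

    Returns ``(values, present)`` where ``present`` is False iff the organ
    region is empty (in which case the 13 region-dependent values are NaN).
    """
    values, present = stack_frame_features(np.asarray(confidence)[None])
    return values[0], bool(present[0])


def stack_frame_features(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-frame descriptors for a (T, H, W) confidence stack.

    Returns ``(features, present)`` with shapes (T, 17) and (T,).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected a (n_frames, height, width) stack")
    T, H, W = stack.shape
    feats = np.empty((T, 17))

    feats[:, 0] = stack.mean(axis=(1, 2))
    feats[:, 1] = stack.std(axis=(1, 2))
    feats[:, 2] = stack.max(axis=(1, 2))
    feats[:, 3] = stack.min(axis=(1, 2))

    mask = stack > REGION_THRESHOLD
    cnt = mask.sum(axis=(1, 2)).astype(float)
    present = cnt > 0
    safe = np.where(present, cnt, 1.0)

    r_sum = np.where(mask, stack, 0.0).sum(axis=(1, 2))
    r_mean = r_sum / safe
    dev = np.where(mask, stack - r_mean[:, None, None], 0.0)
    feats[:, 4] = r_mean
    feats[:, 5] = np.sqrt((dev * dev).sum(axis=(1, 2)) / safe)
    feats[:, 6] = np.where(mask, stack, -np.inf).max(axis=(1, 2))
    feats[:, 7] = np.where(mask, stack, np.inf).min(axis=(1, 2))

    rows = np.arange(H, dtype=float)[None, :, None]
    cols = np.arange(W, dtype=float)[None, None, :]
    feats[:, 8] = (mask * rows).sum(axis=(1, 2)) / safe
    feats[:, 9] = (mask * cols).sum(axis=(1, 2)) / safe
    feats[:, 10] = cnt

    row_any = mask.any(axis=2)  # (T, H)
    col_any = mask.any(axis=1)  # (T, W)
    min_row = row_any.argmax(axis=1).astype(float)
    max_row = (H - 1) - row_any[:, ::-1].argmax(axis=1).astype(float)
    min_col = col_any.argmax(axis=1).astype(float)
    max_col = (W - 1) - col_any[:, ::-1].argmax(axis=1).astype(float)
    feats[:, 11] = max_col - min_col + 1
    feats[:, 12] = max_row - min_row + 1
    feats[:, 13] = min_row
    feats[:, 14] = min_col
    feats[:, 15] = max_row
    feats[:, 16] = max_col

    feats[np.ix_(~present, _REGION_DEPENDENT)] = np.nan
    return feats, present


def sliding_windows(
    n_frames: int, window: int = WINDOW_LENGTH, step: int | None = None
) -> list[FrameWindow]:
    """Full sliding windows [k*step, k*step + window) covering a video.

    With the defaults (window 60, step 30 i.e. half-window overlap) a
    180-frame video yields 5 windows; videos shorter than one window yield
    none; partial trailing windows are discarded.
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    if window <= 0:
        raise ValueError("window must be positive")
    step = window // 2 if step is None else step
    if step <= 0:
        raise ValueError("step must be positive")
    if n_frames < window:
        return []
    k_max = (n_frames - window) // step
    return [FrameWindow(k * step, k * step + window) for k in range(k_max + 1)]


def aggregate_window(
    frame_feats: np.ndarray, present: np.ndarray | None = None
) -> np.ndarray:
    """Aggregate per-frame descriptors over one window into 68 values.

    For each of the 17 descriptors the (mean, population std, max, min) is
    taken over the frames in which the organ is present; if the organ is
    never present the whole record is NaN.
    """
    frame_feats = np.asarray(frame_feats, dtype=float)
    if frame_feats.ndim != 2 or frame_feats.shape[1] != len(FRAME_FEATURE_NAMES):
        raise ValueError("expected a (n_frames, 17) feature block")
    if present is None:
        present = ~np.isnan(frame_feats).any(axis=1)
    present = np.asarray(present, dtype=bool)
    sel = frame_feats[present]
    out = np.full(len(FEATURE_COLUMNS), np.nan)
    if sel.size == 0:
        return out
    out[0::4] = sel.mean(axis=0)
    out[1::4] = sel.std(axis=0)
    out[2::4] = sel.max(axis=0)
    out[3::4] = sel.min(axis=0)
    return out


def _iter_videos(cohort) -> Iterator[tuple[str, str, dict[str, np.ndarray], dict | None]]:
    """Normalise cohort items to (patient_id, video_id, stacks, labels)."""
    for item in cohort:
        if isinstance(item, SyntheticVideo):
            yield item.patient_id, item.patient_id, item.maps, item.ground_truth.labels
        else:
            pid, stacks = item[0], item[1]
            labels = item[2] if len(item) > 2 else None
            yield pid, pid, stacks, labels


def build_dataset(
    cohort: Iterable,
    window: int = WINDOW_LENGTH,
    step: int = WINDOW_STEP,
    organs: tuple[str, ...] = ORGANS,
) -> pd.DataFrame:
    """Assemble the windowed feature table for a cohort of videos.

    ``cohort`` is an iterable of :class:`~popsono.simulate.SyntheticVideo`
    or of ``(patient_id, {organ: (T, H, W) stack}, labels_dict)`` tuples
    (labels optional).  One record is emitted per (window, organ), so the
    row count is (total windows) x (number of organs).  Videos shorter than
    one window are logged and skipped.
    """
    records: list[dict] = []
    have_labels = False
    for pid, vid, stacks, labels in _iter_videos(cohort):
        n_frames = next(iter(stacks.values())).shape[0]
        wins = sliding_windows(n_frames, window, step)
        if not wins:
            logger.warning(
                "video %s has %d frames (< window %d); skipped", vid, n_frames, window
            )
            continue
        per_organ = {
            organ: stack_frame_features(stacks[organ]) for organ in organs
        }
        for w_idx, (start, end) in enumerate(wins):
            for organ in organs:
                feats, present = per_organ[organ]
                agg = aggregate_window(feats[start:end], present[start:end])
                rec: dict[str, object] = {
                    "patient_id": pid,
                    "video_id": vid,
                    "window_index": w_idx,
                    "window_start": start,
                    "window_end": end,
                    "organ": organ,
                }
                rec.update(zip(FEATURE_COLUMNS, agg))
                if labels is not None:
                    have_labels = True
                    rec.update(labels)
                records.append(rec)
    columns = list(PROVENANCE_COLUMNS) + ["organ"] + list(FEATURE_COLUMNS)
    if have_labels:
        columns += list(TARGET_NAMES)
    return pd.DataFrame(records, columns=columns)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the feature table as CSV plus a JSON sidecar schema."""
    path = Path(path)
    table.to_csv(path, index=False)
    schema = {
        "feature_columns": list(FEATURE_COLUMNS),
        "organ_vocabulary": list(ORGANS),
        "provenance_columns": list(PROVENANCE_COLUMNS),
        "target_columns": [c for c in TARGET_NAMES if c in table.columns],
    }
    path.with_suffix(".schema.json").write_text(json.dumps(schema, indent=2))


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
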