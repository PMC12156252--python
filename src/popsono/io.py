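"""HDF5 persistence for confidence-map cohorts.

Layout: one group per patient under ``/patients``; one dataset per organ of
shape (n_frames, height, width), float32 in [0, 1], gzip-compressed.
Attributes record the physical scale and frame count.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import h5py
import numpy as np

from popsono.simulate import SyntheticVideo


def save_cohort(path: str | Path, videos: Iterable[SyntheticVideo]) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        root = f.create_group("patients")
        for video in videos:
            grp = root.create_group(video.patient_id)
            grp.attrs["mm_per_pixel"] = video.config.mm_per_pixel
            grp.attrs["n_frames"] = video.n_frames
            for organ, stack in video.maps.items():
                ds = grp.create_dataset(
                    organ,
                    data=stack.astype(np.float32),
                    compression="gzip",
                    compression_opts=4,
                )
                ds.attrs["organ"] = organ
                ds.attrs["n_frames"] = stack.shape[0]
    return path


def iter_stacks(path: str | Path) -> Iterator[tuple[str, dict[str, np.ndarray]]]:
    """Yield (patient_id, {organ: stack}) pairs, one patient in memory at a time."""
    with h5py.File(path, "r") as f:
        for pid in sorted(f["patients"]):
            grp = f["patients"][pid]
            yield pid, {organ: grp[organ][()] for organ in grp}


def cohort_mm_per_pixel(path: str | Path) -> float:
    with h5py.File(path, "r") as f:
        pids = sorted(f["patients"])
        if not pids:
            raise ValueError("empty cohort file")
        return float(f["patients"][pids[0]].attrs["mm_per_pixel"])
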