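"""Session container I/O (HDF5) and standard-format exports (TIFF, CSV).

The on-disk session layout has groups ``/behavior`` (1 kHz series),
``/fluorescence`` (roi traces, neuropil, frame rate), ``/ground_truth``
(planted parameters and latent, when synthetic) and ``/meta`` (seed and
configuration as key-value attributes).
"""

from __future__ import annotations

import dataclasses

import h5py
import numpy as np
import tifffile

from .behavior import BehaviorSession
from .synthetic import GroundTruth, SimConfig


def save_session(
    path,
    behavior: BehaviorSession,
    raw: np.ndarray | None = None,
    neuropil: np.ndarray | None = None,
    truth: GroundTruth | None = None,
    config: SimConfig | None = None,
    frame_rate: float | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        b = f.create_group("behavior")
        for name in ("t", "position", "forward_speed", "rot_speed", "vr_speed", "lick", "epoch"):
            b.create_dataset(name, data=getattr(behavior, name))
        b.create_dataset("reward_times", data=behavior.reward_times)
        b.attrs["rate"] = behavior.rate
        b.attrs["track_length"] = behavior.track_length
        b.attrs["end_zone_cm"] = behavior.end_zone_cm
        b.attrs["epoch_names"] = list(behavior.epoch_names)
        if raw is not None:
            g = f.create_group("fluorescence")
            g.create_dataset("roi", data=raw)
            if neuropil is not None:
                g.create_dataset("neuropil", data=neuropil)
            g.attrs["frame_rate"] = frame_rate if frame_rate is not None else (
                config.frame_rate if config else np.nan
            )
        if truth is not None:
            g = f.create_group("ground_truth")
            for fld in dataclasses.fields(truth):
                g.create_dataset(fld.name, data=getattr(truth, fld.name))
        m = f.create_group("meta")
        if config is not None:
            m.attrs["seed"] = config.seed
            for fld in dataclasses.fields(config):
                v = getattr(config, fld.name)
                if v is None:
                    m.attrs[fld.name] = "none"
                elif isinstance(v, (int, float, str)):
                    m.attrs[fld.name] = v
                elif isinstance(v, tuple):
                    m.attrs[fld.name] = list(v)
                else:
                    m.create_dataset(fld.name, data=np.asarray(v))


def load_session(path):
    """Load a session container; returns ``(behavior, raw, neuropil, truth, meta)``.

    Missing groups come back as ``None`` (``meta`` as a dict).
    """
    with h5py.File(path, "r") as f:
        b = f["behavior"]
        behavior = BehaviorSession(
            t=b["t"][:],
            position=b["position"][:],
            forward_speed=b["forward_speed"][:],
            rot_speed=b["rot_speed"][:],
            vr_speed=b["vr_speed"][:],
            lick=b["lick"][:],
            reward_times=b["reward_times"][:],
            epoch=b["epoch"][:],
            epoch_names=tuple(
                s.decode() if isinstance(s, bytes) else str(s) for s in b.attrs["epoch_names"]
            ),
            rate=float(b.attrs["rate"]),
            track_length=float(b.attrs["track_length"]),
            end_zone_cm=float(b.attrs["end_zone_cm"]),
        )
        raw = neuropil = truth = None
        frame_rate = None
        if "fluorescence" in f:
            raw = f["fluorescence/roi"][:]
            frame_rate = float(f["fluorescence"].attrs["frame_rate"])
            if "neuropil" in f["fluorescence"]:
                neuropil = f["fluorescence/neuropil"][:]
        if "ground_truth" in f:
            g = f["ground_truth"]
            truth = GroundTruth(**{k: g[k][:] for k in g})
        meta = dict(f["meta"].attrs) if "meta" in f else {}
        meta["frame_rate"] = frame_rate
    return behavior, raw, neuropil, truth, meta


def write_movie(path, stack: np.ndarray) -> None:
    """Write an image stack as a multi-page TIFF."""
    tifffile.imwrite(path, np.asarray(stack, np.float32))


def read_movie(path) -> np.ndarray:
    return tifffile.imread(path)


def export_roi_table(rois, path) -> None:
    """ROI geometry as CSV (id, plane, centroid_um, area_um2, layer)."""
    rois.to_table().to_csv(path, index=False)
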