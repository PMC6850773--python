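"""Imaging preprocessing: motion correction, ROI detection, neuropil
subtraction, sliding-percentile ΔF/F, and quality filters.

The baseline F0 is the 8th percentile of raw fluorescence in a 300 s window
centered on each frame (truncated at the trace edges), which removes slow
drift such as photobleaching while preserving behavior-locked modulation.
Neuropil contamination is removed as F_corrected = F_roi - r * F_annulus with
r = 0.8.  Cells whose ΔF/F in the first familiar epoch has sample skewness
below 0.3 are flagged as unresponsive and dropped from analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import skew
from skimage.measure import label as cc_label

try:  # pragma: no cover
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass
class Roi:
    """A detected cell region: pixel mask plus geometry and metadata."""

    id: int
    mask: np.ndarray  # boolean image mask
    plane: int = 0
    layer: str = "unknown"  # SO | SP | unknown
    px_size_um: float = 1.0
    annulus: np.ndarray | None = None
    mean_brightness: float = float("nan")

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.px_size_um**2

    @property
    def centroid_px(self) -> tuple[float, float]:
        ys, xs = np.nonzero(self.mask)
        return float(ys.mean()), float(xs.mean())

    @property
    def centroid_um(self) -> tuple[float, float]:
        cy, cx = self.centroid_px
        return cy * self.px_size_um, cx * self.px_size_um


@dataclass
class RoiSet:
    rois: list

    def __len__(self):
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def __getitem__(self, i):
        return self.rois[i]

    def centroids_um(self) -> np.ndarray:
        return np.array([r.centroid_um for r in self.rois]).reshape(-1, 2)

    def to_table(self):
        import pandas as pd

        rows = [
            {
                "id": r.id,
                "plane": r.plane,
                "centroid_y_um": r.centroid_um[0],
                "centroid_x_um": r.centroid_um[1],
                "area_um2": r.area_um2,
                "layer": r.layer,
            }
            for r in self.rois
        ]
        return pd.DataFrame(rows)


@dataclass
class DffMatrix:
    """Cells x frames ΔF/F with per-cell validity flags and the F0 baseline."""

    values: np.ndarray
    frame_rate: float
    valid: np.ndarray
    f0: np.ndarray
    drop_reason: list = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# motion correction


@dataclass
class MotionResult:
    stack: np.ndarray
    shifts: np.ndarray  # (frames, 2) integer (dy, dx)
    peak_corr: np.ndarray  # normalized correlation peak per frame
    unreliable: np.ndarray  # flagged frames (low peak or excessive shift)


def _xcorr_shift(ref_f, frame, shape):
    """Integer shift maximizing circular cross-correlation, via FFT."""
    c = np.fft.irfft2(ref_f * np.conj(np.fft.rfft2(frame)), s=shape)
    peak = np.unravel_index(np.argmax(c), c.shape)
    shift = np.array(peak)
    shift[shift > np.array(shape) // 2] -= np.array(shape)[shift > np.array(shape) // 2]
    return -shift, c.max()


def motion_correct(
    stack: np.ndarray,
    max_shift_px: int = 20,
    min_peak_corr: float = 0.3,
    n_ref_frames: int = 100,
) -> MotionResult:
    """Rigidly register each frame to the mean of the first ``n_ref_frames``.

    The shift maximizes the cross-correlation with the reference (computed on
    mean-subtracted frames and normalized, so ``peak_corr`` is a correlation
    coefficient).  Frames whose peak correlation falls below
    ``min_peak_corr`` or whose shift exceeds ``max_shift_px`` are flagged
    unreliable and left unshifted.
    """
    stack = np.asarray(stack, float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a stack with at least 2 frames")
    n, h, w = stack.shape
    ref = stack[: min(n_ref_frames, n)].mean(axis=0)
    ref0 = ref - ref.mean()
    ref_f = np.fft.rfft2(ref0)
    ref_norm = np.linalg.norm(ref0)
    out = np.empty_like(stack)
    shifts = np.zeros((n, 2), int)
    peaks = np.zeros(n)
    bad = np.zeros(n, bool)
    for i in range(n):
        fr = stack[i] - stack[i].mean()
        nrm = np.linalg.norm(fr)
        if nrm == 0 or ref_norm == 0:
            bad[i] = True
            out[i] = stack[i]
            continue
        shift, cmax = _xcorr_shift(ref_f, fr, (h, w))
        peaks[i] = cmax / (ref_norm * nrm)
        if peaks[i] < min_peak_corr or np.abs(shift).max() > max_shift_px:
            bad[i] = True
            out[i] = stack[i]
        else:
            shifts[i] = shift
            out[i] = np.roll(np.roll(stack[i], -shift[0], axis=0), -shift[1], axis=1)
    return MotionResult(stack=out, shifts=shifts, peak_corr=peaks, unreliable=bad)


# ---------------------------------------------------------------------------
# ROI detection


def detect_rois(
    stack: np.ndarray,
    px_size_um: float = 1.0,
    sd_z_threshold: float = 1.5,
    min_area_um2: float = 90.0,
    plane: int = 0,
    connectivity: int = 2,
    robust: bool = True,
) -> RoiSet:
    """Detect active somata as contiguous regions of high temporal variance.

    The per-pixel temporal SD map is z-scored across pixels, thresholded at
    ``sd_z_threshold``, and 8-connected components (``connectivity=2``) with
    area above ``min_area_um2`` are kept.  ``robust`` z-scores with the
    median and MAD (scaled to the normal), so that a handful of very active
    somata cannot inflate the scale and mask dimmer cells; set it False for
    plain mean/SD standardization.  Overlapping cells are not split
    automatically; use :func:`apply_mask_edits` to supply manual separations.
    """
    stack = np.asarray(stack, float)
    if stack.ndim != 3 or stack.shape[0] < 10:
        raise ValueError("need a motion-corrected stack with at least 10 frames")
    sd_map = stack.std(axis=0)
    if robust:
        mu = np.median(sd_map)
        sigma = 1.4826 * np.median(np.abs(sd_map - mu))
    else:
        mu, sigma = sd_map.mean(), sd_map.std()
    if sigma == 0:
        return RoiSet(rois=[])
    z = (sd_map - mu) / sigma
    lbl = cc_label(z > sd_z_threshold, connectivity=connectivity)
    mean_img = stack.mean(axis=0)
    rois = []
    for k in range(1, lbl.max() + 1):
        mask = lbl == k
        if mask.sum() * px_size_um**2 > min_area_um2:
            rois.append(
                Roi(
                    id=len(rois),
                    mask=mask,
                    plane=plane,
                    px_size_um=px_size_um,
                    mean_brightness=float(mean_img[mask].mean()),
                )
            )
    return RoiSet(rois=rois)


def apply_mask_edits(rois: RoiSet, edits: dict) -> RoiSet:
    """Manual-edit hook: replace ROI masks with externally supplied splits.

    ``edits`` maps an ROI id to a list of replacement boolean masks (e.g. two
    masks to split a merged pair).  Returns a new RoiSet with fresh ids.
    """
    out = []
    for r in rois:
        if r.id in edits:
            for m in edits[r.id]:
                out.append(
                    Roi(id=0, mask=m, plane=r.plane, layer=r.layer, px_size_um=r.px_size_um)
                )
        else:
            out.append(r)
    for i, r in enumerate(out):
        r.id = i
    return RoiSet(rois=out)


def make_annuli(rois: RoiSet, shape: tuple, inner_um: float = 5.0, outer_um: float = 20.0) -> RoiSet:
    """Attach a perisomatic annulus (``inner_um``-``outer_um`` from the ROI
    boundary) to each ROI, excluding every detected ROI's pixels."""
    all_masks = np.zeros(shape, bool)
    for r in rois:
        all_masks |= r.mask
    for r in rois:
        dist = ndimage.distance_transform_edt(~r.mask, sampling=r.px_size_um)
        ring = (dist > inner_um) & (dist <= outer_um) & ~all_masks
        r.annulus = ring
    return rois


def extract_traces(stack: np.ndarray, rois: RoiSet, use_annulus: bool = False) -> np.ndarray:
    """Mean fluorescence per frame over each ROI mask (or its annulus)."""
    out = np.empty((len(rois), stack.shape[0]))
    for i, r in enumerate(rois):
        m = r.annulus if use_annulus else r.mask
        if m is None or not m.any():
            out[i] = np.nan
        else:
            out[i] = stack[:, m].mean(axis=1)
    return out


def dedupe_across_planes(rois: RoiSet, match_radius_um: float = 10.0) -> RoiSet:
    """Collapse the same cell recorded in several planes onto one ROI.

    ROIs from different planes whose centroids fall within
    ``match_radius_um`` are grouped (transitively); within each group only the
    ROI with the highest mean brightness is retained.
    """
    n = len(rois)
    if n == 0:
        return RoiSet(rois=[])
    cents = rois.centroids_um()
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if rois[i].plane != rois[j].plane and np.hypot(*(cents[i] - cents[j])) < match_radius_um:
                parent[find(i)] = find(j)
    groups: dict = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    keep = sorted(
        max(idxs, key=lambda k: (np.nan_to_num(rois[k].mean_brightness, nan=-np.inf), -k))
        for idxs in groups.values()
    )
    out = [rois[i] for i in keep]
    for i, r in enumerate(out):
        r.id = i
    return RoiSet(rois=out)


# ---------------------------------------------------------------------------
# neuropil correction and ΔF/F


def neuropil_correct(f_roi: np.ndarray, f_annulus: np.ndarray, r: float = 0.8) -> np.ndarray:
    """Subtract the perisomatic (annulus) signal: ``f_roi - r * f_annulus``."""
    f_roi = np.asarray(f_roi, float)
    f_annulus = np.asarray(f_annulus, float)
    if f_roi.shape != f_annulus.shape:
        raise ValueError("ROI and annulus traces must have equal length")
    if f_annulus.size == 0 or np.all(np.isnan(f_annulus)):
        warnings.warn("empty annulus; skipping neuropil correction")
        return f_roi.copy()
    return f_roi - r * f_annulus


if _HAVE_NUMBA:

    @njit(cache=True)
    def _sliding_percentile_stream(x, half, q):  # pragma: no cover - jitted
        n = x.shape[0]
        out = np.empty(n)
        lo = 0
        hi = min(n, half + 1)
        buf = np.empty(n if n < 2 * half + 2 else 2 * half + 2, x.dtype)
        srt = np.sort(x[lo:hi])
        m = hi - lo
        buf[:m] = srt
        for t in range(n):
            new_lo = t - half if t - half > 0 else 0
            new_hi = t + half + 1 if t + half + 1 < n else n
            for i in range(lo, new_lo):
                v = x[i]
                j = np.searchsorted(buf[:m], v)
                for k2 in range(j, m - 1):
                    buf[k2] = buf[k2 + 1]
                m -= 1
            for i in range(hi, new_hi):
                v = x[i]
                j = np.searchsorted(buf[:m], v)
                for k2 in range(m, j, -1):
                    buf[k2] = buf[k2 - 1]
                buf[j] = v
                m += 1
            lo, hi = new_lo, new_hi
            pos = q * (m - 1)
            k = int(pos)
            frac = pos - k
            if k + 1 < m:
                out[t] = buf[k] * (1.0 - frac) + buf[k + 1] * frac
            else:
                out[t] = buf[k]
        return out


def _sliding_percentile_numpy(x, half, q):
    n = len(x)
    out = np.empty(n)
    w = 2 * half + 1
    if n >= w:
        from numpy.lib.stride_tricks import sliding_window_view

        win = sliding_window_view(x, w)
        pos = q * (w - 1)
        k = int(pos)
        frac = pos - k
        part = np.partition(win, (k, min(k + 1, w - 1)), axis=1)
        out[half : n - half] = part[:, k] * (1 - frac) + part[:, min(k + 1, w - 1)] * frac
    for t in list(range(min(half, n))) + list(range(max(n - half, 0), n)):
        seg = x[max(0, t - half) : min(n, t + half + 1)]
        out[t] = np.percentile(seg, q * 100)
    return out


def sliding_percentile(x: np.ndarray, window_frames: int, percentile: float) -> np.ndarray:
    """Percentile of ``x`` in a centered window of ``window_frames`` around
    each sample, truncated (shrinking) at the edges, with linear interpolation
    between order statistics."""
    x = np.asarray(x, float)
    half = max(int(window_frames) // 2, 1)
    q = percentile / 100.0
    if _HAVE_NUMBA:
        return _sliding_percentile_stream(x, half, q)
    return _sliding_percentile_numpy(x, half, q)


def compute_dff(
    f: np.ndarray, frame_rate: float, window_s: float = 300.0, percentile: float = 8.0
):
    """Sliding-percentile ΔF/F.

    ``F0(t)`` is the ``percentile``-th percentile of ``f`` in a ``window_s``
    window centered on ``t`` (truncated at the edges);
    ``ΔF/F = (f - F0) / F0``.  Returns ``(dff, f0, valid)``; ``valid`` is
    False when F0 is non-positive anywhere (the cell should be excluded).
    """
    f = np.asarray(f, float)
    if f.size < 2:
        raise ValueError("trace must have at least 2 frames")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    f0 = sliding_percentile(f, int(round(window_s * frame_rate)), percentile)
    valid = bool(np.all(f0 > 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (f - f0) / f0
    return dff, f0, valid


def skewness_filter(dff_fam: np.ndarray, threshold: float = 0.3):
    """Keep a cell iff the sample skewness of its first-familiar-epoch ΔF/F is
    at least ``threshold``.  Returns ``(keep, reason)``."""
    dff_fam = np.asarray(dff_fam, float)
    if np.std(dff_fam) < 1e-12:
        return False, "flat"
    sk = skew(dff_fam)
    if sk >= threshold:
        return True, ""
    return False, f"skewness {sk:.3f} < {threshold}"
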