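"""Image-analysis metrics: apparent SNR/CNR, blood-signal homogeneity, and
threshold-based ventricular volumetry (EDV/ESV/SV/EF).

Apparent SNR is the ROI mean divided by the standard deviation of a noise
ROI placed outside the body; CNR = SNR(blood) - SNR(reference tissue).
All standard deviations use the sample (n-1) convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["FunctionReport", "apparent_snr", "cnr", "homogeneity",
           "segment_chamber", "function_report", "ventricular_function",
           "corner_noise_roi", "label_roi"]


@dataclass(frozen=True)
class FunctionReport:
    """Ventricular function indices: volumes in uL, EF as a fraction."""

    edv: float
    esv: float
    ed_frame: int
    es_frame: int

    @property
    def sv(self) -> float:
        return self.edv - self.esv

    @property
    def ef(self) -> float:
        return self.sv / self.edv

    def as_dict(self) -> dict:
        return {"EDV_uL": self.edv, "ESV_uL": self.esv, "SV_uL": self.sv,
                "EF_percent": 100.0 * self.ef, "ED_frame": self.ed_frame,
                "ES_frame": self.es_frame}


def _roi_values(vol: np.ndarray, roi: np.ndarray) -> np.ndarray:
    roi = np.asarray(roi)
    vals = vol[roi] if roi.dtype == bool else vol[tuple(roi.T)]
    if vals.size == 0:
        raise ValueError("empty ROI")
    return vals


def apparent_snr(vol: np.ndarray, roi, noise_roi) -> float:
    """ROI mean divided by the noise-ROI standard deviation (sample, n-1)."""
    noise = _roi_values(vol, noise_roi)
    sd = float(np.std(noise, ddof=1))
    if sd == 0:
        raise ValueError("noise ROI has zero standard deviation (noiseless input)")
    return float(np.mean(_roi_values(vol, roi))) / sd


def cnr(vol: np.ndarray, blood_roi, tissue_roi, noise_roi) -> float:
    """SNR(blood) - SNR(tissue); negative pre-contrast, positive post."""
    return apparent_snr(vol, blood_roi, noise_roi) - apparent_snr(vol, tissue_roi, noise_roi)


def homogeneity(cine_data: np.ndarray, rois) -> float:
    """Std across cine frames of the per-frame ROI mean blood signal.

    ``rois`` is either one ROI applied to all frames or a sequence with one
    ROI per frame.  Sample (n-1) standard deviation.
    """
    n_frames = cine_data.shape[0]
    if n_frames < 2:
        raise ValueError("homogeneity needs at least two cine frames")
    per_frame = isinstance(rois, (list, tuple)) and len(rois) == n_frames
    means = [float(np.mean(_roi_values(cine_data[f], rois[f] if per_frame else rois)))
             for f in range(n_frames)]
    return float(np.std(means, ddof=1))


def segment_chamber(vol: np.ndarray, seed_voxel, threshold_fraction: float,
                    reference_intensity: float | None = None) -> np.ndarray:
    """Connected bright component containing a seed voxel.

    Voxels above ``threshold_fraction`` x blood-pool reference intensity are
    kept; the 6-connected component containing the seed is returned as a
    boolean mask.  The reference defaults to the mean over the 3^3
    neighborhood of the seed.
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold fraction must lie in (0, 1)")
    seed = tuple(int(s) for s in seed_voxel)
    if reference_intensity is None:
        sl = tuple(slice(max(0, s - 1), s + 2) for s in seed)
        reference_intensity = float(np.mean(vol[sl]))
    mask = vol >= threshold_fraction * reference_intensity
    if not mask[seed]:
        raise ValueError("seed voxel falls below the segmentation threshold")
    labels, _ = ndimage.label(mask)
    return labels == labels[seed]


def function_report(ed_mask: np.ndarray, es_mask: np.ndarray,
                    voxel_volume_ul: float, ed_frame: int = 0,
                    es_frame: int = 0) -> FunctionReport:
    """EDV/ESV from segmented masks; SV and EF are derived properties."""
    edv = float(np.count_nonzero(ed_mask)) * voxel_volume_ul
    esv = float(np.count_nonzero(es_mask)) * voxel_volume_ul
    if esv > edv:
        raise ValueError("ESV exceeds EDV: end-diastole/systole misidentified")
    return FunctionReport(edv=edv, esv=esv, ed_frame=ed_frame, es_frame=es_frame)


def ventricular_function(cine_data: np.ndarray, seed_voxel,
                         voxel_size_um: float,
                         threshold_fraction: float = 0.5) -> FunctionReport:
    """Segment a chamber in every frame and report EDV/ESV/SV/EF.

    End-diastole/systole are the frames of maximal/minimal segmented volume.
    The blood-pool reference intensity is taken once, from the frame whose
    seed neighborhood is brightest, so the threshold is common to all frames.
    """
    n_frames = cine_data.shape[0]
    seed = tuple(int(s) for s in seed_voxel)
    sl = tuple(slice(max(0, s - 1), s + 2) for s in seed)
    ref = max(float(np.mean(cine_data[f][sl])) for f in range(n_frames))
    counts = []
    masks = []
    for f in range(n_frames):
        m = segment_chamber(cine_data[f], seed, threshold_fraction,
                            reference_intensity=ref)
        masks.append(m)
        counts.append(int(np.count_nonzero(m)))
    ed = int(np.argmax(counts))
    es = int(np.argmin(counts))
    voxel_ul = (voxel_size_um / 1000.0) ** 3  # mm^3 == uL
    return function_report(masks[ed], masks[es], voxel_ul, ed_frame=ed, es_frame=es)


def corner_noise_roi(shape, size: int = 10, offset: int = 2) -> np.ndarray:
    """Boolean mask of a size^3 box in the (0,0,0) corner, outside the body."""
    mask = np.zeros(shape, dtype=bool)
    mask[offset:offset + size, offset:offset + size, offset:offset + size] = True
    return mask


def label_roi(label_map: np.ndarray, label: int, erode: int = 1) -> np.ndarray:
    """Boolean ROI of one tissue label, eroded to avoid partial-volume rims."""
    mask = label_map == label
    if erode > 0:
        mask = ndimage.binary_erosion(mask, iterations=erode)
    if not mask.any():
        raise ValueError(f"label {label} produced an empty ROI after erosion")
    return mask
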