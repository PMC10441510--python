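"""Image quality control: intensity rescaling, normalized mutual information
against a template, an automated review threshold, prediction-slice selection
and median aggregation of per-slice predictions.

NMI uses the Studholme normalization (H(A)+H(B))/H(A,B) over a joint
histogram with equal-width bins on [0, 255]^2, so it is bounded in [1, 2]
(1 = independent, 2 = identical up to binning).
"""

from __future__ import annotations

import numpy as np

from .config import N_PREDICTION_SLICES, TEMPLATE_SHAPE

__all__ = [
    "rescale_intensity",
    "normalized_mutual_information",
    "propose_qc_threshold",
    "select_prediction_slices",
    "aggregate_slice_predictions",
]

INTENSITY_RANGE = (0.0, 255.0)


def _as_array(volume) -> np.ndarray:
    """Accept a nibabel image or a bare ndarray."""
    if hasattr(volume, "get_fdata"):
        return np.asarray(volume.get_fdata())
    return np.asarray(volume, dtype=float)


def rescale_intensity(volume):
    """Linearly map intensities to [0, 255] (min -> 0, max -> 255).

    The affine of a nibabel input is preserved. A constant volume has no
    defined rescale and raises.
    """
    data = _as_array(volume)
    lo, hi = float(np.min(data)), float(np.max(data))
    if hi == lo:
        raise ValueError("cannot rescale a constant volume")
    scaled = (data - lo) * (INTENSITY_RANGE[1] / (hi - lo))
    if hasattr(volume, "affine"):
        import nibabel as nib
        return nib.Nifti1Image(scaled, volume.affine)
    return scaled


def normalized_mutual_information(a, b, n_bins: int = 64) -> float:
    """NMI = (H(A) + H(B)) / H(A, B), joint histogram on [0, 255]^2.

    Symmetric in its arguments; requires equal shapes and ``n_bins >= 2``.
    """
    x, y = _as_array(a), _as_array(b)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    joint, _, _ = np.histogram2d(
        x.ravel(), y.ravel(), bins=n_bins,
        range=[INTENSITY_RANGE, INTENSITY_RANGE])
    p = joint / joint.sum()
    px, py = p.sum(axis=1), p.sum(axis=0)

    def entropy(q: np.ndarray) -> float:
        q = np.sort(q[q > 0])  # canonical order: NMI(a,b) == NMI(b,a) exactly
        return float(-np.sum(q * np.log(q)))

    h_joint = entropy(p.ravel())
    if h_joint == 0.0:
        raise ValueError("joint entropy is zero (constant volumes); NMI undefined")
    return (entropy(px) + entropy(py)) / h_joint


def propose_qc_threshold(nmi_values, threshold: float | None = None):
    """Tukey lower fence (Q1 - 1.5*IQR) as a reproducible surrogate for the
    visual 'below the main unimodal distribution' rule.

    Returns ``(threshold, flags)`` where ``flags[i]`` is ``"review"`` for
    values strictly below the threshold, ``"pass"`` otherwise. A user-supplied
    ``threshold`` overrides the rule verbatim.
    """
    values = np.asarray(nmi_values, dtype=float)
    if threshold is None:
        if values.size < 10:
            raise ValueError(
                "need at least 10 NMI values to propose a threshold; "
                "supply one manually")
        q1, q3 = np.percentile(values, [25.0, 75.0])
        threshold = float(q1 - 1.5 * (q3 - q1))
    flags = np.where(values < threshold, "review", "pass")
    return float(threshold), flags.tolist()


def select_prediction_slices(volume, n_slices: int = N_PREDICTION_SLICES,
                             expected_shape=TEMPLATE_SHAPE) -> np.ndarray:
    """Indices of the axial slices used for prediction: a contiguous window of
    ``n_slices`` centred on the slice whose world z-coordinate is nearest 0
    (n/2 strictly below, n/2 at/above).

    The volume must sit on the template grid (shape check against
    ``expected_shape``; pass ``expected_shape=None`` to skip).
    """
    data_shape = volume.shape
    if expected_shape is not None and tuple(data_shape) != tuple(expected_shape):
        raise ValueError(
            f"volume shape {tuple(data_shape)} does not match the template "
            f"grid {tuple(expected_shape)}")
    nz = data_shape[2]
    affine = np.asarray(volume.affine)
    # world z of voxel (0, 0, k)
    z_world = affine[2, 3] + affine[2, 2] * np.arange(nz)
    center = int(np.argmin(np.abs(z_world)))
    half = n_slices // 2
    start, stop = center - half, center + (n_slices - half)
    if start < 0 or stop > nz:
        raise ValueError(
            f"grid with {nz} axial slices too small for a {n_slices}-slice "
            f"window centred at index {center}")
    return np.arange(start, stop)


def aggregate_slice_predictions(per_slice_ages) -> float:
    """Whole-scan brain age as the sample median of the per-slice predictions
    (even counts: mean of the central pair). Order-invariant and robust to
    corruption of fewer than half the slices."""
    values = np.asarray(per_slice_ages, dtype=float)
    if values.size == 0:
        raise ValueError("no slice predictions to aggregate")
    if not np.all(np.isfinite(values)):
        raise ValueError("slice predictions must be finite")
    return float(np.median(values))
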