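"""Per-label Mahalanobis machinery shared by mapping and unseen metrics."""

from __future__ import annotations

import numpy as np

__all__ = ["LabelGaussian", "fit_label_gaussians"]


class LabelGaussian:
    """Mean, shrunk covariance and boundary of one reference label.

    The covariance is regularised as ``cov + eps * (trace(cov)/d) * I`` and
    inverted by pseudo-inverse, so small labels in high dimension stay
    usable. ``boundary`` is the configured quantile (linear interpolation)
    of the reference cells' own Mahalanobis distances.
    """

    def __init__(self, coords: np.ndarray, eps: float, quantile: float):
        self.mean = coords.mean(axis=0)
        d = coords.shape[1]
        if coords.shape[0] > 1:
            cov = np.cov(coords, rowvar=False)
        else:
            cov = np.eye(d)
        cov = np.atleast_2d(cov)
        tr = np.trace(cov)
        if tr <= 0:
            cov = np.eye(d)
            tr = float(d)
        cov = cov + eps * (tr / d) * np.eye(d)
        self.precision = np.linalg.pinv(cov)
        self.boundary = float(
            np.quantile(self.distance(coords), quantile, method="linear")
        )

    def distance(self, x: np.ndarray) -> np.ndarray:
        diff = np.atleast_2d(x) - self.mean
        return np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", diff, self.precision, diff), 0.0))


def fit_label_gaussians(
    coords: np.ndarray, labels: np.ndarray, eps: float, quantile: float
) -> dict:
    out = {}
    for lab in np.unique(labels):
        out[lab] = LabelGaussian(coords[labels == lab], eps, quantile)
    return out
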