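"""scikit-learn compatible estimators wrapping the ABCD pipeline stages.

These classes compose with sklearn ``Pipeline`` and model selection:

- :class:`OtsuThresholder` — fit learns ``threshold_`` from an image (or a
  stack of images pooled into one histogram), transform binarizes.
- :class:`LesionSegmenter` — stateless transformer running the full
  saliency/trimap/matting pipeline per image.
- :class:`AsymmetryFeatureExtractor` — transforms lesion cut-outs into the
  (similarity, correlation, skewness) feature matrix.
- :class:`CartAsymmetryClassifier` — fit/predict facade over the in-package
  CART tree, exposing ``tree_`` and JSON round-tripping.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import asymmetry as _asym
from . import classifier as _cart
from . import segmentation as _seg
from . import thresholding as _thr

__all__ = [
    "OtsuThresholder",
    "LesionSegmenter",
    "AsymmetryFeatureExtractor",
    "CartAsymmetryClassifier",
]

_SELECTORS = {
    "otsu": _thr.otsu_threshold,
    "otsu2": _thr.otsu2_threshold,
    "otsu2prime": _thr.otsu2prime_threshold,
}


class OtsuThresholder(TransformerMixin, BaseEstimator):
    """Threshold selector with the classic or dispersion-weighted objective.

    Parameters
    ----------
    method : {"otsu", "otsu2", "otsu2prime"}
        Objective family: classic between-class variance, dispersion
        weights replacing the class probabilities, or the product form.
    lesion_dark : bool
        Whether the foreground of the transformed mask is the dark class.
    """

    def __init__(self, method: str = "otsu2", lesion_dark: bool = True):
        self.method = method
        self.lesion_dark = lesion_dark

    def fit(self, X, y=None):
        if self.method not in _SELECTORS:
            raise ValueError(f"unknown method {self.method!r}")
        hist = _thr.compute_histogram(np.asarray(X))
        self.threshold_, self.diagnostics_ = _SELECTORS[self.method](hist)
        return self

    def transform(self, X):
        check_is_fitted(self, "threshold_")
        return _thr.apply_threshold(np.asarray(X), self.threshold_,
                                    lesion_dark=self.lesion_dark)


class LesionSegmenter(TransformerMixin, BaseEstimator):
    """Stateless transformer: RGB images -> binary lesion masks."""

    def __init__(self, saliency: str = "spectral", threshold_method: str = "otsu2",
                 erode_radius: float = 5.0, dilate_radius: float = 5.0,
                 alpha_cut: float = 0.5, knn_k: int = 10):
        self.saliency = saliency
        self.threshold_method = threshold_method
        self.erode_radius = erode_radius
        self.dilate_radius = dilate_radius
        self.alpha_cut = alpha_cut
        self.knn_k = knn_k

    def _config(self) -> _seg.SegmentConfig:
        return _seg.SegmentConfig(
            saliency=self.saliency,
            threshold_method=self.threshold_method,
            erode_radius=self.erode_radius,
            dilate_radius=self.dilate_radius,
            alpha_cut=self.alpha_cut,
            knn_k=self.knn_k,
        )

    def fit(self, X, y=None):
        self.n_images_ = len(X) if hasattr(X, "__len__") else 1
        return self

    def transform(self, X):
        cfg = self._config()
        single = isinstance(X, np.ndarray) and X.ndim == 3
        images = [X] if single else list(X)
        masks = [_seg.segment(img, cfg)[1] for img in images]
        return masks[0] if single else masks

    def segment(self, image):
        """Full pipeline on one image, returning (LesionImage, mask)."""
        return _seg.segment(image, self._config())


class AsymmetryFeatureExtractor(TransformerMixin, BaseEstimator):
    """Lesions -> (n, 3) matrix of (similarity, correlation, skewness)."""

    feature_names = ("sift_similarity", "projection_correlation", "skewness_summary")

    def __init__(self, ratio: float = 0.7, mirror: bool = False,
                 center: str = "centroid"):
        self.ratio = ratio
        self.mirror = mirror
        self.center = center

    def fit(self, X, y=None):
        self.n_features_out_ = 3
        return self

    def transform(self, X):
        feats = [
            _asym.asymmetry_features(lesion, ratio=self.ratio, mirror=self.mirror,
                                     center=self.center).as_array()
            for lesion in X
        ]
        return np.vstack(feats)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names)


class CartAsymmetryClassifier(ClassifierMixin, BaseEstimator):
    """CART tree grown to purity on asymmetry feature vectors."""

    def __init__(self, seed: int = 0):
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.tree_ = _cart.fit_cart(X, y, seed=self.seed)
        self.classes_ = np.asarray(self.tree_.classes)
        self.n_features_in_ = self.tree_.n_features
        return self

    def predict(self, X):
        check_is_fitted(self, "tree_")
        return np.atleast_1d(_cart.predict(self.tree_, X))

    def to_json(self, path=None) -> str:
        check_is_fitted(self, "tree_")
        return self.tree_.to_json(path)

    @classmethod
    def from_json(cls, source) -> "CartAsymmetryClassifier":
        est = cls()
        est.tree_ = _cart.CartTree.from_json(source)
        est.classes_ = np.asarray(est.tree_.classes)
        est.n_features_in_ = est.tree_.n_features
        return est
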