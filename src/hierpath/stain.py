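"""H&E color handling: color balancing and stain normalization.

Two complementary tools for the two levels of the pipeline:

* **Color balancing** — a per-pixel gain / color-matrix / gamma transform
  ``RGB_out = (alpha * A * I_w * RGB_in) ** gamma`` (intensities in [0, 1])
  that aligns broad color casts between scanners and labs.  Applied to
  parent-level model inputs.
* **Stain normalization** — separates an image into hematoxylin and eosin
  contributions by non-negative matrix factorization in optical-density
  space and re-renders it with a target stain profile, preserving the
  spatial concentration maps (tissue structure).  Applied to child-level
  (Celiac severity) model inputs, which all share one staining center.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import NMF

# Reference H&E absorption (optical-density) directions, unit-norm columns.
# Hematoxylin absorbs strongly in red/green (appears blue-purple); eosin
# absorbs mostly green (appears pink).
HEMATOXYLIN_OD = np.array([0.650, 0.704, 0.286])
HEMATOXYLIN_OD = HEMATOXYLIN_OD / np.linalg.norm(HEMATOXYLIN_OD)
EOSIN_OD = np.array([0.072, 0.990, 0.105])
EOSIN_OD = EOSIN_OD / np.linalg.norm(EOSIN_OD)
REFERENCE_STAIN_MATRIX = np.stack([HEMATOXYLIN_OD, EOSIN_OD], axis=1)  # (3, 2)


# ---------------------------------------------------------------------------
# color balancing


@dataclass(frozen=True)
class ColorBalanceSpec:
    """Parameters of the gain–matrix–gamma color transform.

    ``blend_percentage`` interpolates between the input (0) and the fully
    balanced image (100); fractional settings reproduce the usual
    0.01–50 "color balancing percentage" sweep.
    """

    exposure_gain: float = 1.0
    color_matrix: tuple = ((1.0, 0, 0), (0, 1.0, 0), (0, 0, 1.0))
    illuminant_gains: tuple = (1.0, 1.0, 1.0)
    gamma: float = 1.0
    blend_percentage: float = 100.0

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.exposure_gain <= 0:
            raise ValueError("exposure gain must be positive")
        if any(g <= 0 for g in self.illuminant_gains):
            raise ValueError("illuminant gains must be positive")
        if not 0 <= self.blend_percentage <= 100:
            raise ValueError("blend percentage must lie in [0, 100]")

    @property
    def matrix(self) -> np.ndarray:
        """Combined linear operator alpha * A * diag(illuminant gains)."""
        a = np.asarray(self.color_matrix, dtype=float)
        if a.shape != (3, 3):
            raise ValueError("color matrix must be 3x3")
        return self.exposure_gain * a * np.asarray(self.illuminant_gains)


def identity_balance_spec() -> ColorBalanceSpec:
    return ColorBalanceSpec()


def color_balance(image: np.ndarray, spec: ColorBalanceSpec) -> np.ndarray:
    """Apply the gain–matrix–gamma transform to an RGB image.

    Pixels are normalized to [0, 1], passed through the linear operator,
    clipped, gamma-corrected, blended with the input at
    ``blend_percentage``, and returned in the input dtype/range.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    is_int = np.issubdtype(image.dtype, np.integer)
    x = image.astype(np.float64) / 255.0 if is_int else image.astype(np.float64)
    lin = np.clip(x @ spec.matrix.T, 0.0, 1.0)
    balanced = lin**spec.gamma
    p = spec.blend_percentage / 100.0
    out = (1.0 - p) * np.clip(x, 0.0, 1.0) + p * balanced
    if is_int:
        return np.clip(np.rint(out * 255.0), 0, 255).astype(image.dtype)
    return out


def estimate_balance_spec(
    image: np.ndarray, white_percentile: float = 99.0
) -> ColorBalanceSpec:
    """Estimate channel-independent illuminant gains from an image.

    Slide background transmits the illuminant unchanged, so the bright
    tail of each channel estimates the white point; the returned spec
    rescales each channel so that white maps to 1.  This inverts diagonal
    color casts (it does not estimate gamma).
    """
    image = np.asarray(image)
    x = image.astype(np.float64) / 255.0 if np.issubdtype(
        image.dtype, np.integer
    ) else image.astype(np.float64)
    white = np.percentile(x.reshape(-1, 3), white_percentile, axis=0)
    gains = 1.0 / np.maximum(white, 1e-3)
    return ColorBalanceSpec(illuminant_gains=tuple(gains))


def inverse_balance_spec(
    gains: tuple[float, float, float], gamma: float
) -> ColorBalanceSpec:
    """Spec that undoes a forward cast ``y = (diag(gains) x) ** gamma``.

    Because the transform applies gains before gamma, the inverse uses
    gains ``g ** -gamma`` together with exponent ``1/gamma``.
    """
    g = np.asarray(gains, dtype=float)
    return ColorBalanceSpec(
        illuminant_gains=tuple(g**-gamma), gamma=1.0 / gamma
    )


# ---------------------------------------------------------------------------
# optical density


def rgb_to_od(image: np.ndarray, i0: float = 255.0, eps: float = 1.0) -> np.ndarray:
    """Beer–Lambert optical density ``-log((I + eps) / i0)`` per channel."""
    arr = np.asarray(image, dtype=np.float64)
    return np.maximum(-np.log((arr + eps) / i0), 0.0)


def od_to_rgb(od: np.ndarray, i0: float = 255.0, eps: float = 1.0) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`, clipped to the 8-bit range."""
    arr = i0 * np.exp(-np.asarray(od, dtype=np.float64)) - eps
    return np.clip(arr, 0.0, 255.0)


# ---------------------------------------------------------------------------
# stain normalization


@dataclass
class StainNormalizationModel:
    """Fitted two-stain model: OD ~ stain_matrix @ concentrations.

    ``stain_matrix`` is (3, 2) with unit-norm non-negative columns
    (hematoxylin first), and ``concentration_percentiles`` holds the 99th
    percentile of each stain's concentration over the fitted tissue pixels,
    used to match concentration scale between images.
    """

    stain_matrix: np.ndarray
    concentration_percentiles: np.ndarray
    background_intensity: float = 255.0
    eps: float = 1.0

    def __post_init__(self):
        w = np.asarray(self.stain_matrix, dtype=float)
        if w.shape != (3, 2):
            raise ValueError("stain matrix must be 3x2 (two stains in RGB OD)")
        if np.any(w < -1e-9):
            raise ValueError("stain matrix must be non-negative")
        self.stain_matrix = w / np.linalg.norm(w, axis=0, keepdims=True)
        self.concentration_percentiles = np.asarray(
            self.concentration_percentiles, dtype=float
        )


def fit_stain_model(
    image: np.ndarray,
    sparsity: float = 0.0,
    seed: int = 0,
    od_threshold: float = 0.15,
    max_pixels: int = 20000,
) -> StainNormalizationModel:
    """Fit a two-stain NMF model to an RGB image.

    Pixels with mean optical density below ``od_threshold`` (background:
    white transmits fully, so OD ~ 0) are excluded from fitting.  An
    optional L1 penalty on concentrations encourages stain sparsity.
    """
    od = rgb_to_od(image).reshape(-1, 3)
    tissue = od[od.mean(axis=1) >= od_threshold]
    if len(tissue) == 0:
        raise ValueError("no tissue pixels above the OD threshold (all-white image?)")
    rng = np.random.default_rng(seed)
    if len(tissue) > max_pixels:
        tissue = tissue[rng.choice(len(tissue), size=max_pixels, replace=False)]
    # Warm-start the factorization at the canonical H&E absorption
    # directions; without a prior, two-stain NMF on dense mixtures is not
    # identifiable (any non-negative rotation of the factors fits equally
    # well).  Multiplicative updates then adapt both factors to the image.
    h_init = np.ascontiguousarray(REFERENCE_STAIN_MATRIX.T)  # (2, 3)
    w_init = np.maximum(tissue @ np.linalg.pinv(h_init), 1e-4)
    nmf = NMF(
        n_components=2,
        init="custom",
        solver="mu",
        max_iter=2000,
        tol=1e-7,
        alpha_W=sparsity,
        l1_ratio=1.0,
        random_state=int(seed) % (2**31),
    )
    conc = nmf.fit_transform(tissue, W=w_init, H=h_init.copy())  # (n_pixels, 2)
    stains = nmf.components_  # (2, 3) rows are stain OD directions
    norms = np.linalg.norm(stains, axis=1)
    stains = stains / norms[:, None]
    conc = conc * norms[None, :]
    # hematoxylin has the larger blue-channel OD component
    h_first = np.argsort(-stains[:, 2])
    stains = stains[h_first]
    conc = conc[:, h_first]
    percentiles = np.percentile(conc, 99, axis=0)
    return StainNormalizationModel(
        stain_matrix=stains.T, concentration_percentiles=percentiles
    )


def stain_concentrations(
    image: np.ndarray, model: StainNormalizationModel
) -> np.ndarray:
    """Per-pixel stain concentration maps (H, W, 2), least squares, clipped
    to non-negative."""
    od = rgb_to_od(image, model.background_intensity, model.eps)
    h, w, _ = od.shape
    pinv = np.linalg.pinv(model.stain_matrix)  # (2, 3)
    conc = od.reshape(-1, 3) @ pinv.T
    return np.maximum(conc, 0.0).reshape(h, w, 2)


def normalize_stain(
    image: np.ndarray,
    source_model: StainNormalizationModel,
    target_model: StainNormalizationModel,
) -> np.ndarray:
    """Re-render ``image`` with the target stain profile.

    The source concentration maps are kept spatially intact, rescaled
    channel-wise so their 99th percentiles match the target's, and
    projected back through the target stain matrix.
    """
    image = np.asarray(image)
    conc = stain_concentrations(image, source_model)
    src_p = np.maximum(source_model.concentration_percentiles, 1e-8)
    scale = target_model.concentration_percentiles / src_p
    od_new = (conc * scale) @ target_model.stain_matrix.T
    out = od_to_rgb(od_new, target_model.background_intensity, target_model.eps)
    if np.issubdtype(image.dtype, np.integer):
        return np.rint(out).astype(image.dtype)
    return out


def reference_stain_model(
    concentration_percentiles: tuple[float, float] = (1.0, 1.0),
) -> StainNormalizationModel:
    """A standard H&E target profile usable when no target image exists."""
    return StainNormalizationModel(
        stain_matrix=REFERENCE_STAIN_MATRIX.copy(),
        concentration_percentiles=np.asarray(concentration_percentiles, float),
    )


def save_stain_model(model: StainNormalizationModel, path: str | Path) -> None:
    payload = {
        "stain_matrix": model.stain_matrix.tolist(),
        "concentration_percentiles": model.concentration_percentiles.tolist(),
        "background_intensity": model.background_intensity,
        "eps": model.eps,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_stain_model(path: str | Path) -> StainNormalizationModel:
    payload = json.loads(Path(path).read_text())
    return StainNormalizationModel(
        stain_matrix=np.asarray(payload["stain_matrix"]),
        concentration_percentiles=np.asarray(payload["concentration_percentiles"]),
        background_intensity=payload["background_intensity"],
        eps=payload["eps"],
    )
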