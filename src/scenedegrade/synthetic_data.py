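"""Synthetic stand-ins for the study's materials: 1/f images, two object
categories, simulated observers, and a spectral-feature classifier.

Natural scenes have amplitude spectra that fall off roughly as 1/f; the
generator reproduces that regime with random Hermitian phase, then plants
category-specific geometry on top: smooth curved blob clusters ("animal"
surrogate, energy at low radial frequencies) versus rectilinear grid/edge
structure ("vehicle" surrogate, energy at higher frequencies along the
cardinal orientations). Observer simulation draws per-trial correctness
from the same Weibull accuracy model the fitting module estimates, with an
optional per-image latent difficulty shared between paired observers to
induce image-level error correlation. The stand-in classifier is a
regularized logistic model on radial band energies and orientation-energy
ratios; it is a desk-scale artificial categorizer for exercising the test
loop, driven by amplitude statistics rather than shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import degrade, spectra
from .psychometrics import clarity_axis, weibull

__all__ = [
    "SyntheticImageParams",
    "ObserverModel",
    "gen_pink_image",
    "gen_two_class_set",
    "crop_augment",
    "simulate_observer",
    "simulate_paired_observers",
    "spectral_features",
    "spectral_feature_classifier",
    "radial_amplitude_slope",
]

CATEGORIES = ("animal", "vehicle")


@dataclass(frozen=True)
class SyntheticImageParams:
    """Knobs of the synthetic natural-image generator.

    Defaults mirror the study's picture geometry (323 x 431 pixels) and the
    1/f amplitude regime of natural scenes; ``class_signal`` scales the
    category-specific structure added on top of the pink background.
    """

    height_px: int = 323
    width_px: int = 431
    spectral_slope: float = 1.0
    class_signal: float = 60.0

    def __post_init__(self) -> None:
        if self.spectral_slope < 0 or self.class_signal < 0:
            raise ValueError("spectral_slope and class_signal must be >= 0")


@dataclass(frozen=True)
class ObserverModel:
    """Weibull accuracy parameters per degradation kind for one simulated observer."""

    alpha: dict[str, float]
    beta: dict[str, float] = field(default_factory=dict)
    lam: float = 0.0
    shared_difficulty_sd: float = 0.0

    def params(self, kind: str) -> tuple[float, float, float]:
        return self.alpha[kind], self.beta.get(kind, 3.0), self.lam


def _pink_field(h: int, w: int, slope: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean field with amplitude ~ f^-slope and random Hermitian phase."""
    grid = spectra.frequency_grid(h, w)
    with np.errstate(divide="ignore"):
        amp = np.where(grid.radial_cpi > 0, grid.radial_cpi ** (-slope), 0.0)
    phase = np.angle(np.fft.fft2(rng.standard_normal((h, w))))
    img = np.fft.ifft2(amp * np.exp(1j * phase)).real
    return img


def gen_pink_image(params: SyntheticImageParams, seed: int) -> np.ndarray:
    """One standardized 1/f noise image on the 0-255 scale.

    The radially averaged amplitude spectrum falls off as f^-slope; pixels
    are standardized to mean 128 / SD 72.11 (clipped at the display range).
    """
    rng = np.random.default_rng(seed)
    img = _pink_field(params.height_px, params.width_px, params.spectral_slope, rng)
    return degrade.normalize_mean_sd(img)


def _blob_structure(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth curved blobs: a cluster of anisotropic Gaussians (low-frequency energy)."""
    yy, xx = np.mgrid[0:h, 0:w]
    out = np.zeros((h, w))
    for _ in range(rng.integers(3, 6)):
        cy, cx = rng.uniform(0.2, 0.8) * h, rng.uniform(0.2, 0.8) * w
        sy = rng.uniform(0.06, 0.14) * h
        sx = rng.uniform(0.06, 0.14) * w
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        ry = dy * np.cos(theta) - dx * np.sin(theta)
        rx = dy * np.sin(theta) + dx * np.cos(theta)
        out += rng.choice([-1.0, 1.0]) * np.exp(-(ry ** 2 / (2 * sy ** 2)
                                                  + rx ** 2 / (2 * sx ** 2)))
    return out


def _grid_structure(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Rectilinear structure: sharp-edged axis-aligned rectangles plus a
    cardinal square-wave grating (high-frequency, cardinal-orientation energy)."""
    out = np.zeros((h, w))
    for _ in range(rng.integers(4, 8)):
        y0 = int(rng.uniform(0.05, 0.7) * h)
        x0 = int(rng.uniform(0.05, 0.7) * w)
        y1 = y0 + int(rng.uniform(0.08, 0.25) * h)
        x1 = x0 + int(rng.uniform(0.08, 0.25) * w)
        out[y0:min(y1, h), x0:min(x1, w)] += rng.choice([-1.0, 1.0])
    # fine square-wave grating: concentrates energy well into the high band
    period = int(rng.integers(4, 7))
    axis = rng.integers(0, 2)
    coords = np.arange(h if axis == 0 else w)
    grating = np.sign(np.sin(2 * np.pi * coords / period))
    out += 1.5 * (grating[:, None] if axis == 0 else grating[None, :])
    return out


def gen_two_class_set(n_per_class: int, params: SyntheticImageParams,
                      seed: int) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Balanced labeled image set: pink background plus class geometry.

    Returns ``(images, manifest)`` where ``images`` maps image id to a
    standardized 0-255 array and the manifest records id, category and seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    ss = np.random.SeedSequence([seed, 0xA11CE])
    streams = ss.spawn(2 * n_per_class)
    images: dict[str, np.ndarray] = {}
    rows = []
    idx = 0
    for label in CATEGORIES:
        for i in range(n_per_class):
            rng = np.random.default_rng(streams[idx])
            base = _pink_field(params.height_px, params.width_px,
                               params.spectral_slope, rng)
            base = base / max(base.std(), 1e-12)
            struct = (_blob_structure if label == "animal" else _grid_structure)(
                params.height_px, params.width_px, rng)
            smax = np.abs(struct).max()
            if smax > 0 and params.class_signal > 0:
                base = base + (params.class_signal / 72.11) * struct / smax
            img = degrade.normalize_mean_sd(base)
            image_id = f"{label}_{i:04d}"
            images[image_id] = img
            rows.append({"image_id": image_id, "category": label, "seed_index": idx})
            idx += 1
    return images, pd.DataFrame(rows)


#: fixed 2 x 5 raster of crop-window offsets, as fractions of each dimension
CROP_OFFSETS = tuple((dy, dx) for dy in (0.0, 0.10)
                     for dx in (0.0, 0.05, 0.10, 0.15, 0.20))


def crop_augment(image: np.ndarray, n_versions: int = 10) -> list[np.ndarray]:
    """Deterministic 80% crops on a fixed 2 x 5 offset raster.

    Each crop is floor(0.8 H) x floor(0.8 W); the window starts at the top
    left and advances by 10% of the height vertically and 5% of the width
    horizontally, giving 10 distinct positions.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    ch, cw = int(0.8 * h), int(0.8 * w)
    if ch < 1 or cw < 1:
        raise ValueError("image too small for an 80% crop")
    if n_versions > len(CROP_OFFSETS):
        raise ValueError(f"at most {len(CROP_OFFSETS)} distinct crop positions")
    crops = []
    for dy, dx in CROP_OFFSETS[:n_versions]:
        y0, x0 = int(dy * h), int(dx * w)
        crops.append(image[y0:y0 + ch, x0:x0 + cw].copy())
    return crops


def simulate_observer(model: ObserverModel, design, seed: int,
                      observer_id: str = "obs") -> pd.DataFrame:
    """Trial table for one simulated observer.

    ``design`` is an iterable of ``(kind, level, n_trials)``. Each trial is
    correct with the Weibull probability at that condition's clarity; the
    decision label follows from correctness and a balanced true category.
    """
    rng = np.random.default_rng(seed)
    rows = []
    trial = 0
    for kind, level, n_trials in design:
        alpha, beta, lam = model.params(kind)
        x = clarity_axis(kind, level)
        p = weibull(max(x, 1e-12), alpha, beta, lam=lam) if x > 0 else 0.5
        for i in range(n_trials):
            true_cat = CATEGORIES[i % 2]
            correct = bool(rng.random() < p)
            decision = true_cat if correct else CATEGORIES[1 - i % 2]
            rows.append({"observer_id": observer_id,
                         "stimulus_id": f"{kind}_{level:.6g}_{i:05d}",
                         "true_category": true_cat,
                         "degradation_kind": kind, "level": float(level),
                         "decision": decision, "correct": correct})
            trial += 1
    return pd.DataFrame(rows)


def simulate_paired_observers(model_h: ObserverModel, model_c: ObserverModel,
                              design, shared_difficulty_sd: float,
                              seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two aligned trial tables with controllable image-level error correlation.

    Every stimulus carries a latent difficulty d ~ Normal(0, sd) that
    multiplies both observers' effective clarity by exp(d); with sd = 0 the
    two observers' errors are conditionally independent given the level.
    """
    if shared_difficulty_sd < 0:
        raise ValueError("shared_difficulty_sd must be >= 0")
    rng = np.random.default_rng(seed)
    tables: dict[str, list] = {"h": [], "c": []}
    for kind, level, n_trials in design:
        x = clarity_axis(kind, level)
        d = rng.normal(0.0, shared_difficulty_sd, size=n_trials)
        for i in range(n_trials):
            true_cat = CATEGORIES[i % 2]
            x_eff = max(x * np.exp(d[i]), 1e-12)
            sid = f"{kind}_{level:.6g}_{i:05d}"
            for tag, model in (("h", model_h), ("c", model_c)):
                alpha, beta, lam = model.params(kind)
                p = weibull(x_eff, alpha, beta, lam=lam)
                correct = bool(rng.random() < p)
                decision = true_cat if correct else CATEGORIES[1 - i % 2]
                tables[tag].append({
                    "observer_id": tag, "stimulus_id": sid,
                    "true_category": true_cat, "degradation_kind": kind,
                    "level": float(level), "decision": decision,
                    "correct": correct})
    return pd.DataFrame(tables["h"]), pd.DataFrame(tables["c"])


def radial_amplitude_slope(image: np.ndarray, f_lo_frac: float = 0.1,
                           f_hi_frac: float = 0.6, n_bins: int = 24) -> float:
    """Log-log slope of the radially averaged amplitude spectrum.

    Amplitudes are averaged in radial annuli between ``f_lo_frac`` and
    ``f_hi_frac`` of Nyquist and regressed on log frequency; -1 for a 1/f
    image, 0 for a whitened (flat) one.
    """
    image = np.asarray(image, dtype=float)
    spec = spectra.decompose(image - image.mean())
    grid = spectra.frequency_grid(*image.shape)
    f = grid.radial_cpi.ravel()
    a = spec.amplitude.ravel()
    lo, hi = f_lo_frac * grid.nyquist_cpi, f_hi_frac * grid.nyquist_cpi
    edges = np.geomspace(lo, hi, n_bins + 1)
    which = np.digitize(f, edges) - 1
    keep = (which >= 0) & (which < n_bins)
    sums = np.bincount(which[keep], weights=a[keep], minlength=n_bins)
    counts = np.bincount(which[keep], minlength=n_bins)
    centers = np.sqrt(edges[:-1] * edges[1:])
    ok = counts > 0
    mean_amp = sums[ok] / counts[ok]
    slope = np.polyfit(np.log(centers[ok]), np.log(mean_amp), 1)[0]
    return float(slope)


def band_energy_ratio(image: np.ndarray, low: tuple[float, float] = (0.02, 0.1),
                      high: tuple[float, float] = (0.25, 0.8)) -> float:
    """Log ratio of high-band to low-band spectral power (class diagnostic).

    Band edges are fractions of Nyquist. Rectilinear/grating structure
    pushes this up; smooth blob structure pulls it down.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        image = image.mean(axis=2)
    spec = spectra.decompose(image - image.mean())
    grid = spectra.frequency_grid(*image.shape)
    power = spec.amplitude ** 2
    f = grid.radial_cpi / grid.nyquist_cpi
    lo = power[(f >= low[0]) & (f < low[1])].sum()
    hi = power[(f >= high[0]) & (f < high[1])].sum()
    return float(np.log((hi + 1e-12) / (lo + 1e-12)))


def spectral_features(image: np.ndarray, n_bands: int = 7,
                      lo_frac: float = 0.06) -> np.ndarray:
    """Adjacent-band log-energy ratios plus a cardinal-orientation ratio.

    Power is pooled in ``n_bands`` log-spaced radial bands between
    ``lo_frac`` and 1.0 of Nyquist; the features are the log ratios of
    neighboring bands (the local spectral slope profile), which are
    invariant to any gain shared by a band pair, plus the
    cardinal-to-oblique energy ratio above 0.1 Nyquist. Ratios degrade
    gracefully when a band filter empties part of the spectrum, giving the
    stand-in classifier a graded rather than cliff-edge response to
    degradation.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        image = image.mean(axis=2)
    spec = spectra.decompose(image - image.mean())
    grid = spectra.frequency_grid(*image.shape)
    power = spec.amplitude ** 2
    f = grid.radial_cpi
    edges = np.geomspace(lo_frac, 1.0, n_bands + 1) * grid.nyquist_cpi
    band_log = np.array([
        np.log(power[(f >= lo) & (f < hi)].sum() + 1e-12)
        for lo, hi in zip(edges[:-1], edges[1:])])
    feats = list(np.diff(band_log))
    fv = np.fft.fftfreq(image.shape[0])[:, None]
    fu = np.fft.fftfreq(image.shape[1])[None, :]
    theta = np.abs(np.arctan2(fv, fu + 1e-300))
    theta = np.minimum(theta, np.pi - theta)  # fold to [0, pi/2]
    hi_mask = f > 0.1 * grid.nyquist_cpi
    cardinal = power[hi_mask & ((theta < np.pi / 8) | (theta > 3 * np.pi / 8))].sum()
    oblique = power[hi_mask & (theta >= np.pi / 8) & (theta <= 3 * np.pi / 8)].sum()
    feats.append(np.log((cardinal + 1e-12) / (oblique + 1e-12)))
    return np.asarray(feats)


def spectral_feature_classifier(train_images: dict[str, np.ndarray],
                                train_labels: dict[str, str],
                                test_images: dict[str, np.ndarray]
                                ) -> pd.Series:
    """Train a regularized logistic model on spectral features; score test images.

    Returns a Series of P(animal) in [0, 1] indexed by test image id,
    suitable for :func:`scenedegrade.compare_stats.aggregate_predictions`.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.preprocessing import StandardScaler

    ids = list(train_images)
    y = np.array([1 if train_labels[i] == "animal" else 0 for i in ids])
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both categories")
    X = np.stack([spectral_features(train_images[i]) for i in ids])
    scaler = StandardScaler().fit(X)
    clf = LogisticRegression(C=1.0, max_iter=2000)
    clf.fit(scaler.transform(X), y)
    test_ids = list(test_images)
    Xt = np.stack([spectral_features(test_images[i]) for i in test_ids])
    scores = clf.predict_proba(scaler.transform(Xt))[:, 1]
    return pd.Series(scores, index=test_ids, name="p_animal")
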