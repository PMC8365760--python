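"""Stimulus degradation operators and luminance renormalizations.

Four operators act in the frequency domain on 0-255 float images:

* low-pass / high-pass spatial-frequency filtering with a parabolic
  (in octaves) amplitude falloff spanning exactly three octaves between the
  passband edge F0 and the full-attenuation frequency F1;
* weighted-mean phase scrambling, which circularly mixes the original phase
  spectrum with a random Hermitian phase field while preserving the
  amplitude spectrum bin by bin;
* spectral whitening, which flattens the 1/f amplitude falloff of natural
  scenes by a gain rising linearly with radial frequency under a
  quartic-exponential guard near Nyquist.

Two renormalizations map degraded floats back to display range: a full-range
stretch to [0, 255] (applied to every degraded stimulus) and an affine
standardization to mean 128 / SD 72.11 (applied to the base picture set).

The level grids used for the human observers (4 levels per condition) and
for the artificial classifiers (15 levels per condition) are packaged in
``HUMAN_LEVELS`` / ``CNN_LEVELS``; the four matched levels shared by the two
designs are in ``MATCHED_LEVELS``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import spectra

__all__ = [
    "FilterParams",
    "DegradationSpec",
    "HUMAN_LEVELS",
    "CNN_LEVELS",
    "MATCHED_LEVELS",
    "OCTAVE_SPAN",
    "filter_gain",
    "apply_band_filter",
    "phase_scramble",
    "whiten",
    "normalize_mean_sd",
    "stretch_full_range",
    "apply_degradation",
    "build_stimulus_set",
    "to_uint8",
]

#: octaves between the passband edge F0 and full attenuation at F1
OCTAVE_SPAN = 3.0

#: degradation levels shown to human participants (F1 in cpi; phase weight as
#: a fraction of noise phase)
HUMAN_LEVELS: dict[str, tuple[float, ...]] = {
    "highpass": (120.68, 85.33, 60.34, 10.67),
    "lowpass": (5.66, 9.19, 14.93, 64.0),
    "phase_scramble": (0.70, 0.65, 0.60, 0.40),
}

#: the 15-level grids used to test the artificial classifiers
CNN_LEVELS: dict[str, tuple[float, ...]] = {
    "highpass": (170.67, 120.68, 85.33, 60.34, 42.67, 30.17, 21.33, 15.09,
                 10.67, 7.54, 5.33, 3.77, 2.67, 1.89, 1.33),
    "lowpass": (2.14, 3.48, 5.66, 9.19, 14.93, 24.25, 39.40, 64.00, 103.97,
                168.90, 274.37, 445.72, 724.08, 1176.27, 1910.85),
    "phase_scramble": (0.85, 0.80, 0.75, 0.70, 0.65, 0.60, 0.55, 0.50, 0.45,
                       0.40, 0.35, 0.30, 0.25, 0.20, 0.15),
}

#: levels present in both designs, hence directly comparable
MATCHED_LEVELS: dict[str, tuple[float, ...]] = HUMAN_LEVELS


@dataclass(frozen=True)
class FilterParams:
    """Low- or high-pass filter parameterized by its full-attenuation frequency.

    F0 (where attenuation begins) sits exactly three octaves inside F1:
    ``F0 = F1/8`` for a low-pass filter, ``F0 = F1*8`` for a high-pass one.
    """

    kind: str  # "lowpass" | "highpass"
    F1: float

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "highpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.F1 <= 0:
            raise ValueError("F1 must be positive")

    @property
    def F0(self) -> float:
        ratio = 2.0 ** OCTAVE_SPAN
        return self.F1 / ratio if self.kind == "lowpass" else self.F1 * ratio


@dataclass(frozen=True)
class DegradationSpec:
    """One degradation operation: kind, level, and (for stochastic kinds) seed.

    ``level`` is F1 in cpi for the filters and the noise-phase weight
    w in [0, 1] for phase scrambling; it is ignored for whitening.
    """

    kind: str  # lowpass | highpass | phase_scramble | whiten
    level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "highpass", "phase_scramble", "whiten"):
            raise ValueError(f"unknown degradation kind {self.kind!r}")
        if self.kind == "phase_scramble" and not 0.0 <= self.level <= 1.0:
            raise ValueError("phase weight must lie in [0, 1]")


def filter_gain(f, params: FilterParams):
    """Amplitude gain of the band filter at radial frequency ``f`` (cpi).

    Low-pass: 1 for f <= F0, 0 for f >= F1, and ``1 - (x/3)**2`` with
    ``x = log2(f/F0)`` octaves past the edge. High-pass is mirrored (gain 1
    for f >= F0, parabola in the octaves below). f = 0 returns gain 0 under
    a high-pass filter; callers that must preserve the image mean exempt the
    DC bin (as :func:`apply_band_filter` does).
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    with np.errstate(divide="ignore"):
        if params.kind == "lowpass":
            octaves = np.log2(np.where(f > 0, f / params.F0, 1.0))
            octaves = np.where(f > 0, octaves, 0.0)
        else:
            octaves = np.where(f > 0, params.F0 / np.maximum(f, 1e-300), np.inf)
            octaves = np.log2(octaves)
    x = np.clip(octaves, 0.0, OCTAVE_SPAN)
    gain = 1.0 - (x / OCTAVE_SPAN) ** 2
    return gain if gain.ndim else float(gain)


def _per_channel(image: np.ndarray):
    """Yield 2-D channel views of a grayscale or H x W x C image."""
    if image.ndim == 2:
        yield image
    elif image.ndim == 3:
        for c in range(image.shape[2]):
            yield image[:, :, c]
    else:
        raise ValueError("expected a 2-D grayscale or 3-D multichannel image")


def _assemble(channels: list[np.ndarray], template: np.ndarray) -> np.ndarray:
    if template.ndim == 2:
        return channels[0]
    return np.stack(channels, axis=-1)


def apply_band_filter(image: np.ndarray, params: FilterParams) -> np.ndarray:
    """Multiply each frequency bin's amplitude by the filter gain; phase untouched.

    The DC bin is always passed so the image mean survives high-pass
    filtering (outputs are renormalized afterwards anyway). Returns an
    unnormalized float image.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape[:2]
    grid = spectra.frequency_grid(h, w)
    gain = filter_gain(grid.radial_cpi, params)
    gain.flat[0] = 1.0  # DC exemption
    out = []
    for chan in _per_channel(image):
        spec = spectra.decompose(chan)
        out.append(spectra.recompose(
            spectra.Spectrum(spec.amplitude * gain, spec.phase, h, w)))
    return _assemble(out, image)


def _hermitian_noise_phase(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random phase field with Hermitian antisymmetry.

    Taking the phase of the DFT of white Gaussian noise yields phases
    uniform on (-pi, pi] at every free bin while the self-conjugate bins
    (DC, Nyquist rows/columns) land on {0, pi}, exactly the constraint a
    real image's phase spectrum satisfies.
    """
    return np.angle(np.fft.fft2(rng.standard_normal((h, w))))


def phase_scramble(image: np.ndarray, w: float, seed: int) -> np.ndarray:
    """Weighted-mean phase scrambling.

    The new phase at each bin is the argument of the circular mixture
    ``(1-w)*exp(i*phi_orig) + w*exp(i*phi_noise)``; the amplitude spectrum is
    kept exactly. ``w = 0`` reproduces the input; ``w = 1`` keeps only the
    random phase. Color channels share a single noise-phase field so that
    chromatic structure is displaced coherently.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("noise weight w must lie in [0, 1]")
    image = np.asarray(image, dtype=float)
    h, wid = image.shape[:2]
    rng = np.random.default_rng(seed)
    noise_phase = _hermitian_noise_phase(h, wid, rng)
    out = []
    for chan in _per_channel(image):
        spec = spectra.decompose(chan)
        mixed = (1.0 - w) * np.exp(1j * spec.phase) + w * np.exp(1j * noise_phase)
        new_phase = np.angle(mixed)
        # a zero-length mixture has undefined argument; fall back to the
        # noise phase (measure-zero event, keeps Hermitian symmetry)
        dead = np.abs(mixed) < 1e-12
        new_phase = np.where(dead, noise_phase, new_phase)
        out.append(spectra.recompose(
            spectra.Spectrum(spec.amplitude, new_phase, h, wid)))
    return _assemble(out, image)


def whitening_gain(f, nyquist_cpi: float):
    """Whitening gain W(f) = (f/fN) * exp(1 - (f/fN)^4).

    Rises linearly with radial frequency over the natural-image passband and
    rolls off smoothly just above Nyquist, flattening a 1/f amplitude
    spectrum while avoiding amplification of corner-frequency noise.
    """
    t = np.asarray(f, dtype=float) / nyquist_cpi
    return t * np.exp(1.0 - t ** 4)


def whiten(image: np.ndarray) -> np.ndarray:
    """Flatten the amplitude spectrum by the radial whitening gain.

    The DC bin keeps gain 1 so the image mean is preserved; phase is
    untouched. Returns an unnormalized float image.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape[:2]
    grid = spectra.frequency_grid(h, w)
    gain = whitening_gain(grid.radial_cpi, grid.nyquist_cpi)
    gain.flat[0] = 1.0
    out = []
    for chan in _per_channel(image):
        spec = spectra.decompose(chan)
        out.append(spectra.recompose(
            spectra.Spectrum(spec.amplitude * gain, spec.phase, h, w)))
    return _assemble(out, image)


def _luminance(image: np.ndarray) -> np.ndarray:
    """Per-pixel channel mean (identity for grayscale)."""
    return image if image.ndim == 2 else image.mean(axis=2)


def normalize_mean_sd(image: np.ndarray, target_mean: float = 128.0,
                      target_sd: float = 72.11) -> np.ndarray:
    """Affine rescale to the target luminance mean and SD, clipped to [0, 255].

    Statistics are computed on the per-pixel channel mean; the same affine
    map is applied to every channel. Raises on a constant image (its SD
    cannot be rescaled).
    """
    image = np.asarray(image, dtype=float)
    lum = _luminance(image)
    sd = lum.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant image (zero variance)")
    scaled = (image - lum.mean()) * (target_sd / sd) + target_mean
    return np.clip(scaled, 0.0, 255.0)


def stretch_full_range(image: np.ndarray) -> np.ndarray:
    """Linearly map the luminance range onto the full [0, 255] interval."""
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    if hi == lo:
        raise ValueError("cannot stretch a constant image")
    return (image - lo) * (255.0 / (hi - lo))


def to_uint8(image: np.ndarray) -> np.ndarray:
    """Quantize a [0, 255] float image to 8 bits (final step before writing)."""
    return np.clip(np.rint(image), 0, 255).astype(np.uint8)


def apply_degradation(image: np.ndarray, spec: DegradationSpec,
                      renormalize: bool = True) -> np.ndarray:
    """Run one degradation and (by default) stretch to the full 0-255 range.

    A filter whose full-attenuation frequency exceeds every frequency the
    grid carries wipes out all structure; the stimulus is then a blank
    mid-gray picture rather than an error.
    """
    if spec.kind in ("lowpass", "highpass"):
        out = apply_band_filter(image, FilterParams(spec.kind, spec.level))
    elif spec.kind == "phase_scramble":
        out = phase_scramble(image, spec.level, spec.seed)
    else:
        out = whiten(image)
    if renormalize:
        if np.ptp(out) <= 1e-9 * max(1.0, np.abs(out).max()):
            return np.full_like(np.asarray(out, dtype=float), 127.5)
        out = stretch_full_range(out)
    return out


def _stimulus_seed(master_seed: int, image_id: str, kind: str, level: float) -> int:
    """Deterministic per-stimulus seed from the master seed and identity."""
    tag = zlib.crc32(f"{image_id}|{kind}|{level:.6g}".encode())
    return int((master_seed * 2654435761 + tag) % (2 ** 31))


def build_stimulus_set(
    images: Mapping[str, np.ndarray] | Sequence[str],
    kinds: Iterable[str],
    levels_per_kind: Mapping[str, Sequence[float]],
    seed: int,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Enumerate (and optionally materialize) the full degraded-stimulus design.

    Parameters
    ----------
    images
        Either a mapping ``{image_id: pixel array}`` (stimuli are computed,
        and written as PNG when ``out_dir`` is given) or a bare sequence of
        image ids (manifest enumeration only).
    kinds, levels_per_kind
        Degradation kinds and the level grid for each.
    seed
        Master seed; per-stimulus phase-scramble seeds are derived from it
        and the stimulus identity, so re-running reproduces identical pixels.

    Returns
    -------
    DataFrame with one row per (image, kind, level):
    stimulus_id, source, kind, level, seed, path.
    """
    if hasattr(images, "keys"):
        ids = list(images.keys())
        arrays: Mapping[str, np.ndarray] | None = images  # type: ignore[assignment]
    else:
        ids = list(images)
        arrays = None
    if not ids:
        raise ValueError("empty image list")
    kinds = list(kinds)
    for kind in kinds:
        if kind not in levels_per_kind or len(levels_per_kind[kind]) == 0:
            raise ValueError(f"no level grid supplied for kind {kind!r}")

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    rows = []
    for image_id in ids:
        for kind in kinds:
            for level in levels_per_kind[kind]:
                s = _stimulus_seed(seed, str(image_id), kind, float(level))
                stim_id = f"{image_id}__{kind}__{level:.6g}"
                path = ""
                if arrays is not None and out_path is not None:
                    stim = apply_degradation(
                        arrays[image_id], DegradationSpec(kind, float(level), s))
                    path = str(out_path / f"{stim_id}.png")
                    _write_png(path, to_uint8(stim))
                rows.append({"stimulus_id": stim_id, "source": image_id,
                             "kind": kind, "level": float(level),
                             "seed": s, "path": path})
    manifest = pd.DataFrame(rows)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
    return manifest


def _write_png(path: str, arr: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, arr)
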