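"""Multi-stage environment simulation: luminance, weather, occlusion.

Pasting alone only relocates lesions; field imagery additionally degrades
visibility. This stage stacks three pixel-level perturbations — in the
fixed order luminance → weather → occlusion, so that occlusion-derived
visibility metadata reflects the final raster:

* luminance: multiplicative gain with clipping (gain 1 is the identity);
* weather: fog (alpha blend toward a light-gray veil with spatial noise,
  reducing contrast), rain (oriented bright streaks) or blur (Gaussian,
  sigma proportional to intensity — intensities compose in quadrature);
* occlusion: dark elliptical/rectangular occluders with per-box visible
  fractions measured on the raster, redrawn while any pasted box would
  lose more than ``max_box_occlusion`` of its area.

Effects never touch annotation geometry — only pixels and visibility
metadata. Intensity 0 (or probability 0) is a bit-exact no-op.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

logger = logging.getLogger(__name__)

WEATHER_KINDS = ("fog", "rain", "blur")

#: Gaussian-blur sigma (pixels) at intensity 1.
BLUR_SIGMA_SCALE = 3.0


@dataclass
class EnvProfile:
    """Configuration of the environment stage.

    The defaults are deliberately harsh (gain down to 0.4, up to half of a
    box occludable) because the point of the stage is visibility
    degradation; every knob is config-exposed.
    """

    luminance_range: tuple[float, float] = (0.4, 1.6)
    luminance_probability: float = 0.5
    weather: tuple[tuple[str, tuple[float, float], float], ...] = (
        ("fog", (0.2, 0.6), 0.25),
        ("rain", (0.2, 0.7), 0.2),
        ("blur", (0.1, 0.5), 0.25),
    )
    occluder_count_range: tuple[int, int] = (1, 3)
    occluder_size_range: tuple[float, float] = (0.05, 0.2)
    max_box_occlusion: float = 0.5
    occlusion_probability: float = 0.3
    occlusion_retries: int = 20

    def __post_init__(self) -> None:
        for kind, _, prob in self.weather:
            if kind not in WEATHER_KINDS:
                raise ValueError(f"unknown weather kind {kind!r}")
            if not (0.0 <= prob <= 1.0):
                raise ValueError("weather probability must be in [0, 1]")
        for p in (self.luminance_probability, self.occlusion_probability):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")
        if not (0.0 <= self.max_box_occlusion < 1.0):
            raise ValueError("max_box_occlusion must be in [0, 1)")


def luminance_perturb(image: np.ndarray, gain: float) -> np.ndarray:
    """Multiplicative brightness change with clipping; gain 1 is bit-exact identity."""
    if gain <= 0:
        raise ValueError(f"gain must be positive, got {gain}")
    if gain == 1.0:
        return image.copy()
    return np.clip(np.rint(image.astype(np.float64) * gain), 0, 255).astype(np.uint8)


def weather_sim(
    image: np.ndarray,
    kind: str,
    intensity: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Apply one weather effect at the given intensity in [0, 1].

    Intensity 0 is a bit-exact identity for every kind. Fog and rain use
    ``rng`` for their spatial noise (a fresh default generator if omitted).
    """
    if kind not in WEATHER_KINDS:
        raise ValueError(f"unknown weather kind {kind!r}")
    if not (0.0 <= intensity <= 1.0):
        raise ValueError("intensity must be in [0, 1]")
    if intensity == 0.0:
        return image.copy()
    rng = rng if rng is not None else np.random.default_rng()
    h, w = image.shape[:2]
    img = image.astype(np.float64)
    if kind == "fog":
        veil = 220.0
        noise = gaussian_filter(rng.standard_normal((h, w)), max(h, w) / 16)
        noise = (noise - noise.min()) / (np.ptp(noise) + 1e-12)  # [0, 1]
        a = intensity * (0.55 + 0.45 * noise)[..., None]
        out = img * (1 - a) + veil * a
    elif kind == "rain":
        streaks = np.zeros((h, w))
        n_drops = int(intensity * h * w / 200)
        xs = rng.integers(0, w, n_drops)
        ys = rng.integers(0, h, n_drops)
        length = max(3, int(0.05 * h))
        slant = rng.integers(-2, 3)
        for t in range(length):
            yy = np.clip(ys + t, 0, h - 1)
            xx = np.clip(xs + (t * slant) // length, 0, w - 1)
            streaks[yy, xx] = 1.0
        streaks = gaussian_filter(streaks, 0.6)
        out = img + 160.0 * intensity * streaks[..., None]
    else:  # blur
        sigma = BLUR_SIGMA_SCALE * intensity
        out = np.stack(
            [gaussian_filter(img[..., c], sigma) for c in range(img.shape[-1])],
            axis=-1,
        )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _occluder_mask(
    h: int, w: int, count: int, size_range: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Boolean raster of ``count`` random dark occluders (ellipses/rectangles)."""
    mask = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(count):
        frac = rng.uniform(*size_range)
        oh = max(2, int(frac * h * rng.uniform(0.6, 1.4)))
        ow = max(2, int(frac * w * rng.uniform(0.6, 1.4)))
        cy = rng.integers(0, h)
        cx = rng.integers(0, w)
        if rng.random() < 0.5:
            mask |= ((xx - cx) / (ow / 2)) ** 2 + ((yy - cy) / (oh / 2)) ** 2 <= 1.0
        else:
            mask |= (np.abs(xx - cx) <= ow // 2) & (np.abs(yy - cy) <= oh // 2)
    return mask


def box_visible_fractions(
    annotations, mask: np.ndarray
) -> list[float]:
    """Per-annotation unoccluded-area fraction measured on the occluder raster."""
    h, w = mask.shape
    fractions = []
    for ann in annotations:
        x0, y0, x1, y1 = ann.to_pixels(w, h)
        area = max(1, (x1 - x0) * (y1 - y0))
        occluded = int(mask[y0:y1, x0:x1].sum())
        fractions.append(1.0 - occluded / area)
    return fractions


def occlude(sample, profile: EnvProfile, rng: np.random.Generator):
    """Draw occluders on a sample and record per-box visible fractions.

    Occluders are redrawn (up to ``profile.occlusion_retries``) while any
    pasted box would exceed ``max_box_occlusion``; on exhaustion the effect
    is skipped (logged) and all fractions stay 1. Returns the (mutated)
    sample and its visible-fraction list.
    """
    h, w = sample.image.shape[:2]
    pasted = range(sample.n_original, len(sample.annotations))
    for _ in range(profile.occlusion_retries):
        count = int(rng.integers(profile.occluder_count_range[0],
                                 profile.occluder_count_range[1] + 1))
        mask = _occluder_mask(h, w, count, profile.occluder_size_range, rng)
        fractions = box_visible_fractions(sample.annotations, mask)
        if all(fractions[i] >= 1.0 - profile.max_box_occlusion for i in pasted):
            img = sample.image.astype(np.float64)
            shade = np.array([0.25, 0.22, 0.2])
            img[mask] = img[mask] * shade
            sample.image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
            sample.visible_fractions = fractions
            return sample, fractions
    logger.info("occlusion skipped for %s: retry budget exhausted", sample.image_id)
    fractions = [1.0] * len(sample.annotations)
    sample.visible_fractions = fractions
    return sample, fractions


def apply_env(sample, profile: EnvProfile, rng: np.random.Generator):
    """Run the full luminance → weather → occlusion stack on one sample.

    Each effect fires with its configured probability; applied effects are
    appended to ``sample.effects``. Deterministic for a given rng state.
    """
    effects: list[dict] = []
    if rng.random() < profile.luminance_probability:
        gain = float(rng.uniform(*profile.luminance_range))
        sample.image = luminance_perturb(sample.image, gain)
        effects.append({"effect": "luminance", "gain": gain})
    for kind, (lo, hi), prob in profile.weather:
        if rng.random() < prob:
            intensity = float(rng.uniform(lo, hi))
            sample.image = weather_sim(sample.image, kind, intensity, rng)
            effects.append({"effect": kind, "intensity": intensity})
    sample.visible_fractions = [1.0] * len(sample.annotations)
    if rng.random() < profile.occlusion_probability:
        occlude(sample, profile, rng)
        effects.append({"effect": "occlusion"})
    sample.effects.extend(effects)
    return sample
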