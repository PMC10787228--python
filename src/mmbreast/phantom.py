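"""Synthetic phantom cohorts of per-pixel Mueller-matrix fields.

Each phantom *measurement image* is a ground-truth 16-element Mueller field
standing in for one polarimetric acquisition of a tissue slide.  The
generative model per element:

    per-image mean  ~  Normal(profile.element_mean, profile.element_std)
    per-pixel field =  mean + correlated texture + white noise

where the texture is Gaussian-filtered white noise rescaled to a target
standard deviation (``texture_sd``) with correlation length
``texture_correlation_length`` pixels, and the white noise has standard
deviation ``pixel_noise_sd``.  A passivity clamp enforces |mij| <= m11 at
every pixel.  Everything is reproducible from
``(spec.seed, sample_index, image_index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .profiles import CLASS_LABELS, ClassProfile, builtin_profiles

__all__ = [
    "PhantomSpec",
    "MuellerFieldTruth",
    "generate_sample",
    "generate_cohort",
    "DEFAULT_COHORT_COUNTS",
]

#: Study-default cohort composition: 35 healthy and 60 cancer samples
#: (20 benign, 20 grade-2, 20 grade-3).
DEFAULT_COHORT_COUNTS: dict[str, int] = {
    "healthy": 35,
    "benign": 20,
    "grade2": 20,
    "grade3": 20,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic cohort.

    Defaults echo the study conditions: 35/20/20/20 samples per class and six
    measurement images per sample (35 healthy samples -> 210 images).
    """

    cohort_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COHORT_COUNTS)
    )
    images_per_sample: int = 6
    height: int = 64
    width: int = 64
    texture_correlation_length: float = 4.0
    texture_sd: float = 0.01
    pixel_noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.cohort_counts.values()):
            raise ValueError("cohort counts must be non-negative")
        if self.images_per_sample < 1:
            raise ValueError("images_per_sample must be positive")
        if self.height < 8 or self.width < 8:
            raise ValueError("image dimensions must be at least 8x8")
        if self.texture_correlation_length < 0:
            raise ValueError("correlation length must be non-negative")
        if self.texture_sd < 0 or self.pixel_noise_sd < 0:
            raise ValueError("noise amplitudes must be non-negative")


@dataclass
class MuellerFieldTruth:
    """Ground-truth Mueller field of one phantom measurement image.

    ``elements`` has shape (16, height, width) in canonical row-major element
    order; m11 is strictly positive and |mij| <= m11 holds pixelwise.
    """

    sample_id: str
    label: str
    elements: np.ndarray
    image_index: int = 0

    def __post_init__(self) -> None:
        el = np.asarray(self.elements, dtype=float)
        if el.ndim != 3 or el.shape[0] != 16:
            raise ValueError("elements must have shape (16, H, W)")
        self.elements = el

    def validate(self) -> None:
        m11 = self.elements[0]
        if not (m11 > 0).all():
            raise ValueError("m11 must be strictly positive everywhere")
        if (np.abs(self.elements) > m11[None] + 1e-12).any():
            raise ValueError("passivity violated: |mij| > m11 somewhere")


def _correlated_texture(
    rng: np.random.Generator, shape: tuple[int, int], corr_len: float, sd: float
) -> np.ndarray:
    """Zero-mean Gaussian texture with ~``corr_len``-pixel correlation and
    pointwise standard deviation ``sd``."""
    if sd == 0.0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    if corr_len > 0:
        white = ndimage.gaussian_filter(white, sigma=corr_len, mode="wrap")
    # demean within the image (texture models sub-image structure only; the
    # between-image mean variation is carried by the profile stds) and rescale
    # to the requested pointwise standard deviation
    white = white - white.mean()
    s = white.std()
    if s > 0:
        white = white / s
    return sd * white


def _project_physical(elements: np.ndarray) -> np.ndarray:
    """Shrink the polarized part where a 36-state intensity would go negative.

    The elementwise clamp |mij| <= m11 does not by itself guarantee that every
    probe/analyzer intensity (1/2) s_y^T M s_x is non-negative; noise tails can
    leave a pixel slightly unphysical.  At such pixels all elements except m11
    are scaled by the largest factor that restores non-negative intensities
    (the pixel is pulled toward the ideal depolarizer).  In-place; a no-op on
    pixels that are already physical, so noise-free fields are untouched.
    """
    from .polarimeter import stokes_matrix

    S = stokes_matrix()  # (6, 4)
    h, w = elements.shape[1:]
    M = elements.reshape(4, 4, h, w)
    # T[y, x] = s_y^T M s_x  (intensity up to the gain/2 factor)
    T = np.einsum("ya,abhw,xb->yxhw", S, M, S, optimize=True)
    tmin = T.min(axis=(0, 1))
    m11 = elements[0]
    bad = tmin < 0
    if bad.any():
        lam = m11[bad] / (m11[bad] - tmin[bad])
        elements[1:, bad] *= lam
    return elements


def generate_sample(
    profile: ClassProfile,
    spec: PhantomSpec,
    sample_index: int,
    image_index: int = 0,
    sample_id: str | None = None,
) -> MuellerFieldTruth:
    """Generate one phantom measurement image for a sample of class
    ``profile.label``.

    Fully deterministic given ``(spec.seed, sample_index, image_index)``; the
    per-image element means are independent draws across images, modeling
    between-image variation of repeated acquisitions of one slide.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed) & 0x7FFFFFFF, 977, sample_index, image_index])
    )
    shape = (spec.height, spec.width)
    elements = np.empty((16,) + shape)
    means = rng.normal(profile.element_mean, profile.element_std)
    means[0] = 1.0  # m11 mean is the normalization reference
    for k in range(16):
        tex = _correlated_texture(
            rng, shape, spec.texture_correlation_length, spec.texture_sd
        )
        noise = (
            rng.normal(0.0, spec.pixel_noise_sd, size=shape)
            if spec.pixel_noise_sd > 0
            else 0.0
        )
        elements[k] = means[k] + tex + noise
    # physicality: m11 > 0, |mij| <= m11 (clamp, not resample, to keep the
    # draw deterministic and cheap; violations are rare at default amplitudes)
    np.clip(elements[0], 1e-6, None, out=elements[0])
    m11 = elements[0]
    np.clip(elements[1:], -m11[None], m11[None], out=elements[1:])
    _project_physical(elements)
    sid = sample_id if sample_id is not None else f"S{sample_index:03d}"
    return MuellerFieldTruth(
        sample_id=sid, label=profile.label, elements=elements, image_index=image_index
    )


def generate_cohort(
    spec: PhantomSpec,
    profiles: dict[str, ClassProfile] | None = None,
) -> tuple[list[MuellerFieldTruth], pd.DataFrame]:
    """Generate a full cohort of phantom measurement images.

    Returns the list of truth fields (``cohort_counts[label] *
    images_per_sample`` images per class, class order fixed) and a manifest
    DataFrame with columns ``sample_id, class, path, seed, image_index``
    (``path`` empty until images are written to disk).

    The whole cohort is a pure function of ``(spec, profiles)``.
    """
    if profiles is None:
        profiles = builtin_profiles()
    total = sum(spec.cohort_counts.get(lbl, 0) for lbl in spec.cohort_counts)
    if total == 0:
        raise ValueError("cohort is empty: all class counts are zero")

    truths: list[MuellerFieldTruth] = []
    rows = []
    sample_index = 0
    class_order = [c for c in CLASS_LABELS if c in spec.cohort_counts]
    # preserve any extra labels the caller supplied, after the canonical four
    class_order += [c for c in spec.cohort_counts if c not in class_order]
    for label in class_order:
        count = spec.cohort_counts.get(label, 0)
        for _ in range(count):
            sid = f"{label[0].upper()}{sample_index:03d}"
            for img in range(spec.images_per_sample):
                truths.append(
                    generate_sample(
                        profiles[label], spec, sample_index, img, sample_id=sid
                    )
                )
                rows.append(
                    {
                        "sample_id": sid,
                        "class": label,
                        "path": "",
                        "seed": spec.seed,
                        "image_index": img,
                    }
                )
            sample_index += 1
    manifest = pd.DataFrame(rows)
    return truths, manifest


def noise_free(spec: PhantomSpec) -> PhantomSpec:
    """Copy of ``spec`` with texture and white noise switched off."""
    return replace(spec, texture_sd=0.0, pixel_noise_sd=0.0)
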