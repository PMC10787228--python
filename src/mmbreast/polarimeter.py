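"""Forward simulation of a 36-state backscattering polarimeter.

The instrument probes a sample with six fully polarized input states
(H, V, P, M, R, L: horizontal, vertical, +45 deg, 135 deg, right- and
left-circular) and analyzes the backscattered light with the same six states,
yielding 36 intensity images per sample.  Under ideal optics the recorded
intensity for input state ``x`` and analyzer state ``y`` is

    I_xy = gain * a_y^T M s_x,      a_y = (1/2) s_y,

where ``M`` is the pixel's Mueller matrix, ``s_x`` the input Stokes vector and
``a_y`` the ideal-projector analyzer row (an ideal analyzer passes half the
matched fully-polarized intensity).  This is the minimal model under which the
standard 36-measurement reconstruction is exactly invertible.
"""

from __future__ import annotations

from dataclasses import dataclass
from zlib import crc32

import numpy as np

from .phantom import MuellerFieldTruth

__all__ = [
    "STATE_LABELS",
    "PolState",
    "canonical_states",
    "element_mueller",
    "NoiseConfig",
    "PolarizationStack",
    "simulate_stack",
]

STATE_LABELS: tuple[str, ...] = ("H", "V", "P", "M", "R", "L")

_STOKES = {
    "H": (1.0, 1.0, 0.0, 0.0),
    "V": (1.0, -1.0, 0.0, 0.0),
    "P": (1.0, 0.0, 1.0, 0.0),
    "M": (1.0, 0.0, -1.0, 0.0),
    "R": (1.0, 0.0, 0.0, 1.0),
    "L": (1.0, 0.0, 0.0, -1.0),
}


@dataclass(frozen=True)
class PolState:
    """A fully polarized probe/analyzer state with unit intensity."""

    label: str
    stokes: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        s = np.asarray(self.stokes, dtype=float)
        if s.shape != (4,):
            raise ValueError("Stokes vector must have 4 components")
        if s[0] != 1.0:
            raise ValueError("probe states are normalized to S0 = 1")
        if not np.isclose(s[1] ** 2 + s[2] ** 2 + s[3] ** 2, 1.0):
            raise ValueError("probe states must be fully polarized")


def canonical_states() -> list[PolState]:
    """The six canonical probe states H, V, P, M, R, L."""
    return [PolState(lbl, _STOKES[lbl]) for lbl in STATE_LABELS]


def stokes_matrix() -> np.ndarray:
    """(6, 4) array of the canonical Stokes vectors, row order H,V,P,M,R,L."""
    return np.array([_STOKES[lbl] for lbl in STATE_LABELS])


def element_mueller(kind: str, angle: float) -> np.ndarray:
    """Mueller matrix of an ideal rotated optical element.

    ``kind`` is ``"linear_polarizer"`` or ``"quarter_wave_plate"``; ``angle``
    is the element's axis orientation in degrees.  Used to validate that the
    generator/analyzer trains (polarizer + quarter-wave plate on stepping
    motors) realize the canonical states, and as a hook for modeling
    non-ideal optics.
    """
    if not np.isfinite(angle):
        raise ValueError("angle must be finite")
    th = np.deg2rad(angle)
    c2, s2 = np.cos(2 * th), np.sin(2 * th)
    if kind == "linear_polarizer":
        return 0.5 * np.array(
            [
                [1, c2, s2, 0],
                [c2, c2 * c2, c2 * s2, 0],
                [s2, c2 * s2, s2 * s2, 0],
                [0, 0, 0, 0],
            ],
            dtype=float,
        )
    if kind == "quarter_wave_plate":
        # ideal linear retarder, retardance pi/2, fast axis at `angle`
        return np.array(
            [
                [1, 0, 0, 0],
                [0, c2 * c2, c2 * s2, -s2],
                [0, c2 * s2, s2 * s2, c2],
                [0, s2, -c2, 0],
            ],
            dtype=float,
        )
    raise ValueError(f"unknown optical element kind {kind!r}")


@dataclass(frozen=True)
class NoiseConfig:
    """Detector noise model for the simulated camera.

    ``shot_noise`` applies Poisson statistics after scaling intensities by
    ``full_well`` counts; ``read_noise_sd`` adds Gaussian read noise on the
    intensity scale.  ``seed`` fixes the noise stream.
    """

    shot_noise: bool = False
    full_well: float = 10000.0
    read_noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be non-negative")
        if self.shot_noise and self.full_well <= 0:
            raise ValueError("full_well must be positive for shot noise")

    @property
    def enabled(self) -> bool:
        return self.shot_noise or self.read_noise_sd > 0


#: Noise-free configuration, for exact round-trip checks.
NOISELESS = NoiseConfig(shot_noise=False, read_noise_sd=0.0)


@dataclass
class PolarizationStack:
    """The 36 intensity images of one acquisition.

    ``images[(x, y)]`` is the 2-D image for input state ``x`` and analyzer
    state ``y``; all 36 ordered pairs over H, V, P, M, R, L are present.
    """

    sample_id: str
    images: dict[tuple[str, str], np.ndarray]
    gain: float = 1.0
    meta: dict | None = None

    def __post_init__(self) -> None:
        keys = set(self.images)
        expected = {(a, b) for a in STATE_LABELS for b in STATE_LABELS}
        if keys != expected:
            missing = sorted(expected - keys)
            raise ValueError(f"stack incomplete; missing state pairs: {missing}")
        shapes = {im.shape for im in self.images.values()}
        if len(shapes) != 1:
            raise ValueError("all stack images must share dimensions")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.images.values())).shape


def simulate_stack(
    truth: MuellerFieldTruth,
    noise: NoiseConfig = NOISELESS,
    gain: float = 1.0,
) -> PolarizationStack:
    """Project a ground-truth Mueller field through the 36 state pairs.

    Raises if any noiseless intensity is negative beyond numerical tolerance
    (an unphysical truth field); post-noise negatives are floored at zero as
    a real camera would clip them.
    """
    el = truth.elements  # (16, H, W)
    M = el.reshape(4, 4, *el.shape[1:])
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [int(noise.seed) & 0x7FFFFFFF, 1451, crc32(truth.sample_id.encode()), truth.image_index]
        )
    )
    images: dict[tuple[str, str], np.ndarray] = {}
    for xlbl in STATE_LABELS:
        sx = np.asarray(_STOKES[xlbl])
        # Stokes vector leaving the sample: (M s_x)_i
        out = np.tensordot(sx, M, axes=([0], [1]))  # (4, H, W)
        for ylbl in STATE_LABELS:
            sy = np.asarray(_STOKES[ylbl])
            intensity = 0.5 * gain * np.tensordot(sy, out, axes=([0], [0]))
            if intensity.min() < -1e-9 * max(gain, 1.0):
                raise ValueError(
                    f"negative noiseless intensity for state pair "
                    f"({xlbl}, {ylbl}): unphysical truth field"
                )
            np.clip(intensity, 0.0, None, out=intensity)
            if noise.shot_noise:
                counts = rng.poisson(intensity * noise.full_well)
                intensity = counts / noise.full_well
            if noise.read_noise_sd > 0:
                intensity = intensity + rng.normal(
                    0.0, noise.read_noise_sd, size=intensity.shape
                )
            np.clip(intensity, 0.0, None, out=intensity)
            images[(xlbl, ylbl)] = intensity
    return PolarizationStack(
        sample_id=truth.sample_id,
        images=images,
        gain=gain,
        meta={"label": truth.label, "image_index": truth.image_index},
    )
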