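"""Mueller-matrix image reconstruction from 36-state stacks.

Each of the 16 Mueller elements is a signed sum of four state-pair images
(first letter = input state, second = analyzer state), e.g.

    m11 = HH + HV + VH + VV        m23 = PH - PV - MH + MV

Under the ideal-projector forward model every such sum equals ``2 * gain *
mij``, a uniform scale that drops out after m11 normalization, so the
normalized reconstruction is exact on noise-free data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profiles import ELEMENT_NAMES
from .polarimeter import PolarizationStack

__all__ = [
    "RECONSTRUCTION_TERMS",
    "MuellerImage",
    "ElementAverages",
    "reconstruct_mueller",
    "normalize_by_m11",
    "element_averages",
    "render_display",
    "display_inverse",
    "reconstruction_design_matrix",
]

# Row i of the matrix fixes the analyzer combination, column j the input
# combination: row/column 1 uses the sum (H + V), rows/columns 2-4 the
# differences (H - V), (P - M), (R - L).
def _terms() -> dict[str, list[tuple[str, str, int]]]:
    out: dict[str, list[tuple[str, str, int]]] = {}
    axis = {1: ("H", "V"), 2: ("P", "M"), 3: ("R", "L")}
    for i in range(1, 5):
        for j in range(1, 5):
            name = f"m{i}{j}"
            ins = [("H", 1), ("V", 1)] if j == 1 else [
                (axis[j - 1][0], 1),
                (axis[j - 1][1], -1),
            ]
            outs = [("H", 1), ("V", 1)] if i == 1 else [
                (axis[i - 1][0], 1),
                (axis[i - 1][1], -1),
            ]
            out[name] = [
                (x, y, sx * sy) for (y, sy) in outs for (x, sx) in ins
            ]
    return out


#: element name -> four (input_state, analyzer_state, +/-1) terms
RECONSTRUCTION_TERMS: dict[str, list[tuple[str, str, int]]] = _terms()


@dataclass
class MuellerImage:
    """16 per-pixel Mueller element images.

    ``elements`` has shape (16, H, W) in canonical order.  When
    ``normalized`` is True, m11 == 1 on valid pixels and ``mask`` marks the
    pixels where the raw m11 was above the validity threshold.
    """

    sample_id: str
    elements: np.ndarray
    normalized: bool = False
    mask: np.ndarray | None = None
    label: str | None = None
    image_index: int = 0

    def __post_init__(self) -> None:
        el = np.asarray(self.elements, dtype=float)
        if el.ndim != 3 or el.shape[0] != 16:
            raise ValueError("elements must have shape (16, H, W)")
        self.elements = el
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != el.shape[1:]:
                raise ValueError("mask shape must match image shape")

    def element(self, name: str) -> np.ndarray:
        return self.elements[ELEMENT_NAMES.index(name)]


@dataclass
class ElementAverages:
    """Per-image feature vector: mean normalized intensity of each element."""

    sample_id: str
    values: np.ndarray
    label: str | None = None
    image_index: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (16,):
            raise ValueError("values must be a 16-vector")
        if not np.isfinite(v).all():
            raise ValueError("averages must be finite")
        self.values = v

    def value_of(self, name: str) -> float:
        return float(self.values[ELEMENT_NAMES.index(name)])


def reconstruct_mueller(stack: PolarizationStack) -> MuellerImage:
    """Raw Mueller element images from a complete 36-image stack.

    Pixelwise signed four-term sums; no scale factor is applied (the common
    factor cancels in m11 normalization).  Raises naming the missing state
    pair if the stack is incomplete.
    """
    h, w = stack.shape
    elements = np.zeros((16, h, w))
    for k, name in enumerate(ELEMENT_NAMES):
        for x, y, sign in RECONSTRUCTION_TERMS[name]:
            try:
                img = stack.images[(x, y)]
            except KeyError:
                raise KeyError(
                    f"stack for {stack.sample_id!r} is missing state pair ({x}, {y})"
                ) from None
            elements[k] += sign * img
    meta = stack.meta or {}
    return MuellerImage(
        sample_id=stack.sample_id,
        elements=elements,
        normalized=False,
        label=meta.get("label"),
        image_index=meta.get("image_index", 0),
    )


def normalize_by_m11(raw: MuellerImage, epsilon: float = 1e-9) -> MuellerImage:
    """Divide every element pixelwise by raw m11.

    Pixels with raw m11 <= ``epsilon`` are masked invalid rather than
    propagating infinities; an all-invalid image is an error.  Idempotent on
    already-normalized images.
    """
    m11 = raw.elements[0]
    mask = m11 > epsilon
    if raw.mask is not None:
        mask = mask & raw.mask
    if not mask.any():
        raise ValueError(f"image {raw.sample_id!r}: no valid pixels (m11 ~ 0)")
    safe = np.where(mask, m11, 1.0)
    elements = raw.elements / safe[None]
    elements[:, ~mask] = np.nan
    return MuellerImage(
        sample_id=raw.sample_id,
        elements=elements,
        normalized=True,
        mask=mask,
        label=raw.label,
        image_index=raw.image_index,
    )


def element_averages(normalized: MuellerImage) -> ElementAverages:
    """Arithmetic mean of each element over valid pixels (reporting scale)."""
    if not normalized.normalized:
        raise ValueError("element_averages expects an m11-normalized image")
    mask = (
        normalized.mask
        if normalized.mask is not None
        else np.ones(normalized.elements.shape[1:], bool)
    )
    if not mask.any():
        raise ValueError("no valid pixels to average")
    vals = normalized.elements[:, mask].mean(axis=1)
    return ElementAverages(
        sample_id=normalized.sample_id,
        values=vals,
        label=normalized.label,
        image_index=normalized.image_index,
    )


def render_display(normalized: np.ndarray | MuellerImage) -> np.ndarray:
    """8-bit display rendering: v in [-1, 1] -> round(255*(v+1)/2), clipped.

    Round-half-up, so v = 0 maps to 128.  Display only; statistics are
    computed on the float values.
    """
    v = normalized.elements if isinstance(normalized, MuellerImage) else normalized
    v = np.asarray(v, dtype=float)
    p = np.floor(255.0 * (np.clip(v, -1.0, 1.0) + 1.0) / 2.0 + 0.5)
    return np.clip(np.nan_to_num(p, nan=0.0), 0, 255).astype(np.uint8)


def display_inverse(p: np.ndarray) -> np.ndarray:
    """Inverse display map: byte p -> 2p/255 - 1 (round-trip error <= 1/255)."""
    return 2.0 * np.asarray(p, dtype=float) / 255.0 - 1.0


def reconstruction_design_matrix() -> np.ndarray:
    """(16, 36) signed coefficient matrix of the reconstruction.

    Columns are state pairs in (input, analyzer) lexicographic order over
    H, V, P, M, R, L; entries are in {-1, 0, +1}.  Full row rank 16 over the
    36 measurements.
    """
    from .polarimeter import STATE_LABELS

    pairs = [(x, y) for x in STATE_LABELS for y in STATE_LABELS]
    A = np.zeros((16, 36))
    for k, name in enumerate(ELEMENT_NAMES):
        for x, y, sign in RECONSTRUCTION_TERMS[name]:
            A[k, pairs.index((x, y))] = sign
    return A
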