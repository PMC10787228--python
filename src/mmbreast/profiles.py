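"""Class-conditional Mueller-element profiles for breast tissue.

A backscattering Mueller-matrix polarimeter reduces each tissue slide to a
16-vector of average normalized element intensities (m11 ... m44, m11 == 1 by
normalization).  Published cohort statistics for stained breast histology
slides report, for each of four diagnostic classes (healthy, benign, grade-2
malignant, grade-3 malignant), the cohort mean and the between-image standard
deviation of every element.  Those per-class mean/std pairs are the
``ClassProfile`` objects below; they drive both the synthetic phantom
generator and the reference nearest-centroid classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ELEMENT_NAMES",
    "CLASS_LABELS",
    "ClassProfile",
    "builtin_profiles",
    "element_index",
]

#: Fixed element order, row-major over the 4x4 Mueller matrix.
ELEMENT_NAMES: tuple[str, ...] = tuple(
    f"m{i}{j}" for i in range(1, 5) for j in range(1, 5)
)

#: Fixed class order; also the deterministic tie-break order for classification.
CLASS_LABELS: tuple[str, ...] = ("healthy", "benign", "grade2", "grade3")


def element_index(name: str) -> int:
    """Return the position of element ``name`` (e.g. ``"m23"``) in the
    canonical row-major order."""
    try:
        return ELEMENT_NAMES.index(name)
    except ValueError:
        raise KeyError(f"unknown Mueller element {name!r}") from None


@dataclass(frozen=True)
class ClassProfile:
    """Per-class element statistics of m11-normalized Mueller images.

    Parameters
    ----------
    label:
        Diagnostic class, one of ``CLASS_LABELS``.
    element_mean:
        16-vector of average normalized intensities (dimensionless, reporting
        scale), order ``ELEMENT_NAMES``.  ``element_mean[m11] == 1``.
    element_std:
        16-vector of between-image standard deviations on the same scale;
        ``element_std[m11] == 0``.
    """

    label: str
    element_mean: np.ndarray = field(repr=False)
    element_std: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        mean = np.asarray(self.element_mean, dtype=float)
        std = np.asarray(self.element_std, dtype=float)
        if mean.shape != (16,) or std.shape != (16,):
            raise ValueError("element_mean and element_std must be 16-vectors")
        if not (np.isfinite(mean).all() and np.isfinite(std).all()):
            raise ValueError("profile statistics must be finite")
        if (std < 0).any():
            raise ValueError("standard deviations must be non-negative")
        if mean[0] != 1.0 or std[0] != 0.0:
            raise ValueError("m11 must have mean 1 and std 0 (normalization element)")
        mean.flags.writeable = False
        std.flags.writeable = False
        object.__setattr__(self, "element_mean", mean)
        object.__setattr__(self, "element_std", std)

    def mean_of(self, name: str) -> float:
        return float(self.element_mean[element_index(name)])

    def std_of(self, name: str) -> float:
        return float(self.element_std[element_index(name)])


# Cohort statistics (mean, between-image std) of the 16 normalized elements
# for healthy / benign / grade-2 / grade-3 breast tissue slides measured with
# a backscattering 36-state polarimeter.  Row order is ELEMENT_NAMES.
_TABLE: dict[str, list[tuple[float, float]]] = {
    "healthy": [
        (1.0000, 0.0000),
        (0.4845, 0.0141),
        (0.4840, 0.0272),
        (0.4674, 0.0187),
        (0.4611, 0.0117),
        (0.2275, 0.0273),
        (0.6394, 0.0175),
        (0.4566, 0.0169),
        (0.4535, 0.0136),
        (0.3201, 0.0087),
        (0.2282, 0.0208),
        (0.5156, 0.0258),
        (0.5124, 0.0122),
        (0.4803, 0.0286),
        (0.4755, 0.0293),
        (0.6524, 0.0037),
    ],
    "benign": [
        (1.0000, 0.0000),
        (0.4911, 0.0286),
        (0.4938, 0.0029),
        (0.4528, 0.0025),
        (0.4923, 0.0267),
        (0.2248, 0.0180),
        (0.2237, 0.0071),
        (0.4669, 0.0163),
        (0.4851, 0.0042),
        (0.6840, 0.0027),
        (0.2243, 0.0064),
        (0.4827, 0.0041),
        (0.4859, 0.0088),
        (0.4886, 0.0121),
        (0.4781, 0.0268),
        (0.5646, 0.0043),
    ],
    "grade2": [
        (1.0000, 0.0000),
        (0.4785, 0.0132),
        (0.4825, 0.0056),
        (0.4666, 0.0055),
        (0.4815, 0.0010),
        (0.2271, 0.0258),
        (0.2432, 0.0267),
        (0.4722, 0.0088),
        (0.5244, 0.0062),
        (0.7114, 0.0048),
        (0.2111, 0.0017),
        (0.4573, 0.0121),
        (0.4831, 0.0052),
        (0.4788, 0.0032),
        (0.4721, 0.0042),
        (0.4366, 0.0031),
    ],
    "grade3": [
        (1.0000, 0.0000),
        (0.4581, 0.0007),
        (0.5273, 0.0127),
        (0.5049, 0.0043),
        (0.4737, 0.0030),
        (0.2197, 0.0187),
        (0.1915, 0.0101),
        (0.4952, 0.0034),
        (0.5737, 0.0018),
        (0.8129, 0.0177),
        (0.2052, 0.0049),
        (0.4414, 0.0026),
        (0.4833, 0.0100),
        (0.5239, 0.0113),
        (0.4916, 0.0469),
        (0.3562, 0.0022),
    ],
}


def builtin_profiles() -> dict[str, ClassProfile]:
    """Return the four built-in class profiles (fresh, immutable objects).

    The values are the reported per-class cohort means and between-image
    standard deviations of the normalized Mueller elements for healthy,
    benign, grade-2 and grade-3 breast tissue.
    """
    out: dict[str, ClassProfile] = {}
    for label in CLASS_LABELS:
        rows = _TABLE[label]
        out[label] = ClassProfile(
            label=label,
            element_mean=np.array([m for m, _ in rows]),
            element_std=np.array([s for _, s in rows]),
        )
    return out
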