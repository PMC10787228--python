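"""Group statistics over Mueller element intensities.

The analysis battery applied to per-image element averages and element
images: percentage differences between group means, two-group t-tests,
one-way ANOVA with pairwise post-hoc comparisons, the element-element
correlation matrix, and pooled pixel-intensity frequency distribution
histograms (FDHs) with a histogram-overlap separability ranking.

Tests are scipy-backed; p-values are reported raw by default (an optional
Bonferroni flag exists for the post-hoc table).  Significance stars follow
the common four-band convention: * <= 0.0332, ** <= 0.0021, *** <= 0.0002,
**** < 0.0001 (configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mueller import ElementAverages, MuellerImage
from .profiles import ELEMENT_NAMES, element_index

__all__ = [
    "STAR_BANDS",
    "significance_stars",
    "GroupComparison",
    "FDH",
    "percentage_difference",
    "two_group_test",
    "one_way_anova",
    "correlation_matrix",
    "fdh",
    "overlap_coefficient",
    "separation_report",
]

#: (threshold, stars) bands, strongest first.
STAR_BANDS: tuple[tuple[float, str], ...] = (
    (0.0001, "****"),
    (0.0002, "***"),
    (0.0021, "**"),
    (0.0332, "*"),
)


def significance_stars(
    p: float, bands: tuple[tuple[float, str], ...] = STAR_BANDS
) -> str:
    """Star label for a p-value (``"ns"`` above the weakest band)."""
    for thresh, stars in bands:
        if p <= thresh:
            return stars
    return "ns"


@dataclass
class GroupComparison:
    """Result of one group comparison on one element."""

    element: str
    group_labels: tuple[str, ...]
    group_means: tuple[float, ...]
    group_stds: tuple[float, ...]
    statistic: float
    p_value: float
    stars: str
    test: str
    percentage_difference: float | None = None
    posthoc: pd.DataFrame | None = field(default=None, repr=False)


@dataclass
class FDH:
    """Pooled pixel-intensity frequency distribution histogram."""

    element: str
    label: str
    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def frequencies(self) -> np.ndarray:
        tot = self.counts.sum()
        return self.counts / tot if tot > 0 else self.counts.astype(float)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (the tabulation convention used for reporting)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage_difference(h: float, c: float) -> float:
    """Percentage difference between two non-negative mean intensities.

    ``100 * |h - c| / max(h, c)``; symmetric and scale-invariant.  Both-zero
    input returns 0 by convention.
    """
    h, c = float(h), float(c)
    if h < 0 or c < 0:
        raise ValueError("mean intensities must be non-negative")
    m = max(h, c)
    if m == 0:
        return 0.0
    return 100.0 * abs(h - c) / m


def two_group_test(
    a,
    b,
    variant: str = "welch",
    element: str = "",
    labels: tuple[str, str] = ("group1", "group2"),
) -> GroupComparison:
    """Two-sided two-group comparison of sample averages.

    ``variant="welch"`` is the default (unequal group sizes are the norm:
    e.g. 35 healthy vs 60 cancer samples make a paired design ill-defined);
    ``variant="paired"`` requires equal-length inputs.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    with warnings.catch_warnings():
        # constant groups (e.g. the m11 column, identically 1) raise a
        # precision-loss warning and yield nan; handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        if variant == "welch":
            res = sps.ttest_ind(a, b, equal_var=False)
        elif variant == "paired":
            if a.size != b.size:
                raise ValueError("paired test requires equal group lengths")
            res = sps.ttest_rel(a, b)
        else:
            raise ValueError(f"unknown test variant {variant!r}")
    t = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(t):  # identical constant groups: no evidence of difference
        t, p = 0.0, 1.0
    pd_pct = None
    ma, mb = float(a.mean()), float(b.mean())
    if ma >= 0 and mb >= 0:
        pd_pct = percentage_difference(ma, mb)
    return GroupComparison(
        element=element,
        group_labels=labels,
        group_means=(ma, mb),
        group_stds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        statistic=t,
        p_value=p,
        stars=significance_stars(p),
        test=f"t-{variant}",
        percentage_difference=pd_pct,
    )


def one_way_anova(
    groups: dict[str, np.ndarray] | list,
    element: str = "",
    posthoc_variant: str = "welch",
    bonferroni: bool = False,
) -> GroupComparison:
    """One-way ANOVA across >= 2 groups plus all pairwise post-hoc tests.

    Returns the F statistic and p-value; ``posthoc`` holds one row per group
    pair (Welch tests by default, raw p-values unless ``bonferroni``).
    """
    if isinstance(groups, dict):
        labels = list(groups)
        arrays = [np.asarray(groups[k], float) for k in labels]
    else:
        arrays = [np.asarray(g, float) for g in groups]
        labels = [f"group{i + 1}" for i in range(len(arrays))]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(g.size < 2 for g in arrays):
        raise ValueError("each group needs at least 2 observations")
    res = sps.f_oneway(*arrays)
    F = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(F):
        F, p = 0.0, 1.0
    rows = []
    n_pairs = len(arrays) * (len(arrays) - 1) // 2
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            cmp_ = two_group_test(
                arrays[i],
                arrays[j],
                variant=posthoc_variant,
                element=element,
                labels=(labels[i], labels[j]),
            )
            p_ij = cmp_.p_value
            if bonferroni:
                p_ij = min(1.0, p_ij * n_pairs)
            rows.append(
                {
                    "element": element,
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_a": cmp_.group_means[0],
                    "mean_b": cmp_.group_means[1],
                    "statistic": cmp_.statistic,
                    "p_value": p_ij,
                    "stars": significance_stars(p_ij),
                }
            )
    return GroupComparison(
        element=element,
        group_labels=tuple(labels),
        group_means=tuple(float(g.mean()) for g in arrays),
        group_stds=tuple(float(g.std(ddof=1)) for g in arrays),
        statistic=F,
        p_value=p,
        stars=significance_stars(p),
        test="anova",
        posthoc=pd.DataFrame(rows),
    )


#: elements entering the correlation matrix (m11 is constant 1, excluded)
CORR_ELEMENTS: tuple[str, ...] = tuple(e for e in ELEMENT_NAMES if e != "m11")


def correlation_matrix(samples: list[ElementAverages]) -> pd.DataFrame:
    """15 x 15 Pearson correlation of element averages across samples.

    Pooled over all supplied samples (a per-class matrix is obtained by
    passing one class's samples).  Zero-variance elements yield NaN rows and
    columns (coefficient undefined) except the unit diagonal.
    """
    if len(samples) < 3:
        raise ValueError("correlation needs at least 3 samples")
    idx = [element_index(e) for e in CORR_ELEMENTS]
    X = np.stack([s.values[idx] for s in samples])  # (n, 15)
    sd = X.std(axis=0, ddof=1)
    # constant columns (to float round-off) have an undefined coefficient
    degenerate = sd < 1e-12 * (np.abs(X.mean(axis=0)) + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X, rowvar=False)
    C[degenerate, :] = np.nan
    C[:, degenerate] = np.nan
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=CORR_ELEMENTS, columns=CORR_ELEMENTS)


def fdh(
    images: list[MuellerImage],
    element: str,
    label: str = "",
    bins: int = 64,
    value_range: tuple[float, float] = (-1.0, 1.0),
) -> FDH:
    """Pooled pixel-intensity histogram of one element over a class's images.

    Fixed axis (default 64 bins on [-1, 1]) so histograms of different
    classes are directly comparable; out-of-range pixels are clipped into the
    end bins, so counts sum to the number of contributing valid pixels.
    """
    if not images:
        raise ValueError("need at least one image")
    if bins < 2:
        raise ValueError("need at least 2 bins")
    k = element_index(element)
    lo, hi = value_range
    pools = []
    for im in images:
        mask = im.mask if im.mask is not None else np.ones(im.elements.shape[1:], bool)
        pools.append(np.clip(im.elements[k][mask], lo, hi))
    pooled = np.concatenate(pools)
    counts, edges = np.histogram(pooled, bins=bins, range=value_range)
    return FDH(element=element, label=label, bin_edges=edges, counts=counts)


def overlap_coefficient(a: FDH, b: FDH) -> float:
    """Histogram overlap: sum of bin-wise minima of normalized frequencies.

    1 for identical distributions, 0 for disjoint supports.
    """
    if not np.array_equal(a.bin_edges, b.bin_edges):
        raise ValueError("FDHs must share bin edges")
    return float(np.minimum(a.frequencies, b.frequencies).sum())


def separation_report(fdhs: dict[str, dict[str, FDH]]) -> pd.DataFrame:
    """Rank elements by between-class FDH separation.

    ``fdhs[element][label]`` holds one histogram per class.  The score is
    ``1 - overlap`` averaged over all class pairs; 0 means identical
    class distributions, 1 disjoint ones.  Deterministic ordering: descending
    score, ties broken by canonical element index.
    """
    rows = []
    for element, per_class in fdhs.items():
        labels = list(per_class)
        pair_scores = [
            1.0 - overlap_coefficient(per_class[a], per_class[b])
            for i, a in enumerate(labels)
            for b in labels[i + 1 :]
        ]
        rows.append(
            {
                "element": element,
                "separation": float(np.mean(pair_scores)) if pair_scores else 0.0,
                "_idx": element_index(element),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["separation", "_idx"], ascending=[False, True], kind="mergesort"
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df.drop(columns="_idx").reset_index(drop=True)
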