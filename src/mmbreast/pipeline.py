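"""End-to-end pipeline: phantom cohort -> stacks -> elements -> statistics.

Mirrors the four-stage experimental procedure (sample preparation, 36-image
acquisition, Mueller element + parameter computation, data analysis) on
synthetic phantoms.  A single seed governs all randomness; a rerun with the
same configuration is bit-identical, and all tables are written as CSV with a
JSON run report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import (
    DEFAULT_FEATURES,
    classify_sample,
    confusion_matrix,
    reference_model,
)
from .mmt import MMTConfig, mmt_for_sample
from .mueller import ElementAverages, element_averages, normalize_by_m11, reconstruct_mueller
from .phantom import PhantomSpec, generate_cohort
from .polarimeter import NoiseConfig, simulate_stack
from .profiles import CLASS_LABELS, ELEMENT_NAMES, builtin_profiles
from .stats import (
    correlation_matrix,
    fdh,
    one_way_anova,
    round_half_up,
    separation_report,
    two_group_test,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "cohort_element_averages", "averages_frame"]

#: classes pooled as "cancer" for the healthy-vs-cancer comparison
CANCER_LABELS = ("benign", "grade2", "grade3")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one synthetic end-to-end run."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    gain: float = 1.0
    a0: float = 2.0
    mmt_mode: str = "from_averages"
    features: tuple[str, ...] = DEFAULT_FEATURES
    fdh_bins: int = 64
    seed: int = 0

    def seeded(self) -> "PipelineConfig":
        """Propagate the top-level seed into the phantom and noise streams."""
        return replace(
            self,
            phantom=replace(self.phantom, seed=self.seed),
            noise=replace(self.noise, seed=self.seed + 1),
        )


@dataclass
class RunReport:
    """All artifacts of one pipeline run."""

    config: PipelineConfig
    manifest: pd.DataFrame
    image_averages: pd.DataFrame
    sample_features: pd.DataFrame
    mmt: pd.DataFrame
    two_group: pd.DataFrame
    anova: pd.DataFrame
    posthoc: pd.DataFrame
    correlation: pd.DataFrame
    fdh_table: pd.DataFrame
    separation: pd.DataFrame
    predictions: pd.DataFrame
    confusion: pd.DataFrame


def averages_frame(avgs: list[ElementAverages]) -> pd.DataFrame:
    rows = []
    for a in avgs:
        row = {"sample_id": a.sample_id, "class": a.label, "image_index": a.image_index}
        row.update({name: a.values[k] for k, name in enumerate(ELEMENT_NAMES)})
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_element_averages(
    spec: PhantomSpec,
    noise: NoiseConfig,
    gain: float = 1.0,
    profiles=None,
    keep_images: bool = False,
):
    """Generate a cohort and run it through acquisition + reconstruction.

    Returns ``(averages, images, manifest)`` where ``averages`` is a list of
    per-image :class:`ElementAverages` and ``images`` the normalized
    :class:`MuellerImage` list (empty unless ``keep_images``).
    """
    truths, manifest = generate_cohort(spec, profiles)
    avgs: list[ElementAverages] = []
    images = []
    for truth in truths:
        stack = simulate_stack(truth, noise=noise, gain=gain)
        norm = normalize_by_m11(reconstruct_mueller(stack))
        avgs.append(element_averages(norm))
        if keep_images:
            images.append(norm)
    return avgs, images, manifest


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    profiles: dict | None = None,
) -> RunReport:
    """Execute the full synthetic pipeline; optionally write all artifacts.

    Stages: phantom generation -> 36-state forward simulation -> Mueller
    reconstruction and m11 normalization -> per-image element averages ->
    MMT parameters -> statistics (two-group, ANOVA + post-hoc, correlation,
    FDHs, separation ranking) -> nearest-centroid classification against the
    reference profiles.  Any stage error aborts with a stage-tagged message.
    """
    config = config.seeded()
    if profiles is None:
        profiles = builtin_profiles()

    stage = "simulate"
    try:
        avgs, images, manifest = cohort_element_averages(
            config.phantom, config.noise, config.gain, profiles, keep_images=True
        )
        img_avg = averages_frame(avgs)

        stage = "mmt"
        mmt_cfg = MMTConfig(a0=config.a0, mode=config.mmt_mode)
        mmt_rows = []
        for a in avgs:
            r = mmt_for_sample(a, mmt_cfg)
            mmt_rows.append(
                {
                    "sample_id": r.sample_id,
                    "class": r.label,
                    "image_index": a.image_index,
                    "A": r.A,
                    "b": r.b,
                    "t": r.t,
                    "delta": r.delta,
                    "mode": r.mode,
                    "a0": r.a0,
                }
            )
        mmt_df = pd.DataFrame(mmt_rows)

        stage = "stats"
        by_class = {
            lbl: img_avg[img_avg["class"] == lbl] for lbl in CLASS_LABELS
            if (img_avg["class"] == lbl).any()
        }
        healthy = by_class.get("healthy")
        cancer = img_avg[img_avg["class"].isin(CANCER_LABELS)]
        two_rows = []
        if healthy is not None and len(healthy) >= 2 and len(cancer) >= 2:
            for name in ELEMENT_NAMES:
                cmp_ = two_group_test(
                    healthy[name].to_numpy(),
                    cancer[name].to_numpy(),
                    variant="welch",
                    element=name,
                    labels=("healthy", "cancer"),
                )
                two_rows.append(
                    {
                        "element": name,
                        "healthy_mean": cmp_.group_means[0],
                        "healthy_std": cmp_.group_stds[0],
                        "cancer_mean": cmp_.group_means[1],
                        "cancer_std": cmp_.group_stds[1],
                        "percentage_difference": round_half_up(
                            cmp_.percentage_difference, 1
                        ),
                        "statistic": cmp_.statistic,
                        "p_value": cmp_.p_value,
                        "stars": cmp_.stars,
                        "test": cmp_.test,
                    }
                )
        two_df = pd.DataFrame(two_rows)

        anova_rows, posthoc_frames = [], []
        if len(by_class) >= 2:
            for name in ELEMENT_NAMES:
                if name == "m11":
                    continue
                groups = {lbl: df[name].to_numpy() for lbl, df in by_class.items()}
                res = one_way_anova(groups, element=name)
                anova_rows.append(
                    {
                        "element": name,
                        "F": res.statistic,
                        "p_value": res.p_value,
                        "stars": res.stars,
                        **{
                            f"{lbl}_mean": m
                            for lbl, m in zip(res.group_labels, res.group_means)
                        },
                    }
                )
                posthoc_frames.append(res.posthoc)
        anova_df = pd.DataFrame(anova_rows)
        posthoc_df = (
            pd.concat(posthoc_frames, ignore_index=True)
            if posthoc_frames
            else pd.DataFrame()
        )

        corr_df = correlation_matrix(avgs) if len(avgs) >= 3 else pd.DataFrame()

        images_by_class: dict[str, list] = {}
        for im in images:
            images_by_class.setdefault(im.label, []).append(im)
        fdhs = {
            name: {
                lbl: fdh(ims, name, label=lbl, bins=config.fdh_bins)
                for lbl, ims in images_by_class.items()
            }
            for name in ELEMENT_NAMES
            if name != "m11"
        }
        fdh_rows = []
        for name, per_class in fdhs.items():
            for lbl, h in per_class.items():
                for i in range(len(h.counts)):
                    fdh_rows.append(
                        {
                            "element": name,
                            "class": lbl,
                            "bin_left": h.bin_edges[i],
                            "bin_right": h.bin_edges[i + 1],
                            "count": int(h.counts[i]),
                        }
                    )
        fdh_df = pd.DataFrame(fdh_rows)
        sep_df = separation_report(fdhs)

        stage = "classify"
        model = reference_model(config.features, profiles)
        feat_rows, pred_rows = [], []
        for sid, grp in img_avg.groupby("sample_id", sort=False):
            feats = grp[list(ELEMENT_NAMES)].mean()
            label = grp["class"].iloc[0]
            x = feats[list(config.features)].to_numpy(dtype=float)
            pred, dists = classify_sample(x, model)
            feat_rows.append(
                {"sample_id": sid, "class": label, **feats.to_dict()}
            )
            pred_rows.append(
                {
                    "sample_id": sid,
                    "class": label,
                    "predicted": pred,
                    **{f"dist_{k}": v for k, v in dists.items()},
                }
            )
        feat_df = pd.DataFrame(feat_rows)
        pred_df = pd.DataFrame(pred_rows)
        conf_df = confusion_matrix(
            pred_df["class"].tolist(), pred_df["predicted"].tolist()
        )
    except Exception as exc:  # noqa: BLE001 - re-raise with stage tag
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    report = RunReport(
        config=config,
        manifest=manifest,
        image_averages=img_avg,
        sample_features=feat_df,
        mmt=mmt_df,
        two_group=two_df,
        anova=anova_df,
        posthoc=posthoc_df,
        correlation=corr_df,
        fdh_table=fdh_df,
        separation=sep_df,
        predictions=pred_df,
        confusion=conf_df,
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


_TABLES = {
    "manifest": "manifest.csv",
    "image_averages": "element_averages.csv",
    "sample_features": "sample_features.csv",
    "mmt": "mmt.csv",
    "two_group": "two_group.csv",
    "anova": "anova.csv",
    "posthoc": "posthoc.csv",
    "correlation": "correlation.csv",
    "fdh_table": "fdh.csv",
    "separation": "separation.csv",
    "predictions": "predictions.csv",
    "confusion": "confusion.csv",
}


def write_report(report: RunReport, out_dir: str | Path) -> dict[str, str]:
    """Write all tables as CSV plus ``report.json``; returns SHA256 checksums.

    Floats are serialized with ``repr`` precision so identical runs produce
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}
    for attr, fname in _TABLES.items():
        df: pd.DataFrame = getattr(report, attr)
        path = out / fname
        index = attr in ("correlation", "confusion")
        df.to_csv(path, index=index, float_format="%.12g")
        checksums[fname] = hashlib.sha256(path.read_bytes()).hexdigest()
    counts = report.manifest.groupby("class")["sample_id"].nunique().to_dict()
    accuracy = (
        float(
            (report.predictions["class"] == report.predictions["predicted"]).mean()
        )
        if len(report.predictions)
        else float("nan")
    )
    summary = {
        "seed": report.config.seed,
        "n_samples": int(report.manifest["sample_id"].nunique()),
        "n_images": int(len(report.manifest)),
        "samples_per_class": {k: int(v) for k, v in sorted(counts.items())},
        "accuracy": accuracy,
        "confusion": {
            lbl: report.confusion.loc[lbl].to_dict() for lbl in report.confusion.index
        },
        "tables": checksums,
    }
    (out / "report.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return checksums
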