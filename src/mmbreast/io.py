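"""File formats: multi-page float TIFFs, stack sidecars, manifests.

Ground-truth and reconstructed element images are written as 16-page 32-bit
float TIFFs (fixed element order m11 ... m44, row-major).  Polarization
stacks are written either as one 36-page TIFF with a JSON sidecar mapping
pages to (input, analyzer) state pairs, or as one file per pair named
``{sample_id}_{in}{out}.tif``; both layouts can be read back, so real
36-image acquisitions following the same naming convention are accepted.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .mueller import MuellerImage
from .phantom import MuellerFieldTruth
from .polarimeter import STATE_LABELS, PolarizationStack

__all__ = [
    "write_elements_tiff",
    "read_elements_tiff",
    "write_stack",
    "read_stack",
    "write_manifest",
    "read_manifest",
]

#: state pairs in canonical (input, analyzer) lexicographic order
STATE_PAIRS: list[tuple[str, str]] = [
    (x, y) for x in STATE_LABELS for y in STATE_LABELS
]


def write_elements_tiff(path: str | Path, elements: np.ndarray) -> Path:
    """Write a (16, H, W) element array as a 16-page float32 TIFF."""
    el = np.asarray(elements, dtype=np.float32)
    if el.ndim != 3 or el.shape[0] != 16:
        raise ValueError("elements must have shape (16, H, W)")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, el)
    return path


def read_elements_tiff(path: str | Path) -> np.ndarray:
    el = tifffile.imread(path)
    if el.ndim != 3 or el.shape[0] != 16:
        raise ValueError(f"{path}: expected a 16-page element TIFF")
    return np.asarray(el, dtype=float)


def write_stack(
    stack: PolarizationStack, out_dir: str | Path, layout: str = "multipage"
) -> list[Path]:
    """Write a 36-image stack.

    ``layout="multipage"``: ``{sample_id}.tif`` (36 float32 pages in
    canonical pair order) plus ``{sample_id}.json`` sidecar.
    ``layout="per_pair"``: 36 files ``{sample_id}_{in}{out}.tif``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = stack.sample_id
    suffix = f"_i{stack.meta['image_index']:02d}" if stack.meta and "image_index" in stack.meta else ""
    stem = f"{sid}{suffix}"
    if layout == "multipage":
        pages = np.stack(
            [stack.images[pair] for pair in STATE_PAIRS]
        ).astype(np.float32)
        tif = out_dir / f"{stem}.tif"
        tifffile.imwrite(tif, pages)
        sidecar = out_dir / f"{stem}.json"
        sidecar.write_text(
            json.dumps(
                {
                    "sample_id": sid,
                    "gain": stack.gain,
                    "meta": stack.meta or {},
                    "pages": ["".join(p) for p in STATE_PAIRS],
                },
                indent=1,
                sort_keys=True,
            )
        )
        return [tif, sidecar]
    if layout == "per_pair":
        paths = []
        for x, y in STATE_PAIRS:
            p = out_dir / f"{stem}_{x}{y}.tif"
            tifffile.imwrite(p, stack.images[(x, y)].astype(np.float32))
            paths.append(p)
        return paths
    raise ValueError(f"unknown stack layout {layout!r}")


def read_stack(source: str | Path, sample_id: str | None = None) -> PolarizationStack:
    """Read a stack from a multipage TIFF (+ sidecar) or a per-pair directory.

    ``source`` is either the ``.tif`` multipage file or a directory holding
    ``{sample_id}_{in}{out}.tif`` files (``sample_id`` required then).
    """
    source = Path(source)
    if source.is_dir():
        if sample_id is None:
            raise ValueError("sample_id is required when reading a per-pair directory")
        images = {}
        for x, y in STATE_PAIRS:
            p = source / f"{sample_id}_{x}{y}.tif"
            if not p.exists():
                raise FileNotFoundError(f"missing state-pair image {p}")
            images[(x, y)] = np.asarray(tifffile.imread(p), dtype=float)
        return PolarizationStack(sample_id=sample_id, images=images)
    pages = np.asarray(tifffile.imread(source), dtype=float)
    if pages.ndim != 3 or pages.shape[0] != 36:
        raise ValueError(f"{source}: expected a 36-page stack TIFF")
    sidecar = source.with_suffix(".json")
    meta: dict = {}
    order = STATE_PAIRS
    gain = 1.0
    sid = sample_id or source.stem
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        sid = info.get("sample_id", sid)
        gain = float(info.get("gain", 1.0))
        meta = info.get("meta", {})
        order = [(p[0], p[1]) for p in info["pages"]]
    images = {pair: pages[i] for i, pair in enumerate(order)}
    return PolarizationStack(sample_id=sid, images=images, gain=gain, meta=meta or None)


def truth_to_path(truth: MuellerFieldTruth, out_dir: str | Path) -> Path:
    """Canonical truth-image filename for a phantom measurement."""
    return Path(out_dir) / f"{truth.sample_id}_i{truth.image_index:02d}_truth.tif"


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False)


def elements_to_image(
    path: str | Path,
    sample_id: str,
    normalized: bool = True,
    label: str | None = None,
    image_index: int = 0,
) -> MuellerImage:
    """Load an element TIFF back into a :class:`MuellerImage`."""
    el = read_elements_tiff(path)
    mask = np.isfinite(el).all(axis=0) if normalized else None
    return MuellerImage(
        sample_id=sample_id,
        elements=el,
        normalized=normalized,
        mask=mask,
        label=label,
        image_index=image_index,
    )
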