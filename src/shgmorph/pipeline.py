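"""End-to-end orchestration: images → masks → networks → features → stats.

Each input TIFF (one ROI of one specimen) is cropped into randomly
intercepted interstitial regions; every region runs through GMM
segmentation, skeletonization, fiber extraction and the eight features.
Per-region artifacts (mask TIFF, network JSON), the feature CSV, the group
summary CSV and a reproducibility manifest land in the output directory.
A failing region or file is logged and skipped; the run reports failures
instead of aborting.
"""

from __future__ import annotations

import glob as _glob
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import FeatureSet, compute_feature_set
from .io import (
    PipelineConfig,
    feature_row,
    logger,
    read_image,
    write_feature_table,
    write_image,
    write_mask,
    write_network,
)
from .network import FiberNetwork, extract_fibers, skeletonize
from .sampling import RegionSpec, sample_regions
from .segmentation import BinaryMask, SHGImage, segment
from .stats import group_summary_table
from .synthetic import FieldSpec, analytic_features, render_field, sample_fibers

__all__ = ["PipelineResult", "process_region", "run_pipeline", "simulate_dataset"]


@dataclass
class PipelineResult:
    features: pd.DataFrame
    failures: list[str]
    out_dir: Path

    @property
    def ok(self) -> bool:
        return not self.failures


def process_region(
    image: SHGImage, config: PipelineConfig
) -> tuple[BinaryMask, FiberNetwork, FeatureSet]:
    """Segmentation → skeleton → fiber network → features for one region."""
    mask = segment(image, tol=config.seg_tol, max_iter=config.seg_max_iter)
    skel = skeletonize(mask)
    network = extract_fibers(
        skel,
        min_len_px=config.min_len_px,
        max_turn_deg=config.max_turn_deg,
        pixel_size_um=image.pixel_size_um,
        simplify_tol_px=config.simplify_tol_px,
    )
    feats = compute_feature_set(image, network, mask)
    return mask, network, feats


def _expand_inputs(config: PipelineConfig) -> list[tuple[str, str, Path]]:
    """(specimen, group, path) triples from the config's group → glob map."""
    out = []
    for group, patterns in config.inputs.items():
        for pat in patterns:
            matches = sorted(_glob.glob(pat)) or [pat]
            for m in matches:
                out.append((Path(m).stem, group, Path(m)))
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the whole quantification over the configured inputs.

    Writes ``features.csv`` (one row per specimen/ROI/region, fixed column
    order), ``group_summary.csv`` (per-feature group mean ± SD, ANOVA and
    Tukey stars), per-region masks and network JSONs, and
    ``manifest.json`` recording config, seed and version.
    """
    out = Path(config.out_dir)
    (out / "regions").mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []
    failures: list[str] = []
    entries = _expand_inputs(config)
    for roi_idx, (specimen, group, path) in enumerate(entries):
        try:
            image = read_image(path, pixel_size_um=config.pixel_size_um)
            rspec = RegionSpec(
                roi_size_um=max(image.shape) * image.pixel_size_um,
                region_size_um=config.region_size_um,
                n_regions=config.n_regions,
                seed=config.seed + roi_idx,
            )
            regions = sample_regions(image, rspec)
        except Exception as exc:  # noqa: BLE001 — isolate per-file failures
            logger.error("skipping %s: %s", path, exc)
            failures.append(f"{path}: {exc}")
            continue
        for ridx, (sub, (r0, c0)) in enumerate(regions):
            tag = f"{specimen}_roi{roi_idx}_reg{ridx}"
            try:
                mask, network, feats = process_region(sub, config)
                rows.append(feature_row(specimen, group, roi_idx, ridx, feats))
                write_mask(out / "regions" / f"{tag}_mask.tif", mask)
                write_network(out / "regions" / f"{tag}_network.json", network)
            except Exception as exc:  # noqa: BLE001
                logger.error("region %s (at %d,%d) failed: %s", tag, r0, c0, exc)
                failures.append(f"{tag}: {exc}")
    df = write_feature_table(out / "features.csv", rows)

    # group statistics (only meaningful with >= 3 groups of >= 2 regions)
    summaries = group_summary_table(df, unit=config.unit,
                                    posthoc=config.posthoc) if len(df) else []
    srows = []
    for s in summaries:
        row: dict = {"feature": s.feature, "anova_F": s.anova_F, "anova_p": s.anova_p}
        for g in s.n:
            row[f"{g}_n"] = s.n[g]
            row[f"{g}_mean"] = s.mean[g]
            row[f"{g}_sd"] = s.sd[g]
        for a, b, p, st in s.pairwise:
            row[f"p_{a}_vs_{b}"] = p
            row[f"sig_{a}_vs_{b}"] = st
        srows.append(row)
    pd.DataFrame(srows).to_csv(out / "group_summary.csv", index=False,
                               encoding="utf-8")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "n_rows": len(df),
        "failures": failures,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return PipelineResult(features=df, failures=failures, out_dir=out)


def simulate_dataset(spec: FieldSpec, out_dir: str | Path) -> Path:
    """Generate one synthetic region and write image, clean mask, per-fiber
    truth CSV and a JSON sidecar (spec + analytic oracle features)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = sample_fibers(spec)
    image, mask = render_field(truth, spec)
    write_image(out / "image.tif", image)
    write_mask(out / "mask.tif", mask)
    rows = [
        {
            "fiber": i,
            "width_px": f.width_px,
            "true_length_um": f.true_length_um,
            "true_straightness": f.true_straightness,
            "orientation_deg": f.orientation_deg,
        }
        for i, f in enumerate(truth.fibers)
    ]
    pd.DataFrame(rows).to_csv(out / "truth.csv", index=False, encoding="utf-8")
    oracle = analytic_features(truth, spec)
    sidecar = {
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in spec.__dict__.items()},
        "true_area_fraction": truth.true_area_fraction,
        "n_crosslinks": len(truth.true_crosslink_points),
        "oracle_features": {
            k: (None if isinstance(v, float) and np.isnan(v) else v)
            for k, v in oracle.as_dict().items()
        },
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return out
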