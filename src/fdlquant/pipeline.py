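"""End-to-end orchestration: simulate -> segment -> quantify -> score -> stats.

A single :class:`RunConfig` (YAML-loadable) drives every stage; one master
seed fans out to per-stage child seeds so any stage can be reproduced in
isolation.  ``run_all`` writes signals.csv, scores.csv, cases.csv,
stats.json and run.log into the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chr_scoring import case_table, group_mean_scores
from .densitometry import GroupStats, RoiSignal, aggregate_group, quantify_image
from .group_stats import ancova, pairwise_ttests, shapiro_gate
from .image_io import GROUP_ORDER, load_manifest, load_two_channel, write_table
from .synthetic_data import (
    CHR_GROUP_RANGES,
    FDL_GROUP_MEANS,
    FDL_GROUP_SDS,
    FdlSimConfig,
    derive_seed,
    generate_case_covariates,
    generate_chr_group_cohort,
    generate_fdl_group_set,
)

logger = logging.getLogger(__name__)

# stage keys for child-seed derivation
_STAGE_FDL, _STAGE_CHR, _STAGE_COV = 0, 1, 2


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full pipeline run."""

    seed: int = 0
    outdir: str = "fdlquant_run"
    # fluorescence simulation
    n_cases: int = 2
    images_per_case: int = 2
    n_cells: int = 25
    image_height_px: int = 512
    image_width_px: int = 512
    group_means: Mapping[str, float] = field(default_factory=lambda: dict(FDL_GROUP_MEANS))
    group_sds: Mapping[str, float] = field(default_factory=lambda: dict(FDL_GROUP_SDS))
    # segmentation
    min_area_px: int = 400
    connectivity: int = 8
    threshold_method: str = "otsu"
    fixed_value: int | None = None
    merge_rule: str = "mean2"
    # chromogenic cohort
    chr_n_cases: int = 5
    chr_neurons_per_case: int = 300
    chr_group_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(CHR_GROUP_RANGES)
    )
    holm: bool = False

    def __post_init__(self) -> None:
        if set(self.group_means) != set(GROUP_ORDER):
            raise ValueError(f"group_means must cover exactly {GROUP_ORDER}")
        if set(self.group_sds) != set(GROUP_ORDER):
            raise ValueError(f"group_sds must cover exactly {GROUP_ORDER}")
        if set(self.chr_group_ranges) != set(GROUP_ORDER):
            raise ValueError(f"chr_group_ranges must cover exactly {GROUP_ORDER}")
        if self.min_area_px < 0:
            raise ValueError("min_area_px must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("chr_group_ranges",):
            if key in d:
                d[key] = {k: tuple(v) for k, v in d[key].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["group_means"] = dict(self.group_means)
        d["group_sds"] = dict(self.group_sds)
        d["chr_group_ranges"] = {k: list(v) for k, v in self.chr_group_ranges.items()}
        return d


def _stage_fail(stage: str, exc: Exception) -> RuntimeError:
    return RuntimeError(f"pipeline stage {stage!r} failed: {exc}")


def quantify_manifest(
    manifest: pd.DataFrame,
    *,
    min_area_px: int = 400,
    connectivity: int = 8,
    threshold_method: str = "otsu",
    fixed_value: int | None = None,
    merge_rule: str = "mean2",
) -> pd.DataFrame:
    """Per-ROI signal table for every image listed in a manifest."""
    frames = []
    for row in manifest.itertuples(index=False):
        img = load_two_channel(row.image_path)
        df = quantify_image(
            img,
            min_area_px=min_area_px,
            connectivity=connectivity,
            threshold_method=threshold_method,
            fixed_value=fixed_value,
            merge_rule=merge_rule,
        )
        df.insert(0, "image", Path(row.image_path).name)
        df.insert(1, "case_id", row.case_id)
        df.insert(2, "group", getattr(row, "group", f"{row.stage}-{row.region}"))
        frames.append(df)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def group_stats_from_signals(signals: pd.DataFrame) -> list[GroupStats]:
    """Pooled per-group statistics from a per-ROI signal table."""
    out = []
    for group in GROUP_ORDER:
        sub = signals[(signals["group"] == group) & (~signals["flagged"])]
        if len(sub) < 2:
            continue
        sigs = [
            RoiSignal(int(r.label_id), r.R, r.G, r.X) for r in sub.itertuples(index=False)
        ]
        out.append(aggregate_group(sigs, group))
    return out


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the stats report (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"fdlquant {__version__} on python {platform.python_version()}",
        f"config: {json.dumps(config.to_dict(), sort_keys=True)}",
    ]
    report: dict = {"seed": config.seed}

    # --- stage 1: simulate fluorescence slides -----------------------------
    try:
        fdl_configs = {
            label: FdlSimConfig(
                image_height_px=config.image_height_px,
                image_width_px=config.image_width_px,
                n_cells=config.n_cells,
                mean_red_fraction=config.group_means[label],
                red_fraction_sd=config.group_sds[label],
                seed=derive_seed(config.seed, _STAGE_FDL, gi),
            )
            for gi, label in enumerate(GROUP_ORDER)
        }
        slides_dir = outdir / "slides"
        generate_fdl_group_set(
            fdl_configs,
            slides_dir,
            n_cases=config.n_cases,
            images_per_case=config.images_per_case,
        )
        manifest = load_manifest(slides_dir / "manifest.csv")
    except Exception as exc:
        raise _stage_fail("simulate", exc) from exc

    # --- stage 2+3: segment and quantify ------------------------------------
    try:
        signals = quantify_manifest(
            manifest,
            min_area_px=config.min_area_px,
            connectivity=config.connectivity,
            threshold_method=config.threshold_method,
            fixed_value=config.fixed_value,
            merge_rule=config.merge_rule,
        )
        write_table(signals, outdir / "signals.csv")
        n_rois = 0 if signals.empty else int((~signals["flagged"]).sum())
        log_lines.append(f"quantify: {n_rois} measurable ROIs")
    except Exception as exc:
        raise _stage_fail("quantify", exc) from exc

    if n_rois == 0:
        report["fdl"] = {"note": "no objects passed the area filter", "groups": []}
    else:
        gstats = group_stats_from_signals(signals)
        report["fdl"] = {"groups": [g.to_dict() for g in gstats]}

    # --- stage 4: chromogenic cohort ----------------------------------------
    try:
        neurons = generate_chr_group_cohort(
            config.chr_group_ranges,
            n_cases=config.chr_n_cases,
            neurons_per_case=config.chr_neurons_per_case,
            seed=derive_seed(config.seed, _STAGE_CHR),
        )
        write_table(neurons, outdir / "scores.csv")
        cases = case_table(neurons)
        cov = generate_case_covariates(
            cases["case_id"].tolist(), seed=derive_seed(config.seed, _STAGE_COV)
        )
        cases = cases.merge(cov, on="case_id")
        write_table(cases, outdir / "cases.csv")
    except Exception as exc:
        raise _stage_fail("score", exc) from exc

    # --- stage 5: statistics -------------------------------------------------
    try:
        by_group = {
            g: cases.loc[cases["group"] == g, "mean_score"].to_numpy()
            for g in GROUP_ORDER
        }
        chr_report: dict = {"group_means": group_mean_scores(cases)}
        pooled = cases["mean_score"].to_numpy()
        chr_report["shapiro"] = shapiro_gate(pooled).to_dict()
        chr_report["t_tests"] = [
            t.to_dict() for t in pairwise_ttests(by_group, holm=config.holm)
        ]
        chr_report["ancova"] = ancova(cases).to_dict()
        report["chr"] = chr_report
    except Exception as exc:
        raise _stage_fail("stats", exc) from exc

    with open(outdir / "stats.json", "w") as fh:
        json.dump(report, fh, indent=2)
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    logger.info("run complete: %s", outdir)
    return report
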