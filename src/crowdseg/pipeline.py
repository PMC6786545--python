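"""One-shot analysis pipeline: annotation table in, report bundle out.

Stages, in order: deduplicate -> rasterize -> consensus (both panels, all
thresholds) -> individual scoring against the reference consensus ->
consensus-vs-consensus -> pairwise reference-panel agreement -> annotator
behaviour statistics.  Every stage logs record counts; all numeric outputs
are plain delimited text, figures are regenerable PNG artifacts.

The pipeline is deterministic given its inputs: identical annotation and
metadata tables produce byte-identical numeric tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .annotator_stats import (
    build_annotator_summaries,
    covariate_accuracy_regression,
    points_vs_images_correlation,
    session_counts,
    session_throughput_test,
)
from .consensus import (
    build_consensus_map,
    deduplicate_records,
    flag_low_coverage,
    threshold_consensus,
)
from .geometry import BinaryMask, ImageGrid, OutlineRecord, rasterize_record
from .io import read_annotations, read_metadata, table_to_records, write_consensus_map
from .metrics import (
    AgreementTable,
    DiceResult,
    pairwise_panel_agreement,
    score_consensus_vs_consensus,
    score_individuals,
    threshold_sensitivity,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "infer_grid", "rasterize_all"]

log = logging.getLogger("crowdseg")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration for a pipeline run."""

    annotations: Path
    metadata: Path
    out_dir: Path
    reference_group: str = "expert"
    subject_group: str = "citizen"
    thresholds: tuple[float, ...] = (0.25, 0.5, 0.75)
    primary_threshold: float = 0.5
    min_coverage: int = 3
    max_bad_row_fraction: float = 0.05
    grid: Optional[ImageGrid] = None  # inferred from the data when absent
    seed: int = 0
    log_level: str = "INFO"
    write_figures: bool = True
    write_consensus_maps: bool = False

    def __post_init__(self) -> None:
        ts = tuple(float(t) for t in self.thresholds)
        if any(not (0.0 < t < 1.0) for t in ts):
            raise ValueError("thresholds must lie strictly in (0, 1)")
        if list(ts) != sorted(ts):
            raise ValueError("thresholds must be sorted ascending")
        object.__setattr__(self, "thresholds", ts)
        for name in ("annotations", "metadata", "out_dir"):
            object.__setattr__(self, name, Path(getattr(self, name)))
        if not self.annotations.exists():
            raise FileNotFoundError(self.annotations)
        if not self.metadata.exists():
            raise FileNotFoundError(self.metadata)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d = {k: (str(v) if isinstance(v, Path) else v) for k, v in d.items()}
        if self.grid is not None:
            d["grid"] = {"height": self.grid.height, "width": self.grid.width,
                         "pixel_spacing": self.grid.pixel_spacing}
        d["package_version"] = __version__
        return json.dumps(d, indent=2, default=str)


@dataclass
class PipelineResult:
    """In-memory bundle of every table the pipeline writes."""

    config: RunConfig
    grid: ImageGrid
    individual: AgreementTable
    consensus_vs_consensus: AgreementTable
    reference_pairwise: AgreementTable
    sensitivity: pd.DataFrame
    throughput: pd.DataFrame
    annotator_summary: pd.DataFrame
    stats: dict
    n_duplicates_removed: int
    low_coverage_images: list[str] = field(default_factory=list)


def infer_grid(annotations: pd.DataFrame, margin: int = 3) -> ImageGrid:
    """Smallest grid containing every vertex, plus a margin."""
    h = int(np.ceil(pd.to_numeric(annotations["y"], errors="coerce").max())) + margin
    w = int(np.ceil(pd.to_numeric(annotations["x"], errors="coerce").max())) + margin
    return ImageGrid(max(h, 1), max(w, 1))


def rasterize_all(
    records: Sequence[OutlineRecord], grid: ImageGrid
) -> dict[tuple[str, str], BinaryMask]:
    """Rasterize records into a {(annotator_id, image_id): mask} cache.

    Later records for the same key overwrite earlier ones, so deduplicate
    first when that matters.
    """
    return {(r.annotator_id, r.image_id): rasterize_record(r, grid) for r in records}


def _group_masks_by_image(
    masks: dict[tuple[str, str], BinaryMask], annotator_ids: set[str]
) -> dict[str, dict[str, BinaryMask]]:
    out: dict[str, dict[str, BinaryMask]] = {}
    for (ann, img), m in masks.items():
        if ann in annotator_ids:
            out.setdefault(img, {})[ann] = m
    return out


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage and write the report bundle to ``config.out_dir``."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(config.to_json())

    annotations = read_annotations(config.annotations)
    metadata = read_metadata(config.metadata)
    records, n_bad = table_to_records(annotations)
    if len(annotations) and n_bad / len(annotations) > config.max_bad_row_fraction:
        raise RuntimeError(
            f"{n_bad}/{len(annotations)} annotation rows malformed "
            f"(> {config.max_bad_row_fraction:.0%} allowed)"
        )
    log.info("parsed %d records from %d rows (%d malformed rows skipped)",
             len(records), len(annotations), n_bad)

    groups = metadata.set_index("annotator_id")["group"].to_dict()
    subject_ids = {a for a, g in groups.items() if g == config.subject_group}
    reference_ids = {a for a, g in groups.items() if g == config.reference_group}
    if not subject_ids or not reference_ids:
        raise RuntimeError(
            f"metadata must contain both groups "
            f"{config.subject_group!r} and {config.reference_group!r}"
        )

    kept, removed = deduplicate_records(records)
    log.info("deduplicated: %d kept, %d duplicate(s) removed", len(kept), len(removed))

    grid = config.grid or infer_grid(annotations)
    log.info("rasterizing %d records on a %dx%d grid", len(kept), grid.height, grid.width)
    masks = rasterize_all(kept, grid)

    subj_by_img = _group_masks_by_image(masks, subject_ids)
    ref_by_img = _group_masks_by_image(masks, reference_ids)
    low_cov = flag_low_coverage({i: len(v) for i, v in subj_by_img.items()},
                                config.min_coverage)

    # consensus maps once per panel; segmentations at every threshold
    subj_maps = {i: build_consensus_map(list(v.values())) for i, v in subj_by_img.items()}
    ref_maps = {i: build_consensus_map(list(v.values())) for i, v in ref_by_img.items()}
    t0 = config.primary_threshold
    subj_cons = {i: threshold_consensus(m, t0, source=config.subject_group)
                 for i, m in subj_maps.items()}
    ref_cons = {i: threshold_consensus(m, t0, source=config.reference_group)
                for i, m in ref_maps.items()}
    if config.write_consensus_maps:
        cdir = out / "consensus_maps"
        cdir.mkdir(exist_ok=True)
        for i, m in subj_maps.items():
            write_consensus_map(m, cdir / f"{i}__{config.subject_group}.txt",
                                image_id=i, panel=config.subject_group)
        for i, m in ref_maps.items():
            write_consensus_map(m, cdir / f"{i}__{config.reference_group}.txt",
                                image_id=i, panel=config.reference_group)

    subject_records = [r for r in kept if r.annotator_id in subject_ids]
    individual = score_individuals(subject_records, ref_cons, grid,
                                   reference_name=f"{config.reference_group}_consensus",
                                   mask_cache=masks)
    log.info("scored %d individual (annotator, image) pairs", len(individual))

    cvc = score_consensus_vs_consensus(subj_cons, ref_cons,
                                       name_a=f"{config.subject_group}_consensus",
                                       name_b=f"{config.reference_group}_consensus")
    pairwise_rows: list[DiceResult] = []
    for img, panel in sorted(ref_by_img.items()):
        pairwise_rows.extend(pairwise_panel_agreement(panel, img))
    pairwise = AgreementTable(pairwise_rows)

    sensitivity = threshold_sensitivity(
        {i: list(v.values()) for i, v in subj_by_img.items()},
        {i: list(v.values()) for i, v in ref_by_img.items()},
        config.thresholds,
    )

    # annotator behaviour; duplicates count toward throughput, so use the
    # raw (pre-dedup) table here
    throughput = session_counts(annotations)
    summaries = build_annotator_summaries(annotations, metadata, individual.by_annotator())
    stats = _behaviour_stats(throughput, summaries, subject_ids)
    stats["n_duplicates_removed"] = len(removed)
    stats["n_malformed_rows"] = n_bad
    stats["low_coverage_images"] = low_cov

    _write_tables(out, individual, cvc, pairwise, sensitivity, throughput, summaries, stats)
    if config.write_figures:
        _write_figures(out, individual, cvc, pairwise, throughput, summaries, annotations)
    _write_report(out, config, individual, cvc, pairwise, sensitivity, stats)
    log.info("report bundle written to %s", out)

    return PipelineResult(
        config=config, grid=grid, individual=individual, consensus_vs_consensus=cvc,
        reference_pairwise=pairwise, sensitivity=sensitivity, throughput=throughput,
        annotator_summary=summaries, stats=stats,
        n_duplicates_removed=len(removed), low_coverage_images=low_cov,
    )


def _behaviour_stats(throughput: pd.DataFrame, summaries: pd.DataFrame,
                     subject_ids: set[str]) -> dict:
    """Session throughput tests and the two covariate correlations.

    Each statistic is attempted independently; tiny or degenerate inputs
    record None for that entry instead of failing the run.
    """
    stats: dict = {}
    subj = summaries[summaries["annotator_id"].isin(subject_ids)]
    sess = {s: g["n_images"].to_numpy(float)
            for s, g in throughput[throughput["annotator_id"].isin(subject_ids)]
            .groupby("session")}
    sessions = sorted(sess)
    for a, b in zip(sessions, sessions[1:]):
        key = f"throughput_s{int(a)}_vs_s{int(b)}"
        try:
            u, p = session_throughput_test(sess[a], sess[b])
            stats[key] = {"U": u, "p": p, "n_a": len(sess[a]), "n_b": len(sess[b])}
        except ValueError as exc:
            log.warning("%s skipped: %s", key, exc)
            stats[key] = None
    for key, fn in (
        ("points_vs_images", lambda: points_vs_images_correlation(subj)),
        ("age_vs_accuracy", lambda: covariate_accuracy_regression(subj)),
    ):
        try:
            res = fn()
            stats[key] = {"r": res[0], "p": res[1]}
            if len(res) > 2:
                stats[key]["slope_per_decade"] = res[2]
        except ValueError as exc:
            log.warning("%s skipped: %s", key, exc)
            stats[key] = None
    return stats


def _write_tables(out: Path, individual: AgreementTable, cvc: AgreementTable,
                  pairwise: AgreementTable, sensitivity: pd.DataFrame,
                  throughput: pd.DataFrame, summaries: pd.DataFrame, stats: dict) -> None:
    individual.scores.to_csv(out / "individual_scores.csv", index=False)
    individual.summary().to_csv(out / "individual_summary.csv", index=False)
    cvc.scores.to_csv(out / "consensus_accuracy.csv", index=False)
    pairwise.scores.to_csv(out / "reference_pairwise.csv", index=False)
    pairwise.by_image().to_csv(out / "reference_pairwise_by_image.csv", index=False)
    sensitivity.to_csv(out / "threshold_sensitivity.csv", index=False)
    throughput.to_csv(out / "throughput.csv", index=False)
    summaries.to_csv(out / "annotator_summary.csv", index=False)
    (out / "stats.json").write_text(json.dumps(stats, indent=2, default=float))


def _write_figures(out: Path, individual: AgreementTable, cvc: AgreementTable,
                   pairwise: AgreementTable, throughput: pd.DataFrame,
                   summaries: pd.DataFrame, annotations: pd.DataFrame) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fdir = out / "figures"
    fdir.mkdir(exist_ok=True)

    # images per session (throughput)
    fig, ax = plt.subplots(figsize=(5, 4))
    sessions = sorted(throughput["session"].dropna().unique())
    data = [throughput.loc[throughput["session"] == s, "n_images"] for s in sessions]
    if data:
        ax.boxplot(data, tick_labels=[f"session {int(s)}" for s in sessions])
    ax.set_ylabel("images segmented")
    fig.savefig(fdir / "throughput_by_session.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    # mean points per image vs images analysed
    fig, ax = plt.subplots(figsize=(5, 4))
    pts = annotations.groupby(["annotator_id", "image_id", "session"], dropna=False).size()
    sd = pts.groupby("annotator_id").std()
    df = summaries.set_index("annotator_id")
    ax.errorbar(df["mean_points_per_image"], df["total_images"],
                xerr=sd.reindex(df.index), fmt="o", ms=4, lw=1, capsize=2)
    ax.set_xlabel("mean points per image")
    ax.set_ylabel("images analysed")
    fig.savefig(fdir / "points_vs_images.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    # accuracy by annotator (individuals vs reference consensus)
    fig, ax = plt.subplots(figsize=(8, 4))
    anns = sorted(individual.scores["subject"].unique())
    data = [individual.scores.loc[individual.scores["subject"] == a, "dice"] for a in anns]
    if data:
        ax.boxplot(data, tick_labels=anns)
        ax.tick_params(axis="x", rotation=90, labelsize=6)
    ax.set_ylabel("Dice vs reference consensus")
    fig.savefig(fdir / "accuracy_by_annotator.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    # accuracy by image: individuals (boxes), consensus (dots), pairwise (boxes)
    fig, ax = plt.subplots(figsize=(10, 4))
    imgs = sorted(cvc.scores["image_id"].unique())
    pos = np.arange(len(imgs))
    ind = [individual.scores.loc[individual.scores["image_id"] == i, "dice"] for i in imgs]
    pw = [pairwise.scores.loc[pairwise.scores["image_id"] == i, "dice"] for i in imgs]
    if any(len(d) for d in ind):
        ax.boxplot(ind, positions=pos - 0.15, widths=0.25, showfliers=False,
                   boxprops={"color": "tab:blue"})
    if any(len(d) for d in pw):
        ax.boxplot(pw, positions=pos + 0.15, widths=0.25, showfliers=False,
                   boxprops={"color": "tab:red"})
    cons = cvc.scores.set_index("image_id")["dice"].reindex(imgs)
    ax.plot(pos, cons, ".", color="tab:green", ms=4, label="subject consensus")
    ax.set_xticks([])
    ax.set_xlabel("image")
    ax.set_ylabel("Dice")
    ax.legend(loc="lower right", fontsize=7)
    fig.savefig(fdir / "accuracy_by_image.png", dpi=120, bbox_inches="tight")
    plt.close(fig)


def _fmt_stat(entry: Optional[dict]) -> str:
    if entry is None:
        return "not computable on this input"
    parts = [f"{k} = {v:.4g}" if isinstance(v, float) else f"{k} = {v}"
             for k, v in entry.items()]
    return ", ".join(parts)


def _write_report(out: Path, config: RunConfig, individual: AgreementTable,
                  cvc: AgreementTable, pairwise: AgreementTable,
                  sensitivity: pd.DataFrame, stats: dict) -> None:
    by_img = individual.by_image()
    lines = [
        "# Segmentation evaluation report",
        "",
        f"crowdseg {__version__}; subject group `{config.subject_group}`, "
        f"reference group `{config.reference_group}`, "
        f"primary threshold {config.primary_threshold}.",
        "",
        "## Throughput",
        "",
    ]
    for key, val in stats.items():
        if key.startswith("throughput_"):
            lines.append(f"- {key.removeprefix('throughput_')}: Mann-Whitney {_fmt_stat(val)}")
    lines += [
        "",
        "## Points vs images analysed",
        "",
        f"- Pearson {_fmt_stat(stats.get('points_vs_images'))}",
        "",
        "## Individual accuracy vs reference consensus",
        "",
        f"- {len(individual)} (annotator, image) scores over {len(by_img)} images",
    ]
    if len(by_img):
        med = by_img["median"]
        lines.append(
            f"- per-image median Dice: range {med.min():.3f}-{med.max():.3f}, "
            f"mean {med.mean():.3f}, SD {med.std(ddof=1):.3f}"
        )
    lines += [
        f"- age vs accuracy: Pearson {_fmt_stat(stats.get('age_vs_accuracy'))}",
        "",
        "## Consensus accuracy",
        "",
    ]
    if len(cvc):
        d = cvc.scores["dice"]
        lines.append(
            f"- subject consensus vs reference consensus over {len(cvc)} images: "
            f"range {d.min():.3f}-{d.max():.3f}, mean {d.mean():.3f}, SD {d.std(ddof=1):.3f}"
        )
    lines += ["", "### Threshold sensitivity", ""]
    for _, row in sensitivity.iterrows():
        lines.append(
            f"- threshold {row['threshold']:.2f}: mean {row['mean']:.3f}, SD {row['sd']:.3f} "
            f"({int(row['n_images'])} images)"
        )
    lines += ["", "## Reference-panel pairwise agreement", ""]
    if len(pairwise):
        pm = pairwise.by_image()["median"]
        lines.append(
            f"- per-image median pairwise Dice: range {pm.min():.3f}-{pm.max():.3f}, "
            f"mean {pm.mean():.3f}, SD {pm.std(ddof=1):.3f}"
        )
    lines += [
        "",
        "## Data handling",
        "",
        f"- duplicate records removed from accuracy analyses: {stats['n_duplicates_removed']}",
        f"- malformed annotation rows skipped: {stats['n_malformed_rows']}",
        f"- low-coverage images: {len(stats['low_coverage_images'])}",
        "",
    ]
    (out / "report.md").write_text("\n".join(lines))
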