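"""Synthetic ground truth and imperfect annotators.

The human study this package evaluates — dozens of lay annotators outlining
vertebrae on lumbar MR slices — has no deposited data, so every pipeline
stage is exercised against a simulator with the same statistical structure:

* ~150 images, each containing one vertebra-like shape: a large rounded
  *body* (a smoothly perturbed ellipse, star-convex about its center) plus
  a thin *posterior process* lobe.  Agreement is systematically harder on
  the thin structure than on the round body, reproducing the qualitative
  contrast seen in real inter-rater data.
* a citizen panel (default 29) in which each annotator segments a random
  subset of images, workload drawn from a truncated normal (parent mean 85,
  SD 43, bounded to [1, n_images]); an expert panel (default 3) segmenting
  every image.
* per-annotator noise: each outline samples ``n_points`` positions
  arc-length-uniformly along the true boundary and perturbs them — radially
  from the shape center for the body (keeps outlines simple polygons),
  along the outward normal for the thin process — by ``bias + N(0, sigma)``
  pixels.  With probability ``gross_error_rate`` the whole outline is
  replaced by a displaced, shrunken version (an attention lapse).

All randomness flows from a single top-level seed through named substreams,
so shapes, assignments and any individual outline are independently
reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import BinaryMask, ImageGrid, OutlineRecord, Polygon, rasterize_polygon

__all__ = [
    "GroundTruthShape",
    "AnnotatorModel",
    "StudyDesign",
    "StudyResult",
    "generate_shapes",
    "simulate_outline",
    "simulate_study",
    "default_citizen_models",
    "default_expert_models",
    "sample_workloads",
    "workload_moments",
    "estimate_annotator_noise",
]

_DENSE = 720  # boundary samples used for arc-length parameterization


def _substream(seed: int, *keys) -> np.random.Generator:
    """A named, reproducible child RNG of the top-level seed."""
    ints = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()))
        else:
            ints.append(int(k) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(ints))


# ---------------------------------------------------------------------------
# ground truth


@dataclass(frozen=True)
class GroundTruthShape:
    """A vertebra-like object: round body plus optional thin posterior lobe.

    The body boundary is ``r(θ) = r_ellipse(θ - rot) * (1 + Σ c_k cos(kθ + ψ_k))``
    about ``center`` — star-convex by construction, so radial noise keeps
    simulated outlines simple.  The process is a tapered thin lobe attached
    on the posterior side, stored directly as a polygon.
    """

    image_id: str
    grid: ImageGrid
    center: tuple[float, float]
    radii: tuple[float, float]  # ellipse semi-axes (a, b) in px
    rotation: float  # radians
    harmonics: tuple[tuple[int, float, float], ...]  # (k, amplitude, phase)
    process: Optional[Polygon] = None

    def body_radius(self, theta: np.ndarray) -> np.ndarray:
        """Distance from center to the body boundary at polar angle theta."""
        theta = np.asarray(theta, dtype=float)
        a, b = self.radii
        t = theta - self.rotation
        r = a * b / np.hypot(b * np.cos(t), a * np.sin(t))
        mod = np.ones_like(r)
        for k, amp, phase in self.harmonics:
            mod += amp * np.cos(k * theta + phase)
        return r * mod

    def body_polygon(self, n_points: int = _DENSE) -> Polygon:
        theta = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
        r = self.body_radius(theta)
        cx, cy = self.center
        return Polygon(np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)]))

    @property
    def regions(self) -> tuple[Polygon, ...]:
        """Ground-truth outline regions: body first, then the process."""
        body = self.body_polygon()
        return (body,) if self.process is None else (body, self.process)

    def body_mask(self) -> BinaryMask:
        return rasterize_polygon(self.body_polygon(), self.grid)

    def process_mask(self) -> BinaryMask:
        if self.process is None:
            return BinaryMask(self.grid, np.zeros(self.grid.shape, dtype=bool))
        return rasterize_polygon(self.process, self.grid)

    def ground_truth_mask(self) -> BinaryMask:
        return self.body_mask().union(self.process_mask())


@dataclass(frozen=True)
class AnnotatorModel:
    """Noise model for one annotator.

    sigma
        Boundary jitter SD in pixels (applied per placed point).
    bias
        Signed systematic offset in pixels: positive dilates (outlines
        drawn consistently outside the true edge), negative erodes.
    n_points
        Point budget per image; the study's per-annotator means spanned
        roughly 36-130 points.
    gross_error_rate
        Probability that an outline is grossly wrong (displaced/shrunken).
    """

    annotator_id: str
    sigma: float
    bias: float = 0.0
    n_points: int = 80
    gross_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")
        if not (0.0 <= self.gross_error_rate <= 1.0):
            raise ValueError("gross_error_rate must lie in [0, 1]")


@dataclass(frozen=True)
class StudyDesign:
    """Size and sampling structure of a simulated annotation study."""

    n_images: int = 150
    n_citizens: int = 29
    n_experts: int = 3
    workload_mean: float = 85.0
    workload_sd: float = 43.0
    n_sessions: int = 3
    grid: ImageGrid = field(default_factory=lambda: ImageGrid(128, 128, (0.49, 0.49)))
    body_radius_range: tuple[float, float] = (0.14, 0.23)  # fraction of min(h, w)
    process_probability: float = 1.0
    age_range: tuple[float, float] = (18.0, 73.0)
    age_sigma_slope: float = 0.0  # extra jitter px per year above the midpoint age
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_images, self.n_citizens, self.n_experts) < 1:
            raise ValueError("design counts must be >= 1")
        r_max = self.body_radius_range[1] * min(self.grid.height, self.grid.width)
        if r_max < 6:
            raise ValueError("grid too small for the configured shape scale")


def workload_moments(design: StudyDesign) -> tuple[float, float]:
    """Exact mean and SD of the (continuous) truncated workload distribution."""
    lo, hi = 1.0, float(design.n_images)
    a = (lo - design.workload_mean) / design.workload_sd
    b = (hi - design.workload_mean) / design.workload_sd
    m, v = stats.truncnorm.stats(a, b, loc=design.workload_mean, scale=design.workload_sd,
                                 moments="mv")
    return float(m), float(np.sqrt(v))


def sample_workloads(design: StudyDesign, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw integer per-citizen workloads from the truncated normal."""
    lo, hi = 1.0, float(design.n_images)
    a = (lo - design.workload_mean) / design.workload_sd
    b = (hi - design.workload_mean) / design.workload_sd
    draws = stats.truncnorm.rvs(a, b, loc=design.workload_mean, scale=design.workload_sd,
                                size=n, random_state=rng)
    return np.clip(np.rint(draws), 1, design.n_images).astype(int)


def generate_shapes(design: StudyDesign) -> list[GroundTruthShape]:
    """Deterministically generate one ground-truth shape per image."""
    rng = _substream(design.seed, "shapes")
    h, w = design.grid.shape
    scale = min(h, w)
    shapes = []
    for i in range(design.n_images):
        image_id = f"img_{i + 1:03d}"
        mean_r = rng.uniform(*design.body_radius_range) * scale
        aspect = rng.uniform(0.72, 0.98)
        a, b = mean_r / np.sqrt(aspect), mean_r * np.sqrt(aspect)
        cx = rng.uniform(0.40, 0.60) * w
        cy = rng.uniform(0.35, 0.55) * h
        rotation = rng.uniform(0, np.pi)
        harmonics = tuple(
            (k, float(np.clip(rng.normal(0.0, 0.03), -0.08, 0.08)), float(rng.uniform(0, 2 * np.pi)))
            for k in (2, 3, 4)
        )
        shape = GroundTruthShape(image_id, design.grid, (cx, cy), (a, b), rotation, harmonics)
        if rng.uniform() < design.process_probability:
            shape = replace(shape, process=_make_process(shape, rng))
        shapes.append(shape)
    return shapes


def _make_process(shape: GroundTruthShape, rng: np.random.Generator) -> Polygon:
    """A thin, tapered lobe attached to the body's posterior (+y) side."""
    theta_p = np.pi / 2 + rng.normal(0.0, 0.15)  # +y is "down" in image coords
    r_base = float(shape.body_radius(np.array([theta_p]))[0])
    mean_r = float(np.mean(shape.radii))
    length = rng.uniform(0.55, 0.95) * mean_r
    half_w = rng.uniform(2.2, 3.6)
    d = np.array([np.cos(theta_p), np.sin(theta_p)])
    n = np.array([-d[1], d[0]])
    cx, cy = shape.center
    base = np.array([cx, cy]) + (r_base - 2.0) * d  # overlap body so the union connects
    s = np.linspace(0.0, 1.0, 8)
    taper = half_w * (1.0 - 0.45 * s)
    left = base[None, :] + np.outer(s * length, d) + np.outer(taper, n)
    right = base[None, :] + np.outer(s * length, d) - np.outer(taper, n)
    pts = np.vstack([left, right[::-1]])
    return Polygon(pts)


# ---------------------------------------------------------------------------
# outline simulation


def _resample_closed(pts: np.ndarray, n: int, phase: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample n points arc-length-uniformly along a closed polyline.

    Returns the sampled points and the unit tangents at the samples.
    ``phase`` in [0, 1) rotates the sampling offsets along the perimeter.
    """
    closed = np.vstack([pts, pts[:1]])
    seg = np.diff(closed, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    targets = (phase + np.arange(n) / n) % 1.0 * total
    idx = np.searchsorted(cum, targets, side="right") - 1
    idx = np.clip(idx, 0, len(seglen) - 1)
    frac = (targets - cum[idx]) / np.where(seglen[idx] > 0, seglen[idx], 1.0)
    sampled = closed[idx] + seg[idx] * frac[:, None]
    tangents = seg[idx] / np.where(seglen[idx] > 0, seglen[idx], 1.0)[:, None]
    return sampled, tangents


def _perturb_body(shape: GroundTruthShape, n: int, model: AnnotatorModel,
                  rng: np.random.Generator) -> np.ndarray:
    phase = rng.uniform()
    theta = (2 * np.pi * (phase + np.arange(n) / n)) % (2 * np.pi)
    r = shape.body_radius(theta) + model.bias + rng.normal(0.0, model.sigma, size=n)
    r = np.maximum(r, 1.0)
    cx, cy = shape.center
    return np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])


def _perturb_normal(poly: Polygon, n: int, model: AnnotatorModel,
                    rng: np.random.Generator) -> np.ndarray:
    pts, tangents = _resample_closed(poly.points, n, rng.uniform())
    normals = np.column_stack([tangents[:, 1], -tangents[:, 0]])
    centroid = poly.points.mean(axis=0)
    flip = np.einsum("ij,ij->i", normals, pts - centroid) < 0
    normals[flip] *= -1.0
    offsets = model.bias + rng.normal(0.0, model.sigma, size=n)
    return pts + normals * offsets[:, None]


def _gross_outline(shape: GroundTruthShape, n: int, rng: np.random.Generator) -> np.ndarray:
    """A displaced, shrunken body outline: the 'wrong structure' failure."""
    theta = np.linspace(0, 2 * np.pi, max(n, 8), endpoint=False)
    r = 0.55 * shape.body_radius(theta)
    mean_r = float(np.mean(shape.radii))
    ang = rng.uniform(0, 2 * np.pi)
    shift = rng.uniform(0.4, 0.8) * mean_r * np.array([np.cos(ang), np.sin(ang)])
    cx, cy = shape.center
    return np.column_stack(
        [cx + shift[0] + r * np.cos(theta), cy + shift[1] + r * np.sin(theta)]
    )


def simulate_outline(
    shape: GroundTruthShape, model: AnnotatorModel, session: int = 1
) -> OutlineRecord:
    """One annotator's noisy outline(s) of one shape.

    Deterministic given (shape.image_id, model.annotator_id, model.seed,
    session).  The point budget is split ~72/28 between body and process
    when a process exists.
    """
    rng = _substream(model.seed, "outline", model.annotator_id, shape.image_id, session)
    if rng.uniform() < model.gross_error_rate:
        pts = _gross_outline(shape, model.n_points, rng)
        return OutlineRecord(model.annotator_id, shape.image_id, [Polygon(pts)], session)
    if shape.process is None:
        n_body, n_proc = model.n_points, 0
    else:
        n_body = max(8, int(round(0.72 * model.n_points)))
        n_proc = max(6, model.n_points - n_body)
    regions = [Polygon(_perturb_body(shape, n_body, model, rng))]
    if n_proc:
        regions.append(Polygon(_perturb_normal(shape.process, n_proc, model, rng)))
    return OutlineRecord(model.annotator_id, shape.image_id, regions, session)


# ---------------------------------------------------------------------------
# panels and the full study


def default_citizen_models(design: StudyDesign, ages: np.ndarray) -> list[AnnotatorModel]:
    """Heterogeneous citizen noise models drawn from the design's seed.

    Jitter SDs are log-normal (median ~1.5 px, a long tail of sloppier
    annotators), biases are centered Gaussians, and point budgets span the
    observed 36-130 range.  An optional planted age effect adds
    ``age_sigma_slope`` px of jitter per year above the panel midpoint.
    """
    rng = _substream(design.seed, "citizen-models")
    mid_age = float(np.mean(design.age_range))
    models = []
    for i in range(design.n_citizens):
        sigma = float(np.clip(rng.lognormal(np.log(1.5), 0.45), 0.4, 4.5))
        sigma += design.age_sigma_slope * (float(ages[i]) - mid_age)
        sigma = max(sigma, 0.2)
        models.append(
            AnnotatorModel(
                annotator_id=f"citizen_{i + 1:02d}",
                sigma=sigma,
                bias=float(rng.normal(0.0, 0.8)),
                n_points=int(rng.integers(36, 131)),
                gross_error_rate=0.02,
                seed=design.seed,
            )
        )
    return models


def default_expert_models(design: StudyDesign) -> list[AnnotatorModel]:
    """Low-noise, nearly unbiased expert models."""
    rng = _substream(design.seed, "expert-models")
    return [
        AnnotatorModel(
            annotator_id=f"expert_{i + 1}",
            sigma=float(rng.uniform(0.5, 0.9)),
            bias=float(rng.normal(0.0, 0.2)),
            n_points=int(rng.integers(80, 131)),
            gross_error_rate=0.0,
            seed=design.seed,
        )
        for i in range(design.n_experts)
    ]


@dataclass
class StudyResult:
    """Everything a simulated study produces."""

    design: StudyDesign
    shapes: list[GroundTruthShape]
    records: list[OutlineRecord]
    annotations: pd.DataFrame  # canonical vertex table
    metadata: pd.DataFrame  # annotator_id, age, group
    citizen_models: list[AnnotatorModel]
    expert_models: list[AnnotatorModel]
    uncovered_images: list[str]  # images no citizen segmented

    @property
    def ground_truth(self) -> dict[str, BinaryMask]:
        return {s.image_id: s.ground_truth_mask() for s in self.shapes}


def simulate_study(
    design: StudyDesign,
    citizen_models: Optional[Sequence[AnnotatorModel]] = None,
    expert_models: Optional[Sequence[AnnotatorModel]] = None,
) -> StudyResult:
    """Run the full simulated study.

    Experts segment every image; each citizen segments a workload-sized
    uniform random subset, split across sessions.  Outputs the canonical
    annotation table, annotator metadata with synthetic ages, and the
    ground-truth shapes.
    """
    from .io import records_to_table  # local import to avoid a cycle

    rng_assign = _substream(design.seed, "assignment")
    rng_age = _substream(design.seed, "ages")
    ages = np.round(rng_age.uniform(*design.age_range, size=design.n_citizens), 1)

    if citizen_models is None:
        citizen_models = default_citizen_models(design, ages)
    if expert_models is None:
        expert_models = default_expert_models(design)
    if len(citizen_models) != design.n_citizens or len(expert_models) != design.n_experts:
        raise ValueError("model counts must match the design's panel sizes")

    shapes = generate_shapes(design)
    by_id = {s.image_id: s for s in shapes}
    image_ids = [s.image_id for s in shapes]

    workloads = sample_workloads(design, design.n_citizens, rng_assign)
    records: list[OutlineRecord] = []
    covered: set[str] = set()
    for model, load in zip(citizen_models, workloads):
        chosen = rng_assign.choice(image_ids, size=int(load), replace=False)
        rng_assign.shuffle(chosen)
        sessions = np.array_split(chosen, design.n_sessions)
        for s_idx, imgs in enumerate(sessions, start=1):
            for img in imgs:
                records.append(simulate_outline(by_id[img], model, session=s_idx))
                covered.add(img)
    for model in expert_models:
        for img in image_ids:
            records.append(simulate_outline(by_id[img], model, session=1))

    metadata = pd.DataFrame(
        {
            "annotator_id": [m.annotator_id for m in citizen_models]
            + [m.annotator_id for m in expert_models],
            "age": list(ages) + [np.nan] * design.n_experts,
            "group": ["citizen"] * design.n_citizens + ["expert"] * design.n_experts,
        }
    )
    uncovered = sorted(set(image_ids) - covered)
    return StudyResult(
        design=design,
        shapes=shapes,
        records=records,
        annotations=records_to_table(records),
        metadata=metadata,
        citizen_models=list(citizen_models),
        expert_models=list(expert_models),
        uncovered_images=uncovered,
    )


# ---------------------------------------------------------------------------
# parameter recovery


def estimate_annotator_noise(
    records: Sequence[OutlineRecord], shapes: Mapping[str, GroundTruthShape]
) -> pd.DataFrame:
    """Estimate each annotator's jitter SD and bias from their outlines.

    For every body-region vertex the signed radial deviation from the true
    boundary, ``d = |p - center| - r_true(θ(p))``, is exactly the planted
    ``bias + N(0, sigma)`` perturbation, so the pooled per-annotator mean
    and SD of deviations recover bias and sigma.  Gross-error outlines are
    not modelled here; estimates are only unbiased for records generated
    with ``gross_error_rate = 0`` (or after screening them out).

    Returns a frame with columns annotator_id, sigma_hat, bias_hat, n_vertices.
    """
    devs: dict[str, list[np.ndarray]] = {}
    for rec in records:
        shape = shapes.get(rec.image_id)
        if shape is None:
            continue
        pts = rec.regions[0].points  # body region
        cx, cy = shape.center
        dx, dy = pts[:, 0] - cx, pts[:, 1] - cy
        theta = np.arctan2(dy, dx)
        d = np.hypot(dx, dy) - shape.body_radius(theta)
        devs.setdefault(rec.annotator_id, []).append(d)
    rows = []
    for ann in sorted(devs):
        d = np.concatenate(devs[ann])
        rows.append(
            {
                "annotator_id": ann,
                "sigma_hat": float(d.std(ddof=1)),
                "bias_hat": float(d.mean()),
                "n_vertices": int(d.size),
            }
        )
    return pd.DataFrame(rows)
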