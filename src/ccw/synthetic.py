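"""Procedural carcass images with exact analytic ground truth.

The study cohort this generator emulates is 301 suspended chicken carcasses
photographed from three standardized views (ventral, dorsal, lateral) with
three replicate captures per view — 2709 images in all — on a dark backdrop
with a known pixel-per-centimetre calibration.

Each synthetic carcass is a union of analytic primitives on a square canvas:

* torso — an axis-aligned ellipse (semi-axes scale with the carcass size
  factor ``s``),
* head — a disc hanging below the torso (the bird is suspended by the legs),
* legs — two vertical capsules (segment plus hemispherical caps) above the
  torso.

Because the primitives are analytic and pairwise disjoint, every part has a
closed-form area, so rasterized pixel counts can be checked against exact
oracles.  A pixel belongs to a part iff its center (col + 0.5, row + 0.5)
lies inside the shape; where dilated or annotated shapes ever overlap, the
priority torso < leg < head resolves the pixel (last wins).  The lateral
view narrows all horizontal torso/leg placement by a fixed aspect factor.

Appearance is deliberately minimal: background intensity ~ N(20, sigma_tex),
foreground ~ N(180, sigma_tex), clipped to [0, 255].  Replicate captures
re-draw a global position jitter (sigma_pos), a small per-replicate size
jitter (sigma_scale), and fresh texture noise.

Carcass weights follow a noisy linear allometric model on the per-part areas
averaged over views:  ``W = beta0 + sum_p beta_p * area_p + N(0, sigma_w)``,
with part weights generated analogously.  When ``sigma_w`` is left
unspecified, :func:`generate_dataset` calibrates it so that the deterministic
part of the weight explains a target fraction (default 0.9) of the cohort
weight variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset_io import CarcassRecord, CLASS_NAMES, PART_CLASSES

VIEWS = ("ventral", "dorsal", "lateral")
PARTS = ("torso", "head", "leg")
LATERAL_ASPECT = 0.65


@dataclass
class SyntheticCarcassSpec:
    """Geometry and noise parameters for one synthetic carcass."""

    carcass_id: str
    s: float = 1.0                      # dimensionless size factor
    canvas: int = 640                   # square canvas side, px
    torso_semi_axes: tuple[float, float] = (80.0, 110.0)   # (horizontal, vertical) px
    head_radius: float = 33.0           # px
    leg_length: float = 92.0            # capsule segment length, px
    leg_width: float = 24.0             # capsule diameter, px
    leg_splay_deg: float = 8.0          # outward leg tilt from vertical
    gap: float = 10.0                   # clearance between parts, px
    views: tuple[str, ...] = VIEWS
    sigma_pos: float = 2.0              # replicate position jitter, px
    sigma_tex: float = 8.0              # texture noise, intensity units
    sigma_scale: float = 0.01           # replicate size jitter, relative
    px_per_cm: float = 10.0

    def __post_init__(self):
        if self.s <= 0:
            raise ValueError("scale s must be positive")
        for name in ("head_radius", "leg_length", "leg_width", "px_per_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if min(self.torso_semi_axes) <= 0:
            raise ValueError("torso_semi_axes must be positive")
        if not self.views:
            raise ValueError("views must be non-empty")
        unknown = set(self.views) - set(VIEWS)
        if unknown:
            raise ValueError(f"unknown views {sorted(unknown)}; choose from {VIEWS}")
        if self.sigma_pos < 0 or self.sigma_tex < 0 or self.sigma_scale < 0:
            raise ValueError("jitter/noise sigmas must be non-negative")
        self._check_fit()

    def _check_fit(self) -> None:
        ax, ay = self.torso_semi_axes
        s = self.s
        margin = 4.0 * self.sigma_pos + 2.0
        half = self.canvas / 2.0
        vertical = s * (self.leg_length + self.leg_width / 2 + 2 * self.gap
                        + 2 * ay + 2 * self.head_radius)
        if vertical + 2 * margin > self.canvas:
            raise ValueError(
                f"vertical extent {vertical:.1f}px (leg_length + torso semi-axis "
                f"+ head_radius stack) does not fit canvas {self.canvas}"
            )
        splay = np.deg2rad(self.leg_splay_deg)
        leg_reach = 0.9 * ax + 2 * (np.sin(splay) * self.leg_length
                                    + self.leg_width)
        horizontal = s * max(2 * ax, leg_reach)
        if horizontal + 2 * margin > self.canvas:
            raise ValueError(
                f"horizontal extent {horizontal:.1f}px (torso_semi_axes[0] / "
                f"leg splay reach) does not fit canvas {self.canvas}"
            )
        del half


def default_spec(carcass_id: str, s: float = 1.0, canvas: int = 640,
                 **overrides) -> SyntheticCarcassSpec:
    """Default geometry, scaled proportionally for non-640 canvases."""
    k = canvas / 640.0
    params = dict(
        carcass_id=carcass_id, s=s, canvas=canvas,
        torso_semi_axes=(80.0 * k, 110.0 * k), head_radius=33.0 * k,
        leg_length=92.0 * k, leg_width=24.0 * k, gap=max(2.0, 10.0 * k),
        sigma_pos=2.0 * k, sigma_tex=8.0, px_per_cm=10.0 * k,
    )
    params.update(overrides)
    return SyntheticCarcassSpec(**params)


# ---------------------------------------------------------------------------
# geometry


def _view_shapes(spec: SyntheticCarcassSpec, view: str, s: float,
                 jitter: tuple[float, float] = (0.0, 0.0)) -> list[tuple]:
    """Analytic primitives for one view, in raster (x, y) coordinates.

    Returns a list of (part, kind, params) in paint priority order
    torso < leg < head.
    """
    ax, ay = spec.torso_semi_axes
    aspect = LATERAL_ASPECT if view == "lateral" else 1.0
    ax_v = ax * aspect * s
    ay_v = ay * s
    r = spec.head_radius * s
    leg_l = spec.leg_length * s
    leg_w = spec.leg_width * s
    gap = spec.gap * s
    c = spec.canvas
    # vertical placement: center the leg-torso-head stack on the canvas
    top_extent = ay_v + gap + leg_l + leg_w / 2
    bottom_extent = ay_v + gap + 2 * r
    cy = (c + top_extent - bottom_extent) / 2.0 + jitter[1]
    cx = c / 2.0 + jitter[0]
    leg_dx = 0.45 * ax_v
    splay = np.deg2rad(spec.leg_splay_deg)
    sx, sy = np.sin(splay) * leg_l, np.cos(splay) * leg_l
    leg_y1 = cy - ay_v - gap - leg_w / 2        # foot of the leg segment
    head_cy = cy + ay_v + gap + r
    return [
        ("torso", "ellipse", (cx, cy, ax_v, ay_v)),
        ("leg", "capsule", (cx - leg_dx - sx, leg_y1 - sy,
                            cx - leg_dx, leg_y1, leg_w / 2)),
        ("leg", "capsule", (cx + leg_dx + sx, leg_y1 - sy,
                            cx + leg_dx, leg_y1, leg_w / 2)),
        ("head", "disc", (cx, head_cy, r)),
    ]


def shape_membership(kind: str, params: tuple, x: np.ndarray,
                     y: np.ndarray) -> np.ndarray:
    """Vectorized point-in-shape test at arbitrary coordinates."""
    if kind == "ellipse":
        cx, cy, ax, ay = params
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0
    if kind == "disc":
        cx, cy, r = params
        return (x - cx) ** 2 + (y - cy) ** 2 <= r * r
    if kind == "capsule":
        x0, y0, x1, y1, r = params
        dx, dy = x1 - x0, y1 - y0
        denom = dx * dx + dy * dy
        t = np.clip(((x - x0) * dx + (y - y0) * dy) / denom, 0.0, 1.0)
        px, py = x0 + t * dx, y0 + t * dy
        return (x - px) ** 2 + (y - py) ** 2 <= r * r
    raise ValueError(f"unknown shape kind {kind!r}")


def rasterize_view(spec: SyntheticCarcassSpec, view: str, s: float | None = None,
                   jitter: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Paint the view's label mask (pixel-center membership, priority order)."""
    s = spec.s if s is None else s
    c = spec.canvas
    ys, xs = np.mgrid[0:c, 0:c]
    x = xs + 0.5
    y = ys + 0.5
    labels = np.zeros((c, c), dtype=np.int64)
    for part, kind, params in _view_shapes(spec, view, s, jitter):
        inside = shape_membership(kind, params, x, y)
        labels[inside] = PART_CLASSES[part]
    return labels


def analytic_areas_cm2(spec: SyntheticCarcassSpec, view: str,
                       s: float | None = None) -> dict[str, float]:
    """Closed-form per-part areas (cm^2) for one view."""
    s = spec.s if s is None else s
    ax, ay = spec.torso_semi_axes
    aspect = LATERAL_ASPECT if view == "lateral" else 1.0
    ppc2 = spec.px_per_cm**2
    torso = np.pi * (ax * aspect * s) * (ay * s)
    head = np.pi * (spec.head_radius * s) ** 2
    leg_r = spec.leg_width * s / 2
    leg = 2 * (spec.leg_length * s * spec.leg_width * s + np.pi * leg_r**2)
    return {"torso": torso / ppc2, "head": head / ppc2, "leg": leg / ppc2}


def render_view(spec: SyntheticCarcassSpec, labels: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Dark-background / bright-foreground RGB rendering of a label mask."""
    c = spec.canvas
    base = np.where(labels[..., None] > 0, 180.0, 20.0)
    noise = rng.normal(0.0, spec.sigma_tex, size=(c, c, 3)) if spec.sigma_tex > 0 \
        else 0.0
    return np.clip(base + noise, 0, 255).astype(np.uint8)


def generate_carcass(spec: SyntheticCarcassSpec, seed: int,
                     replicates: int = 1, masks_only: bool = False) -> dict:
    """Generate images and masks for every (view, replicate) of one carcass.

    Returns a dict with ``images[(view, rep)]`` (H, W, 3 uint8),
    ``masks[(view, rep)]`` (label arrays), and ``true_areas_cm2[view][part]``
    (jitter-free analytic areas used by the weight model).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF]))
    images: dict = {}
    masks: dict = {}
    for rep in range(1, replicates + 1):
        jx, jy = (rng.normal(0.0, spec.sigma_pos, size=2)
                  if spec.sigma_pos > 0 else (0.0, 0.0))
        s_rep = spec.s * (1.0 + (rng.normal(0.0, spec.sigma_scale)
                                 if spec.sigma_scale > 0 else 0.0))
        for view in spec.views:
            labels = rasterize_view(spec, view, s=s_rep, jitter=(jx, jy))
            if not masks_only:
                images[(view, rep)] = render_view(spec, labels, rng)
            masks[(view, rep)] = labels
    areas = {view: analytic_areas_cm2(spec, view) for view in spec.views}
    return {"images": images, "masks": masks, "true_areas_cm2": areas,
            "class_map": dict(CLASS_NAMES)}


# ---------------------------------------------------------------------------
# weights


@dataclass
class WeightModel:
    """Noisy linear area -> weight model (grams, grams per cm^2)."""

    beta0: float = 80.0
    betas: dict[str, float] = field(
        default_factory=lambda: {"torso": 2.6, "head": 2.2, "leg": 2.4}
    )
    sigma_w: float | None = 60.0        # None => calibrate from the cohort
    part_intercepts: dict[str, float] = field(
        default_factory=lambda: {"torso": 30.0, "head": 5.0, "leg": 8.0}
    )
    part_sigma_frac: dict[str, float] = field(
        default_factory=lambda: {"torso": 0.6, "head": 0.1, "leg": 0.12}
    )

    def __post_init__(self):
        if self.sigma_w is not None and self.sigma_w < 0:
            raise ValueError("sigma_w must be non-negative")

    def deterministic_weights(self, areas: dict[str, dict[str, float]]
                              ) -> tuple[float, dict[str, float]]:
        """(total, per-part) weights without noise; areas[part][view] in cm^2."""
        mean_area = {p: float(np.mean(list(v.values()))) for p, v in areas.items()}
        for p, a in mean_area.items():
            if a < 0:
                raise ValueError(f"negative area for part {p!r}")
        part = {
            p: self.part_intercepts.get(p, 0.0) + self.betas.get(p, 0.0) * a
            for p, a in mean_area.items()
        }
        total = self.beta0 + sum(
            self.betas.get(p, 0.0) * a for p, a in mean_area.items()
        )
        return total, part


def assign_weights(true_areas_cm2: dict[str, dict[str, float]],
                   model: WeightModel, seed: int,
                   carcass_id: str = "c0") -> CarcassRecord:
    """Draw a noisy weight record for one carcass from its true areas."""
    if model.sigma_w is None:
        raise ValueError("sigma_w must be a number for single-carcass sampling")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 977]))
    total_det, part_det = model.deterministic_weights(true_areas_cm2)
    clamped: list[str] = []
    total = total_det + rng.normal(0.0, model.sigma_w) if model.sigma_w > 0 \
        else total_det
    if total < 0:
        total = 0.0
        clamped.append("total")
    part_g = {}
    for p, det in part_det.items():
        sig = model.sigma_w * model.part_sigma_frac.get(p, 0.0)
        w = det + rng.normal(0.0, sig) if sig > 0 else det
        if w < 0:
            w = 0.0
            clamped.append(p)
        part_g[p] = float(w)
    return CarcassRecord(carcass_id, float(total), part_g, clamped)


# ---------------------------------------------------------------------------
# cohort


@dataclass
class DatasetManifest:
    """Lazy cohort manifest: image records plus weights; pixels on demand."""

    images: pd.DataFrame          # carcass_id, view, replicate, px_per_cm
    weights: pd.DataFrame         # carcass_id, weight_total_g, weight_<part>_g
    specs: dict[str, SyntheticCarcassSpec]
    seed: int
    weight_model: WeightModel

    def render(self, carcass_id: str, view: str, replicate: int):
        """Deterministically materialize one (image, mask) pair."""
        spec = self.specs[carcass_id]
        sample = generate_carcass(spec, seed=_carcass_seed(self.seed, carcass_id),
                                  replicates=max(
                                      self.images.replicate.max(), replicate))
        return sample["images"][(view, replicate)], sample["masks"][(view, replicate)]

    def render_carcass(self, carcass_id: str, masks_only: bool = False) -> dict:
        spec = self.specs[carcass_id]
        reps = int(self.images.replicate.max())
        return generate_carcass(spec, seed=_carcass_seed(self.seed, carcass_id),
                                replicates=reps, masks_only=masks_only)

    def true_areas(self, carcass_id: str) -> dict[str, dict[str, float]]:
        spec = self.specs[carcass_id]
        return {p: {v: analytic_areas_cm2(spec, v)[p] for v in spec.views}
                for p in PARTS}

    def to_csv(self, images_path, weights_path) -> None:
        self.images.to_csv(images_path, index=False, float_format="%.6f")
        self.weights.to_csv(weights_path, index=False, float_format="%.6f")


def analytic_areas_table(manifest: "DatasetManifest") -> pd.DataFrame:
    """Closed-form per-part areas as a tidy table (one replicate per view).

    Bypasses rasterization entirely; useful when only the area -> weight
    relationship is under study.
    """
    rows = []
    for cid, spec in manifest.specs.items():
        for view in spec.views:
            for part, a in analytic_areas_cm2(spec, view).items():
                rows.append({"carcass_id": cid, "view": view, "replicate": 1,
                             "part": part, "area_cm2": a})
    return pd.DataFrame(rows)


def _carcass_seed(seed: int, carcass_id: str) -> int:
    idx = int(carcass_id.split("_")[-1])
    return int(np.random.SeedSequence([seed & 0x7FFFFFFF, idx]).generate_state(1)[0]
               & 0x7FFFFFFF)


def generate_dataset(n_carcasses: int, views: int = 3, replicates: int = 3,
                     seed: int = 0, canvas: int = 640,
                     weight_model: WeightModel | None = None,
                     signal_fraction: float = 0.9, size_cv: float = 0.12,
                     part_cv: float = 0.05, **spec_overrides) -> DatasetManifest:
    """Generate a cohort manifest of ``n_carcasses`` x views x replicates records.

    Carcass size factors are drawn ~ N(1, size_cv) (clipped to [0.75, 1.3]);
    on top of the shared factor, each part (torso, head, legs) receives an
    independent linear-size multiplier ~ N(1, part_cv) (clipped to
    [0.85, 1.15]), so per-part areas vary independently across the cohort the
    way real conformation does.  If the weight model's ``sigma_w`` is
    ``None``, it is calibrated so the deterministic area term explains
    ``signal_fraction`` of the cohort weight variance.
    """
    if n_carcasses < 1:
        raise ValueError("n_carcasses must be at least 1")
    view_names = VIEWS[:views]
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 11]))
    model = weight_model if weight_model is not None else WeightModel(sigma_w=None)

    specs: dict[str, SyntheticCarcassSpec] = {}
    for i in range(n_carcasses):
        cid = f"carcass_{i:04d}"
        s = float(np.clip(rng.normal(1.0, size_cv), 0.75, 1.3))
        tm, hm, lm = np.clip(rng.normal(1.0, part_cv, size=3), 0.85, 1.15)
        base = default_spec(cid, s=s, canvas=canvas, views=view_names,
                            **spec_overrides)
        specs[cid] = replace(
            base,
            torso_semi_axes=(base.torso_semi_axes[0] * tm,
                             base.torso_semi_axes[1] * tm),
            head_radius=base.head_radius * hm,
            leg_length=base.leg_length * lm,
            leg_width=base.leg_width * lm,
        )

    all_areas = {cid: {p: {v: analytic_areas_cm2(sp, v)[p] for v in view_names}
                       for p in PARTS}
                 for cid, sp in specs.items()}

    if model.sigma_w is None:
        det_totals = np.array(
            [model.deterministic_weights(all_areas[cid])[0] for cid in specs]
        )
        sd_det = float(det_totals.std(ddof=1)) if n_carcasses > 1 else 0.0
        f = signal_fraction
        sigma = sd_det * np.sqrt((1.0 - f) / f) if f < 1.0 else 0.0
        model = replace(model, sigma_w=float(sigma))

    weight_rows = []
    for cid in specs:
        rec = assign_weights(all_areas[cid], model,
                             seed=_carcass_seed(seed, cid), carcass_id=cid)
        row = {"carcass_id": cid, "weight_total_g": rec.total_g}
        for p in PARTS:
            row[f"weight_{p}_g"] = rec.part_g[p]
        row["clamped"] = ";".join(rec.clamped)
        weight_rows.append(row)

    image_rows = [
        {"carcass_id": cid, "view": v, "replicate": r,
         "px_per_cm": specs[cid].px_per_cm}
        for cid in specs for v in view_names for r in range(1, replicates + 1)
    ]
    return DatasetManifest(
        images=pd.DataFrame(image_rows),
        weights=pd.DataFrame(weight_rows),
        specs=specs, seed=seed, weight_model=model,
    )
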