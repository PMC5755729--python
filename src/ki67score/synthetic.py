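"""Synthetic IHC slides and patient cohorts with known ground truth.

No real slide images or patient tables ship with the package, so every
downstream module is exercised against simulated data whose truth is known
by construction:

* ``simulate_slide`` renders a brightfield H-DAB image from an inhomogeneous
  hard-core point process. Hot-spot disks raise both the local nucleus
  density and the Ki67-positive fraction; each nucleus is forward-synthesized
  through the same Beer-Lambert stain basis the analyzer inverts, so the
  analysis pipeline can be validated end to end against the generating truth.
* ``truth_indices`` applies the tiling/scoring definitions directly to the
  true nucleus table, bypassing imaging — the oracle for recovery tests.
* ``simulate_cohort`` draws clinico-pathological records whose qualitative
  correlation structure matches hormone receptor-positive, HER2-negative
  early breast cancer: Ki67 rises with grade and mitotic score, falls with
  ER/PgR Allred scores, and the Recurrence Score is driven chiefly by Ki67.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from skimage.draw import ellipse as draw_ellipse

from .errors import ConfigurationError, GenerationError
from .imaging import NucleusDetection, SlideImage, StainBasis
from .tiling import SlideScore, score_detections

__all__ = [
    "HotSpot",
    "SlideSpec",
    "CohortSpec",
    "simulate_slide",
    "truth_indices",
    "simulate_cohort",
    "COHORT_PREDICTORS",
]


@dataclass(frozen=True)
class HotSpot:
    """A disk of elevated proliferation: density multiplier + positivity p_hot."""

    center_x_um: float
    center_y_um: float
    radius_um: float
    density_multiplier: float = 6.0
    p_positive: float = 0.85


@dataclass(frozen=True)
class SlideSpec:
    """Generative parameters for one synthetic slide.

    Defaults describe a 3x3 mm tumor region at 1 um/px with two hot spots
    whose disks fully cover one 500x500 um tile each (so at least two tiles
    clear the 500-cell hot-spot criterion), a background proliferative
    fraction of 12%, and nucleus geometry/density consistent with moderately
    cellular breast carcinoma after hard-core thinning.
    """

    width_um: float = 3000.0
    height_um: float = 3000.0
    mpp: float = 1.0
    base_density_per_mm2: float = 550.0
    hotspots: tuple[HotSpot, ...] = (
        HotSpot(750.0, 750.0, 400.0, density_multiplier=6.0, p_positive=0.85),
        HotSpot(2250.0, 1750.0, 400.0, density_multiplier=6.0, p_positive=0.55),
    )
    p_base_positive: float = 0.12
    nucleus_radius_px: tuple[float, float] = (2.4, 3.2)
    # stain OD (concentration) levels per class
    negative_hema_od: float = 0.80
    negative_dab_od: float = 0.03
    positive_hema_od: float = 0.25
    positive_dab_od: float = 0.90
    noise_sd: float = 2.5  # additive intensity noise, 8-bit units
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_base_positive <= 1):
            raise ConfigurationError("p_base_positive must lie in [0, 1]")
        for h in self.hotspots:
            if not (0 <= h.p_positive <= 1):
                raise ConfigurationError("hot-spot positivity must lie in [0, 1]")
            if not (h.radius_um <= h.center_x_um <= self.width_um - h.radius_um
                    and h.radius_um <= h.center_y_um <= self.height_um - h.radius_um):
                raise ConfigurationError("hot spot must lie inside the canvas")
        # density 0 is allowed (blank slide, useful as a degenerate fixture)
        if self.base_density_per_mm2 < 0 or self.mpp <= 0:
            raise ConfigurationError("density must be >= 0 and mpp positive")
        if self.nucleus_radius_px[0] <= 0 or self.nucleus_radius_px[0] > self.nucleus_radius_px[1]:
            raise ConfigurationError("nucleus radius range must be positive and ordered")


def _min_separation_px(spec: SlideSpec) -> float:
    # 1.5x the max nucleus *diameter*: rendered nuclei can never touch,
    # making the detection-count oracle exact.
    return 3.0 * spec.nucleus_radius_px[1]


def _hard_core_thin(points: np.ndarray, min_sep: float, rng: np.random.Generator) -> np.ndarray:
    """Sequential hard-core thinning on a spatial hash grid (O(n))."""
    if len(points) == 0:
        return points
    order = rng.permutation(len(points))
    cell = min_sep
    grid: dict[tuple[int, int], list[int]] = {}
    kept: list[int] = []
    min_sep2 = min_sep * min_sep
    for idx in order:
        x, y = points[idx]
        cx, cy = int(x // cell), int(y // cell)
        ok = True
        for gx in range(cx - 1, cx + 2):
            for gy in range(cy - 1, cy + 2):
                for j in grid.get((gx, gy), ()):
                    dx = x - points[j][0]
                    dy = y - points[j][1]
                    if dx * dx + dy * dy < min_sep2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            kept.append(idx)
            grid.setdefault((cx, cy), []).append(idx)
    return points[np.sort(np.array(kept, dtype=int))]


def _sample_centers(spec: SlideSpec, rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson draw (base + hot-spot surplus) with hard-core thinning."""
    min_sep = _min_separation_px(spec) * spec.mpp  # um
    peak_density = spec.base_density_per_mm2 * max(
        [h.density_multiplier for h in spec.hotspots], default=1.0
    )
    # Random sequential adsorption jams near 0.547 / d^2; refuse clearly
    # infeasible requests instead of silently under-delivering.
    saturation = 0.547 / (min_sep / 1000.0) ** 2
    if peak_density > saturation:
        raise GenerationError(
            f"requested density {peak_density:.0f}/mm2 exceeds the hard-core "
            f"packing limit ~{saturation:.0f}/mm2 at min separation {min_sep:.1f} um"
        )
    area_mm2 = spec.width_um * spec.height_um / 1e6
    n_base = rng.poisson(spec.base_density_per_mm2 * area_mm2)
    pts = [rng.uniform([0, 0], [spec.width_um, spec.height_um], size=(n_base, 2))]
    for h in spec.hotspots:
        extra = (h.density_multiplier - 1.0) * spec.base_density_per_mm2
        n_hot = rng.poisson(max(extra, 0.0) * np.pi * (h.radius_um / 1000.0) ** 2)
        r = h.radius_um * np.sqrt(rng.uniform(size=n_hot))
        theta = rng.uniform(0, 2 * np.pi, size=n_hot)
        pts.append(np.column_stack([
            h.center_x_um + r * np.cos(theta),
            h.center_y_um + r * np.sin(theta),
        ]))
    points_um = np.concatenate(pts, axis=0)
    points_px = points_um / spec.mpp
    return _hard_core_thin(points_px, _min_separation_px(spec), rng)


def simulate_slide(
    spec: SlideSpec | None = None,
    basis: StainBasis | None = None,
) -> tuple[SlideImage, pd.DataFrame, shapely.Polygon]:
    """Render a synthetic H-DAB slide with its ground-truth nucleus table.

    Returns ``(image, truth, region)`` where ``truth`` has columns
    x_px, y_px, radius_px, in_hotspot, label; the region annotation is the
    full canvas rectangle. Deterministic for a fixed spec (seed included).
    """
    spec = spec or SlideSpec()
    basis = basis or StainBasis.hdab_default()
    rng = np.random.default_rng(spec.seed)
    W = round(spec.width_um / spec.mpp)
    H = round(spec.height_um / spec.mpp)

    centers = _sample_centers(spec, rng)
    # Bernoulli labels: p_hot inside any hot-spot disk, else the base rate
    x_um = centers[:, 0] * spec.mpp
    y_um = centers[:, 1] * spec.mpp
    p = np.full(len(centers), spec.p_base_positive)
    in_hot = np.zeros(len(centers), dtype=bool)
    for h in spec.hotspots:
        d2 = (x_um - h.center_x_um) ** 2 + (y_um - h.center_y_um) ** 2
        inside = d2 <= h.radius_um**2
        p[inside] = h.p_positive
        in_hot |= inside
    positive = rng.uniform(size=len(centers)) < p

    r_lo, r_hi = spec.nucleus_radius_px
    radii = rng.uniform(r_lo, r_hi, size=len(centers))
    eccen = rng.uniform(0.7, 1.0, size=len(centers))
    angles = rng.uniform(0, np.pi, size=len(centers))

    hema = np.zeros((H, W), dtype=np.float32)
    dab = np.zeros((H, W), dtype=np.float32)
    jitter = rng.normal(1.0, 0.05, size=len(centers)).clip(0.8, 1.2)
    for i in range(len(centers)):
        rr, cc = draw_ellipse(
            centers[i, 1], centers[i, 0],
            radii[i], radii[i] * eccen[i],
            shape=(H, W), rotation=angles[i],
        )
        if positive[i]:
            hema[rr, cc] = spec.positive_hema_od * jitter[i]
            dab[rr, cc] = spec.positive_dab_od * jitter[i]
        else:
            hema[rr, cc] = spec.negative_hema_od * jitter[i]
            dab[rr, cc] = spec.negative_dab_od * jitter[i]

    m = basis.matrix.astype(np.float32)
    od = hema[..., None] * m[0] + dab[..., None] * m[1]
    intensity = 255.0 * np.power(10.0, -od)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=intensity.shape)
    pixels = np.clip(np.rint(intensity), 0, 255).astype(np.uint8)

    truth = pd.DataFrame({
        "x_px": centers[:, 0],
        "y_px": centers[:, 1],
        "radius_px": radii,
        "in_hotspot": in_hot,
        "label": np.where(positive, "positive", "negative"),
    })
    region = shapely.box(0.0, 0.0, float(W), float(H))
    return SlideImage(pixels=pixels, mpp=spec.mpp), truth, region


def truth_indices(
    truth: pd.DataFrame,
    region: shapely.Polygon,
    mpp: float,
    *,
    tile_size_um: float = 500.0,
    min_cells: int = 500,
    top_k: int = 5,
) -> SlideScore:
    """Score the TRUE nucleus table with the exact tiling/index definitions.

    Bypasses the imaging pipeline entirely; used as the oracle in
    end-to-end recovery tests.
    """
    detections = [
        NucleusDetection(
            centroid_x=float(r.x_px), centroid_y=float(r.y_px),
            area_px2=0.0, mean_dab_od=0.0, mean_hema_od=0.0,
            label=str(r.label),
        )
        for r in truth.itertuples()
    ]
    return score_detections(
        detections, region, mpp,
        tile_size_um=tile_size_um, min_cells=min_cells, top_k=top_k,
    )


# ---------------------------------------------------------------------------
# Cohorts

#: Default 13-variable chart predictor set (the RT-PCR odx_* columns extend
#: it to 16 when requested).
COHORT_PREDICTORS = [
    "age",
    "tumor_size_mm",
    "grade",
    "nuclear_grade",
    "differentiation",
    "mitotic_score",
    "er_intensity",
    "er_allred",
    "pgr_intensity",
    "pgr_allred",
    "ki67",
    "lvi",
    "nodes_positive",
]
ODX_PREDICTORS = ["odx_er", "odx_pgr", "odx_her2"]


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for a synthetic patient cohort.

    The default coefficient vector gives Ki67 the dominant weight in the
    Recurrence Score, with smaller contributions from grade, mitotic score
    and (negatively) the hormone-receptor Allred scores; marginals roughly
    follow the frequencies typical of a hormone receptor-positive,
    HER2-negative early-stage cohort, targeting a risk-group split near
    62/28/10 (low/intermediate/high).
    """

    n: int = 328
    rs_intercept: float = 6.0
    coefficients: dict[str, float] = field(default_factory=lambda: {
        "ki67": 0.9,
        "grade": 1.2,
        "mitotic_score": 1.5,
        "er_allred": -0.8,
        "pgr_allred": -0.5,
    })
    noise_sd: float = 5.0
    single_signal: bool = False  # rs driven by Ki67 alone (harness validation)
    include_odx: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("cohort size must be >= 1")
        unknown = set(self.coefficients) - set(COHORT_PREDICTORS) - set(ODX_PREDICTORS)
        if unknown:
            raise ConfigurationError(f"coefficients reference unknown predictors: {sorted(unknown)}")


def _ordinal(rng, n, levels, probs):
    return rng.choice(levels, size=n, p=probs)


def simulate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Draw a cohort with the qualitative structure of HR+/HER2- breast cancer.

    Ki67 is lognormal with a location shifted up by grade and mitotic score
    and down by ER/PgR Allred scores; rs is the configured linear combination
    plus Gaussian noise, truncated to [0, 100]. In ``single_signal`` mode the
    score depends on Ki67 alone (rs = 5 + 0.8*ki67 + small noise), giving a
    known-answer benchmark for the cross-validation harness.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    grade = _ordinal(rng, n, [1, 2, 3], [0.21, 0.63, 0.16])
    mitotic = np.clip(grade + rng.choice([-1, 0, 0, 1], size=n), 1, 3)
    df = pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "age": np.clip(rng.normal(56, 10, n), 29, 85).round(1),
        "tumor_size_mm": np.clip(rng.lognormal(2.8, 0.45, n), 2.0, 60.0).round(1),
        "grade": grade,
        "nuclear_grade": _ordinal(rng, n, [1, 2, 3], [0.10, 0.56, 0.34]),
        "differentiation": _ordinal(rng, n, [1, 2, 3], [0.10, 0.28, 0.62]),
        "mitotic_score": mitotic,
        "er_intensity": _ordinal(rng, n, [1, 2, 3], [0.03, 0.05, 0.92]),
        "er_allred": _ordinal(rng, n, [4, 5, 6, 7, 8], [0.03, 0.05, 0.10, 0.22, 0.60]),
        "pgr_intensity": _ordinal(rng, n, [1, 2, 3], [0.06, 0.29, 0.65]),
        "pgr_allred": _ordinal(rng, n, [0, 2, 3, 4, 5, 6, 7, 8],
                               [0.06, 0.04, 0.05, 0.07, 0.10, 0.15, 0.23, 0.30]),
        "lvi": rng.choice([0, 1], size=n, p=[0.75, 0.25]),
        "nodes_positive": rng.poisson(0.6, n),
    })
    # Ki67 rises with grade and mitotic score, falls with ER/PgR Allred.
    mu = (
        np.log(11.0)
        + 0.40 * (df["grade"] - 2)
        + 0.50 * (df["mitotic_score"] - 2)
        - 0.12 * (df["er_allred"] - 7)
        - 0.06 * (df["pgr_allred"] - 6)
    )
    df["ki67"] = np.clip(rng.lognormal(mu, 0.35), 0.3, 95.0).round(2)

    if spec.single_signal:
        rs = 5.0 + 0.8 * df["ki67"] + rng.normal(0, 1.5, n)
    else:
        rs = spec.rs_intercept + rng.normal(0, spec.noise_sd, n)
        centering = {"grade": 2, "mitotic_score": 2, "er_allred": 7, "pgr_allred": 6}
        for name, coef in spec.coefficients.items():
            rs = rs + coef * (df[name] - centering.get(name, 0))
    df["rs"] = np.clip(rs, 0.0, 100.0).round(1)

    if spec.include_odx:
        # RT-PCR expression scores: ER/PgR track their Allred scores, HER2 is
        # uninformative in a HER2-negative cohort.
        df["odx_er"] = (6.0 + 0.45 * df["er_allred"] + rng.normal(0, 0.5, n)).round(2)
        df["odx_pgr"] = (4.5 + 0.50 * df["pgr_allred"] + rng.normal(0, 0.7, n)).round(2)
        df["odx_her2"] = rng.normal(9.0, 0.5, n).round(2)
    return df
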