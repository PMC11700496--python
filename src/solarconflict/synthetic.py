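"""Synthetic landscapes with the statistical structure the analysis assumes.

Generates, from a single seeded configuration: spatially autocorrelated
standardised environmental surfaces with a controllable pairwise
correlation structure (smoothed Gaussian fields mixed through a Cholesky
factor), a global-horizontal-irradiance surface, a long-right-tailed slope
surface, a categorical land-cover mosaic with prescribed class
proportions, random substation and photovoltaic-facility points,
non-overlapping rectangular protected areas, a rectangular species range,
and a virtual species whose true suitability is a logistic function of the
environmental surfaces — deliberately a different functional family from
the Gibbs estimator, so recovery tests are not circular — with occurrence
points sampled proportionally to that suitability.

Scene generation is a pure function of the configuration (seed included).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit
from shapely.geometry import box

from .raster_core import (
    BinaryMask,
    CategoricalRaster,
    GridSpec,
    PointSet,
    PolygonSet,
    Raster,
    polygon_mask,
    read_ascii_grid,
    read_points_csv,
    read_points_geojson,
    read_polygons_geojson,
    write_ascii_grid,
    write_points_csv,
    write_points_geojson,
    write_polygons_geojson,
)
from .sdm import OccurrenceSet

DEFAULT_LANDCOVER_PROPORTIONS = {
    "shrubland": 0.30,
    "grassland": 0.20,
    "barren land": 0.12,
    "cropland": 0.12,
    "urban/built-up": 0.08,
    "forest": 0.10,
    "wetland": 0.04,
    "open water": 0.03,
    "snow/ice": 0.01,
}

#: linear then quadratic coefficients per environmental variable; the
#: negative quadratics give each variable a unimodal niche response, so
#: suitable habitat is rare (mean suitability ~0.1) as for habitat
#: specialists — a strong, recoverable signal
DEFAULT_TRUE_BETAS = (2.0, -1.5, 1.0, 0.0, -2.0, -1.5, -1.0, -0.8)


@dataclass
class SceneConfig:
    """Everything that determines a scene, seed included."""

    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 1000.0  # metres
    seed: int = 0
    n_env_vars: int = 4
    smoothing_length: float = 5.0  # cells
    env_correlation: list | None = None  # None -> identity
    landcover_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LANDCOVER_PROPORTIONS)
    )
    n_substations: int = 15
    n_facilities: int = 25
    protected_fraction: float = 0.10
    true_betas: tuple[float, ...] = DEFAULT_TRUE_BETAS
    n_presences: int = 500
    duplicate_fraction: float = 0.10
    range_area_bounds: tuple[float, float] = (0.4, 0.8)

    def __post_init__(self) -> None:
        total = sum(self.landcover_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"land-cover proportions sum to {total}, not 1")
        if not 0 <= self.protected_fraction < 1:
            raise ValueError("protected_fraction must be in [0, 1)")
        if len(self.true_betas) != 2 * self.n_env_vars:
            raise ValueError(
                "true_betas must have one linear and one quadratic "
                f"coefficient per variable ({2 * self.n_env_vars} values)"
            )
        if self.env_correlation is not None:
            c = np.asarray(self.env_correlation, dtype=float)
            if c.shape != (self.n_env_vars, self.n_env_vars) or not np.allclose(c, c.T):
                raise ValueError("env_correlation must be a symmetric k x k matrix")
            if np.linalg.eigvalsh(c).min() < -1e-9:
                raise ValueError("env_correlation must be positive semi-definite")

    def grid_spec(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols, self.cell_size, crs_label="synthetic-metres")

    def correlation_matrix(self) -> np.ndarray:
        if self.env_correlation is None:
            return np.eye(self.n_env_vars)
        return np.asarray(self.env_correlation, dtype=float)


@dataclass
class Scene:
    spec: GridSpec
    ghi: Raster
    slope: Raster
    env: dict[str, Raster]
    landcover: CategoricalRaster
    substations: PointSet
    facilities: PointSet
    protected: PolygonSet
    range_polys: PolygonSet
    true_suitability: Raster
    occurrences: OccurrenceSet
    config: SceneConfig


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    f -= f.mean()
    f /= f.std()
    return f


def gen_env_rasters(cfg: SceneConfig) -> dict[str, Raster]:
    """Standardised, spatially autocorrelated, cross-correlated covariates."""
    spec = cfg.grid_spec()
    rng = np.random.default_rng([cfg.seed, 1])
    fields = np.stack(
        [_smooth_field(rng, spec.shape, cfg.smoothing_length).ravel()
         for _ in range(cfg.n_env_vars)]
    )
    corr = cfg.correlation_matrix()
    # empirically whiten the smoothed fields, then colour by the Cholesky
    # factor: the SAMPLE correlation matrix equals the target exactly
    # (small jitter keeps Cholesky defined for rank-deficient rho=1 targets)
    jitter = 1e-10 * np.eye(cfg.n_env_vars)
    sample_cov = fields @ fields.T / fields.shape[1]
    white = np.linalg.solve(np.linalg.cholesky(sample_cov + jitter), fields)
    mixed = np.linalg.cholesky(corr + jitter) @ white
    mixed -= mixed.mean(axis=1, keepdims=True)
    mixed /= mixed.std(axis=1, keepdims=True)
    return {
        f"env{i + 1}": Raster(spec, mixed[i].reshape(spec.shape))
        for i in range(cfg.n_env_vars)
    }


def gen_ghi(cfg: SceneConfig) -> Raster:
    """Irradiance surface in kWh/m^2/day, smooth with a broad gradient."""
    spec = cfg.grid_spec()
    rng = np.random.default_rng([cfg.seed, 2])
    f = _smooth_field(rng, spec.shape, cfg.smoothing_length)
    return Raster(spec, 5.75 + 0.5 * f)


def gen_structural_layers(
    cfg: SceneConfig,
) -> tuple[Raster, CategoricalRaster, PointSet, PointSet, PolygonSet, PolygonSet]:
    """Slope, land cover, substations, facilities, protected areas, range."""
    spec = cfg.grid_spec()
    xmin, ymin, xmax, ymax = spec.extent
    w, h = xmax - xmin, ymax - ymin

    # slope: half-normal of a smoothed field, scaled so both sides of the
    # 5-degree rule occur (sd 4 degrees -> ~21% of cells exceed 5)
    rng = np.random.default_rng([cfg.seed, 3])
    slope = Raster(spec, 4.0 * np.abs(_smooth_field(rng, spec.shape, cfg.smoothing_length)))

    # land cover: quantile-sliced smoothed field matching class proportions
    rng = np.random.default_rng([cfg.seed, 4])
    f = _smooth_field(rng, spec.shape, cfg.smoothing_length)
    names = list(cfg.landcover_proportions)
    cum = np.cumsum([cfg.landcover_proportions[n] for n in names])
    cuts = np.quantile(f, cum[:-1])
    codes = np.digitize(f, cuts) + 1  # codes 1..K
    legend = {i + 1: n for i, n in enumerate(names)}
    landcover = CategoricalRaster(spec, codes.astype(float), legend)

    rng = np.random.default_rng([cfg.seed, 5])
    substations = PointSet(
        np.column_stack(
            [xmin + rng.random(cfg.n_substations) * w, ymin + rng.random(cfg.n_substations) * h]
        )
    )
    facilities = PointSet(
        np.column_stack(
            [xmin + rng.random(cfg.n_facilities) * w, ymin + rng.random(cfg.n_facilities) * h]
        )
    )

    # protected areas: non-overlapping random rectangles up to the target cover
    rng = np.random.default_rng([cfg.seed, 6])
    rects = []
    covered = 0.0
    target = cfg.protected_fraction * w * h
    attempts = 0
    while covered < target and attempts < 500:
        attempts += 1
        rw, rh = (0.05 + 0.15 * rng.random(2)) * (w, h)
        x0 = xmin + rng.random() * (w - rw)
        y0 = ymin + rng.random() * (h - rh)
        cand = box(x0, y0, x0 + rw, y0 + rh)
        if any(cand.intersects(r) for r in rects):
            continue
        rects.append(cand)
        covered += cand.area
    protected = PolygonSet(rects)

    # species range: one rectangle covering a random 40-80% of the extent
    rng = np.random.default_rng([cfg.seed, 7])
    lo, hi = cfg.range_area_bounds
    area_frac = lo + (hi - lo) * rng.random()
    aspect = 0.8 + 0.45 * rng.random()
    wf = min(1.0, np.sqrt(area_frac * aspect))
    hf = min(1.0, area_frac / wf)
    x0 = xmin + rng.random() * (w - wf * w)
    y0 = ymin + rng.random() * (h - hf * h)
    range_polys = PolygonSet([box(x0, y0, x0 + wf * w, y0 + hf * h)])

    return slope, landcover, substations, facilities, protected, range_polys


def gen_virtual_species(
    cfg: SceneConfig,
    env: dict[str, Raster],
    range_polys: PolygonSet | None = None,
) -> tuple[Raster, OccurrenceSet]:
    """Ground-truth suitability plus occurrences sampled from it.

    True suitability is logistic(beta . [z, z^2]) over the standardised
    covariates. Occurrence cells are drawn without replacement with
    probability proportional to suitability inside the range; each point is
    jittered uniformly within its cell and a fraction of points is
    duplicated exactly to exercise downstream de-duplication.
    """
    spec = next(iter(env.values())).spec
    k = cfg.n_env_vars
    betas = np.asarray(cfg.true_betas, dtype=float)
    eta = np.zeros(spec.shape)
    for i, name in enumerate(sorted(env, key=lambda s: int(s.removeprefix("env")))):
        z = env[name].values
        eta += betas[i] * z + betas[k + i] * z**2
    true_suit = Raster(spec, expit(eta))

    candidate = np.isfinite(true_suit.values)
    if range_polys is not None and len(range_polys):
        candidate &= polygon_mask(range_polys, spec).one_set()
    flat = np.flatnonzero(candidate.ravel())
    if cfg.n_presences > flat.size:
        raise ValueError(
            f"n_presences={cfg.n_presences} exceeds {flat.size} candidate cells"
        )
    weights = true_suit.values.ravel()[flat]
    rng = np.random.default_rng([cfg.seed, 8])
    picks = rng.choice(flat, size=cfg.n_presences, replace=False, p=weights / weights.sum())
    rows, cols = np.divmod(picks, spec.n_cols)
    cs = spec.cell_size
    xs = spec.origin_x + (cols + rng.random(len(picks))) * cs
    ys = spec.origin_y - (rows + rng.random(len(picks))) * cs
    coords = np.column_stack([xs, ys])
    n_dup = int(np.floor(cfg.duplicate_fraction * len(coords)))
    if n_dup:
        coords = np.vstack([coords, coords[rng.choice(len(coords), n_dup, replace=False)]])
    occ = OccurrenceSet(PointSet(coords), species="virtual_species", range_class="resident")
    return true_suit, occ


def generate_scene(cfg: SceneConfig | None = None) -> Scene:
    """Full scene from one configuration; pure function of the config."""
    cfg = cfg or SceneConfig()
    env = gen_env_rasters(cfg)
    ghi = gen_ghi(cfg)
    slope, landcover, substations, facilities, protected, range_polys = gen_structural_layers(cfg)
    true_suit, occurrences = gen_virtual_species(cfg, env, range_polys)
    return Scene(
        spec=cfg.grid_spec(),
        ghi=ghi,
        slope=slope,
        env=env,
        landcover=landcover,
        substations=substations,
        facilities=facilities,
        protected=protected,
        range_polys=range_polys,
        true_suitability=true_suit,
        occurrences=occurrences,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Scene persistence
# ---------------------------------------------------------------------------


def write_scene(scene: Scene, directory: str | Path) -> dict:
    """Write every layer plus a manifest; returns the manifest dict."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(scene.ghi, d / "ghi.asc")
    write_ascii_grid(scene.slope, d / "slope.asc")
    write_ascii_grid(scene.landcover, d / "landcover.asc")
    write_ascii_grid(scene.true_suitability, d / "true_suitability.asc")
    for name, r in scene.env.items():
        write_ascii_grid(r, d / f"{name}.asc")
    write_points_geojson(scene.substations, d / "substations.geojson")
    write_points_geojson(scene.facilities, d / "facilities.geojson")
    write_polygons_geojson(scene.protected, d / "protected.geojson")
    write_polygons_geojson(scene.range_polys, d / "range.geojson")
    write_points_csv(scene.occurrences.points, d / "occurrences.csv")
    cfg = asdict(scene.config)
    cfg["true_betas"] = list(cfg["true_betas"])
    cfg["range_area_bounds"] = list(cfg["range_area_bounds"])
    manifest = {
        "config": cfg,
        "seed": scene.config.seed,
        "legend": {str(k): v for k, v in scene.landcover.legend.items()},
        "species": scene.occurrences.species,
        "range_class": scene.occurrences.range_class,
        "env_vars": sorted(scene.env, key=lambda s: int(s.removeprefix("env"))),
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def read_scene(directory: str | Path) -> Scene:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    cfg_d = dict(manifest["config"])
    cfg_d["true_betas"] = tuple(cfg_d["true_betas"])
    cfg_d["range_area_bounds"] = tuple(cfg_d["range_area_bounds"])
    cfg = SceneConfig(**cfg_d)
    legend = {int(k): v for k, v in manifest["legend"].items()}
    lc = read_ascii_grid(d / "landcover.asc")
    occ_points = read_points_csv(d / "occurrences.csv")
    return Scene(
        spec=cfg.grid_spec(),
        ghi=read_ascii_grid(d / "ghi.asc"),
        slope=read_ascii_grid(d / "slope.asc"),
        env={v: read_ascii_grid(d / f"{v}.asc") for v in manifest["env_vars"]},
        landcover=CategoricalRaster(lc.spec, lc.values, legend),
        substations=read_points_geojson(d / "substations.geojson"),
        facilities=read_points_geojson(d / "facilities.geojson"),
        protected=read_polygons_geojson(d / "protected.geojson"),
        range_polys=read_polygons_geojson(d / "range.geojson"),
        true_suitability=read_ascii_grid(d / "true_suitability.asc"),
        occurrences=OccurrenceSet(
            occ_points, species=manifest["species"], range_class=manifest["range_class"]
        ),
        config=cfg,
    )


def regenerate_from_manifest(manifest_path: str | Path) -> Scene:
    manifest = json.loads(Path(manifest_path).read_text())
    cfg_d = dict(manifest["config"])
    cfg_d["true_betas"] = tuple(cfg_d["true_betas"])
    cfg_d["range_area_bounds"] = tuple(cfg_d["range_area_bounds"])
    return generate_scene(SceneConfig(**cfg_d))
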