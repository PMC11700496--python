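"""Presence-background species distribution modelling (Maxent).

The model is the maximum-entropy (Gibbs) distribution over the landscape:
with feature vector f(x) and coefficients lambda, the density over the
background sample is q(x) = exp(lambda . f(x)) / Z, fitted by minimising
the L1-penalised convex objective

    F(lambda) = -mean_presence(lambda . f)
                + log sum_background exp(lambda . f)
                + sum_j beta_j |lambda_j|,

with per-feature penalty beta_j = reg_scale * sd_j(background) / sqrt(m)
(m presences). At the optimum every feature satisfies the L1 box (KKT)
condition |empirical presence mean - model expectation| <= beta_j. The
reported suitability is the cloglog transform 1 - exp(-exp(H) q(x)), with
H the entropy of the fitted background density.

Also provided: occurrence cleaning with one-per-cell thinning, uniform
background sampling, train/test splitting, permutation importance, the
contribution-ordered Spearman collinearity filter (|rho| <= 0.7 by
default), Mann-Whitney AUC, the max(sensitivity + specificity) threshold,
TSS, and binarisation clipped to range polygons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp, softmax
from scipy.stats import spearmanr

from .raster_core import BinaryMask, GridSpec, PointSet, PolygonSet, Raster, polygon_mask

DEFAULT_FEATURE_CLASSES = ("linear", "quadratic", "hinge")
DEFAULT_N_HINGE_KNOTS = 10


class MaxentConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Occurrence handling
# ---------------------------------------------------------------------------


@dataclass
class OccurrenceSet:
    """Cleaned species occurrences: at most one point per grid cell."""

    points: PointSet
    species: str = "species"
    range_class: str = "unspecified"  # resident | breeding | unspecified

    def __len__(self) -> int:
        return len(self.points)


def clean_occurrences(
    raw: PointSet,
    spec: GridSpec,
    valid_region: PolygonSet | None = None,
    seed: int = 0,
    species: str = "species",
    range_class: str = "unspecified",
) -> OccurrenceSet:
    """Clean raw occurrence records and thin to one point per grid cell.

    Drops non-finite and out-of-extent coordinates, exact duplicates, and
    points outside ``valid_region`` (if given); then keeps exactly one
    uniformly random point per occupied cell (seeded).
    """
    coords = np.asarray(raw.coords, dtype=float).reshape(-1, 2)
    coords = coords[np.isfinite(coords).all(axis=1)]
    if len(coords):
        row, col = spec.point_to_cell(coords[:, 0], coords[:, 1])
        keep = row >= 0
        coords, row, col = coords[keep], row[keep], col[keep]
    if len(coords):
        coords, idx = np.unique(coords, axis=0, return_index=True)
        order = np.argsort(idx)  # keep deterministic but original-order stable
        coords = coords[order]
        row, col = spec.point_to_cell(coords[:, 0], coords[:, 1])
    if valid_region is not None and len(valid_region) and len(coords):
        import shapely

        union = shapely.unary_union(valid_region.polygons)
        shapely.prepare(union)
        inside = shapely.contains_xy(union, coords[:, 0], coords[:, 1])
        coords, row, col = coords[inside], row[inside], col[inside]
    if len(coords) == 0:
        raise ValueError("no occurrence records survived cleaning")
    rng = np.random.default_rng(seed)
    cell_id = row * spec.n_cols + col
    kept_rows = []
    for cid in np.unique(cell_id):
        members = np.flatnonzero(cell_id == cid)
        kept_rows.append(members[rng.integers(len(members))] if len(members) > 1 else members[0])
    coords = coords[np.sort(kept_rows)]
    return OccurrenceSet(PointSet(coords), species=species, range_class=range_class)


def sample_background(
    spec: GridSpec,
    n: int = 10_000,
    valid_region: PolygonSet | None = None,
    seed: int = 0,
    valid_mask: BinaryMask | None = None,
) -> PointSet:
    """Sample n cell centers uniformly with replacement from valid cells.

    Valid cells are covariate-complete (``valid_mask`` equal to 1, when
    given) and, when ``valid_region`` is given, have their center inside it.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ok = np.ones(spec.shape, dtype=bool)
    if valid_mask is not None:
        ok &= valid_mask.one_set()
    if valid_region is not None and len(valid_region):
        ok &= polygon_mask(valid_region, spec).one_set()
    flat = np.flatnonzero(ok.ravel())
    if flat.size == 0:
        raise ValueError("no valid cells to sample background from")
    rng = np.random.default_rng(seed)
    picks = rng.choice(flat, size=n, replace=True)
    cx, cy = spec.cell_centers()
    return PointSet(np.column_stack([cx.ravel()[picks], cy.ravel()[picks]]))


def split_train_test(
    occ: OccurrenceSet, test_fraction: float = 0.2, seed: int = 0
) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Disjoint, exhaustive seeded split; test size round-half-away, min 1."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(occ)
    if n < 2:
        raise ValueError("need at least 2 occurrences to split")
    n_test = max(1, int(np.floor(n * test_fraction + 0.5)))
    n_test = min(n_test, n - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    test_idx, train_idx = np.sort(order[:n_test]), np.sort(order[n_test:])
    mk = lambda idx: OccurrenceSet(
        PointSet(occ.points.coords[idx]), occ.species, occ.range_class
    )
    return mk(train_idx), mk(test_idx)


# ---------------------------------------------------------------------------
# Feature construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureSpec:
    """One feature column: class, underlying variable(s), knot for hinges.

    ``mean``/``sd`` are the background standardisation of the underlying
    variable (first variable for products); hinges act on the raw scale
    with ``lo``/``hi`` the background min/max.
    """

    name: str
    kind: str  # linear | quadratic | product | hinge
    variables: tuple[str, ...]
    mean: float = 0.0
    sd: float = 1.0
    mean2: float = 0.0
    sd2: float = 1.0
    knot: float | None = None
    reverse: bool = False
    lo: float = 0.0
    hi: float = 1.0


class FeatureBuilder:
    """Maps a table of raw covariates to the model's feature matrix.

    Standardisation statistics and hinge knots are frozen from the
    background sample at construction.
    """

    def __init__(self, specs: list[FeatureSpec], variables: list[str]):
        self.specs = specs
        self.variables = variables

    @classmethod
    def from_background(
        cls,
        background: pd.DataFrame,
        classes: Iterable[str] = DEFAULT_FEATURE_CLASSES,
        n_hinge_knots: int = DEFAULT_N_HINGE_KNOTS,
    ) -> "FeatureBuilder":
        classes = set(classes)
        unknown = classes - {"linear", "quadratic", "product", "hinge"}
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
        variables = []
        stats: dict[str, tuple[float, float, float, float]] = {}
        for var in background.columns:
            x = background[var].to_numpy(dtype=float)
            mu, sd = float(np.mean(x)), float(np.std(x))
            if sd == 0:
                warnings.warn(f"dropping zero-variance variable {var!r}", stacklevel=3)
                continue
            variables.append(var)
            stats[var] = (mu, sd, float(np.min(x)), float(np.max(x)))
        specs: list[FeatureSpec] = []
        for var in variables:
            mu, sd, lo, hi = stats[var]
            if "linear" in classes:
                specs.append(FeatureSpec(f"{var}", "linear", (var,), mean=mu, sd=sd))
            if "quadratic" in classes:
                specs.append(FeatureSpec(f"{var}^2", "quadratic", (var,), mean=mu, sd=sd))
            if "hinge" in classes and hi > lo:
                qs = np.linspace(0.0, 1.0, n_hinge_knots + 2)[1:-1]
                knots = np.quantile(background[var].to_numpy(dtype=float), qs)
                for k in knots:
                    if hi > k:
                        specs.append(
                            FeatureSpec(
                                f"hinge({var},{k:.6g})", "hinge", (var,),
                                knot=float(k), lo=lo, hi=hi,
                            )
                        )
                    if k > lo:
                        specs.append(
                            FeatureSpec(
                                f"hinge_rev({var},{k:.6g})", "hinge", (var,),
                                knot=float(k), reverse=True, lo=lo, hi=hi,
                            )
                        )
        if "product" in classes:
            for i, v1 in enumerate(variables):
                for v2 in variables[i + 1 :]:
                    m1, s1, _, _ = stats[v1]
                    m2, s2, _, _ = stats[v2]
                    specs.append(
                        FeatureSpec(
                            f"{v1}*{v2}", "product", (v1, v2),
                            mean=m1, sd=s1, mean2=m2, sd2=s2,
                        )
                    )
        return cls(specs, variables)

    def transform(self, table: pd.DataFrame | Mapping[str, np.ndarray]) -> np.ndarray:
        if not isinstance(table, pd.DataFrame):
            table = pd.DataFrame(dict(table))
        missing = [v for v in self.variables if v not in table.columns]
        if missing:
            raise KeyError(f"missing covariates: {missing}")
        n = len(table)
        out = np.empty((n, len(self.specs)))
        for j, fs in enumerate(self.specs):
            x = table[fs.variables[0]].to_numpy(dtype=float)
            if fs.kind == "linear":
                out[:, j] = (x - fs.mean) / fs.sd
            elif fs.kind == "quadratic":
                out[:, j] = ((x - fs.mean) / fs.sd) ** 2
            elif fs.kind == "product":
                y = table[fs.variables[1]].to_numpy(dtype=float)
                out[:, j] = (x - fs.mean) / fs.sd * (y - fs.mean2) / fs.sd2
            else:  # hinge
                if fs.reverse:
                    out[:, j] = np.clip((fs.knot - x) / (fs.knot - fs.lo), 0.0, None)
                else:
                    out[:, j] = np.clip((x - fs.knot) / (fs.hi - fs.knot), 0.0, None)
        return out


def build_features(
    values: pd.DataFrame,
    classes: Iterable[str] = DEFAULT_FEATURE_CLASSES,
    n_hinge_knots: int = DEFAULT_N_HINGE_KNOTS,
) -> tuple[np.ndarray, FeatureBuilder]:
    """Build the feature matrix for ``values``, standardised on ``values``.

    Returns the matrix and the fitted :class:`FeatureBuilder` (reusable on
    presence points and prediction grids).
    """
    builder = FeatureBuilder.from_background(values, classes, n_hinge_knots)
    return builder.transform(values), builder


# ---------------------------------------------------------------------------
# Gibbs (Maxent) fitting
# ---------------------------------------------------------------------------


@dataclass
class MaxentModel:
    """Fitted L1-regularised Gibbs distribution over the background sample."""

    builder: FeatureBuilder
    lam: np.ndarray
    log_partition: float
    entropy_H: float
    reg_beta: np.ndarray
    seed: int = 0

    @property
    def variables(self) -> list[str]:
        return self.builder.variables

    def background_density(self, background_features: np.ndarray) -> np.ndarray:
        eta = background_features @ self.lam
        return np.exp(eta - logsumexp(eta))


def fit_maxent(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    reg_scale: float = 1.0,
    seed: int = 0,
    builder: FeatureBuilder | None = None,
    tol: float = 1e-6,
    max_iter: int = 20_000,
) -> MaxentModel:
    """Minimise the L1-penalised Gibbs objective by FISTA proximal gradient.

    Convergence is declared when the KKT residual (subgradient optimality
    violation) falls below ``tol``; non-convergence raises, reporting the
    final residual.
    """
    Fp = np.atleast_2d(np.asarray(presence_features, dtype=float))
    Fb = np.atleast_2d(np.asarray(background_features, dtype=float))
    m, n_feat = Fp.shape
    B = Fb.shape[0]
    if m < 1 or B < 2:
        raise ValueError("need >= 1 presence and >= 2 background rows")
    if builder is None:
        builder = FeatureBuilder([], [])

    if n_feat == 0:
        lam = np.zeros(0)
        return MaxentModel(builder, lam, float(np.log(B)), float(np.log(B)),
                           np.zeros(0), seed)

    p_bar = Fp.mean(axis=0)
    beta = reg_scale * Fb.std(axis=0) / np.sqrt(m)

    def grad_smooth(lam: np.ndarray) -> np.ndarray:
        w = softmax(Fb @ lam)
        return -p_bar + Fb.T @ w

    def smooth(lam: np.ndarray) -> float:
        return float(-p_bar @ lam + logsumexp(Fb @ lam))

    def kkt_residual(lam: np.ndarray, g: np.ndarray) -> float:
        r = np.where(
            lam != 0,
            np.abs(g + beta * np.sign(lam)),
            np.maximum(np.abs(g) - beta, 0.0),
        )
        return float(np.max(r))

    # FISTA with monotone backtracking and gradient-based adaptive restart
    lam = np.zeros(n_feat)
    z = lam.copy()
    t = 1.0
    L = 1.0
    for _ in range(max_iter):
        gz = grad_smooth(z)
        fz = smooth(z)
        while True:
            step = 1.0 / L
            cand = np.sign(z - step * gz) * np.maximum(np.abs(z - step * gz) - step * beta, 0.0)
            diff = cand - z
            if smooth(cand) <= fz + gz @ diff + 0.5 * L * diff @ diff + 1e-12:
                break
            L *= 2.0
        lam_new = cand
        if (z - lam_new) @ (lam_new - lam) > 0.0:  # momentum restart
            t = 1.0
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = lam_new + (t - 1.0) / t_new * (lam_new - lam)
        lam, t = lam_new, t_new
        g = grad_smooth(lam)
        if kkt_residual(lam, g) <= tol:
            break
    else:
        raise MaxentConvergenceError(
            f"Maxent fit did not converge in {max_iter} iterations; "
            f"final KKT residual {kkt_residual(lam, grad_smooth(lam)):.3e}"
        )

    eta_b = Fb @ lam
    logZ = float(logsumexp(eta_b))
    q = np.exp(eta_b - logZ)
    entropy = float(-np.sum(q * np.log(np.clip(q, 1e-300, None))))
    return MaxentModel(builder, lam, logZ, entropy, beta, seed)


def predict(model: MaxentModel, rasters: Mapping[str, Raster]) -> Raster:
    """Cloglog habitat suitability surface, 1 - exp(-exp(H) q(x)).

    q is the raw Gibbs density normalised over the background sample; cells
    with any missing covariate are missing in the output.
    """
    missing = [v for v in model.variables if v not in rasters]
    if missing:
        raise KeyError(f"missing covariate layers: {missing}")
    if model.variables:
        spec = rasters[model.variables[0]].spec
        for v in model.variables:
            if rasters[v].spec != spec:
                raise ValueError(f"raster {v!r} is not on the shared grid; align first")
        stack = {v: rasters[v].values.ravel() for v in model.variables}
        complete = np.logical_and.reduce(
            [np.isfinite(stack[v]) for v in model.variables]
        )
        table = pd.DataFrame({v: stack[v][complete] for v in model.variables})
        feats = model.builder.transform(table)
        eta = feats @ model.lam
        out = np.full(spec.n_rows * spec.n_cols, np.nan)
        q = np.exp(eta - model.log_partition)
        out[complete] = 1.0 - np.exp(-np.exp(model.entropy_H) * q)
        return Raster(spec, out.reshape(spec.shape))
    # featureless model: uniform density over the background sample
    spec = next(iter(rasters.values())).spec
    const = 1.0 - np.exp(-1.0)
    return Raster(spec, np.full(spec.shape, const))


def score_at_points(suitability: Raster, points: PointSet) -> np.ndarray:
    """Suitability sampled at the cell containing each point."""
    row, col = suitability.spec.point_to_cell(points.x, points.y)
    out = np.full(len(points), np.nan)
    inside = row >= 0
    out[inside] = suitability.values[row[inside], col[inside]]
    return out


# ---------------------------------------------------------------------------
# Importance, variable selection
# ---------------------------------------------------------------------------


def _auc_from_tables(
    model: MaxentModel, presence_tab: pd.DataFrame, background_tab: pd.DataFrame
) -> float:
    sp = model.builder.transform(presence_tab) @ model.lam
    sb = model.builder.transform(background_tab) @ model.lam
    return auc(sp, sb)


def permutation_importance_tables(
    model: MaxentModel,
    presence_tab: pd.DataFrame,
    background_tab: pd.DataFrame,
    n_reps: int = 5,
    seed: int = 0,
) -> dict[str, float]:
    """Mean training-AUC drop per permuted variable, as percentages.

    Each variable's values are permuted jointly across presence and
    background evaluation points; negative drops are floored at zero and
    the raw drops normalised to sum to 100 when any is positive.
    """
    rng = np.random.default_rng(seed)
    base = _auc_from_tables(model, presence_tab, background_tab)
    m = len(presence_tab)
    combined = pd.concat([presence_tab, background_tab], ignore_index=True)
    drops: dict[str, float] = {}
    for var in model.variables:
        ds = []
        for _ in range(n_reps):
            shuffled = combined.copy()
            shuffled[var] = rng.permutation(shuffled[var].to_numpy())
            ds.append(base - _auc_from_tables(model, shuffled.iloc[:m], shuffled.iloc[m:]))
        drops[var] = max(0.0, float(np.mean(ds)))
    total = sum(drops.values())
    if total > 0:
        return {v: 100.0 * d / total for v, d in drops.items()}
    return {v: 0.0 for v in drops}


def permutation_importance(
    model: MaxentModel,
    presence: OccurrenceSet | PointSet,
    background: PointSet,
    rasters: Mapping[str, Raster],
    n_reps: int = 5,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation importance evaluated at presence and background cells."""
    pts = presence.points if isinstance(presence, OccurrenceSet) else presence
    ptab = extract_covariates(rasters, pts, model.variables)
    btab = extract_covariates(rasters, background, model.variables)
    return permutation_importance_tables(model, ptab, btab, n_reps, seed)


def extract_covariates(
    rasters: Mapping[str, Raster], points: PointSet, variables: Sequence[str] | None = None
) -> pd.DataFrame:
    """Raster values at the cell of each point, as a table (may contain NaN)."""
    variables = list(variables) if variables is not None else list(rasters)
    cols = {}
    for v in variables:
        cols[v] = score_at_points(rasters[v], points)
    return pd.DataFrame(cols)


@dataclass
class SelectionTrace:
    """Outcome of contribution-ordered collinearity pruning."""

    contributions: list[tuple[str, float]]  # rank order used for the scan
    dropped: list[tuple[str, str, float]]  # (kept, dropped, rho)
    retained: list[str] = field(default_factory=list)
    model: MaxentModel | None = None


def select_variables(
    presence_tab: pd.DataFrame,
    background_tab: pd.DataFrame,
    rho_threshold: float = 0.7,
    seed: int = 0,
    classes: Iterable[str] = DEFAULT_FEATURE_CLASSES,
    n_hinge_knots: int = DEFAULT_N_HINGE_KNOTS,
    reg_scale: float = 1.0,
    n_reps: int = 5,
) -> SelectionTrace:
    """Drop collinear variables, keeping the higher-contribution member.

    A full model is fitted, variables are ranked by permutation importance
    (ties broken alphabetically) and scanned in rank order: a variable is
    dropped iff its Spearman |rho| with any already-retained variable
    exceeds ``rho_threshold`` (rho on background covariate values). The
    model is refitted on the retained set.
    """
    builder = FeatureBuilder.from_background(background_tab, classes, n_hinge_knots)
    full = fit_maxent(
        builder.transform(presence_tab),
        builder.transform(background_tab),
        reg_scale=reg_scale,
        seed=seed,
        builder=builder,
    )
    imp = permutation_importance_tables(full, presence_tab, background_tab, n_reps, seed)
    order = sorted(imp.items(), key=lambda kv: (-kv[1], kv[0]))
    retained: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for var, _ in order:
        conflict = None
        for kept in retained:
            rho = spearmanr(
                background_tab[kept].to_numpy(), background_tab[var].to_numpy()
            ).statistic
            if abs(rho) > rho_threshold:
                conflict = (kept, var, float(rho))
                break
        if conflict is None:
            retained.append(var)
        else:
            dropped.append(conflict)
    sub_b = background_tab[retained]
    sub_p = presence_tab[retained]
    sub_builder = FeatureBuilder.from_background(sub_b, classes, n_hinge_knots)
    refit = fit_maxent(
        sub_builder.transform(sub_p),
        sub_builder.transform(sub_b),
        reg_scale=reg_scale,
        seed=seed,
        builder=sub_builder,
    )
    return SelectionTrace(order, dropped, retained, refit)


# ---------------------------------------------------------------------------
# Evaluation: AUC, threshold, TSS
# ---------------------------------------------------------------------------


def auc(presence_scores: Sequence[float], background_scores: Sequence[float]) -> float:
    """Mann-Whitney AUC: P(presence score > background score), ties 0.5."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("auc requires non-empty score lists")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


def best_threshold(
    presence_scores: Sequence[float], background_scores: Sequence[float]
) -> tuple[float, float, float]:
    """Threshold maximising sensitivity + specificity over observed scores.

    sensitivity(t) = fraction of presences >= t; specificity(t) = fraction
    of background < t. Objective ties are broken by the smallest t (most
    inclusive presence map). Returns (threshold, sensitivity, specificity).
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("best_threshold requires non-empty score lists")
    cands = np.unique(np.concatenate([p, b]))
    sens = (p[:, None] >= cands[None, :]).mean(axis=0)
    spec = (b[:, None] < cands[None, :]).mean(axis=0)
    obj = sens + spec
    i = int(np.argmax(obj))  # argmax returns the first (smallest t) maximiser
    return float(cands[i]), float(sens[i]), float(spec[i])


@dataclass
class EvalReport:
    """Discrimination metrics for a fitted model on held-out data."""

    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    tss: float

    def to_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "tss": self.tss,
        }


def evaluate(
    model: MaxentModel,
    test_presence: OccurrenceSet | PointSet,
    background: PointSet,
    rasters: Mapping[str, Raster],
) -> EvalReport:
    """AUC, best threshold and TSS from suitability sampled at point cells."""
    suit = predict(model, rasters)
    pts = test_presence.points if isinstance(test_presence, OccurrenceSet) else test_presence
    sp = score_at_points(suit, pts)
    sb = score_at_points(suit, background)
    sp, sb = sp[np.isfinite(sp)], sb[np.isfinite(sb)]
    a = auc(sp, sb)
    t, sens, spec = best_threshold(sp, sb)
    return EvalReport(a, t, sens, spec, sens + spec - 1.0)


def binarize_and_clip(
    suitability: Raster, threshold: float, range_polys: PolygonSet
) -> BinaryMask:
    """Presence = suitability >= threshold, clipped to the range polygons.

    Cells outside the range (or with missing suitability) are missing, so
    downstream overlap denominators never count out-of-range cells.
    """
    spec = suitability.spec
    inside = polygon_mask(range_polys, spec).one_set()
    v = suitability.values
    out = np.full(spec.shape, np.nan)
    ok = inside & np.isfinite(v)
    out[ok] = (v[ok] >= threshold).astype(float)
    return BinaryMask(spec, out)
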