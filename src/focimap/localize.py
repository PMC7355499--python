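"""Conduction-velocity estimation and geodesic source localization.

Given one most-probable path (FO, FI, LI, LO) and the activations matched
to it, the wavefront speed is estimated from the C(4,2) = 6 sensor-pair
combinations — geodesic separation over median activation-time
difference — giving a mean μ and spread σ_c.  The source location s0 and
per-activation onset times t_k then minimize

    Σ_k Σ_e ( Geo(s0, s_e)/CV* + t_k − x_{e,k} )²

subject to 0 ≤ t_k < x_{FO,k} and Geo(s0, s_e) ≤ ρ (the maximum
plausible source-to-sensor distance).  For fixed s0 and CV* the optimal
onsets have the closed form t_k = clip(mean_e(x_{e,k} − Geo/CV*), 0,
x_{FO,k}); the outer problem is an exhaustive vertex search in mesh mode
(distance fields are seeded at the four sensors and read back by
geodesic symmetry) and a multi-start continuous minimization in planar
mode.  Monte-Carlo replicates redraw CV* ~ N(μ, σ_c²) truncated positive
and bootstrap the matched activations; replicate locations are averaged
into a point estimate with a dispersion diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import minimize

from .activation import ActivationMatrix
from .geometry import CatheterLayout, SurfaceMesh, geodesic_field, snap_to_surface
from .paths import PathMatchedSample, ProbablePath

__all__ = [
    "CVEstimate",
    "LocalizationConfig",
    "SourceFit",
    "LocalizationResult",
    "PlanarGeometry",
    "MeshGeometry",
    "estimate_cv",
    "fit_source_location",
    "monte_carlo_localize",
    "aggregate_placements",
    "pool_by_truth",
]


class PlanarGeometry:
    """Flat-tissue geometry: geodesic distance = Euclidean distance.

    Keeps every localization quantity available in closed form, which the
    solver tests exploit.  ``sensor_positions`` maps pair index → (3,) mm.
    """

    def __init__(self, sensor_positions: dict):
        self.sensor_positions = {int(k): np.asarray(v, dtype=float) for k, v in sensor_positions.items()}

    @classmethod
    def from_layout(cls, layout: CatheterLayout) -> "PlanarGeometry":
        return cls({p.pair_index: p.midpoint for p in layout.pairs})

    def sensor_distance(self, a: int, b: int) -> float:
        return float(np.linalg.norm(self.sensor_positions[a] - self.sensor_positions[b]))

    def sensor_array(self, pair_indices) -> np.ndarray:
        return np.stack([self.sensor_positions[p] for p in pair_indices])


class MeshGeometry:
    """Surface-mesh geometry: distances along the triangle edge graph.

    Sensors live on mesh vertices (pair index → vertex id); candidate
    sources are mesh vertices.  Distance fields are cached per seed.
    """

    def __init__(self, mesh: SurfaceMesh, sensor_vertices: dict):
        self.mesh = mesh
        self.sensor_vertices = {int(k): int(v) for k, v in sensor_vertices.items()}
        self._fields: dict[int, np.ndarray] = {}

    @classmethod
    def from_layout(cls, layout: CatheterLayout, mesh: SurfaceMesh) -> "MeshGeometry":
        return cls(mesh, snap_to_surface(layout, mesh))

    def field_from_vertex(self, vertex: int) -> np.ndarray:
        if vertex not in self._fields:
            self._fields[vertex] = geodesic_field(self.mesh, vertex).distance_per_vertex
        return self._fields[vertex]

    def sensor_distance(self, a: int, b: int) -> float:
        return float(self.field_from_vertex(self.sensor_vertices[a])[self.sensor_vertices[b]])

    def fields_for_sensors(self, pair_indices) -> np.ndarray:
        """(n_sensors, V) distances from each path sensor to every vertex."""
        return np.stack([self.field_from_vertex(self.sensor_vertices[p]) for p in pair_indices])


@dataclass(frozen=True)
class CVEstimate:
    """Conduction velocity distilled from the 6 path sensor pairs."""

    mean_mu: float  # mm/ms
    sd_sigma_c: float  # mm/ms
    pairwise_values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairwise_values", np.asarray(self.pairwise_values, dtype=float))


@dataclass(frozen=True)
class LocalizationConfig:
    """Solver settings.

    ``rho_max`` bounds the source-to-sensor distance (mm); the candidate
    region is a planar bounding box (xmin, xmax, ymin, ymax) or a mesh
    vertex id array (None → all vertices / box spanned by ``rho_max``
    around the sensors).
    """

    rho_max: float = 50.0
    n_mc_replicates_M: int = 100
    candidate_region: object = None
    seed: int = 0
    n_starts: int = 9
    onset_tol: float = 1e-6
    bootstrap: bool = True

    def __post_init__(self) -> None:
        if self.rho_max <= 0:
            raise ValueError("rho_max must be positive")
        if self.n_mc_replicates_M < 1:
            raise ValueError("need at least one Monte-Carlo replicate")


@dataclass(frozen=True)
class SourceFit:
    """One solution of the localization problem."""

    s0: np.ndarray  # (3,) mm
    vertex: int | None  # mesh mode only
    onsets: np.ndarray  # t_k per matched activation, ms
    sse: float  # ms²
    cv_used: float  # mm/ms
    diagnostics: dict


@dataclass(frozen=True)
class LocalizationResult:
    """Monte-Carlo localization summary for one catheter placement."""

    fits: tuple
    point_estimate: np.ndarray  # (3,) mm
    vertex_estimate: int | None
    dispersion: dict  # per-axis sd (mm) and mean spread (mm)
    path: ProbablePath
    cv: CVEstimate


def estimate_cv(
    matrix: ActivationMatrix,
    path: ProbablePath,
    matched: PathMatchedSample,
    geometry,
    min_dt_ms: float = 0.1,
    rel_dt_frac: float = 0.25,
) -> CVEstimate:
    """CV from each of the 6 sensor-pair combinations on the path.

    Per pair (a, b): geodesic separation divided by the absolute median,
    over matched activations, of the activation-time difference.  Pairs
    whose median time difference is below ``min_dt_ms``, or below
    ``rel_dt_frac`` of the largest pairwise difference, are excluded with
    a warning: a sensor pair the wavefront reaches near-simultaneously
    lies across, not along, the propagation direction, and its ratio of
    straight-line separation to time difference overestimates the speed
    without bound.
    """
    if matched.T_star < 1:
        raise ValueError("need at least one path-matched activation")
    sensors = list(dict.fromkeys(path.as_tuple))  # dedupe, keep slot order
    if len(sensors) < 2:
        raise ValueError("path has fewer than two distinct sensors")
    sub = matrix.subset_by_ids(matched.activation_ids)
    dts = {
        (a, b): float(np.median(sub.lat[:, sub.column_of(b)] - sub.lat[:, sub.column_of(a)]))
        for a, b in combinations(sensors, 2)
    }
    cutoff = max(min_dt_ms, rel_dt_frac * max(abs(v) for v in dts.values()))
    values = []
    for (a, b), dt in dts.items():
        if abs(dt) < cutoff:
            warnings.warn(
                f"sensor pair ({a}, {b}): median time difference {dt:.3g} ms below "
                f"{cutoff:.3g} ms, excluded from CV estimation",
                stacklevel=2,
            )
            continue
        values.append(geometry.sensor_distance(a, b) / abs(dt))
    if len(values) < 2:
        raise ValueError("fewer than two usable sensor pairs for CV estimation")
    values = np.array(values)
    return CVEstimate(mean_mu=float(values.mean()), sd_sigma_c=float(values.std(ddof=1)), pairwise_values=values)


def _matched_lats(matrix: ActivationMatrix, path: ProbablePath, activation_ids) -> tuple[np.ndarray, np.ndarray]:
    """(T*, 4) LATs at the path sensors plus the FO column separately."""
    sub = matrix.subset_by_ids(activation_ids)
    cols = [sub.column_of(p) for p in path.as_tuple]
    lat = sub.lat[:, cols]
    return lat, sub.lat[:, sub.column_of(path.FO)]


def _closed_form_objective(d: np.ndarray, lat: np.ndarray, lat_fo: np.ndarray, cv: float, tol: float):
    """SSE over candidates with onsets profiled out.

    ``d`` is (V, n_e) source-to-sensor distances per candidate, ``lat``
    (T*, n_e).  Returns (sse per candidate, onsets per candidate).
    """
    travel = d / cv  # (V, n_e)
    m = lat.mean(axis=1)[None, :] - travel.mean(axis=1)[:, None]  # (V, T*)
    t = np.clip(m, 0.0, np.maximum(lat_fo[None, :] - tol, 0.0))
    resid = travel[:, None, :] + t[:, :, None] - lat[None, :, :]  # (V, T*, n_e)
    return np.einsum("vte,vte->v", resid, resid), t


def fit_source_location(
    matrix: ActivationMatrix,
    path: ProbablePath,
    matched: PathMatchedSample,
    cv_value: float,
    geometry,
    config: LocalizationConfig,
    activation_ids=None,
    starts=None,
) -> SourceFit:
    """Minimize the activation-time misfit over candidate source locations.

    Mesh mode enumerates candidate vertices exhaustively (exact given the
    per-sensor distance fields).  Planar mode runs L-BFGS-B from a grid
    of deterministic starts over the candidate box; ``starts`` overrides
    the start list (used for warm-started Monte-Carlo replicates).
    """
    if cv_value <= 0:
        raise ValueError("conduction velocity must be positive")
    ids = matched.activation_ids if activation_ids is None else activation_ids
    lat, lat_fo = _matched_lats(matrix, path, ids)
    sensors = list(path.as_tuple)

    if isinstance(geometry, MeshGeometry):
        fields = geometry.fields_for_sensors(sensors)  # (4, V)
        cand = config.candidate_region
        cand = np.arange(geometry.mesh.n_vertices) if cand is None else np.asarray(cand, dtype=int)
        d = fields[:, cand].T  # (V, 4)
        feasible = (d <= config.rho_max).all(axis=1)
        if not feasible.any():
            raise ValueError(
                f"no candidate vertex lies within rho_max = {config.rho_max} mm of all "
                "four path sensors; increase rho_max or widen the candidate region"
            )
        sse, t = _closed_form_objective(d[feasible], lat, lat_fo, cv_value, config.onset_tol)
        k = int(np.argmin(sse))
        vtx = int(cand[feasible][k])
        top = np.sort(sse)[: max(1, len(sse) // 10)]
        return SourceFit(
            s0=geometry.mesh.vertices[vtx],
            vertex=vtx,
            onsets=t[k],
            sse=float(sse[k]),
            cv_used=float(cv_value),
            diagnostics={"flatness": float(top[-1] - top[0]), "n_candidates": int(feasible.sum())},
        )

    pos = geometry.sensor_array(sensors)  # (4, 3)
    box = config.candidate_region
    if box is None:
        c = pos.mean(axis=0)
        box = (c[0] - config.rho_max, c[0] + config.rho_max, c[1] - config.rho_max, c[1] + config.rho_max)
    xmin, xmax, ymin, ymax = box

    def objective(xy: np.ndarray) -> float:
        s0 = np.array([xy[0], xy[1], 0.0])
        d = np.linalg.norm(pos - s0, axis=1)[None, :]  # (1, 4)
        sse, _ = _closed_form_objective(d, lat, lat_fo, cv_value, config.onset_tol)
        excess = np.maximum(d - config.rho_max, 0.0)
        return float(sse[0] + 1e6 * np.sum(excess**2))

    if starts is None:
        # vectorized coarse scan of the candidate box, then polish the best cells
        g = 41
        xs = np.linspace(xmin, xmax, g)
        ys = np.linspace(ymin, ymax, g)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        cand = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
        d_all = np.linalg.norm(cand[:, None, :] - pos[None, :, :], axis=2)  # (G, 4)
        sse_all, _ = _closed_form_objective(d_all, lat, lat_fo, cv_value, config.onset_tol)
        sse_all += 1e6 * np.sum(np.maximum(d_all - config.rho_max, 0.0) ** 2, axis=1)
        order = np.argsort(sse_all)[: max(1, config.n_starts // 3)]
        starts = [cand[i, :2] for i in order]
    best = None
    optima = []
    for x0 in starts:
        res = minimize(objective, np.asarray(x0, dtype=float), method="L-BFGS-B", bounds=[(xmin, xmax), (ymin, ymax)])
        optima.append(res.fun)
        if best is None or res.fun < best.fun:
            best = res
    s0 = np.array([best.x[0], best.x[1], 0.0])
    d = np.linalg.norm(pos - s0, axis=1)
    if (d > config.rho_max + 1e-3).any():
        raise ValueError(
            f"best planar fit violates rho_max = {config.rho_max} mm "
            f"(max source-to-sensor distance {d.max():.1f} mm); increase rho_max"
        )
    at_boundary = bool((d > config.rho_max - 1e-3).any())
    sse, t = _closed_form_objective(d[None, :], lat, lat_fo, cv_value, config.onset_tol)
    return SourceFit(
        s0=s0,
        vertex=None,
        onsets=t[0],
        sse=float(sse[0]),
        cv_used=float(cv_value),
        diagnostics={"start_spread": float(np.ptp(optima)), "n_starts": len(starts), "at_rho_boundary": at_boundary},
    )


def monte_carlo_localize(
    matrix: ActivationMatrix,
    path: ProbablePath,
    matched: PathMatchedSample,
    cv: CVEstimate,
    geometry,
    config: LocalizationConfig,
    max_truncation_retries: int = 100,
) -> LocalizationResult:
    """Propagate CV and sampling uncertainty through the localization.

    Each replicate draws CV* from N(μ, σ_c²) truncated to positive values,
    bootstrap-resamples the matched activations, and re-solves the fit
    (planar replicates are warm-started from the first full multi-start
    solution).  The point estimate is the mean of replicate locations; in
    mesh mode it is the vertex minimizing the mean geodesic distance to
    the replicate vertices, so it stays on the surface.
    """
    rng = np.random.default_rng(config.seed)

    def draw_cv() -> float:
        if cv.sd_sigma_c == 0.0:
            return cv.mean_mu
        for _ in range(max_truncation_retries):
            v = rng.normal(cv.mean_mu, cv.sd_sigma_c)
            if v > 0:
                return v
        raise RuntimeError("could not draw a positive conduction velocity")

    fits = []
    warm = None
    for r in range(config.n_mc_replicates_M):
        cv_star = draw_cv()
        ids = matched.activation_ids
        if config.bootstrap:
            ids = rng.choice(ids, size=len(ids), replace=True)
        starts = None if warm is None else [warm]
        fit = fit_source_location(matrix, path, matched, cv_star, geometry, config, activation_ids=ids, starts=starts)
        if warm is None and fit.vertex is None:
            warm = fit.s0[:2]
        fits.append(fit)

    locs = np.stack([f.s0 for f in fits])
    if isinstance(geometry, MeshGeometry):
        reps = np.array([f.vertex for f in fits])
        uniq, inv = np.unique(reps, return_inverse=True)
        fields = np.stack([geometry.field_from_vertex(int(u)) for u in uniq])  # (U, V)
        mean_geo = fields[inv].mean(axis=0)
        vtx = int(np.argmin(mean_geo))
        point = geometry.mesh.vertices[vtx]
        spread = float(np.mean([geometry.field_from_vertex(vtx)[v] for v in reps]))
    else:
        vtx = None
        point = locs.mean(axis=0)
        spread = float(np.mean(np.linalg.norm(locs - point, axis=1)))
    return LocalizationResult(
        fits=tuple(fits),
        point_estimate=point,
        vertex_estimate=vtx,
        dispersion={"per_axis_sd": locs.std(axis=0, ddof=0), "mean_spread": spread},
        path=path,
        cv=cv,
    )


def aggregate_placements(results: list[LocalizationResult], truth=None) -> dict:
    """Pool point estimates from multiple catheter placements.

    Returns the pooled centroid, the RMS spread about it, the individual
    estimates, and — when a ground-truth location is supplied (test
    mode) — per-placement and centroid distances to the truth.
    """
    if not results:
        raise ValueError("need at least one placement result")
    pts = np.stack([r.point_estimate for r in results])
    centroid = pts.mean(axis=0)
    spread = float(np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1))))
    out = {"centroid": centroid, "spread_rms": spread, "estimates": pts, "n_placements": len(results)}
    if truth is not None:
        truth = np.asarray(truth, dtype=float)
        out["distance_to_truth"] = np.linalg.norm(pts - truth, axis=1)
        out["centroid_error"] = float(np.linalg.norm(centroid - truth))
    return out


def pool_by_truth(results: list[LocalizationResult], truths) -> list[dict]:
    """Assign each placement estimate to its nearest true source and pool.

    Resolves the label-switching between per-placement path ranks and the
    underlying sources (rank 1 at one placement may be a different source
    than rank 1 at another); the assignment only fixes labels, the
    estimates themselves are untouched.
    """
    truths = np.atleast_2d(np.asarray(truths, dtype=float))
    groups: list[list[LocalizationResult]] = [[] for _ in truths]
    for r in results:
        k = int(np.argmin(np.linalg.norm(truths - r.point_estimate, axis=1)))
        groups[k].append(r)
    out = []
    for k, grp in enumerate(groups):
        if grp:
            out.append(aggregate_placements(grp, truth=truths[k]))
        else:
            out.append({"centroid": None, "n_placements": 0, "estimates": np.empty((0, 3))})
    return out
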