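"""Bray-Curtis dissimilarity, nonmetric MDS, covariance ellipses and the
repeated-start topology-consistency check.

The NMDS solver is nonmetric SMACOF: each iteration fits disparities to the
configuration distances by Kruskal's primary monotone regression (ties in the
input dissimilarities are free to order themselves) and then applies a
Guttman-transform update.  Stress is Kruskal's stress-1 on the 0-1 scale,

    stress = sqrt( sum (d_ij - dhat_ij)^2 / sum d_ij^2 ),

the convention under which the study-scale oligotype ordination sits around
0.2.  Because NMDS optimizes from random starts, the stability of the layout
is assessed by re-running with independent starts and Procrustes-superimposing
every solution onto the best one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import isotonic_regression

from .community import AbundanceTable

DEFAULT_N_STARTS = 8
DEFAULT_MAX_ITER = 500
DEFAULT_TOL = 1e-7
DEFAULT_N_TRIALS = 50
DEFAULT_CONSISTENCY_THRESHOLD = 0.99


@dataclass
class EllipseParams:
    mean: np.ndarray
    covariance: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    degenerate: bool


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # index = samples; columns x, y (k dims)
    stress: float
    converged: bool
    stress_history: list[float] = field(default_factory=list)
    n_trials: int = 0
    n_consistent: int = 0
    group_ellipses: dict[str, EllipseParams] = field(default_factory=dict)


def bray_curtis(table: AbundanceTable | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between sample rows.

    BC(i,j) = sum|x_it - x_jt| / sum(x_it + x_jt); symmetric with zero
    diagonal, in [0, 1] for non-negative data.  Two all-zero samples would
    make the quotient undefined, so that is an error.
    """
    data = table.data if isinstance(table, AbundanceTable) else table
    values = np.asarray(data, dtype=float)
    if (values < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    zero_rows = np.flatnonzero(values.sum(axis=1) == 0)
    if len(zero_rows) >= 2:
        names = list(data.index[zero_rows])
        raise ValueError(f"Bray-Curtis undefined for all-zero sample pair: {names}")
    dm = squareform(pdist(values, metric="braycurtis"))
    return pd.DataFrame(dm, index=data.index, columns=data.index)


def _as_matrix(dist) -> tuple[np.ndarray, list]:
    if isinstance(dist, pd.DataFrame):
        return dist.to_numpy(dtype=float), list(dist.index)
    arr = np.asarray(dist, dtype=float)
    return arr, list(range(arr.shape[0]))


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float((d**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def _monotone_disparities(
    dvec: np.ndarray, d: np.ndarray, order: np.ndarray
) -> np.ndarray:
    """Kruskal primary monotone regression of d against the dissimilarity order."""
    dhat_sorted = isotonic_regression(d[order])
    dhat = np.empty_like(d)
    dhat[order] = dhat_sorted
    return dhat


def _pcoa_init(D: np.ndarray, dims: int) -> np.ndarray:
    """Classical-scaling (principal coordinates) starting configuration."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    idx = np.argsort(eigvals)[::-1][:dims]
    lam = np.clip(eigvals[idx], 0.0, None)
    X = eigvecs[:, idx] * np.sqrt(lam)
    # break exact degeneracy so the Guttman transform cannot stall
    if not np.isfinite(X).all() or np.allclose(X, 0):
        X = np.full((n, dims), 1e-6)
    return X


def _nmds_single(
    D: np.ndarray,
    dims: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, float, list[float], bool]:
    n = D.shape[0]
    iu = np.triu_indices(n, k=1)
    dvec = D[iu]
    X = rng.standard_normal((n, dims)) if init is None else init.copy()
    history: list[float] = []
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        d = pdist(X)
        # primary approach: ties in dvec are ordered by the current distances
        order = np.lexsort((d, dvec))
        dhat = _monotone_disparities(dvec, d, order)
        stress = _stress1(d, dhat)
        history.append(stress)
        if prev - stress < tol:
            converged = True
            break
        prev = stress
        # Guttman transform with the fitted disparities
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, dhat / d, 0.0)
        B = np.zeros((n, n))
        B[iu] = -ratio
        B += B.T
        np.fill_diagonal(B, -B.sum(axis=1))
        X = (B @ X) / n
    X = X - X.mean(axis=0)
    return X, history[-1], history, converged


def nmds(
    dist,
    dims: int = 2,
    n_starts: int = DEFAULT_N_STARTS,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int | None = None,
) -> OrdinationResult:
    """Nonmetric MDS of a distance matrix into `dims` dimensions.

    The first start is a classical-scaling (principal coordinates)
    configuration; the remaining `n_starts - 1` starts are seeded random
    configurations, and the lowest-stress result is returned, centred at the
    origin.  Deterministic for a fixed seed.  If the winning start did not
    converge within `max_iter`, ``converged`` is False.
    """
    D, labels = _as_matrix(dist)
    n = D.shape[0]
    if n < dims + 1:
        raise ValueError(f"need at least {dims + 1} points for {dims}-D NMDS")
    rngs = np.random.SeedSequence(seed).spawn(max(n_starts, 1))
    best = None
    for i, child in enumerate(rngs):
        rng = np.random.default_rng(child)
        init = _pcoa_init(D, dims) if i == 0 else None
        X, stress, history, conv = _nmds_single(D, dims, rng, max_iter, tol, init=init)
        if best is None or stress < best[1]:
            best = (X, stress, history, conv)
    X, stress, history, conv = best
    coords = pd.DataFrame(X, index=labels, columns=[f"axis{i + 1}" for i in range(dims)])
    return OrdinationResult(
        coordinates=coords, stress=stress, converged=conv, stress_history=history
    )


def covariance_ellipse(
    coordinates: pd.DataFrame, group_labels: pd.Series
) -> dict[str, EllipseParams]:
    """Per-group mean and sample covariance of 2-D coordinates.

    The 1-SD ellipse has axes along the covariance eigenvectors with
    half-widths sqrt(eigenvalue); a near-zero eigenvalue (collinear group)
    flags the ellipse as degenerate.  Groups need >= 3 points.
    """
    out: dict[str, EllipseParams] = {}
    for group in sorted(group_labels.unique()):
        members = group_labels.index[group_labels == group]
        pts = coordinates.loc[members].to_numpy(dtype=float)
        if pts.shape[0] < 3:
            raise ValueError(f"group {group!r} has fewer than 3 points")
        mean = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False, ddof=1)
        eigvals, eigvecs = np.linalg.eigh(cov)
        scale = max(eigvals.max(), 1.0)
        degenerate = bool(eigvals.min() <= 1e-12 * scale)
        out[group] = EllipseParams(mean, cov, eigvals, eigvecs, degenerate)
    return out


def procrustes_correlation(X: np.ndarray, Y: np.ndarray) -> float:
    """Correlation after optimal translation/rotation/reflection/scaling.

    Defined as sqrt(1 - disparity) where disparity is the standardized
    residual sum of squares of the superimposition; 1 means identical shapes.
    """
    _, _, disparity = _scipy_procrustes(np.asarray(X, float), np.asarray(Y, float))
    return float(np.sqrt(max(0.0, 1.0 - disparity)))


def topology_consistency(
    dist,
    n_trials: int = DEFAULT_N_TRIALS,
    seed: int | None = None,
    threshold: float = DEFAULT_CONSISTENCY_THRESHOLD,
    dims: int = 2,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    n_starts_per_trial: int = 4,
) -> tuple[int, int]:
    """How often independently restarted NMDS fits agree on the layout.

    Each trial is a fresh NMDS fit keeping the best of
    `n_starts_per_trial` random starts (the way shell NMDS front-ends retry
    random starts within one run); trials are seeded independently.  Every
    trial configuration is Procrustes-superimposed onto the lowest-stress
    one and counted consistent when its Procrustes correlation is >=
    `threshold`.
    """
    D, _ = _as_matrix(dist)
    children = np.random.SeedSequence(seed).spawn(n_trials)
    runs = []
    for child in children:
        best_X, best_stress = None, np.inf
        for start in child.spawn(n_starts_per_trial):
            rng = np.random.default_rng(start)
            X, stress, _, _ = _nmds_single(D, dims, rng, max_iter, tol)
            if stress < best_stress:
                best_X, best_stress = X, stress
        runs.append((best_X, best_stress))
    best_X = min(runs, key=lambda t: t[1])[0]
    n_consistent = sum(
        1 for X, _ in runs if procrustes_correlation(X, best_X) >= threshold
    )
    return n_consistent, n_trials


def ordinate_table(
    table: AbundanceTable,
    n_starts: int = DEFAULT_N_STARTS,
    n_trials: int = 0,
    seed: int | None = None,
) -> OrdinationResult:
    """Bray-Curtis NMDS of an abundance table with per-individual ellipses."""
    dm = bray_curtis(table)
    result = nmds(dm, n_starts=n_starts, seed=seed)
    result.group_ellipses = covariance_ellipse(
        result.coordinates, table.individuals()
    )
    if n_trials:
        result.n_consistent, result.n_trials = topology_consistency(
            dm, n_trials=n_trials, seed=seed
        )
    return result


def write_ordination(
    result: OrdinationResult,
    table: AbundanceTable,
    outdir: str | Path,
    stem: str,
) -> dict[str, str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    coords = result.coordinates.copy()
    coords.insert(0, "sample", coords.index)
    coords["individual"] = table.individuals().values
    coords["timepoint"] = table.sample_meta["timepoint"].values
    coords_path = outdir / f"{stem}_coordinates.tsv"
    coords.to_csv(coords_path, sep="\t", index=False)
    report = {
        "stress": result.stress,
        "converged": result.converged,
        "n_trials": result.n_trials,
        "n_consistent": result.n_consistent,
    }
    json_path = outdir / f"{stem}_ordination.json"
    json_path.write_text(json.dumps(report, indent=2))
    return {"coordinates": str(coords_path), "report": str(json_path)}
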