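"""Vertex-wise age-contrast statistics on the unfolded hippocampal surface.

Per vertex, an ordinary least squares model

    DV ~ b0 + b1 age + b2 sex + b3 age:sex

is fitted across participants and the t-statistic of the age coefficient
(t = b1 / SE(b1)) is extracted, giving an age-contrast map.  These maps
are summarized by

* their absolute Pearson correlation with contrived positional gradients
  (the unfolded AP and PD coordinates themselves), locating age effects
  along the hippocampal axes, together with the mean absolute t;
* spin-test correlations against reference maps: the correlation null is
  built by random rigid transformations of one map in the unfolded
  rectangular grid (toroidal translations plus optional axis flips),
  which preserve spatial autocorrelation.

Reference maps here are synthetic stand-ins (seeded Gaussian random
fields on the unfolded grid) for published myelin / histology / synaptic
density maps; any user-supplied per-vertex map on the same grid works.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .geometry import SurfaceModel
from .parcel_stats import fdr_bh

__all__ = [
    "VertexStatMap",
    "vertex_glm_tmap",
    "positional_gradients",
    "gradient_correlation",
    "SpinTestResult",
    "spin_test",
    "reference_map_battery",
    "synthetic_reference_maps",
    "REFERENCE_MAP_NAMES",
]

# stand-ins for the published comparison maps (myelin-sensitive qR1,
# silver-stained fibers, synaptic density PET, interneuron immunolabels,
# cell-body stain); generated synthetically on the unfolded grid
REFERENCE_MAP_NAMES = ("qR1", "bielschowsky", "SV2A", "calretinin",
                       "calbindin", "parvalbumin", "merker")


@dataclass
class VertexStatMap:
    """Age-contrast map: per-vertex t plus fit metadata."""

    metric: str
    t: np.ndarray              # (n_vertices,)
    beta: np.ndarray           # (n_vertices, 4) coefficient estimates
    df_resid: int
    valid: np.ndarray          # (n_vertices,) bool
    exact_fit: np.ndarray = None   # vertices with zero residual variance


def _design(cohort: pd.DataFrame) -> np.ndarray:
    age = cohort["age"].to_numpy(float)
    male = (cohort["sex"].to_numpy() == "M").astype(float)
    return np.column_stack([np.ones(len(cohort)), age, male, age * male])


def vertex_glm_tmap(maps: np.ndarray, cohort: pd.DataFrame,
                    metric: str = "") -> VertexStatMap:
    """Per-vertex OLS age contrast across participants.

    ``maps`` is (n_participants, n_vertices) of hemisphere-averaged
    per-vertex values aligned with the rows of ``cohort`` (one row per
    participant with ``age`` and ``sex``).  Vertices with missing data
    drop those participants from that vertex's fit; zero-residual
    (exact-fit) vertices get infinite |t| and are flagged; zero-variance
    vertices are masked invalid.
    """
    if len(cohort) < 5:
        raise ValueError("need at least 5 participants")
    X_full = _design(cohort)
    n, n_vert = maps.shape
    if n != len(cohort):
        raise ValueError("maps rows must align with cohort rows")
    t = np.full(n_vert, np.nan)
    beta_out = np.full((n_vert, 4), np.nan)
    valid = np.zeros(n_vert, dtype=bool)
    exact = np.zeros(n_vert, dtype=bool)
    df_glob = n - 4

    complete = ~np.isnan(maps).any(axis=0)

    def fit_block(X, Y):
        """OLS t for the age column, shared design, many DVs."""
        XtX_inv = np.linalg.inv(X.T @ X)
        B = XtX_inv @ X.T @ Y                    # (4, nv)
        resid = Y - X @ B
        dof = X.shape[0] - X.shape[1]
        sse = (resid ** 2).sum(axis=0)
        sigma2 = sse / dof
        se_age = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tv = B[1] / se_age
        return B, tv, sse, dof

    if complete.any():
        Y = maps[:, complete]
        var_ok = Y.std(axis=0) > 0
        B, tv, sse, dof = fit_block(X_full, Y)
        idx = np.nonzero(complete)[0]
        beta_out[idx] = B.T
        t[idx] = tv
        exact[idx] = sse <= 1e-24
        valid[idx] = var_ok
        t[idx[~var_ok]] = np.nan

    for j in np.nonzero(~complete)[0]:
        keep = ~np.isnan(maps[:, j])
        if keep.sum() < 5:
            continue
        y = maps[keep, j]
        if y.std() == 0:
            continue
        B, tv, sse, dof = fit_block(X_full[keep], y[:, None])
        beta_out[j] = B[:, 0]
        t[j] = tv[0]
        exact[j] = sse[0] <= 1e-24
        valid[j] = True

    return VertexStatMap(metric=metric, t=t, beta=beta_out,
                         df_resid=df_glob, valid=valid, exact_fit=exact)


# --------------------------------------------------------------------------
# Positional gradients
# --------------------------------------------------------------------------

def positional_gradients(surface: SurfaceModel):
    """Contrived positional maps: the unfolded AP and PD coordinates."""
    return (surface.vertices_unfolded[:, 0].copy(),
            surface.vertices_unfolded[:, 1].copy())


def gradient_correlation(tmap: VertexStatMap, surface: SurfaceModel):
    """(|R_AP|, |R_PD|, mean |t|) of an age-contrast map.

    Absolute Pearson correlations of the t-map with the positional AP and
    PD gradients over jointly valid vertices, plus the mean absolute t —
    a coarse scalar for the total age relationship of the metric.
    """
    ap, pd_grad = positional_gradients(surface)
    m = tmap.valid & np.isfinite(tmap.t)
    if m.sum() < 3:
        raise ValueError("fewer than 3 valid vertices")
    tv = tmap.t[m]
    if np.std(tv) == 0:
        raise ValueError("constant t-map: correlation undefined")
    r_ap = abs(stats.pearsonr(tv, ap[m])[0])
    r_pd = abs(stats.pearsonr(tv, pd_grad[m])[0])
    return float(r_ap), float(r_pd), float(np.abs(tv).mean())


# --------------------------------------------------------------------------
# Spin test
# --------------------------------------------------------------------------

@dataclass
class SpinTestResult:
    r: float
    p: float
    null: np.ndarray
    n_perm: int
    seed: int
    p_adj: float = np.nan


def _masked_pearson(a, b):
    m = np.isfinite(a) & np.isfinite(b)
    if m.sum() < 3:
        return np.nan
    aa, bb = a[m] - a[m].mean(), b[m] - b[m].mean()
    denom = np.sqrt((aa ** 2).sum() * (bb ** 2).sum())
    if denom == 0:
        return np.nan
    return float((aa * bb).sum() / denom)


def spin_test(map_a: np.ndarray, map_b: np.ndarray, surface: SurfaceModel,
              n_perm: int = 2500, seed: int = 0,
              flips: bool = True) -> SpinTestResult:
    """Spatial permutation correlation test on the unfolded grid.

    The null distribution is built by applying ``n_perm`` random rigid
    transformations of ``map_b`` in the unfolded rectangular grid —
    toroidal translations along AP and PD plus (optionally) independent
    axis flips — and recomputing the Pearson correlation each time.
    These transforms preserve the map's spatial autocorrelation, unlike
    value permutation.  Two-sided p with the finite-sample correction
    p = (1 + #{|R_null| >= |R_obs|}) / (n_perm + 1).
    """
    n_ap, n_pd = surface.grid_shape
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if n_ap < 4 or n_pd < 4:
        raise ValueError("grid too small for distinct shifts")
    A = np.asarray(map_a, dtype=float).reshape(n_ap, n_pd)
    B = np.asarray(map_b, dtype=float).reshape(n_ap, n_pd)
    r_obs = _masked_pearson(A.ravel(), B.ravel())
    rng = np.random.default_rng(seed)
    dx = rng.integers(0, n_ap, size=n_perm)
    dy = rng.integers(0, n_pd, size=n_perm)
    fx = rng.integers(0, 2, size=n_perm).astype(bool) if flips \
        else np.zeros(n_perm, dtype=bool)
    fy = rng.integers(0, 2, size=n_perm).astype(bool) if flips \
        else np.zeros(n_perm, dtype=bool)
    null = np.empty(n_perm)
    for k in range(n_perm):
        Bk = B[::-1] if fx[k] else B
        Bk = Bk[:, ::-1] if fy[k] else Bk
        Bk = np.roll(Bk, (dx[k], dy[k]), axis=(0, 1))
        null[k] = _masked_pearson(A.ravel(), Bk.ravel())
    p = (1.0 + np.sum(np.abs(null) >= abs(r_obs))) / (n_perm + 1.0)
    return SpinTestResult(r=r_obs, p=float(p), null=null, n_perm=n_perm,
                          seed=seed)


def reference_map_battery(tmaps: dict, reference_maps: dict,
                          surface: SurfaceModel, n_perm: int = 2500,
                          seed: int = 0) -> pd.DataFrame:
    """All-pairs correlation of age-contrast maps with reference maps.

    Returns a tidy frame (tmap, reference, r, p, p_adj) where p comes
    from the spin test and the Benjamini-Hochberg adjustment spans the
    full matrix of tests.
    """
    rows = []
    for i, (tname, tmap) in enumerate(tmaps.items()):
        tvals = tmap.t if isinstance(tmap, VertexStatMap) else tmap
        for j, (rname, ref) in enumerate(reference_maps.items()):
            ref = np.asarray(ref, dtype=float)
            if ref.shape[0] != np.asarray(tvals).shape[0]:
                raise ValueError("reference map shape mismatch")
            res = spin_test(tvals, ref, surface, n_perm=n_perm,
                            seed=seed + 1000 * i + j)
            rows.append({"tmap": tname, "reference": rname,
                         "r": res.r, "p": res.p})
    out = pd.DataFrame(rows)
    out["p_adj"] = fdr_bh(out["p"].to_numpy())
    return out


def synthetic_reference_maps(surface: SurfaceModel,
                             names=REFERENCE_MAP_NAMES, seed: int = 0,
                             smoothness: float = 4.0) -> dict:
    """Seeded synthetic reference maps with controlled autocorrelation.

    Gaussian random fields on the unfolded grid (white noise smoothed
    with a Gaussian kernel of ``smoothness`` grid units, standardized).
    These are stand-ins for the published qR1 / histology / PET maps,
    which are not redistributed here.
    """
    n_ap, n_pd = surface.grid_shape
    rng = np.random.default_rng(seed)
    out = {}
    for name in names:
        field = rng.normal(size=(n_ap, n_pd))
        field = ndimage.gaussian_filter(field, smoothness, mode="wrap")
        field = (field - field.mean()) / field.std()
        out[name] = field.ravel()
    return out
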