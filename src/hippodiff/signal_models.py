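"""Closed-form / quadrature forward models for diffusion MRI compartments.

Implements the three signal models used throughout the package:

* a single diffusion tensor (``dti_signal``), with FA / MD / principal
  eigenvector derived metrics;
* a three-compartment Watson-dispersed stick + tortuosity zeppelin + free
  water model (``noddi_signal``) with fixed diffusivities
  (parallel 1.7 um^2/ms, CSF 3.0 um^2/ms) and the orientation dispersion
  index ``watson_odi``;
* a direction-averaged (powder) soma/neurite model (``sandi_powder_signal``)
  combining a powder stick, a Gaussian extracellular ball and an impermeable
  sphere under the Gaussian phase distribution (GPD) approximation
  (``sphere_signal_gpd``), with intrasoma diffusivity fixed to 3.0 um^2/ms.

Units everywhere: b-values in ms/um^2, diffusivities in um^2/ms, pulse
timings delta / Delta in ms, radii in um.  All signals are computed relative
to S0 = 1; unattenuated amplitude is handled at fitting time only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf, hyp1f1

__all__ = [
    "D_PAR_FIXED",
    "D_ISO_FIXED",
    "D_IS_FIXED",
    "AcquisitionScheme",
    "default_scheme",
    "uniform_sphere_directions",
    "TensorParams",
    "NODDIParams",
    "SANDIParams",
    "dti_signal",
    "tensor_metrics",
    "tensor_from_eigen",
    "watson_odi",
    "odi_to_kappa",
    "watson_cos2_moment",
    "noddi_signal",
    "stick_powder_signal",
    "sphere_signal_gpd",
    "sandi_powder_signal",
    "sphere_bessel_roots",
]

# Fixed diffusivities (um^2/ms): parallel intraneurite/extraneurite for the
# dispersed-stick model, free-water, and intrasoma.
D_PAR_FIXED = 1.7
D_ISO_FIXED = 3.0
D_IS_FIXED = 3.0

# Default pulse timings (ms) for a strong-gradient multishell protocol.
DEFAULT_DELTA = 7.0
DEFAULT_BIG_DELTA = 24.0

_DEFAULT_BVALUES = (0.0, 0.5, 1.2, 2.4, 4.0, 6.0)
_DEFAULT_NDIRS = (14, 30, 30, 60, 60, 60)


# --------------------------------------------------------------------------
# Acquisition scheme
# --------------------------------------------------------------------------

def uniform_sphere_directions(n: int, n_iter: int = 200) -> np.ndarray:
    """Near-uniform unit directions on the sphere.

    A deterministic Fibonacci lattice refined by a few steps of electrostatic
    repulsion between antipodally-symmetrized charges, giving equal-weight
    point sets whose arithmetic mean closely approximates the spherical
    average of smooth (antipodally symmetric) integrands.
    """
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    # electrostatic refinement on the projective sphere (antipodal pairs),
    # with tangential steps capped to keep the descent stable
    for it in range(n_iter):
        d_plus = pts[:, None, :] - pts[None, :, :]
        d_minus = pts[:, None, :] + pts[None, :, :]
        r2p = np.einsum("ijk,ijk->ij", d_plus, d_plus)
        r2m = np.einsum("ijk,ijk->ij", d_minus, d_minus)
        np.fill_diagonal(r2p, np.inf)
        np.fill_diagonal(r2m, np.inf)
        force = (d_plus / r2p[..., None] ** 1.5).sum(axis=1)
        force += (d_minus / r2m[..., None] ** 1.5).sum(axis=1)
        # project onto the tangent plane; take a normalized step whose
        # length decays over the iterations
        force -= np.einsum("ij,ij->i", force, pts)[:, None] * pts
        norm = np.linalg.norm(force, axis=1, keepdims=True)
        step = 0.05 / np.sqrt(n) * (1.0 - it / n_iter) ** 2
        pts = pts + step * force / np.maximum(norm, 1e-30)
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


@dataclass(frozen=True)
class AcquisitionScheme:
    """Multi-shell pulsed-gradient acquisition.

    Parameters
    ----------
    bvalues:
        Shell b-values in ms/um^2 (one entry per shell, b = 0 allowed).
    n_dirs_per_shell:
        Number of volumes in each shell.
    directions:
        (n_volumes, 3) unit gradient directions, one row per volume.
        b = 0 volumes carry a placeholder direction.
    delta, Delta:
        Gradient pulse duration and separation in ms (delta < Delta).
    """

    bvalues: tuple
    n_dirs_per_shell: tuple
    directions: np.ndarray
    delta: float = DEFAULT_DELTA
    Delta: float = DEFAULT_BIG_DELTA
    shell_of_volume: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        bvalues = tuple(float(b) for b in self.bvalues)
        ndirs = tuple(int(n) for n in self.n_dirs_per_shell)
        if len(bvalues) != len(ndirs):
            raise ValueError("bvalues and n_dirs_per_shell length mismatch")
        if any(b < 0 for b in bvalues):
            raise ValueError("negative b-value")
        if not self.delta < self.Delta:
            raise ValueError("delta must be smaller than Delta")
        directions = np.asarray(self.directions, dtype=float)
        if directions.shape != (sum(ndirs), 3):
            raise ValueError("directions shape does not match volume count")
        shell_of_volume = np.repeat(np.arange(len(bvalues)), ndirs)
        norms = np.linalg.norm(directions, axis=1)
        nonzero = np.array(bvalues)[shell_of_volume] > 0
        if np.any(np.abs(norms[nonzero] - 1.0) > 1e-6):
            raise ValueError("diffusion-weighted directions must be unit norm")
        object.__setattr__(self, "bvalues", bvalues)
        object.__setattr__(self, "n_dirs_per_shell", ndirs)
        object.__setattr__(self, "directions", directions)
        object.__setattr__(self, "shell_of_volume", shell_of_volume)

    # -- convenience views ------------------------------------------------
    @property
    def n_volumes(self) -> int:
        return self.directions.shape[0]

    @property
    def bvals_per_volume(self) -> np.ndarray:
        return np.array(self.bvalues)[self.shell_of_volume]

    def shell_indices(self, shell: int) -> np.ndarray:
        return np.nonzero(self.shell_of_volume == shell)[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals_per_volume == 0.0

    def bmatrices(self) -> np.ndarray:
        """(n_volumes, 3, 3) b-matrices B = b * g g^T (ms/um^2)."""
        g = self.directions
        b = self.bvals_per_volume
        return b[:, None, None] * np.einsum("ij,ik->ijk", g, g)

    def subscheme(self, b_max: float) -> "AcquisitionScheme":
        """Scheme restricted to shells with b <= b_max."""
        keep = [i for i, b in enumerate(self.bvalues) if b <= b_max]
        vol_keep = np.isin(self.shell_of_volume, keep)
        return AcquisitionScheme(
            bvalues=tuple(self.bvalues[i] for i in keep),
            n_dirs_per_shell=tuple(self.n_dirs_per_shell[i] for i in keep),
            directions=self.directions[vol_keep],
            delta=self.delta,
            Delta=self.Delta,
        )

    # -- I/O (FSL-style whitespace text files) ----------------------------
    def save(self, prefix) -> None:
        prefix = Path(prefix)
        np.savetxt(prefix.with_suffix(".bval"),
                   self.bvals_per_volume[None, :], fmt="%.6g")
        np.savetxt(prefix.with_suffix(".bvec"), self.directions.T, fmt="%.10g")
        np.savetxt(prefix.with_suffix(".timing"),
                   np.array([[self.delta, self.Delta]]), fmt="%.6g")

    @classmethod
    def load(cls, prefix) -> "AcquisitionScheme":
        prefix = Path(prefix)
        bvals = np.atleast_1d(np.loadtxt(prefix.with_suffix(".bval")).ravel())
        bvecs = np.loadtxt(prefix.with_suffix(".bvec")).T.reshape(-1, 3)
        delta, Delta = np.loadtxt(prefix.with_suffix(".timing")).ravel()
        # volumes arrive shell-ordered from save(); rebuild shell structure
        shells, counts, order = [], [], np.argsort(bvals, kind="stable")
        bvals, bvecs = bvals[order], bvecs[order]
        for b in np.unique(bvals):
            shells.append(float(b))
            counts.append(int(np.sum(bvals == b)))
        return cls(bvalues=tuple(shells), n_dirs_per_shell=tuple(counts),
                   directions=bvecs, delta=float(delta), Delta=float(Delta))


def default_scheme(delta: float = DEFAULT_DELTA,
                   Delta: float = DEFAULT_BIG_DELTA) -> AcquisitionScheme:
    """The six-shell protocol: b = 0 (14), 0.5 (30), 1.2 (30), 2.4 (60),
    4.0 (60), 6.0 (60) ms/um^2."""
    dirs = []
    for b, n in zip(_DEFAULT_BVALUES, _DEFAULT_NDIRS):
        if b == 0:
            dirs.append(np.tile([0.0, 0.0, 0.0], (n, 1)))
        else:
            dirs.append(uniform_sphere_directions(n))
    return AcquisitionScheme(
        bvalues=_DEFAULT_BVALUES, n_dirs_per_shell=_DEFAULT_NDIRS,
        directions=np.vstack(dirs), delta=delta, Delta=Delta)


# --------------------------------------------------------------------------
# Parameter containers
# --------------------------------------------------------------------------

@dataclass
class TensorParams:
    """Symmetric 3x3 diffusion tensor (um^2/ms) with unattenuated signal."""

    D: np.ndarray
    S0: float = 1.0

    def __post_init__(self):
        D = np.asarray(self.D, dtype=float)
        if D.shape != (3, 3) or not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("D must be a symmetric 3x3 matrix")
        if np.linalg.eigvalsh(D).min() < -1e-10:
            raise ValueError("D must be positive semi-definite")
        self.D = 0.5 * (D + D.T)


@dataclass
class NODDIParams:
    """Watson-dispersed stick + tortuosity zeppelin + free water."""

    f_iso: float
    f_in: float
    kappa: float
    mu: np.ndarray
    d_par: float = D_PAR_FIXED
    d_iso: float = D_ISO_FIXED

    def __post_init__(self):
        if not (0.0 <= self.f_iso <= 1.0 and 0.0 <= self.f_in <= 1.0):
            raise ValueError("signal fractions must lie in [0, 1]")
        if self.kappa < 0:
            raise ValueError("Watson concentration must be >= 0")
        mu = np.asarray(self.mu, dtype=float)
        n = np.linalg.norm(mu)
        if n == 0:
            raise ValueError("mu must be a nonzero vector")
        self.mu = mu / n


@dataclass
class SANDIParams:
    """Powder-averaged stick + sphere + extracellular ball."""

    f_ec: float
    f_in: float
    r_s: float
    d_in: float
    d_ec: float
    d_is: float = D_IS_FIXED

    def __post_init__(self):
        if not (0.0 <= self.f_ec <= 1.0 and 0.0 <= self.f_in <= 1.0):
            raise ValueError("signal fractions must lie in [0, 1]")
        if not (0.0 < self.r_s <= 12.0):
            raise ValueError("soma radius must lie in (0, 12] um")
        for d in (self.d_in, self.d_ec, self.d_is):
            if not (0.0 < d <= 3.0):
                raise ValueError("diffusivities must lie in (0, 3] um^2/ms")

    # derived signal fractions (sum to one by construction)
    @property
    def f_neurite(self) -> float:
        return (1.0 - self.f_ec) * self.f_in

    @property
    def f_soma(self) -> float:
        return (1.0 - self.f_ec) * (1.0 - self.f_in)


# --------------------------------------------------------------------------
# Diffusion tensor
# --------------------------------------------------------------------------

def dti_signal(params: TensorParams, scheme: AcquisitionScheme,
               volume_index=None) -> np.ndarray:
    """S = S0 * exp(-<B, D>_F) with B the per-volume b-matrix."""
    B = scheme.bmatrices()
    if volume_index is not None:
        B = B[np.atleast_1d(volume_index)]
    s = params.S0 * np.exp(-np.einsum("vij,ij->v", B, params.D))
    if volume_index is not None and np.isscalar(volume_index):
        return float(s[0])
    return s


def tensor_from_eigen(eigenvalues, e1=(1.0, 0.0, 0.0)) -> np.ndarray:
    """Axially-oriented tensor: first eigenvalue along ``e1``, the remaining
    two spanning its orthogonal complement."""
    e1 = np.asarray(e1, dtype=float)
    e1 = e1 / np.linalg.norm(e1)
    # complete an orthonormal frame
    helper = np.array([1.0, 0.0, 0.0])
    if abs(e1 @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    V = np.stack([e1, e2, e3], axis=1)
    return V @ np.diag(np.asarray(eigenvalues, dtype=float)) @ V.T


def tensor_metrics(D: np.ndarray):
    """(FA, MD, principal eigenvector) of a symmetric tensor.

    MD is the eigenvalue mean; FA the normalized eigenvalue variance
    FA = sqrt(3/2) * ||lambda - MD|| / ||lambda||; an all-zero tensor has
    FA defined as 0.  The principal eigenvector is sign-canonicalized so its
    first nonzero component is positive.
    """
    D = np.asarray(D, dtype=float)
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("tensor must be symmetric")
    lam, V = np.linalg.eigh(D)
    md = float(lam.mean())
    norm = float(np.sqrt((lam ** 2).sum()))
    if norm == 0.0:
        fa = 0.0
    else:
        fa = float(np.sqrt(1.5 * ((lam - md) ** 2).sum()) / norm)
    e1 = V[:, np.argmax(lam)]
    for c in e1:
        if c != 0:
            if c < 0:
                e1 = -e1
            break
    return fa, md, e1


# --------------------------------------------------------------------------
# Watson distribution helpers
# --------------------------------------------------------------------------

def watson_odi(kappa) -> np.ndarray:
    """Orientation dispersion index ODI = (2/pi) * arctan(1/kappa).

    Monotone decreasing in the Watson concentration ``kappa``; ODI(0) = 1
    by the limit convention and ODI -> 0 as kappa -> infinity.
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be >= 0")
    with np.errstate(divide="ignore"):
        odi = (2.0 / np.pi) * np.arctan2(1.0, kappa)
    return odi if odi.ndim else float(odi)


def odi_to_kappa(odi) -> np.ndarray:
    odi = np.asarray(odi, dtype=float)
    if np.any((odi <= 0) | (odi > 1)):
        raise ValueError("ODI must lie in (0, 1]")
    kappa = 1.0 / np.tan(odi * np.pi / 2.0)
    return kappa if kappa.ndim else float(kappa)


def watson_cos2_moment(kappa: float) -> float:
    """E[(n . mu)^2] under a Watson distribution with concentration kappa.

    Equal to M(3/2, 5/2, kappa) / (3 M(1/2, 3/2, kappa)) with M the
    confluent hypergeometric function; 1/3 at kappa = 0 (isotropic) and
    -> 1 as kappa -> infinity.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa == 0.0:
        return 1.0 / 3.0
    if kappa > 300.0:
        # asymptotic expansion; hyp1f1 overflows for very large kappa
        return 1.0 - 1.0 / kappa - 0.5 / kappa ** 2
    return float(hyp1f1(1.5, 2.5, kappa) / (3.0 * hyp1f1(0.5, 1.5, kappa)))


# Gauss-Legendre nodes in cos(theta) on [-1, 1] and uniform azimuth grid.
_GL_ORDER = 64
_N_PHI = 48
_GL_T, _GL_W = np.polynomial.legendre.leggauss(_GL_ORDER)
_PHI = np.arange(_N_PHI) * (2.0 * np.pi / _N_PHI)
_COS_PHI = np.cos(_PHI)


def watson_stick_kernel(bd: np.ndarray, cos_ang: np.ndarray) -> np.ndarray:
    """Quadrature kernel for the Watson-averaged stick.

    For each volume i with diffusion weighting ``bd[i] = b_i * d_par`` and
    gradient at angle ``cos_ang[i]`` from the Watson axis, returns the
    azimuthally averaged stick attenuation at each polar node t_j:

        K[j, i] = (1/n_phi) sum_k exp(-bd_i (t_j c_i + s_j s'_i cos phi_k)^2)

    Independent of kappa, so it can be cached per voxel during fitting.
    """
    bd = np.asarray(bd, dtype=float)
    c = np.asarray(cos_ang, dtype=float)
    s_node = np.sqrt(np.maximum(0.0, 1.0 - _GL_T ** 2))  # (J,)
    s_grad = np.sqrt(np.maximum(0.0, 1.0 - c ** 2))      # (I,)
    # dot(n, g) for node j, azimuth k, volume i
    dot = (_GL_T[:, None, None] * c[None, None, :]
           + s_node[:, None, None] * s_grad[None, None, :]
           * _COS_PHI[None, :, None])
    return np.exp(-bd[None, None, :] * dot ** 2).mean(axis=1)  # (J, I)


def _watson_weights(kappa: float) -> np.ndarray:
    """Normalized Gauss-Legendre weights w_j exp(kappa t_j^2) / Z."""
    # subtract max exponent for numerical stability at large kappa
    e = kappa * _GL_T ** 2
    e -= e.max()
    w = _GL_W * np.exp(e)
    return w / w.sum()


def noddi_signal(params: NODDIParams, scheme: AcquisitionScheme,
                 volume_index=None, stick_kernel: np.ndarray | None = None
                 ) -> np.ndarray:
    """Three-compartment dispersed-stick signal, relative to S0 = 1.

    S = (1 - f_iso) (f_in S_in + (1 - f_in) S_en) + f_iso S_iso with

    * S_in the Watson-averaged stick attenuation (Gauss-Legendre quadrature
      in cos theta, trapezoidal in azimuth);
    * S_en a zeppelin with the tortuosity constraint
      d_perp = d_par (1 - f_in), orientationally averaged at the tensor
      level over the same Watson distribution;
    * S_iso = exp(-b d_iso).
    """
    b = scheme.bvals_per_volume
    g = scheme.directions
    cos_ang = g @ params.mu
    if volume_index is not None:
        idx = np.atleast_1d(volume_index)
        b, cos_ang = b[idx], cos_ang[idx]
    if params.kappa > 512.0:
        # coherent-stick limit; the polar quadrature cannot resolve the
        # Watson peak beyond this concentration
        s_in = np.exp(-b * params.d_par * cos_ang ** 2)
    else:
        if stick_kernel is None:
            stick_kernel = watson_stick_kernel(b * params.d_par, cos_ang)
        w = _watson_weights(params.kappa)
        s_in = w @ stick_kernel
    # dispersed zeppelin: average the tensor over the Watson distribution
    tau1 = watson_cos2_moment(params.kappa)
    d_perp = params.d_par * (1.0 - params.f_in)
    mean_cos2 = tau1 * cos_ang ** 2 + (1.0 - tau1) * (1.0 - cos_ang ** 2) / 2.0
    s_en = np.exp(-b * (d_perp + (params.d_par - d_perp) * mean_cos2))
    s_iso = np.exp(-b * params.d_iso)
    s = ((1.0 - params.f_iso)
         * (params.f_in * s_in + (1.0 - params.f_in) * s_en)
         + params.f_iso * s_iso)
    if volume_index is not None and np.isscalar(volume_index):
        return float(s[0])
    return s


# --------------------------------------------------------------------------
# SANDI powder model
# --------------------------------------------------------------------------

def stick_powder_signal(b, d) -> np.ndarray:
    """Direction-averaged stick: sqrt(pi / (4 b d)) * erf(sqrt(b d)).

    Limit 1 at b d -> 0.
    """
    bd = np.asarray(b, dtype=float) * d
    out = np.ones_like(bd)
    nz = bd > 1e-12
    out[nz] = np.sqrt(np.pi / (4.0 * bd[nz])) * erf(np.sqrt(bd[nz]))
    return out if out.ndim else float(out)


def sphere_bessel_roots(n: int = 60) -> np.ndarray:
    """First ``n`` positive roots of d/dx [j_1(x)] = 0, i.e. of
    2 x cos x + (x^2 - 2) sin x = 0, for the impermeable-sphere GPD series."""
    f = lambda x: 2.0 * x * np.cos(x) + (x * x - 2.0) * np.sin(x)
    roots = []
    for m in range(n):
        lo, hi = m * np.pi + 1e-9, (m + 1) * np.pi - 1e-9
        if m == 0:
            lo = 1e-3
        roots.append(brentq(f, lo, hi, xtol=1e-14))
    return np.array(roots)


_SPHERE_ROOTS = sphere_bessel_roots(60)


def sphere_signal_gpd(r_s, d_is, b, delta, Delta, n_roots: int = 20,
                      check_truncation: bool = True):
    """GPD signal for diffusion restricted in an impermeable sphere.

    Murday-Cotts / Balinov expression under rectangular pulsed gradients:

        -ln S = 2 g2 sum_m [2 D a_m^2 delta - 2
                            + 2 exp(-D a_m^2 delta) + 2 exp(-D a_m^2 Delta)
                            - exp(-D a_m^2 (Delta - delta))
                            - exp(-D a_m^2 (Delta + delta))]
                          / (D^2 a_m^6 (a_m^2 R^2 - 2))

    with a_m = x_m / R, x_m the roots of j_1'(x) = 0, and the squared
    gradient amplitude g2 = b / (delta^2 (Delta - delta/3)).  Monotone
    non-increasing in the radius at fixed (b, timings); -> 1 as r_s -> 0
    or b -> 0.
    """
    b = np.asarray(b, dtype=float)
    r = float(r_s)
    if r <= 0 or d_is <= 0:
        raise ValueError("r_s and d_is must be positive")
    if n_roots > _SPHERE_ROOTS.size:
        raise ValueError("n_roots exceeds precomputed root table")
    alpha = _SPHERE_ROOTS[:n_roots] / r                      # 1/um
    ad = d_is * alpha ** 2                                   # 1/ms
    g2 = b / (delta ** 2 * (Delta - delta / 3.0))            # 1/(ms um^2) * ...
    num = (2.0 * ad * delta - 2.0
           + 2.0 * np.exp(-ad * delta) + 2.0 * np.exp(-ad * Delta)
           - np.exp(-ad * (Delta - delta)) - np.exp(-ad * (Delta + delta)))
    den = d_is ** 2 * alpha ** 6 * (alpha ** 2 * r ** 2 - 2.0)
    terms = num / den
    if check_truncation and terms.size >= 2:
        tail = abs(terms[-1])
        total = abs(terms.sum())
        if total > 0 and tail / total > 1e-6:
            import warnings
            warnings.warn(
                "sphere GPD series truncation error above tolerance; "
                "increase n_roots", RuntimeWarning)
    ln_s = -2.0 * np.atleast_1d(g2)[..., None] * terms[None, :]
    s = np.exp(ln_s.sum(axis=-1))
    return s if np.asarray(b).ndim else float(s[0])


def sandi_powder_signal(params: SANDIParams, b, delta: float = DEFAULT_DELTA,
                        Delta: float = DEFAULT_BIG_DELTA,
                        n_roots: int = 20):
    """Direction-averaged soma/neurite signal at shell b-value(s) ``b``.

    S(b) = (1 - f_ec) (f_in S_in + (1 - f_in) S_is) + f_ec S_ec with the
    powder stick S_in, the GPD sphere S_is, and the Gaussian ball
    S_ec = exp(-b d_ec).
    """
    b_arr = np.atleast_1d(np.asarray(b, dtype=float))
    if np.any(b_arr < 0):
        raise ValueError("b-values must be >= 0")
    s_in = stick_powder_signal(b_arr, params.d_in)
    s_is = sphere_signal_gpd(params.r_s, params.d_is, b_arr, delta, Delta,
                             n_roots=n_roots, check_truncation=False)
    s_ec = np.exp(-b_arr * params.d_ec)
    s = ((1.0 - params.f_ec)
         * (params.f_in * s_in + (1.0 - params.f_in) * s_is)
         + params.f_ec * s_ec)
    return s if np.asarray(b).ndim else float(s[0])
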