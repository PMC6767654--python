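"""Stochastic coefficient models: random diffusivity and velocity fields.

Five coefficient models feed the transport equation:

* D1 — homogeneous diffusivity as a shifted gamma random variable,
  D*(w) = 0.25 D_Gad + Gamma(k=3, theta=0.75 D_Gad / 3).
* D2 — heterogeneous diffusivity: a stationary Gaussian (Matern) field
  mapped through a Gaussian copula so that every point has the same
  shifted-gamma marginal as D1, with correlation length 0.01 m.
* V1 — glymphatic circulation: the curl of a vector potential of three
  i.i.d. standard Matern fields (correlation length 1020 um), scaled by
  v_avg * eta * 10^(-E) with E ~ Exponential(mean 0.2); divergence-free
  with zero-mean components.
* V2 — V1 plus a deterministic large-scale directional field v_dir.
* V3 — radial paraarterial inflow towards the ventricles with a gamma
  magnitude (shape 2) and a homogeneous drainage sink r = 1e-5 1/s.

Gaussian fields are sampled by circulant embedding on a regular auxiliary
box grid (FFT), then interpolated to mesh vertices.  The Matern smoothness
convention is nu = 1/2 (exponential covariance) with the correlation
length defined as the distance at which correlation decays to 1/e.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import special, stats

from .geometry import LabeledMesh

LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass
class MaternSpec:
    """Auxiliary-grid specification of a standard Matern Gaussian field.

    The sampling box must strictly contain the mesh the field will be
    interpolated onto.  ``strict`` enforces grid_spacing <= lambda/3 (three
    grid cells per correlation length); relax only deliberately, e.g. to
    reproduce a coarse production sampling box.
    """

    correlation_length: float
    box_origin: tuple = (0.0, 0.0, 0.0)
    box_extent: tuple = (0.16, 0.21, 0.17)
    grid_spacing: float = 0.0023
    nu: float = 0.5
    marginal_variance: float = 1.0
    strict: bool = True

    def __post_init__(self):
        if self.correlation_length <= 0 or self.grid_spacing <= 0:
            raise ValueError("correlation length and grid spacing must be positive")
        if self.strict and self.grid_spacing > self.correlation_length / 3:
            raise ValueError(
                f"grid spacing {self.grid_spacing} too coarse for correlation length "
                f"{self.correlation_length} (needs <= lambda/3; pass strict=False to override)")

    @classmethod
    def for_mesh(cls, mesh: LabeledMesh, correlation_length: float,
                 grid_spacing: float, margin: float = 0.005, **kw) -> "MaternSpec":
        lo, hi = mesh.bounding_box()
        return cls(correlation_length=correlation_length,
                   box_origin=tuple(lo - margin), box_extent=tuple(hi - lo + 2 * margin),
                   grid_spacing=grid_spacing, **kw)


@dataclass
class DiffusionSpec:
    """Gamma diffusivity models D1 (random variable) / D2 (random field)."""

    model: str = "D1"
    D_Gad: float = 1.2e-10          # m^2/s, parenchymal gadobutrol diffusivity
    offset_factor: float = 0.25
    gamma_shape: float = 3.0
    gamma_scale: float = None       # m^2/s; defaults to 0.75 D_Gad / k
    field_correlation_length: float = 0.01  # m, D2 only

    def __post_init__(self):
        if self.gamma_scale is None:
            self.gamma_scale = 0.75 * self.D_Gad / self.gamma_shape
        if min(self.D_Gad, self.offset_factor, self.gamma_shape, self.gamma_scale) <= 0:
            raise ValueError("diffusion parameters must be positive")

    @property
    def offset(self) -> float:
        """Infimum of the sampled diffusivity, 0.25 * D_Gad."""
        return self.offset_factor * self.D_Gad

    @property
    def mean(self) -> float:
        return self.offset + self.gamma_shape * self.gamma_scale


@dataclass
class VelocitySpec:
    """Velocity models V1/V2/V3 and their calibration constants."""

    model: str = "V1"
    v_avg: float = 1.7e-7           # m/s, target RMS velocity magnitude
    lambda_v: float = 1020e-6       # m, Matern correlation length (V1/V2)
    exp_mean: float = 0.2           # mean of the exponential exponent E
    eta: Optional[float] = None     # calibrated scaling (V1/V2)
    v_f: float = 2e-6               # m/s, directional field magnitude (V2)
    R: float = 0.08                 # m, inflow region radius (V3)
    x_c: tuple = (0.0, 0.0, 0.0)    # ventricle center (V3)
    inflow_gamma_shape: float = 2.0
    inflow_gamma_scale: Optional[float] = None  # calibrated (V3)
    drainage_r: float = 0.0         # 1/s; 1e-5 for V3

    def __post_init__(self):
        if self.model == "V3" and self.drainage_r == 0.0:
            self.drainage_r = 1e-5
        if self.drainage_r < 0:
            raise ValueError("drainage rate must be non-negative")
        if self.eta is not None and self.eta <= 0:
            raise ValueError("eta must be positive once calibrated")


@dataclass
class CoefficientSample:
    """One realization of the transport coefficients.

    diffusivity: scalar (m^2/s) or nodal field; velocity: nodal (nv, 3)
    field in m/s or None for the pure-diffusion models.
    """

    diffusivity: Union[float, np.ndarray]
    velocity: Optional[np.ndarray]
    drainage_r: float
    seed: int
    sample_index: int = 0
    model: str = ""
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Matern correlation and circulant-embedding sampler
# ---------------------------------------------------------------------------

def matern_correlation(r, correlation_length: float, nu: float = 0.5):
    """Matern correlation with rho(lambda) = exp(-1).

    For nu = 1/2 this is the exponential model exp(-r/lambda); for general
    nu the range parameter is solved so correlation is 1/e at r = lambda.
    """
    r = np.asarray(r, dtype=float)
    if nu == 0.5:
        return np.exp(-r / correlation_length)
    from scipy.optimize import brentq

    def rho(s):  # s = kappa * r
        s = np.maximum(s, 1e-12)
        return 2 ** (1 - nu) / special.gamma(nu) * s ** nu * special.kv(nu, s)

    kappa = brentq(lambda k: rho(k) - np.exp(-1.0), 1e-6, 1e3) / correlation_length
    out = np.where(r > 0, rho(kappa * np.maximum(r, 1e-300)), 1.0)
    return out


class MaternFieldSampler:
    """Stationary Gaussian sampling on a regular box grid via circulant embedding.

    The covariance is embedded in a periodic torus twice the grid size; its
    FFT gives the eigenvalues, tiny negative ones are clipped and the
    marginal variance rescaled to be exact.  One sample costs one complex
    FFT of the embedded grid.
    """

    def __init__(self, spec: MaternSpec):
        self.spec = spec
        h = spec.grid_spacing
        origin = np.asarray(spec.box_origin, dtype=float)
        extent = np.asarray(spec.box_extent, dtype=float)
        self.shape = tuple(int(np.ceil(e / h)) + 1 for e in extent)
        self.axes = [origin[d] + h * np.arange(self.shape[d]) for d in range(3)]
        m = tuple(2 * n for n in self.shape)
        dists = []
        for d in range(3):
            k = np.arange(m[d])
            dists.append(np.minimum(k, m[d] - k) * h)
        r = np.sqrt(dists[0][:, None, None] ** 2 + dists[1][None, :, None] ** 2
                    + dists[2][None, None, :] ** 2)
        cov = spec.marginal_variance * matern_correlation(r, spec.correlation_length, spec.nu)
        lam = np.fft.fftn(cov).real
        if lam.min() < -1e-6 * lam.max():
            # clipping is a standard remedy; record how much mass is lost
            self.clipped_fraction = float(-lam[lam < 0].sum() / lam[lam > 0].sum())
        else:
            self.clipped_fraction = 0.0
        lam = np.maximum(lam, 0.0)
        self._M = float(np.prod(m))
        variance = lam.sum() / self._M
        self._sqrt_lam = np.sqrt(lam * (spec.marginal_variance / variance))
        self._m = m
        # covariance of the 8 corners of one grid cell (for exact-marginal
        # interpolation of copula-transformed fields)
        corners = np.array([[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)],
                           dtype=float) * h
        d8 = np.linalg.norm(corners[:, None, :] - corners[None, :, :], axis=-1)
        self._corner_cov = spec.marginal_variance * matern_correlation(
            d8, spec.correlation_length, spec.nu)

    @property
    def grid_points(self) -> int:
        return int(np.prod(self.shape))

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        """One realization on the grid, shape ``self.shape``."""
        eps = rng.standard_normal(self._m) + 1j * rng.standard_normal(self._m)
        z = np.fft.ifftn(self._sqrt_lam * eps) * np.sqrt(self._M)
        n1, n2, n3 = self.shape
        return np.ascontiguousarray(z.real[:n1, :n2, :n3])

    # -- interpolation ------------------------------------------------------
    def _locate(self, points: np.ndarray):
        h = self.spec.grid_spacing
        origin = np.array([ax[0] for ax in self.axes])
        rel = (np.atleast_2d(points) - origin) / h
        idx = np.floor(rel).astype(int)
        upper = np.array(self.shape) - 1
        if np.any(rel < -1e-9) or np.any(rel > upper + 1e-9):
            raise ValueError("points outside the Matern sampling box")
        idx = np.clip(idx, 0, upper - 1)
        frac = rel - idx
        return idx, frac

    def interpolate(self, grid_field: np.ndarray, points: np.ndarray,
                    normalize: bool = False) -> np.ndarray:
        """Trilinear interpolation of a gridded field to arbitrary points.

        With ``normalize=True`` the interpolated value is divided by its
        exact pointwise standard deviation (w^T C w)^(1/2), so a standard
        Gaussian field keeps an exactly standard marginal off-grid (used by
        the copula construction of D2); the correction is continuous.
        """
        idx, frac = self._locate(points)
        fx, fy, fz = frac[:, 0], frac[:, 1], frac[:, 2]
        w = np.stack([(1 - fx) * (1 - fy) * (1 - fz), (1 - fx) * (1 - fy) * fz,
                      (1 - fx) * fy * (1 - fz), (1 - fx) * fy * fz,
                      fx * (1 - fy) * (1 - fz), fx * (1 - fy) * fz,
                      fx * fy * (1 - fz), fx * fy * fz], axis=1)
        vals = np.empty((len(idx), 8))
        c = 0
        for di in (0, 1):
            for dj in (0, 1):
                for dk in (0, 1):
                    vals[:, c] = grid_field[idx[:, 0] + di, idx[:, 1] + dj, idx[:, 2] + dk]
                    c += 1
        out = np.einsum("ij,ij->i", w, vals)
        if normalize:
            sigma2 = np.einsum("ij,jk,ik->i", w, self._corner_cov, w)
            out = out / np.sqrt(sigma2 / self.spec.marginal_variance)
        return out


def sample_matern_scalar(spec: MaternSpec, rng: np.random.Generator,
                         sampler: Optional[MaternFieldSampler] = None) -> np.ndarray:
    """One zero-mean, unit-variance Matern field realization on the box grid."""
    sampler = sampler or MaternFieldSampler(spec)
    return sampler.sample(rng)


# ---------------------------------------------------------------------------
# diffusion models
# ---------------------------------------------------------------------------

def sample_diffusion_D1(spec: DiffusionSpec, rng: np.random.Generator,
                        size=None):
    """Shifted-gamma diffusivity draw(s): 0.25 D_Gad + Gamma(k, theta)."""
    draw = rng.gamma(spec.gamma_shape, spec.gamma_scale, size=size)
    return spec.offset + draw


def sample_diffusion_D2(spec: DiffusionSpec, mesh: LabeledMesh,
                        rng: np.random.Generator,
                        sampler: Optional[MaternFieldSampler] = None) -> np.ndarray:
    """Nodal diffusivity field with exact shifted-gamma pointwise marginal.

    A standard Matern field is interpolated (marginal-exactly) to the mesh
    vertices and pushed through the Gaussian copula Phi -> Gamma(k, theta)
    quantile map; the induced spatial correlation is approximately (not
    exactly) Matern.
    """
    if sampler is None:
        sampler = MaternFieldSampler(MaternSpec.for_mesh(
            mesh, spec.field_correlation_length, spec.field_correlation_length / 3))
    g = sampler.sample(rng)
    z = sampler.interpolate(g, mesh.vertices, normalize=True)
    u = special.ndtr(z)
    # avoid the exact endpoints of the quantile map
    u = np.clip(u, 1e-15, 1 - 1e-15)
    return spec.offset + stats.gamma.ppf(u, spec.gamma_shape, scale=spec.gamma_scale)


# ---------------------------------------------------------------------------
# velocity models
# ---------------------------------------------------------------------------

def _curl_grid(psi: np.ndarray, h: float) -> np.ndarray:
    """Curl of a gridded vector potential, centred differences (np.gradient).

    psi has shape (3, n1, n2, n3); returns (3, n1, n2, n3).  Centred
    difference operators commute, so the matching discrete divergence of
    the result vanishes identically in the grid interior.
    """
    dzy = np.gradient(psi[2], h, axis=1)
    dyz = np.gradient(psi[1], h, axis=2)
    dxz = np.gradient(psi[0], h, axis=2)
    dzx = np.gradient(psi[2], h, axis=0)
    dyx = np.gradient(psi[1], h, axis=0)
    dxy = np.gradient(psi[0], h, axis=1)
    return np.stack([dzy - dyz, dxz - dzx, dyx - dxy])


def _raw_curl_sample(sampler: MaternFieldSampler, rng: np.random.Generator) -> np.ndarray:
    psi = np.stack([sampler.sample(rng) for _ in range(3)])
    return _curl_grid(psi, sampler.spec.grid_spacing)


def expected_log10_attenuation(exp_mean: float, power: int = 1) -> float:
    """E[10^(-power * E)] for E ~ Exponential(mean exp_mean), closed form."""
    beta = 1.0 / exp_mean
    return beta / (beta + power * LN10)


def calibrate_eta(spec: VelocitySpec, matern: MaternSpec,
                  n_calibration_samples: int = 50,
                  rng: Optional[np.random.Generator] = None,
                  sampler: Optional[MaternFieldSampler] = None,
                  mesh: Optional[LabeledMesh] = None) -> float:
    """Calibrate the V1/V2 scaling constant eta.

    eta is chosen so E[||v||^2]^(1/2) = v_avg for
    v = v_avg * eta * 10^(-E) * curl(psi):
    eta = (E[10^(-2E)] * E[||curl psi||^2])^(-1/2), with the exponential
    factor in closed form and the curl second moment estimated by Monte
    Carlo.  The curl statistics depend on the grid spacing (the potential
    has exponential covariance), so eta must be calibrated at the spacing
    later used for sampling.  With ``mesh`` given, the second moment is
    measured on the curl interpolated to the mesh vertices — the field the
    transport solver actually sees — otherwise on the sampling grid.
    Stores the result on ``spec.eta``.
    """
    if n_calibration_samples < 2:
        raise ValueError("need at least 2 calibration samples")
    rng = rng if rng is not None else np.random.default_rng(0)
    sampler = sampler or MaternFieldSampler(matern)
    sq = 0.0
    for _ in range(n_calibration_samples):
        curl = _raw_curl_sample(sampler, rng)
        if mesh is not None:
            at_nodes = np.stack([sampler.interpolate(curl[d], mesh.vertices)
                                 for d in range(3)])
            sq += np.mean(np.sum(at_nodes ** 2, axis=0))
        else:
            sq += np.mean(np.sum(curl ** 2, axis=0))
    mean_curl_sq = sq / n_calibration_samples
    if mean_curl_sq <= 0:
        raise ValueError("degenerate grid: curl field has zero variance")
    e_atten = expected_log10_attenuation(spec.exp_mean, power=2)
    spec.eta = float(1.0 / np.sqrt(e_atten * mean_curl_sq))
    return spec.eta


def sample_velocity_V1_grid(spec: VelocitySpec, sampler: MaternFieldSampler,
                            rng: np.random.Generator) -> np.ndarray:
    """One glymphatic-circulation velocity sample on the grid, (3, n1, n2, n3)."""
    if spec.eta is None:
        raise ValueError("eta is not calibrated; call calibrate_eta first")
    # E drawn from its own substream so the field sample stream is unaffected
    e_rng, f_rng = (np.random.default_rng(s) for s in rng.bit_generator.seed_seq.spawn(2))
    E = e_rng.exponential(spec.exp_mean)
    curl = _raw_curl_sample(sampler, f_rng)
    return spec.v_avg * spec.eta * 10.0 ** (-E) * curl


def sample_velocity_V1(spec: VelocitySpec, matern: MaternSpec, mesh: LabeledMesh,
                       rng: np.random.Generator,
                       sampler: Optional[MaternFieldSampler] = None) -> np.ndarray:
    """Glymphatic velocity sample interpolated to mesh vertices, (nv, 3)."""
    sampler = sampler or MaternFieldSampler(matern)
    vgrid = sample_velocity_V1_grid(spec, sampler, rng)
    return np.stack([sampler.interpolate(vgrid[d], mesh.vertices) for d in range(3)], axis=1)


def evaluate_directional_velocity(points, v_f: float = 2e-6) -> np.ndarray:
    """Deterministic large-scale directional field v_dir (m/s).

    v_dir(x) = -v_f * ( arctan(15 x1)(|x1| - 0.1),
                        arctan(15 x2)(|x2| - 0.1),
                        -0.9 x3 + 0.06 - sqrt(x1^2 + x2^2) ).
    """
    x = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.empty_like(x)
    out[:, 0] = np.arctan(15 * x[:, 0]) * (np.abs(x[:, 0]) - 0.1)
    out[:, 1] = np.arctan(15 * x[:, 1]) * (np.abs(x[:, 1]) - 0.1)
    out[:, 2] = -0.9 * x[:, 2] + 0.06 - np.hypot(x[:, 0], x[:, 1])
    return -v_f * out


def sample_velocity_V2(spec: VelocitySpec, matern: MaternSpec, mesh: LabeledMesh,
                       rng: np.random.Generator,
                       sampler: Optional[MaternFieldSampler] = None) -> np.ndarray:
    """V1 sample plus the deterministic directional field at the vertices."""
    v1 = sample_velocity_V1(spec, matern, mesh, rng, sampler=sampler)
    return v1 + evaluate_directional_velocity(mesh.vertices, spec.v_f)


def v3_radial_profile(points, spec: VelocitySpec) -> np.ndarray:
    """Scalar profile of the V3 inflow ansatz at ``points`` (excluding v-bar).

    exp(-3 (R - d)^2 / (R^2 - (R - d)^2)) with d = ||x - x_c||; the limit 0
    is taken at d = 0 and the profile vanishes for d >= 2R where the
    printed expression is undefined.
    """
    x = np.atleast_2d(np.asarray(points, dtype=float))
    d = np.linalg.norm(x - np.asarray(spec.x_c)[None, :], axis=1)
    R = spec.R
    denom = R ** 2 - (R - d) ** 2  # = d (2R - d)
    out = np.zeros_like(d)
    ok = (d > 0) & (d < 2 * R)
    out[ok] = np.exp(-3 * (R - d[ok]) ** 2 / denom[ok])
    return out


def calibrate_v3_scale(spec: VelocitySpec, mesh: LabeledMesh) -> float:
    """Calibrate the V3 gamma scale so E[||v||^2]^(1/2) = v_avg over the mesh.

    ||v|| = vbar * profile * d with E[vbar^2] = k (k+1) theta^2, so
    theta = v_avg / sqrt(k (k+1) * <profile^2 d^2>) where <.> is the
    volume-average mesh quadrature (midpoint rule).
    """
    cent = mesh.cell_centroids
    prof = v3_radial_profile(cent, spec)
    d = np.linalg.norm(cent - np.asarray(spec.x_c)[None, :], axis=1)
    w = mesh.cell_volumes
    mean_sq_profile = float(np.sum(w * (prof * d) ** 2) / w.sum())
    k = spec.inflow_gamma_shape
    spec.inflow_gamma_scale = float(
        spec.v_avg / np.sqrt(k * (k + 1) * mean_sq_profile))
    return spec.inflow_gamma_scale


def sample_velocity_V3(spec: VelocitySpec, mesh: LabeledMesh,
                       rng: np.random.Generator):
    """Radial inflow sample at the vertices plus the drainage rate.

    Returns ``(v, r)`` with v of shape (nv, 3); v(x_c) = 0 exactly.
    """
    lo, hi = mesh.bounding_box()
    if np.any(np.asarray(spec.x_c) < lo) or np.any(np.asarray(spec.x_c) > hi):
        raise ValueError("inflow center x_c lies outside the mesh bounding box")
    if spec.inflow_gamma_scale is None:
        calibrate_v3_scale(spec, mesh)
    vbar = rng.gamma(spec.inflow_gamma_shape, spec.inflow_gamma_scale)
    prof = v3_radial_profile(mesh.vertices, spec)
    v = vbar * prof[:, None] * (np.asarray(spec.x_c)[None, :] - mesh.vertices)
    return v, spec.drainage_r


# ---------------------------------------------------------------------------
# per-model dispatcher (Table-1 coefficient structure)
# ---------------------------------------------------------------------------

MODELS = ("D1", "D2", "V1", "V2", "V3")


def sample_coefficients(model: str, mesh: LabeledMesh, seed: int,
                        diffusion: Optional[DiffusionSpec] = None,
                        velocity: Optional[VelocitySpec] = None,
                        matern: Optional[MaternSpec] = None,
                        sampler: Optional[MaternFieldSampler] = None,
                        sample_index: int = 0) -> CoefficientSample:
    """One CoefficientSample with the coefficient structure of the model table.

    D1/D2: v = 0, r = 0, stochastic D*.  V1/V2/V3: D* = D_Gad constant,
    stochastic v; r > 0 only for V3.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    diffusion = diffusion or DiffusionSpec(model=model if model in ("D1", "D2") else "D1")
    rng = np.random.default_rng(seed)
    if model == "D1":
        return CoefficientSample(float(sample_diffusion_D1(diffusion, rng)), None, 0.0,
                                 seed, sample_index, model)
    if model == "D2":
        d = sample_diffusion_D2(diffusion, mesh, rng, sampler=sampler)
        return CoefficientSample(d, None, 0.0, seed, sample_index, model)
    velocity = velocity or VelocitySpec(model=model)
    if model in ("V1", "V2"):
        if matern is None and sampler is None:
            matern = MaternSpec.for_mesh(mesh, velocity.lambda_v, 0.0023, strict=False)
        fn = sample_velocity_V1 if model == "V1" else sample_velocity_V2
        v = fn(velocity, matern, mesh, rng, sampler=sampler)
        return CoefficientSample(diffusion.D_Gad, v, 0.0, seed, sample_index, model)
    v, r = sample_velocity_V3(velocity, mesh, rng)
    return CoefficientSample(diffusion.D_Gad, v, r, seed, sample_index, model)
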