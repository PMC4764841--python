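"""Simplified distributed-dipole source imaging.

A toy cortical surface (a rippled sphere, standing in for a folded cortex)
carries single current dipoles perpendicular to the surface.  The forward
model is the closed-form magnetic field of a current dipole in a spherical
volume conductor (Sarvas solution), projected on the radial magnetometer
orientations.  The inverse is a Tikhonov-regularized minimum-norm filter
whose noise covariance is estimated from a pre-movement baseline window; the
hierarchical-Bayes machinery of full variational source imaging is not
implemented — its hyperparameters (m0, gamma0) are carried in the
configuration for provenance only, because the downstream quantities
(estimated slow cortical potentials and their per-vertex ANOVA maps) need
only a linear inverse filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

from .errors import (
    ConditioningError,
    GeometryError,
    InvalidConfigError,
    StratificationError,
)

MU0_OVER_4PI = 1e-7


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CorticalMesh:
    """Dipole support: vertex positions (m) and unit current orientations."""

    vertices: np.ndarray  # (n_vertices, 3), strictly inside the conductor
    normals: np.ndarray   # (n_vertices, 3), unit norm

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def vertex_spacing(self) -> float:
        """Median nearest-neighbour distance (m)."""
        v = self.vertices
        d2 = np.sum((v[:, None, :] - v[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        return float(np.median(np.sqrt(d2.min(axis=1))))


def _fibonacci_sphere_cap(n: int, z_min: float) -> np.ndarray:
    i = np.arange(n)
    z = z_min + (1.0 - z_min) * (i + 0.5) / n
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_cortical_mesh(
    n_vertices: int = 400,
    radius: float = 0.07,
    ripple_amplitude: float = 0.12,
    ripple_frequency: float = 6.0,
    n_ripple_modes: int = 6,
    z_min: float = -0.3,
    seed: int = 0,
) -> CorticalMesh:
    """Rippled-sphere toy cortex.

    The surface is r(u) = radius * (1 + rho(u)) over unit directions u, with
    rho a sum of seeded sinusoidal modes.  The ripple gives the vertex
    normals generic (non-radial) components, as cortical folding does; a
    purely spherical mesh would be magnetically silent in a spherical
    conductor.
    """
    if n_vertices < 4:
        raise InvalidConfigError("mesh needs at least 4 vertices")
    rng = np.random.default_rng(seed)
    dirs = rng.standard_normal((n_ripple_modes, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    phases = rng.uniform(0, 2 * np.pi, n_ripple_modes)
    amps = ripple_amplitude / np.sqrt(n_ripple_modes) * np.ones(n_ripple_modes)

    u = _fibonacci_sphere_cap(n_vertices, z_min)

    proj = u @ dirs.T  # (n, modes)
    rho = (amps * np.cos(ripple_frequency * proj + phases)).sum(axis=1)
    grad_rho = -(amps * ripple_frequency
                 * np.sin(ripple_frequency * proj + phases)) @ dirs

    r = radius * (1.0 + rho)
    vertices = r[:, None] * u
    # normal of the implicit surface |x| - radius*(1 + rho(x/|x|))
    tang = grad_rho - (np.sum(grad_rho * u, axis=1, keepdims=True)) * u
    normals = u - radius * tang / r[:, None]
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return CorticalMesh(vertices=vertices, normals=normals)


# --------------------------------------------------------------------------
# forward model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LeadField:
    """Linear map from unit dipole currents at mesh vertices to sensors."""

    matrix: np.ndarray  # (n_sensors, n_vertices)
    mesh: CorticalMesh


def sarvas_field(
    dipole_pos: np.ndarray,
    dipole_moment: np.ndarray,
    sensor_pos: np.ndarray,
) -> np.ndarray:
    """Magnetic field (T) of a current dipole in a spherical conductor.

    Closed-form solution for the field outside a sphere centred at the
    origin; independent of the conductivity profile.  Radial dipoles are
    exactly silent.  Shapes: dipole_pos (3,), dipole_moment (3,),
    sensor_pos (m, 3); returns (m, 3).
    """
    r0 = np.asarray(dipole_pos, dtype=float)
    q = np.asarray(dipole_moment, dtype=float)
    r = np.atleast_2d(np.asarray(sensor_pos, dtype=float))
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r, axis=1)
    ar = np.sum(a_vec * r, axis=1)
    f = a * (rn * a + rn**2 - r @ r0)
    grad_f = (
        (a**2 / rn + ar / a + 2 * a + 2 * rn)[:, None] * r
        - (a + 2 * rn + ar / a)[:, None] * r0
    )
    qxr0 = np.cross(q, r0)
    b = MU0_OVER_4PI / f[:, None] ** 2 * (
        f[:, None] * qxr0 - (r @ qxr0)[:, None] * grad_f
    )
    return b


def compute_lead_field(mesh: CorticalMesh, array) -> LeadField:
    """Lead field for unit dipoles along the mesh normals, measured along
    each sensor's orientation."""
    radii = np.linalg.norm(mesh.vertices, axis=1)
    if np.any(radii >= array.head_radius):
        raise GeometryError(
            "mesh vertices must lie strictly inside the conductor sphere"
        )
    if np.any(np.linalg.norm(array.positions, axis=1) <= array.head_radius):
        raise GeometryError("sensors must lie outside the conductor sphere")
    cols = []
    for v, n in zip(mesh.vertices, mesh.normals):
        b = sarvas_field(v, n, array.positions)
        cols.append(np.sum(b * array.orientations, axis=1))
    return LeadField(matrix=np.column_stack(cols), mesh=mesh)


# --------------------------------------------------------------------------
# inverse
# --------------------------------------------------------------------------

@dataclass
class InverseConfig:
    """Regularized minimum-norm settings.

    ``lam`` scales the noise-covariance term relative to the signal term of
    the Gram matrix (dimensionless).  ``m0``/``gamma0`` are hierarchical
    prior hyperparameters recorded for provenance; the simplified linear
    inverse does not use them.
    """

    lam: float = 0.01
    baseline_window_ms: tuple = (-1500.0, -500.0)
    train_window_ms: tuple = (0.0, 1000.0)
    escp_window_ms: tuple = (0.0, 500.0)
    m0: float = 100.0
    gamma0: float = 10.0

    def validate(self):
        if self.lam < 0:
            raise InvalidConfigError("lam must be >= 0")


@dataclass
class CurrentEstimate:
    """Per-trial cortical current summaries.

    ``escp_raw`` holds per-trial, per-vertex mean currents over the eSCP
    window (0-500 ms after the cue); ``escp`` is the per-vertex z-score of
    that quantity against the distribution of baseline-window means across
    trials.  Full vertex-by-time traces are kept only when requested.
    """

    escp_raw: np.ndarray            # (n_trials, n_vertices)
    escp: np.ndarray                # (n_trials, n_vertices)
    trial_types: tuple
    inverse_filter: np.ndarray      # (n_vertices, n_sensors)
    traces: np.ndarray | None = None  # (n_trials, n_vertices, n_times)
    trace_times_ms: np.ndarray | None = None

    def by_type(self) -> dict:
        out = {}
        for m in sorted(set(self.trial_types)):
            sel = [i for i, t in enumerate(self.trial_types) if t == m]
            out[m] = self.escp[sel]
        return out


def make_inverse_filter(
    lf: LeadField, noise_cov: np.ndarray, lam: float,
    depth_weight: float = 0.5,
) -> np.ndarray:
    """Depth-weighted minimum-norm filter.

    W = R L^T (L R L^T + lam * mu * C)^-1 with source covariance
    R = diag(||l_j||^(-2 * depth_weight)), the standard compensation for the
    superficial bias of unweighted minimum norm (the default exponent 0.5
    balances superficial and deep sources), and mu = tr(LRL^T)/tr(C).
    """
    l = lf.matrix
    col = np.linalg.norm(l, axis=0)
    col[col == 0] = col[col > 0].min() if np.any(col > 0) else 1.0
    r = col ** (-2.0 * depth_weight)
    lr = l * r
    gram = lr @ l.T
    if lam == 0.0:
        cond = np.linalg.cond(gram)
        if cond > 1e12:
            raise ConditioningError(
                f"sensor Gram matrix condition number {cond:.2e}; "
                "use lam > 0"
            )
        return np.linalg.solve(gram.T, lr).T
    mu = np.trace(gram) / np.trace(noise_cov)
    return np.linalg.solve((gram + lam * mu * noise_cov).T, lr).T


def estimate_currents(
    session,
    lf: LeadField,
    cfg: InverseConfig | None = None,
    store_traces: bool = False,
) -> CurrentEstimate:
    """Apply the inverse filter to each cue-aligned trial.

    The noise covariance is estimated from the baseline window of every
    trial; one filter is computed per session and applied trial by trial.
    """
    cfg = cfg or InverseConfig()
    cfg.validate()
    if lf.matrix.shape[0] != session.sensor_array.n_sensors:
        raise GeometryError("lead field does not match the session's array")
    rate = session.rate
    cues = session.schedule.cue_times
    b0, b1 = cfg.baseline_window_ms
    e0, e1 = cfg.escp_window_ms

    def _epoch(t_cue, w0, w1):
        i0 = int(round(t_cue * rate + w0 * rate / 1000.0))
        i1 = int(round(t_cue * rate + w1 * rate / 1000.0))
        if i0 < 0 or i1 > session.n_samples:
            raise InvalidConfigError("trial window outside the session")
        return session.data[:, i0:i1]

    baseline = np.concatenate([_epoch(t, b0, b1) for t in cues], axis=1)
    baseline = baseline - baseline.mean(axis=1, keepdims=True)
    noise_cov = baseline @ baseline.T / baseline.shape[1]
    w = make_inverse_filter(lf, noise_cov, cfg.lam)

    n_trials = len(cues)
    escp_raw = np.empty((n_trials, lf.mesh.n_vertices))
    base_means = np.empty_like(escp_raw)
    traces = [] if store_traces else None
    for i, t in enumerate(cues):
        cur = w @ _epoch(t, e0, e1)
        escp_raw[i] = cur.mean(axis=1)
        base_means[i] = (w @ _epoch(t, b0, b1)).mean(axis=1)
        if store_traces:
            full = w @ _epoch(t, b0, e1 + 500.0)
            traces.append(full)
    if not np.all(np.isfinite(escp_raw)):
        raise ConditioningError("non-finite current estimates")
    mu = base_means.mean(axis=0)
    sd = base_means.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    escp = (escp_raw - mu) / sd
    kw = {}
    if store_traces:
        kw["traces"] = np.stack(traces)
        kw["trace_times_ms"] = np.arange(b0, e1 + 500.0, 1000.0 / rate)
    return CurrentEstimate(
        escp_raw=escp_raw,
        escp=escp,
        trial_types=tuple(session.schedule.cue_types),
        inverse_filter=w,
        **kw,
    )


# --------------------------------------------------------------------------
# group statistics
# --------------------------------------------------------------------------

def escp_anova_map(
    escp_by_type: dict, alpha: float = 0.05
) -> dict:
    """Per-vertex one-way ANOVA of eSCP across movement-type trial groups.

    Returns F and p per vertex and a display mask at p < alpha (unadjusted,
    as the analysis reports it).
    """
    groups = list(escp_by_type.values())
    if len(groups) < 2:
        raise StratificationError("need at least two movement-type groups")
    for g in groups:
        if np.asarray(g).shape[0] < 2:
            raise StratificationError(
                "each group needs >= 2 trials for the ANOVA"
            )
    f, p = spstats.f_oneway(*[np.asarray(g) for g in groups], axis=0)
    return {"F": f, "p": p, "mask": p < alpha, "alpha": alpha}
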