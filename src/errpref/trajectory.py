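"""Obstacle-avoiding reaching trajectories from a modulated dynamical system.

A nominal first-order attractor dynamics ``xdot = f(x)`` is locally deformed
around a convex obstacle by a state-dependent modulation matrix,

    xdot = M(x; rho, Gamma(x)) f(x),        M = E D E^{-1},

where the first column of ``E`` is the outward normal of the obstacle's
isopotential ``Gamma`` and ``D`` holds the eigenvalues

    lambda_n = 1 - Gamma^{-1/rho}   (normal),
    lambda_t = 1 + Gamma^{-1/rho}   (tangent, all d-1 directions).

``Gamma(x) = sum_i ((x_i - c_i) / (s a_i))^(2 p_i)`` equals 1 on the
(safety-inflated) obstacle boundary and grows without bound away from it.
The reactivity ``rho`` controls how far from the obstacle the deflection
starts; the safety factor ``s`` scales the obstacle's virtual size.

Each trajectory is summarised by two costs: *energy efficiency* (total path
length travelled) and *comfort* (minimum clearance between the end-effector
and the obstacle surface).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ObstacleModel",
    "ControllerParams",
    "NominalDynamics",
    "Trajectory",
    "TrajectoryCosts",
    "InvalidObstacleError",
    "DegenerateGeometryError",
    "InvalidStartError",
    "UndefinedMetricError",
    "gamma",
    "gamma_gradient",
    "basis_matrix",
    "eigenvalue_matrix",
    "modulation_matrix",
    "integrate_trajectory",
    "simulate_costs",
    "path_length",
    "min_obstacle_distance",
    "surface_distance",
    "expected_full_trajectory",
    "deviation_onset",
    "default_workspace",
]


class InvalidObstacleError(ValueError):
    """Obstacle parameters violate their constraints (non-positive scales...)."""


class DegenerateGeometryError(ValueError):
    """The modulation geometry is undefined (e.g. query at the obstacle center)."""


class InvalidStartError(ValueError):
    """Integration started inside the (inflated) obstacle."""


class UndefinedMetricError(ValueError):
    """A trajectory metric was requested on a degenerate trajectory."""


@dataclass(frozen=True)
class ObstacleModel:
    """Convex super-ellipsoidal obstacle ``Gamma(x) = sum ((x_i-c_i)/a_i)^(2 p_i)``.

    Parameters
    ----------
    center : array_like, shape (d,)
        Obstacle center in workspace coordinates.
    axis_scales : array_like, shape (d,)
        Per-axis scale ``a`` (strictly positive).
    shape_exponents : array_like of int, shape (d,)
        Per-axis exponent ``p`` (integers >= 1). ``p = 1`` gives an ellipsoid.
    """

    center: np.ndarray
    axis_scales: np.ndarray
    shape_exponents: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "axis_scales", np.asarray(self.axis_scales, dtype=float))
        p = np.asarray(self.shape_exponents)
        if np.any(self.axis_scales <= 0):
            raise InvalidObstacleError("axis_scales must be strictly positive")
        if np.any(p < 1) or not np.issubdtype(p.dtype, np.integer):
            raise InvalidObstacleError("shape_exponents must be integers >= 1")
        object.__setattr__(self, "shape_exponents", p.astype(int))

    @property
    def ndim(self) -> int:
        return self.center.size

    @property
    def is_ellipsoid(self) -> bool:
        return bool(np.all(self.shape_exponents == 1))


@dataclass(frozen=True)
class ControllerParams:
    """Reactivity/safety pair plus integration settings.

    ``reactivity`` (rho, dimensionless, sampled in [1, 8]) sets how early the
    deflection from the nominal path begins; ``safety`` (s >= 1, sampled in
    [1.0, 1.5]) inflates the obstacle's virtual size.
    """

    reactivity: float
    safety: float
    dt: float = 0.002
    max_steps: int = 20000

    def __post_init__(self):
        if self.reactivity < 1:
            raise ValueError("reactivity rho must be >= 1")
        if self.safety < 1.0:
            raise ValueError("safety s must be >= 1.0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


@dataclass(frozen=True)
class NominalDynamics:
    """Linear attractor ``f(x) = gain * (target - x)``; fixed point at target."""

    target: np.ndarray
    gain: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "target", np.asarray(self.target, dtype=float))
        if self.gain <= 0:
            raise ValueError("gain must be positive")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.gain * (self.target - np.asarray(x, dtype=float))


@dataclass
class Trajectory:
    """Uniformly sampled end-effector path; ``completed`` marks target reach."""

    states: np.ndarray  # (T, d)
    times: np.ndarray  # (T,)
    completed: bool


@dataclass(frozen=True)
class TrajectoryCosts:
    """Energy efficiency (path length) and comfort (minimum obstacle clearance)."""

    efficiency: float
    comfort: float


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def gamma(x, obstacle: ObstacleModel, s: float = 1.0):
    """Isopotential value Gamma(x; s) = sum_i ((x_i - c_i)/(s a_i))^(2 p_i).

    Equals 1 on the s-inflated boundary, 0 at the center, and increases
    without bound away from the obstacle. Vectorised over leading axes of x.
    """
    if s < 1.0 and not np.isclose(s, 1.0):
        raise ValueError("safety s must be >= 1")
    x = np.asarray(x, dtype=float)
    u = (x - obstacle.center) / (s * obstacle.axis_scales)
    return np.sum(u ** (2 * obstacle.shape_exponents), axis=-1)


def gamma_gradient(x, obstacle: ObstacleModel, s: float = 1.0):
    """Gradient of Gamma with respect to x (vectorised over leading axes)."""
    x = np.asarray(x, dtype=float)
    a = s * obstacle.axis_scales
    u = (x - obstacle.center) / a
    return (2 * obstacle.shape_exponents / a) * u ** (2 * obstacle.shape_exponents - 1)


def basis_matrix(x, obstacle: ObstacleModel, s: float = 1.0) -> np.ndarray:
    """Orthonormal basis E whose first column is the outward normal n(x).

    The remaining d-1 columns span the tangent plane of the Gamma isoline.
    Deterministic (QR completion with a sign fix).
    """
    g = gamma_gradient(x, obstacle, s)
    norm = np.linalg.norm(g)
    if norm < 1e-12:
        raise DegenerateGeometryError("zero Gamma gradient (query at obstacle center?)")
    n = g / norm
    d = n.size
    A = np.column_stack([n, np.eye(d)])
    Q = np.linalg.qr(A)[0]
    if np.dot(Q[:, 0], n) < 0:
        Q = -Q
    return Q


def eigenvalue_matrix(gamma_value: float, rho: float, d: int) -> np.ndarray:
    """Diagonal modulation eigenvalues diag(lambda_n, lambda_t, ..., lambda_t).

    lambda_n = 1 - Gamma^{-1/rho} scales the normal velocity component (0 on
    the boundary, blocking approach); all tangent eigenvalues are set to
    lambda_t = 1 + Gamma^{-1/rho} (symmetric tangent amplification).
    """
    if gamma_value <= 0:
        raise DegenerateGeometryError("Gamma must be positive")
    if rho < 1:
        raise ValueError("rho must be >= 1")
    inv = gamma_value ** (-1.0 / rho)
    lam = np.full(d, 1.0 + inv)
    lam[0] = 1.0 - inv
    return np.diag(lam)


def modulation_matrix(x, params: ControllerParams, obstacle: ObstacleModel) -> np.ndarray:
    """Modulation matrix M(x) = E D E^{-1}; M -> I far from the obstacle."""
    g = gamma(x, obstacle, params.safety)
    if g <= 0:
        raise DegenerateGeometryError("Gamma must be positive for modulation")
    E = basis_matrix(x, obstacle, params.safety)
    D = eigenvalue_matrix(g, params.reactivity, E.shape[0])
    return E @ D @ E.T


# ---------------------------------------------------------------------------
# Surface distance
# ---------------------------------------------------------------------------

def _surface_scale(x, obstacle: ObstacleModel):
    """Scale k such that center + k*(x-center) lies on the obstacle surface.

    Vectorised bisection on the monotone map k -> Gamma(center + k u); for an
    ellipsoid (all p = 1) the closed form k = Gamma^{-1/2} is used.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    g = gamma(x, obstacle)
    if obstacle.is_ellipsoid:
        with np.errstate(divide="ignore"):
            return 1.0 / np.sqrt(g)
    u = x - obstacle.center
    w = ((u / obstacle.axis_scales) ** (2 * obstacle.shape_exponents))
    p2 = 2 * obstacle.shape_exponents

    def gk(k):
        return np.sum(w * k[:, None] ** p2, axis=-1)

    lo = np.zeros(len(x))
    hi = np.ones(len(x))
    while np.any(gk(hi) < 1.0):  # points inside: expand bracket
        hi = np.where(gk(hi) < 1.0, hi * 2.0, hi)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        inside = gk(mid) < 1.0
        lo = np.where(inside, mid, lo)
        hi = np.where(inside, hi, mid)
    return 0.5 * (lo + hi)


def surface_distance(x, obstacle: ObstacleModel):
    """Signed distance from x to the obstacle surface along the ray to center.

    Positive outside, negative inside. Vectorised over rows of x.
    """
    x2 = np.atleast_2d(np.asarray(x, dtype=float))
    k = _surface_scale(x2, obstacle)
    r = np.linalg.norm(x2 - obstacle.center, axis=-1)
    d = r * (1.0 - k)
    return d[0] if np.ndim(x) == 1 else d


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

_TANGENT_NUDGE = 1e-2       # symmetry-breaking tangential kick (fraction of speed)
_NUDGE_GAMMA_MAX = 1e4      # only nudge within this Gamma range of the obstacle


def _tangent_direction(n: np.ndarray) -> np.ndarray:
    """A deterministic unit vector orthogonal to each row of n (3-D)."""
    z = np.zeros_like(n)
    z[:, 2] = 1.0
    t = np.cross(n, z)
    bad = np.linalg.norm(t, axis=1) < 1e-8
    if np.any(bad):
        y = np.zeros_like(n[bad])
        y[:, 1] = 1.0
        t[bad] = np.cross(n[bad], y)
    return t / np.linalg.norm(t, axis=1, keepdims=True)


def _integrate_batch(starts, nominal, rho, s, obstacle, dt, max_steps,
                     target_tol, record_states=False):
    """Euler-integrate a batch of trajectories sharing nominal dynamics.

    Returns dict with path lengths, minimum surface clearance, minimum
    inflated-Gamma value, completion flags, step counts, and (optionally)
    the full state history (n, T, d).
    """
    x = np.atleast_2d(np.asarray(starts, dtype=float)).copy()
    nb, d = x.shape
    rho = np.broadcast_to(np.asarray(rho, dtype=float), (nb,)).copy()
    s = np.broadcast_to(np.asarray(s, dtype=float), (nb,)).copy()
    g0 = _gamma_rows(x, s, obstacle)
    if np.any(g0 <= 1.0):
        raise InvalidStartError("start position inside the inflated obstacle")

    active = np.ones(nb, dtype=bool)
    plen = np.zeros(nb)
    min_clear = surface_distance(x, obstacle)
    min_gamma = g0.copy()
    nsteps = np.zeros(nb, dtype=int)
    history = [x.copy()] if record_states else None

    # group identical (rho, s) rows for vectorised modulation
    for step in range(max_steps):
        if not active.any():
            break
        xa = x[active]
        f = nominal(xa)
        v = _modulated_velocity_rows(xa, f, rho[active], s[active], obstacle)
        step_vec = v * dt
        x[active] = xa + step_vec
        plen[active] += np.linalg.norm(step_vec, axis=1)
        sd = surface_distance(x[active], obstacle)
        min_clear[active] = np.minimum(min_clear[active], sd)
        gs = _gamma_rows(x[active], s[active], obstacle)
        min_gamma[active] = np.minimum(min_gamma[active], gs)
        nsteps[active] += 1
        if record_states:
            history.append(x.copy())
        reached = np.linalg.norm(x - nominal.target, axis=1) < target_tol
        active &= ~reached

    out = {
        "states": x,
        "path_length": plen,
        "min_clearance": min_clear,
        "min_gamma": min_gamma,
        "completed": ~active,
        "n_steps": nsteps,
    }
    if record_states:
        out["history"] = np.stack(history, axis=1)  # (n, T, d)
    return out


def _gamma_rows(x, s, obstacle):
    u = (x - obstacle.center) / (s[:, None] * obstacle.axis_scales)
    return np.sum(u ** (2 * obstacle.shape_exponents), axis=-1)


def _modulated_velocity_rows(x, f, rho, s, obstacle):
    """Row-wise (rho_i, s_i) variant of :func:`_modulated_velocity`."""
    a = s[:, None] * obstacle.axis_scales
    u = (x - obstacle.center) / a
    p = obstacle.shape_exponents
    g = np.sum(u ** (2 * p), axis=-1)
    grad = (2 * p / a) * u ** (2 * p - 1)
    gn = np.linalg.norm(grad, axis=1, keepdims=True)
    n = grad / np.maximum(gn, 1e-300)
    inv = np.clip(g, 1e-12, None) ** (-1.0 / rho)
    vn = np.sum(f * n, axis=1, keepdims=True)
    vt = f - vn * n
    speed = np.linalg.norm(f, axis=1)
    headon = (
        (np.linalg.norm(vt, axis=1) < 1e-6 * np.maximum(speed, 1e-300))
        & (vn[:, 0] < 0)
        & (g < _NUDGE_GAMMA_MAX)
        & (g > 0)
    )
    if np.any(headon):
        t = _tangent_direction(n[headon])
        f = f.copy()
        f[headon] += _TANGENT_NUDGE * speed[headon, None] * t
        vn = np.sum(f * n, axis=1, keepdims=True)
    lam_t = 1.0 + inv
    lam_n = 1.0 - inv
    return lam_t[:, None] * f + ((lam_n - lam_t)[:, None]) * vn * n


def integrate_trajectory(start, nominal: NominalDynamics, params: ControllerParams,
                         obstacle: ObstacleModel, target_tol: float = 1e-3) -> Trajectory:
    """Fixed-step Euler integration of xdot = M(x) f(x) until the target.

    Stops when within ``target_tol`` of the attractor or after
    ``params.max_steps`` steps (then ``completed`` is False). Deterministic:
    identical inputs give bitwise-identical state sequences.
    """
    start = np.asarray(start, dtype=float)
    out = _integrate_batch(
        start[None, :], nominal, params.reactivity, params.safety, obstacle,
        params.dt, params.max_steps, target_tol, record_states=True)
    T = out["n_steps"][0] + 1
    states = out["history"][0, :T]
    times = np.arange(T) * params.dt
    return Trajectory(states=states, times=times, completed=bool(out["completed"][0]))


def simulate_costs(rho, s, nominal: NominalDynamics, obstacle: ObstacleModel,
                   start, dt: float = 0.002, max_steps: int = 20000,
                   target_tol: float = 1e-3):
    """Batch-simulate trials and return (efficiency, comfort, min_gamma, completed).

    ``efficiency`` is the travelled path length, ``comfort`` the minimum
    clearance to the obstacle surface (clamped at 0 — a non-positive value is
    a collision), and ``min_gamma`` the minimum of the safety-inflated Gamma
    along the path (impenetrability diagnostic; >= 1 means never inside the
    inflated boundary).
    """
    rho = np.atleast_1d(np.asarray(rho, dtype=float))
    s = np.atleast_1d(np.asarray(s, dtype=float))
    starts = np.broadcast_to(np.asarray(start, dtype=float), (len(rho), len(nominal.target)))
    out = _integrate_batch(starts, nominal, rho, s, obstacle, dt, max_steps, target_tol)
    comfort = np.maximum(out["min_clearance"], 0.0)
    return out["path_length"], comfort, out["min_gamma"], out["completed"]


# ---------------------------------------------------------------------------
# Trajectory costs
# ---------------------------------------------------------------------------

def path_length(traj: Trajectory) -> float:
    """Total distance travelled: sum of consecutive Euclidean step lengths."""
    if traj.states.shape[0] < 2:
        raise UndefinedMetricError("path length needs at least two states")
    steps = np.diff(traj.states, axis=0)
    return float(np.sum(np.linalg.norm(steps, axis=1)))


def min_obstacle_distance(traj: Trajectory, obstacle: ObstacleModel,
                          reference: str = "surface") -> float:
    """Minimum distance between the end-effector and the obstacle.

    ``reference="surface"`` (default) measures clearance to the obstacle
    surface along the ray to its center; ``"center"`` measures distance to the
    obstacle center.
    """
    if traj.states.shape[0] < 1:
        raise UndefinedMetricError("empty trajectory")
    if reference == "center":
        return float(np.min(np.linalg.norm(traj.states - obstacle.center, axis=1)))
    if reference != "surface":
        raise ValueError("reference must be 'surface' or 'center'")
    return float(np.min(surface_distance(traj.states, obstacle)))


def expected_full_trajectory(params: ControllerParams, nominal: NominalDynamics,
                             obstacle: ObstacleModel, start) -> TrajectoryCosts:
    """Costs of the complete trajectory the controller would have produced.

    Interrupted (erroneous) trials are evaluated on the full simulated path
    for their (rho, s) — the observer is assumed to judge the forward-model
    prediction of the whole movement, so interruption never changes costs.
    """
    traj = integrate_trajectory(start, nominal, params, obstacle)
    eff = path_length(traj)
    comfort = max(0.0, min_obstacle_distance(traj, obstacle))
    return TrajectoryCosts(efficiency=eff, comfort=comfort)


def deviation_onset(traj: Trajectory, start, target, threshold: float = 5e-3) -> float:
    """Arc-length fraction at which the path first deviates from the straight
    start-target line by more than ``threshold``; 1.0 if it never does."""
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)
    u = target - start
    u = u / np.linalg.norm(u)
    rel = traj.states - start
    along = rel @ u
    perp = rel - np.outer(along, u)
    dist = np.linalg.norm(perp, axis=1)
    idx = np.nonzero(dist > threshold)[0]
    if idx.size == 0:
        return 1.0
    steps = np.linalg.norm(np.diff(traj.states, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(steps)])
    return float(arc[idx[0]] / arc[-1])


def default_workspace():
    """Default left-to-right reach over a table with a central obstacle.

    Returns ``(obstacle, nominal, start)``: a vertical ellipsoid (wine-glass
    envelope, a = (0.12, 0.12, 0.20) m) at the origin, a unit-gain attractor
    at (0.5, 0, 0), and the start at (-0.5, 0, 0).
    """
    obstacle = ObstacleModel(center=np.zeros(3),
                             axis_scales=np.array([0.12, 0.12, 0.20]),
                             shape_exponents=np.array([1, 1, 1]))
    nominal = NominalDynamics(target=np.array([0.5, 0.0, 0.0]), gain=1.0)
    start = np.array([-0.5, 0.0, 0.0])
    return obstacle, nominal, start
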