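"""Verification analytics for the simulator.

Covers: the analytic Fisher-KPP traveling-wave profile and front-speed
measurement; an L2 convergence score for profile comparison; closed-form
Schnakenberg steady states with Hopf-point location and the Turing
(diffusion-driven) instability band; and per-sample spatial summary
statistics.

For the Schnakenberg kinetics

    dU/dt = k1 - k_-1 U + k3 V U^2,      dV/dt = k2 - k3 V U^2,

the positive steady state is U* = (k1 + k2)/k_-1, V* = k2/(k3 U*^2).
At the steady state the Jacobian has

    trace J = -k_-1 + 2 k2 / U* - k3 U*^2,
    det J   =  k_-1 k3 U*^2  (always positive),

and a Hopf bifurcation sits where trace J = 0 with det J > 0.  Diffusion
destabilises a stable state iff the dispersion polynomial

    h(q^2) = D_U D_V q^4 - (D_V f_U + D_U g_V) q^2 + det J

has two positive real roots; the open interval between them is the band
of linearly growing wavenumbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SchnakenbergParams",
    "WaveMeasurement",
    "fisher_analytic_profile",
    "measure_wave_speed",
    "l2_convergence_score",
    "schnakenberg_steady_state",
    "schnakenberg_jacobian",
    "hopf_point",
    "turing_band",
    "spatial_summary",
]


@dataclass
class SchnakenbergParams:
    k1: float
    k_minus1: float
    k2: float
    k3: float
    d_u: float = 0.0
    d_v: float = 0.0

    def __post_init__(self):
        if self.k_minus1 <= 0 or self.k3 <= 0 or min(self.k1, self.k2) < 0:
            raise ValueError("rate constants must be positive "
                             "(k1, k2 may be zero)")
        if min(self.d_u, self.d_v) < 0:
            raise ValueError("diffusivities must be non-negative")


@dataclass
class WaveMeasurement:
    times: np.ndarray
    front_positions: np.ndarray
    speed: float
    window: tuple


def fisher_analytic_profile(z, c, order=1):
    """Traveling-wave profile U(z), z = x - c t, of the unit logistic front.

    ``order`` 0 is the logistic sigmoid 1 / (1 + e^{z/c}); order 1 adds
    the 1/c^2 correction term of the large-speed expansion.
    """
    if c <= 0:
        raise ValueError("wave speed must be positive")
    z = np.asarray(z, dtype=float)
    # form the exponential stably on both tails
    w = np.exp(-np.abs(z) / c)
    sig = np.where(z >= 0, w / (1.0 + w), 1.0 / (1.0 + w))
    u = sig
    if order >= 1:
        # e^{z/c} / (1 + e^{z/c})^2 = sig * (1 - sig), stable everywhere
        g = sig * (1.0 - sig)
        with np.errstate(divide="ignore"):
            log_term = np.where(g > 0, np.log(4.0 * g), 0.0)
        u = u + (g / c**2) * log_term
    return u


def _front_crossing(x, u, level):
    """Rightmost downward crossing of ``level``, linearly interpolated."""
    above = u >= level
    idx = None
    for i in range(len(u) - 1):
        if above[i] and not above[i + 1]:
            idx = i
    if idx is None:
        return None
    u0, u1 = u[idx], u[idx + 1]
    frac = (u0 - level) / (u0 - u1)
    return x[idx] + frac * (x[idx + 1] - x[idx])


def measure_wave_speed(trajectory, species=0, level=0.5, window=0.5, y=None):
    """Front speed from mid-height level-set positions on the mid slice.

    The front is the rightmost interpolated downward crossing of
    ``level`` on the 1D slice at mid-domain height.  The speed is the
    least-squares slope of front position against time over the last
    ``window`` fraction of valid samples (late-time, past the
    accelerating transient).
    """
    x, profiles = trajectory.slice_values(species, y=y)
    times, fronts = [], []
    for t, u in zip(trajectory.times, profiles):
        pos = _front_crossing(x, u, level)
        if pos is not None:
            times.append(t)
            fronts.append(pos)
    if len(times) < 3:
        raise ValueError(
            "fewer than 3 samples contain a front crossing; cannot fit")
    times = np.array(times)
    fronts = np.array(fronts)
    start = int(np.floor(len(times) * (1.0 - window)))
    start = min(start, len(times) - 3)
    t_w, f_w = times[start:], fronts[start:]
    slope = np.polyfit(t_w, f_w, 1)[0]
    return WaveMeasurement(times=times, front_positions=fronts,
                           speed=float(slope),
                           window=(float(t_w[0]), float(t_w[-1])))


def l2_convergence_score(sim_profile, reference_profile, cap=0.5,
                         failed=False):
    """Root-mean-square difference of two co-sampled profiles.

    Scores above ``cap`` are reported as ``cap``; a failed (diverged or
    unsolved) run reports 1.0.
    """
    if failed:
        return 1.0
    sim = np.asarray(sim_profile, dtype=float)
    ref = np.asarray(reference_profile, dtype=float)
    if sim.shape != ref.shape:
        raise ValueError(f"profile shapes differ: {sim.shape} vs {ref.shape}")
    score = float(np.sqrt(np.mean((sim - ref) ** 2)))
    return min(score, cap)


def schnakenberg_steady_state(p: SchnakenbergParams):
    """Closed-form positive homogeneous steady state (U*, V*)."""
    u = (p.k1 + p.k2) / p.k_minus1
    v = p.k2 / (p.k3 * u**2)
    return u, v


def schnakenberg_jacobian(p: SchnakenbergParams, u=None, v=None):
    """Jacobian of the reaction kinetics at (u, v) (default: steady state)."""
    if u is None or v is None:
        u, v = schnakenberg_steady_state(p)
    f_u = -p.k_minus1 + 2.0 * p.k3 * u * v
    f_v = p.k3 * u**2
    g_u = -2.0 * p.k3 * u * v
    g_v = -p.k3 * u**2
    return np.array([[f_u, f_v], [g_u, g_v]])


def _trace_at_u(u, k_minus1, k2, k3):
    # at the steady state k3 V U^2 = k2, so 2 k3 U V = 2 k2 / U
    return -k_minus1 + 2.0 * k2 / u - k3 * u**2


def hopf_point(k_minus1, k2, k3, u_max=None, tol=1e-10):
    """Hopf bifurcation of the Schnakenberg kinetics in k1.

    Solves trace J(U*) = -k_-1 + 2 k2/U - k3 U^2 = 0 for the unique
    positive root (the trace is strictly decreasing in U), then recovers
    k1* = k_-1 U* - k2.  Returns ``(k1_star, u_star)``, or None if the
    root does not correspond to a genuine Hopf point (det J <= 0) or k1
    would be non-positive.
    """
    if min(k_minus1, k2, k3) <= 0:
        raise ValueError("rate constants must be positive")
    lo = 1e-9
    if u_max is None:
        u_max = 10.0 * (k_minus1 + k2 + k3)
    f = lambda u: _trace_at_u(u, k_minus1, k2, k3)
    if f(lo) <= 0 or f(u_max) >= 0:
        return None
    u_star = brentq(f, lo, u_max, xtol=tol)
    k1_star = k_minus1 * u_star - k2
    if k1_star <= 0:
        return None
    p = SchnakenbergParams(k1_star, k_minus1, k2, k3)
    if np.linalg.det(schnakenberg_jacobian(p)) <= 0:
        return None
    return k1_star, u_star


def turing_band(p: SchnakenbergParams):
    """Band of diffusion-destabilised squared wavenumbers, or None.

    Requires the steady state to be stable without diffusion (trace < 0,
    det > 0); otherwise the band is empty by definition.  Returns
    ``(q2_minus, q2_plus)`` when the dispersion quadratic has two
    positive roots, else None.
    """
    J = schnakenberg_jacobian(p)
    trace = J[0, 0] + J[1, 1]
    det = float(np.linalg.det(J))
    if not (trace < 0 and det > 0):
        return None
    if p.d_u <= 0 or p.d_v <= 0:
        return None
    b = p.d_v * J[0, 0] + p.d_u * J[1, 1]
    a = p.d_u * p.d_v
    disc = b**2 - 4.0 * a * det
    if b <= 0 or disc <= 0:
        return None
    root = np.sqrt(disc)
    return ((b - root) / (2.0 * a), (b + root) / (2.0 * a))


def dispersion_growth_rate(p: SchnakenbergParams, q2):
    """Largest eigenvalue real part of J - q^2 diag(D_U, D_V)."""
    J = schnakenberg_jacobian(p)
    A = J - np.asarray(q2) * np.diag([p.d_u, p.d_v]) if np.isscalar(q2) \
        else None
    if A is not None:
        return float(np.max(np.linalg.eigvals(A).real))
    return np.array([dispersion_growth_rate(p, q) for q in q2])


def spatial_summary(trajectory):
    """Per-sample mean/min/max/quartiles/std per species over the nodes.

    Returns a dict ``species -> record array`` with fields time, mean,
    min, q25, median, q75, max, std.
    """
    out = {}
    fields = np.array(trajectory.fields)     # (n_samples, n_nodes, n_species)
    if fields.size == 0:
        raise ValueError("empty trajectory")
    for k, name in enumerate(trajectory.species):
        u = fields[:, :, k]
        out[name] = {
            "time": np.array(trajectory.times),
            "mean": u.mean(axis=1),
            "min": u.min(axis=1),
            "q25": np.percentile(u, 25, axis=1),
            "median": np.percentile(u, 50, axis=1),
            "q75": np.percentile(u, 75, axis=1),
            "max": u.max(axis=1),
            "std": u.std(axis=1),
        }
    return out
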