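"""Analytic prediction of stationary phases from network structure.

Two self-consistency solvers predict each node's stationary relative phase
``phi_j*`` in the co-rotating frame, without simulating:

* **MFA** (mean-field approximation): every node is assumed to feel the
  global mean field ``R exp(i Theta)``.  A locked node satisfies

      phi_j* = arcsin(Delta_j / (S/N * n_j * R)) - beta,      (gauge Phi = 0)

  where ``Delta_j = omega_j - Omega`` and ``n_j`` is the weighted degree.
  The pair ``(R, Omega)`` is determined self-consistently from the phases
  it implies.

* **LOP** (local order parameter): each node feels its own local field
  ``r_j exp(i Theta_j) = (1/n_j) sum_k A[j,k] <exp(i phi_k)>``, which makes
  the stationary condition exact rather than mean-field:

      phi_j* = Theta_j - beta + arcsin(Delta_j / (S/N * n_j * r_j)).

  The phase vector is iterated to a damped fixed point, with ``Omega``
  re-solved at every sweep so the population gauge ``Phi = 0`` holds.

In both methods a node is *locked* iff its effective coupling exceeds its
detuning, ``S/N * n_j * R > |Delta_j|`` (MFA) or
``S/N * n_j * r_j > |Delta_j|`` (LOP).  A drifting (unlocked) node has no
fixed phase; its stationary density is ``P(phi) ~ 1/|dphi/dt|`` and it
enters the order parameters through the circular mean of that density.

The principal arcsin branch is used throughout: it is the stable fixed
point of the one-dimensional phase equation (the coupling restores
perturbations when ``cos(Theta_j - phi_j - beta) > 0``).  Because arcsin is
monotonically increasing, a larger degree ``n_j`` (smaller argument) gives
a smaller phase ``phi_j`` -- the hub phase-lag principle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .networks import Network, degrees
from .simulate import SimConfig, wrap_phase

__all__ = [
    "AnalyticSolution",
    "solve_mfa",
    "solve_lop",
    "drift_distribution",
    "drift_phasor",
]


@dataclass
class AnalyticSolution:
    """Stationary-state prediction of one analytic method.

    ``phi_star`` holds the locked fixed-point phase for locked nodes and
    the circular-mean phase of the drift density for unlocked nodes, both
    in (-pi, pi].  ``node_phasor`` is the corresponding complex mean
    ``<exp(i phi_j)>`` (unit modulus when locked, shrunken when drifting);
    order parameters recomputed from it reproduce the stored values.
    """

    method: str
    phi_star: np.ndarray
    locked: np.ndarray
    omega: float
    residual: float
    n_iter: int
    node_phasor: np.ndarray
    global_R: float | None = None
    local_r: np.ndarray | None = None
    local_Theta: np.ndarray | None = None
    node_ids: list[str] | None = None
    degree: np.ndarray | None = None

    @property
    def n_locked(self) -> int:
        return int(self.locked.sum())


# ---------------------------------------------------------------------------
# elementary pieces
# ---------------------------------------------------------------------------


def _locked_phase(delta, K, Theta, beta):
    """Stable fixed point of dphi/dt = Delta + K sin(Theta - phi - beta)."""
    return Theta - beta + np.arcsin(np.clip(delta / K, -1.0, 1.0))


def drift_phasor(delta: float, K: float, Theta: float, beta: float) -> complex:
    """Circular mean ``<exp(i phi)>`` of a drifting node (closed form).

    With ``u = phi - Theta + beta`` the drift is ``du/dt = Delta - K sin u``
    and the stationary density is ``P(u) ~ 1/|Delta - K sin u|``, giving

        <exp(i u)> = i * (Delta - sign(Delta) sqrt(Delta^2 - K^2)) / K.
    """
    if K <= 0:
        return 0.0 + 0.0j
    if abs(delta) <= K:
        raise ValueError("node is locked (|Delta| <= K); no drift density")
    root = np.sign(delta) * np.sqrt(delta * delta - K * K)
    mean_u = 1j * (delta - root) / K
    return complex(mean_u * np.exp(1j * (Theta - beta)))


def _node_phasors(delta, K, Theta, beta):
    """Per-node ``<exp(i phi_j)>`` given field (K_j, Theta_j): locked nodes
    contribute a unit phasor at the fixed point, drifting nodes their
    drift-averaged phasor."""
    delta = np.asarray(delta, dtype=float)
    K = np.asarray(K, dtype=float)
    Theta = np.broadcast_to(np.asarray(Theta, dtype=float), delta.shape)
    locked = K > np.abs(delta)
    z = np.zeros(delta.shape, dtype=complex)
    if locked.any():
        z[locked] = np.exp(
            1j * _locked_phase(delta[locked], K[locked], Theta[locked], beta)
        )
    drifting = ~locked
    if drifting.any():
        d = delta[drifting]
        k = K[drifting]
        with np.errstate(invalid="ignore"):
            root = np.sign(d) * np.sqrt(np.maximum(d * d - k * k, 0.0))
        mean_u = np.where(k > 0, 1j * (d - root) / np.where(k > 0, k, 1.0), 0.0)
        z[drifting] = mean_u * np.exp(1j * (Theta[drifting] - beta))
    return z, locked


def _solve_gauge_omega(omega_nat, K_of_Om, Theta, beta, bracket):
    """Find Omega such that the population mean phasor has zero angle.

    ``K_of_Om`` maps Omega to the per-node effective coupling (it may
    depend on Omega only through nothing -- fields are held frozen during
    the scalar solve).  Bisection/brentq on Im(mean phasor) over
    ``bracket``; the bracket is widened a few times if needed.
    """

    def f(Om):
        z, _ = _node_phasors(omega_nat - Om, K_of_Om, Theta, beta)
        return float(z.mean().imag)

    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    width = hi - lo
    tries = 0
    while flo * fhi > 0 and tries < 6:
        lo -= 0.5 * width
        hi += 0.5 * width
        flo, fhi = f(lo), f(hi)
        tries += 1
    if flo * fhi > 0:
        # no sign change: fall back to the natural-frequency mean
        return float(np.mean(omega_nat))
    return float(brentq(f, lo, hi, xtol=1e-12))


# ---------------------------------------------------------------------------
# MFA
# ---------------------------------------------------------------------------


def solve_mfa(
    network: Network,
    config: SimConfig,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> AnalyticSolution:
    """Mean-field self-consistent stationary phases.

    Iterates the scalar pair ``(R, Omega)``: given ``R``, ``Omega`` is
    chosen by root-finding so the implied population mean phasor has zero
    angle (the gauge ``Phi = 0``); the real part of that phasor is the
    updated ``R``.  An incoherent network (no ``R > 0`` solution) is
    reported as ``R = 0`` with all nodes unlocked, not as an error.
    """
    N = network.n_nodes
    nj = degrees(network, "weighted")
    omega_nat = config.omega(N)
    beta = config.effective_beta(N)
    pref = config.coupling / N
    w_mean = float(omega_nat.mean())
    bracket = (w_mean - max(config.coupling, 1.0), w_mean + max(config.coupling, 1.0))

    R = 0.7
    Omega = w_mean
    damp = 0.5
    last_gap = np.inf
    for it in range(1, max_iter + 1):
        K = pref * nj * R
        Omega = _solve_gauge_omega(omega_nat, K, 0.0, beta, bracket)
        z, locked = _node_phasors(omega_nat - Omega, K, 0.0, beta)
        R_new = float(z.mean().real)
        last_gap = abs(R_new - R)
        if R_new <= 1e-9:
            R = 0.0
            break
        R = R + damp * (R_new - R)
        if last_gap < tol:
            break
    else:
        raise RuntimeError(
            f"MFA self-consistency did not converge in {max_iter} iterations "
            f"(last residual {last_gap:.3e})"
        )

    if R == 0.0:
        z = np.zeros(N, dtype=complex)
        locked = np.zeros(N, dtype=bool)
        phi = np.zeros(N)
        residual = 0.0
    else:
        K = pref * nj * R
        z, locked = _node_phasors(omega_nat - Omega, K, 0.0, beta)
        phi = np.angle(z)
        delta = omega_nat - Omega
        residual = _stationarity_residual(delta, K, 0.0, beta, phi, locked)
        residual = max(residual, abs(float(z.mean().imag)), last_gap)
    return AnalyticSolution(
        method="MFA",
        phi_star=wrap_phase(phi),
        locked=locked,
        omega=Omega,
        residual=residual,
        n_iter=it,
        node_phasor=z,
        global_R=R,
        node_ids=list(network.node_ids),
        degree=nj,
    )


def _stationarity_residual(delta, K, Theta, beta, phi, locked):
    """max_j |dphi_j/dt| over locked nodes at the candidate solution."""
    if not np.any(locked):
        return 0.0
    Theta = np.broadcast_to(np.asarray(Theta, dtype=float), np.shape(delta))
    drift = delta + K * np.sin(Theta - phi - beta)
    return float(np.max(np.abs(drift[locked])))


# ---------------------------------------------------------------------------
# LOP
# ---------------------------------------------------------------------------


def solve_lop(
    network: Network,
    config: SimConfig,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    damping: float = 0.3,
    init: str = "mfa",
) -> AnalyticSolution:
    """Local-order-parameter fixed point.

    The state is the vector of node phasors ``z_j = <exp(i phi_j)>``
    together with the collective frequency ``Omega``, which plays the role
    of a nonlinear eigenvalue: a stationary solution exists only at the
    correct ``Omega``.  One sweep computes the local fields
    ``r_j exp(i Theta_j) = (A z)_j / n_j``, evaluates the stationary
    phasor of every node under its frozen local field, and measures the
    residual collective rotation ``alpha`` (the angle of the population
    mean phasor, which the ``Phi = 0`` gauge requires to vanish).  The new
    phasors are de-rotated by ``alpha`` and blended into the state with
    factor ``damping`` while ``Omega`` is nudged by the rotation rate --
    an off-resonant ``Omega`` reveals itself as a steady precession.  If
    the damped iteration fails to converge it is retried once with a third
    of the damping before raising.
    """
    try:
        return _lop_iterate(network, config, tol, max_iter, damping, init)
    except RuntimeError:
        return _lop_iterate(network, config, tol, max_iter, damping / 3.0, init)


def _lop_iterate(network, config, tol, max_iter, damping, init):
    N = network.n_nodes
    A = network.adjacency
    nj = degrees(network, "weighted")
    nj_safe = np.where(nj > 0, nj, 1.0)
    omega_nat = config.omega(N)
    beta = config.effective_beta(N)
    pref = config.coupling / N
    w_mean = float(omega_nat.mean())

    if init == "mfa":
        warm = solve_mfa(network, config, tol=max(tol, 1e-10))
        z = warm.node_phasor.copy()
        Omega = warm.omega
        if warm.global_R == 0.0:
            z = np.ones(N, dtype=complex)  # coherent restart from synchrony
    elif init == "zero":
        z = np.ones(N, dtype=complex)
        Omega = w_mean
    elif init == "random":
        rng = np.random.default_rng(config.seed)
        z = np.exp(1j * rng.uniform(-np.pi, np.pi, N))
        Omega = w_mean
    else:
        raise ValueError(f"unknown init {init!r}; use 'mfa', 'zero' or 'random'")

    step = np.inf
    gain = 0.5  # Omega responds at half the phasor damping
    for it in range(1, max_iter + 1):
        h = (A @ z) / nj_safe
        r = np.abs(h)
        Theta = np.angle(h)
        K = pref * nj * r
        z_new, locked = _node_phasors(omega_nat - Omega, K, Theta, beta)
        mean_phasor = z_new.mean()
        if np.abs(mean_phasor) < 1e-12:
            alpha = 0.0  # incoherent state: gauge angle undefined
        else:
            alpha = float(np.angle(mean_phasor))
        z_new = z_new * np.exp(-1j * alpha)
        step = max(float(np.max(np.abs(z_new - z))), abs(alpha))
        z = z + damping * (z_new - z)
        Omega = Omega + gain * damping * alpha
        if step < tol:
            break
    else:
        raise RuntimeError(
            f"LOP fixed point did not converge in {max_iter} iterations "
            f"(last step {step:.3e}, damping {damping})"
        )

    h = (A @ z) / nj_safe
    r = np.abs(h)
    Theta = np.angle(h)
    K = pref * nj * r
    delta = omega_nat - Omega
    z_fin, locked = _node_phasors(delta, K, Theta, beta)
    phi = np.angle(z_fin)
    residual = _stationarity_residual(delta, K, Theta, beta, phi, locked)
    residual = max(residual, step)
    return AnalyticSolution(
        method="LOP",
        phi_star=wrap_phase(phi),
        locked=locked,
        omega=Omega,
        residual=residual,
        n_iter=it,
        node_phasor=z_fin,
        local_r=r,
        local_Theta=wrap_phase(Theta),
        node_ids=list(network.node_ids),
        degree=nj,
    )


# ---------------------------------------------------------------------------
# drifting nodes
# ---------------------------------------------------------------------------


def drift_distribution(
    node_index: int,
    solution: AnalyticSolution,
    config: SimConfig,
    grid_size: int = 720,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Stationary phase density of a drifting node under its frozen field.

    Returns ``(grid, density, circular_mean)`` with ``grid`` uniform on
    (-pi, pi] and ``density`` normalised so that
    ``sum(density) * (2 pi / grid_size) == 1``.  The density is
    ``P(phi) ~ 1/|Delta_j + K_j sin(Theta_j - phi - beta)|``; near the
    locking boundary (``K_j -> |Delta_j|``) the mass concentrates at the
    would-be locked phase.
    """
    if solution.locked[node_index]:
        raise ValueError(
            f"node {node_index} is phase-locked; use solution.phi_star instead"
        )
    delta, K, Theta = _node_field(node_index, solution, config)
    grid = -np.pi + 2.0 * np.pi * (np.arange(1, grid_size + 1)) / grid_size
    speed = np.abs(delta + K * np.sin(Theta - grid - _beta(solution, config)))
    dens = 1.0 / np.maximum(speed, 1e-300)
    dens /= dens.sum() * (2.0 * np.pi / grid_size)
    mean = float(np.angle((dens * np.exp(1j * grid)).sum()))
    return grid, dens, mean


def _beta(solution: AnalyticSolution, config: SimConfig) -> float:
    return config.effective_beta(len(solution.phi_star))


def _node_field(node_index, solution, config):
    """(Delta_j, K_j, Theta_j) of one node under the stored solution."""
    N = len(solution.phi_star)
    omega_nat = config.omega(N)
    delta = float(omega_nat[node_index] - solution.omega)
    pref = config.coupling / N
    nj = float(solution.degree[node_index])
    if solution.method == "MFA":
        return delta, pref * nj * float(solution.global_R), 0.0
    return (
        delta,
        pref * nj * float(solution.local_r[node_index]),
        float(solution.local_Theta[node_index]),
    )
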