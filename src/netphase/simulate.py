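"""Numerical integration of the Kuramoto model with frustration or delays.

The dynamical model is

    dtheta_j/dt = omega_j
                  + (S/N) * sum_k A[j, k] * sin(theta_k(t - tau_jk) - theta_j(t) - beta)
                  + xi_j(t)

with ``beta = 0`` in the explicit-delay modes and ``tau_jk = 0`` in the
phase-offset mode.  Small uniform transmission delays ``tau`` are
well-approximated by the phase offset ``beta = omega * tau`` (short-delay
approximation), which is the default operating mode.  ``xi_j`` is Gaussian
noise drawn independently at every Euler step; see
``SimConfig.noise_convention`` for the two supported scalings (per-step,
the default, and continuous white noise / Euler--Maruyama).

Besides the single-run :func:`simulate`, the module provides
:func:`ensemble_phase_statistics`, a batched integrator that runs many
noise/initial-condition realisations at once and accumulates the
run-averaged quantities the analysis needs (time-averaged relative phases,
the pairwise dPLI matrix, and the collective frequency) without storing
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .networks import Network

__all__ = [
    "SimConfig",
    "PhaseTrajectory",
    "EnsembleStats",
    "simulate",
    "ensemble_phase_statistics",
    "collective_frequency",
    "relative_phases",
    "wrap_phase",
    "global_order_parameter",
]

TWO_PI = 2.0 * np.pi


def wrap_phase(x: np.ndarray | float) -> np.ndarray:
    """Wrap angles to the interval (-pi, pi]."""
    w = np.mod(x, TWO_PI)
    return np.where(w > np.pi, w - TWO_PI, w)


@dataclass
class SimConfig:
    """All dynamical parameters of a simulation.

    Parameters
    ----------
    coupling
        Global coupling strength ``S`` (the per-edge strength is ``S/N``).
    freq_hz
        Natural frequency in Hz, scalar or per-node; 10 Hz by default
        (alpha-band collective rhythm).
    delay_mode
        ``"offset"`` (phase frustration ``beta``), ``"uniform_delay"``
        (explicit identical delay ``tau_s``), or ``"distance_delay"``
        (per-edge delays ``distance / velocity`` from node coordinates).
    beta_rad
        Phase offset in radians (offset mode).  ``None`` defaults to
        ``omega_mean * 4 ms``, the offset equivalent of the smallest
        standard conduction delay.
    tau_s
        Uniform transmission delay in seconds (uniform_delay mode).
    velocity_m_per_s
        Conduction velocity (distance_delay mode); distances are in mm.
    noise_sd, noise_mean
        Gaussian noise intensity and drift (rad/s).
    noise_convention
        How ``noise_sd`` enters the Euler step.  ``"per_step"`` (default)
        draws the noise once per step and integrates it like the drift,
        ``dtheta += dt * noise_sd * randn()`` -- the convention of typical
        fixed-step neural-simulation code, for which "unit-SD noise" is a
        weak perturbation that leaves the synchronised state intact.
        ``"white"`` treats ``noise_sd`` as the intensity of continuous
        white noise (Euler--Maruyama, ``dtheta += noise_sd * sqrt(dt) *
        randn()``), which at the same nominal SD is a far stronger
        perturbation.
    dt_s, duration_s, transient_s
        Euler--Maruyama step, total integration time, and discarded
        burn-in (default: first half of ``duration_s``).
    seed
        Seed for initial phases and noise.
    n_runs
        Number of independent realisations for run-averaged statistics.
    """

    coupling: float = 5.0
    freq_hz: float | Sequence[float] = 10.0
    delay_mode: str = "offset"
    beta_rad: float | None = None
    tau_s: float | None = None
    velocity_m_per_s: float | None = None
    noise_sd: float = 1.0
    noise_mean: float = 0.0
    noise_convention: str = "per_step"
    dt_s: float = 1e-3
    duration_s: float = 60.0
    transient_s: float | None = None
    seed: int = 0
    n_runs: int = 20

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.coupling < 0:
            raise ValueError("coupling S must be >= 0")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        transient = self.duration_s / 2 if self.transient_s is None else self.transient_s
        if not (self.duration_s > transient >= 0):
            raise ValueError("need duration_s > transient_s >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_convention not in ("per_step", "white"):
            raise ValueError(
                f"unknown noise_convention {self.noise_convention!r}; "
                "use 'per_step' or 'white'"
            )
        if self.delay_mode == "offset":
            if self.tau_s is not None or self.velocity_m_per_s is not None:
                raise ValueError("offset mode takes beta_rad only, not tau_s/velocity")
        elif self.delay_mode == "uniform_delay":
            if self.tau_s is None:
                raise ValueError("uniform_delay mode requires tau_s")
            if self.beta_rad is not None or self.velocity_m_per_s is not None:
                raise ValueError("uniform_delay mode takes tau_s only")
            if self.tau_s < 0 or self.tau_s >= self.duration_s:
                raise ValueError("tau_s must be in [0, duration_s)")
        elif self.delay_mode == "distance_delay":
            if self.velocity_m_per_s is None or self.velocity_m_per_s <= 0:
                raise ValueError("distance_delay mode requires velocity_m_per_s > 0")
            if self.beta_rad is not None or self.tau_s is not None:
                raise ValueError("distance_delay mode takes velocity_m_per_s only")
        else:
            raise ValueError(f"unknown delay_mode {self.delay_mode!r}")

    # -- derived quantities -------------------------------------------------
    def omega(self, n_nodes: int) -> np.ndarray:
        """Natural frequencies in rad/s, broadcast to ``n_nodes``."""
        w = TWO_PI * np.asarray(self.freq_hz, dtype=float)
        return np.broadcast_to(w, (n_nodes,)).copy()

    @property
    def transient(self) -> float:
        return self.duration_s / 2 if self.transient_s is None else self.transient_s

    def noise_step_sd(self) -> float:
        """Standard deviation of the per-step noise increment (rad)."""
        if self.noise_convention == "white":
            return self.noise_sd * np.sqrt(self.dt_s)
        return self.noise_sd * self.dt_s

    def effective_beta(self, n_nodes: int = 1) -> float:
        """Phase offset used by the analytic solvers.

        Offset mode returns ``beta_rad`` (default ``omega_mean * 4 ms``);
        delay modes are converted by the short-delay approximation
        ``beta = omega_mean * tau``.
        """
        w_mean = float(np.mean(self.omega(n_nodes)))
        if self.delay_mode == "offset":
            return w_mean * 4e-3 if self.beta_rad is None else self.beta_rad
        if self.delay_mode == "uniform_delay":
            return w_mean * self.tau_s
        raise ValueError(
            "distance_delay has no single offset equivalent; supply an "
            "offset-mode config for the analytic solvers"
        )

    def as_offset(self, n_nodes: int = 1) -> "SimConfig":
        """Equivalent offset-mode configuration (``beta = omega * tau``)."""
        beta = self.effective_beta(n_nodes)
        return replace(
            self, delay_mode="offset", beta_rad=beta, tau_s=None, velocity_m_per_s=None
        )


@dataclass
class PhaseTrajectory:
    """Phase time series theta_j(t), wrapped to (-pi, pi].

    ``phases`` has shape (n_nodes, n_samples) and covers the stationary
    window only (the burn-in is discarded by the integrator).  ``t0_s`` is
    the absolute time of the first stored sample.
    """

    phases: np.ndarray
    dt_s: float
    node_ids: list[str] | None = None
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.ndim != 2:
            raise ValueError("phases must be a (n_nodes, n_samples) matrix")
        if self.node_ids is None:
            self.node_ids = [str(i) for i in range(self.phases.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.phases.shape[0]

    @property
    def n_samples(self) -> int:
        return self.phases.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + self.dt_s * np.arange(self.n_samples)

    def unwrapped(self) -> np.ndarray:
        return np.unwrap(self.phases, axis=1)


@dataclass
class EnsembleStats:
    """Run-averaged stationary statistics of a simulation ensemble."""

    mean_phi: np.ndarray          # time- and run-averaged relative phase (rad)
    dpli: np.ndarray              # pairwise dPLI matrix, antisymmetric
    node_dpli: np.ndarray         # row means of dpli excluding the diagonal
    omega: float                  # collective frequency (rad/s), run average
    omega_per_run: np.ndarray
    n_runs: int
    node_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def _coupling_term(s, c, theta, beta, M):
    """(S/N)-free coupling sum_k A[j,k] sin(theta_k - theta_j - beta).

    Uses sum_k A_jk sin(theta_k - x) = cos(x) (A s)_j - sin(x) (A c)_j with
    x = theta_j + beta; ``M = A.T`` so batched states multiply from the left.
    """
    As = s @ M
    Ac = c @ M
    x = theta + beta
    return np.cos(x) * As - np.sin(x) * Ac


def simulate(network: Network, config: SimConfig) -> PhaseTrajectory:
    """Integrate one realisation and return the stationary trajectory.

    Initial phases are uniform on (-pi, pi]; the burn-in window
    (``config.transient``) is discarded.  Identical seed and config give a
    bit-identical trajectory.
    """
    config.validate()
    if config.delay_mode == "offset":
        return _simulate_offset(network, config)
    return _simulate_delay(network, config)


def _simulate_offset(network: Network, config: SimConfig) -> PhaseTrajectory:
    N = network.n_nodes
    A = network.adjacency
    M = np.ascontiguousarray(A.T)
    omega = config.omega(N)
    beta = config.effective_beta(N)
    S, dt = config.coupling, config.dt_s
    pref = S / N
    step_sd = config.noise_step_sd()
    n_steps = int(round(config.duration_s / dt))
    i0 = int(round(config.transient / dt))

    rng = np.random.default_rng(config.seed)
    theta = rng.uniform(-np.pi, np.pi, N)
    out = np.empty((N, n_steps - i0))
    for step in range(n_steps):
        s = np.sin(theta)
        c = np.cos(theta)
        if step >= i0:
            out[:, step - i0] = theta
        drift = omega + pref * _coupling_term(s, c, theta, beta, M) + config.noise_mean
        theta = theta + dt * drift
        if config.noise_sd:
            theta = theta + step_sd * rng.standard_normal(N)
        if step % 1000 == 0 and not np.all(np.isfinite(theta)):
            raise FloatingPointError(f"non-finite phase at step {step}")
    return PhaseTrajectory(
        wrap_phase(out), dt_s=dt, node_ids=list(network.node_ids), t0_s=i0 * dt
    )


def _simulate_delay(network: Network, config: SimConfig) -> PhaseTrajectory:
    N = network.n_nodes
    A = network.adjacency
    omega = config.omega(N)
    S, dt = config.coupling, config.dt_s
    pref = S / N
    step_sd = config.noise_step_sd()
    n_steps = int(round(config.duration_s / dt))
    i0 = int(round(config.transient / dt))

    if config.delay_mode == "uniform_delay":
        d_steps = np.full((N, N), int(round(config.tau_s / dt)), dtype=int)
    else:
        dist_m = network.distances() * 1e-3  # coordinates are in mm
        d_steps = np.rint(dist_m / config.velocity_m_per_s / dt).astype(int)
    d_steps[A == 0] = 0
    max_d = int(d_steps.max())
    if max_d >= n_steps:
        raise ValueError(
            f"delay of {max_d} steps exceeds the history horizon of "
            f"{n_steps} integration steps"
        )

    # sparse edge arrays: contribution of k onto j with per-edge lag
    jj, kk = np.nonzero(A)
    ww = A[jj, kk]
    dd = d_steps[jj, kk]

    rng = np.random.default_rng(config.seed)
    theta0 = rng.uniform(-np.pi, np.pi, N)
    L = max_d + 1
    hist = np.empty((L, N))
    # backward extrapolation theta(t<0) = theta(0) - omega*|t|
    for b in range(L):
        hist[(-b) % L] = theta0 - omega * (b * dt)
    theta = theta0.copy()
    out = np.empty((N, n_steps - i0))
    for step in range(n_steps):
        if step >= i0:
            out[:, step - i0] = theta
        past = hist[(step - dd) % L, kk]
        contrib = ww * np.sin(past - theta[jj])
        term = np.zeros(N)
        np.add.at(term, jj, contrib)
        theta = theta + dt * (omega + pref * term + config.noise_mean)
        if config.noise_sd:
            theta = theta + step_sd * rng.standard_normal(N)
        hist[(step + 1) % L] = theta
        if step % 1000 == 0 and not np.all(np.isfinite(theta)):
            raise FloatingPointError(f"non-finite phase at step {step}")
    return PhaseTrajectory(
        wrap_phase(out), dt_s=dt, node_ids=list(network.node_ids), t0_s=i0 * dt
    )


def ensemble_phase_statistics(
    network: Network,
    config: SimConfig,
    dpli_interval_s: float = 0.05,
) -> EnsembleStats:
    """Run ``config.n_runs`` realisations and accumulate stationary statistics.

    All runs are integrated simultaneously (state matrix runs x nodes), and
    statistics are accumulated online over the stationary window:

    * ``mean_phi`` -- circular mean over time and runs of
      ``theta_j - Phi(t)`` where ``Phi(t)`` is the instantaneous circular
      mean phase (population gauge ``Phi = 0``);
    * ``dpli`` -- time/run average of ``sign(wrap(theta_i - theta_j))``,
      sampled every ``dpli_interval_s``;
    * ``omega`` -- least-squares slope of the unwrapped mean phase,
      averaged over runs.

    Only the offset mode is batched; delay modes fall back to repeated
    single-run integration.
    """
    config.validate()
    if config.delay_mode != "offset":
        return _ensemble_from_single_runs(network, config, dpli_interval_s)

    N = network.n_nodes
    M = np.ascontiguousarray(network.adjacency.T)
    omega = config.omega(N)
    beta = config.effective_beta(N)
    S, dt = config.coupling, config.dt_s
    pref = S / N
    step_sd = config.noise_step_sd()
    n_steps = int(round(config.duration_s / dt))
    i0 = int(round(config.transient / dt))
    R = config.n_runs
    dpli_every = max(1, int(round(dpli_interval_s / dt)))
    ang_every = 5  # mean-phase samples for the collective-frequency fit

    rng = np.random.default_rng(config.seed)
    theta = rng.uniform(-np.pi, np.pi, (R, N))
    Zrel = np.zeros((R, N), dtype=complex)
    sgn_sum = np.zeros((N, N))
    n_sgn = 0
    n_ang = (n_steps - i0 + ang_every - 1) // ang_every
    mean_ang = np.empty((R, n_ang))
    i_ang = 0
    for step in range(n_steps):
        s = np.sin(theta)
        c = np.cos(theta)
        if step >= i0:
            ph = c + 1j * s
            m = ph.mean(axis=1)
            absm = np.abs(m)
            u = np.where(absm > 0, m / np.where(absm > 0, absm, 1.0), 1.0)
            Zrel += ph * np.conj(u)[:, None]
            if (step - i0) % ang_every == 0:
                mean_ang[:, i_ang] = np.angle(m)
                i_ang += 1
            if (step - i0) % dpli_every == 0:
                # sign(wrap(ti - tj)) == sign(sin(ti - tj))
                d = s[:, :, None] * c[:, None, :] - c[:, :, None] * s[:, None, :]
                sgn_sum += np.sign(d).sum(axis=0)
                n_sgn += R
        drift = omega + pref * _coupling_term(s, c, theta, beta, M) + config.noise_mean
        theta = theta + dt * drift
        if config.noise_sd:
            theta = theta + step_sd * rng.standard_normal((R, N))
        if step % 1000 == 0 and not np.all(np.isfinite(theta)):
            raise FloatingPointError(f"non-finite phase at step {step}")

    mean_phi = np.angle(Zrel.sum(axis=0))
    dpli = sgn_sum / max(n_sgn, 1)
    np.fill_diagonal(dpli, 0.0)
    node_dpli = dpli.sum(axis=1) / max(N - 1, 1)
    t = dt * ang_every * np.arange(i_ang)
    y = np.unwrap(mean_ang[:, :i_ang], axis=1)
    tc = t - t.mean()
    slopes = (y @ tc) / (tc @ tc)
    return EnsembleStats(
        mean_phi=mean_phi,
        dpli=dpli,
        node_dpli=node_dpli,
        omega=float(slopes.mean()),
        omega_per_run=slopes,
        n_runs=R,
        node_ids=list(network.node_ids),
    )


def _ensemble_from_single_runs(
    network: Network, config: SimConfig, dpli_interval_s: float
) -> EnsembleStats:
    from . import directionality as dire

    N = network.n_nodes
    Z = np.zeros(N, dtype=complex)
    sgn = np.zeros((N, N))
    omegas = []
    step = max(1, int(round(dpli_interval_s / config.dt_s)))
    for r in range(config.n_runs):
        cfg = replace(config, seed=config.seed + r, n_runs=1)
        traj = simulate(network, cfg)
        om = collective_frequency(traj)
        omegas.append(om)
        phi_t, phi_mean = relative_phases(traj, om)
        Z += np.exp(1j * phi_mean)
        sub = PhaseTrajectory(traj.phases[:, ::step], traj.dt_s * step, traj.node_ids)
        sgn += dire.dpli_matrix(sub)
    dpli = sgn / config.n_runs
    node_dpli = dpli.sum(axis=1) / max(N - 1, 1)
    return EnsembleStats(
        mean_phi=np.angle(Z),
        dpli=dpli,
        node_dpli=node_dpli,
        omega=float(np.mean(omegas)),
        omega_per_run=np.asarray(omegas),
        n_runs=config.n_runs,
        node_ids=list(network.node_ids),
    )


# ---------------------------------------------------------------------------
# trajectory reductions
# ---------------------------------------------------------------------------


def collective_frequency(traj: PhaseTrajectory) -> float:
    """Collective frequency Omega (rad/s).

    Least-squares slope of the unwrapped circular-mean phase versus time.
    """
    if traj.n_samples < 2:
        raise ValueError("need at least 2 samples to estimate a frequency")
    mean_ang = np.angle(np.exp(1j * traj.phases).mean(axis=0))
    y = np.unwrap(mean_ang)
    t = traj.dt_s * np.arange(y.size)
    tc = t - t.mean()
    return float((y @ tc) / (tc @ tc))


def relative_phases(
    traj: PhaseTrajectory, omega: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Relative phases phi_j(t) in the co-rotating frame, gauge Phi = 0.

    Subtracting the instantaneous circular-mean phase Phi(t) removes the
    collective rotation Omega*t and pins the population mean phase to zero
    at every sample, so the result does not depend on ``omega`` (accepted
    for interface symmetry).  Returns ``(phi_t, phi_mean)`` where ``phi_t``
    is (n_nodes, n_samples) wrapped to (-pi, pi] and ``phi_mean`` is the
    circular mean over the stationary window.
    """
    ph = np.exp(1j * traj.phases)
    m = ph.mean(axis=0)
    absm = np.abs(m)
    u = np.where(absm > 0, m / np.where(absm > 0, absm, 1.0), 1.0)
    rel = ph * np.conj(u)[None, :]
    phi_t = np.angle(rel)
    phi_mean = np.angle(rel.mean(axis=1))
    return phi_t, phi_mean


def global_order_parameter(traj: PhaseTrajectory) -> np.ndarray:
    """R(t): modulus of the population mean phasor at each sample."""
    return np.abs(np.exp(1j * traj.phases).mean(axis=0))
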