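"""Fixed-step integrator for delay differential systems on a shared grid.

Delays must be integer multiples of the step ``dt``, so delayed values are
read directly off the stored grid with no interpolation.  History before
t = 0 is constant at the initial condition.  The main scheme is classical
RK4 with delayed taps evaluated on the half-grid for the interior stages
(linear interpolation between the two bracketing stored points, which are
always in the strict past because the smallest delay far exceeds ``dt``);
a structurally independent forward-Euler integrator serves as a
cross-check oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Trajectory", "integrate", "euler_oracle"]


@dataclass
class Trajectory:
    """Solution on a uniform time grid.

    ``y`` has shape ``(n_steps + 1, *state_shape)`` with ``y[k]`` the state
    at ``t = k * dt``.
    """

    t: np.ndarray
    y: np.ndarray
    dt: float

    @property
    def t_end(self) -> float:
        return float(self.t[-1])

    def at_time(self, time: float) -> np.ndarray:
        """State at a grid time (nearest grid point)."""
        k = int(round(time / self.dt))
        if not 0 <= k < len(self.t):
            raise ValueError(f"time {time} outside trajectory range")
        return self.y[k]

    def window(self, t_start: float, t_end: float):
        """(t, y) restricted to [t_start, t_end] inclusive."""
        mask = (self.t >= t_start - 1e-9) & (self.t <= t_end + 1e-9)
        return self.t[mask], self.y[mask]


def _delay_steps(delays, dt: float) -> dict:
    steps = {}
    for tau in delays:
        if tau < 0:
            raise ValueError("delays must be >= 0")
        m = tau / dt
        if abs(m - round(m)) > 1e-9:
            raise ValueError(f"delay {tau} is not an integer multiple of dt={dt}")
        steps[tau] = int(round(m))
    return steps


def _check_grid(t_end: float, dt: float) -> int:
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t_end < dt:
        raise ValueError("t_end must be >= dt")
    n = t_end / dt
    if abs(n - round(n)) > 1e-9:
        raise ValueError("t_end must be an integer multiple of dt")
    return int(round(n))


def _tap(hist: np.ndarray, k: int, m: int, y0: np.ndarray) -> np.ndarray:
    """Grid state at step k - m; constant initial history for k - m < 0."""
    idx = k - m
    return y0 if idx < 0 else hist[idx]


def _tap_half(hist: np.ndarray, k: int, m: int, y0: np.ndarray) -> np.ndarray:
    """State at t = (k + 1/2 - m) dt by linear interpolation of the grid."""
    a = _tap(hist, k, m, y0)
    b = _tap(hist, k + 1, m, y0)
    return 0.5 * (a + b)


def integrate(rhs, initial, delays, t_end: float, dt: float, clip_negative: bool = True):
    """Integrate ``y'(t) = rhs(t, y, delayed)`` with RK4 on a fixed grid.

    Parameters
    ----------
    rhs:
        Callable ``rhs(t, y, delayed)`` where ``delayed`` maps each delay
        in ``delays`` to the state at ``t - delay``.
    initial:
        Initial state (any array shape); also the constant history.
    delays:
        Iterable of lags (min); each must be a multiple of ``dt`` and, if
        positive, at least ``dt`` (interior-stage taps must lie in the past).
    clip_negative:
        Clip tiny negative undershoots to 0 after each step (the removal
        terms vanish with their species, but a fixed-step scheme can
        undershoot by O(dt^5)).

    Returns
    -------
    Trajectory
    """
    y0 = np.asarray(initial, dtype=float).copy()
    n_steps = _check_grid(t_end, dt)
    dsteps = _delay_steps(delays, dt)
    for tau, m in dsteps.items():
        if m < 1:
            raise ValueError(
                f"delay {tau} must be >= dt; zero-delay terms read the current state"
            )

    hist = np.empty((n_steps + 1,) + y0.shape, dtype=float)
    hist[0] = y0
    t = 0.0
    for k in range(n_steps):
        yk = hist[k]
        d0 = {tau: _tap(hist, k, m, y0) for tau, m in dsteps.items()}
        dh = {tau: _tap_half(hist, k, m, y0) for tau, m in dsteps.items()}
        d1 = {tau: _tap(hist, k + 1, m, y0) for tau, m in dsteps.items()}

        k1 = rhs(t, yk, d0)
        k2 = rhs(t + dt / 2, yk + dt / 2 * k1, dh)
        k3 = rhs(t + dt / 2, yk + dt / 2 * k2, dh)
        k4 = rhs(t + dt, yk + dt * k3, d1)
        ynew = yk + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(ynew)):
            bad = np.argwhere(~np.isfinite(ynew))
            raise FloatingPointError(
                f"non-finite state at t={t + dt:.3f} min, index {bad[0].tolist()}"
            )
        if clip_negative:
            np.clip(ynew, 0.0, None, out=ynew)
        hist[k + 1] = ynew
        t += dt

    tgrid = np.arange(n_steps + 1) * dt
    return Trajectory(t=tgrid, y=hist, dt=dt)


def euler_oracle(rhs, initial, delays, t_end: float, dt: float, clip_negative: bool = True):
    """Forward-Euler reference integrator; independent code path from RK4."""
    y0 = np.asarray(initial, dtype=float).copy()
    n_steps = _check_grid(t_end, dt)
    dsteps = _delay_steps(delays, dt)

    out = [y0]
    y = y0.copy()
    for k in range(n_steps):
        delayed = {}
        for tau, m in dsteps.items():
            idx = k - m
            delayed[tau] = y0 if idx < 0 else out[idx]
        dy = rhs(k * dt, y, delayed)
        y = y + dt * np.asarray(dy, dtype=float)
        if not np.all(np.isfinite(y)):
            raise FloatingPointError(f"non-finite state at t={(k + 1) * dt:.3f} min")
        if clip_negative:
            y = np.clip(y, 0.0, None)
        out.append(y)
    tgrid = np.arange(n_steps + 1) * dt
    return Trajectory(t=tgrid, y=np.stack(out), dt=dt)
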