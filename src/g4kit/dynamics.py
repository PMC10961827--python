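"""Synthetic stochastic dynamics with known kinetics and thermodynamics.

Two generators stand in for molecular-dynamics state and collective
variable (CV) time series:

* a two-state (folded/unfolded) telegraph process with exact exponential
  dwell sampling, for exercising dwell-time and lifetime estimators, and
* overdamped (Euler-Maruyama) Langevin dynamics on an analytic 1D
  potential, optionally with a harmonic umbrella bias, for exercising
  free-energy-profile estimators.

All randomness is drawn from one seeded generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import DwellRecord, StateSeries

__all__ = [
    "TelegraphParams",
    "LangevinParams",
    "Potential",
    "simulate_telegraph",
    "simulate_langevin",
]


@dataclass
class TelegraphParams:
    """Two-state Markov (telegraph) kinetics.

    Rates in 1/ns; the process starts folded (F) and unfolds with rate
    k_unfold, refolds with rate k_fold. The mean folded dwell is
    1/k_unfold.
    """

    k_unfold: float
    k_fold: float
    t_total: float
    dt: float
    seed: int

    def __post_init__(self):
        if self.k_unfold < 0 or self.k_fold < 0:
            raise ValueError("rates must be >= 0")
        if self.dt <= 0 or self.t_total <= 0:
            raise ValueError("dt and t_total must be positive")
        kmax = max(self.k_unfold, self.k_fold)
        if kmax > 0 and self.dt > 0.1 / kmax:
            raise ValueError("dt must be small compared to 1/max(rate)")


def simulate_telegraph(params: TelegraphParams) -> StateSeries:
    """Sample a telegraph process on the dt grid.

    Dwells are drawn exactly from exponential distributions (the grid only
    discretizes reporting, so estimator tests are not biased by the time
    step). The returned series carries the ground-truth event log in
    ``series.events`` (the final event truncated at t_total and flagged
    censored).
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.t_total / params.dt)) + 1
    if n < 1:
        raise ValueError("zero-length series")
    times = np.arange(n) * params.dt
    events: list[DwellRecord] = []
    switch_times = []
    t, state = 0.0, "F"
    while t < params.t_total:
        rate = params.k_unfold if state == "F" else params.k_fold
        dwell = np.inf if rate == 0 else rng.exponential(1.0 / rate)
        end = t + dwell
        if end >= params.t_total:
            events.append(DwellRecord(state, params.t_total - t, censored=True))
            break
        events.append(DwellRecord(state, dwell, censored=False))
        switch_times.append(end)
        t = end
        state = "U" if state == "F" else "F"
    # grid labels: state flips at each switch time
    flips = np.searchsorted(np.asarray(switch_times), times, side="right")
    labels = np.where(flips % 2 == 0, "F", "U")
    series = StateSeries(times=times, labels=labels, censored_tail=True)
    series.events = events
    return series


@dataclass
class Potential:
    """U(x) = a (x^2 - b^2)^2 + c x + 0.5 k_h (x - x0)^2, kcal/mol."""

    a: float = 0.0
    b: float = 0.0
    c: float = 0.0
    k_h: float = 0.0
    x0: float = 0.0

    def __post_init__(self):
        if self.a < 0 or self.k_h < 0:
            raise ValueError("a and k_h must be >= 0")
        if self.a == 0 and self.k_h == 0:
            # force-free diffusion is allowed only when c is also 0
            pass

    def U(self, x):
        x = np.asarray(x, dtype=float)
        return (self.a * (x ** 2 - self.b ** 2) ** 2 + self.c * x
                + 0.5 * self.k_h * (x - self.x0) ** 2)

    def dU(self, x):
        x = np.asarray(x, dtype=float)
        return (4.0 * self.a * x * (x ** 2 - self.b ** 2) + self.c
                + self.k_h * (x - self.x0))


@dataclass
class LangevinParams:
    """Overdamped Langevin dynamics on a 1D potential.

    kT in kcal/mol, D in CV^2/ns, dt in ns. The Euler-Maruyama update is
    x <- x - (D/kT) U'(x) dt + sqrt(2 D dt) xi.
    """

    potential: Potential
    kT: float = 0.596
    D: float = 1.0
    dt: float = 1e-3
    n_steps: int = 100_000
    x_init: float = 0.0
    seed: int = 0
    bias: tuple[float, float] | None = None   # (center, k) umbrella

    def __post_init__(self):
        if self.kT <= 0 or self.D <= 0 or self.dt <= 0 or self.n_steps < 1:
            raise ValueError("kT, D, dt must be positive and n_steps >= 1")


def simulate_langevin(params: LangevinParams) -> np.ndarray:
    """Euler-Maruyama trajectory of length n_steps (initial point excluded).

    An optional harmonic umbrella bias 0.5 k (x - center)^2 is added to
    the potential (for WHAM window generation). Raises if the trajectory
    blows up numerically.
    """
    rng = np.random.default_rng(params.seed)
    pot = params.potential
    mob = params.D / params.kT * params.dt
    sig = np.sqrt(2.0 * params.D * params.dt)
    noise = rng.standard_normal(params.n_steps)
    if params.bias is not None:
        bc, bk = params.bias
    else:
        bc, bk = 0.0, 0.0
    a4 = 4.0 * pot.a
    b2 = pot.b ** 2
    c = pot.c
    kh, x0 = pot.k_h, pot.x0
    bound = 1e6
    x = params.x_init
    out = np.empty(params.n_steps)
    for i in range(params.n_steps):
        grad = a4 * x * (x * x - b2) + c + kh * (x - x0) + bk * (x - bc)
        x = x - mob * grad + sig * noise[i]
        out[i] = x
        if not (-bound < x < bound):
            raise FloatingPointError(
                f"Langevin trajectory diverged at step {i}; "
                f"dt={params.dt} is too large for this potential/D")
    return out
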