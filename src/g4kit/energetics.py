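"""Free-energy-profile estimation: Boltzmann inversion and WHAM.

Profiles are reported in kcal/mol, min-shifted to zero over the sampled
(unmasked) bins. The weighted-histogram analysis method (WHAM) combines
umbrella windows with harmonic biases by self-consistent iteration of the
window free energies; with a single unbiased window it reduces exactly to
Boltzmann inversion of the histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FreeEnergyProfile",
    "pmf_from_samples",
    "wham",
    "profile_stats",
]


@dataclass
class FreeEnergyProfile:
    bin_centers: np.ndarray
    F: np.ndarray              # kcal/mol, NaN on masked (empty) bins
    counts: np.ndarray
    kT: float
    mask: np.ndarray           # True where the bin is unmasked (sampled)
    degenerate: bool = False   # all samples in one bin

    def __post_init__(self):
        if self.mask.any():
            self.F = self.F - np.nanmin(self.F[self.mask])

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])

    def interp(self, x: float) -> float:
        good = self.mask
        return float(np.interp(x, self.bin_centers[good], self.F[good]))

    def to_table(self):
        import pandas as pd
        return pd.DataFrame({"cv": self.bin_centers, "F_kcal_mol": self.F,
                             "counts": self.counts, "sampled": self.mask})

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.bin_centers[self.mask], self.F[self.mask], **kwargs)
        ax.set_xlabel("collective variable")
        ax.set_ylabel("free energy (kcal/mol)")
        return ax


def _grid(samples, bins, range_):
    edges = np.histogram_bin_edges(samples, bins=bins, range=range_)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return edges, centers


def pmf_from_samples(samples, kT: float, bins: int = 100,
                     range_: tuple[float, float] | None = None
                     ) -> FreeEnergyProfile:
    """Boltzmann inversion of a sampled density:
    F_i = -kT ln(c_i / (N dx)), min-shifted; empty bins masked."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("no samples")
    edges, centers = _grid(samples, bins, range_)
    counts, _ = np.histogram(samples, bins=edges)
    mask = counts > 0
    dx = edges[1] - edges[0]
    F = np.full(len(centers), np.nan)
    with np.errstate(divide="ignore"):
        F[mask] = -kT * np.log(counts[mask] / (samples.size * dx))
    return FreeEnergyProfile(centers, F, counts, kT, mask,
                             degenerate=(mask.sum() <= 1))


def wham(window_samples: list, window_biases: list[tuple[float, float]],
         kT: float, bins: int = 100,
         range_: tuple[float, float] | None = None,
         tol: float = 1e-10, max_iter: int = 100_000) -> FreeEnergyProfile:
    """Standard histogram WHAM for harmonic umbrella windows.

    ``window_biases`` holds (center, k) per window with bias
    0.5 k (x - center)^2. Iterates the window free energies f_i until
    max|df| < tol, then returns the unbiased profile. Raises if
    neighbouring windows share no histogram support or on
    non-convergence.
    """
    if len(window_samples) == 0:
        raise ValueError("need at least one window")
    if len(window_samples) != len(window_biases):
        raise ValueError("one bias per window required")
    samples = [np.asarray(s, dtype=float) for s in window_samples]
    allx = np.concatenate(samples)
    edges, centers = _grid(allx, bins, range_)
    dx = edges[1] - edges[0]
    n_win = len(samples)
    hists = np.array([np.histogram(s, bins=edges)[0] for s in samples])

    # overlap check between windows adjacent in bias-center order
    order = np.argsort([c for c, _ in window_biases])
    for w1, w2 in zip(order, order[1:]):
        if not np.any((hists[w1] > 0) & (hists[w2] > 0)):
            c1, c2 = window_biases[w1][0], window_biases[w2][0]
            raise ValueError(
                f"windows centered at {c1:g} and {c2:g} share no histogram "
                "support; add an intermediate window")

    N = hists.sum(axis=1).astype(float)
    H = hists.sum(axis=0).astype(float)
    bias_u = np.array([[0.5 * k * (x - c) ** 2 for x in centers]
                       for c, k in window_biases])        # (n_win, n_bins)
    boltz = np.exp(-bias_u / kT)
    f = np.zeros(n_win)
    for _ in range(max_iter):
        denom = (N * np.exp(f / kT)) @ boltz              # (n_bins,)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, H / denom, 0.0)
        z = boltz @ p                                     # (n_win,)
        f_new = -kT * np.log(z)
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    else:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {np.max(np.abs(f_new - f)):.3e})")
    denom = (N * np.exp(f / kT)) @ boltz
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(denom > 0, H / denom, 0.0)
    mask = H > 0
    F = np.full(len(centers), np.nan)
    with np.errstate(divide="ignore"):
        F[mask] = -kT * np.log(p[mask] / dx)
    return FreeEnergyProfile(centers, F, H.astype(int), kT, mask,
                             degenerate=(mask.sum() <= 1))


@dataclass
class ProfileStats:
    delta_F_fold: float        # F(folded min) - F(unfolded min), kcal/mol
    barrier: float | None      # F(max between minima) - F(folded min)
    folded_min_cv: float
    unfolded_min_cv: float
    barrier_cv: float | None


def profile_stats(profile: FreeEnergyProfile, boundary_cv: float,
                  folded_below: bool = True) -> ProfileStats:
    """Basin and barrier statistics of a two-basin profile.

    The folded basin is the side of ``boundary_cv`` given by
    ``folded_below``; the folding free energy is the difference between
    the basin minima, and the barrier is measured from the folded
    minimum to the highest sampled point between the two minima (flagged
    absent for a monotonic profile).
    """
    x, F, m = profile.bin_centers, profile.F, profile.mask
    below = m & (x < boundary_cv)
    above = m & (x >= boundary_cv)
    if below.sum() < 2 or above.sum() < 2:
        raise ValueError("need >=2 sampled bins on each side of the boundary")
    i_b = np.flatnonzero(below)[np.nanargmin(F[below])]
    i_a = np.flatnonzero(above)[np.nanargmin(F[above])]
    i_fold, i_unfold = (i_b, i_a) if folded_below else (i_a, i_b)
    dF = float(F[i_fold] - F[i_unfold])
    lo, hi = sorted((i_fold, i_unfold))
    between = np.arange(lo + 1, hi)
    between = between[m[between]]
    barrier = barrier_cv = None
    if between.size:
        i_top = between[np.nanargmax(F[between])]
        height = float(F[i_top] - F[i_fold])
        if height > 0 and F[i_top] > max(F[i_fold], F[i_unfold]):
            barrier, barrier_cv = height, float(x[i_top])
    return ProfileStats(dF, barrier, float(x[i_fold]), float(x[i_unfold]),
                        barrier_cv)
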