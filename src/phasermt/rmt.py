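"""Adaptive resting-motor-threshold estimation from MEP exceedance data.

The probability that a stimulus of intensity x (%MSO) evokes an MEP
exceeding 50 uV is modelled as a cumulative Gaussian Phi((x - mu)/sigma).
The likelihood of the per-trial binary outcomes is evaluated on a dense
(threshold, spread) grid; marginalising over the spread with a uniform
prior yields the probability density of the RMT over the 0-100 %MSO
intensity axis, whose mode is the RMT estimate.  The probability that
one condition's RMT exceeds another's is the integral of the product
density over the triangular half of the joint grid.

Threshold tracking is maximum-a-posteriori: each next stimulus intensity
is the current posterior mode of its condition, so the procedure
concentrates sampling at the running RMT estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr

CONDITIONS = ("positive_peak", "negative_peak", "random")


@dataclass
class ThresholdGrid:
    """Evaluation grid over (threshold, spread), both in %MSO.

    The intensity axis covers the stimulator's full 0-100 %MSO range at
    0.1 %MSO steps (below the stimulator resolution); the spread axis is
    log-spaced over 0.5-10 %MSO.
    """

    intensities: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.0, 100.05, 0.1), 1)
    )
    spreads: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.5, 10.0, 16)
    )

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.spreads = np.asarray(self.spreads, dtype=float)
        if np.any(np.diff(self.intensities) <= 0) or np.any(np.diff(self.spreads) <= 0):
            raise ValueError("grids must be strictly increasing")
        if np.any(self.spreads <= 0):
            raise ValueError("spreads must be positive")
        if self.intensities[0] > 0.0 or self.intensities[-1] < 100.0:
            raise ValueError("intensity grid must cover 0-100 %MSO")

    @property
    def dx(self) -> float:
        return float(self.intensities[1] - self.intensities[0])

    def matches(self, other: "ThresholdGrid") -> bool:
        return (
            self.intensities.shape == other.intensities.shape
            and np.allclose(self.intensities, other.intensities)
        )


@dataclass
class LikelihoodSurface:
    """Log-likelihood of the trial outcomes over the (threshold, spread) grid."""

    grid: ThresholdGrid
    loglik: np.ndarray  # shape (n_intensities, n_spreads)

    @property
    def likelihood(self) -> np.ndarray:
        """Stably exponentiated likelihood (scaled so its maximum is 1)."""
        return np.exp(self.loglik - self.loglik.max())


@dataclass
class RmtPosterior:
    """Probability density of the RMT over the 0-100 %MSO intensity axis."""

    grid: ThresholdGrid
    density: np.ndarray
    rmt_mode: float

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)


_term_cache: dict[tuple, np.ndarray] = {}


def _grid_key(grid: ThresholdGrid) -> tuple:
    return (len(grid.intensities), float(grid.intensities[0]),
            float(grid.intensities[-1]), len(grid.spreads),
            float(grid.spreads[0]), float(grid.spreads[-1]))


def _loglik_term(intensity: float, exceeded: bool, grid: ThresholdGrid) -> np.ndarray:
    # tracked intensities repeat (posterior modes rounded to 0.1 %MSO), so
    # per-(intensity, outcome) grid terms are worth memoising
    key = (_grid_key(grid), round(float(intensity), 6), bool(exceeded))
    out = _term_cache.get(key)
    if out is None:
        if len(_term_cache) > 4096:
            _term_cache.clear()
        z = (intensity - grid.intensities[:, None]) / grid.spreads[None, :]
        out = log_ndtr(z) if exceeded else log_ndtr(-z)
        _term_cache[key] = out
    return out


def likelihood_surface(trials, grid: ThresholdGrid | None = None) -> LikelihoodSurface:
    """Cumulative-Gaussian likelihood of (intensity, exceeded-50uV) trials.

    L(mu, sigma) = prod_i Phi(z_i)^y_i (1 - Phi(z_i))^(1-y_i) with
    z_i = (x_i - mu)/sigma, computed in the log domain.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("need at least one trial")
    if grid is None:
        grid = ThresholdGrid()
    ll = np.zeros((len(grid.intensities), len(grid.spreads)))
    for intensity, exceeded in trials:
        ll += _loglik_term(float(intensity), bool(exceeded), grid)
    return LikelihoodSurface(grid=grid, loglik=ll)


def _posterior_from_loglik(loglik: np.ndarray, grid: ThresholdGrid) -> RmtPosterior:
    m = loglik.max()
    if not np.isfinite(m):
        raise ValueError("degenerate likelihood surface")
    w = np.exp(loglik - m).sum(axis=1)  # uniform prior over the spread grid
    total = w.sum()
    if total <= 0.0 or not np.isfinite(total):
        raise ValueError("degenerate all-zero likelihood surface")
    density = w / (total * grid.dx)
    # ties at the maximum resolve to the lowest intensity (threshold =
    # minimum sufficient intensity); np.argmax returns the first maximum
    mode = float(grid.intensities[int(np.argmax(density))])
    return RmtPosterior(grid=grid, density=density, rmt_mode=mode)


def rmt_posterior(surface: LikelihoodSurface) -> RmtPosterior:
    """Marginalise the likelihood over the spread axis (uniform prior) and
    normalise to a probability density on the intensity axis."""
    return _posterior_from_loglik(surface.loglik, surface.grid)


def prob_pos_exceeds_neg(pdf_pos: RmtPosterior, pdf_neg: RmtPosterior) -> float:
    """P(RMT_pos > RMT_neg) by triangular integration of the joint density.

    The two posteriors are assumed independent (product joint density);
    probability mass on the grid diagonal (exact ties) is split evenly,
    which makes P(A>B) + P(B>A) = 1 hold exactly.
    """
    if not pdf_pos.grid.matches(pdf_neg.grid):
        raise ValueError("posteriors must share the same intensity grid")
    dx = pdf_pos.grid.dx
    f = pdf_pos.density * dx
    g = pdf_neg.density * dx
    f = f / f.sum()
    g = g / g.sum()
    g_below = np.concatenate(([0.0], np.cumsum(g)[:-1]))  # strict lower mass
    p = float(f @ g_below + 0.5 * f @ g)
    return min(max(p, 0.0), 1.0)


class ThresholdTracker:
    """Per-condition MAP threshold tracking with incremental posteriors.

    Keeps an append-only trial history and a running log-likelihood
    surface per condition.  Before any data the configured starting
    intensity is returned; afterwards the next intensity is the current
    posterior mode rounded to the stimulator resolution.
    """

    def __init__(self, grid: ThresholdGrid | None = None,
                 conditions=CONDITIONS, start_intensity: float = 50.0,
                 resolution: float = 0.1) -> None:
        self.grid = grid if grid is not None else ThresholdGrid()
        self.start_intensity = float(start_intensity)
        self.resolution = float(resolution)
        self.history: dict[str, list[tuple[float, bool]]] = {c: [] for c in conditions}
        self._loglik: dict[str, np.ndarray] = {
            c: np.zeros((len(self.grid.intensities), len(self.grid.spreads)))
            for c in conditions
        }

    @property
    def conditions(self):
        return tuple(self.history)

    def _check(self, condition: str) -> None:
        if condition not in self.history:
            raise ValueError(f"unknown condition {condition!r}")

    def update(self, condition: str, intensity: float, exceeded: bool) -> None:
        self._check(condition)
        self.history[condition].append((float(intensity), bool(exceeded)))
        self._loglik[condition] += _loglik_term(float(intensity), bool(exceeded), self.grid)

    def posterior(self, condition: str) -> RmtPosterior:
        self._check(condition)
        return _posterior_from_loglik(self._loglik[condition], self.grid)

    def next_intensity(self, condition: str) -> float:
        self._check(condition)
        if not self.history[condition]:
            return self.start_intensity
        mode = self.posterior(condition).rmt_mode
        return float(np.clip(round(mode / self.resolution) * self.resolution, 0.0, 100.0))

    @property
    def estimates(self) -> dict[str, float]:
        return {
            c: (self.posterior(c).rmt_mode if self.history[c] else self.start_intensity)
            for c in self.history
        }


def track_next_intensity(state: ThresholdTracker, condition: str) -> float:
    """Next stimulation intensity for a condition (see ThresholdTracker)."""
    return state.next_intensity(condition)


def run_threshold_session(responder, schedule, grid: ThresholdGrid | None = None,
                          start_intensity: float = 50.0, seed=None,
                          rng=None):
    """Simulate one interleaved threshold-tracking session.

    Three independent trackers (one per condition) are interleaved
    according to ``schedule`` (blocks of three, one stimulus per
    condition per block).  The responder's MEP amplitudes are drawn from
    the generative model; the 50-uV exceedance flag feeds the tracker.

    Returns ``(tracker, posteriors)`` with one :class:`RmtPosterior` per
    condition.
    """
    from .synth import mep_response  # local import to avoid a module cycle

    if rng is None:
        rng = np.random.default_rng(seed)
    schedule = list(schedule)
    conditions = tuple(dict.fromkeys(schedule))
    for c in conditions:
        if c not in CONDITIONS:
            raise ValueError(f"unknown condition {c!r} in schedule")
    tracker = ThresholdTracker(grid=grid, conditions=conditions,
                               start_intensity=start_intensity)
    for condition in schedule:
        intensity = tracker.next_intensity(condition)
        amp = mep_response(intensity, responder, condition, rng)
        tracker.update(condition, intensity, amp > 50.0)
    posteriors = {c: tracker.posterior(c) for c in conditions}
    return tracker, posteriors
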