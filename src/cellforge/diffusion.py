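"""DDPM core: noise schedule, closed-form forward corruption, the single
reverse step, and the epsilon-prediction training objective.

The forward process q(x_t | x_{t-1}) = N(sqrt(1-beta_t) x_{t-1}, beta_t I)
admits the closed-form marginal x_t = sqrt(abar_t) x0 + sqrt(1-abar_t) eps
with abar_t the running product of alpha_t = 1 - beta_t.  The reverse step
uses the posterior mean with the predicted noise plugged in and a fixed
variance beta_t I; the last step (t = 0 target) adds no noise.

Time steps are indexed t in {0, ..., T-1} (half-open convention, matching
the cache-schedule index range [0, T-1]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class ScheduleError(ValueError):
    """Invalid noise-schedule parameters."""


@dataclass(frozen=True)
class NoiseSchedule:
    """beta_t, alpha_t and abar_t over T discrete steps."""

    beta: np.ndarray
    alpha: np.ndarray
    alpha_bar: np.ndarray

    @property
    def T(self) -> int:
        return len(self.beta)

    def __post_init__(self):
        b = self.beta
        if b.ndim != 1 or len(b) < 1:
            raise ScheduleError("beta must be a non-empty 1-D vector")
        if not ((b > 0) & (b < 1)).all():
            raise ScheduleError("every beta_t must lie in (0, 1)")
        if not np.allclose(self.alpha, 1.0 - b):
            raise ScheduleError("alpha_t must equal 1 - beta_t")
        if not np.allclose(self.alpha_bar, np.cumprod(self.alpha)):
            raise ScheduleError("alpha_bar must be the running product of alpha")


def make_schedule(T: int = 1000, kind: str = "linear",
                  beta_start: float = 1e-4, beta_end: float = 0.02
                  ) -> NoiseSchedule:
    """Build a noise schedule.

    ``linear`` interpolates beta from beta_start to beta_end (the standard
    DDPM construction); ``constant`` uses beta_start throughout.
    """
    if T < 1:
        raise ScheduleError("T must be >= 1")
    if not (0 < beta_start <= beta_end < 1):
        raise ScheduleError("need 0 < beta_start <= beta_end < 1")
    if kind == "linear":
        beta = np.linspace(beta_start, beta_end, T)
    elif kind == "constant":
        beta = np.full(T, beta_start)
    else:
        raise ScheduleError(f"unknown schedule kind '{kind}'")
    alpha = 1.0 - beta
    return NoiseSchedule(beta=beta, alpha=alpha, alpha_bar=np.cumprod(alpha))


@dataclass
class DiffusionState:
    """A noised latent batch x_t at step index t in [0, T-1]."""

    x: np.ndarray
    t: int


def forward_sample(x0: np.ndarray, t: int, eps: np.ndarray,
                   schedule: NoiseSchedule) -> DiffusionState:
    """Closed-form corruption x_t = sqrt(abar_t) x0 + sqrt(1-abar_t) eps.

    The noise is passed in, not drawn, so the map is a pure function.
    """
    x0 = np.asarray(x0, dtype=float)
    if eps.shape != x0.shape:
        raise ValueError(f"eps shape {eps.shape} != x0 shape {x0.shape}")
    if not (0 <= t < schedule.T):
        raise ValueError(f"t={t} outside [0, {schedule.T - 1}]")
    ab = schedule.alpha_bar[t]
    return DiffusionState(np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps, t)


def reverse_step(state: DiffusionState, eps_hat: np.ndarray,
                 schedule: NoiseSchedule,
                 rng: np.random.Generator) -> DiffusionState:
    """One ancestral reverse step from x_t to x_{t-1}.

    mean = (x_t - (1-alpha_t)/sqrt(1-abar_t) eps_hat) / sqrt(alpha_t),
    plus sqrt(beta_t) z with z ~ N(0, I); the final step (t == 1, which
    produces the t = 0 sample) is noiseless.
    """
    t = state.t
    if t < 1:
        raise ValueError("reverse_step requires t >= 1 (t=0 is the clean sample)")
    a = schedule.alpha[t]
    ab = schedule.alpha_bar[t]
    mean = (state.x - (1.0 - a) / np.sqrt(1.0 - ab) * eps_hat) / np.sqrt(a)
    if t > 1:
        mean = mean + np.sqrt(schedule.beta[t]) * rng.standard_normal(state.x.shape)
    return DiffusionState(mean, t - 1)


def training_loss(model, z0: np.ndarray, labels: np.ndarray,
                  schedule: NoiseSchedule, rng: np.random.Generator) -> float:
    """Monte-Carlo epsilon-prediction MSE on one batch.

    Samples t uniformly over [1, T-1] per cell and eps ~ N(0, I), then
    returns mean((model(x_t, t, y) - eps)^2) over all entries.
    """
    z0 = np.asarray(z0, dtype=float)
    n = z0.shape[0]
    t = rng.integers(1, schedule.T, size=n)
    eps = rng.standard_normal(z0.shape)
    ab = schedule.alpha_bar[t][:, None]
    x_t = np.sqrt(ab) * z0 + np.sqrt(1.0 - ab) * eps
    eps_hat = model(x_t, t, labels)
    loss = float(np.mean((eps_hat - eps) ** 2))
    if not np.isfinite(loss):
        raise FloatingPointError("diffusion training loss is not finite")
    return loss
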