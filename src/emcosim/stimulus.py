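"""Ornstein-Uhlenbeck stimulus current.

A mean-reverting noise current drives in-vivo-like irregular firing.  The
"relative" mode used by the circuit builder scales both the mean and the noise
amplitude of the process to a per-cell baseline current near rheobase, so that
cells of different size and excitability receive comparable effective drive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OUStimulusParams", "ou_step", "ou_segment"]


@dataclass(frozen=True)
class OUStimulusParams:
    """Parameters of the OU process  dx = (mean - x)/tau dt + amplitude dW.

    mean and amplitude are in nA when the stimulus is injected as a current.
    ``relative`` marks parameter sets whose mean/amplitude are fractions of a
    cell-specific baseline current (resolved by the circuit builder before
    simulation).
    """

    mean: float = 0.0
    tau: float = 3.0  # ms
    amplitude: float = 0.0  # nA * ms^-1/2
    relative: bool = False

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"OU time constant must be > 0, got {self.tau}")
        if self.amplitude < 0:
            raise ValueError("OU amplitude must be >= 0")

    def resolve(self, baseline: float) -> "OUStimulusParams":
        """Return an absolute-units copy scaled by a baseline current (nA)."""
        if not self.relative:
            return self
        return OUStimulusParams(
            mean=self.mean * baseline,
            tau=self.tau,
            amplitude=self.amplitude * baseline,
            relative=False,
        )


def ou_step(x, p: OUStimulusParams, dt: float, noise):
    """One Euler-Maruyama step of the OU process.

    ``noise`` is a standard-normal draw (scalar or array).  The stationary
    variance of the discretised process is amplitude^2 * tau / 2.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    return x + (p.mean - x) * (dt / p.tau) + p.amplitude * np.sqrt(dt) * noise


def ou_segment(x0: float, p: OUStimulusParams, n_steps: int, dt: float, rng) -> np.ndarray:
    """Vector of OU values for ``n_steps`` steps starting from x0 (x0 excluded)."""
    out = np.empty(n_steps)
    noise = rng.standard_normal(n_steps)
    x = x0
    for i in range(n_steps):
        x = ou_step(x, p, dt, noise[i])
        out[i] = x
    return out
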