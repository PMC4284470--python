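"""Deterministic iteration maps for competing protocell subpopulations.

After a slow irrRAF has begun to die out stochastically, the population
splits into protocells carrying only the fast irrRAF (X) and protocells
still carrying both (Y).  With synchronized divisions the generation-level
dynamics is the linear map

    X_{t+1} = 2 X_t + alpha Y_t
    Y_{t+1} = (2 - alpha) Y_t

where alpha is the per-division probability that a two-irrRAF protocell
produces a one-irrRAF daughter; if each of the N species of the slow
irrRAF is present in a single copy and partitioning is even and lossless,
alpha = 1/2^N.  Both subpopulations grow, but the Y fraction decays like
((2 - alpha)/2)^t.  Adding logistic growth-limiting terms,

    X_{t+1} = 2 X_t + alpha Y_t - beta_X (X_t + Y_t) X_t
    Y_{t+1} = (2 - alpha) Y_t - beta_Y (X_t + Y_t) Y_t,

the Y fraction still vanishes when beta_X = beta_Y, but if carrying the
extra irrRAF lowers the crowding penalty (beta_Y < beta_X) the two kinds
coexist at a stable positive fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "PopulationState",
    "alpha_single_copies",
    "step_linear",
    "step_limited",
    "trajectory",
]


def alpha_single_copies(N: int) -> float:
    """Probability that an even lossless division strands all N
    single-copy species of an irrRAF in the same daughter: 1/2^N."""
    if not isinstance(N, (int, np.integer)) or N < 1:
        raise ValueError("N must be an integer >= 1")
    return 0.5**N


@dataclass(frozen=True)
class PopulationState:
    X: float
    Y: float
    alpha: float
    beta_X: float = 0.0
    beta_Y: float = 0.0
    t: int = 0
    clipped: bool = False

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.X < 0 or self.Y < 0:
            raise ValueError("abundances must be non-negative")
        if self.beta_X < 0 or self.beta_Y < 0:
            raise ValueError("beta coefficients must be non-negative")

    @property
    def y_fraction(self) -> float:
        tot = self.X + self.Y
        return self.Y / tot if tot > 0 else 0.0


def step_linear(state: PopulationState) -> PopulationState:
    """One generation of the unlimited map: X' = 2X + aY, Y' = (2 - a)Y."""
    a = state.alpha
    return replace(
        state,
        X=2.0 * state.X + a * state.Y,
        Y=(2.0 - a) * state.Y,
        t=state.t + 1,
        clipped=False,
    )


def step_limited(state: PopulationState) -> PopulationState:
    """One generation with logistic growth limitation; negative outputs
    are clipped to zero and flagged."""
    a = state.alpha
    tot = state.X + state.Y
    x = 2.0 * state.X + a * state.Y - state.beta_X * tot * state.X
    y = (2.0 - a) * state.Y - state.beta_Y * tot * state.Y
    clipped = x < 0 or y < 0
    return replace(
        state, X=max(x, 0.0), Y=max(y, 0.0), t=state.t + 1, clipped=clipped
    )


def trajectory(
    map_kind: str, state0: PopulationState, T: int
) -> tuple[pd.DataFrame, float]:
    """Iterate the map for T generations.

    Returns the full (X, Y, Y-fraction) series and the asymptotic
    Y-fraction estimate (mean over the last 10% of steps).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    step = {"linear": step_linear, "limited": step_limited}.get(map_kind)
    if step is None:
        raise ValueError(f"unknown map kind {map_kind!r}")
    rows = []
    s = state0
    rows.append((s.t, s.X, s.Y, s.y_fraction, s.clipped))
    for _ in range(T):
        s = step(s)
        rows.append((s.t, s.X, s.Y, s.y_fraction, s.clipped))
    df = pd.DataFrame(rows, columns=["t", "X", "Y", "y_fraction", "clipped"])
    n_tail = max(1, T // 10)
    asymptotic = float(df["y_fraction"].tail(n_tail).mean())
    return df, asymptotic
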