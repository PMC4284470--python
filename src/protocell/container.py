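"""Membrane geometry, container growth and the division operator.

The protocell is a turgid sphere with a membrane of constant thickness
``delta`` and constant lipid number density ``rho``.  The container size is
the lipid count ``C`` (proportional to membrane mass), related to the inner
radius r through the spherical-shell relation

    C = rho * (4/3) * pi * ((r + delta)^3 - r^3),

whose inversion gives the internal (aqueous) volume

    r(C)   = (delta/2) * (sqrt(C / (pi rho delta^3) - 1/3) - 1)
    V_r(C) = (4/3) * pi * r^3  ~  O(C^{3/2})  as delta -> 0.

Lipids are produced inside at a rate proportional to the counts of the
container-coupled species and go instantaneously to the membrane.  When C
reaches the threshold ``theta`` the protocell divides into two daughters of
lipid count theta/2 each; because V_r(theta/2)/V_r(theta) -> 2^{-3/2} =
0.3535... as delta -> 0, about 30% of the internal material is lost to the
environment at each division (if internal concentrations are conserved).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ContainerGeometry",
    "min_lipid_count",
    "inner_radius",
    "internal_volume",
    "surface_area",
    "shell_mass",
    "daughter_volume_ratio",
    "lost_fraction",
    "growth_propensity",
    "partition_counts",
]


def min_lipid_count(delta: float, rho: float) -> float:
    """Lipid count at which the membrane fills the whole sphere (r = 0)."""
    return (4.0 / 3.0) * math.pi * rho * delta**3


def inner_radius(C, delta: float, rho: float):
    """Inner radius of the spherical shell holding ``C`` lipids."""
    C = np.asarray(C, dtype=float)
    arg = C / (math.pi * rho * delta**3) - 1.0 / 3.0
    if np.any(C < min_lipid_count(delta, rho) * (1 - 1e-12)):
        raise ValueError(
            "C below the minimum lipid count (4/3)*pi*rho*delta^3: "
            "no positive internal volume"
        )
    r = 0.5 * delta * (np.sqrt(arg) - 1.0)
    return np.maximum(r, 0.0)[()] if r.ndim == 0 else np.maximum(r, 0.0)


def internal_volume(C, delta: float, rho: float):
    """Internal aqueous volume V_r(C) of the protocell."""
    r = inner_radius(C, delta, rho)
    return (4.0 / 3.0) * math.pi * np.asarray(r) ** 3


def surface_area(C, delta: float, rho: float):
    """Inner membrane surface A = 4 pi r(C)^2."""
    r = inner_radius(C, delta, rho)
    return 4.0 * math.pi * np.asarray(r) ** 2


def shell_mass(r, delta: float, rho: float):
    """Lipid count of a shell of inner radius r (inverse of inner_radius)."""
    r = np.asarray(r, dtype=float)
    return rho * (4.0 / 3.0) * math.pi * ((r + delta) ** 3 - r**3)


def daughter_volume_ratio(theta: float, delta: float, rho: float) -> float:
    """V_r(theta/2) / V_r(theta); tends to 2^{-3/2} = 0.3535... as the
    relative membrane thickness delta^3 rho / theta -> 0."""
    v_m = internal_volume(theta, delta, rho)
    if v_m == 0:
        raise ValueError("mother volume is zero at this (theta, delta, rho)")
    return float(internal_volume(theta / 2.0, delta, rho) / v_m)


def lost_fraction(theta: float, delta: float, rho: float) -> float:
    """Fraction of internal material lost per division, 1 - 2*q with
    q the daughter/mother volume ratio; ~29.3% in the thin-membrane limit."""
    return 1.0 - 2.0 * daughter_volume_ratio(theta, delta, rho)


@dataclass
class ContainerGeometry:
    """Geometry parameters plus the current lipid count.

    ``g`` is the lipid-increment granularity of the stochastic growth
    channel: each firing adds ``g`` lipids at propensity
    sum_i k_i^cont x_i / g, so the mean growth rate is unchanged and
    ``g = 1`` recovers the exact one-lipid-at-a-time channel.
    """

    delta: float
    rho: float
    theta: float
    C: float
    g: int = 1

    def __post_init__(self) -> None:
        if self.g < 1:
            raise ValueError("growth granularity g must be a positive integer")
        bound = min_lipid_count(self.delta, self.rho)
        if self.C <= bound:
            raise ValueError("initial C leaves no positive internal volume")
        if self.theta / 2.0 <= bound:
            raise ValueError("theta/2 leaves daughters with no volume")

    @property
    def volume(self) -> float:
        return float(internal_volume(self.C, self.delta, self.rho))

    @property
    def area(self) -> float:
        return float(surface_area(self.C, self.delta, self.rho))

    @property
    def daughter_ratio(self) -> float:
        return daughter_volume_ratio(self.theta, self.delta, self.rho)

    def copy(self) -> "ContainerGeometry":
        return ContainerGeometry(self.delta, self.rho, self.theta, self.C, self.g)


def growth_propensity(k_cont: np.ndarray, counts: np.ndarray, g: int) -> float:
    """Propensity of the container-growth channel.

    The deterministic rate is dC/dt = sum_i k_i^cont [x_i] V_r =
    sum_i k_i^cont x_i (count-proportional); each firing adds g lipids.
    """
    return float(np.dot(k_cont, counts)) / g


def partition_counts(
    counts: np.ndarray,
    q: float,
    rng: np.random.Generator,
    mode: str = "trinomial_with_loss",
):
    """Partition molecule counts at division.

    ``trinomial_with_loss``: every molecule independently goes to
    daughter 1 / daughter 2 / the environment with probabilities
    (q, q, 1 - 2q), q being the daughter/mother volume ratio (internal
    concentrations are conserved on average, the volume deficit is lost).

    ``binomial_no_loss``: (1/2, 1/2, 0) — the idealization used for the
    single-copy loss probability alpha = 1/2^N.

    Returns (daughter1, daughter2, lost) integer arrays summing exactly to
    ``counts`` per species.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if mode == "trinomial_with_loss":
        if not 0.0 < q <= 0.5:
            raise ValueError("daughter volume ratio q must lie in (0, 1/2]")
        p = [q, q, 1.0 - 2.0 * q]
    elif mode == "binomial_no_loss":
        p = [0.5, 0.5, 0.0]
    else:
        raise ValueError(f"unknown partition mode {mode!r}")
    draws = np.stack(
        [rng.multinomial(int(n), p) for n in counts], axis=0
    )  # (n_species, 3)
    return draws[:, 0], draws[:, 1], draws[:, 2]
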