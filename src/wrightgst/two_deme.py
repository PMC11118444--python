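"""Asymmetric two-deme structured coalescent: identities and negative indices.

Two demes of unequal size exchange migrants at unequal backward rates.  A
pair of gene lineages is tracked backward through three states — both in
deme 0 (W0), both in deme 1 (W1), one in each (B) — with, in units of 2N
generations (N the average deme size):

    pair coalescence at rate 1/(2r) in deme 0 and 1/(2(1-r)) in deme 1,
    per-lineage migration at rate M_i/2 out of deme i,
    pair mutation at rate theta.

Identity by state is the probability that the pair coalesces before either
lineage mutates (the infinite-alleles reading), giving a linear first-step
system for (g_w0, g_w1, g_b).  Deme-specific structure indices built from
these identities — Weir & Goudet's beta_WT0 and a G_ST*-analog — can be
*negative* when between-deme identity exceeds within-deme-0 identity, which
requires deme 0 to hold a fraction r of reproductives above the closed-form
threshold

    r_min = [1 + M0 + 2(M1 + theta)] / [2(M0 + M1 + theta)] > 1/2.

Under hard migration (equal migrant numbers, r M0 = (1-r) M1) the threshold
is never reached and both indices stay non-negative.  The module also
provides expected pair coalescence times and Slatkin's F_ST* built from
them, and the IBS analog of Nei's distance D*.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TwoDemeParams",
    "ScaledTwoDemeParams",
    "TwoDemeIdentities",
    "CoalescenceTimes",
    "scale_two_deme",
    "steady_state_identities_twodeme",
    "beta_wt0",
    "gst0_star",
    "index_difference",
    "r_min",
    "hard_migration_partner",
    "is_hard_migration",
    "nei_distance_star",
    "expected_coalescence_times",
    "slatkin_fst",
]

HARD_MIGRATION_ATOL = 1e-12

#: backward migration rate above which the separation-of-timescales
#: assumption (rates of order 1/N) is clearly violated
_RAW_RATE_WARN = 0.15


@dataclass(frozen=True)
class TwoDemeParams:
    """Raw parameters: deme sizes, backward migration rates, mutation rate."""

    N0: int
    N1: int
    m0: float = 0.0
    m1: float = 0.0
    u: float = 0.0

    def __post_init__(self) -> None:
        if self.N0 < 1 or self.N1 < 1:
            raise ValueError("deme sizes must be >= 1")
        for name in ("m0", "m1"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0.0 <= self.u < 1.0):
            raise ValueError("u must lie in [0, 1)")
        if max(self.m0, self.m1) > _RAW_RATE_WARN:
            warnings.warn(
                "backward migration rate exceeds 0.15: the diffusion scaling "
                "assumes rates of order 1/N, closed-form thresholds may not hold",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ScaledTwoDemeParams:
    """Scaled parameters: r = N0/(N0+N1), M_i = 4N m_i, theta = 4N u."""

    r: float
    M0: float
    M1: float
    theta: float

    def __post_init__(self) -> None:
        if not (0.0 < self.r < 1.0):
            raise ValueError("r must lie strictly in (0, 1)")
        for name in ("M0", "M1", "theta"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TwoDemeIdentities:
    """Stationary IBS probabilities (g_w0, g_w1, g_b)."""

    g_w0: float
    g_w1: float
    g_b: float

    def __post_init__(self) -> None:
        for name in ("g_w0", "g_w1", "g_b"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} = {v} outside [0, 1]")


@dataclass(frozen=True)
class CoalescenceTimes:
    """Expected pair coalescence times (units of 2N generations).

    E_W0, E_W1, E_B condition on the starting configuration; E_Ts and E_T
    are the within-deme and population-wide expectations under uniform
    sampling of two individuals from the metapopulation (pair weights
    r^2, (1-r)^2, 2r(1-r); E_Ts conditions on cohabitation).
    """

    E_W0: float
    E_W1: float
    E_B: float
    E_Ts: float
    E_T: float


def scale_two_deme(p: TwoDemeParams) -> ScaledTwoDemeParams:
    """Convert raw sizes and rates to coalescent scaling.

    N is the *average* deme size (N0 + N1)/2; r = N0/(N0 + N1).
    """
    N = (p.N0 + p.N1) / 2.0
    return ScaledTwoDemeParams(
        r=p.N0 / (p.N0 + p.N1),
        M0=4.0 * N * p.m0,
        M1=4.0 * N * p.m1,
        theta=4.0 * N * p.u,
    )


def _first_step_matrix(sp: ScaledTwoDemeParams, theta: float) -> np.ndarray:
    r = sp.r
    return np.array(
        [
            [1.0 / (2.0 * r) + sp.M0 + theta, 0.0, -sp.M0],
            [0.0, 1.0 / (2.0 * (1.0 - r)) + sp.M1 + theta, -sp.M1],
            [-sp.M1 / 2.0, -sp.M0 / 2.0, (sp.M0 + sp.M1) / 2.0 + theta],
        ]
    )


def steady_state_identities_twodeme(sp: ScaledTwoDemeParams) -> TwoDemeIdentities:
    """Solve the three-state first-step system for the stationary identities.

    g_X = P(coalescence before any mutation | pair starts in state X).  With
    theta = 0 all identities are 1 (every pair eventually coalesces).  With
    both migration rates zero the demes never share ancestry: g_b = 0 is
    returned with a warning, while each within-deme identity reduces to the
    single-deme value 1/(1 + 2 N_i theta-share) form of its own coalescence
    race.
    """
    if sp.theta == 0.0:
        return TwoDemeIdentities(1.0, 1.0, 1.0)
    if sp.M0 == 0.0 and sp.M1 == 0.0:
        warnings.warn(
            "no migration: demes never coalesce, between-deme identity is 0",
            stacklevel=2,
        )
        g0 = (1.0 / (2.0 * sp.r)) / (1.0 / (2.0 * sp.r) + sp.theta)
        g1 = (1.0 / (2.0 * (1.0 - sp.r))) / (1.0 / (2.0 * (1.0 - sp.r)) + sp.theta)
        return TwoDemeIdentities(g0, g1, 0.0)
    A = _first_step_matrix(sp, sp.theta)
    b = np.array([1.0 / (2.0 * sp.r), 1.0 / (2.0 * (1.0 - sp.r)), 0.0])
    g_w0, g_w1, g_b = np.linalg.solve(A, b)
    return TwoDemeIdentities(g_w0, g_w1, g_b)


def beta_wt0(g_w0: float, g_b: float) -> float:
    """Deme-0-specific index beta_WT0 = (g_w0 - g_b)/(1 - g_b).

    Negative exactly when between-deme identity exceeds within-deme-0
    identity.
    """
    if g_b >= 1.0:
        raise ValueError("g_b = 1: between-deme identity saturated, index undefined")
    return (g_w0 - g_b) / (1.0 - g_b)


def gst0_star(g_w0: float, g_b: float, r: float) -> float:
    """Deme-0-specific G_ST* analog, weighting diversities by deme share r.

    (1 - r)(g_w0 - g_b) / [r(1 - g_w0) + (1 - r)(1 - g_b)]; shares the sign
    of g_w0 - g_b but is always weakly smaller than beta_WT0 in magnitude.
    """
    denom = r * (1.0 - g_w0) + (1.0 - r) * (1.0 - g_b)
    if denom <= 0.0:
        raise ValueError("population monomorphic (g_w0 = g_b = 1): index undefined")
    return (1.0 - r) * (g_w0 - g_b) / denom


def index_difference(g_w0: float, g_b: float, r: float) -> float:
    """Closed form for beta_WT0 - G_ST,0*.

    (g_w0 - g_b) r (1 - g_w0) / ([r(1 - g_w0) + (1 - r)(1 - g_b)](1 - g_b));
    equals the direct subtraction identically.
    """
    denom = r * (1.0 - g_w0) + (1.0 - r) * (1.0 - g_b)
    if denom <= 0.0 or g_b >= 1.0:
        raise ValueError("degenerate identities: difference undefined")
    return (g_w0 - g_b) * r * (1.0 - g_w0) / (denom * (1.0 - g_b))


def r_min(M0: float, M1: float, theta: float) -> float:
    """Smallest deme-0 share r at which the deme-0 indices can reach zero.

    [1 + M0 + 2(M1 + theta)] / [2(M0 + M1 + theta)]; always > 1/2, and > 1
    (negativity unattainable for any r) unless M0 > 1.  Decreases in M0:
    more incoming migrants make between-deme similarity easier to exceed
    within-deme similarity.
    """
    denom = 2.0 * (M0 + M1 + theta)
    if denom == 0.0:
        raise ValueError("M0 + M1 + theta must be > 0")
    return (1.0 + M0 + 2.0 * (M1 + theta)) / denom


def hard_migration_partner(r: float, M0: float) -> float:
    """M1 that balances migrant numbers: r M0 = (1 - r) M1."""
    if not (0.0 < r < 1.0):
        raise ValueError("r must lie strictly in (0, 1)")
    return r * M0 / (1.0 - r)


def is_hard_migration(sp: ScaledTwoDemeParams) -> bool:
    """True when migrant numbers are balanced between the demes."""
    return abs(sp.r * sp.M0 - (1.0 - sp.r) * sp.M1) <= HARD_MIGRATION_ATOL


def nei_distance_star(ids: TwoDemeIdentities) -> float:
    """IBS analog of Nei's genetic distance.

    D* = -(1/2)[ln(g_b/g_w0) + ln(g_b/g_w1)]; strictly positive at any
    two-deme steady state with mutation, unlike the deme-specific indices.
    """
    if min(ids.g_w0, ids.g_w1, ids.g_b) <= 0.0:
        raise ValueError("all identities must be strictly positive for D*")
    return -0.5 * (
        math.log(ids.g_b / ids.g_w0) + math.log(ids.g_b / ids.g_w1)
    )


def expected_coalescence_times(sp: ScaledTwoDemeParams) -> CoalescenceTimes:
    """Expected pair coalescence times by first-step analysis (theta = 0).

    Requires at least one positive migration rate; otherwise the B state
    never coalesces and the chain is reducible.
    """
    if sp.M0 == 0.0 and sp.M1 == 0.0:
        raise ValueError("M0 = M1 = 0: lineages in distinct demes never coalesce")
    sp0 = ScaledTwoDemeParams(r=sp.r, M0=sp.M0, M1=sp.M1, theta=0.0)
    A = _first_step_matrix(sp0, 0.0)
    E_W0, E_W1, E_B = np.linalg.solve(A, np.ones(3))
    r = sp.r
    w0, w1, wb = r * r, (1.0 - r) ** 2, 2.0 * r * (1.0 - r)
    E_Ts = (w0 * E_W0 + w1 * E_W1) / (w0 + w1)
    E_T = w0 * E_W0 + w1 * E_W1 + wb * E_B
    return CoalescenceTimes(E_W0=E_W0, E_W1=E_W1, E_B=E_B, E_Ts=E_Ts, E_T=E_T)


def slatkin_fst(ct: CoalescenceTimes) -> float:
    """Coalescence-time structure index F_ST* = (E(T) - E(Ts))/E(T)."""
    if ct.E_T <= 0.0:
        raise ValueError("E(T) must be positive")
    return (ct.E_T - ct.E_Ts) / ct.E_T


def deme1_view(sp: ScaledTwoDemeParams) -> ScaledTwoDemeParams:
    """Label-exchanged parameters, for deme-1-specific indices."""
    return ScaledTwoDemeParams(r=1.0 - sp.r, M0=sp.M1, M1=sp.M0, theta=sp.theta)
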