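"""Island model with partial selfing and K-allele mutation.

Exact one-generation recursions for the triple of IBS probabilities

    f    between the two gametes that united to form a random individual,
    g_w  between genes in distinct individuals of one deme,
    g_b  between genes in distinct demes,

under Wright's island model (d demes of N diploid reproductives, backward
migration rate m, selfing rate s, mutation rate u with K allelic classes).
The map is affine in (f, g_w, g_b); the steady state is the unique fixed
point for u in (0, 1), obtained by an exact 3x3 linear solve.

Closed-form large-N limits are provided alongside: the selfing equilibrium
G_IS* = (s/2)/(1 - s/2), and the migration-mutation equilibrium

    G_ST* = Delta / (Delta + [d/(d-1)] (M d/(d-1) + theta K/(K-1))),

with M = 4Nm, theta = 4Nu and Delta = N/N_e = 1/(1 - s/2) the relative
coalescence rate induced by selfing.  At Delta = 1, d -> infinity, K ->
infinity, theta = 0 this collapses to Wright's 1/(1 + M).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .hierarchy import GStatistics, assemble_island_levels, level_associations

__all__ = [
    "INFINITE_ALLELES",
    "IslandParams",
    "ScaledIslandParams",
    "IdentityTriple",
    "uniparental_prob",
    "outcross_resolution_prob",
    "effective_number",
    "mutation_transition",
    "one_generation_recursion",
    "steady_state_identities",
    "gis_star",
    "gis_star_finite",
    "gst_star_asymptotic",
    "unstructured_identity_limit",
    "island_g_statistics",
]

#: Sentinel for the infinite-alleles mutation model (an explicit flag, not a
#: large-K approximation).
INFINITE_ALLELES = math.inf

#: Probability that two lineages tracing to a shared uniparental ancestor
#: derive from the same gene complement (Mendelian segregation).
SAME_COMPLEMENT_PROB = 0.5


def _validate_K(K: float | int) -> float | int:
    if K == INFINITE_ALLELES:
        return INFINITE_ALLELES
    if int(K) != K or K < 2:
        raise ValueError(f"K must be an integer >= 2 or infinity, got {K}")
    return int(K)


@dataclass(frozen=True)
class IslandParams:
    """Raw per-generation parameters of the island model."""

    N: int          # diploid reproductives per deme
    d: int          # number of demes
    s: float = 0.0  # selfing probability
    u: float = 0.0  # mutation rate per gene per generation
    m: float = 0.0  # backward migration rate
    K: float | int = INFINITE_ALLELES  # allelic classes (inf = infinite alleles)

    def __post_init__(self) -> None:
        if self.N < 1 or self.d < 1:
            raise ValueError("N >= 1 and d >= 1 required")
        if not (0.0 <= self.s <= 1.0):
            raise ValueError("s must lie in [0, 1]")
        if not (0.0 <= self.u < 1.0):
            raise ValueError("u must lie in [0, 1)")
        if not (0.0 <= self.m <= 1.0):
            raise ValueError("m must lie in [0, 1]")
        if self.d == 1 and self.m != 0.0:
            raise ValueError("a single deme admits no migration: set m = 0")
        object.__setattr__(self, "K", _validate_K(self.K))

    def scaled(self) -> "ScaledIslandParams":
        return ScaledIslandParams(
            M=4.0 * self.N * self.m,
            theta=4.0 * self.N * self.u,
            Delta=effective_number(self.N, self.s)[1],
            d=self.d,
            K=self.K,
        )


@dataclass(frozen=True)
class ScaledIslandParams:
    """Coalescent-scaled parameters: M = 4Nm, theta = 4Nu, Delta = N/N_e."""

    M: float
    theta: float
    Delta: float
    d: int
    K: float | int = INFINITE_ALLELES

    def __post_init__(self) -> None:
        if self.M < 0 or self.theta < 0:
            raise ValueError("M and theta must be >= 0")
        if self.Delta < 1.0:
            raise ValueError("Delta = N/N_e must be >= 1 under partial selfing")
        if self.d < 1:
            raise ValueError("d >= 1 required")
        object.__setattr__(self, "K", _validate_K(self.K))


@dataclass(frozen=True)
class IdentityTriple:
    """IBS probabilities (f, g_w, g_b)."""

    f: float
    g_w: float
    g_b: float

    def __post_init__(self) -> None:
        for name in ("f", "g_w", "g_b"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} = {v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.f, self.g_w, self.g_b])


def uniparental_prob(s: float, N: int) -> float:
    """Probability sigma = s + (1 - s)/N that a random offspring is uniparental.

    Even a nominally outcrossed egg is fertilized by a gamete of its own
    parent with probability 1/N, since selfing does not change an
    individual's contribution to the local gamete pool.
    """
    if not (0.0 <= s <= 1.0) or N < 1:
        raise ValueError("require s in [0, 1] and N >= 1")
    return s + (1.0 - s) / N


def outcross_resolution_prob(sigma: float) -> float:
    """Probability that two within-individual lineages resolve to an outcross.

    Tracing a pair of lineages held by a single individual backward, each
    generation the shared parent is uniparental (probability sigma, after
    which the lineages coalesce with probability 1/2) or biparental
    (probability 1 - sigma, separating the lineages into distinct
    individuals).  Of the two absorbing outcomes the process resolves to
    outcross with probability (1 - sigma)/(1 - sigma/2).
    """
    if not (0.0 <= sigma <= 1.0):
        raise ValueError("sigma must lie in [0, 1]")
    if sigma == 1.0:
        return 0.0
    c = SAME_COMPLEMENT_PROB
    return (1.0 - sigma) / (1.0 - sigma + sigma * c)


def effective_number(N: int, s: float) -> tuple[float, float]:
    """(N_e, Delta) under partial selfing: N_e = N(1 - s/2), Delta = 1/(1 - s/2).

    Selfing accelerates pair coalescence within demes, shrinking the
    effective number; Delta ranges from 1 (pure outcrossing) to 2 (full
    selfing).
    """
    if not (0.0 <= s <= 1.0) or N < 1:
        raise ValueError("require s in [0, 1] and N >= 1")
    Ne = N * (1.0 - s / 2.0)
    return Ne, 1.0 / (1.0 - s / 2.0)


def _mutation_coefficients(u: float, K: float | int) -> tuple[float, float]:
    """(A, B): P(pair stays IBS | was IBS), P(pair becomes IBS | was non-IBS).

    Each lineage independently mutates with probability u per transmission,
    moving to any of the K - 1 other classes uniformly.  For infinite
    alleles every mutation is novel: A = (1 - u)^2, B = 0.
    """
    if K == INFINITE_ALLELES:
        return (1.0 - u) ** 2, 0.0
    K = float(K)
    A = (1.0 - u) ** 2 + u**2 / (K - 1.0)
    B = 2.0 * u * (1.0 - u) / (K - 1.0) + u**2 * (K - 2.0) / (K - 1.0) ** 2
    return A, B


def mutation_transition(g: float, u: float, K: float | int) -> float:
    """One generation of K-allele mutation applied to an identity probability."""
    if not (0.0 <= g <= 1.0):
        raise ValueError("g must lie in [0, 1]")
    if not (0.0 <= u < 1.0):
        raise ValueError("u must lie in [0, 1)")
    A, B = _mutation_coefficients(u, _validate_K(K))
    return A * g + B * (1.0 - g)


def _migration_mixing(m: float, d: int) -> tuple[float, float]:
    """(psi, chi): P(two lineages land in one parental deme | currently
    together), and the same probability given currently apart.

    Each lineage's parental deme is its own with probability 1 - m, each of
    the other d - 1 demes with probability m/(d - 1).
    """
    if d == 1:
        return 1.0, 0.0
    psi = (1.0 - m) ** 2 + m**2 / (d - 1.0)
    chi = 2.0 * m * (1.0 - m) / (d - 1.0) + m**2 * (d - 2.0) / (d - 1.0) ** 2
    return psi, chi


def _affine_map(p: IslandParams) -> tuple[np.ndarray, np.ndarray]:
    """The one-generation map x' = T x + c on x = (f, g_w, g_b).

    Event order per generation, backward in time: parental-deme choice
    (migration), parent choice within the deme (drift/selfing), then
    mutation on each transmitted gene.
    """
    N, d = p.N, p.d
    sigma = uniparental_prob(p.s, N)
    psi, chi = _migration_mixing(p.m, d)
    A, B = _mutation_coefficients(p.u, p.K)

    # w = P(IBS | two lineages in one parental deme, distinct offspring):
    # same parent individual with prob 1/N, whereupon the pair of sampled
    # genes match with prob (1 + f)/2; otherwise distinct parents, g_w.
    # As affine coefficients on (f, g_w, g_b, 1):
    w = np.array([1.0 / (2.0 * N), 1.0 - 1.0 / N, 0.0, 1.0 / (2.0 * N)])

    same = psi * w + (1.0 - psi) * np.array([0.0, 0.0, 1.0, 0.0])
    apart = chi * w + (1.0 - chi) * np.array([0.0, 0.0, 1.0, 0.0])

    # uniting gametes: uniparental (prob sigma) -> the pair matches with
    # probability (1 + f)/2; biparental -> one random gene each of two
    # distinct residents of one deme, i.e. exactly the g_w configuration.
    f_row = sigma * np.array([0.5, 0.0, 0.0, 0.5]) + (1.0 - sigma) * np.array(
        [0.0, 1.0, 0.0, 0.0])

    pre = np.vstack([f_row, same, apart])
    T = (A - B) * pre[:, :3]
    c = (A - B) * pre[:, 3] + B
    return T, c


def one_generation_recursion(x: IdentityTriple, p: IslandParams) -> IdentityTriple:
    """Advance (f, g_w, g_b) by one generation."""
    T, c = _affine_map(p)
    f, g_w, g_b = T @ x.as_array() + c
    return IdentityTriple(f=f, g_w=g_w, g_b=g_b)


def steady_state_identities(p: IslandParams) -> IdentityTriple:
    """Stationary (f, g_w, g_b): the unique fixed point of the affine map.

    Without mutation every lineage pair eventually coalesces and the
    population fixes, so all identities equal 1.  For u > 0 the linear
    system (I - T) x = c is solved exactly.
    """
    if p.u == 0.0:
        return IdentityTriple(1.0, 1.0, 1.0)
    T, c = _affine_map(p)
    M = np.eye(3) - T
    if abs(np.linalg.det(M)) < 1e-300:  # pragma: no cover - cannot occur for u in (0,1)
        raise RuntimeError("singular identity system; this should be impossible for u in (0, 1)")
    f, g_w, g_b = np.linalg.solve(M, c)
    eps = 1e-9
    if not (-eps <= min(f, g_w, g_b) and max(f, g_w, g_b) <= 1 + eps):
        raise RuntimeError("steady-state identities left [0, 1]; invalid parameters?")
    clip = lambda v: min(max(v, 0.0), 1.0)
    return IdentityTriple(clip(f), clip(g_w), clip(g_b))


def gis_star(s: float) -> float:
    """Large-N selfing equilibrium of the within-deme index: (s/2)/(1 - s/2)."""
    if not (0.0 <= s <= 1.0):
        raise ValueError("s must lie in [0, 1]")
    return (s / 2.0) / (1.0 - s / 2.0)


def gis_star_finite(x: IdentityTriple) -> float:
    """Finite-population G_1* = (f - g_w)/(1 - g_w) from an identity triple."""
    if x.g_w >= 1.0:
        raise ValueError("g_w = 1: deme monomorphic, G_1* undefined")
    return (x.f - x.g_w) / (1.0 - x.g_w)


def gst_star_asymptotic(sp: ScaledIslandParams) -> float:
    """Closed-form G_ST* of the island model in scaled parameters.

    Delta / (Delta + [d/(d-1)] (M d/(d-1) + theta K/(K-1))); the mutation
    term carries the K-allele factor K/(K-1) (1 for infinite alleles) —
    fewer allelic classes make mutation more effective at producing IBS and
    hence weigh theta more heavily.
    """
    if sp.d < 2:
        raise ValueError("G_ST* requires at least two demes")
    kfac = 1.0 if sp.K == INFINITE_ALLELES else sp.K / (sp.K - 1.0)
    dd = sp.d / (sp.d - 1.0)
    return sp.Delta / (sp.Delta + dd * (sp.M * dd + sp.theta * kfac))


def unstructured_identity_limit(theta: float) -> float:
    """Equilibrium IBS probability 1/(1 + theta) of a panmictic population.

    Malecot's limit for a sample of two under infinite alleles, matching the
    Ewens Sampling Formula.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    return 1.0 / (1.0 + theta)


def island_g_statistics(p: IslandParams) -> tuple[IdentityTriple, GStatistics]:
    """Steady-state identities and the finite-N hierarchy G-statistics."""
    x = steady_state_identities(p)
    h = assemble_island_levels(x.f, x.g_w, x.g_b, p.N, p.d)
    return x, level_associations(h)
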