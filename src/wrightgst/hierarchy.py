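"""Hierarchy of non-identity-by-state probabilities and G*-statistics.

A structured population can be described by an ordered sequence of
probabilities ``h_0 <= ... <= h_L`` (not necessarily monotone), where
``h_i`` is the probability that a pair of genes randomly sampled at level
``i`` of the hierarchy — uniting gametes, a deme, the metapopulation, ... —
belong to *different* allelic classes (non-IBS).  The association between
adjacent levels,

    G_i* = (h_i - h_{i-1}) / h_i,

is the diversity-based analog of Wright's F-statistics: the non-IBS
probability at each level is measured *relative to* the level immediately
below it.  The product of the complements telescopes,

    prod_i (1 - G_i*) = h_0 / h_L = 1 - G_IT*,

mirroring the classical partitioning 1 - F_IT = (1 - F_IS)(1 - F_ST).

This module also houses the classical F-partition arithmetic and a
recursive-kinship pedigree inbreeding calculator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "NonIdentityHierarchy",
    "GStatistics",
    "Pedigree",
    "level_associations",
    "wright_partition",
    "assemble_island_levels",
    "kinship",
    "kinship_inbreeding",
    "read_pedigree",
]

#: absolute tolerance for the partition-closure identity; all quantities are O(1)
PARTITION_ATOL = 1e-12


@dataclass(frozen=True)
class NonIdentityHierarchy:
    """Ordered non-IBS probabilities h_0 ... h_L across population levels.

    ``levels[0]`` refers to the base level (uniting gametes); successive
    entries refer to successively more inclusive groupings.
    """

    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        levels = tuple(float(h) for h in self.levels)
        if len(levels) < 2:
            raise ValueError("a hierarchy needs at least two levels (L >= 1)")
        for i, h in enumerate(levels):
            if not (0.0 <= h <= 1.0):
                raise ValueError(f"h_{i} = {h} outside [0, 1]")
        object.__setattr__(self, "levels", levels)

    @property
    def L(self) -> int:
        """Number of levels above the base."""
        return len(self.levels) - 1

    def __iter__(self):
        return iter(self.levels)

    def __getitem__(self, i: int) -> float:
        return self.levels[i]


@dataclass(frozen=True)
class GStatistics:
    """Per-level associations G_1* ... G_L* and the total G_IT*.

    Each G_i* <= 1 but may be negative: a negative value means genes are
    *less* diverse at level i than at the level below — a meaningful signal,
    not an estimation artifact — so values are never clamped.
    """

    per_level: tuple[float, ...]
    total: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_level", tuple(float(g) for g in self.per_level))
        for i, g in enumerate(self.per_level, start=1):
            if g > 1.0 + PARTITION_ATOL:
                raise ValueError(f"G_{i}* = {g} exceeds 1")

    def to_dict(self) -> dict:
        return {"G": list(self.per_level), "GIT": self.total}


def level_associations(h: NonIdentityHierarchy | Sequence[float]) -> GStatistics:
    """Compute G_i* = (h_i - h_{i-1})/h_i for every level and G_IT* = 1 - h_0/h_L.

    Raises
    ------
    ValueError
        If any ``h_i`` with ``i >= 1`` is zero: the ratio h_{i-1}/h_i is then
        undefined (the population is fixed at that level).
    """
    if not isinstance(h, NonIdentityHierarchy):
        h = NonIdentityHierarchy(tuple(h))
    levels = h.levels
    for i in range(1, len(levels)):
        if levels[i] == 0.0:
            raise ValueError(
                f"h_{i} = 0: population fixed at level {i}, association undefined"
            )
    per_level = tuple(
        (levels[i] - levels[i - 1]) / levels[i] for i in range(1, len(levels))
    )
    total = 1.0 - levels[0] / levels[-1]
    return GStatistics(per_level=per_level, total=total)


def wright_partition(F_IT: float, G_w: float) -> tuple[float, float]:
    """Split a total correlation F_IT into (F_IS, F_ST) given G_w.

    ``G_w`` is the correlation between a pair of gametes sampled at random
    from the whole population; it equals F_ST directly (the correlation among
    uniting gametes after one hypothetical generation of random mating),
    while F_IS = (F_IT - G_w)/(1 - G_w) measures the excess correlation of
    gametes that actually united.  The identity
    1 - F_IT = (1 - F_IS)(1 - F_ST) is exact by construction.
    """
    if G_w >= 1.0:
        raise ValueError("G_w = 1: within-population correlation saturated, F_IS undefined")
    F_IS = (F_IT - G_w) / (1.0 - G_w)
    F_ST = G_w
    return F_IS, F_ST


def assemble_island_levels(
    f: float, g_w: float, g_b: float, N: int, d: int
) -> NonIdentityHierarchy:
    """Build the three-level non-IBS hierarchy of the island model.

    Exact finite-N / finite-d assembly, no O(1/N) truncation:

        h_0 = 1 - f
        h_1 = [(1 + f)/2]/N + (1 - g_w)(1 - 1/N)
        h_2 = h_1/d + (1 - g_b)(1 - 1/d)

    ``h_1`` mixes the within-individual comparison (two genes in one zygote
    match with probability (1 + f)/2, hence mismatch (1 - f)/2 ... the 1/N
    term carries the full within-individual contribution) with the
    cross-individual one; ``h_2`` likewise mixes within- and between-deme
    sampling with weight 1/d on a shared deme.
    """
    for name, v in (("f", f), ("g_w", g_w), ("g_b", g_b)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} = {v} outside [0, 1]")
    if N < 1 or d < 1:
        raise ValueError("N and d must be >= 1")
    h0 = 1.0 - f
    h1 = ((1.0 + f) / 2.0) / N + (1.0 - g_w) * (1.0 - 1.0 / N)
    h2 = h1 / d + (1.0 - g_b) * (1.0 - 1.0 / d)
    return NonIdentityHierarchy((h0, h1, h2))


# ---------------------------------------------------------------------------
# Pedigree inbreeding
# ---------------------------------------------------------------------------

_UNKNOWN = {"0", ".", "", "NA"}


@dataclass
class Pedigree:
    """A diploid pedigree: each non-founder has exactly two recorded parents.

    Founders (individuals with no recorded parents) are treated as non-inbred
    and mutually unrelated, the standard base-population convention.  Parent
    links must form a DAG; the two parents of an individual may coincide
    (selfing).
    """

    parents: Mapping[str, tuple[str, str] | None]
    _order: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        for ind, pp in self.parents.items():
            if pp is not None:
                for p in pp:
                    if p not in self.parents:
                        raise ValueError(f"parent {p!r} of {ind!r} not in pedigree")
        self._order = self._toposort()

    def _toposort(self) -> list[str]:
        order: list[str] = []
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(ind: str, stack: list[str]) -> None:
            st = state.get(ind)
            if st == 1:
                return
            if st == 0:
                cycle = " -> ".join(stack + [ind])
                raise ValueError(f"pedigree contains a cycle: {cycle}")
            state[ind] = 0
            pp = self.parents[ind]
            if pp is not None:
                for p in pp:
                    visit(p, stack + [ind])
            state[ind] = 1
            order.append(ind)

        for ind in self.parents:
            visit(ind, [])
        return order

    @property
    def individuals(self) -> list[str]:
        return list(self.parents)

    def founders(self) -> list[str]:
        return [i for i, pp in self.parents.items() if pp is None]


def kinship(p: Pedigree) -> dict[tuple[str, str], float]:
    """Full kinship matrix by the standard tabular recursion.

    phi(a, a) = (1 + F_a)/2 with F_a the inbreeding of a;
    phi(a, b) = [phi(a, sire_b) + phi(a, dam_b)]/2 for b not an ancestor of a,
    evaluated in topological order; distinct founders have phi = 0.
    """
    order = p._order
    idx = {ind: i for i, ind in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    for j, b in enumerate(order):
        pp = p.parents[b]
        if pp is None:
            phi[j, j] = 0.5
            continue
        si, di = idx[pp[0]], idx[pp[1]]
        # parents precede b in topological order, so rows si, di are complete
        phi[j, j] = 0.5 * (1.0 + phi[si, di])
        for i in range(j):
            phi[j, i] = phi[i, j] = 0.5 * (phi[i, si] + phi[i, di])
    return {
        (a, b): phi[idx[a], idx[b]] for a in order for b in order
    }


def kinship_inbreeding(p: Pedigree, individual: str) -> float:
    """Inbreeding coefficient F of ``individual``: the kinship of its parents.

    Founders return 0 by the base-population convention.
    """
    if individual not in p.parents:
        raise KeyError(f"unknown individual {individual!r}")
    pp = p.parents[individual]
    if pp is None:
        return 0.0
    phi = kinship(p)
    return phi[(pp[0], pp[1])]


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a 3-column delimited pedigree file: id, sire, dam.

    One header line; '0' or '.' mark unknown parents.  An individual with
    exactly one known parent is rejected — the recursion needs both or
    neither.
    """
    parents: dict[str, tuple[str, str] | None] = {}
    rows: list[tuple[str, str, str]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header:
            raise ValueError(f"{path}: empty pedigree file")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            fields = line.replace(",", "\t").split("\t" if "\t" in line else None)
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            rows.append((fields[0], fields[1], fields[2]))
    for ind, sire, dam in rows:
        s_known = sire not in _UNKNOWN
        d_known = dam not in _UNKNOWN
        if s_known != d_known:
            raise ValueError(f"individual {ind!r} has exactly one known parent")
        parents[ind] = (sire, dam) if s_known else None
    # implicit founders: parents referenced but never listed
    for ind, sire, dam in rows:
        if parents[ind] is not None:
            for par in (sire, dam):
                parents.setdefault(par, None)
    return Pedigree(parents)


def hierarchy_report(h: NonIdentityHierarchy, g: GStatistics | None = None) -> str:
    """JSON report {"h": [...], "G": [...], "GIT": x}."""
    if g is None:
        g = level_associations(h)
    return json.dumps({"h": list(h.levels), **g.to_dict()})
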