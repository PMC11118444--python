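"""Stochastic oracles: forward Wright-Fisher and backward pair samplers.

These simulators realize the same demographic models as the analytic
solvers but share no algebra with them, so agreement between the two is a
genuine cross-check.  Three samplers are provided:

* :func:`forward_island` — discrete-generation Wright-Fisher island model
  with partial selfing, backward migration and K-allele (or infinite-
  alleles) mutation, tracking every gene in the metapopulation and reading
  off IBS fractions at stationarity.
* :func:`pair_coalescent_island` — two gene lineages followed backward
  through the island model's generation structure (deme choice, parent
  choice, Mendelian segregation), with mutation counts accumulated along
  both branches; long sojourns in a state are skipped geometrically.
* :func:`pair_coalescent_twodeme` — the continuous-time race among
  coalescence, migration and mutation of the scaled two-deme model.

All randomness flows from one seeded :class:`numpy.random.Generator`;
replicate means and their standard errors are returned with seed
provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .island_model import INFINITE_ALLELES, IslandParams
from .two_deme import ScaledTwoDemeParams

__all__ = [
    "SimConfig",
    "SimEstimates",
    "forward_island",
    "pair_coalescent_island",
    "pair_coalescent_twodeme",
    "genotype_sample",
]


@dataclass(frozen=True)
class SimConfig:
    """Run-length and replication settings for the simulators."""

    params: IslandParams | ScaledTwoDemeParams
    burn_in: int | None = None       # default 20 * (2 N d) for the island model
    sample_every: int = 50
    n_samples: int = 100
    replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_every < 1 or self.n_samples < 1 or self.replicates < 1:
            raise ValueError("sample_every, n_samples and replicates must be positive")
        if self.burn_in is not None and self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")

    def resolved_burn_in(self) -> int:
        if self.burn_in is not None:
            return self.burn_in
        if isinstance(self.params, IslandParams):
            return 20 * 2 * self.params.N * self.params.d
        return 0


@dataclass(frozen=True)
class SimEstimates:
    """Monte Carlo identity estimates with standard errors and provenance."""

    estimates: dict[str, float]
    se: dict[str, float]
    n_eff: int
    seed: int
    extras: dict = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.estimates[key]


# ---------------------------------------------------------------------------
# forward Wright-Fisher island model
# ---------------------------------------------------------------------------


def _ibs_statistics(pop: np.ndarray, deme: np.ndarray, N: int, d: int):
    """Exhaustive (f, g_w, g_b) from one population state.

    ``pop`` is (N*d, 2) allele labels; g_w averages all ordered
    cross-individual gene pairs within each deme (equal deme weights) via
    allele counts, g_b all cross-deme gene pairs.
    """
    hom = pop[:, 0] == pop[:, 1]
    f = float(hom.mean())
    _, inv = np.unique(pop, return_inverse=True)
    lab = inv.reshape(pop.shape)
    L = int(lab.max()) + 1
    counts = np.zeros((d, L))
    np.add.at(counts, (np.repeat(deme, 2), lab.ravel()), 1.0)
    G = counts @ counts.T
    hom_per_deme = np.bincount(deme, weights=hom.astype(float), minlength=d)
    # ordered same-class gene pairs within a deme, minus pairs inside one
    # individual (2 self-pairs each, plus 2 more if homozygous)
    gw_num = np.diag(G) - (2.0 * N + 2.0 * hom_per_deme)
    g_w = float((gw_num / (2.0 * N * (2.0 * N - 2.0))).mean())
    if d > 1:
        g_b = float((G.sum() - np.trace(G)) / (d * (d - 1)) / (4.0 * N * N))
    else:
        g_b = np.nan
    return f, g_w, g_b


def _init_population(p: IslandParams, rng: np.random.Generator):
    n = p.N * p.d
    if p.K == INFINITE_ALLELES:
        return np.zeros((n, 2), dtype=np.int64), 1
    return rng.integers(0, int(p.K), size=(n, 2)), 0


def _advance_generation(pop: np.ndarray, deme: np.ndarray, p: IslandParams,
                        rng: np.random.Generator, counter: int):
    """One Wright-Fisher generation; returns (new population, label counter).

    Each offspring chooses a parental deme by backward migration, a mother
    uniformly in it, and a father who is the mother with probability s (or
    by the uniform draw hitting her); inherited genes mutate independently.
    """
    N, d, s, u, m, K = p.N, p.d, p.s, p.u, p.m, p.K
    n = N * d
    pd = deme.copy()
    if d > 1 and m > 0.0:
        mig = rng.random(n) < m
        nmig = int(mig.sum())
        if nmig:
            pd[mig] = (pd[mig] + rng.integers(1, d, size=nmig)) % d
    base = pd * N
    mother = base + rng.integers(0, N, size=n)
    father = np.where(rng.random(n) < s, mother, base + rng.integers(0, N, size=n))
    new = np.empty_like(pop)
    new[:, 0] = pop[mother, rng.integers(0, 2, size=n)]
    new[:, 1] = pop[father, rng.integers(0, 2, size=n)]
    if u > 0.0:
        mut = rng.random((n, 2)) < u
        nmut = int(mut.sum())
        if nmut:
            if K == INFINITE_ALLELES:
                new[mut] = np.arange(counter, counter + nmut)
                counter += nmut
            else:
                new[mut] = (new[mut] + rng.integers(1, int(K), size=nmut)) % int(K)
    return new, counter


def _forward_replicate(p: IslandParams, burn_in: int, sample_every: int,
                       n_samples: int, rng: np.random.Generator) -> np.ndarray:
    deme = np.repeat(np.arange(p.d), p.N)
    pop, counter = _init_population(p, rng)
    samples = np.empty((n_samples, 3))
    taken = 0
    total = burn_in + sample_every * n_samples
    for gen in range(1, total + 1):
        pop, counter = _advance_generation(pop, deme, p, rng, counter)
        if gen > burn_in and (gen - burn_in) % sample_every == 0:
            samples[taken] = _ibs_statistics(pop, deme, p.N, p.d)
            taken += 1
    return samples


def forward_island(cfg: SimConfig) -> SimEstimates:
    """Estimate stationary (f, g_w, g_b) by forward simulation.

    Runs ``cfg.replicates`` independent populations; the reported standard
    errors are computed across replicate means, which are independent by
    construction.  A warning is issued if the first and second halves of
    the sampling window disagree by more than two standard errors
    (stationarity check).
    """
    p = cfg.params
    if not isinstance(p, IslandParams):
        raise TypeError("forward_island requires IslandParams")
    if p.N < 2:
        raise ValueError("need N >= 2 to form within-deme pairs")
    burn_in = cfg.resolved_burn_in()
    root = np.random.default_rng(cfg.seed)
    streams = root.spawn(cfg.replicates)
    reps = np.array([
        _forward_replicate(p, burn_in, cfg.sample_every, cfg.n_samples, rng)
        for rng in streams
    ])  # (R, n_samples, 3)
    names = ("f", "g_w", "g_b")
    per_rep = reps.mean(axis=1)  # (R, 3)
    means = per_rep.mean(axis=0)
    if cfg.replicates > 1:
        se = per_rep.std(axis=0, ddof=1) / np.sqrt(cfg.replicates)
    else:
        half = cfg.n_samples // 2
        se = reps[0].std(axis=0, ddof=1) / np.sqrt(max(half, 1))
    # stationarity: first vs second half of the sampling window
    half = cfg.n_samples // 2
    if half >= 2:
        h1 = reps[:, :half].mean(axis=(0, 1))
        h2 = reps[:, half:].mean(axis=(0, 1))
        with np.errstate(invalid="ignore"):
            drift = np.abs(h1 - h2) > 2.0 * np.maximum(se, 1e-12)
        if np.any(drift[~np.isnan(h1 - h2)]):
            warnings.warn(
                "sampling-window halves differ by > 2 SE; increase burn_in "
                "or the sampling span", stacklevel=2)
    est = {k: float(v) for k, v in zip(names, means)}
    ses = {k: float(v) for k, v in zip(names, se)}
    return SimEstimates(estimates=est, se=ses, n_eff=cfg.replicates * cfg.n_samples,
                        seed=cfg.seed)


# ---------------------------------------------------------------------------
# backward two-lineage samplers
# ---------------------------------------------------------------------------

def _kallele_identity(nmut: np.ndarray, K: float | int) -> np.ndarray:
    """P(two genes IBS | nmut mutation events separate them).

    The symmetric K-allele chain has second eigenvalue -1/(K-1):
    P(same class) = 1/K + (1 - 1/K)(-1/(K-1))^n.  For infinite alleles any
    mutation destroys identity.
    """
    if K == INFINITE_ALLELES:
        return (nmut == 0).astype(float)
    K = float(K)
    return 1.0 / K + (1.0 - 1.0 / K) * (-1.0 / (K - 1.0)) ** nmut


def _pair_island_once(p: IslandParams, start: int, n_rep: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Identity indicators for n_rep backward pair histories.

    States: 0 = uniting gametes of one individual, 1 = distinct individuals
    in one deme, 2 = distinct demes.  Sojourns are skipped geometrically;
    mutations along both branches accumulate as Binomial(2 t, u).
    """
    from .island_model import _migration_mixing, uniparental_prob

    N, d, u, K = p.N, p.d, p.u, p.K
    sigma = uniparental_prob(p.s, N)
    psi, chi = _migration_mixing(p.m, d)
    if start == 2 and chi == 0.0:
        # isolated demes never coalesce: identity is the stationary
        # uniform-allele match probability
        warnings.warn("no migration: between-deme lineages never coalesce",
                      stacklevel=3)
        if K == INFINITE_ALLELES:
            return np.zeros(n_rep)
        return np.full(n_rep, 1.0 / float(K))

    # per-generation transition table rows F, W, B over (C, F, W, B)
    trans = np.array([
        [sigma / 2.0, sigma / 2.0, 1.0 - sigma, 0.0],
        [psi / (2.0 * N), psi / (2.0 * N), psi * (1.0 - 1.0 / N), 1.0 - psi],
        [chi / (2.0 * N), chi / (2.0 * N), chi * (1.0 - 1.0 / N), 1.0 - chi],
    ])
    stay = np.array([trans[0, 1], trans[1, 2], trans[2, 3]])  # self-loops

    state = np.full(n_rep, start, dtype=np.int64)
    nmut = np.zeros(n_rep, dtype=np.int64)
    active = np.ones(n_rep, dtype=bool)
    while active.any():
        idx = np.flatnonzero(active)
        st = state[idx]
        leave = 1.0 - stay[st]
        t = rng.geometric(leave)  # generations until the state changes
        if u > 0.0:
            nmut[idx] += rng.binomial(2 * t, u)
        # jump distribution among the non-self targets
        probs = trans[st].copy()
        probs[np.arange(len(idx)), st + 1] = 0.0
        probs /= leave[:, None]
        cum = probs.cumsum(axis=1)
        r = rng.random(len(idx))
        dest = (r[:, None] >= cum).sum(axis=1)  # 0=C, 1=F, 2=W, 3=B
        coal = dest == 0
        active[idx[coal]] = False
        state[idx[~coal]] = dest[~coal] - 1
    return _kallele_identity(nmut, K)


def pair_coalescent_island(cfg: SimConfig) -> SimEstimates:
    """Backward-time Monte Carlo estimates of (f, g_w, g_b) for the island model."""
    p = cfg.params
    if not isinstance(p, IslandParams):
        raise TypeError("pair_coalescent_island requires IslandParams")
    rng = np.random.default_rng(cfg.seed)
    n_rep = cfg.replicates
    names = ("f", "g_w", "g_b")
    starts = (0, 1, 2)
    est: dict[str, float] = {}
    ses: dict[str, float] = {}
    for name, start in zip(names, starts):
        if start == 2 and p.d < 2:
            est[name] = float("nan")
            ses[name] = float("nan")
            continue
        vals = _pair_island_once(p, start, n_rep, rng)
        est[name] = float(vals.mean())
        ses[name] = float(vals.std(ddof=1) / np.sqrt(n_rep))
    return SimEstimates(estimates=est, se=ses, n_eff=n_rep, seed=cfg.seed)


def pair_coalescent_twodeme(cfg: SimConfig) -> SimEstimates:
    """Backward-time estimates of (g_w0, g_w1, g_b) for the two-deme model.

    Simulates the continuous-time race among coalescence, migration and
    mutation; the identity indicator is 1 when coalescence wins.
    """
    sp = cfg.params
    if not isinstance(sp, ScaledTwoDemeParams):
        raise TypeError("pair_coalescent_twodeme requires ScaledTwoDemeParams")
    rng = np.random.default_rng(cfg.seed)
    n_rep = cfg.replicates
    r, M0, M1, th = sp.r, sp.M0, sp.M1, sp.theta
    # state rows W0, W1, B; event columns: coalesce, mutate, move
    rates = np.array([
        [1.0 / (2.0 * r), th, M0],
        [1.0 / (2.0 * (1.0 - r)), th, M1],
        [0.0, th, (M0 + M1) / 2.0],
    ])
    est: dict[str, float] = {}
    ses: dict[str, float] = {}
    for name, start in (("g_w0", 0), ("g_w1", 1), ("g_b", 2)):
        state = np.full(n_rep, start, dtype=np.int64)
        out = np.full(n_rep, -1.0)
        active = np.ones(n_rep, dtype=bool)
        if M0 == 0.0 and M1 == 0.0 and start == 2:
            out[:] = 0.0
            active[:] = False
            warnings.warn("no migration: between-deme identity is 0", stacklevel=2)
        while active.any():
            idx = np.flatnonzero(active)
            st = state[idx]
            rt = rates[st]
            tot = rt.sum(axis=1)
            # a state with zero total rate cannot occur here (theta = 0 with
            # start B and no migration is handled above; theta > 0 always races)
            if np.any(tot <= 0.0):
                raise RuntimeError("reducible pair chain: no event possible")
            u01 = rng.random(len(idx)) * tot
            ev = (u01 >= rt.cumsum(axis=1)[:, :2].T).sum(axis=0)  # 0 coal, 1 mut, 2 move
            coal = ev == 0
            mut = ev == 1
            out[idx[coal]] = 1.0
            out[idx[mut]] = 0.0
            active[idx[coal | mut]] = False
            mv = idx[ev == 2]
            if mv.size:
                frm = state[mv]
                dest = np.where(frm < 2, 2, 0)
                inB = frm == 2
                if inB.any():
                    # which lineage migrates: deme-0 lineage with prob M0/(M0+M1)
                    pick = rng.random(int(inB.sum())) < (M0 / (M0 + M1))
                    dest[inB] = np.where(pick, 1, 0)  # deme-0 lineage joins deme 1 -> W1
                state[mv] = dest
        vals = out
        est[name] = float(vals.mean())
        ses[name] = float(vals.std(ddof=1) / np.sqrt(n_rep))
    return SimEstimates(estimates=est, se=ses, n_eff=n_rep, seed=cfg.seed)


# ---------------------------------------------------------------------------
# synthetic genotype generation
# ---------------------------------------------------------------------------

def genotype_sample(p: IslandParams, n_individuals_per_deme: int, n_loci: int,
                    seed: int, burn_in: int | None = None,
                    locus_spacing: int | None = None):
    """Sample a genotype table from stationary island-model populations.

    Loci are independent draws: each locus is read from a widely separated
    stationary state (spacing defaults to 2 N d generations, several times
    the within-deme coalescent scale).  Individuals are drawn without
    replacement within each deme, independently per locus.
    """
    from .estimators import GenotypeTable

    if n_individuals_per_deme > p.N:
        raise ValueError(
            f"cannot sample {n_individuals_per_deme} individuals from demes of size {p.N}")
    rng = np.random.default_rng(seed)
    ids = [f"d{dm}_i{i}" for dm in range(p.d) for i in range(n_individuals_per_deme)]
    demes = [f"deme{dm}" for dm in range(p.d) for _ in range(n_individuals_per_deme)]
    loci = [f"L{j}" for j in range(n_loci)]
    n_tot = p.d * n_individuals_per_deme
    codes = np.full((n_tot, n_loci, 2), -1, dtype=np.int64)
    if n_loci == 0:
        return GenotypeTable.from_codes(ids, demes, loci, codes)

    spacing = locus_spacing if locus_spacing is not None else 2 * p.N * p.d
    if burn_in is None:
        burn_in = 20 * 2 * p.N * p.d
    states = _forward_states(p, burn_in, spacing, n_loci, rng)
    for j, pop in enumerate(states):
        for dm in range(p.d):
            take = rng.choice(p.N, size=n_individuals_per_deme, replace=False)
            rows = slice(dm * n_individuals_per_deme, (dm + 1) * n_individuals_per_deme)
            codes[rows, j, :] = pop[dm * p.N + take]
    return GenotypeTable.from_codes(ids, demes, loci, codes)


def _forward_states(p: IslandParams, burn_in: int, spacing: int, n_states: int,
                    rng: np.random.Generator):
    """Population states separated by ``spacing`` generations at stationarity."""
    deme = np.repeat(np.arange(p.d), p.N)
    pop, counter = _init_population(p, rng)
    out = []
    total = burn_in + spacing * n_states
    for gen in range(1, total + 1):
        pop, counter = _advance_generation(pop, deme, p, rng, counter)
        if gen > burn_in and (gen - burn_in) % spacing == 0:
            out.append(pop.copy())
            if len(out) == n_states:
                break
    return out
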