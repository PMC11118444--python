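"""Genotype I/O and plug-in estimators of the IBS hierarchy.

The estimators are direct sample analogs of the model parameters:

    f_hat    proportion of homozygous individuals at a locus,
    g_w_hat  mean allele-match probability over all pairs of distinct
             individuals within a deme (each pair averages its four
             cross-gene comparisons), demes weighted equally,
    g_b_hat  the same over cross-deme pairs of individuals.

No small-sample bias correction is applied: the quantities estimated are
the model's identity probabilities, not any particular unbiased F-statistic
estimator.  Multilocus combination averages the non-IBS levels h_i across
loci *before* forming ratios (ratio of averages, Nei's H-bar construction);
per-locus values are also returned so users can combine differently.

Input formats: a TSV genotype table (columns ``id``, ``deme``, then one
column per locus coded ``a/b``, missing ``./.`` or ``.``) or a VCF with
diploid GT fields plus a two-column sample-to-deme map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .hierarchy import GStatistics, NonIdentityHierarchy, level_associations

__all__ = [
    "GenotypeTable",
    "read_genotypes",
    "write_genotypes",
    "estimate_identities",
    "estimate_hierarchy",
    "IdentityEstimates",
    "HierarchyEstimate",
]

_MISSING_TOKENS = {".", "./.", ".|.", "NA", ""}


@dataclass(frozen=True)
class GenotypeTable:
    """Diploid genotypes with deme labels.

    ``codes`` is (n_individuals, n_loci, 2) of integer allele codes,
    -1 marking missing; ``alleles[j]`` maps locus-j codes back to labels.
    """

    ids: tuple[str, ...]
    demes: tuple[str, ...]
    loci: tuple[str, ...]
    codes: np.ndarray
    alleles: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.demes):
            raise ValueError("ids and demes must align")
        if self.codes.shape != (len(self.ids), len(self.loci), 2):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"({len(self.ids)}, {len(self.loci)}, 2)")
        both = (self.codes >= 0).sum(axis=2)
        if np.any(both == 1):
            raise ValueError("half-missing genotypes are not representable")

    @classmethod
    def from_codes(cls, ids, demes, loci, codes, alleles=None) -> "GenotypeTable":
        codes = np.asarray(codes, dtype=np.int64)
        if alleles is None:
            # compact raw labels to 0..k-1 per locus, keeping -1 for missing
            alleles_list = []
            remapped = np.full_like(codes, -1)
            for j in range(codes.shape[1]):
                col = codes[:, j, :]
                present = col >= 0
                uniq, inv = np.unique(col[present], return_inverse=True)
                remapped[:, j, :][present] = inv
                alleles_list.append(tuple(str(int(a)) for a in uniq))
            codes = remapped
            alleles = tuple(alleles_list)
        return cls(tuple(ids), tuple(demes), tuple(loci), codes,
                   tuple(tuple(a) for a in alleles))

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def deme_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for d in self.demes:
            seen.setdefault(d, None)
        return tuple(seen)


def _parse_token(token: str, lut: dict[str, int], lineno: int, locus: str) -> tuple[int, int]:
    token = token.strip()
    if token in _MISSING_TOKENS:
        return -1, -1
    sep = "/" if "/" in token else ("|" if "|" in token else None)
    if sep is None:
        raise ValueError(
            f"line {lineno}: malformed genotype {token!r} at locus {locus} "
            "(expected 'a/b')")
    parts = token.split(sep)
    if len(parts) != 2 or not parts[0] or not parts[1]:
        raise ValueError(
            f"line {lineno}: malformed genotype {token!r} at locus {locus}")
    if "." in parts:
        if parts[0] == parts[1] == ".":
            return -1, -1
        raise ValueError(
            f"line {lineno}: half-missing genotype {token!r} at locus {locus}")
    out = []
    for p in parts:
        if p not in lut:
            lut[p] = len(lut)
        out.append(lut[p])
    return out[0], out[1]


def _read_table(path: str | Path) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2 or list(df.columns[:2]) != ["id", "deme"]:
        raise ValueError(f"{path}: first two columns must be 'id' and 'deme'")
    loci = list(df.columns[2:])
    n, L = len(df), len(loci)
    codes = np.full((n, L, 2), -1, dtype=np.int64)
    luts: list[dict[str, int]] = [dict() for _ in loci]
    values = df.iloc[:, 2:].to_numpy(dtype=object) if L else np.empty((n, 0), dtype=object)
    for i in range(n):
        for j, locus in enumerate(loci):
            token = values[i, j]
            token = "" if token is None or (isinstance(token, float) and np.isnan(token)) else str(token)
            codes[i, j] = _parse_token(token, luts[j], i + 2, locus)
    alleles = tuple(tuple(sorted(lut, key=lut.get)) for lut in luts)
    return GenotypeTable(tuple(df["id"].astype(str)), tuple(df["deme"].astype(str)),
                         tuple(loci), codes, alleles)


def _read_deme_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: deme map needs two columns (sample, deme)")
    return dict(zip(df[0], df[1]))


def _read_vcf(path: str | Path, deme_map: dict[str, str]) -> GenotypeTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in deme_map]
    if missing:
        raise ValueError(f"samples absent from deme map: {', '.join(missing)}")
    loci: list[str] = []
    cols: list[np.ndarray] = []
    alleles: list[tuple[str, ...]] = []
    for var in vcf:
        name = var.ID or f"{var.CHROM}:{var.POS}"
        col = np.full((len(samples), 2), -1, dtype=np.int64)
        for i, gt in enumerate(var.genotypes):
            ploidy = len(gt) - 1  # last entry is the phased flag
            if ploidy != 2:
                raise ValueError(
                    f"sample {samples[i]} at {name}: ploidy {ploidy}, need diploid")
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue
            col[i] = (a, b)
        loci.append(name)
        cols.append(col)
        alleles.append(tuple([var.REF] + list(var.ALT)))
    codes = (np.stack(cols, axis=1) if cols
             else np.empty((len(samples), 0, 2), dtype=np.int64))
    return GenotypeTable(tuple(samples), tuple(deme_map[s] for s in samples),
                         tuple(loci), codes, tuple(alleles))


def read_genotypes(path: str | Path, format: str = "table",
                   deme_map: str | Path | None = None) -> GenotypeTable:
    """Read genotypes from a TSV table or a VCF (with a sample-to-deme map)."""
    if format == "table":
        return _read_table(path)
    if format == "vcf":
        if deme_map is None:
            raise ValueError("VCF input requires a deme_map file")
        return _read_vcf(path, _read_deme_map(deme_map))
    raise ValueError(f"unknown format {format!r} (expected 'table' or 'vcf')")


def write_genotypes(g: GenotypeTable, path: str | Path) -> None:
    """Write the TSV genotype-table dialect read by :func:`read_genotypes`."""
    with open(path, "w") as fh:
        fh.write("id\tdeme" + "".join(f"\t{l}" for l in g.loci) + "\n")
        for i in range(g.n_individuals):
            row = [g.ids[i], g.demes[i]]
            for j in range(g.n_loci):
                a, b = g.codes[i, j]
                if a < 0:
                    row.append("./.")
                else:
                    lab = g.alleles[j]
                    row.append(f"{lab[a]}/{lab[b]}")
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IdentityEstimates:
    """Per-locus and combined plug-in IBS estimates.

    Combined values are unweighted means of the per-locus values; a
    statistic that no locus could supply is NaN, never zero.
    """

    f_locus: np.ndarray        # (L,)
    g_w_locus: np.ndarray      # (L,) equal-deme-weight means
    g_b_locus: np.ndarray      # (L,) means over deme pairs
    g_w_deme: pd.DataFrame     # loci x demes
    g_b_pair: pd.DataFrame     # loci x deme pairs
    f: float
    g_w: float
    g_b: float


def _locus_identity_counts(codes: np.ndarray, deme_idx: np.ndarray, n_demes: int):
    """Within- and between-deme gene-identity sums for one locus.

    Returns per-deme g_w (NaN when < 2 callable individuals), the deme-pair
    g_b matrix (NaN for uncallable pairs), and the homozygote fraction.
    """
    called = codes[:, 0] >= 0
    f_hat = float((codes[called, 0] == codes[called, 1]).mean()) if called.any() else np.nan

    L = int(codes.max()) + 1 if called.any() else 1
    counts = np.zeros((n_demes, L))
    hom = np.zeros(n_demes)
    n_called = np.zeros(n_demes)
    for dm in range(n_demes):
        rows = called & (deme_idx == dm)
        n_called[dm] = rows.sum()
        if not rows.any():
            continue
        sub = codes[rows]
        np.add.at(counts[dm], sub.ravel(), 1.0)
        hom[dm] = (sub[:, 0] == sub[:, 1]).sum()
    G = counts @ counts.T
    g_w = np.full(n_demes, np.nan)
    for dm in range(n_demes):
        n = n_called[dm]
        if n >= 2:
            g_w[dm] = (G[dm, dm] - (2.0 * n + 2.0 * hom[dm])) / (2.0 * n * (2.0 * n - 2.0))
    g_b = np.full((n_demes, n_demes), np.nan)
    for a in range(n_demes):
        for b in range(a + 1, n_demes):
            if n_called[a] >= 1 and n_called[b] >= 1:
                g_b[a, b] = G[a, b] / (4.0 * n_called[a] * n_called[b])
    return f_hat, g_w, g_b, n_called


def estimate_identities(g: GenotypeTable) -> IdentityEstimates:
    """Plug-in estimates of (f, g_w, g_b) per locus and combined."""
    demes = g.deme_names
    deme_idx = np.array([demes.index(d) for d in g.demes])
    nd = len(demes)
    L = g.n_loci
    f_l = np.full(L, np.nan)
    gw_l = np.full(L, np.nan)
    gb_l = np.full(L, np.nan)
    gw_deme = np.full((L, nd), np.nan)
    pairs = [(a, b) for a in range(nd) for b in range(a + 1, nd)]
    gb_pair = np.full((L, len(pairs)), np.nan)
    for j in range(L):
        f_hat, g_w, g_b, _ = _locus_identity_counts(g.codes[:, j, :], deme_idx, nd)
        f_l[j] = f_hat
        gw_deme[j] = g_w
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            gw_l[j] = np.nanmean(g_w) if not np.all(np.isnan(g_w)) else np.nan
        for k, (a, b) in enumerate(pairs):
            gb_pair[j, k] = g_b[a, b]
        if pairs:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                gb_l[j] = (np.nanmean(gb_pair[j])
                           if not np.all(np.isnan(gb_pair[j])) else np.nan)

    def _combine(x: np.ndarray) -> float:
        ok = ~np.isnan(x)
        return float(x[ok].mean()) if ok.any() else float("nan")

    return IdentityEstimates(
        f_locus=f_l, g_w_locus=gw_l, g_b_locus=gb_l,
        g_w_deme=pd.DataFrame(gw_deme, index=list(g.loci), columns=list(demes)),
        g_b_pair=pd.DataFrame(
            gb_pair, index=list(g.loci),
            columns=[f"{demes[a]}|{demes[b]}" for a, b in pairs]),
        f=_combine(f_l), g_w=_combine(gw_l), g_b=_combine(gb_l),
    )


@dataclass(frozen=True)
class HierarchyEstimate:
    """Per-locus and multilocus hierarchy levels and G*-statistics."""

    h_locus: np.ndarray            # (L, 3) or (L, 2) for a single deme
    h_combined: NonIdentityHierarchy
    g_combined: GStatistics
    g_locus: list[GStatistics | None]
    identities: IdentityEstimates
    N_used: float
    d_used: int


def estimate_hierarchy(g: GenotypeTable, N: int | None = None,
                       d: int | None = None) -> HierarchyEstimate:
    """Assemble the non-IBS hierarchy from genotype data.

    ``N`` and ``d`` default to the sampled counts (mean individuals per deme
    and number of demes); pass census values to override — the 1/N terms in
    the h-formulas refer to the census deme size, and the sampled size is
    only a stand-in when the census is unknown.

    Multilocus G-statistics come from loci-averaged h-levels (ratio of
    averages).  With a single deme only the within-deme level exists: the
    hierarchy is (h_0, h_1) and G_2* is not defined.
    """
    ids = estimate_identities(g)
    if ids.f == 1.0 and ids.g_w == 1.0 and (np.isnan(ids.g_b) or ids.g_b == 1.0):
        raise ValueError("monomorphic data: no variation to partition")
    demes = g.deme_names
    d_used = d if d is not None else len(demes)
    if N is None:
        per_deme = pd.Series(list(g.demes)).value_counts()
        N_used = float(per_deme.mean())
    else:
        N_used = float(N)
    if N_used < 1:
        raise ValueError("N must be >= 1")

    L = g.n_loci
    multi_deme = len(demes) >= 2 and d_used >= 2
    width = 3 if multi_deme else 2
    h_locus = np.full((L, width), np.nan)
    g_locus: list[GStatistics | None] = []
    for j in range(L):
        f, gw, gb = ids.f_locus[j], ids.g_w_locus[j], ids.g_b_locus[j]
        if np.isnan(f) or np.isnan(gw) or (multi_deme and np.isnan(gb)):
            g_locus.append(None)
            continue
        h0 = 1.0 - f
        h1 = ((1.0 + f) / 2.0) / N_used + (1.0 - gw) * (1.0 - 1.0 / N_used)
        if multi_deme:
            h2 = h1 / d_used + (1.0 - gb) * (1.0 - 1.0 / d_used)
            h_locus[j] = (h0, h1, h2)
        else:
            h_locus[j] = (h0, h1)
        try:
            g_locus.append(level_associations(tuple(h_locus[j])))
        except ValueError:
            g_locus.append(None)

    ok = ~np.isnan(h_locus[:, 0])
    if not ok.any():
        raise ValueError("no locus yielded a complete set of identity estimates")
    h_mean = h_locus[ok].mean(axis=0)
    h_combined = NonIdentityHierarchy(tuple(h_mean))
    g_combined = level_associations(h_combined)  # raises on monomorphic data
    return HierarchyEstimate(
        h_locus=h_locus, h_combined=h_combined, g_combined=g_combined,
        g_locus=g_locus, identities=ids, N_used=N_used, d_used=d_used,
    )
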