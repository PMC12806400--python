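"""Taxon-compound associations, functional groups, and community statistics.

The screening core: Spearman (or Pearson) correlations between every genus
and every measured compound, Benjamini-Hochberg adjusted within each
compound-class family, then rule-based group assignment:

* **Flavor group** — taxa with at least one strong positive association to
  an ester AND one to an acid (acid or organic_acid class);
* **Amino-acid group** — taxa with >= ``min_hits`` strong positive
  associations to free amino acids;
* **Major group** — mean relative abundance strictly above 0.1 %.

Also provides the community-level statistics used alongside the screen:
alpha diversity (Shannon, Pielou evenness, observed genera), Bray-Curtis /
Jaccard distance matrices, the Mantel permutation test between two distance
matrices, and ANOSIM group separation.  Permutation p-values use the
(1 + exceedances) / (1 + permutations) convention so p is never zero;
exhaustive enumeration is available for small n.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .tables_io import (
    ACID_CLASSES,
    AbundanceTable,
    CompoundTable,
    DataValidationError,
)

ASSOCIATION_COLUMNS = ["taxon", "compound", "compound_class", "rho", "p", "q", "n", "degenerate"]


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise DataValidationError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise DataValidationError("distance matrix is not symmetric")
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def pairwise_association(
    abund: AbundanceTable,
    comp: CompoundTable,
    method: str = "spearman",
) -> pd.DataFrame:
    """Correlate every (taxon, compound) pair across shared samples.

    Returns one row per pair with rho, the test p-value, and a BH-adjusted
    q computed within each compound-class family.  Constant vectors are
    flagged degenerate with rho 0 and p 1.
    """
    if method not in ("spearman", "pearson"):
        raise DataValidationError(f"unknown correlation method {method!r}")
    shared = [s for s in abund.samples if s in set(comp.samples)]
    if len(shared) < 4:
        raise DataValidationError(
            f"need >= 4 shared samples for correlation, got {len(shared)}"
        )
    a = abund.data[shared].to_numpy()
    c = comp.data[shared].to_numpy()
    n = len(shared)
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr

    rows = []
    for i, taxon in enumerate(abund.taxa):
        x = a[i]
        x_const = np.ptp(x) == 0
        for j, compound in enumerate(comp.compounds):
            y = c[j]
            if x_const or np.ptp(y) == 0:
                rho, p, degenerate = 0.0, 1.0, True
            else:
                res = corr(x, y)
                rho, p = float(res.statistic), float(res.pvalue)
                degenerate = False
                if not np.isfinite(rho):
                    rho, p, degenerate = 0.0, 1.0, True
            rows.append(
                (taxon, compound, comp.compound_class[compound], rho, p, n, degenerate)
            )
    out = pd.DataFrame(
        rows, columns=["taxon", "compound", "compound_class", "rho", "p", "n", "degenerate"]
    )
    out["q"] = np.nan
    for _, idx in out.groupby("compound_class").groups.items():
        out.loc[idx, "q"] = multipletests(out.loc[idx, "p"], method="fdr_bh")[1]
    return out[ASSOCIATION_COLUMNS]


def _positive_hits(
    results: pd.DataFrame, classes: frozenset[str] | set[str], alpha: float, rho_min: float
) -> pd.DataFrame:
    mask = (
        results["compound_class"].isin(classes)
        & (results["rho"] >= rho_min)
        & (results["q"] < alpha)
        & ~results["degenerate"]
    )
    return results[mask]


def assign_flavor_group(
    results: pd.DataFrame, alpha: float = 0.05, rho_min: float = 0.6
) -> set[str]:
    """Taxa strongly associated with both ester and acid production."""
    classes = set(results["compound_class"])
    if "ester" not in classes:
        raise DataValidationError("no ester-class compounds in association results")
    if not (classes & ACID_CLASSES):
        raise DataValidationError("no acid-class compounds in association results")
    ester_taxa = set(_positive_hits(results, {"ester"}, alpha, rho_min)["taxon"])
    acid_taxa = set(_positive_hits(results, ACID_CLASSES, alpha, rho_min)["taxon"])
    return ester_taxa & acid_taxa


def assign_amino_acid_group(
    results: pd.DataFrame,
    alpha: float = 0.05,
    rho_min: float = 0.6,
    min_hits: int = 2,
) -> set[str]:
    """Taxa with at least ``min_hits`` strong free-amino-acid associations."""
    if "amino_acid" not in set(results["compound_class"]):
        raise DataValidationError("no amino_acid-class compounds in association results")
    hits = _positive_hits(results, {"amino_acid"}, alpha, rho_min)
    counts = hits.groupby("taxon").size()
    return set(counts[counts >= min_hits].index)


def assign_major_group(abund: AbundanceTable, threshold: float = 0.001) -> set[str]:
    """Taxa whose mean relative abundance strictly exceeds the threshold."""
    means = abund.data.mean(axis=1)
    return set(means[means > threshold].index)


def distance_matrix(abund: AbundanceTable, metric: str = "bray_curtis") -> DistanceMatrix:
    """Pairwise sample dissimilarities (Bray-Curtis or presence Jaccard)."""
    x = abund.data.to_numpy().T  # samples x taxa
    zero = np.flatnonzero(x.sum(axis=1) <= 0)
    if len(zero):
        raise DataValidationError(
            f"all-zero samples have no defined dissimilarity: "
            f"{[abund.samples[i] for i in zero]}"
        )
    if metric == "bray_curtis":
        d = pdist(x, metric="braycurtis")
    elif metric == "jaccard":
        d = pdist(x > 0, metric="jaccard")
    elif metric == "euclidean":
        d = pdist(x, metric="euclidean")
    else:
        raise DataValidationError(f"unknown metric {metric!r}")
    return DistanceMatrix(abund.samples, squareform(d), metric)


def compound_distance_matrix(comp: CompoundTable, standardize: bool = True) -> DistanceMatrix:
    """Euclidean sample distances on (optionally z-scored) compound profiles."""
    x = comp.data.to_numpy().T
    if standardize:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    return DistanceMatrix(comp.samples, squareform(pdist(x)), "euclidean")


def _tri_corr(v1: np.ndarray, v2: np.ndarray, method: str) -> float:
    if method == "spearman":
        v1 = stats.rankdata(v1)
        v2 = stats.rankdata(v2)
    v1 = v1 - v1.mean()
    v2 = v2 - v2.mean()
    denom = np.sqrt((v1 @ v1) * (v2 @ v2))
    if denom == 0:
        raise DataValidationError("degenerate (constant) distance matrix in Mantel test")
    return float(v1 @ v2 / denom)


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "spearman",
    permutations: int = 999,
    seed: int = 0,
    exact: bool = False,
) -> tuple[float, float]:
    """Mantel permutation test of association between two distance matrices.

    The second matrix's rows and columns are permuted jointly.  With
    ``exact=True`` all n! permutations are enumerated (n <= 8 enforced) and
    p = #{r_perm >= r_obs} / n! (the identity permutation is included).
    """
    if d1.labels != d2.labels:
        raise DataValidationError("Mantel test requires identical sample labels/order")
    n = len(d1.labels)
    if n < 4:
        raise DataValidationError("Mantel test needs >= 4 samples")
    iu = np.triu_indices(n, k=1)
    v1 = d1.values[iu]
    r_obs = _tri_corr(v1, d2.values[iu], method)
    if exact:
        if n > 8:
            raise DataValidationError("exact Mantel enumeration limited to n <= 8")
        count, total = 0, 0
        for perm in itertools.permutations(range(n)):
            p = np.asarray(perm)
            r = _tri_corr(v1, d2.values[np.ix_(p, p)][iu], method)
            count += r >= r_obs - 1e-12
            total += 1
        return r_obs, count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        p = rng.permutation(n)
        r = _tri_corr(v1, d2.values[np.ix_(p, p)][iu], method)
        count += r >= r_obs
    return r_obs, (1 + count) / (1 + permutations)


def _anosim_r(ranks: np.ndarray, same_group: np.ndarray, n: int) -> float:
    rb = ranks[~same_group].mean()
    rw = ranks[same_group].mean()
    return float((rb - rw) / (n * (n - 1) / 4.0))


def anosim(
    d: DistanceMatrix,
    labels: list[str] | np.ndarray | pd.Series,
    permutations: int = 999,
    seed: int = 0,
    exact: bool = False,
) -> tuple[float, float]:
    """ANOSIM rank-based between/within group separation on a distance matrix.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4),
    with all M = n(n-1)/2 pairwise distances ranked once (average ranks on
    ties).  p by label permutation; ``exact=True`` enumerates every distinct
    assignment of samples to the observed group sizes.
    """
    labels = np.asarray(labels)
    n = len(d.labels)
    if len(labels) != n:
        raise DataValidationError("labels length does not match distance matrix")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise DataValidationError("ANOSIM needs >= 2 groups")
    if (counts < 2).any():
        small = groups[counts < 2].tolist()
        raise DataValidationError(f"ANOSIM groups with a single member: {small}")
    iu = np.triu_indices(n, k=1)
    ranks = stats.rankdata(d.values[iu])
    same = labels[iu[0]] == labels[iu[1]]
    r_obs = _anosim_r(ranks, same, n)

    if exact:
        codes = np.searchsorted(groups, labels)
        seen = set()
        count = total = 0
        for perm in itertools.permutations(range(n)):
            key = tuple(codes[list(perm)])
            if key in seen:
                continue
            seen.add(key)
            lab = np.asarray(key)
            r = _anosim_r(ranks, lab[iu[0]] == lab[iu[1]], n)
            count += r >= r_obs - 1e-12
            total += 1
        return r_obs, count / total

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        lab = rng.permutation(labels)
        r = _anosim_r(ranks, lab[iu[0]] == lab[iu[1]], n)
        count += r >= r_obs
    return r_obs, (1 + count) / (1 + permutations)


def alpha_diversity(abund: AbundanceTable) -> pd.DataFrame:
    """Per-sample Shannon entropy (nats), Pielou evenness, observed genera.

    Pielou = H / ln(S); defined as 0 for single-taxon samples.
    """
    out = []
    for s in abund.samples:
        p = abund.data[s].to_numpy()
        p = p[p > 0]
        total = p.sum()
        if total <= 0:
            raise DataValidationError(f"all-zero sample {s!r} has no diversity")
        p = p / total
        shannon = float(-(p * np.log(p)).sum())
        observed = int(len(p))
        pielou = shannon / np.log(observed) if observed > 1 else 0.0
        out.append((s, shannon, pielou, observed))
    return pd.DataFrame(out, columns=["sample_id", "shannon", "pielou", "observed"]).set_index(
        "sample_id"
    )
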