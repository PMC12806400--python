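"""Community-assembly analysis: Raup-Crick null model and NMDS ordination.

The Raup-Crick index standardizes how many genera two samples share
against a null model in which each community is reassembled at its observed
richness by drawing species from the regional pool with probability
proportional to occurrence frequency (sequential weighted draws without
replacement).  With the half-weight tie convention,

    p_sim = (#{null_shared > obs} + 0.5 * #{null_shared = obs}) / reps
    RC    = 2 * (p_sim - 0.5)            in [-1, 1]

RC near -1 means the pair shares more species than the null expects
(deterministic assembly), near +1 fewer than expected, near 0 neutral.
Null communities are drawn with the Gumbel-top-k formulation of weighted
sampling without replacement, which is distributionally identical to
sequential renormalized draws and vectorizes over replicates.

NMDS is nonmetric SMACOF: configuration distances are monotonically
(isotonically) regressed on the input dissimilarities and the reported fit
is Kruskal stress-1 = sqrt(sum (dhat - d)^2 / sum d^2); the best of several
random restarts is returned.  RC matrices are shifted by (RC + 1) / 2
before embedding — a rank-preserving map to non-negative dissimilarities.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .association import DistanceMatrix
from .tables_io import AbundanceTable, DataValidationError, NumericError, SampleMetadata


@dataclass
class RCMatrix:
    """Pairwise Raup-Crick values with the null-model parameters used."""

    labels: list[str]
    values: np.ndarray
    reps: int
    seed: int
    pool_frequencies: pd.Series

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T, atol=0):
            raise DataValidationError("RC matrix must be exactly symmetric")
        off = v[~np.eye(len(v), dtype=bool)]
        if len(off) and (np.abs(off) > 1 + 1e-12).any():
            raise DataValidationError("RC values must lie in [-1, 1]")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# raup_crick reps={self.reps} seed={self.seed}\n")
            self.to_frame().rename_axis("sample_id").to_csv(fh, sep="\t")


@dataclass
class NMDSResult:
    coordinates: pd.DataFrame  # samples x k
    stress: float
    converged: bool
    restarts_used: int

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# nmds stress={self.stress:.6g} converged={self.converged} "
                f"restarts={self.restarts_used}\n"
            )
            self.coordinates.rename_axis("sample_id").to_csv(fh, sep="\t")


def _draw_shared_counts(
    rng: np.random.Generator, log_w: np.ndarray, n1: int, n2: int, reps: int
) -> np.ndarray:
    """Shared-species counts for ``reps`` independent null community pairs."""
    s = len(log_w)
    shared = np.empty(reps, dtype=np.int64)
    # batch to bound memory at reps ~ 1e5
    step = max(1, min(reps, 20_000))
    done = 0
    while done < reps:
        b = min(step, reps - done)
        g1 = log_w[None, :] + rng.gumbel(size=(b, s))
        g2 = log_w[None, :] + rng.gumbel(size=(b, s))
        m1 = np.zeros((b, s), dtype=bool)
        m2 = np.zeros((b, s), dtype=bool)
        idx1 = np.argpartition(-g1, n1 - 1, axis=1)[:, :n1]
        idx2 = np.argpartition(-g2, n2 - 1, axis=1)[:, :n2]
        np.put_along_axis(m1, idx1, True, axis=1)
        np.put_along_axis(m2, idx2, True, axis=1)
        shared[done : done + b] = (m1 & m2).sum(axis=1)
        done += b
    return shared


def rc_from_null_counts(null_shared: np.ndarray, obs: int) -> float:
    """Fold null shared-species counts into an RC value (half-weight ties)."""
    reps = len(null_shared)
    p_sim = ((null_shared > obs).sum() + 0.5 * (null_shared == obs).sum()) / reps
    return float(2.0 * (p_sim - 0.5))


def raup_crick(abund: AbundanceTable, reps: int = 999, seed: int = 0) -> RCMatrix:
    """Pairwise Raup-Crick matrix for the samples of ``abund``.

    Presence is abundance > 0; the regional pool is every genus observed in
    at least one sample, weighted by its occurrence count.  Each pair draws
    its nulls from an independent sub-stream keyed by the pair's (sorted)
    index, so results do not depend on evaluation order.
    """
    presence = abund.data.to_numpy() > 0
    freq = presence.sum(axis=1)
    pool = freq > 0
    if not pool.any():
        raise DataValidationError("empty regional pool: no genus present anywhere")
    richness = presence.sum(axis=0)
    empty = np.flatnonzero(richness == 0)
    if len(empty):
        raise DataValidationError(
            f"samples with zero richness: {[abund.samples[i] for i in empty]}"
        )
    pres = presence[pool]
    log_w = np.log(freq[pool].astype(float))
    n = len(abund.samples)
    if n < 2:
        raise DataValidationError("Raup-Crick needs >= 2 samples")

    rc = np.zeros((n, n))
    labels = abund.samples
    for i in range(n):
        for j in range(i + 1, n):
            obs = int((pres[:, i] & pres[:, j]).sum())
            # sub-stream keyed on the (sorted) sample labels, so the value
            # for a pair does not depend on sample order or visit order
            if labels[i] <= labels[j]:
                a, b = labels[i], labels[j]
                ra, rb = int(richness[i]), int(richness[j])
            else:
                a, b = labels[j], labels[i]
                ra, rb = int(richness[j]), int(richness[i])
            key = (zlib.crc32(a.encode()), zlib.crc32(b.encode()))
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))
            null = _draw_shared_counts(rng, log_w, ra, rb, reps)
            rc[i, j] = rc[j, i] = rc_from_null_counts(null, obs)
    return RCMatrix(
        labels=abund.samples,
        values=rc,
        reps=reps,
        seed=seed,
        pool_frequencies=pd.Series(freq[pool], index=np.asarray(abund.taxa)[pool]),
    )


# --- NMDS -------------------------------------------------------------------


def _monotone_fit(delta: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Least-squares monotone regression of dist on delta (ties averaged)."""
    order = np.argsort(delta, kind="stable")
    d_sorted = delta[order]
    # collapse tied dissimilarities into weighted blocks (secondary approach)
    block_start = np.flatnonzero(np.r_[True, np.diff(d_sorted) > 0])
    block_id = np.cumsum(np.r_[True, np.diff(d_sorted) > 0]) - 1
    y = dist[order]
    counts = np.bincount(block_id)
    means = np.bincount(block_id, weights=y) / counts
    fit = isotonic_regression(means, weights=counts, increasing=True).x
    out = np.empty_like(dist)
    out[order] = fit[block_id]
    return out


def kruskal_stress(delta: np.ndarray, dist: np.ndarray) -> float:
    """Kruskal stress-1 of configuration distances against dissimilarities."""
    dhat = _monotone_fit(delta, dist)
    denom = float((dist**2).sum())
    if denom <= 0:
        raise NumericError("degenerate NMDS configuration (all points coincide)")
    return float(np.sqrt(((dhat - dist) ** 2).sum() / denom))


def _guttman_update(x: np.ndarray, delta: np.ndarray, n: int) -> np.ndarray:
    dist = pdist(x)
    dhat = _monotone_fit(delta, dist)
    # fix disparity scale so the iteration cannot shrink to the origin
    scale = np.sqrt(len(dhat) / max((dhat**2).sum(), 1e-300))
    dhat = dhat * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dist > 0, dhat / dist, 0.0)
    b = -squareform(ratio)
    np.fill_diagonal(b, -b.sum(axis=1))
    return b @ x / n


def nmds(
    d: "DistanceMatrix | RCMatrix",
    k: int = 2,
    restarts: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> NMDSResult:
    """Nonmetric multidimensional scaling by SMACOF with isotonic disparities.

    Returns the centered configuration with the lowest Kruskal stress-1
    over ``restarts`` random initializations.
    """
    values = np.asarray(d.values, dtype=float)
    if isinstance(d, RCMatrix):
        values = (values + 1.0) / 2.0
        np.fill_diagonal(values, 0.0)
    if not np.isfinite(values).all():
        raise NumericError("non-finite dissimilarity passed to NMDS")
    n = len(d.labels)
    if n < k + 1:
        raise DataValidationError(f"NMDS with k={k} needs at least {k + 1} samples")
    delta = squareform(values, checks=False)

    rng = np.random.default_rng(seed)
    best_x, best_stress, best_converged = None, np.inf, False
    for _ in range(restarts):
        x = rng.normal(size=(n, k))
        prev = np.inf
        converged = False
        for _ in range(max_iter):
            x = _guttman_update(x, delta, n)
            stress = kruskal_stress(delta, pdist(x))
            if prev - stress < tol:
                converged = True
                break
            prev = stress
        stress = kruskal_stress(delta, pdist(x))
        if stress < best_stress:
            best_x, best_stress, best_converged = x, stress, converged
    assert best_x is not None
    best_x = best_x - best_x.mean(axis=0, keepdims=True)
    # report stress recomputed at the final (centered) coordinates
    best_stress = kruskal_stress(delta, pdist(best_x))
    coords = pd.DataFrame(
        best_x, index=d.labels, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return NMDSResult(coords, best_stress, best_converged, restarts)


def assembly_summary(
    rc: RCMatrix,
    meta: SampleMetadata,
    deterministic_band: float = 0.95,
    neutral_band: float = 0.5,
) -> pd.DataFrame:
    """Aggregate within-group RC values per fermentation day and overall.

    Reports, for each group (and each day with >= 2 samples), the mean RC,
    the fraction with |RC| above the deterministic band, and the fraction
    with |RC| below the neutral band.
    """
    missing = [s for s in rc.labels if s not in meta.frame.index]
    if missing:
        raise DataValidationError(f"RC samples absent from metadata: {missing}")
    frame = meta.frame.loc[rc.labels]
    idx = {s: i for i, s in enumerate(rc.labels)}
    rows = []
    for group, sub in frame.groupby("group", sort=True):
        scopes: list[tuple[object, list[str]]] = [("all", list(sub.index))]
        for day, day_sub in sub.groupby("day", sort=True):
            scopes.append((int(day), list(day_sub.index)))
        for day, members in scopes:
            pairs = [
                rc.values[idx[a], idx[b]]
                for ai, a in enumerate(members)
                for b in members[ai + 1 :]
            ]
            if not pairs:
                continue
            vals = np.asarray(pairs)
            rows.append(
                (
                    group,
                    day,
                    len(vals),
                    float(vals.mean()),
                    float((np.abs(vals) > deterministic_band).mean()),
                    float((np.abs(vals) < neutral_band).mean()),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["group", "day", "n_pairs", "mean_rc", "frac_deterministic", "frac_neutral"],
    )
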