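"""Community statistics for the detection matrix and the visual census.

Replicate-based species accumulation, incidence Chao1 richness (singletons
and doubletons counted over PCR replicates), surface/bottom partitions,
per-station group counts, Bray-Curtis dissimilarity, a permutation-tested
Mantel correlogram of community similarity against geographic distance, exact
sample-based rarefaction (species accumulation) curves, and the detection
rate / detection efficiency comparison against visual census records.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln

from .decontam import DetectionMatrix
from .simulate import BOTTOM, SURFACE


# --------------------------------------------------------------------------
# richness
# --------------------------------------------------------------------------
@dataclass
class RichnessEstimate:
    """Chao1 estimate from replicate incidence of one water sample."""

    s_obs: int
    f1: int
    f2: int
    chao1: float


def chao1(incidence: np.ndarray | pd.DataFrame, bias_corrected: bool = True) -> RichnessEstimate:
    """Incidence-based Chao1 over PCR replicates.

    ``incidence`` is species x replicates (boolean or counts).  A singleton
    is a species seen in exactly one replicate, a doubleton in exactly two.
    The bias-corrected form S_obs + f1(f1-1)/(2(f2+1)) stays defined at
    f2 = 0; the classic form f1^2/(2 f2) is available and returns infinity
    when f2 = 0 with f1 > 0.
    """
    arr = np.asarray(incidence, dtype=bool)
    if arr.ndim != 2:
        raise ValueError("incidence must be species x replicates")
    det = arr.sum(axis=1)
    s_obs = int((det > 0).sum())
    f1 = int((det == 1).sum())
    f2 = int((det == 2).sum())
    if bias_corrected:
        estimate = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    elif f2 > 0:
        estimate = s_obs + f1**2 / (2.0 * f2)
    else:
        estimate = math.inf if f1 > 0 else float(s_obs)
    return RichnessEstimate(s_obs, f1, f2, float(estimate))


def replicate_accumulation(matrix: DetectionMatrix, layer: str) -> pd.DataFrame:
    """Mean detected species over all size-k subsets of PCR replicates.

    For each station in the given layer the detected-species count of every
    subset of k replicates is averaged (k = 1..R); the station means are then
    averaged.  Returns a frame with columns k, mean_species, n_stations.
    """
    detected = matrix.detected()
    detected = detected[detected["layer"] == layer]
    replicates = sorted(matrix.data["replicate"].unique())
    r = len(replicates)
    per_station: list[list[float]] = []
    for station, group in detected.groupby("station"):
        sets = {
            rep: set(group.loc[group["replicate"] == rep, "taxon"]) for rep in replicates
        }
        means = []
        for k in range(1, r + 1):
            sizes = [
                len(set().union(*(sets[rep] for rep in combo)))
                for combo in itertools.combinations(replicates, k)
            ]
            means.append(float(np.mean(sizes)))
        per_station.append(means)
    if not per_station:
        return pd.DataFrame(columns=["k", "mean_species", "n_stations"])
    arr = np.array(per_station)
    return pd.DataFrame(
        {"k": np.arange(1, r + 1), "mean_species": arr.mean(axis=0), "n_stations": len(arr)}
    )


def richness_table(matrix: DetectionMatrix, bias_corrected: bool = True) -> pd.DataFrame:
    """Per-station, per-layer observed richness and Chao1 estimates."""
    rows = []
    layers = [l for l in (SURFACE, BOTTOM) if (matrix.data["layer"] == l).any()]
    for station in sorted(matrix.data["station"].unique()):
        for layer in layers:
            inc = matrix.station_layer_incidence(station, layer)
            if inc.empty:
                continue
            est = chao1(inc.to_numpy(), bias_corrected)
            rows.append(
                {
                    "station": station,
                    "layer": layer,
                    "s_obs": est.s_obs,
                    "f1": est.f1,
                    "f2": est.f2,
                    "chao1": est.chao1,
                }
            )
    return pd.DataFrame(rows, columns=["station", "layer", "s_obs", "f1", "f2", "chao1"])


def mean_chao1(matrix: DetectionMatrix, layer: str, bias_corrected: bool = True) -> float:
    """Mean Chao1 richness across stations of one layer."""
    table = richness_table(matrix, bias_corrected)
    table = table[table["layer"] == layer]
    return float(table["chao1"].mean()) if len(table) else float("nan")


# --------------------------------------------------------------------------
# layer partition and station group counts
# --------------------------------------------------------------------------
@dataclass
class LayerPartition:
    surface_only: int
    bottom_only: int
    both: int
    detections_surface: int
    detections_bottom: int

    @property
    def total_species(self) -> int:
        return self.surface_only + self.bottom_only + self.both

    @property
    def total_detections(self) -> int:
        return self.detections_surface + self.detections_bottom


def partition_by_layer(matrix: DetectionMatrix) -> LayerPartition:
    """Split the species inventory into surface-only / bottom-only / both."""
    surface = matrix.species_by_layer(SURFACE)
    bottom = matrix.species_by_layer(BOTTOM)
    detected = matrix.detected()
    return LayerPartition(
        surface_only=len(surface - bottom),
        bottom_only=len(bottom - surface),
        both=len(surface & bottom),
        detections_surface=int((detected["layer"] == SURFACE).sum()),
        detections_bottom=int((detected["layer"] == BOTTOM).sum()),
    )


def partition_from_sets(surface: set, bottom: set) -> LayerPartition:
    """Partition arithmetic on explicit per-layer species sets."""
    return LayerPartition(
        surface_only=len(surface - bottom),
        bottom_only=len(bottom - surface),
        both=len(surface & bottom),
        detections_surface=0,
        detections_bottom=0,
    )


def station_group_counts(
    matrix: DetectionMatrix, habitat_of: Mapping[str, str], fishery: Iterable[str]
) -> pd.DataFrame:
    """Per-station species counts for all fish, fishery targets, freshwater.

    Species are pooled over layers and replicates.  Taxa with an unknown
    habitat flag count only towards the all-fish column.
    """
    fishery_set = set(fishery)
    rows = []
    detected = matrix.detected()
    for station, group in detected.groupby("station"):
        species = set(group["taxon"])
        rows.append(
            {
                "station": station,
                "all_fish": len(species),
                "fishery": len(species & fishery_set),
                "freshwater": sum(habitat_of.get(sp) == "freshwater" for sp in species),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# dissimilarity and the Mantel correlogram
# --------------------------------------------------------------------------
def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) of two abundance vectors."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = (a + b).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis is undefined for two all-zero vectors")
    return float(np.abs(a - b).sum() / denom)


def detection_abundance(matrix: DetectionMatrix) -> pd.DataFrame:
    """Station x taxon abundance proxy: number of positive PCR detections.

    With two layers and three replicates each entry lies in 0..6.  This is
    the default community quantity fed to the correlogram.
    """
    detected = matrix.detected()
    return (
        detected.pivot_table(
            index="station", columns="taxon", values="detected", aggfunc="sum", fill_value=0
        )
        .astype(float)
    )


@dataclass
class CorrelogramClass:
    index: int
    midpoint: float
    n_pairs: int
    mantel_r: float
    p_value: float | None
    p_corrected: float | None
    significant: bool


@dataclass
class CorrelogramResult:
    classes: list[CorrelogramClass]
    n_permutations: int
    break_points: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "class": c.index,
                    "midpoint_m": c.midpoint,
                    "n_pairs": c.n_pairs,
                    "mantel_r": c.mantel_r,
                    "p_value": c.p_value,
                    "p_corrected": c.p_corrected,
                    "significant": c.significant,
                }
                for c in self.classes
            ]
        )


def _class_mantel_r(dvals: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Pearson correlation of the condensed dissimilarities with each
    class-membership indicator row, sign-flipped so that a positive value
    means communities in that distance class are more similar than average."""
    d = dvals - dvals.mean()
    dn = np.linalg.norm(d)
    w = weights - weights.mean(axis=1, keepdims=True)
    wn = np.linalg.norm(w, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (w @ d) / (wn * dn)
    return -r


def mantel_correlogram(
    community: pd.DataFrame | np.ndarray,
    coordinates: np.ndarray,
    n_classes: int | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
    correction: str = "holm",
    exhaustive: bool = False,
) -> CorrelogramResult:
    """Mantel correlogram of Bray-Curtis dissimilarity vs geographic distance.

    Distances are binned into ``n_classes`` equal-width classes (Sturges'
    rule on the number of pairs by default).  Per class, the Mantel statistic
    between the community dissimilarity matrix and the class-membership model
    matrix is tested by permuting station labels (two-sided,
    ``(exceedances+1)/(n_perm+1)``).  ``correction`` is "holm" (step-down,
    controls the familywise error across classes; the default of the usual
    correlogram tools), "progressive" (k-th class p multiplied by k,
    class-by-class), or "none".  Classes with fewer than two member pairs are
    dropped.  ``exhaustive`` enumerates every station permutation instead of
    sampling (small n only).
    """
    comm = np.asarray(community, dtype=float)
    coords = np.asarray(coordinates, dtype=float)
    n = comm.shape[0]
    if n < 4:
        raise ValueError("need at least 4 stations")
    if coords.shape[0] != n:
        raise ValueError("community and coordinates disagree on station count")
    dmat = squareform(pdist(comm, metric="braycurtis"))
    if np.isnan(dmat).any():
        raise ValueError("Bray-Curtis undefined: some station has an all-zero community")
    gmat = squareform(pdist(coords))
    iu = np.triu_indices(n, 1)
    dvals = dmat[iu]
    gvals = gmat[iu]
    m = len(gvals)
    if n_classes is None:
        n_classes = int(np.ceil(np.log2(m) + 1))
    edges = np.linspace(0.0, gvals.max() * (1 + 1e-9), n_classes + 1)

    weights = []
    kept = []
    for c in range(n_classes):
        w = (gvals >= edges[c]) & (gvals < edges[c + 1])
        if c == n_classes - 1:
            w = (gvals >= edges[c]) & (gvals <= edges[c + 1])
        if w.sum() >= 2:
            weights.append(w.astype(float))
            kept.append(c)
    weights = np.array(weights)
    r_obs = _class_mantel_r(dvals, weights)

    degenerate = np.isclose(dvals.std(), 0.0)
    p_values: list[float | None]
    if degenerate or n_perm == 0 and not exhaustive:
        p_values = [None] * len(kept)
    else:
        exceed = np.zeros(len(kept))
        if exhaustive:
            perms = list(itertools.permutations(range(n)))
            total = len(perms) - 1  # identity contributes the +1
            for perm in perms[1:]:
                dp = dmat[np.ix_(perm, perm)][iu]
                rp = _class_mantel_r(dp, weights)
                exceed += np.abs(rp) >= np.abs(r_obs) - 1e-12
            p_values = list((exceed + 1) / (total + 1))
        else:
            rng = np.random.default_rng(seed)
            for _ in range(n_perm):
                perm = rng.permutation(n)
                dp = dmat[np.ix_(perm, perm)][iu]
                rp = _class_mantel_r(dp, weights)
                exceed += np.abs(rp) >= np.abs(r_obs) - 1e-12
            p_values = list((exceed + 1) / (n_perm + 1))

    corrected = _correct_pvalues(p_values, correction)
    classes = []
    for i, (c, r) in enumerate(zip(kept, r_obs)):
        mid = 0.5 * (edges[c] + edges[c + 1])
        p = p_values[i]
        p_corr = corrected[i]
        sig = p_corr is not None and p_corr <= alpha
        classes.append(
            CorrelogramClass(c, float(mid), int(weights[i].sum()), float(r_obs[i]), p, p_corr, sig)
        )
    return CorrelogramResult(classes, 0 if exhaustive else n_perm, edges)


def _correct_pvalues(p_values: list, method: str) -> list:
    if any(p is None for p in p_values):
        return [None] * len(p_values)
    m = len(p_values)
    if method == "none":
        return list(p_values)
    if method == "progressive":
        out = []
        running = 0.0
        for i, p in enumerate(p_values):
            running = max(running, min(1.0, p * (i + 1)))
            out.append(running)
        return out
    if method == "holm":
        order = np.argsort(p_values, kind="stable")
        out = [0.0] * m
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, p_values[idx] * (m - rank)))
            out[idx] = running
        return out
    raise ValueError(f"unknown correction {method!r}")


# --------------------------------------------------------------------------
# census comparison
# --------------------------------------------------------------------------
@dataclass
class CensusTable:
    """Visual-census records: one row per census x species with a count."""

    data: pd.DataFrame  # census_id, species, count

    def __post_init__(self) -> None:
        required = {"census_id", "species", "count"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"census table needs columns {sorted(required)}")
        if (self.data["count"] < 0).any():
            raise ValueError("census counts must be non-negative")

    @classmethod
    def from_tsv(cls, path) -> "CensusTable":
        return cls(pd.read_csv(path, sep="\t"))

    def incidence(self) -> pd.DataFrame:
        """census x species boolean incidence.

        Censuses whose records are all zero still appear as rows: an empty
        census is sampling effort and must count towards rarefaction.
        """
        table = self.data.pivot_table(
            index="census_id", columns="species", values="count", aggfunc="sum", fill_value=0
        ).gt(0)
        return table.loc[:, table.any(axis=0)]

    def species(self) -> set[str]:
        return set(self.data.loc[self.data["count"] > 0, "species"])


@dataclass
class AccumulationCurve:
    """Expected species count after t censuses, with a variance band."""

    t: np.ndarray
    s_mean: np.ndarray
    s_var: np.ndarray

    @property
    def s_sd(self) -> np.ndarray:
        return np.sqrt(np.maximum(self.s_var, 0.0))


def _log_binom(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where((k < 0) | (k > n), -np.inf, out)


def accumulation_curve(census: CensusTable) -> AccumulationCurve:
    """Exact sample-based rarefaction of the census species counts.

    E[S(t)] = sum_i 1 - C(T - T_i, t) / C(T, t), with the closed-form
    variance including pairwise co-occurrence covariances.
    """
    inc = census.incidence().to_numpy()
    big_t, n_sp = inc.shape
    if big_t < 1:
        raise ValueError("need at least one census")
    t_i = inc.sum(axis=0)
    t = np.arange(1, big_t + 1)
    log_tot = _log_binom(big_t, t)
    alpha = np.exp(_log_binom((big_t - t_i)[:, None], t[None, :]) - log_tot[None, :])
    s_mean = (1.0 - alpha).sum(axis=0)

    var = (alpha * (1.0 - alpha)).sum(axis=0)
    co = inc.T.astype(int) @ inc.astype(int)
    pairs_i, pairs_j = np.triu_indices(n_sp, 1)
    union = t_i[pairs_i] + t_i[pairs_j] - co[pairs_i, pairs_j]
    gamma = np.exp(_log_binom((big_t - union)[:, None], t[None, :]) - log_tot[None, :])
    var = var + 2.0 * (gamma - alpha[pairs_i] * alpha[pairs_j]).sum(axis=0)
    return AccumulationCurve(t, s_mean, var)


@dataclass
class DetectionRate:
    n_detected: int
    n_observed: int
    n_no_reference: int
    n_indistinguishable: int

    @property
    def rate_all(self) -> float:
        denom = self.n_observed - self.n_no_reference
        if denom <= 0:
            raise ValueError("empty denominator")
        return round(100.0 * self.n_detected / denom, 1)

    @property
    def rate_strict(self) -> float:
        denom = self.n_observed - self.n_no_reference - self.n_indistinguishable
        if denom <= 0:
            raise ValueError("empty denominator")
        return round(100.0 * self.n_detected / denom, 1)


def detection_rate(
    observed: set,
    detected: set,
    no_reference: set = frozenset(),
    indistinguishable: set = frozenset(),
) -> DetectionRate:
    """Share of visually observed species recovered by metabarcoding.

    The denominator drops species without reference barcodes; the strict
    variant additionally drops species indistinguishable at the marker.
    """
    usable = observed - set(no_reference)
    strict_excl = usable & set(indistinguishable)
    return DetectionRate(
        n_detected=len(detected & usable),
        n_observed=len(observed),
        n_no_reference=len(observed & set(no_reference)),
        n_indistinguishable=len(strict_excl),
    )


@dataclass
class DetectionEfficiency:
    requisite_censuses: int | None
    reached: bool
    s_final: float


def detection_efficiency(curve: AccumulationCurve, s_meta: float) -> DetectionEfficiency:
    """Smallest census count whose expected species total reaches s_meta."""
    hits = np.nonzero(curve.s_mean >= s_meta - 1e-9)[0]
    if len(hits) == 0:
        return DetectionEfficiency(None, False, float(curve.s_mean[-1]))
    return DetectionEfficiency(int(curve.t[hits[0]]), True, float(curve.s_mean[-1]))
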