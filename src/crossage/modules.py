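"""Unsigned weighted co-expression modules and antiparallel subgroups.

Soft-threshold adjacency a_ij = |cor(x_i, x_j)|^beta with the power
chosen as the smallest integer whose network passes a scale-free
topology fit threshold; module detection by average-linkage clustering
of the topological-overlap dissimilarity with a static tree cut; one
module eigengene (first principal component of the standardized module
expression, unit variance, sign-aligned with the module mean profile)
per module. Because the network is unsigned, anticorrelated gene sets
can share a module; they are separated afterwards by hierarchically
clustering age-summarized per-gene profiles at a fixed correlation
distance threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy import stats

GREY = "grey"


@dataclass(frozen=True)
class SoftPowerScan:
    powers: list[int]
    fit_index: dict[int, float]
    mean_connectivity: dict[int, float]
    chosen_power: int
    fit_threshold: float
    threshold_met: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "power": self.powers,
                "fit_index": [self.fit_index[p] for p in self.powers],
                "mean_connectivity": [self.mean_connectivity[p] for p in self.powers],
            }
        )


@dataclass
class ModuleSet:
    membership: pd.Series  # gene -> module label ("grey" = unassigned)
    eigengenes: pd.DataFrame  # samples x modules
    module_sizes: pd.Series
    mean_intra_correlation: pd.Series  # signed mean pairwise Pearson r
    cut_height: float

    @property
    def modules(self) -> list[str]:
        return [m for m in self.module_sizes.index if m != GREY]


@dataclass
class SubgroupSplit:
    module: str
    subgroups: pd.Series  # gene -> subgroup label
    profile_first: pd.Series | None  # per-age summary of largest subgroup
    profile_second: pd.Series | None
    antiparallel: bool
    profile_correlation: float | None
    distance_threshold: float


def scale_free_fit(connectivities, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log regression of connectivity frequency on
    connectivity (equal-width binning); 1 would be a perfect power law,
    the sign is flipped when the slope is positive."""
    k = np.asarray(connectivities, dtype=float)
    if np.all(k == k[0]):
        raise ValueError("scale-free fit undefined: all connectivities equal")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k, freq = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        mean_k.append(k[mask].mean())
        freq.append(mask.mean())
    mean_k = np.asarray(mean_k)
    freq = np.asarray(freq)
    ok = mean_k > 0
    if ok.sum() < 2:
        raise ValueError("fewer than 2 usable bins for the scale-free fit")
    logf = np.log10(freq[ok])
    if np.ptp(logf) < 1e-12:
        return 0.0  # flat connectivity histogram: no power-law evidence
    slope, _, r, _, _ = stats.linregress(np.log10(mean_k[ok]), logf)
    return float(r**2 * (-np.sign(slope) if slope != 0 else 1.0))


def _adjacency(X: pd.DataFrame, beta: float) -> np.ndarray:
    cor = np.corrcoef(X.to_numpy(dtype=float))
    a = np.abs(cor) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def _drop_constant(X: pd.DataFrame) -> pd.DataFrame:
    sd = X.std(axis=1, ddof=0)
    const = sd[sd == 0]
    if len(const):
        warnings.warn(f"dropping {len(const)} constant gene rows", stacklevel=3)
        X = X.drop(index=const.index)
    return X


def pick_power(X: pd.DataFrame, powers=tuple(range(1, 13)),
               threshold: float = 0.94, n_bins: int = 10) -> SoftPowerScan:
    """Scan soft-threshold powers; choose the smallest whose unsigned
    network exceeds the scale-free fit threshold (else the best fit,
    flagged via ``threshold_met``)."""
    X = _drop_constant(X)
    if len(X) < 30:
        warnings.warn("fewer than 30 genes: power scan is unreliable", stacklevel=2)
    powers = [int(p) for p in powers]
    fits: dict[int, float] = {}
    meank: dict[int, float] = {}
    for p in powers:
        a = _adjacency(X, p)
        k = a.sum(axis=1)
        meank[p] = float(k.mean())
        try:
            fits[p] = scale_free_fit(k, n_bins=n_bins)
        except ValueError:
            fits[p] = float("-inf")
    chosen, met = choose_power(fits, threshold)
    return SoftPowerScan(
        powers=powers, fit_index=fits, mean_connectivity=meank,
        chosen_power=chosen, fit_threshold=threshold, threshold_met=met,
    )


def choose_power(fits: dict[int, float], threshold: float) -> tuple[int, bool]:
    """Smallest power whose fit exceeds the threshold; otherwise the
    best-fitting power, flagged as not meeting the threshold."""
    above = [p for p, f in fits.items() if f > threshold]
    if above:
        return min(above), True
    return max(fits, key=lambda p: fits[p]), False


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix of a (hollow) adjacency."""
    a = adjacency
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def _zscore_rows(X: pd.DataFrame) -> pd.DataFrame:
    mu = X.mean(axis=1)
    sd = X.std(axis=1, ddof=0).replace(0, np.nan)
    return X.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)


def module_eigengene(X_module: pd.DataFrame) -> pd.Series:
    """First PC of the standardized module expression, unit variance,
    sign-aligned with the module's mean standardized profile."""
    Z = _zscore_rows(X_module).to_numpy(dtype=float)
    _, _, Vt = np.linalg.svd(Z - Z.mean(axis=1, keepdims=True), full_matrices=False)
    me = Vt[0]
    sd = me.std(ddof=0)
    me = me / sd if sd > 0 else me
    ref = Z.mean(axis=0)
    if np.dot(me, ref - ref.mean()) < 0:
        me = -me
    return pd.Series(me, index=X_module.columns)


def detect_modules(X: pd.DataFrame, beta: float, min_module_size: int = 10,
                   cut_height: float | None = None) -> ModuleSet:
    """Average-linkage clustering of 1 - TOM with a static cut.

    When ``cut_height`` is None the cut is scanned downward across the
    merge-height range (TOM distances concentrate just below 1, so the
    scan is relative to that range, not to absolute height) and the
    largest height yielding the most modules of ``min_module_size`` is
    kept.
    """
    X = _drop_constant(X)
    genes = list(X.index)
    if len(genes) < min_module_size:
        warnings.warn("fewer genes than min_module_size: single grey module", stacklevel=2)
        return _grey_only(X)
    a = _adjacency(X, beta)
    dissim = 1.0 - topological_overlap(a)
    np.fill_diagonal(dissim, 0.0)
    condensed = ssd.squareform(dissim, checks=False)
    link = sch.linkage(condensed, method="average")
    max_h = link[:, 2].max()

    def cut(h: float) -> pd.Series:
        labels = sch.fcluster(link, t=h, criterion="distance")
        return pd.Series(labels, index=genes)

    if cut_height is None:
        # TOM distances concentrate just below 1, so scan relative to the
        # merge-height range, from just under the top merge downward, and
        # keep the largest height that maximizes the number of adequately
        # sized modules
        min_h = link[:, 2].min()
        span = max(max_h - min_h, 1e-12)
        heights = max_h - np.linspace(0.005, 0.98, 60) * span
        best_h, best_n = float(heights[0]), -1
        for h in heights:
            n_mod = int((cut(h).value_counts() >= min_module_size).sum())
            if n_mod > best_n:
                best_h, best_n = float(h), n_mod
        cut_height = best_h
    labels = cut(cut_height)

    sizes = labels.value_counts()
    keep = sizes[sizes >= min_module_size].index
    order = sorted(keep, key=lambda c: (-sizes[c], c))
    rename = {c: f"ME_{i + 1}" for i, c in enumerate(order)}
    membership = labels.map(lambda c: rename.get(c, GREY))

    eigengenes = {}
    intra = {}
    module_sizes = {}
    for mod in sorted(set(membership)):
        members = membership.index[membership == mod]
        module_sizes[mod] = len(members)
        if mod == GREY:
            continue
        sub = X.loc[members]
        eigengenes[mod] = module_eigengene(sub)
        cor = np.corrcoef(sub.to_numpy(dtype=float))
        iu = np.triu_indices(len(members), k=1)
        intra[mod] = float(cor[iu].mean()) if len(iu[0]) else np.nan
    me_df = pd.DataFrame(eigengenes, index=X.columns)
    return ModuleSet(
        membership=membership,
        eigengenes=me_df,
        module_sizes=pd.Series(module_sizes),
        mean_intra_correlation=pd.Series(intra),
        cut_height=float(cut_height),
    )


def _grey_only(X: pd.DataFrame) -> ModuleSet:
    return ModuleSet(
        membership=pd.Series(GREY, index=X.index),
        eigengenes=pd.DataFrame(index=X.columns),
        module_sizes=pd.Series({GREY: len(X)}),
        mean_intra_correlation=pd.Series(dtype=float),
        cut_height=float("nan"),
    )


def profile_summary(X: pd.DataFrame, samples: pd.DataFrame,
                    groups: pd.Series | None = None) -> pd.DataFrame:
    """Median value per age level, pooling organs/strains/sexes.

    Expects harmonized (z-scale) expression, so the per-age median is a
    median of z-scores. Returns genes x ages (or groups x ages when
    ``groups`` maps genes to group labels, averaging member genes'
    summaries).
    """
    if "age_months" not in samples.columns:
        raise KeyError("sample table lacks an age_months column")
    ages = samples["age_months"]
    Z = X
    cols = {}
    for age, idx in ages.groupby(ages).groups.items():
        cols[age] = Z.loc[:, idx].median(axis=1)
    summary = pd.DataFrame(cols)
    summary = summary[sorted(summary.columns)]
    if groups is None:
        return summary
    groups = pd.Series(groups).reindex(summary.index)
    return summary.groupby(groups, observed=True).mean()


def split_antiparallel(X_module: pd.DataFrame, samples: pd.DataFrame,
                       distance_threshold: float = 0.22,
                       module: str = "", antiparallel_cutoff: float = -0.5) -> SubgroupSplit:
    """Split a module into subgroups of opposed age trajectories.

    Genes are clustered (average-linkage) on the correlation distance of
    their age-summarized profiles and the tree is cut at the distance
    threshold; the two most frequent subgroups are summarized and the
    split is flagged antiparallel when their profiles correlate below
    the cutoff.
    """
    if len(X_module) < 4:
        raise ValueError("module must contain >= 4 genes to split")
    prof = profile_summary(X_module, samples)
    # genes with flat profiles carry no trajectory: park them in their own bin
    sd = prof.std(axis=1, ddof=0)
    usable = prof[sd > 0]
    if len(usable) < 2:
        return SubgroupSplit(module, pd.Series("SG1", index=X_module.index),
                             None, None, False, None, distance_threshold)
    cor = np.corrcoef(usable.to_numpy(dtype=float))
    dist = 1.0 - cor
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    link = sch.linkage(ssd.squareform(dist, checks=False), method="average")
    labels = sch.fcluster(link, t=distance_threshold, criterion="distance")
    labels = pd.Series(labels, index=usable.index)
    sizes = labels.value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    rename = {c: f"SG{i + 1}" for i, c in enumerate(order)}
    subgroups = labels.map(rename).reindex(X_module.index).fillna("flat")

    if len(order) < 2:
        p1 = prof.loc[labels.index[labels == order[0]]].mean()
        return SubgroupSplit(module, subgroups, p1, None, False, None, distance_threshold)
    p1 = prof.loc[labels.index[labels == order[0]]].mean()
    p2 = prof.loc[labels.index[labels == order[1]]].mean()
    r = float(np.corrcoef(p1.to_numpy(), p2.to_numpy())[0, 1])
    return SubgroupSplit(
        module=module, subgroups=subgroups, profile_first=p1, profile_second=p2,
        antiparallel=bool(r < antiparallel_cutoff), profile_correlation=r,
        distance_threshold=distance_threshold,
    )
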