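"""Nuisance-covariate harmonization scored by PVCA.

Pronounced but biologically irrelevant factors (organ, strain, sex)
overshadow the small age signal in a multi-organ cohort. This module
removes them by per-group z-scoring or parametric empirical-Bayes batch
adjustment (the ComBat location/scale model) applied to consecutively
fitted subgroups, and scores candidate correction orders by the age
variance fraction under principal variance component analysis (PVCA).

PVCA here: principal components of the gene-standardized matrix are
retained up to a cumulative-variance threshold; per PC, one random
intercept per design factor is estimated by a nonnegative
method-of-moments fit of the score covariance on the factor Gram
matrices; the eigenvalue-weighted average of the per-PC fractions is
reported, normalized to sum to one.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

VALID_METHODS = ("zscore", "combat")

#: factor name -> SampleTable column
FACTOR_COLUMNS = {"age": "age_months"}


def _factor_column(samples: pd.DataFrame, factor: str) -> pd.Series:
    col = FACTOR_COLUMNS.get(factor, factor)
    if col not in samples.columns:
        raise KeyError(f"factor {factor!r} (column {col!r}) not in sample table")
    return samples[col]


@dataclass(frozen=True)
class CorrectionStep:
    covariate: str
    method: str

    def __post_init__(self) -> None:
        if self.method not in VALID_METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {VALID_METHODS}")


@dataclass(frozen=True)
class CorrectionPlan:
    steps: tuple[CorrectionStep, ...]
    nesting: bool = True

    def __post_init__(self) -> None:
        covs = [s.covariate for s in self.steps]
        if len(covs) != len(set(covs)):
            raise ValueError("a covariate appears in more than one correction step")

    @staticmethod
    def from_pairs(pairs, nesting: bool = True) -> "CorrectionPlan":
        return CorrectionPlan(tuple(CorrectionStep(c, m) for c, m in pairs), nesting=nesting)

    def to_dict(self) -> dict:
        return {
            "steps": [{"covariate": s.covariate, "method": s.method} for s in self.steps],
            "nesting": self.nesting,
        }

    def describe(self) -> str:
        return " -> ".join(f"{s.method}({s.covariate})" for s in self.steps) or "<identity>"


@dataclass(frozen=True)
class PVCAResult:
    fractions: dict[str, float]
    pcs_used: int
    cum_var_threshold: float

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"PVCA fractions must sum to 1, got {total}")
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError("PVCA fractions must be nonnegative")


def zscore_within(matrix: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Standardize each gene to zero mean / unit variance within groups.

    Genes with zero within-group variance map to 0. Population (ddof=0)
    standard deviation convention.
    """
    groups = pd.Series(groups).reindex(matrix.columns)
    out = np.empty_like(matrix.to_numpy(dtype=float))
    out_df = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    for level, cols in groups.groupby(groups, observed=True).groups.items():
        if len(cols) < 2:
            raise ValueError(f"group {level!r} has fewer than 2 samples; cannot z-score")
        block = matrix.loc[:, cols].to_numpy(dtype=float)
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (block - mu) / sd
        z[np.broadcast_to(sd == 0, z.shape)] = 0.0
        out_df.loc[:, cols] = z
    return out_df


def combat_eb(matrix: pd.DataFrame, batch: pd.Series, max_iter: int = 200,
              tol: float = 1e-6) -> pd.DataFrame:
    """Parametric empirical-Bayes batch adjustment (location/scale model).

    Genes are standardized against the pooled mean/variance; per-batch
    location (gamma) and scale (delta^2) estimates are shrunk toward a
    normal / inverse-gamma prior fit across genes by moments, then the
    standardized values are adjusted and back-transformed. No covariate
    preservation term is modeled.
    """
    batch = pd.Series(batch).reindex(matrix.columns)
    levels = batch.unique()
    if len(levels) == 1:
        warnings.warn("single batch: ComBat adjustment is the identity", stacklevel=2)
        return matrix.copy()
    counts = batch.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"batches with fewer than 2 samples: {list(small.index)}")

    X = matrix.to_numpy(dtype=float)
    n_genes, n = X.shape
    codes = pd.Categorical(batch, categories=list(counts.index)).codes
    n_batches = len(counts)
    n_per = counts.to_numpy(dtype=float)

    batch_means = np.stack([X[:, codes == b].mean(axis=1) for b in range(n_batches)], axis=1)
    grand = batch_means @ (n_per / n)
    resid = X - batch_means[:, codes]
    var_pooled = (resid**2).mean(axis=1)
    var_pooled[var_pooled == 0] = np.finfo(float).tiny

    s = np.sqrt(var_pooled)[:, None]
    Z = (X - grand[:, None]) / s

    gamma_hat = np.stack([Z[:, codes == b].mean(axis=1) for b in range(n_batches)], axis=1)
    delta_hat = np.stack(
        [Z[:, codes == b].var(axis=1, ddof=1) for b in range(n_batches)], axis=1
    )

    # hyperpriors fit by moments across genes
    gamma_bar = gamma_hat.mean(axis=0)
    tau2 = gamma_hat.var(axis=0, ddof=1)
    v = delta_hat.mean(axis=0)
    s2 = delta_hat.var(axis=0, ddof=1)
    s2[s2 == 0] = np.finfo(float).tiny
    lam = (v**2 + 2 * s2) / s2  # inverse-gamma shape ("a")
    theta = (v**3 + v * s2) / s2  # inverse-gamma scale ("b")

    gamma_star = gamma_hat.copy()
    delta_star = delta_hat.copy()
    for b in range(n_batches):
        nb = n_per[b]
        g, d = gamma_hat[:, b], np.maximum(delta_hat[:, b], np.finfo(float).tiny)
        zb = Z[:, codes == b]
        g_new, d_new = g.copy(), d.copy()
        for _ in range(max_iter):
            g_post = (nb * tau2[b] * g + d_new * gamma_bar[b]) / (nb * tau2[b] + d_new)
            sse = ((zb - g_post[:, None]) ** 2).sum(axis=1)
            d_post = (theta[b] + 0.5 * sse) / (nb / 2 + lam[b] - 1)
            change = max(
                np.max(np.abs(g_post - g_new) / np.maximum(np.abs(g_new), 1e-12)),
                np.max(np.abs(d_post - d_new) / np.maximum(np.abs(d_new), 1e-12)),
            )
            g_new, d_new = g_post, d_post
            if change < tol:
                break
        gamma_star[:, b] = g_new
        delta_star[:, b] = d_new

    Z_adj = (Z - gamma_star[:, codes]) / np.sqrt(np.maximum(delta_star[:, codes], 1e-12))
    out = Z_adj * s + grand[:, None]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def apply_plan(matrix: pd.DataFrame, samples: pd.DataFrame,
               plan: CorrectionPlan) -> pd.DataFrame:
    """Apply correction steps in order.

    With nesting on, step k is fit separately within each stratum formed
    by the covariates of steps 1..k-1 ("consecutively fitted subgroups"):
    z-scoring groups by stratum x covariate level, ComBat treats the
    covariate levels as batches within each stratum.
    """
    out = matrix
    prior: list[str] = []
    for step in plan.steps:
        cov = _factor_column(samples, step.covariate)
        if plan.nesting and prior:
            strata = samples[[FACTOR_COLUMNS.get(c, c) for c in prior]].astype(str).agg(
                "|".join, axis=1
            )
        else:
            strata = pd.Series("all", index=samples.index)
        pieces = []
        for stratum, cols in strata.groupby(strata, observed=True).groups.items():
            sub = out.loc[:, cols]
            sub_cov = cov.loc[cols]
            try:
                if step.method == "zscore":
                    pieces.append(zscore_within(sub, sub_cov))
                else:
                    if sub_cov.nunique() == 1:
                        pieces.append(sub.copy())
                    else:
                        pieces.append(combat_eb(sub, sub_cov))
            except ValueError as exc:
                raise ValueError(
                    f"correction step {step.method}({step.covariate}) failed in "
                    f"stratum {stratum!r}: {exc}"
                ) from exc
        out = pd.concat(pieces, axis=1).loc[:, matrix.columns]
        prior.append(step.covariate)
    return out


def _gram(codes: np.ndarray) -> np.ndarray:
    Z = np.eye(int(codes.max()) + 1)[codes]
    return Z @ Z.T


def pvca(matrix: pd.DataFrame, samples: pd.DataFrame, factors,
         cum_var_threshold: float = 0.6) -> PVCAResult:
    """Eigenvalue-weighted random-effect variance fractions across PCs.

    Per retained PC, the centered score covariance is regressed (NNLS)
    on one Gram matrix per factor plus the identity for the residual --
    a method-of-moments variance-component estimate with the negative
    estimates clamped at zero by construction.
    """
    factors = list(factors)
    X = matrix.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    keep = (sd[:, 0] > 0)
    Xz = (X[keep] - mu[keep]) / sd[keep]
    n = Xz.shape[1]

    # sample-space PCA of the standardized matrix
    Xc = Xz - Xz.mean(axis=1, keepdims=True)
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = svals**2
    pos = eigvals > 1e-12 * eigvals[0]
    eigvals, Vt = eigvals[pos], Vt[pos]
    cum = np.cumsum(eigvals) / eigvals.sum()
    k = int(np.searchsorted(cum, cum_var_threshold) + 1)
    k = max(k, 2)
    if k > len(eigvals):
        raise ValueError("fewer than 2 retainable principal components")
    scores = Vt[:k] * svals[pos][:k, None]  # k x n, unit-norm directions scaled

    usable: list[str] = []
    grams: list[np.ndarray] = []
    for f in factors:
        col = _factor_column(samples, f).loc[matrix.columns]
        codes = pd.Categorical(col).codes
        if codes.max() == 0:
            warnings.warn(f"factor {f!r} has a single level; fraction defined 0", stacklevel=2)
            continue
        usable.append(f)
        grams.append(_gram(codes))
    design = np.stack([g.ravel() for g in grams] + [np.eye(n).ravel()], axis=1)

    weights = eigvals[:k] / eigvals[:k].sum()
    fractions = {f: 0.0 for f in factors}
    fractions["residual"] = 0.0
    for j in range(k):
        y = scores[j] - scores[j].mean()
        S = np.outer(y, y)
        comps, _ = scipy.optimize.nnls(design, S.ravel())
        total = comps.sum()
        if total <= 0:
            fractions["residual"] += weights[j]
            continue
        for f, c in zip(usable, comps[:-1]):
            fractions[f] += weights[j] * c / total
        fractions["residual"] += weights[j] * comps[-1] / total
    total = sum(fractions.values())
    fractions = {f: v / total for f, v in fractions.items()}
    return PVCAResult(fractions=fractions, pcs_used=k, cum_var_threshold=cum_var_threshold)


def search_order(matrix: pd.DataFrame, samples: pd.DataFrame, covariates,
                 methods=("zscore", "combat"), age_factor: str = "age",
                 cum_var_threshold: float = 0.6, nesting: bool = True):
    """Exhaustively rank correction plans by the corrected age fraction.

    Enumerates every permutation of the covariates crossed with every
    per-step method assignment; plans are ranked by PVCA age fraction
    (descending), ties broken by fewer ComBat steps then lexicographic
    plan description.
    """
    covariates = list(covariates)
    if len(covariates) > 4:
        raise ValueError("exhaustive order search supports at most 4 covariates")
    methods = tuple(methods)
    pvca_factors = covariates + [age_factor]
    results = []
    for perm in itertools.permutations(covariates):
        for assignment in itertools.product(methods, repeat=len(perm)):
            plan = CorrectionPlan.from_pairs(zip(perm, assignment), nesting=nesting)
            corrected = apply_plan(matrix, samples, plan)
            res = pvca(corrected, samples, pvca_factors, cum_var_threshold)
            results.append((plan, res))
    results.sort(
        key=lambda pr: (
            -pr[1].fractions.get(age_factor, 0.0),
            sum(1 for s in pr[0].steps if s.method == "combat"),
            pr[0].describe(),
        )
    )
    return results
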