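"""Weighted co-expression network: soft threshold, TOM, modules, eigengenes.

The cohort matrix (genes x samples) is turned into a weighted gene network
by soft-thresholding the Pearson correlation matrix, a_ij = |cor|^power
(unsigned, default) or ((1+cor)/2)^power (signed).  The soft-threshold power
is the smallest candidate whose connectivity distribution fits a scale-free
law with signed R^2 at or above the target.  Pairwise similarity is the
topological overlap

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_u a_iu * a_uj  (u != i, j),    k_i = sum_u a_iu  (u != i),

and modules come from average-linkage hierarchical clustering of 1 - TOM
with a static tree cut.  Each module is summarized by its eigengene — the
first principal component of its standardized member genes — which is then
correlated with the binary clinical traits (pairwise-complete over missing
trait values, two-sided t-distribution p values).

The static cut is a deliberate simplification of the dynamic hybrid tree
cut: it is deterministic and fully specified by a single height.  The
default height (0.98) sits between typical within-module dissimilarities
(well below 0.9 at informative powers) and the near-1 dissimilarity of
unrelated genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkConfig:
    candidate_powers: tuple[int, ...] = tuple(range(1, 21))
    scale_free_r2_target: float = 0.8
    signed: bool = False
    min_module_size: int = 20
    cut_height: float = 0.98
    n_bins: int = 10

    def validate(self) -> None:
        if not self.candidate_powers or any(p < 1 for p in self.candidate_powers):
            raise ValueError("candidate_powers must be nonempty positive integers")
        if list(self.candidate_powers) != sorted(self.candidate_powers):
            raise ValueError("candidate_powers must be sorted ascending")
        if not (0.0 < self.cut_height <= 1.0):
            raise ValueError("cut_height must be in (0, 1]")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")


@dataclass
class ModulePartition:
    """gene -> module label; 0 is the unassigned bucket."""

    labels: pd.Series
    n_modules: int

    def members(self, module: int) -> pd.Index:
        return self.labels.index[self.labels == module]


@dataclass
class EigengeneMatrix:
    """Module eigengenes (rows ``ME1``..) x samples, with variance explained."""

    values: pd.DataFrame
    var_explained: pd.Series


def drop_constant_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Remove zero-variance gene rows (their correlation is undefined)."""
    sd = expr.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        logger.warning("dropping %d constant gene rows before correlation", int(constant.sum()))
        expr = expr.loc[~constant]
    return expr


def correlation_matrix(expr: pd.DataFrame) -> np.ndarray:
    """Gene x gene Pearson correlation of the expression matrix."""
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for gene-gene correlation")
    cor = np.corrcoef(expr.to_numpy())
    return np.clip(cor, -1.0, 1.0)


def adjacency_from_correlation(cor: np.ndarray, power: int, signed: bool = False) -> np.ndarray:
    if power < 1:
        raise ValueError("power must be >= 1")
    if signed:
        adj = ((1.0 + cor) / 2.0) ** power
    else:
        adj = np.abs(cor) ** power
    np.fill_diagonal(adj, 1.0)
    return adj


def adjacency(expr: pd.DataFrame, power: int, signed: bool = False) -> np.ndarray:
    """Soft-thresholded adjacency of the gene co-expression network."""
    return adjacency_from_correlation(correlation_matrix(expr), power, signed)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 and slope of the log10(k) vs log10(frequency) fit.

    Connectivities are binned into equal-width bins; the fit uses the mean
    connectivity per occupied bin against the bin's occupancy count.  The
    index is R^2 when the slope is negative (scale-free-like decay) and
    -R^2 otherwise.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 3 or np.allclose(k, k[0]):
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            xs.append(np.log10(k[mask].mean()))
            ys.append(np.log10(mask.sum()))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, _intercept, r, _p, _se = stats.linregress(xs, ys)
    r2 = float(r**2)
    return (r2 if slope < 0 else -r2), float(slope)


def pick_soft_threshold(
    expr: pd.DataFrame, config: NetworkConfig = NetworkConfig()
) -> tuple[int, pd.DataFrame]:
    """Smallest candidate power reaching the scale-free fit target.

    Falls back (with a warning) to the power maximizing the fit index when
    no candidate reaches the target.  Also returns the per-power diagnostics
    table (fit index, slope, mean and max connectivity).
    """
    config.validate()
    if expr.shape[0] < 10:
        raise ValueError("need at least 10 genes to assess scale-free topology")
    expr = drop_constant_genes(expr)
    cor = correlation_matrix(expr)
    records = []
    for power in config.candidate_powers:
        adj = adjacency_from_correlation(cor, power, config.signed)
        k = adj.sum(axis=0) - 1.0
        fit, slope = scale_free_fit(k, config.n_bins)
        records.append(
            {"power": power, "fit_r2": fit, "slope": slope,
             "mean_k": float(k.mean()), "max_k": float(k.max())}
        )
    diag = pd.DataFrame(records)
    reaching = diag[diag["fit_r2"] >= config.scale_free_r2_target]
    if len(reaching):
        power = int(reaching["power"].iloc[0])
    else:
        power = int(diag.loc[diag["fit_r2"].idxmax(), "power"])
        logger.warning(
            "no candidate power reached scale-free R^2 %.2f; using power %d (R^2=%.3f)",
            config.scale_free_r2_target, power, diag["fit_r2"].max(),
        )
    return power, diag


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """Topological overlap similarity of a [0,1] adjacency with unit diagonal."""
    adj = np.asarray(adj, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(adj, adj.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if adj.min() < -1e-12 or adj.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    if not np.allclose(np.diag(adj), 1.0):
        raise ValueError("adjacency diagonal must be 1")
    a2 = adj @ adj
    # with unit diagonal, (A^2)_ij counts a_ii*a_ij + a_ij*a_jj = 2 a_ij extra
    shared = a2 - 2.0 * adj
    k = adj.sum(axis=0) - 1.0
    denom = np.minimum.outer(k, k) + 1.0 - adj
    with np.errstate(invalid="ignore", divide="ignore"):  # 0/0 only on the diagonal
        tom = (shared + adj) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def cluster_modules(
    diss: np.ndarray,
    gene_ids: pd.Index | list[str],
    config: NetworkConfig = NetworkConfig(),
) -> ModulePartition:
    """Average-linkage clustering of the TOM dissimilarity with a static cut.

    Clusters below ``min_module_size`` land in module 0; surviving modules
    are renumbered 1..k by decreasing size (ties by first appearance).
    """
    config.validate()
    diss = np.asarray(diss, dtype=float)
    n = diss.shape[0]
    if diss.shape != (n, n) or not np.allclose(diss, diss.T, atol=1e-10):
        raise ValueError("dissimilarity must be square and symmetric")
    if not np.allclose(np.diag(diss), 0.0, atol=1e-10):
        raise ValueError("dissimilarity diagonal must be 0")
    condensed = diss[np.triu_indices(n, k=1)]
    if condensed.size and np.allclose(condensed, condensed[0]):
        logger.warning("degenerate dissimilarity (all pairs equal); one module returned")
    tree = linkage(condensed, method="average")
    raw = fcluster(tree, t=config.cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    big = sizes[sizes >= config.min_module_size]
    # decreasing size; ties broken by the raw cluster label for determinism
    order = sorted(big.index, key=lambda c: (-big[c], c))
    mapping = {c: i + 1 for i, c in enumerate(order)}
    labels = pd.Series(
        [mapping.get(c, 0) for c in raw], index=pd.Index(gene_ids, name="gene_id"),
        name="module",
    )
    return ModulePartition(labels=labels, n_modules=len(order))


def module_eigengene(expr: pd.DataFrame, partition: ModulePartition) -> EigengeneMatrix:
    """First principal component of each module's standardized member genes.

    Eigengenes are unit-norm over samples and sign-fixed so each correlates
    nonnegatively with its module's mean standardized profile; the variance
    explained is the first squared singular value over the total.
    """
    values, var_explained = {}, {}
    for m in range(1, partition.n_modules + 1):
        sub = expr.loc[partition.members(m)]
        sd = sub.std(axis=1, ddof=0)
        if (sd == 0).any():
            logger.warning("module %d: dropping %d zero-variance genes", m, int((sd == 0).sum()))
            sub = sub.loc[sd > 0]
        if len(sub) < 1:
            raise ValueError(f"module {m} has no genes with variance")
        z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)
        _u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
        eig = vt[0]
        profile = z.mean(axis=0).to_numpy()
        if np.dot(eig, profile - profile.mean()) < 0:
            eig = -eig
        values[f"ME{m}"] = eig
        var_explained[f"ME{m}"] = float(s[0] ** 2 / np.sum(s**2))
    me = pd.DataFrame(values, index=expr.columns).T
    return EigengeneMatrix(values=me, var_explained=pd.Series(var_explained, name="var_explained"))


def module_trait_correlation(me: EigengeneMatrix, traits: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each eigengene with each 0/1 trait.

    Missing trait values are excluded pairwise; p values come from the exact
    t transform of r with n-2 degrees of freedom.  Rows with a constant
    trait (after removing missing values) report NaN.
    """
    records = []
    for me_name, eig in me.values.iterrows():
        for trait in traits.columns:
            t_vals = traits[trait].reindex(eig.index)
            mask = t_vals.notna()
            n = int(mask.sum())
            x = eig[mask].to_numpy()
            y = t_vals[mask].to_numpy(dtype=float)
            if n < 3 or np.std(y) == 0 or np.std(x) == 0:
                if np.std(y) == 0:
                    logger.warning("trait %s constant over complete samples; r undefined", trait)
                records.append(
                    {"module": me_name, "trait": trait, "r": np.nan, "p": np.nan, "n": n,
                     "significant": False}
                )
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            r = max(-1.0, min(1.0, r))
            if abs(r) == 1.0:
                p = 0.0
            else:
                t_stat = r * np.sqrt((n - 2) / (1.0 - r**2))
                p = float(2.0 * stats.t.sf(abs(t_stat), df=n - 2))
            records.append(
                {"module": me_name, "trait": trait, "r": r, "p": p, "n": n,
                 "significant": p < 0.05}
            )
    return pd.DataFrame(records)


@dataclass
class NetworkResult:
    power: int
    power_diagnostics: pd.DataFrame
    partition: ModulePartition
    eigengenes: EigengeneMatrix
    trait_correlation: pd.DataFrame | None = None


def detect_modules(
    expr: pd.DataFrame,
    traits: pd.DataFrame | None = None,
    config: NetworkConfig = NetworkConfig(),
    power: int | None = None,
) -> NetworkResult:
    """Full network stage: power selection, adjacency, TOM, modules, eigengenes."""
    config.validate()
    expr = drop_constant_genes(expr)
    if power is None:
        power, diag = pick_soft_threshold(expr, config)
    else:
        diag = pd.DataFrame({"power": [power], "fit_r2": [np.nan], "slope": [np.nan],
                             "mean_k": [np.nan], "max_k": [np.nan]})
    adj = adjacency(expr, power, config.signed)
    tom = topological_overlap(adj)
    partition = cluster_modules(1.0 - tom, expr.index, config)
    logger.info("detected %d modules at power %d", partition.n_modules, power)
    if partition.n_modules == 0:
        return NetworkResult(power, diag, partition,
                             EigengeneMatrix(pd.DataFrame(columns=expr.columns), pd.Series(dtype=float)))
    eigengenes = module_eigengene(expr, partition)
    trait_corr = None
    if traits is not None:
        trait_corr = module_trait_correlation(eigengenes, traits.loc[expr.columns])
    return NetworkResult(power, diag, partition, eigengenes, trait_corr)
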