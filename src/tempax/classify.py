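"""Cell classification: marker gating and bootstrap-supported clustering.

Hierarchical clustering uses correlation distance (1 - Pearson over the
signature probes, log2 values) with complete linkage. Cluster support is
quantified by multiscale bootstrap resampling of the probes: at each scale
r the probes are resampled to size round(m * r), the samples re-clustered,
and the per-cluster bootstrap probabilities BP_r are fit on the probit
scale to psi(r) = v sqrt(r) + c / sqrt(r), giving the approximately
unbiased support AU = 1 - Phi(v - c) and the plain bootstrap probability
BP = 1 - Phi(v + c).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from . import de
from .io import ExpressionMatrix, QpcrTable

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 10))
UNCLASSIFIED = "unclassified"


# ---------------------------------------------------------------------------
# marker gating

@dataclasses.dataclass(frozen=True)
class MarkerRule:
    label: str
    positive: tuple[str, ...]
    negative: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        overlap = set(self.positive) & set(self.negative)
        if overlap:
            raise ValueError(
                f"rule {self.label}: genes both required-positive and "
                f"required-negative: {sorted(overlap)}"
            )


@dataclasses.dataclass
class MarkerRuleSet:
    """Ordered marker gates; the first matching rule assigns the class."""

    rules: list[MarkerRule]

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.rules:
            out |= set(r.positive) | set(r.negative)
        return out


#: wild-type apical progenitor gate (Ki67+/Ttyh1+/Tbr2-)
AP_RULES = MarkerRuleSet(
    rules=[MarkerRule("AP", positive=("Ki67", "Ttyh1"), negative=("Tbr2",))]
)

#: gate for cell-cycle-arrested electroporated APs (Egfp+/Ttyh1+/Tbr2-/Ki67-)
ARRESTED_AP_RULES = MarkerRuleSet(
    rules=[
        MarkerRule("AP", positive=("Ki67", "Ttyh1"), negative=("Tbr2",)),
        MarkerRule(
            "arrested-AP", positive=("Egfp", "Ttyh1"),
            negative=("Tbr2", "Ki67"),
        ),
    ]
)


def _detection_flags(
    expr: ExpressionMatrix | QpcrTable,
    genes: Sequence[str],
    threshold: float | None,
) -> pd.DataFrame:
    """Boolean genes x cells detection frame for the requested symbols."""
    if isinstance(expr, QpcrTable):
        missing = [g for g in genes if g not in expr.ct.index]
        if missing:
            raise KeyError(f"genes not measured: {missing}")
        return expr.detected.loc[list(genes)]
    if threshold is None:
        raise ValueError("signal threshold required for array matrices")
    probes = expr.symbols_to_probes(genes)
    flags = expr.values.loc[probes] >= threshold
    flags.index = list(genes)
    return flags


def marker_gate(
    expr: ExpressionMatrix | QpcrTable,
    rules: MarkerRuleSet,
    threshold: float | None = None,
) -> pd.Series:
    """Assign per-cell class labels by ordered marker gates.

    Positivity means detected (Ct < 40 for qPCR; signal >= ``threshold``
    for arrays). Cells matching no rule are labelled ``unclassified``.
    """
    genes = sorted(rules.genes)
    for rule in rules.rules:
        for g in rule.positive + rule.negative:
            if isinstance(expr, QpcrTable) and g not in expr.ct.index:
                raise KeyError(
                    f"rule {rule.label!r} references unmeasured gene {g!r}"
                )
    flags = _detection_flags(expr, genes, threshold)
    labels = pd.Series(UNCLASSIFIED, index=flags.columns, dtype=object)
    unassigned = labels == UNCLASSIFIED
    for rule in rules.rules:
        match = unassigned.copy()
        for g in rule.positive:
            match &= flags.loc[g]
        for g in rule.negative:
            match &= ~flags.loc[g]
        labels[match] = rule.label
        unassigned &= ~match
    return labels


# ---------------------------------------------------------------------------
# signature selection

def signature_select(
    log2_values: pd.DataFrame,
    groups: pd.Series | Sequence[str],
    fdr: float = 0.1,
) -> list[str]:
    """Probes differing across groups at the requested FDR (one-way ANOVA)."""
    groups = pd.Series(np.asarray(groups), index=log2_values.columns)
    if groups.nunique() < 2:
        raise ValueError("need >= 2 groups")
    _, p = de.anova_f(log2_values.to_numpy(float), groups.to_numpy())
    method = "storey" if p.size >= de.STOREY_MIN_PROBES else "bh"
    q = de.qvalues(p, method=method)
    return list(log2_values.index[q < fdr])


# ---------------------------------------------------------------------------
# hierarchical clustering with AU support

@dataclasses.dataclass
class ClusterTree:
    """Complete-linkage sample dendrogram with optional bootstrap support.

    ``labels`` are the sample ids in the (lexicographically sorted) order
    used for clustering; ``merges`` is the scipy linkage matrix over that
    order. ``clusters`` lists the leaf-label sets of the internal nodes in
    merge order; the support table is aligned to that list.
    """

    labels: list[str]
    merges: np.ndarray
    clusters: list[frozenset[str]]
    heights: np.ndarray
    support: pd.DataFrame | None = None  # au, bp, v, c per cluster
    bp_r: pd.DataFrame | None = None  # clusters x scales raw BP_r
    n_boot: int | None = None
    scales: tuple[float, ...] | None = None

    def cluster_index(self, members: Sequence[str]) -> int:
        target = frozenset(members)
        for i, cl in enumerate(self.clusters):
            if cl == target:
                return i
        raise KeyError(f"no cluster with members {sorted(target)}")

    def au(self, members: Sequence[str]) -> float:
        if self.support is None:
            raise ValueError("AU values not computed; run au_pvalues")
        return float(self.support["au"].iloc[self.cluster_index(members)])

    def to_newick(self) -> str:
        """Newick string; internal nodes annotated with [AU=..,BP=..]."""
        n = len(self.labels)

        def node(i: int) -> str:
            if i < n:
                return self.labels[i]
            row = int(i - n)
            a, b, h, _ = self.merges[row]
            left, right = node(int(a)), node(int(b))
            ann = ""
            if self.support is not None:
                au = self.support["au"].iloc[row]
                bp = self.support["bp"].iloc[row]
                ann = f"[AU={au:.3f},BP={bp:.3f}]"
            return f"({left},{right}){ann}:{h:.6g}"

        return node(2 * n - 2) + ";"


def _correlation_distance(log2_values: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between columns (samples)."""
    x = log2_values - log2_values.mean(axis=0, keepdims=True)
    norms = np.sqrt((x**2).sum(axis=0))
    if (norms == 0).any():
        raise ValueError(
            "zero-variance sample over the signature: correlation undefined"
        )
    xn = x / norms[None, :]
    d = 1.0 - xn.T @ xn
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def _clusters_from_linkage(merges: np.ndarray, n: int) -> list[int]:
    """Internal-node membership bitmasks in merge order."""
    masks: list[int] = [1 << i for i in range(n)]
    out: list[int] = []
    for a, b in merges[:, :2].astype(int):
        m = masks[a] | masks[b]
        masks.append(m)
        out.append(m)
    return out


def hcluster(
    log2_values: pd.DataFrame, probes: Sequence[str] | None = None
) -> ClusterTree:
    """Correlation-distance complete-linkage tree over samples (columns).

    Samples are ordered lexicographically by id before clustering so the
    result is invariant to input column order.
    """
    if log2_values.shape[1] < 2:
        raise ValueError("need >= 2 samples to cluster")
    if probes is not None:
        missing = set(probes) - set(log2_values.index)
        if missing:
            raise KeyError(f"probes not in matrix: {sorted(missing)}")
        log2_values = log2_values.loc[list(probes)]
    log2_values = log2_values[sorted(log2_values.columns)]
    labels = list(log2_values.columns)
    d = _correlation_distance(log2_values.to_numpy(float))
    merges = linkage(squareform(d, checks=False), method="complete")
    masks = _clusters_from_linkage(merges, len(labels))
    clusters = [
        frozenset(labels[i] for i in range(len(labels)) if m >> i & 1)
        for m in masks
    ]
    return ClusterTree(
        labels=labels,
        merges=merges,
        clusters=clusters,
        heights=merges[:, 2].copy(),
    )


def _bootstrap_bp(
    x: np.ndarray,
    observed: list[int],
    scales: Sequence[float],
    n_boot: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """BP_r matrix (clusters x scales) by probe resampling.

    ``x`` is probes x samples (log2 values); cluster identity across
    replicates is an identical leaf set, tracked as bitmasks.
    """
    m, n = x.shape
    obs_index = {mask: i for i, mask in enumerate(observed)}
    bp = np.zeros((len(observed), len(scales)))
    for si, r in enumerate(scales):
        m_r = max(2, int(round(m * r)))
        idx = rng.integers(0, m, size=(n_boot, m_r))
        y = x[idx, :]  # (B, m_r, n)
        yc = y - y.mean(axis=1, keepdims=True)
        norms = np.sqrt((yc**2).sum(axis=1))  # (B, n)
        norms[norms == 0] = np.inf  # zero-variance sample -> corr 0
        z = yc / norms[:, None, :]
        corr = np.matmul(z.transpose(0, 2, 1), z)
        dist = np.clip(1.0 - corr, 0.0, 2.0)
        iu = np.triu_indices(n, k=1)
        counts = np.zeros(len(observed), dtype=np.int64)
        for b in range(n_boot):
            mg = linkage(dist[b][iu], method="complete")
            for mask in _clusters_from_linkage(mg, n):
                j = obs_index.get(mask)
                if j is not None:
                    counts[j] += 1
        bp[:, si] = counts / n_boot
    return bp


def fit_au(
    bp_row: np.ndarray, scales: np.ndarray, n_boot: int
) -> tuple[float, float, float, float]:
    """Weighted LS fit of the multiscale-bootstrap model for one cluster.

    Fits Phi^-1(1 - BP_r) = v sqrt(r) + c / sqrt(r), weighting by the
    inverse delta-method variance of the probit-transformed BP_r. Returns
    (au, bp_fit, v, c).
    """
    lo, hi = 1.0 / (n_boot + 1), n_boot / (n_boot + 1)
    bp_clip = np.clip(bp_row, lo, hi)
    psi = stats.norm.ppf(1.0 - bp_clip)
    dens = stats.norm.pdf(psi)
    w = dens**2 * n_boot / (bp_clip * (1.0 - bp_clip))
    sq = np.sqrt(scales)
    design = np.stack([sq, 1.0 / sq], axis=1)
    wd = design * w[:, None]
    ata = design.T @ wd
    atb = wd.T @ psi
    v, c = np.linalg.solve(ata, atb)
    au = float(1.0 - stats.norm.cdf(v - c))
    bp_fit = float(1.0 - stats.norm.cdf(v + c))
    return au, bp_fit, float(v), float(c)


def au_pvalues(
    log2_values: pd.DataFrame,
    probes: Sequence[str] | None = None,
    scales: Sequence[float] = DEFAULT_SCALES,
    n_boot: int = 1000,
    seed: int | None = None,
) -> ClusterTree:
    """Cluster samples and attach AU/BP support from multiscale bootstrap."""
    scales = np.asarray(sorted(scales), float)
    if not (scales.min() < 1.0 and scales.max() > 1.0):
        raise ValueError("scales must span values below and above 1")
    if n_boot < 100:
        raise ValueError("need n_boot >= 100")
    tree = hcluster(log2_values, probes=probes)
    if probes is not None:
        log2_values = log2_values.loc[list(probes)]
    x = log2_values[tree.labels].to_numpy(float)
    n = len(tree.labels)
    masks = _clusters_from_linkage(tree.merges, n)
    rng = np.random.default_rng(seed)
    bp = _bootstrap_bp(x, masks, scales, n_boot, rng)

    rows = []
    for i, row in enumerate(bp):
        if (row == 0).all():
            warnings.warn(
                f"cluster {sorted(tree.clusters[i])} never observed in any "
                "bootstrap replicate; AU set to 0",
                stacklevel=2,
            )
            rows.append((0.0, 0.0, np.nan, np.nan))
        elif (row == 1).all():
            # present in every replicate at every scale: the clipped probit
            # curve is constant and the two-term model degenerates
            rows.append((1.0, 1.0, np.nan, np.nan))
        else:
            rows.append(fit_au(row, scales, n_boot))
    tree.support = pd.DataFrame(rows, columns=["au", "bp", "v", "c"])
    tree.bp_r = pd.DataFrame(bp, columns=[f"r={r:g}" for r in scales])
    tree.n_boot = n_boot
    tree.scales = tuple(scales)
    return tree
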