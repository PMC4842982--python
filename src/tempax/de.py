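"""Stage-wise differential expression: per-probe ANOVA, q-values, log fold changes.

All statistics are computed on log2-scale values. Fold changes are
differences of group means on that scale. The q-value default follows
Storey's smoother-based pi0 estimate, with a Benjamini-Hochberg fallback
for short p-value vectors where the smoother is unstable.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: below this many probes the pi0 smoother is considered unstable
STOREY_MIN_PROBES = 100


def anova_f(values: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-way fixed-effects ANOVA for each row of ``values``.

    Parameters
    ----------
    values : (m, n) array of log2 values (m probes, n samples).
    groups : (n,) array of group labels.

    Returns (F, p) arrays of length m. Rows constant everywhere get p = 1;
    rows with zero within-group variance but distinct group means get p = 0.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    k, n = len(labels), values.shape[1]
    if k < 2:
        raise ValueError("need >= 2 groups")
    counts = np.array([(groups == g).sum() for g in labels])
    if (counts < 2).any():
        small = [str(g) for g, c in zip(labels, counts) if c < 2]
        raise ValueError(f"groups with < 2 samples: {small}")

    grand = values.mean(axis=1)
    ssb = np.zeros(values.shape[0])
    ssw = np.zeros(values.shape[0])
    for g, c in zip(labels, counts):
        sub = values[:, groups == g]
        m_g = sub.mean(axis=1)
        ssb += c * (m_g - grand) ** 2
        ssw += ((sub - m_g[:, None]) ** 2).sum(axis=1)

    dfb, dfw = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
    p = np.empty(values.shape[0])
    tot = ssb + ssw
    # tolerance relative to the magnitude of the data
    eps = 1e-12 * max(1.0, float(np.abs(values).max(initial=0.0)) ** 2) * n
    constant = tot <= eps
    degenerate = (ssw <= eps) & ~constant
    ok = ~constant & ~degenerate
    p[constant] = 1.0
    f[constant] = 0.0
    p[degenerate] = 0.0
    f[degenerate] = np.inf
    p[ok] = stats.f.sf(f[ok], dfb, dfw)
    return f, p


def qvalues(pvals: Sequence[float], method: str = "storey") -> np.ndarray:
    """q-values from a p-value vector.

    ``storey``: pi0 estimated by the cubic smoother over
    lambda in {0.05, ..., 0.95}; ``bh``: pi0 = 1. In both cases
    q_i = min_{j >= rank(i)} pi0 * p_(j) * m / j.
    """
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        pi0 = 1.0
    elif method == "storey":
        pi0 = estimate_pi0(p)
    else:
        raise ValueError(f"unknown FDR method {method!r}")

    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * ranked * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is fit with a cubic
    polynomial smoother and evaluated at the largest lambda.
    """
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = p.size
    pi0_lam = np.array(
        [(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas]
    )
    if np.allclose(pi0_lam, pi0_lam[0]):
        pi0 = pi0_lam[0]
    else:
        coeffs = np.polyfit(lambdas, pi0_lam, 3)
        pi0 = float(np.polyval(coeffs, lambdas.max()))
    return float(np.clip(pi0, 1.0 / m, 1.0))


@dataclasses.dataclass
class DeTable:
    """Per-probe ANOVA results with pass flags and per-contrast counts."""

    table: pd.DataFrame
    contrasts: list[tuple[str, str]]
    fdr: float
    lfc: float
    fdr_method: str
    log_base: int = 2

    @property
    def passing(self) -> list[str]:
        return list(self.table.index[self.table["pass"]])

    @property
    def contrast_counts(self) -> dict[str, int]:
        """Among passing probes, how many exceed |lfc| in each contrast."""
        out = {}
        sub = self.table[self.table["pass"]]
        for a, b in self.contrasts:
            col = f"logFC_{a}_vs_{b}"
            out[f"{a}_vs_{b}"] = int((sub[col].abs() > self.lfc).sum())
        return out

    def write(self, path) -> None:
        self.table.rename_axis("probe_id").to_csv(path, sep="\t")


def stagewise_de(
    log2_values: pd.DataFrame,
    stages: pd.Series | Sequence[str],
    contrasts: Sequence[tuple[str, str]] | None = None,
    fdr: float = 0.1,
    lfc: float = 2.5,
    fdr_method: str = "auto",
) -> DeTable:
    """ANOVA across stages + FDR + |logFC| selection on log2 values.

    ``log2_values`` is probes x cells; ``stages`` gives one stage label per
    cell (aligned to columns). Default contrasts are consecutive stage
    pairs in sorted stage order. A probe passes iff q < fdr and the
    maximum absolute contrast logFC exceeds ``lfc``.
    """
    stages = pd.Series(np.asarray(stages), index=log2_values.columns)
    order = sorted(stages.unique())
    if contrasts is None:
        contrasts = list(zip(order, order[1:]))
    contrasts = [tuple(c) for c in contrasts]
    for a, b in contrasts:
        for s in (a, b):
            if s not in set(order):
                raise ValueError(f"contrast names absent stage {s!r}")

    f, p = anova_f(log2_values.to_numpy(float), stages.to_numpy())
    if fdr_method == "auto":
        method = "storey" if len(p) >= STOREY_MIN_PROBES else "bh"
    else:
        method = fdr_method
    q = qvalues(p, method=method)

    table = pd.DataFrame({"F": f, "p": p, "q": q}, index=log2_values.index)
    means = {
        s: log2_values.loc[:, (stages == s).to_numpy()].mean(axis=1)
        for s in order
    }
    max_abs = np.zeros(len(table))
    for a, b in contrasts:
        lf = means[b] - means[a]
        table[f"logFC_{a}_vs_{b}"] = lf
        max_abs = np.maximum(max_abs, lf.abs().to_numpy())
    table["pass"] = (q < fdr) & (max_abs > lfc)
    return DeTable(
        table=table, contrasts=list(contrasts), fdr=fdr, lfc=lfc,
        fdr_method=method,
    )
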