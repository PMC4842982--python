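"""qPCR normalization, reference temporal component, projection and tests.

Normalized expression is [40 - Ct] relative to a reference gene
(40 - (Ct_gene - Ct_ref)). A reference Component 1 is fit by PCA on
wild-type training cells and new (e.g. cell-cycle-arrested) cells are
projected onto it, so their temporal progression can be compared with the
wild-type trajectory by rank tests.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import axes
from .io import QpcrTable

#: switch from exact to tie/continuity-corrected normal Mann-Whitney here
EXACT_MW_LIMIT = 400


@dataclasses.dataclass
class NormalizedQpcr:
    """[40 - Ct] values relative to a reference gene.

    ``censored`` marks entries that were undetected and floored to one unit
    below the minimum detected value of the cell set. ``excluded_cells``
    lists cells dropped because the reference gene itself was undetected.
    """

    values: pd.DataFrame  # genes x cells
    censored: pd.DataFrame  # boolean, same shape
    excluded_cells: list[str]
    reference: str


def qpcr_normalize(q: QpcrTable, reference: str = "Gapdh") -> NormalizedQpcr:
    """Per-cell [40 - delta-Ct] normalization against a reference gene."""
    if reference not in q.ct.index:
        raise KeyError(f"reference gene not measured: {reference}")
    ref_detected = q.detected.loc[reference]
    excluded = [c for c in q.cell_ids if not bool(ref_detected[c])]
    if excluded:
        warnings.warn(
            f"reference gene {reference} undetected in {len(excluded)} "
            f"cell(s); excluded: {excluded}",
            stacklevel=2,
        )
    kept = [c for c in q.cell_ids if c not in set(excluded)]
    ct = q.ct[kept]
    detected = q.detected[kept]
    values = 40.0 - (ct.sub(ct.loc[reference], axis=1))
    detected_vals = values.where(detected)
    floor = float(detected_vals.min().min()) - 1.0
    censored = ~detected
    values = values.where(detected, other=floor)
    return NormalizedQpcr(
        values=values, censored=censored, excluded_cells=excluded,
        reference=reference,
    )


@dataclasses.dataclass
class ReferenceAxis:
    """Component 1 of a PCA on wild-type training cells over a gene panel."""

    panel: list[str]
    center: pd.Series
    loading: pd.Series  # unit-norm Component-1 loading over the panel
    training_scores: pd.Series
    training_stages: pd.Series


def fit_reference_axis(
    values: pd.DataFrame,
    stages: pd.Series | Sequence[str],
    panel: Sequence[str] | None = None,
    stage_order: Sequence[str] | None = None,
) -> ReferenceAxis:
    """Fit the reference Component 1 on training cells.

    ``values`` is genes x cells (normalized [40-Ct] or log2 signal).
    Component 1 is sign-oriented so the latest stage in ``stage_order``
    (sorted stage labels by default) has the highest median score.
    """
    panel = list(panel) if panel is not None else list(values.index)
    missing = set(panel) - set(values.index)
    if missing:
        raise KeyError(f"panel genes missing from matrix: {sorted(missing)}")
    sub = values.loc[panel]
    stages = pd.Series(np.asarray(stages), index=sub.columns)
    if sub.shape[1] < 3:
        raise ValueError("need >= 3 training cells")
    if stages.nunique() < 2:
        raise ValueError("training cells must span >= 2 stages")
    order = list(stage_order) if stage_order is not None else sorted(
        stages.unique()
    )
    pca = axes.fit_pca(sub, n_components=1)
    loading = pca.loadings["PC1"]
    scores = pca.scores["PC1"]
    first = scores[(stages == order[0]).to_numpy()].median()
    last = scores[(stages == order[-1]).to_numpy()].median()
    if last < first:
        loading = -loading
        scores = -scores
    return ReferenceAxis(
        panel=panel,
        center=pca.center,
        loading=loading,
        training_scores=scores,
        training_stages=stages,
    )


def project_cells(axis: ReferenceAxis, values: pd.DataFrame) -> pd.Series:
    """Project new cells (genes x cells) onto the reference Component 1."""
    missing = set(axis.panel) - set(values.index)
    if missing:
        raise KeyError(f"panel genes missing from matrix: {sorted(missing)}")
    sub = values.loc[axis.panel]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any(axis=0)]
        raise ValueError(f"missing panel measurements in cells: {list(bad)}")
    centered = sub.sub(axis.center.loc[axis.panel], axis=0)
    return centered.mul(axis.loading, axis=0).sum(axis=0)


@dataclasses.dataclass
class TestResult:
    statistic: float
    pvalue: float
    method: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def compare_scores(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-tailed Mann-Whitney U comparison of two score vectors.

    Exact enumeration is used when n_a * n_b <= 400 and there are no ties;
    otherwise the normal approximation with tie and continuity correction.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score vectors must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    if a.size * b.size <= EXACT_MW_LIMIT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        pvalue=float(min(res.pvalue, 1.0)),
        method=f"mann-whitney-{method}",
    )


def detection_freq_test(
    flags_a: Sequence[bool], flags_b: Sequence[bool]
) -> tuple[TestResult, np.ndarray]:
    """Two-sided Fisher exact test on detection frequencies of one gene."""
    fa = np.asarray(flags_a, bool)
    fb = np.asarray(flags_b, bool)
    if fa.size == 0 or fb.size == 0:
        raise ValueError("both groups must be non-empty")
    table = np.array(
        [
            [int(fa.sum()), int((~fa).sum())],
            [int(fb.sum()), int((~fb).sum())],
        ]
    )
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return TestResult(float(odds), float(p), "fisher-exact"), table


def stage_dispersion(
    scores: Sequence[float], stages: pd.Series | Sequence[str]
) -> pd.DataFrame:
    """Per-stage IQR and variance of scores; widest-IQR stage flagged."""
    scores = pd.Series(np.asarray(scores, float))
    stages = pd.Series(np.asarray(stages))
    if len(scores) != len(stages):
        raise ValueError("scores and stages differ in length")
    rows = []
    for stage in sorted(stages.unique()):
        vals = scores[(stages == stage).to_numpy()].to_numpy()
        q75, q25 = np.percentile(vals, [75, 25])
        var = float(np.var(vals, ddof=1)) if vals.size > 1 else 0.0
        rows.append(
            dict(stage=stage, n=vals.size, iqr=float(q75 - q25), var=var)
        )
    out = pd.DataFrame(rows).set_index("stage")
    out["widest"] = out["iqr"] == out["iqr"].max()
    return out
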