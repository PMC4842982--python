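"""PCA plus constrained rotation separating temporal and differentiation axes.

The leading two principal components of the progenitor cells are rotated by
an angle theta chosen so that the median horizontal (NewX) coordinate of an
anchor cell group is equal at two stages:

    NewX = cos(theta) * PC1 + sin(theta) * PC2
    NewY = -sin(theta) * PC1 + cos(theta) * PC2

With the anchor medians equalized horizontally, the vertical axis (NewY)
carries the stage-to-stage displacement and is read as the temporal axis;
NewX is read as the differentiation axis. Gene loadings transform with the
same 2x2 rotation, and the top signed NewY / NewX loadings define the
temporal- and differentiation-axis gene sets.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize


@dataclasses.dataclass
class PcaModel:
    """Mean-centred, unscaled PCA of cells over genes."""

    center: pd.Series  # per-gene mean of log2 values
    loadings: pd.DataFrame  # genes x components
    scores: pd.DataFrame  # cells x components
    variance_fraction: np.ndarray  # per component, of total variance

    @property
    def components(self) -> list[str]:
        return list(self.loadings.columns)


def fit_pca(
    log2_values: pd.DataFrame, n_components: int | None = None
) -> PcaModel:
    """PCA of the cells (columns) of a genes x cells log2 matrix.

    No per-gene standardization is applied. Component signs are fixed by
    making the largest-magnitude loading entry positive; callers with a
    stage design should re-orient with :func:`orient_components`.
    """
    n_cells = log2_values.shape[1]
    if n_cells < 3:
        raise ValueError("need >= 3 cells for PCA")
    x = log2_values.to_numpy(float).T  # cells x genes
    center = x.mean(axis=0)
    xc = x - center
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = min(n_components or len(s), len(s))
    # sign convention: dominant loading entry positive
    for j in range(k):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    comp_var = s**2 / (n_cells - 1)
    total_var = float(xc.var(axis=0, ddof=1).sum())
    frac = comp_var[:k] / total_var if total_var > 0 else np.zeros(k)
    names = [f"PC{j + 1}" for j in range(k)]
    return PcaModel(
        center=pd.Series(center, index=log2_values.index),
        loadings=pd.DataFrame(
            vt[:k].T, index=log2_values.index, columns=names
        ),
        scores=pd.DataFrame(
            (u[:, :k] * s[:k]), index=log2_values.columns, columns=names
        ),
        variance_fraction=frac,
    )


def orient_components(
    pca: PcaModel,
    stages: pd.Series,
    early: str,
    late: str,
    components: Sequence[str] = ("PC1", "PC2"),
) -> PcaModel:
    """Flip components so the later stage has the higher median score."""
    stages = stages.reindex(pca.scores.index)
    scores = pca.scores.copy()
    loadings = pca.loadings.copy()
    for comp in components:
        med_early = scores.loc[(stages == early).to_numpy(), comp].median()
        med_late = scores.loc[(stages == late).to_numpy(), comp].median()
        if med_late < med_early:
            scores[comp] *= -1.0
            loadings[comp] *= -1.0
    return PcaModel(
        center=pca.center, loadings=loadings, scores=scores,
        variance_fraction=pca.variance_fraction,
    )


@dataclasses.dataclass
class RotationResult:
    theta: float  # radians
    theta_deg: float
    sin: float
    cos: float
    residual: float  # median-equality constraint residual at theta
    roots_deg: list[float]  # every root found in [-90, 90)

    def to_dict(self) -> dict:
        return {
            "theta_deg": self.theta_deg,
            "sin": self.sin,
            "cos": self.cos,
            "residual": self.residual,
            "roots_deg": self.roots_deg,
        }


def rotation_angle_degrees(sin_theta: float) -> float:
    """Rotation angle in degrees implied by its sine coefficient."""
    if not -1.0 <= sin_theta <= 1.0:
        raise ValueError("sine coefficient must lie in [-1, 1]")
    return math.degrees(math.asin(sin_theta))


def _median_diff(
    theta: np.ndarray | float,
    xa: np.ndarray, ya: np.ndarray,
    xb: np.ndarray, yb: np.ndarray,
    axis: str = "x",
) -> np.ndarray | float:
    """median_B - median_A of the rotated coordinate at angle(s) theta."""
    theta = np.asarray(theta, float)
    ct, st = np.cos(theta), np.sin(theta)
    if axis == "x":
        ca = ct[..., None] * xa + st[..., None] * ya
        cb = ct[..., None] * xb + st[..., None] * yb
    else:
        ca = -st[..., None] * xa + ct[..., None] * ya
        cb = -st[..., None] * xb + ct[..., None] * yb
    out = np.median(cb, axis=-1) - np.median(ca, axis=-1)
    return out if out.ndim else float(out)


def solve_rotation(
    scores: pd.DataFrame,
    anchor_a: Sequence[str],
    anchor_b: Sequence[str],
    grid_step_deg: float = 0.01,
    tol: float = 1e-9,
) -> RotationResult:
    """Find theta equalizing the anchor groups' median NewX.

    The function f(theta) = median_B(NewX) - median_A(NewX) is scanned on a
    ``grid_step_deg`` grid over [-90, 90] and each sign change is refined by
    bisection. With several roots the one maximizing the anchor separation
    |median_B(NewY) - median_A(NewY)| is returned (all roots are reported).
    """
    for name, grp in (("anchor_a", anchor_a), ("anchor_b", anchor_b)):
        if len(grp) == 0:
            raise ValueError(f"{name} is empty")
    xa = scores.loc[list(anchor_a), "PC1"].to_numpy(float)
    ya = scores.loc[list(anchor_a), "PC2"].to_numpy(float)
    xb = scores.loc[list(anchor_b), "PC1"].to_numpy(float)
    yb = scores.loc[list(anchor_b), "PC2"].to_numpy(float)

    grid = np.deg2rad(np.arange(-90.0, 90.0 + grid_step_deg, grid_step_deg))
    f = np.asarray(_median_diff(grid, xa, ya, xb, yb, axis="x"))
    sign_change = np.nonzero((f[:-1] == 0) | (np.sign(f[:-1]) != np.sign(f[1:])))[0]
    if sign_change.size == 0:
        raise ValueError(
            "constraint unsatisfiable: no sign change of the median "
            f"difference over [-90, 90] (extrema {f.min():.4g}, {f.max():.4g})"
        )

    def fun(t: float) -> float:
        return float(_median_diff(t, xa, ya, xb, yb, axis="x"))

    roots: list[float] = []
    for i in sign_change:
        lo, hi = grid[i], grid[i + 1]
        if f[i] == 0.0:
            root = lo
        else:
            root = optimize.brentq(fun, lo, hi, xtol=1e-14)
        if not any(abs(root - r) < 1e-10 for r in roots):
            roots.append(float(root))

    # wrap into [-90, 90)
    roots = sorted(
        r if r < math.pi / 2 else r - math.pi for r in roots
    )
    sep = [
        abs(_median_diff(r, xa, ya, xb, yb, axis="y")) for r in roots
    ]
    best = roots[int(np.argmax(sep))]

    scale = max(
        1.0,
        float(np.max(np.abs(np.concatenate([xa, ya, xb, yb])), initial=0.0)),
    )
    residual = fun(best)
    if abs(residual) > tol * scale:
        raise ValueError(
            f"constraint residual {residual:.3g} exceeds tolerance "
            f"{tol * scale:.3g}"
        )
    return RotationResult(
        theta=best,
        theta_deg=math.degrees(best),
        sin=math.sin(best),
        cos=math.cos(best),
        residual=residual,
        roots_deg=[math.degrees(r) for r in roots],
    )


def rotate_axes(
    pca: PcaModel, rot: RotationResult
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rotated per-cell scores and per-gene loadings (NewX/NewY).

    Only the leading two components are rotated; any higher components are
    passed through unchanged.
    """
    ct, st = rot.cos, rot.sin

    def apply(frame: pd.DataFrame) -> pd.DataFrame:
        pc1 = frame["PC1"].to_numpy(float)
        pc2 = frame["PC2"].to_numpy(float)
        out = frame.drop(columns=["PC1", "PC2"]).copy()
        out.insert(0, "NewY", -st * pc1 + ct * pc2)
        out.insert(0, "NewX", ct * pc1 + st * pc2)
        return out

    return apply(pca.scores), apply(pca.loadings)


@dataclasses.dataclass
class AxisGeneSet:
    """Top-k signed contributors to the temporal (NewY) and NewX axes."""

    temporal_positive: list[str]
    temporal_negative: list[str]
    differentiation_positive: list[str]
    differentiation_negative: list[str]
    ranked: pd.DataFrame  # full loading table with per-axis ranks


def axis_genes(rotated_loadings: pd.DataFrame, k: int = 10) -> AxisGeneSet:
    """Extract top-k positive/negative genes per rotated axis.

    Ties are broken by gene id (ascending) for reproducibility.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(rotated_loadings):
        raise ValueError(
            f"k={k} exceeds gene count {len(rotated_loadings)}"
        )
    frame = rotated_loadings.copy()
    frame["_gene"] = frame.index

    def top(axis: str, ascending: bool) -> list[str]:
        ordered = frame.sort_values(
            [axis, "_gene"], ascending=[ascending, True], kind="mergesort"
        )
        return list(ordered.index[:k])

    ranked = frame.drop(columns="_gene").copy()
    ranked["rank_NewY"] = (-ranked["NewY"]).rank(method="first")
    ranked["rank_NewX"] = (-ranked["NewX"]).rank(method="first")
    return AxisGeneSet(
        temporal_positive=top("NewY", ascending=False),
        temporal_negative=top("NewY", ascending=True),
        differentiation_positive=top("NewX", ascending=False),
        differentiation_negative=top("NewX", ascending=True),
        ranked=ranked,
    )


def parallel_shift_stat(
    log2_values: pd.DataFrame,
    temporal_genes: Sequence[str],
    types: pd.Series,
    stages: pd.Series,
    stage_a: str,
    stage_b: str,
    type_a: str = "AP",
    type_b: str = "IP",
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Fraction of temporal genes with matching shift sign in two cell types.

    Mean shift stage_a -> stage_b is computed separately in the two cell
    classes; the statistic is the sign-agreement fraction with a
    permutation p-value (class labels shuffled within stage).
    """
    types = pd.Series(np.asarray(types), index=log2_values.columns)
    stages = pd.Series(np.asarray(stages), index=log2_values.columns)
    sub = log2_values.loc[list(temporal_genes)]

    masks = {}
    for stage in (stage_a, stage_b):
        for t in (type_a, type_b):
            m = ((stages == stage) & (types == t)).to_numpy()
            if not m.any():
                raise ValueError(f"no {t} cells at stage {stage}")
            masks[stage, t] = m

    x = sub.to_numpy(float)

    def agreement(type_labels: np.ndarray) -> float:
        shifts = {}
        for t in (type_a, type_b):
            sel_a = (stages == stage_a).to_numpy() & (type_labels == t)
            sel_b = (stages == stage_b).to_numpy() & (type_labels == t)
            shifts[t] = x[:, sel_b].mean(axis=1) - x[:, sel_a].mean(axis=1)
        return float(
            (np.sign(shifts[type_a]) == np.sign(shifts[type_b])).mean()
        )

    labels = types.to_numpy().copy()
    observed = agreement(labels)

    rng = np.random.default_rng(seed)
    count = 0
    stage_arr = stages.to_numpy()
    for _ in range(n_perm):
        perm = labels.copy()
        for stage in np.unique(stage_arr):
            idx = np.nonzero(stage_arr == stage)[0]
            perm[idx] = perm[rng.permutation(idx)]
        if agreement(perm) >= observed:
            count += 1
    pvalue = (1 + count) / (1 + n_perm)
    return observed, pvalue
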