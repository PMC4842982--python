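import math

import numpy as np
import pandas as pd
import pytest

from tempax import axes, synthetic
from tempax.axes import (
    axis_genes,
    fit_pca,
    orient_components,
    parallel_shift_stat,
    rotate_axes,
    rotation_angle_degrees,
    solve_rotation,
)


def scores_frame(xy: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        xy, columns=["PC1", "PC2"],
        index=[f"c{i}" for i in range(len(xy))],
    )


def planted_groups(rng, dx, dy, n=50, spread=0.3):
    """Two point-symmetric clouds with median offsets (dx, dy)."""
    base = rng.uniform(-1, 1, size=(n, 2)) * spread
    base = np.vstack([base, -base])  # symmetric: medians exactly 0
    a = scores_frame(np.vstack([base, base + [dx, dy]]))
    ids = list(a.index)
    return a, ids[: 2 * n], ids[2 * n:]


class TestFitPca:
    def test_scores_centered(self, rng):
        frame = pd.DataFrame(rng.normal(size=(30, 10)))
        pca = fit_pca(frame)
        assert np.allclose(pca.scores.mean(axis=0), 0.0, atol=1e-10)

    def test_two_gene_toy_eigenstructure(self):
        # data with sample covariance exactly [[2,1],[1,2]]:
        # PC1 along (1,1)/sqrt(2), variance fractions (0.75, 0.25)
        w1 = np.array([1.0, -1.0, 0.0]) / np.sqrt(2)
        w2 = np.array([1.0, 1.0, -2.0]) / np.sqrt(6)
        e1 = np.array([1.0, 1.0]) / np.sqrt(2)
        e2 = np.array([1.0, -1.0]) / np.sqrt(2)
        x = np.sqrt(6) * np.outer(w1, e1) + np.sqrt(2) * np.outer(w2, e2)
        assert np.allclose(np.cov(x.T), [[2, 1], [1, 2]])
        frame = pd.DataFrame(x.T, index=["g1", "g2"])  # genes x cells
        pca = fit_pca(frame)
        assert np.allclose(np.abs(pca.loadings["PC1"]), np.sqrt(0.5))
        assert pca.variance_fraction[0] == pytest.approx(0.75)
        assert pca.variance_fraction[1] == pytest.approx(0.25)

    def test_loadings_orthonormal(self, rng):
        frame = pd.DataFrame(rng.normal(size=(40, 15)))
        pca = fit_pca(frame, n_components=5)
        load = pca.loadings.to_numpy()
        assert np.allclose(load.T @ load, np.eye(5), atol=1e-10)

    def test_variance_fractions_non_increasing_and_sum_leq_one(self, rng):
        frame = pd.DataFrame(rng.normal(size=(40, 15)))
        pca = fit_pca(frame)
        frac = pca.variance_fraction
        assert (np.diff(frac) <= 1e-12).all()
        assert frac.sum() <= 1.0 + 1e-10

    def test_scores_equal_centered_data_times_loadings(self, rng):
        frame = pd.DataFrame(rng.normal(size=(20, 12)))
        pca = fit_pca(frame, n_components=4)
        centered = frame.to_numpy().T - pca.center.to_numpy()
        assert np.allclose(
            centered @ pca.loadings.to_numpy(), pca.scores.to_numpy()
        )

    def test_too_few_cells(self, rng):
        with pytest.raises(ValueError, match="cells"):
            fit_pca(pd.DataFrame(rng.normal(size=(5, 2))))

    def test_orient_components_puts_late_stage_high(self, rng):
        frame = pd.DataFrame(rng.normal(size=(30, 20)))
        frame.iloc[:, 10:] += 2.0  # late cells shifted
        stages = pd.Series(
            ["E11"] * 10 + ["E14"] * 10, index=frame.columns
        )
        pca = orient_components(fit_pca(frame), stages, "E11", "E14")
        med = pca.scores.groupby(stages).median()
        assert med.loc["E14", "PC1"] >= med.loc["E11", "PC1"]


class TestRotationAngle:
    def test_printed_coefficient_recovers_angle(self):
        # arcsin of the rotation coefficient, in degrees
        assert round(rotation_angle_degrees(0.6864510), 2) == 43.35

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            rotation_angle_degrees(1.5)

    def test_implied_cosine_is_consistent(self):
        sin_t = 0.6864510
        theta = math.radians(rotation_angle_degrees(sin_t))
        assert math.cos(theta) == pytest.approx(
            math.sqrt(1 - sin_t**2), abs=1e-12
        )


class TestSolveRotation:
    def test_already_equal_medians_theta_zero(self, rng):
        # groups share PC1 median, differ on PC2 -> theta = 0
        a, ga, gb = planted_groups(rng, dx=0.0, dy=2.0)
        rot = solve_rotation(a, ga, gb)
        assert rot.theta_deg == pytest.approx(0.0, abs=1e-6)

    def test_diagonal_offset_minus_45(self, rng):
        # median offsets (1, 1) -> theta = -45 deg
        a, ga, gb = planted_groups(rng, dx=1.0, dy=1.0)
        rot = solve_rotation(a, ga, gb)
        assert rot.theta_deg == pytest.approx(-45.0, abs=1e-4)

    def test_residual_below_tolerance(self, rng):
        a, ga, gb = planted_groups(rng, dx=0.7, dy=1.3)
        rot = solve_rotation(a, ga, gb)
        scale = max(1.0, float(np.abs(a.to_numpy()).max()))
        assert abs(rot.residual) <= 1e-9 * scale

    def test_sin_cos_unit_norm(self, rng):
        a, ga, gb = planted_groups(rng, dx=0.4, dy=0.9)
        rot = solve_rotation(a, ga, gb)
        assert rot.sin**2 + rot.cos**2 == pytest.approx(1.0, abs=1e-12)

    def test_empty_anchor_rejected(self, rng):
        a, ga, gb = planted_groups(rng, dx=1.0, dy=1.0)
        with pytest.raises(ValueError, match="empty"):
            solve_rotation(a, [], gb)

    def test_grid_oracle_agreement_small(self, rng):
        # brute-force 1e-4 degree oracle on a handful of configurations
        for seed in range(5):
            r = np.random.default_rng(seed)
            a, ga, gb = planted_groups(
                r, dx=r.uniform(-2, 2), dy=r.uniform(0.5, 2), n=25
            )
            rot = solve_rotation(a, ga, gb)
            oracle = grid_oracle(a, ga, gb)
            assert abs(rot.theta_deg - oracle) < 0.01


def grid_oracle(scores, ga, gb, coarse=0.01, fine=1e-4):
    """Independent hierarchical grid search for the rotation angle."""
    xa = scores.loc[ga, "PC1"].to_numpy()
    ya = scores.loc[ga, "PC2"].to_numpy()
    xb = scores.loc[gb, "PC1"].to_numpy()
    yb = scores.loc[gb, "PC2"].to_numpy()

    def f(deg):
        t = np.deg2rad(np.atleast_1d(deg))
        ct, st = np.cos(t)[:, None], np.sin(t)[:, None]
        return np.median(ct * xb + st * yb, axis=1) - np.median(
            ct * xa + st * ya, axis=1
        )

    def sepy(deg):
        t = np.deg2rad(deg)
        ct, st = np.cos(t), np.sin(t)
        return abs(
            np.median(-st * xb + ct * yb) - np.median(-st * xa + ct * ya)
        )

    grid = np.arange(-90.0, 90.0 + coarse, coarse)
    vals = f(grid)
    best, best_sep = None, -1.0
    for i in np.nonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))[0]:
        sub = np.arange(grid[i], grid[i + 1] + fine / 2, fine)
        sv = f(sub)
        j = int(np.argmin(np.abs(sv)))
        cand = sub[j] if sub[j] < 90.0 else sub[j] - 180.0
        if sepy(cand) > best_sep:
            best, best_sep = cand, sepy(cand)
    return best


class TestRotateAxes:
    def test_theta_zero_identity(self, rng):
        frame = pd.DataFrame(rng.normal(size=(30, 12)))
        pca = fit_pca(frame, n_components=3)
        rot = axes.RotationResult(
            theta=0.0, theta_deg=0.0, sin=0.0, cos=1.0, residual=0.0,
            roots_deg=[0.0],
        )
        scores, loadings = rotate_axes(pca, rot)
        assert np.allclose(scores["NewX"], pca.scores["PC1"])
        assert np.allclose(scores["NewY"], pca.scores["PC2"])
        # higher components pass through unrotated
        assert np.allclose(scores["PC3"], pca.scores["PC3"])

    def test_unit_vector_image(self):
        # (PC1, PC2) = (1, 0) maps to (cos t, -sin t)
        sin_t = 0.6864510
        cos_t = math.sqrt(1 - sin_t**2)
        rot = axes.RotationResult(
            theta=math.asin(sin_t), theta_deg=rotation_angle_degrees(sin_t),
            sin=sin_t, cos=cos_t, residual=0.0, roots_deg=[],
        )
        pca = axes.PcaModel(
            center=pd.Series(dtype=float),
            loadings=pd.DataFrame(columns=["PC1", "PC2"], dtype=float),
            scores=scores_frame(np.array([[1.0, 0.0]])),
            variance_fraction=np.array([1.0]),
        )
        scores, _ = rotate_axes(pca, rot)
        assert scores["NewX"].iloc[0] == pytest.approx(cos_t)
        assert scores["NewY"].iloc[0] == pytest.approx(-sin_t)

    def test_distances_preserved(self, rng):
        frame = pd.DataFrame(rng.normal(size=(25, 15)))
        pca = fit_pca(frame, n_components=2)
        a, ga, gb = planted_groups(rng, dx=1.0, dy=0.5, n=10)
        rot = solve_rotation(pca.scores, pca.scores.index[:5],
                             pca.scores.index[5:])
        scores, loadings = rotate_axes(pca, rot)
        before = pca.scores[["PC1", "PC2"]].to_numpy()
        after = scores[["NewX", "NewY"]].to_numpy()
        d_before = np.linalg.norm(
            before[:, None, :] - before[None, :, :], axis=-1
        )
        d_after = np.linalg.norm(
            after[:, None, :] - after[None, :, :], axis=-1
        )
        assert np.allclose(d_before, d_after, atol=1e-12)


class TestAxisGenes:
    def test_pure_newy_gene_only_in_temporal_lists(self):
        loadings = pd.DataFrame(
            {"NewX": [0.0, 0.9, -0.8], "NewY": [1.0, 0.05, -0.02]},
            index=["tempgene", "diffpos", "diffneg"],
        )
        gs = axis_genes(loadings, k=1)
        assert gs.temporal_positive == ["tempgene"]
        assert "tempgene" not in gs.differentiation_positive
        assert "tempgene" not in gs.differentiation_negative

    def test_k_too_large(self):
        loadings = pd.DataFrame({"NewX": [0.1], "NewY": [0.2]}, index=["g"])
        with pytest.raises(ValueError, match="exceeds"):
            axis_genes(loadings, k=2)

    def test_lists_disjoint_within_axis(self, rng):
        loadings = pd.DataFrame(
            {"NewX": rng.normal(size=50), "NewY": rng.normal(size=50)},
            index=[f"g{i}" for i in range(50)],
        )
        gs = axis_genes(loadings, k=10)
        assert not set(gs.temporal_positive) & set(gs.temporal_negative)
        assert not set(gs.differentiation_positive) & set(
            gs.differentiation_negative
        )

    def test_recovers_planted_temporal_genes(self):
        # full pipeline: PCA + rotation + loading extraction on synthetic
        # progenitors recovers >= 90% planted temporal genes
        cfg = synthetic.SimConfig(
            stages={"E11": 100, "E14": 100},
            mixing={s: {"AP": 0.5, "IP": 0.5, "neuron": 0.0}
                    for s in ("E11", "E14")},
            temporal_effect=1.0,
            diff_effect=1.0,
            noise_sd=0.5,
            seed=42,
        )
        matrix, truth = synthetic.simulate_dataset(cfg)
        cells = truth.cells
        log2 = matrix.log2()
        pca = fit_pca(log2, n_components=2)
        pca = orient_components(pca, cells.stage, "E11", "E14")
        anchors = {
            s: list(cells.index[(cells.cell_type == "AP")
                                & (cells.stage == s)])
            for s in ("E11", "E14")
        }
        rot = solve_rotation(pca.scores, anchors["E11"], anchors["E14"])
        _, loadings = rotate_axes(pca, rot)
        k = 20
        gs = axis_genes(loadings[["NewX", "NewY"]], k=k)
        temporal = set(truth.genes.index[truth.genes.gene_class == "temporal"])
        hits = len(
            (set(gs.temporal_positive) | set(gs.temporal_negative)) & temporal
        )
        assert hits >= 0.9 * 2 * k


class TestParallelShift:
    @staticmethod
    def design(rng, n=20):
        cols = [f"c{i}" for i in range(4 * n)]
        types = pd.Series((["AP"] * n + ["IP"] * n) * 2, index=cols)
        stages = pd.Series(["E11"] * 2 * n + ["E14"] * 2 * n, index=cols)
        return cols, types, stages

    def test_identical_shift_vectors_agree_fully(self, rng):
        cols, types, stages = self.design(rng)
        shifts = rng.normal(0, 2, size=10)
        x = rng.normal(0, 0.01, size=(10, len(cols)))
        x[:, (stages == "E14").to_numpy()] += shifts[:, None]
        frame = pd.DataFrame(x, index=[f"g{i}" for i in range(10)],
                             columns=cols)
        frac, _ = parallel_shift_stat(
            frame, list(frame.index), types, stages, "E11", "E14", seed=0,
            n_perm=50,
        )
        assert frac == 1.0

    def test_independent_shifts_agree_half(self, rng):
        cols, types, stages = self.design(rng, n=50)
        n_genes = 400
        x = rng.normal(0, 0.05, size=(n_genes, len(cols)))
        for t in ("AP", "IP"):
            sel = ((stages == "E14") & (types == t)).to_numpy()
            x[:, sel] += rng.normal(0, 2, size=n_genes)[:, None]
        frame = pd.DataFrame(x, index=[f"g{i}" for i in range(n_genes)],
                             columns=cols)
        frac, p = parallel_shift_stat(
            frame, list(frame.index), types, stages, "E11", "E14", seed=0,
            n_perm=100,
        )
        assert abs(frac - 0.5) < 0.1
        assert p > 0.05

    def test_generator_output_agrees_fully(self, study_dataset):
        _, matrix, truth = study_dataset
        tgenes = list(
            truth.genes.index[truth.genes.gene_class == "temporal"]
        )
        prog = truth.cells[truth.cells.cell_type.isin(["AP", "IP"])]
        frac, _ = parallel_shift_stat(
            matrix.log2()[prog.index], tgenes, prog.cell_type, prog.stage,
            "E11", "E14", seed=1, n_perm=50,
        )
        assert frac == 1.0

    def test_missing_class_at_stage(self, rng):
        cols, types, stages = self.design(rng)
        types[:] = "AP"
        frame = pd.DataFrame(
            rng.normal(size=(5, len(cols))), columns=cols
        )
        with pytest.raises(ValueError, match="no IP cells"):
            parallel_shift_stat(
                frame, list(frame.index), types, stages, "E11", "E14"
            )
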