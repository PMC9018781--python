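import numpy as np
import pandas as pd
import pytest

from pcsig import quantify
from pcsig.pcalign import (
    PCAlignment,
    align_genes,
    alignment_summary,
    center,
    find_condition_pc,
    fit_pca,
)
from pcsig.synthetic import default_design


def noise_logexpr(n_genes, design, seed, shift=None):
    """Pure-noise log-expression for the samples of a two-group design.

    ``shift`` (group -> magnitude) plants a condition effect on a gene
    subset with mixed signs: the first third of genes go up, the second
    third down, the rest stay null — so the pattern survives double
    centering (a shift common to all genes is just a sample offset)."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n_genes, len(design.table)))
    df = pd.DataFrame(
        x, index=[f"g{i}" for i in range(n_genes)], columns=design.sample_ids
    )
    if shift is not None:
        sign = np.zeros(n_genes)
        sign[: n_genes // 3] = 1.0
        sign[n_genes // 3 : 2 * n_genes // 3] = -1.0
        for s, grp in zip(design.sample_ids, design.table["group"]):
            df[s] += sign * shift.get(grp, 0.0)
    return df


class TestCenter:
    def test_gene_mode_row_example(self):
        x = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        out = center(x, mode="gene")
        np.testing.assert_allclose(out.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_double_centering_hand_case_and_idempotence(self):
        x = pd.DataFrame([[1.0, 3.0], [5.0, 7.0]])
        once = center(x, mode="both")
        np.testing.assert_allclose(once.to_numpy(), np.zeros((2, 2)), atol=1e-12)
        rng = np.random.default_rng(0)
        y = pd.DataFrame(rng.normal(size=(6, 5)))
        once = center(y, mode="both")
        twice = center(once, mode="both")
        pd.testing.assert_frame_equal(once, twice)
        assert np.allclose(once.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(once.mean(axis=1), 0, atol=1e-9)

    def test_constant_matrix_warns_and_bad_mode_raises(self):
        with pytest.warns(UserWarning, match="constant"):
            center(pd.DataFrame(np.ones((3, 3))))
        with pytest.raises(ValueError, match="mode"):
            center(pd.DataFrame(np.eye(3)), mode="diagonal")


class TestFitPCA:
    def test_rank_one_pattern_captures_all_variance(self):
        u = np.array([1.0, -1.0, 2.0, 0.5])
        v = np.array([1.0, 2.0, -1.0])
        x = pd.DataFrame(np.outer(u, v))
        model = fit_pca(x)
        assert model.variance_fractions.iloc[0] == pytest.approx(1.0)

    def test_reconstruction_orthogonality_and_sign_convention(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame(rng.normal(size=(8, 6)))
        model = fit_pca(x)
        vf = model.variance_fractions.to_numpy()
        assert (np.diff(vf) <= 1e-12).all() and vf.sum() == pytest.approx(1.0)
        coords = model.coordinates.to_numpy()
        s = model.singular_values.to_numpy()
        recon = model.gene_directions.to_numpy() @ np.diag(s) @ coords.T
        np.testing.assert_allclose(recon, x.to_numpy(), atol=1e-8)
        np.testing.assert_allclose(coords.T @ coords, np.eye(6), atol=1e-10)
        for k in range(coords.shape[1]):
            assert coords[np.argmax(np.abs(coords[:, k])), k] > 0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(pd.DataFrame(np.zeros((5, 4))))
        with pytest.raises(ValueError):
            fit_pca(pd.DataFrame(np.ones((1, 4))))


class TestFindConditionPC:
    def test_planted_global_shift_is_found_and_oriented(self):
        design = default_design().subset(("30mCON", "30mCR"))
        x = noise_logexpr(300, design, seed=1, shift={"30mCR": 2.0})
        model = fit_pca(center(x))
        cpc = find_condition_pc(model, design, ("30mCON", "30mCR"))
        coord = cpc.oriented_coordinates(model)
        assert not cpc.low_confidence
        assert (
            coord[design.samples_of("30mCR")].mean()
            > coord[design.samples_of("30mCON")].mean()
        )

    def test_group_swap_flips_orientation_only(self):
        design = default_design().subset(("30mCON", "30mCR"))
        x = noise_logexpr(200, design, seed=2, shift={"30mCR": 1.5})
        model = fit_pca(center(x))
        fwd = find_condition_pc(model, design, ("30mCON", "30mCR"))
        rev = find_condition_pc(model, design, ("30mCR", "30mCON"))
        assert fwd.pc_index == rev.pc_index
        assert fwd.orientation == -rev.orientation
        pd.testing.assert_series_equal(fwd.separation_scores, rev.separation_scores)

    def test_pure_noise_flagged_low_confidence(self):
        design = default_design().subset(("30mCON", "30mCR"))
        x = noise_logexpr(200, design, seed=3)
        model = fit_pca(center(x))
        cpc = find_condition_pc(model, design, ("30mCON", "30mCR"))
        assert cpc.low_confidence
        assert 1 <= cpc.pc_index <= 6

    def test_missing_group_in_a_muscle_rejected(self):
        design = default_design().subset(("30mCON", "30mCR"))
        x = noise_logexpr(50, design, seed=4)
        dropped = design.table[design.table["muscle"] != "SOL"]
        from pcsig.synthetic import StudyDesign

        model = fit_pca(center(x))
        with pytest.raises(ValueError, match="SOL"):
            find_condition_pc(
                model,
                StudyDesign(
                    pd.concat(
                        [
                            dropped,
                            design.table[
                                (design.table["muscle"] == "SOL")
                                & (design.table["group"] == "30mCON")
                            ],
                        ]
                    )
                ),
                ("30mCON", "30mCR"),
            )


class TestAlignGenes:
    @staticmethod
    def _fitted(seed=5, n_genes=400, shift=1.5):
        design = default_design().subset(("30mCON", "30mCR"))
        x = noise_logexpr(n_genes, design, seed=seed, shift={"30mCR": shift})
        centered = center(x)
        model = fit_pca(centered)
        cpc = find_condition_pc(model, design, ("30mCON", "30mCR"))
        return design, centered, model, cpc

    def test_proportional_and_orthogonal_profiles(self):
        design, centered, model, cpc = self._fitted()
        v = cpc.oriented_coordinates(model).to_numpy()
        probe = centered.copy()
        probe.iloc[0] = 3.0 * v  # exactly proportional
        probe.iloc[1] = 0.0  # zero-variance
        ga = align_genes(probe, model, cpc)
        assert ga["r"].iloc[0] == pytest.approx(1.0, abs=1e-9)
        assert ga["r"].iloc[1] == 0.0 and not ga["aligned"].iloc[1]
        # profile orthogonal to the PC: projection and r both vanish
        w = model.coordinates.iloc[:, -1].to_numpy()  # orthogonal component
        probe.iloc[2] = w
        ga = align_genes(probe, model, cpc)
        assert ga["projection"].iloc[2] == pytest.approx(0.0, abs=1e-9)

    def test_z_standardization_and_summary_consistency(self):
        _, centered, model, cpc = self._fitted()
        ga = align_genes(centered, model, cpc)
        assert ga["z"].mean() == pytest.approx(0.0, abs=1e-6)
        assert ga["z"].std(ddof=0) == pytest.approx(1.0, abs=1e-6)
        st = alignment_summary(ga, model, cpc)
        assert st.n_up + st.n_down == st.n_aligned == int(ga["aligned"].sum())
        assert (ga.loc[~ga["aligned"], "direction"] == "none").all()

    def test_orientation_equivariance_under_group_swap(self):
        design = default_design().subset(("30mCON", "30mCR"))
        x = noise_logexpr(300, design, seed=6, shift={"30mCR": 1.0})
        centered = center(x)
        model = fit_pca(centered)
        fwd = find_condition_pc(model, design, ("30mCON", "30mCR"))
        rev = find_condition_pc(model, design, ("30mCR", "30mCON"))
        ga_f = align_genes(centered, model, fwd)
        ga_r = align_genes(centered, model, rev)
        np.testing.assert_allclose(ga_f["projection"], -ga_r["projection"], atol=1e-9)
        np.testing.assert_allclose(ga_f["z"], -ga_r["z"], atol=1e-6)
        np.testing.assert_allclose(ga_f["r"], -ga_r["r"], atol=1e-9)
        assert (ga_f["aligned"] == ga_r["aligned"]).all()
        up_f = ga_f["direction"] == "up"
        down_r = ga_r["direction"] == "down"
        assert (up_f == down_r).all()

    def test_scale_invariance(self):
        _, centered, model, cpc = self._fitted(seed=7)
        ga1 = align_genes(centered, model, cpc)
        ga2 = align_genes(centered * 37.5, model, cpc)
        np.testing.assert_allclose(ga1["z"], ga2["z"], atol=1e-9)
        np.testing.assert_allclose(ga1["r"], ga2["r"], atol=1e-9)
        assert (ga1["aligned"] == ga2["aligned"]).all()


class TestModelInterface:
    def test_from_counts_fit_and_summary(self, small_study):
        _, design, annotation, counts, _ = small_study
        model = PCAlignment.from_counts(
            counts,
            design,
            ("30mCON", "30mCR"),
            quantify.gene_lengths(annotation),
        )
        res = model.fit()
        text = res.summary()
        assert "30mCON vs 30mCR" in text
        assert res.condition_pc.label in text
        assert res.alignment.shape[1] == 5
        assert 0 < res.summary_stats.variance_fraction < 1

    def test_planted_effect_recovery_on_default_study(self, default_run):
        """On the default study the CR-comparison alignment recovers the
        genes planted with a CR effect at high sensitivity and low false
        discovery, and the condition PC sits below the muscle axes."""
        truth = default_run["truth"]
        res = default_run["results"]["cr"]
        planted = set(truth.index[truth["lfc_cr"] != 0])
        called = set(res.aligned_genes)
        sens = len(called & planted) / len(planted)
        fdp = len(called - planted) / max(len(called), 1)
        assert sens >= 0.8
        assert fdp <= 0.1
        assert res.condition_pc.pc_index in (3, 4)
        # planted direction is respected: CR-up genes called "up"
        up_genes = truth.index[truth["lfc_cr"] > 0]
        dirs = res.alignment.loc[
            res.alignment.index.intersection(up_genes)
        ]
        called_up = dirs.loc[dirs["aligned"], "direction"]
        assert (called_up == "up").mean() > 0.95
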