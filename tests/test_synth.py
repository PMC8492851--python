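"""Generator contracts: determinism, dimensions, count model, kinetics, plates, images."""

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import label as ndi_label

from orgstate import drugscreen, synth
from orgstate.errors import ConfigurationError


def _cfg(**kw):
    base = dict(n_lines=2, cells_per_line=100, n_genes=600)
    base.update(kw)
    return synth.CohortConfig(**base)


class TestGenerateCohort:
    def test_dimensions_follow_config(self):
        adata, truth = synth.generate_cohort(_cfg(), seed=1)
        assert adata.shape == (200, 600)
        assert len(truth.cells) == 200

    def test_seeded_determinism_is_bitwise(self):
        a1, t1 = synth.generate_cohort(_cfg(), seed=3)
        a2, t2 = synth.generate_cohort(_cfg(), seed=3)
        assert (a1.X != a2.X).nnz == 0
        pd.testing.assert_frame_equal(t1.cells, t2.cells)

    def test_default_truth_has_nine_states(self, default_cohort):
        _, truth = default_cohort
        assert truth.cells["state_label"].nunique() == 9
        assert set(truth.cells["state_label"]) == set(synth.STATE_NAMES)

    def test_counts_are_nonnegative_integers(self, small_cohort):
        adata, _ = small_cohort
        x = adata.X.toarray()
        assert (x >= 0).all()
        assert np.array_equal(x, np.rint(x))

    def test_mito_genes_carry_prefix(self, small_cohort):
        adata, _ = small_cohort
        assert adata.var["is_mito"].sum() == 10
        assert all(g.startswith("MT-") for g in adata.var_names[adata.var["is_mito"]])

    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_lines=0),
            dict(cells_per_line=10),
            dict(n_genes=100),
            dict(subtype_mix=[0.5]),  # wrong length for 2 lines
            dict(subtype_mix=[0.5, 1.4]),
            dict(qc_fail_frac=1.5),
        ],
    )
    def test_invalid_config_raises(self, kw):
        with pytest.raises(ConfigurationError):
            synth.generate_cohort(_cfg(**kw), seed=0)

    def test_qc_fail_flags_injected(self, small_cohort):
        _, truth = small_cohort
        flagged = truth.cells["qc_fail"] != "none"
        assert flagged.sum() == round(0.04 * len(truth.cells))

    def test_subtype_weight_in_unit_interval(self, small_cohort):
        _, truth = small_cohort
        w = truth.cells["subtype_weight"]
        assert ((w >= 0) & (w <= 1)).all()

    def test_branches_share_trunk_latent_time_range(self, default_cohort):
        _, truth = default_cohort
        cells = truth.cells
        for branch in ("cycle-reentry", "differentiation"):
            t = cells.loc[cells["branch_id"] == branch, "latent_time"]
            assert t.min() >= truth.bifurcation_time - 1e-9
            assert t.max() <= truth.t_max + 1e-9


class TestNegativeBinomialModel:
    def test_moments_match_config_at_monte_carlo_scale(self):
        rng = np.random.default_rng(0)
        mean, theta, n = 4.0, 10.0, 10_000
        draws = synth.sample_negative_binomial(np.full(n, mean), theta, rng)
        assert draws.mean() == pytest.approx(mean, rel=0.05)
        assert draws.var() == pytest.approx(mean + mean**2 / theta, rel=0.05)

    def test_dispersion_factor_inflates_a_gene(self):
        cfg = _cfg(dispersion_factors={"GENE00001": 100.0})
        adata, truth = synth.generate_cohort(cfg, seed=2)
        col = list(adata.var_names).index("GENE00001")
        assert truth.model.theta[col] == pytest.approx(10.0 / 100.0)


class TestKineticLayers:
    def test_steady_state_ratio_equals_gamma(self, small_cohort):
        adata, truth = small_cohort
        adata = adata.copy()
        synth.generate_kinetic_layers(adata, truth, noise_level=0.0, seed=0)
        s = adata.layers["spliced"].toarray()
        u = adata.layers["unspliced"].toarray()
        # genes with no temporal program are at steady state in every cell
        static = [i for i, g in enumerate(adata.var_names) if g.startswith("GENE")]
        gamma = truth.gamma_true.to_numpy()
        for i in static[:20]:
            expressed = s[:, i] > 0
            if expressed.sum() == 0:
                continue
            ratio = u[expressed, i] / s[expressed, i]
            assert np.allclose(ratio, gamma[i], atol=1e-9)

    def test_mean_ratio_matches_gamma_for_static_genes(self, small_cohort):
        adata, truth = small_cohort
        adata = adata.copy()
        synth.generate_kinetic_layers(adata, truth, noise_level=0.0, seed=0)
        s = adata.layers["spliced"].toarray()
        u = adata.layers["unspliced"].toarray()
        i = list(adata.var_names).index("GENE00001")
        assert u[:, i].mean() / s[:, i].mean() == pytest.approx(
            truth.gamma_true.iloc[i], abs=1e-9
        )

    def test_transient_induced_gene_has_positive_velocity(self, small_cohort):
        adata, truth = small_cohort
        adata = adata.copy()
        synth.generate_kinetic_layers(adata, truth, noise_level=0.0, seed=0)
        s = adata.layers["spliced"].toarray()
        u = adata.layers["unspliced"].toarray()
        gamma = truth.gamma_true.to_numpy()
        v = u - gamma[None, :] * s
        # evaluate the generator's own rates: cells in a rising state wall
        mk = [i for i, g in enumerate(adata.var_names) if g.startswith("MK-Cycling-2")]
        t = truth.cells["latent_time"].to_numpy()
        on_path = truth.cells["on_path"].to_numpy()
        rising = on_path & (t > 0.92) & (t < 1.06)  # entering Cycling-2
        assert rising.sum() > 0
        assert v[np.ix_(rising, mk)].mean() > 0

    def test_seeded_layers_identical(self, small_cohort):
        adata, truth = small_cohort
        a1, a2 = adata.copy(), adata.copy()
        synth.generate_kinetic_layers(a1, truth, noise_level=1.0, seed=5)
        synth.generate_kinetic_layers(a2, truth, noise_level=1.0, seed=5)
        assert (a1.layers["spliced"] != a2.layers["spliced"]).nnz == 0
        assert (a1.layers["unspliced"] != a2.layers["unspliced"]).nnz == 0

    def test_invalid_beta_raises(self, small_cohort):
        adata, truth = small_cohort
        with pytest.raises(ConfigurationError):
            synth.generate_kinetic_layers(
                adata.copy(), truth, beta_per_state={"Cycling-1": -1.0}
            )


class TestDrugPlate:
    def test_default_grid_is_one_to_three_dilution(self):
        grid = synth.default_concentration_grid()
        ratios = grid[:-1] / grid[1:]
        assert np.allclose(ratios, 3.0)

    def test_zero_sensitivity_line_is_flat_at_baseline(self, small_cohort):
        _, base = small_cohort
        truth = synth.SyntheticTruth(
            cells=base.cells,
            gamma_true=base.gamma_true,
            sensitivity=base.sensitivity.copy(),
            model=base.model,
        )
        truth.sensitivity.loc["line00", :] = 0.0
        plate = synth.generate_drug_plate(truth, noise_level=0.0, seed=0)
        cd = drugscreen.death_fraction(plate)
        flat = cd[cd["line_id"] == "line00"]
        assert flat.groupby("drug")["cd"].std().max() < 1e-12

    def test_higher_sensitivity_gives_higher_aucpi(self, small_cohort):
        _, truth = small_cohort
        truth = synth.SyntheticTruth(
            cells=truth.cells,
            gamma_true=truth.gamma_true,
            sensitivity=pd.DataFrame(
                {"5-FU": [0.2, 0.8]}, index=["line00", "line01"]
            ),
            model=truth.model,
        )
        plate = synth.generate_drug_plate(truth, drugs=["5-FU"], noise_level=0.0, seed=0)
        resp = drugscreen.drug_response(plate)
        lo = resp.loc[resp["line_id"] == "line00", "AUCpi"].iloc[0]
        hi = resp.loc[resp["line_id"] == "line01", "AUCpi"].iloc[0]
        assert hi > lo

    def test_nonpositive_concentration_rejected(self, small_cohort):
        _, truth = small_cohort
        with pytest.raises(ConfigurationError):
            synth.generate_drug_plate(truth, conc_grid=[1.0, -0.1], seed=0)


class TestFishImages:
    def test_well_separated_nuclei_give_exact_components(self):
        lay = synth.FishLayout(n_nuclei=5, probe_coverage={"p": 0.2}, noise_sd=0.0)
        imgs = synth.generate_fish_images(lay, seed=0)
        labels, n = ndi_label(imgs.channels["dapi"] > 0.4)
        assert n == 5

    def test_truth_records_requested_coverage(self):
        lay = synth.FishLayout(n_nuclei=5, probe_coverage={"p": 0.2})
        imgs = synth.generate_fish_images(lay, seed=0)
        assert np.allclose(imgs.truth["coverage_p"], 0.2, atol=0.01)

    def test_seeded_rerun_identical(self):
        lay = synth.FishLayout(n_nuclei=6)
        a = synth.generate_fish_images(lay, seed=4)
        b = synth.generate_fish_images(lay, seed=4)
        for name in a.channels:
            assert np.array_equal(a.channels[name], b.channels[name])

    def test_overlapping_nuclei_flagged(self):
        lay = synth.FishLayout(n_nuclei=8, overlap_frac=0.25)
        imgs = synth.generate_fish_images(lay, seed=1)
        assert imgs.truth["overlapping"].sum() == 2


class TestToyFixture:
    def test_stable_and_integer(self):
        a1, meta1 = synth.toy_fixture()
        a2, _ = synth.toy_fixture()
        assert a1.shape == (6, 8)
        assert (a1.X != a2.X).nnz == 0
        x = a1.X.toarray()
        assert (x >= 0).all() and np.array_equal(x, np.rint(x))
        assert meta1["n_cells"] == 6


class TestWriteCohort:
    def test_writes_matrix_truth_and_provenance(self, tmp_path, small_cohort):
        import json

        from orgstate import io_qc

        adata, truth = small_cohort
        synth.write_cohort(adata.copy(), truth, tmp_path / "cohort", seed=7)
        back = io_qc.read_counts_10x(tmp_path / "cohort")
        assert back.shape == adata.shape
        cells = pd.read_csv(tmp_path / "cohort" / "truth_cells.csv", index_col=0)
        assert len(cells) == adata.n_obs
        prov = json.loads((tmp_path / "cohort" / "provenance.json").read_text())
        assert prov["seed"] == 7
        assert prov["config"]["n_lines"] == 2
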