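import numpy as np
import pandas as pd
import pytest

from gxetools.ammi import ammi_decompose
from gxetools.errors import SpecError
from gxetools.simulate import (
    SspSimSpec,
    TwoWaySimSpec,
    simulate_ssp,
    simulate_two_way,
    study_ssp_spec,
    study_two_way_spec,
)
from gxetools.ssp import fit_ssp_anova


def zs(v):
    v = np.asarray(v, dtype=float)
    return v - v.mean()


def unit(v):
    v = zs(v)
    return v / np.linalg.norm(v)


def two_way_spec(**kw):
    base = dict(
        mu=2.0,
        genotype_effects=zs([1.0, -0.5, 0.2, -0.7]),
        tissue_effects=zs([0.3, -0.3, 0.8, -0.4, -0.4]),
        sigma=0.0,
        replicates=2,
        seed=7,
    )
    base.update(kw)
    return TwoWaySimSpec(**base)


class TestTwoWaySpecValidation:
    def test_nonzero_sum_effects_rejected(self):
        with pytest.raises(SpecError):
            two_way_spec(genotype_effects=np.array([1.0, 0.0, 0.0, 0.0]))

    def test_nonzero_sum_score_vector_rejected(self):
        with pytest.raises(SpecError):
            two_way_spec(multiplicative_terms=[
                (1.0, np.array([1.0, 0.0, 0.0, 0.0]), unit([1, -1, 0, 0, 0]))])

    def test_increasing_singular_values_rejected(self):
        with pytest.raises(SpecError):
            two_way_spec(multiplicative_terms=[
                (1.0, unit([1, -1, 0, 0]), unit([1, -1, 0, 0, 0])),
                (2.0, unit([0, 0, 1, -1]), unit([0, 0, 1, -1, 0])),
            ])

    def test_planted_vectors_are_orthonormalized(self):
        spec = two_way_spec(multiplicative_terms=[
            (3.0, [2.0, -2.0, 1.0, -1.0], [1, -1, 0, 0, 0]),
            (1.0, [1.0, -1.0, 1.0, -1.0], [0, 0, 1, -1, 0]),
        ])
        g1 = spec.multiplicative_terms[0][1]
        g2 = spec.multiplicative_terms[1][1]
        assert np.linalg.norm(g1) == pytest.approx(1.0)
        assert np.linalg.norm(g2) == pytest.approx(1.0)
        assert abs(g1 @ g2) < 1e-10


class TestTwoWayGenerator:
    def test_additive_noise_free_has_zero_interaction(self):
        table = simulate_two_way(two_way_spec())
        res = ammi_decompose(table, "sim", n_axes=1)
        assert res.row("Interaction")["ss"] == pytest.approx(0.0, abs=1e-18)

    def test_rank_one_singular_value_recovered_exactly(self):
        spec = two_way_spec(multiplicative_terms=[
            (5.0, [3, -1, -1, -1], [4, -1, -1, -1, -1])])
        res = ammi_decompose(simulate_two_way(spec), "sim", n_axes=1)
        assert res.singular_values[0] == pytest.approx(5.0, abs=1e-8)

    def test_noisy_recovery_of_planted_gene_scores(self):
        gamma = unit([3, -1, -1, -1])
        spec = two_way_spec(
            sigma=0.1, replicates=3, seed=42,
            multiplicative_terms=[
                (4.0, gamma, unit([4, -1, -1, -1, -1])),
                (2.0, unit([0, 1, -1, 0]), unit([0, 1, -1, 0, 0])),
            ],
        )
        res = ammi_decompose(simulate_two_way(spec), "sim")
        corr = abs(np.corrcoef(res.gene_scores[:, 0], gamma)[0, 1])
        assert corr > 0.99

    def test_same_seed_bit_identical_different_seed_not(self):
        spec_a = two_way_spec(sigma=0.5)
        spec_b = two_way_spec(sigma=0.5)
        spec_c = two_way_spec(sigma=0.5, seed=8)
        ta, tb, tc = map(simulate_two_way, (spec_a, spec_b, spec_c))
        pd.testing.assert_frame_equal(ta.data, tb.data)
        assert not np.allclose(ta.data["value"], tc.data["value"])

    def test_cell_means_converge_to_expectation(self):
        spec = two_way_spec(sigma=1.0, replicates=10_000, seed=3)
        table = simulate_two_way(spec)
        df = table.data
        cell = df[(df["gene"] == "G1") & (df["tissue"] == "E1")]["value"]
        expected = spec.expectation()[0, 0]
        assert cell.mean() == pytest.approx(expected, abs=4 * 1.0 / 100)

    def test_lognormal_needs_positive_expectations(self):
        with pytest.raises(SpecError):
            simulate_two_way(two_way_spec(mu=0.0, noise="lognormal", sigma=0.1))

    def test_negative_values_warn(self):
        spec = two_way_spec(mu=0.0, sigma=1.0, seed=1)
        with pytest.warns(UserWarning, match="negative"):
            simulate_two_way(spec)

    def test_config_round_trip(self):
        spec = study_two_way_spec(seed=9)
        back = TwoWaySimSpec.from_dict(spec.to_dict())
        pd.testing.assert_frame_equal(
            simulate_two_way(spec).data, simulate_two_way(back).data)


def ssp_spec(**kw):
    base = dict(
        blocks=2,
        temperatures=["a", "b", "c"],
        tissues=["e1", "e2", "e3", "e4"],
        genes=["g1", "g2"],
        seed=5,
    )
    base.update(kw)
    return SspSimSpec(**base)


class TestSspGenerator:
    def test_all_zero_spec_gives_zero_anova(self):
        res = fit_ssp_anova(simulate_ssp(ssp_spec()))
        assert res.table["ss"].abs().max() == pytest.approx(0.0, abs=1e-20)

    def test_fixed_seed_reproduces_identical_table(self):
        a = simulate_ssp(ssp_spec(sigma_f=0.2, sigma_g=0.1, sigma_e=0.5))
        b = simulate_ssp(ssp_spec(sigma_f=0.2, sigma_g=0.1, sigma_e=0.5))
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_nonzero_sum_effect_rejected(self):
        with pytest.raises(SpecError):
            ssp_spec(temp_effects=np.array([1.0, 0.0, 0.0]))

    def test_wrong_shape_rejected(self):
        with pytest.raises(SpecError):
            ssp_spec(temp_tissue=np.zeros((3, 3)))

    def test_mainplot_error_ms_matches_expected_mean_square(self):
        """Pure main-plot noise: E[main-plot error MS] = s*g*sigma_f^2."""
        sigma_f = 0.4
        ms_values = []
        for rep in range(200):
            spec = ssp_spec(sigma_f=sigma_f, seed=1000 + rep)
            res = fit_ssp_anova(simulate_ssp(spec))
            ms_values.append(res.row("Main-plot error")["ms"])
        s, g = 4, 2
        expected = s * g * sigma_f ** 2
        # MPE MS is expected * chi2_df/df with df=(k-1)(t-1)=2 per run;
        # the mean over 200 runs has s.e. = expected * sqrt(2/df/200)
        assert np.mean(ms_values) == pytest.approx(expected, rel=0.25)

    def test_noise_lands_in_its_stratum(self):
        """Subplot-only noise leaves the sub-subplot error stratum empty."""
        res = fit_ssp_anova(simulate_ssp(ssp_spec(sigma_g=0.5)))
        assert res.row("Split-plot error")["ss"] > 0
        assert res.row("Split-split-plot error")["ss"] == pytest.approx(0.0, abs=1e-18)
        res_f = fit_ssp_anova(simulate_ssp(ssp_spec(sigma_f=0.5)))
        assert res_f.row("Main-plot error")["ss"] > 0
        assert res_f.row("Split-plot error")["ss"] == pytest.approx(0.0, abs=1e-18)

    def test_study_spec_dimensions(self):
        table = simulate_ssp(study_ssp_spec(seed=0))
        assert (len(table.temperatures), len(table.tissues),
                len(table.genes), len(table.blocks)) == (5, 10, 4, 3)
        assert table.is_balanced()

    def test_config_round_trip(self):
        spec = study_ssp_spec(seed=2)
        back = SspSimSpec.from_dict(spec.to_dict())
        pd.testing.assert_frame_equal(
            simulate_ssp(spec).data, simulate_ssp(back).data)
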