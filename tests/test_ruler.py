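"""Proteomic-ruler copy numbers and region-restricted quantification."""

import numpy as np
import pandas as pd
import pytest
from scipy.constants import Avogadro

from nmdar_stoich import ruler, synthetic
from nmdar_stoich.containers import IntensityMatrix

from conftest import GENE_MAP, group_columns


def tiny_matrix(values, mw=(1e5, 1.2e4), histone=(False, True), groups=("A", "B")):
    values = np.asarray(values, dtype=float)
    n_samples = values.shape[1]
    samples = [f"s{i}" for i in range(n_samples)]
    proteins = pd.DataFrame(
        {
            "gene": [f"g{i}" for i in range(values.shape[0])],
            "mw_da": list(mw),
            "is_histone": list(histone),
        },
        index=pd.Index([f"P{i}" for i in range(values.shape[0])], name="protein_id"),
    )
    intensities = pd.DataFrame(values, index=proteins.index, columns=samples)
    group_labels = [groups[i % len(groups)] for i in range(n_samples)]
    return IntensityMatrix(proteins, intensities, pd.Series(group_labels, index=samples))


class TestNormalizeTotal:
    def test_equal_totals_identity(self):
        m = tiny_matrix([[1e9, 1e9], [2e9, 2e9]])
        out = ruler.normalize_total(m)
        pd.testing.assert_frame_equal(out.intensities, m.intensities)

    def test_hand_arithmetic_two_by_two(self):
        # totals 1e9 and 2e9 -> both become 1.5e9; sample ratios shift by 2x
        m = tiny_matrix([[4e8, 8e8], [6e8, 12e8]])
        out = ruler.normalize_total(m)
        np.testing.assert_allclose(out.intensities.sum(), [1.5e9, 1.5e9])
        np.testing.assert_allclose(out.intensities.loc["P0"], [6e8, 6e8])

    def test_within_sample_ratios_preserved(self):
        m = tiny_matrix([[1e8, 9e8], [3e8, 3e8]])
        out = ruler.normalize_total(m)
        for s in m.samples:
            before = m.intensities[s] / m.intensities[s].sum()
            after = out.intensities[s] / out.intensities[s].sum()
            np.testing.assert_allclose(after, before)

    def test_single_sample_unchanged(self):
        m = tiny_matrix([[1e8], [2e8]])
        out = ruler.normalize_total(m)
        pd.testing.assert_frame_equal(out.intensities, m.intensities)

    def test_zero_total_names_sample(self):
        m = tiny_matrix([[0.0, 1e8], [0.0, 2e8]])
        with pytest.raises(ValueError, match="s0"):
            ruler.normalize_total(m)


class TestCopiesPerCell:
    def test_hand_arithmetic_oracle(self):
        # I=1e7, MW=1e5 Da, histone I=1e9, m_DNA=5.5 pg
        m = tiny_matrix([[1e7, 1e7], [1e9, 1e9]])
        out = ruler.copies_per_cell(m, dna_mass_per_cell=5.5)
        expected = 1e7 * Avogadro * 5.5e-12 / (1e5 * 1e9)
        np.testing.assert_allclose(out.copies.loc["P0"], expected, rtol=1e-12)
        assert expected == pytest.approx(3.31e5, rel=0.01)

    def test_scale_invariance_per_sample(self):
        m = tiny_matrix([[1e7, 1e7], [1e9, 1e9]])
        scaled = m.with_intensities(m.intensities * [10.0, 1.0])
        a = ruler.copies_per_cell(m).copies
        b = ruler.copies_per_cell(scaled).copies
        pd.testing.assert_frame_equal(a, b)

    def test_missing_intensity_gives_missing_copies(self):
        m = tiny_matrix([[np.nan, 1e7], [1e9, 1e9]])
        out = ruler.copies_per_cell(m)
        assert np.isnan(out.copies.loc["P0", "s0"])
        assert np.isfinite(out.copies.loc["P0", "s1"])

    def test_no_histones_rejected(self):
        m = tiny_matrix([[1e7, 1e7], [1e9, 1e9]], histone=(False, False))
        with pytest.raises(ValueError, match="histone"):
            ruler.copies_per_cell(m)

    def test_bad_dna_mass_rejected(self):
        m = tiny_matrix([[1e7, 1e7], [1e9, 1e9]])
        with pytest.raises(ValueError, match="dna_mass_per_cell"):
            ruler.copies_per_cell(m, dna_mass_per_cell=-1)


class TestSyntheticRoundTrip:
    def test_zero_noise_recovers_configured_copies(self, noiseless_proteome, noiseless_config):
        matrix, _, truth = noiseless_proteome
        cn = ruler.copies_per_cell(
            ruler.normalize_total(matrix), noiseless_config.dna_mass_per_cell
        )
        for sample in matrix.samples:
            group = matrix.sample_groups[sample]
            rel_err = np.abs(cn.copies[sample] / truth.copies[group] - 1.0)
            assert rel_err.max() < 1e-9

    def test_relative_subunit_cn_recovers_ratios(self, noiseless_proteome, noiseless_config):
        matrix, _, _ = noiseless_proteome
        cn = ruler.copies_per_cell(ruler.normalize_total(matrix))
        cns = {s.group: s for s in ruler.relative_subunit_cn(cn, GENE_MAP, "WT")}
        assert cns["WT"].cn1 == pytest.approx(1.0, abs=1e-12)
        assert cns["WT"].cn2a == pytest.approx(0.79, rel=1e-9)
        assert cns["WT"].cn2b == pytest.approx(1.02, rel=1e-9)
        assert cns["HET"].cn1 == pytest.approx(0.91, rel=1e-9)

    def test_noisy_ratios_unbiased_across_replicates(self):
        """With 10% CV and 5v5 samples the recovered subunit ratios are
        unbiased: the mean over 100 seeded replicates sits within 3
        standard errors of the configured ratios."""
        recovered = []
        for seed in range(100):
            cfg = synthetic.ProteomeSimConfig(
                noise_cv=0.1, missing_rate=0.0, n_background_proteins=60, seed=seed
            )
            matrix, _, _ = synthetic.generate_proteome(cfg)
            cn = ruler.copies_per_cell(ruler.normalize_total(matrix))
            cns = {s.group: s for s in ruler.relative_subunit_cn(cn, GENE_MAP, "WT")}
            recovered.append((cns["WT"].cn2a, cns["WT"].cn2b, cns["HET"].cn1))
        recovered = np.array(recovered)
        for k, target in enumerate((0.79, 1.02, 0.91)):
            mean = recovered[:, k].mean()
            se = recovered[:, k].std(ddof=1) / np.sqrt(len(recovered))
            assert abs(mean - target) < 3 * se + 1e-3

    def test_missing_subunit_gene_rejected(self, noiseless_proteome):
        matrix, _, _ = noiseless_proteome
        cn = ruler.copies_per_cell(matrix)
        with pytest.raises(ValueError, match="Grin9"):
            ruler.relative_subunit_cn(
                cn, {"Grin1": "GluN1", "Grin2a": "GluN2A", "Grin9": "GluN2B"}, "WT"
            )


class TestRegionAbundance:
    def test_all_before_boundary(self):
        peps = pd.DataFrame(
            {"start_res": [1, 50], "end_res": [20, 90], "intensity": [3.0, 4.0]}
        )
        ra = ruler.region_abundance(peps, 768)
        assert ra.abundance_ctd == 0.0
        assert ra.abundance_no_ctd == 7.0

    def test_hand_sum_with_straddler_excluded(self):
        peps = pd.DataFrame(
            {
                "start_res": [80, 650, 760, 800],
                "end_res": [100, 700, 780, 815],
                "intensity": [5.0, 7.0, 99.0, 4.0],
            }
        )
        ra = ruler.region_abundance(peps, 768)
        assert (ra.abundance_no_ctd, ra.abundance_ctd) == (12.0, 4.0)

    def test_reversed_coordinates_rejected(self):
        peps = pd.DataFrame({"start_res": [100], "end_res": [50], "intensity": [1.0]})
        with pytest.raises(ValueError, match="end_res < start_res"):
            ruler.region_abundance(peps, 768)


class TestTruncatedFraction:
    def test_equal_ratios_give_zero(self):
        a = ruler.RegionAbundance("g", 10.0, 4.0, 768)
        assert ruler.truncated_fraction(a, a) == 0.0

    def test_halved_ctd_ratio_gives_half(self):
        control = ruler.RegionAbundance("g", 10.0, 4.0, 768)
        sample = ruler.RegionAbundance("g", 10.0, 2.0, 768)
        assert ruler.truncated_fraction(sample, control) == pytest.approx(0.5)

    def test_fully_truncated_limit(self):
        control = ruler.RegionAbundance("g", 10.0, 4.0, 768)
        sample = ruler.RegionAbundance("g", 10.0, 0.0, 768)
        assert ruler.truncated_fraction(sample, control) == 1.0

    def test_simulated_heterozygote_round_trip(self):
        cfg = synthetic.ProteomeSimConfig(
            noise_cv=0.0, missing_rate=0.0, truncated_fraction=0.5,
            n_background_proteins=10, seed=4,
        )
        _, peptides, _ = synthetic.generate_proteome(cfg)
        g1, g2 = group_columns(cfg)
        control = ruler.region_abundance(peptides, 768, intensity_cols=g1)
        sample = ruler.region_abundance(peptides, 768, intensity_cols=g2)
        assert ruler.truncated_fraction(sample, control) == pytest.approx(0.5, abs=1e-9)
        assert sample.ctd_ratio == pytest.approx(0.5 * control.ctd_ratio, rel=1e-9)
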