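"""Per-locus diversity indices: closed forms, enumeration oracles, panel."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from hexassr.genotypes import (
    AlleleFrequencySpectrum,
    EstimationMode,
    LocusDefinition,
    MarkerClass,
    allele_frequencies,
)
from hexassr.locus_stats import (
    LocusStatistics,
    allelic_richness,
    effective_alleles,
    evenness,
    expected_heterozygosity,
    gametic_heterozygosity,
    gene_diversity,
    locus_panel,
    observed_heterozygosity,
    panel_to_frame,
    r_ratio_test,
    simpson_diversity,
)
from tests.conftest import make_matrix


def spectrum(counts: dict[int, float], mode=EstimationMode.ONE_PER_PHENOTYPE):
    return AlleleFrequencySpectrum(
        locus="L", counts=counts, n_copies=sum(counts.values()), estimation_mode=mode
    )


class TestFrequencyIndices:
    def test_simpson_monomorphic_is_zero(self):
        assert simpson_diversity(spectrum({1: 5})) == 0.0

    @pytest.mark.parametrize("m", [2, 5, 26])
    def test_simpson_uniform_closed_form(self, m):
        spec = spectrum({i: 3 for i in range(m)})
        assert simpson_diversity(spec) == pytest.approx(1 - 1 / m)
        assert effective_alleles(spec) == pytest.approx(m)
        assert evenness(spec) == pytest.approx(1.0)

    def test_simpson_hand_value(self):
        assert simpson_diversity(spectrum({1: 5, 2: 3, 3: 2})) == pytest.approx(0.62)

    def test_effective_alleles_hand_value(self):
        assert effective_alleles(spectrum({1: 5, 2: 3, 3: 2})) == pytest.approx(1 / 0.38)

    def test_en_relates_to_simpson(self):
        spec = spectrum({1: 7, 2: 2, 3: 1, 4: 4})
        assert 1 - 1 / effective_alleles(spec) == pytest.approx(simpson_diversity(spec))

    def test_evenness_hand_value(self):
        spec = spectrum({1: 9, 2: 1})
        inv_lambda = 1 / 0.82
        shannon = -0.9 * math.log(0.9) - 0.1 * math.log(0.1)
        expected = (inv_lambda - 1) / (math.exp(shannon) - 1)
        assert evenness(spec) == pytest.approx(expected)
        assert expected == pytest.approx(0.5714, abs=5e-4)

    def test_evenness_monomorphic_is_nan(self):
        assert math.isnan(evenness(spectrum({1: 4})))

    def test_merging_alleles_never_increases_effective_number(self):
        spec = spectrum({1: 5, 2: 3, 3: 2})
        merged = spectrum({1: 8, 3: 2})
        assert effective_alleles(merged) <= effective_alleles(spec)

    def test_gene_diversity_hand_value(self):
        assert gene_diversity(spectrum({1: 2, 2: 2})) == pytest.approx(2 / 3)

    def test_gene_diversity_dominates_simpson(self):
        spec = spectrum({1: 6, 2: 5, 3: 1})
        assert gene_diversity(spec) >= simpson_diversity(spec)


def rarefaction_oracle(counts: list[int], k: int) -> float:
    """Mean distinct-allele count over all k-subsets of the gene copies."""
    copies = [a for a, c in enumerate(counts) for _ in range(c)]
    subsets = list(itertools.combinations(range(len(copies)), k))
    total = sum(len({copies[i] for i in sub}) for sub in subsets)
    return total / len(subsets)


class TestAllelicRichness:
    def test_k_equals_n_returns_allele_count(self):
        spec = spectrum({1: 3, 2: 5, 3: 1})
        assert allelic_richness(spec, 9) == pytest.approx(3.0)

    def test_k_one_returns_one(self):
        assert allelic_richness(spectrum({1: 3, 2: 5}), 1) == pytest.approx(1.0)

    def test_hand_enumeration(self):
        assert allelic_richness(spectrum({1: 3, 2: 1}), 2) == pytest.approx(1.5)

    @pytest.mark.parametrize(
        "counts", [[3, 1], [2, 2, 2], [5, 3, 1], [4, 4, 2, 1], [7, 2, 1, 1, 1]]
    )
    def test_matches_exhaustive_subset_oracle(self, counts):
        spec = spectrum({i: c for i, c in enumerate(counts)})
        n = sum(counts)
        for k in range(1, n + 1):
            assert allelic_richness(spec, k) == pytest.approx(
                rarefaction_oracle(counts, k), abs=1e-12
            )

    def test_non_decreasing_in_k(self):
        spec = spectrum({1: 6, 2: 3, 3: 2, 4: 1})
        values = [allelic_richness(spec, k) for k in range(1, 13)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_k_out_of_range_errors(self):
        with pytest.raises(ValueError):
            allelic_richness(spectrum({1: 2, 2: 2}), 5)


class TestHeterozygosities:
    def test_observed_heterozygosity_counts_multiallelic_calls(self):
        gm = make_matrix({"LOC1": [(100,), (100, 103), (103, 106), (100,), None]})
        assert observed_heterozygosity(gm, "LOC1") == pytest.approx(2 / 4)

    def test_observed_extremes(self):
        assert observed_heterozygosity(make_matrix({"LOC1": [(1,), (2,)]}), "LOC1") == 0.0
        assert (
            observed_heterozygosity(make_matrix({"LOC1": [(1, 4), (2, 5)]}), "LOC1") == 1.0
        )

    def test_gh_dosage_completion_enumeration(self):
        """Hexaploid dosage (4,2): 1 - [C(4,2)+C(2,2)]/C(6,2) = 8/15."""
        from hexassr.locus_stats import _gh_for_dosage

        assert _gh_for_dosage((4, 2), 6) == pytest.approx(1 - 7 / 15)
        # brute-force over unordered pairs of copies
        copies = [1, 1, 1, 1, 2, 2]
        pairs = list(itertools.combinations(range(6), 2))
        differ = sum(1 for i, j in pairs if copies[i] != copies[j]) / len(pairs)
        assert _gh_for_dosage((4, 2), 6) == pytest.approx(differ)

    def test_gh_extremes(self):
        hom = make_matrix({"LOC1": [(100,)]})
        assert gametic_heterozygosity(hom, "LOC1", EstimationMode.ONE_PER_PHENOTYPE) == 0.0
        full = make_matrix({"LOC1": [(100, 103, 106, 109, 112, 115)]})
        for mode in EstimationMode:
            assert gametic_heterozygosity(full, "LOC1", mode) == pytest.approx(1.0)

    def test_gh_equal_dosage_shortcut(self):
        # 3 observed alleles at equal dosage 2 each: 1 - 3*C(2,2)/C(6,2)
        gm = make_matrix({"LOC1": [(100, 103, 106)]})
        gh = gametic_heterozygosity(gm, "LOC1", EstimationMode.ONE_PER_PHENOTYPE)
        assert gh == pytest.approx(1 - 3 / 15)

    def test_hs_diploid_fully_observed_equals_direct_gene_diversity(self):
        loci = [LocusDefinition("LOC1", 2, MarkerClass.GENOMIC, ploidy=2)]
        gm = make_matrix({"LOC1": [(100, 102), (100,), (102, 104)]}, loci=loci)
        hs = expected_heterozygosity(gm, "LOC1")
        direct = spectrum({100: 3, 102: 2, 104: 1})
        assert hs == pytest.approx(gene_diversity(direct), abs=1e-9)

    def test_hs_monomorphic_is_zero(self):
        gm = make_matrix({"LOC1": [(100,), (100,)]})
        assert expected_heterozygosity(gm, "LOC1") == pytest.approx(0.0, abs=1e-12)


def _stats_row(locus: str, r: float) -> LocusStatistics:
    return LocusStatistics(
        locus=locus, an=10, simpson_1mD=0.5, ev=0.5, ar=5.0, gd=0.5,
        ho=0.5, gh=0.5, hs=0.5, en=5.0, r=r,
    )


class TestRRatioTest:
    def test_equal_ratios_give_null_result(self):
        panel = [_stats_row(f"L{i}", 0.4) for i in range(4)]
        out = r_ratio_test(panel)
        assert all(row.z == 0.0 and row.p == 1.0 for row in out)

    def test_lowest_ratio_has_most_negative_z(self):
        rs = [0.43, 0.21, 0.35, 0.52, 0.26]
        out = r_ratio_test([_stats_row(f"L{i}", r) for i, r in enumerate(rs)])
        zs = {row.r: row.z for row in out}
        assert min(zs, key=zs.get) == 0.21
        # hand-computed standardization
        mean = sum(rs) / len(rs)
        sd = math.sqrt(sum((x - mean) ** 2 for x in rs) / (len(rs) - 1))
        assert zs[0.21] == pytest.approx((0.21 - mean) / sd)

    def test_negating_deviations_negates_z(self):
        rs = [0.3, 0.4, 0.5]
        mean = sum(rs) / len(rs)
        flipped = [2 * mean - r for r in rs]
        z1 = [row.z for row in r_ratio_test([_stats_row(f"A{i}", r) for i, r in enumerate(rs)])]
        z2 = [row.z for row in r_ratio_test([_stats_row(f"B{i}", r) for i, r in enumerate(flipped)])]
        assert z1 == pytest.approx([-z for z in z2])

    def test_too_few_loci_error(self):
        with pytest.raises(ValueError):
            r_ratio_test([_stats_row("L1", 0.3), _stats_row("L2", 0.4)])


class TestLocusPanel:
    def test_single_locus_mean_row_equals_locus_row(self):
        gm = make_matrix({"LOC1": [(100, 103), (100,), (103, 106)]})
        frame = panel_to_frame(locus_panel(gm), mean_row=True)
        locus_row = frame.iloc[0, 1:11].astype(float).to_numpy()
        mean_row = frame.iloc[-1, 1:11].astype(float).to_numpy()
        assert np.allclose(locus_row, mean_row, equal_nan=True)

    def test_panel_on_synthetic_data_respects_invariants(self):
        from hexassr.simulate import SimulationConfig, simulate

        gm, _ = simulate(SimulationConfig(n_varieties=20, seed=11))
        for cls in ("EST", "genomic"):
            panel = locus_panel(gm, cls)
            for row in panel:
                assert 1.0 <= row.en <= row.an + 1e-9
                assert row.ar <= row.an + 1e-9
                assert row.r == pytest.approx(row.en / row.an)
                for frac in (row.simpson_1mD, row.gd, row.ho, row.gh, row.hs):
                    assert 0.0 <= frac <= 1.0 + 1e-9
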