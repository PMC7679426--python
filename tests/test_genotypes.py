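"""Genotype IO, allele binning and dosage-blind frequency estimation."""

from __future__ import annotations

import itertools
import math

import pytest
from hypothesis import given, settings, strategies as st

from hexassr.genotypes import (
    AllelePhenotype,
    EstimationMode,
    GenotypeMatrix,
    LocusDefinition,
    MarkerClass,
    allele_frequencies,
    bin_alleles,
    read_genotypes,
    write_genotypes,
)
from tests.conftest import make_matrix


@pytest.fixture
def csv_pair(tmp_path):
    loci = tmp_path / "loci.csv"
    loci.write_text(
        "name,motif_length,marker_class,ploidy\n"
        "LOC1,3,EST,6\n"
        "LOC2,2,genomic,6\n"
    )
    geno = tmp_path / "geno.csv"
    geno.write_text(
        "sample,LOC1,LOC2\n"
        "s1,143/149/155,200/202\n"
        "s2,,204\n"
        "s3,143/143/149,200/206/208\n"
    )
    return geno, loci


class TestReadWrite:
    def test_parses_cells_and_missing(self, csv_pair):
        gm = read_genotypes(*csv_pair)
        assert gm.sample_ids == ["s1", "s2", "s3"]
        assert gm.calls[0][0].alleles == (143, 149, 155)
        assert gm.calls[1][0].missing
        assert gm.calls[1][1].alleles == (204,)

    def test_duplicate_alleles_collapse_with_warning(self, csv_pair, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="hexassr"):
            gm = read_genotypes(*csv_pair)
        assert gm.calls[2][0].alleles == (143, 149)
        assert any("collapsed" in rec.message for rec in caplog.records)

    def test_round_trip_identity(self, csv_pair, tmp_path):
        gm = read_genotypes(*csv_pair)
        out = tmp_path / "out.csv"
        write_genotypes(gm, out)
        gm2 = read_genotypes(out, csv_pair[1])
        assert gm2.sample_ids == gm.sample_ids
        assert gm2.calls == gm.calls
        # byte-exact on the second round trip
        out2 = tmp_path / "out2.csv"
        write_genotypes(gm2, out2)
        assert out.read_bytes() == out2.read_bytes()

    def test_empty_sample_list_writes_header_only(self, csv_pair, tmp_path):
        gm = read_genotypes(*csv_pair)
        empty = GenotypeMatrix(sample_ids=[], loci=gm.loci, calls=[])
        out = tmp_path / "empty.csv"
        write_genotypes(empty, out)
        assert out.read_text().strip() == "sample,LOC1,LOC2"

    @pytest.mark.parametrize(
        "body,match",
        [
            ("sample,NOPE\ns1,100\n", "unknown locus"),
            ("sample,LOC1\ns1,1/4/7/10/13/16/19\n", "exceed ploidy"),
            ("sample,LOC1\ns1,14x\n", "non-integer"),
        ],
    )
    def test_malformed_inputs_error(self, csv_pair, tmp_path, body, match):
        bad = tmp_path / "bad.csv"
        bad.write_text(body)
        with pytest.raises(ValueError, match=match):
            read_genotypes(bad, csv_pair[1])


class TestBinAlleles:
    def test_on_grid_sizes_map_to_themselves(self, hexaploid_locus):
        raws = [143.0, 146.0, 149.0]
        assert bin_alleles(raws, hexaploid_locus) == {r: int(r) for r in raws}

    def test_fractional_sizes_snap_to_best_grid(self, hexaploid_locus):
        mapping = bin_alleles([143.4, 146.6, 149.5], hexaploid_locus)
        assert mapping == {143.4: 143, 146.6: 146, 149.5: 149}

    def test_best_grid_verified_by_offset_scan(self, hexaploid_locus):
        """Independent 0.1-bp offset scan confirms the chosen integer grid
        minimizes the mean absolute displacement."""
        raws = [143.4, 146.6, 149.5]
        mapping = bin_alleles(raws, hexaploid_locus)
        achieved = sum(abs(r - b) for r, b in mapping.items()) / len(raws)
        motif = hexaploid_locus.motif_length
        for step in range(motif * 10):
            offset = step * 0.1
            binned = [offset + motif * round((r - offset) / motif) for r in raws]
            if all(abs(b - round(b)) < 1e-9 for b in binned) and all(
                abs(r - b) < 1.0 for r, b in zip(raws, binned)
            ):
                mean_disp = sum(abs(r - b) for r, b in zip(raws, binned)) / len(raws)
                assert achieved <= mean_disp + 1e-12

    def test_incompatible_sizes_error_lists_offender(self, hexaploid_locus):
        with pytest.raises(ValueError, match="144.6"):
            bin_alleles([143.0, 144.6], hexaploid_locus)

    @given(
        st.lists(st.integers(40, 90), min_size=1, max_size=8, unique=True),
        st.floats(-0.4, 0.4),
    )
    @settings(max_examples=50, deadline=None)
    def test_order_invariant_and_idempotent(self, repeat_counts, jitter):
        locus = LocusDefinition("L", motif_length=3, marker_class=MarkerClass.EST)
        raws = [2 + 3 * k + jitter for k in repeat_counts]
        forward = bin_alleles(raws, locus)
        backward = bin_alleles(list(reversed(raws)), locus)
        assert forward == backward
        binned = sorted(set(forward.values()))
        again = bin_alleles([float(b) for b in binned], locus)
        assert again == {float(b): b for b in binned}


def _em_loglik_two_alleles(p_a: float, phenos: list[tuple[str, ...]], ploidy: int = 6) -> float:
    """Brute-force log-likelihood for a two-allele locus: sum over all
    dosage completions of each phenotype."""
    p_b = 1.0 - p_a
    total = 0.0
    for pheno in phenos:
        if pheno == ("A",):
            lik = p_a**ploidy
        elif pheno == ("B",):
            lik = p_b**ploidy
        else:  # ("A", "B")
            lik = sum(
                math.comb(ploidy, d) * p_a**d * p_b ** (ploidy - d)
                for d in range(1, ploidy)
            )
        total += math.log(max(lik, 1e-300))
    return total


class TestAlleleFrequencies:
    def test_monomorphic_fixed_point(self):
        gm = make_matrix({"LOC1": [(100,), (100,)]})
        one = allele_frequencies(gm, "LOC1", EstimationMode.ONE_PER_PHENOTYPE)
        assert one.counts == {100: 2} and one.n_copies == 2
        em = allele_frequencies(gm, "LOC1", EstimationMode.EM_DOSAGE)
        assert em.n_copies == 12
        assert em.frequencies[100] == pytest.approx(1.0)

    def test_diploid_full_dosage_equals_direct_counting(self):
        loci = [LocusDefinition("LOC1", 2, MarkerClass.GENOMIC, ploidy=2)]
        gm = make_matrix(
            {"LOC1": [(100, 102), (100,), (102, 104), (104,)]}, loci=loci
        )
        em = allele_frequencies(gm, "LOC1", EstimationMode.EM_DOSAGE)
        # known dosages: het = 1+1, hom = 2 copies
        assert em.frequencies[100] == pytest.approx(3 / 8, abs=1e-9)
        assert em.frequencies[102] == pytest.approx(2 / 8, abs=1e-9)
        assert em.frequencies[104] == pytest.approx(3 / 8, abs=1e-9)

    def test_em_matches_grid_search_likelihood_maximum(self):
        gm = make_matrix({"LOC1": [(100, 103), (100,), (100, 103)]})
        em = allele_frequencies(gm, "LOC1", EstimationMode.EM_DOSAGE)
        phenos = [("A", "B"), ("A",), ("A", "B")]
        grid = [i / 1000 for i in range(1, 1000)]
        best = max(grid, key=lambda p: _em_loglik_two_alleles(p, phenos))
        assert em.frequencies[100] == pytest.approx(best, abs=2e-3)

    def test_em_is_a_fixed_point(self):
        from hexassr.genotypes import dosage_posterior

        gm = make_matrix({"LOC1": [(100, 103), (100,), (100, 103, 106), (103, 106)]})
        em = allele_frequencies(gm, "LOC1", EstimationMode.EM_DOSAGE)
        freqs = em.frequencies
        observed = [p for p in gm.column("LOC1") if not p.missing]
        expected = {a: 0.0 for a in freqs}
        for p in observed:
            for d, w in dosage_posterior(p, freqs, 6):
                for a, di in zip(p.alleles, d):
                    expected[a] += w * di
        total = 6 * len(observed)
        for a in freqs:
            assert expected[a] / total == pytest.approx(freqs[a], abs=1e-9)

    def test_frequencies_sum_to_one(self):
        gm = make_matrix({"LOC1": [(100, 103), (103, 106, 109), (100,), None]})
        for mode in EstimationMode:
            spec = allele_frequencies(gm, "LOC1", mode)
            assert sum(spec.frequencies.values()) == pytest.approx(1.0, abs=1e-9)

    def test_extreme_phenotypes_rank_alleles_identically(self):
        # fully-distinct phenotypes carry no dosage information, so EM and
        # one-per-phenotype counting must rank alleles the same way
        gm = make_matrix(
            {
                "LOC1": [
                    (100, 103, 106, 109, 112, 115),
                    (100, 103, 106, 109, 112, 118),
                    (100, 103, 106, 109, 112, 115),
                ]
            }
        )
        one = allele_frequencies(gm, "LOC1", EstimationMode.ONE_PER_PHENOTYPE)
        em = allele_frequencies(gm, "LOC1", EstimationMode.EM_DOSAGE)
        rank = lambda spec: sorted(spec.counts, key=lambda a: (-spec.counts[a], a))
        assert rank(one) == rank(em)

    def test_all_missing_errors(self):
        gm = make_matrix({"LOC1": [None, None]})
        with pytest.raises(ValueError, match="missing"):
            allele_frequencies(gm, "LOC1", EstimationMode.ONE_PER_PHENOTYPE)
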