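import io
import math

import numpy as np
import pytest

from epiland.landscape_io import (
    LandscapeDescriptor,
    LandscapeRegistry,
    average_replicates,
    bits_to_index,
    builtin_registry,
    census_totals,
    derive_significance_threshold,
    index_to_bits,
    normalize_and_log,
    parse_landscape,
    pre_exponentiate,
    registry_census,
    write_landscape_csv,
)
from epiland.synthetic import SyntheticSpec, generate

from conftest import landscape_csv_text


class TestGenotypeEncoding:
    def test_roundtrip(self):
        for n in (2, 5, 7):
            for g in range(2 ** n):
                assert bits_to_index(index_to_bits(g, n)) == g

    def test_bit_order_follows_header(self):
        # leftmost character is the first declared locus
        assert bits_to_index("10") == 1
        assert bits_to_index("01") == 2

    @pytest.mark.parametrize("bad", ["", "0a", "012"])
    def test_malformed(self, bad):
        with pytest.raises(ValueError):
            bits_to_index(bad)


class TestParsing:
    def test_minimal_complete_landscape(self):
        text = landscape_csv_text({"00": [1.0], "10": [2.0], "01": [5.0], "11": [30.0]})
        table = parse_landscape(io.StringIO(text))
        assert table.n == 2
        assert table.replicates[bits_to_index("01")] == (5.0,)

    def test_missing_genotype_rejected(self):
        text = landscape_csv_text({"00": [1.0], "10": [2.0], "01": [5.0]})
        with pytest.raises(ValueError, match="incomplete landscape"):
            parse_landscape(io.StringIO(text))

    def test_duplicate_genotype_rejected(self):
        text = landscape_csv_text({"00": [1.0], "10": [2.0], "01": [5.0], "11": [30.0]})
        text += "10,2.5\n"
        with pytest.raises(ValueError, match="duplicate"):
            parse_landscape(io.StringIO(text))

    def test_non_numeric_rejected(self):
        text = landscape_csv_text({"00": [1.0], "10": ["oops"], "01": [5.0], "11": [30.0]})
        with pytest.raises(ValueError):
            parse_landscape(io.StringIO(text))

    def test_write_read_roundtrip(self, tmp_path):
        table, _ = generate(SyntheticSpec(n=3, noise_sd=0.1, replicates=2), seed=5)
        path = tmp_path / "ls.csv"
        write_landscape_csv(table, path)
        back = parse_landscape(path)
        for a, b in zip(table.replicates, back.replicates):
            assert a == pytest.approx(b)


class TestPreprocessing:
    def test_pre_exponentiate_values(self):
        text = landscape_csv_text({"00": [0.0], "10": [1.0], "01": [-0.3], "11": [2.0]})
        table = pre_exponentiate(parse_landscape(io.StringIO(text)))
        assert table.replicates[0][0] == pytest.approx(1.0)
        assert table.replicates[bits_to_index("10")][0] == pytest.approx(10.0)
        assert table.replicates[bits_to_index("01")][0] == pytest.approx(10 ** -0.3)
        with pytest.raises(ValueError, match="already"):
            pre_exponentiate(table)

    def test_average_replicates_is_raw_scale_mean(self):
        text = landscape_csv_text(
            {"00": [2.0, 4.0], "10": [5.0], "01": [1.0, 2.0, 3.0], "11": [7.0]}
        )
        table = average_replicates(parse_landscape(io.StringIO(text)))
        assert table.replicates[0] == (3.0,)
        assert table.replicates[bits_to_index("10")] == (5.0,)
        assert table.replicates[bits_to_index("01")] == (2.0,)

    def test_normalize_and_log(self):
        text = landscape_csv_text({"00": [5.0], "10": [10.0], "01": [5.0], "11": [2.5]})
        ls = normalize_and_log(parse_landscape(io.StringIO(text)))
        assert ls.value("00") == 0.0
        assert ls.value("10") == pytest.approx(math.log10(2))
        assert ls.value("11") == pytest.approx(-math.log10(2))

    def test_non_positive_mean_rejected(self):
        text = landscape_csv_text({"00": [5.0], "10": [0.0], "01": [5.0], "11": [2.5]})
        with pytest.raises(ValueError, match="log undefined"):
            normalize_and_log(parse_landscape(io.StringIO(text)))

    def test_normalization_scale_invariant(self):
        base = {"00": [5.0], "10": [10.0], "01": [4.0], "11": [2.5]}
        ls1 = normalize_and_log(parse_landscape(io.StringIO(landscape_csv_text(base))))
        scaled = {k: [v[0] * 37.5] for k, v in base.items()}
        ls2 = normalize_and_log(parse_landscape(io.StringIO(landscape_csv_text(scaled))))
        assert np.allclose(ls1.values, ls2.values)


class TestSignificanceThreshold:
    def test_identical_replicates_give_fold_one(self):
        text = landscape_csv_text(
            {"00": [2.0, 2.0], "10": [3.0, 3.0], "01": [1.0, 1.0], "11": [4.0, 4.0]}
        )
        summary = derive_significance_threshold([parse_landscape(io.StringIO(text))])
        assert summary.median_log10 == 0.0
        assert summary.median_fold == 1.0

    def test_no_replicated_genotypes_rejected(self):
        text = landscape_csv_text({"00": [2.0], "10": [3.0], "01": [1.0], "11": [4.0]})
        with pytest.raises(ValueError, match="replicates"):
            derive_significance_threshold([parse_landscape(io.StringIO(text))])

    def test_median_matches_monte_carlo_oracle(self):
        # Pipeline median 2 SD over many synthetic replicate pairs must match
        # an independent simulation of the same statistic (for pairs the
        # median of 2*SD is 2*sigma*median|N(0,1)| ~ 1.349 sigma, not 2 sigma).
        sigma = 0.1
        tables = [
            generate(SyntheticSpec(n=3, noise_sd=sigma, replicates=2), seed=s)[0]
            for s in range(200)
        ]
        summary = derive_significance_threshold(tables)
        rng = np.random.default_rng(12345)
        draws = rng.normal(0.0, sigma, size=(10_000, 2))
        oracle = np.median(2.0 * np.std(draws, axis=1, ddof=1))
        assert summary.median_log10 == pytest.approx(oracle, rel=0.05)


class TestCensus:
    def test_two_locus_enumeration(self):
        reg = LandscapeRegistry(
            (LandscapeDescriptor(enzyme="E", condition="c", n_loci=2),)
        )
        tot = census_totals(reg)
        assert tot["genotype_phenotype_points"] == 4
        assert tot["positions"] == 2
        assert tot["smes"] == 4
        assert tot["pairwise_combinations"] == 1

    def test_four_locus_single_background_flag(self):
        reg = LandscapeRegistry(
            (LandscapeDescriptor(enzyme="E", condition="c", n_loci=4),)
        )
        tot = census_totals(reg)
        assert tot["fourway_combinations"] == 1
        assert tot["fourway_single_background"] == 1
        assert tot["fourway_viable"] == 0

    def test_closed_forms_match_brute_force(self):
        # census formulas vs explicit enumeration over the genotype lattice
        from itertools import combinations

        for n in (3, 5, 6):
            reg = LandscapeRegistry(
                (LandscapeDescriptor(enzyme="E", condition="c", n_loci=n),)
            )
            df = registry_census(reg)
            row = df.iloc[0]
            smes = sum(
                1 for locus in range(n) for bg in range(2 ** n)
                if not (bg >> locus) & 1
            )
            assert row["smes"] == smes
            for k in (2, 3, 4):
                if k > n:
                    continue
                ee_vals = sum(
                    1
                    for loci in combinations(range(n), k)
                    for bg in range(2 ** n)
                    if all(not (bg >> l) & 1 for l in loci)
                )
                assert row[f"ee_values_order{k}"] == ee_vals
            transitions = sum(
                len(loci)
                for k in range(3, n + 1)
                for loci in combinations(range(n), k)
            )
            assert row["transitions"] == transitions

    def test_builtin_registry_shape(self):
        reg = builtin_registry()
        assert len(reg) == 41
        assert len(reg.subset("structural")) == 15
        assert len(reg.subset("adaptive")) == 11
        assert len(reg.subset("reduced")) == 11
        assert sum(e.pre_exponentiate for e in reg.entries) == 11
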