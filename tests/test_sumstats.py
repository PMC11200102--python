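"""I/O, allele harmonization and proxy substitution."""

import numpy as np
import pandas as pd
import pytest

from coagmr.sumstats import (
    FormatError,
    GeneRegion,
    HarmonizedPair,
    VariantLookupError,
    find_proxy,
    harmonize,
    read_ld_matrix,
    read_sumstats,
    write_ld_matrix,
    write_sumstats,
)
from conftest import make_ld, make_sumstats

HEADER = "variant_id\tchromosome\tposition\teffect_allele\tother_allele\teaf\tbeta\tstandard_error\tp_value\tn"


def _write(tmp_path, lines, name="ss.tsv"):
    p = tmp_path / name
    p.write_text("\n".join(lines) + "\n")
    return p


class TestReadSumstats:
    def test_well_formed_roundtrip(self, tmp_path):
        p = _write(
            tmp_path,
            [
                HEADER,
                "rs1\t1\t100\tA\tG\t0.2\t0.5\t0.05\t1e-10\t10000",
                "rs2\t1\t200\tC\tT\t0.4\t-0.1\t0.04\t0.01\t10000",
                "rs3\t1\t300\tG\tA\t0.1\t0.0\t0.08\t1.0\t10000",
            ],
        )
        sset, audit = read_sumstats(p, "quantitative")
        assert len(sset) == 3 and audit.n_dropped == 0
        out = tmp_path / "round.tsv"
        write_sumstats(sset, out)
        again, _ = read_sumstats(out, "quantitative")
        pd.testing.assert_frame_equal(sset.df, again.df)

    def test_invalid_rows_dropped_and_audited(self, tmp_path):
        p = _write(
            tmp_path,
            [
                HEADER,
                "rs1\t1\t100\tA\tG\t0.2\t0.5\t0\t1e-10\t10000",      # se = 0
                "rs2\t1\t200\tC\tC\t0.4\t0.1\t0.04\t0.01\t10000",    # identical alleles
                "rs3\t1\t300\tG\tA\t1.4\t0.1\t0.04\t0.01\t10000",    # eaf out of range
                "rs4\t1\t400\tG\tA\t0.1\t0.1\t0.04\t0.01\t10000",
            ],
        )
        sset, audit = read_sumstats(p, "quantitative")
        assert len(sset) == 1 and audit.n_dropped == 3
        assert audit.dropped_reasons["nonpositive_se"] == 1

    def test_duplicate_keeps_smaller_pvalue(self, tmp_path):
        p = _write(
            tmp_path,
            [
                HEADER,
                "rs1\t1\t100\tA\tG\t0.2\t0.5\t0.05\t1e-4\t10000",
                "rs1\t1\t100\tA\tG\t0.2\t0.6\t0.05\t1e-8\t10000",
            ],
        )
        sset, audit = read_sumstats(p, "quantitative")
        assert len(sset) == 1 and audit.n_duplicates_removed == 1
        assert sset.row("rs1")["pval"] == pytest.approx(1e-8)

    def test_missing_column_names_the_column(self, tmp_path):
        p = _write(tmp_path, ["variant_id\tchromosome\tposition", "rs1\t1\t100"])
        with pytest.raises(FormatError, match="effect_allele"):
            read_sumstats(p, "quantitative")

    def test_binary_requires_n_cases(self, tmp_path):
        p = _write(tmp_path, [HEADER, "rs1\t1\t100\tA\tG\t0.2\t0.5\t0.05\t1e-4\t10000"])
        with pytest.raises(FormatError, match="n_cases"):
            read_sumstats(p, "binary")

    def test_gzip_transparent(self, tmp_path):
        import gzip

        p = tmp_path / "ss.tsv.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(HEADER + "\nrs1\t1\t100\tA\tG\t0.2\t0.5\t0.05\t1e-4\t10000\n")
        sset, _ = read_sumstats(p, "quantitative")
        assert len(sset) == 1


class TestReadLDMatrix:
    def test_square_symmetric(self, tmp_path):
        p = tmp_path / "ld.tsv"
        p.write_text("\trs1\trs2\nrs1\t1\t0.5\nrs2\t0.5\t1\n")
        ld = read_ld_matrix(p)
        assert ld.r_between("rs1", "rs2") == pytest.approx(0.5)

    def test_tiny_asymmetry_symmetrized(self, tmp_path):
        p = tmp_path / "ld.tsv"
        p.write_text("\trs1\trs2\nrs1\t1\t0.5\nrs2\t0.5000000000001\t1\n")
        ld = read_ld_matrix(p)
        assert ld.r[0, 1] == ld.r[1, 0]

    def test_out_of_range_entry_rejected(self, tmp_path):
        p = tmp_path / "ld.tsv"
        p.write_text("\trs1\trs2\nrs1\t1\t1.5\nrs2\t1.5\t1\n")
        with pytest.raises(FormatError):
            read_ld_matrix(p)

    def test_non_square_rejected(self, tmp_path):
        p = tmp_path / "ld.tsv"
        p.write_text("\trs1\trs2\trs3\nrs1\t1\t0\t0\nrs2\t0\t1\t0\n")
        with pytest.raises(FormatError):
            read_ld_matrix(p)

    def test_roundtrip(self, tmp_path):
        ld = make_ld(["a", "b"], [[1, -0.7], [-0.7, 1]])
        p = tmp_path / "ld.tsv"
        write_ld_matrix(ld, p)
        again = read_ld_matrix(p)
        np.testing.assert_allclose(again.r, ld.r)


class TestHarmonize:
    def _sets(self, out_rows):
        exposure = make_sumstats([{"variant_id": "rs1", "beta": 0.5, "se": 0.05}])
        outcome = make_sumstats(out_rows, trait_id="out")
        return exposure, outcome

    def test_same_orientation_identity(self):
        exp, out = self._sets([{"variant_id": "rs1", "beta": 0.2, "se": 0.04}])
        pairs, audit = harmonize(exp, out)
        assert pairs[0].beta_out == pytest.approx(0.2)
        assert audit.n_matched == 1 and audit.n_flipped == 0

    def test_swapped_alleles_flip_sign(self):
        exp, out = self._sets(
            [{"variant_id": "rs1", "effect_allele": "G", "other_allele": "A", "beta": 0.2, "eaf": 0.7}]
        )
        pairs, audit = harmonize(exp, out)
        assert pairs[0].beta_out == pytest.approx(-0.2)
        assert audit.n_flipped == 1

    def test_palindromic_ambiguous_dropped(self):
        exposure = make_sumstats(
            [{"variant_id": "rs1", "effect_allele": "A", "other_allele": "T", "eaf": 0.50, "beta": 0.5}]
        )
        outcome = make_sumstats(
            [{"variant_id": "rs1", "effect_allele": "A", "other_allele": "T", "eaf": 0.50, "beta": 0.2}],
            trait_id="out",
        )
        pairs, audit = harmonize(exposure, outcome, palindromic_eaf_limit=0.42)
        assert pairs == [] and audit.n_palindromic_dropped == 1

    def test_palindromic_unambiguous_aligned_by_frequency(self):
        exposure = make_sumstats(
            [{"variant_id": "rs1", "effect_allele": "A", "other_allele": "T", "eaf": 0.1, "beta": 0.5}]
        )
        # outcome reports the same variant with the frequencies implying the
        # opposite strand labelling: minor allele disagrees, so beta flips
        outcome = make_sumstats(
            [{"variant_id": "rs1", "effect_allele": "A", "other_allele": "T", "eaf": 0.9, "beta": 0.2}],
            trait_id="out",
        )
        pairs, _ = harmonize(exposure, outcome)
        assert pairs[0].beta_out == pytest.approx(-0.2)

    def test_allele_mismatch_dropped_and_audited(self):
        exp, out = self._sets(
            [{"variant_id": "rs1", "effect_allele": "C", "other_allele": "T", "beta": 0.2}]
        )
        pairs, audit = harmonize(exp, out)
        assert pairs == [] and audit.mismatched_ids == ["rs1"]

    def test_involution_already_aligned(self):
        exp = make_sumstats(
            [{"variant_id": f"rs{i}", "beta": 0.1 * i, "se": 0.05} for i in range(1, 4)]
        )
        out = make_sumstats(
            [{"variant_id": f"rs{i}", "beta": 0.02 * i, "se": 0.03} for i in range(1, 4)],
            trait_id="out",
        )
        pairs1, _ = harmonize(exp, out)
        for p, (_, row) in zip(pairs1, out.df.iterrows()):
            assert p.beta_out == row["beta"]

    def test_global_allele_swap_is_identity(self):
        exp = make_sumstats(
            [{"variant_id": f"rs{i}", "beta": 0.1 * i, "se": 0.05, "eaf": 0.2} for i in range(1, 5)]
        )
        out_rows = [
            {"variant_id": f"rs{i}", "beta": 0.02 * i, "se": 0.03, "eaf": 0.25} for i in range(1, 5)
        ]
        out = make_sumstats(out_rows, trait_id="out")
        swapped = make_sumstats(
            [
                {**r, "effect_allele": "G", "other_allele": "A",
                 "beta": -r["beta"], "eaf": 1 - r["eaf"]}
                for r in out_rows
            ],
            trait_id="out",
        )
        pairs1, _ = harmonize(exp, out)
        pairs2, _ = harmonize(exp, swapped)
        assert [(p.variant_id, pytest.approx(p.beta_out)) for p in pairs1] == [
            (p.variant_id, p.beta_out) for p in pairs2
        ]


class TestFindProxy:
    def _outcome(self):
        return make_sumstats(
            [
                {"variant_id": "rs2", "position": 2000, "beta": 0.3, "se": 0.05},
                {"variant_id": "rs3", "position": 3000, "beta": 0.1, "se": 0.05},
            ],
            trait_id="out",
        )

    def test_argmax_r2_selected(self):
        ld = make_ld(
            ["rs1", "rs2", "rs3"],
            [[1, 0.9, 0.7], [0.9, 1, 0.6], [0.7, 0.6, 1]],
        )
        hit = find_proxy("rs1", self._outcome(), ld)
        assert hit.proxy_id == "rs2" and hit.proxy_r == pytest.approx(0.9)

    def test_below_threshold_absent(self):
        r = np.sqrt(0.5)
        ld = make_ld(["rs1", "rs2"], [[1, r], [r, 1]])
        outcome = make_sumstats(
            [{"variant_id": "rs2", "position": 2000, "beta": 0.3, "se": 0.05}], trait_id="out"
        )
        assert find_proxy("rs1", outcome, ld) is None

    def test_negative_r_flips_outcome_beta(self):
        ld = make_ld(["rs1", "rs2"], [[1, -0.9], [-0.9, 1]])
        outcome = make_sumstats(
            [{"variant_id": "rs2", "position": 2000, "beta": 0.3, "se": 0.05, "eaf": 0.2}],
            trait_id="out",
        )
        hit = find_proxy("rs1", outcome, ld)
        assert hit.beta_out == pytest.approx(-0.3)
        assert hit.eaf_out == pytest.approx(0.8)

    def test_target_not_in_ld_raises(self):
        ld = make_ld(["rs2"])
        with pytest.raises(VariantLookupError):
            find_proxy("rs1", self._outcome(), ld)

    def test_perfect_proxy_equivalent_to_presence(self):
        # proxy with r = 1 must reproduce the harmonized pair the target itself would give
        exp = make_sumstats([{"variant_id": "rs1", "beta": 0.5, "se": 0.05}])
        out_with = make_sumstats(
            [
                {"variant_id": "rs1", "beta": 0.2, "se": 0.04},
                {"variant_id": "rs2", "position": 2000, "beta": 0.2, "se": 0.04},
            ],
            trait_id="out",
        )
        out_without = make_sumstats(
            [{"variant_id": "rs2", "position": 2000, "beta": 0.2, "se": 0.04}], trait_id="out"
        )
        ld = make_ld(["rs1", "rs2"], [[1, 1.0], [1.0, 1]])
        direct, _ = harmonize(exp, out_with, ld)
        proxied, _ = harmonize(exp, out_without, ld)
        assert proxied[0].is_proxy and proxied[0].proxy_id == "rs2"
        assert proxied[0].beta_out == pytest.approx(direct[0].beta_out)
        assert proxied[0].se_out == pytest.approx(direct[0].se_out)

    def test_tie_broken_by_position(self):
        ld = make_ld(
            ["rs1", "rs2", "rs3"],
            [[1, 0.9, 0.9], [0.9, 1, 0.8], [0.9, 0.8, 1]],
        )
        outcome = make_sumstats(
            [
                {"variant_id": "rs3", "position": 500, "beta": 0.1, "se": 0.05},
                {"variant_id": "rs2", "position": 2000, "beta": 0.3, "se": 0.05},
            ],
            trait_id="out",
        )
        assert find_proxy("rs1", outcome, ld).proxy_id == "rs3"


def test_gene_region_window_inclusive():
    region = GeneRegion("F11", "4", 1_000_000, 500_000)
    assert region.contains("4", 500_000) and region.contains("4", 1_500_000)
    assert not region.contains("4", 499_999)
    assert not region.contains("5", 1_000_000)


def test_harmonized_pair_rejects_weak_proxy():
    with pytest.raises(ValueError):
        HarmonizedPair("rs1", 0.5, 0.05, 0.2, 0.04, is_proxy=True, proxy_id="rs2", proxy_r=0.5)
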