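"""Genotype data model: reading, filtering, thinning, imputation."""

import numpy as np
import pytest

from speciesid.genotype_data import (
    DOMINANT,
    MISSING,
    EmptyResultError,
    FilterSpec,
    GenotypeMatrix,
    filter_dominant_markers,
    impute_most_common,
    read_matrix,
    read_vcf,
    thin_markers,
    write_matrix,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
    "##contig=<ID=1>\n"
)


def write_vcf_text(path, samples, records):
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for rec in records:
            fh.write(rec + "\n")


class TestReadVcf:
    def test_indel_dropped(self, tmp_path):
        path = tmp_path / "x.vcf"
        write_vcf_text(
            path,
            ["s1", "s2"],
            [
                "1\t100\tsnp1\tA\tT\t.\tPASS\t.\tGT\t0/1\t1/1",
                "1\t200\tins1\tA\tAT\t.\tPASS\t.\tGT\t0/1\t0/0",
            ],
        )
        gm = read_vcf(str(path), FilterSpec(min_call_rate=0, min_maf=0))
        assert gm.marker_ids == ["snp1"]
        assert gm.calls.tolist() == [[1], [2]]

    def test_call_rate_threshold(self, tmp_path):
        # 7 of 10 samples called: 0.7 < 0.8 -> dropped
        samples = [f"s{i}" for i in range(10)]
        gts = ["0/1"] * 7 + ["./."] * 3
        path = tmp_path / "x.vcf"
        write_vcf_text(
            path, samples, ["1\t1\tlow\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(gts)]
        )
        with pytest.raises(EmptyResultError):
            read_vcf(str(path), FilterSpec(min_call_rate=0.8, min_maf=0))

    def test_depth_mask_then_site_filters(self, tmp_path):
        """Hand-counted survivors of a 5-site fixture with DP in {3, 10}."""
        samples = [f"s{i}" for i in range(5)]

        def site(pos, name, gt_dp):
            return f"1\t{pos}\t{name}\tA\tT\t.\tPASS\t.\tGT:DP\t" + "\t".join(gt_dp)

        records = [
            # all deep, polymorphic -> kept
            site(1, "keep1", ["0/1:10", "1/1:10", "0/0:10", "0/1:10", "0/0:10"]),
            # two shallow calls masked -> call rate 3/5 < 0.8 -> dropped
            site(2, "drop_rate", ["0/1:3", "1/1:3", "0/0:10", "0/1:10", "0/0:10"]),
            # one shallow call masked -> call rate 4/5 = 0.8 -> kept
            site(3, "keep2", ["0/1:3", "1/1:10", "0/0:10", "0/1:10", "0/0:10"]),
            # monomorphic after masking -> MAF 0 -> dropped
            site(4, "drop_maf", ["0/0:10", "0/0:10", "0/0:10", "0/0:10", "0/0:10"]),
            # one uncalled genotype -> call rate 4/5 = 0.8 -> kept
            site(5, "keep3", ["./.:0", "0/1:10", "1/1:10", "0/0:10", "0/1:10"]),
        ]
        path = tmp_path / "x.vcf"
        write_vcf_text(path, samples, records)
        gm = read_vcf(str(path), FilterSpec(min_call_rate=0.8, min_maf=0.01, min_call_depth=5))
        assert gm.marker_ids == ["keep1", "keep2", "keep3"]
        # the masked DP=3 call is MISSING in the surviving site
        assert gm.calls[0, gm.marker_ids.index("keep2")] == MISSING

    def test_unreadable_file(self, tmp_path):
        with pytest.raises(OSError):
            read_vcf(str(tmp_path / "absent.vcf"))


class TestReadMatrix:
    def test_small_dominant(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("\tm1\tm2\tm3\nacc1\t0\t1\t0\nacc2\t1\t1\tNA\n")
        gm = read_matrix(str(path), ploidy_mode=DOMINANT)
        assert gm.accession_ids == ["acc1", "acc2"]
        assert gm.het_flagged == set()
        assert gm.calls[1, 2] == MISSING

    def test_heterozygous_cell_flags_marker(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("\tm1\tm2\nacc1\t0\t2\nacc2\t1\t1\n")
        gm = read_matrix(str(path), ploidy_mode=DOMINANT)
        assert gm.het_flagged == {"m2"}
        assert gm.calls[0, 1] == MISSING  # the anomalous cell itself

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(ValueError):
            read_matrix(str(path))

    def test_duplicate_ids(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("\tm1\nacc1\t0\nacc1\t1\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_matrix(str(path), ploidy_mode=DOMINANT)

    def test_non_integer_cell(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("\tm1\nacc1\t0.5\n")
        with pytest.raises(ValueError, match="non-integer"):
            read_matrix(str(path))

    def test_roundtrip_bit_exact(self, tmp_path, tiny_dosage):
        gm, _ = tiny_dosage
        path = tmp_path / "rt.tsv"
        write_matrix(gm, str(path))
        back = read_matrix(str(path))
        assert back.accession_ids == gm.accession_ids
        assert back.marker_ids == gm.marker_ids
        assert np.array_equal(back.calls, gm.calls)


class TestFilterDominant:
    def _dominant(self, calls, het=()):
        calls = np.asarray(calls)
        return GenotypeMatrix(
            [f"a{i}" for i in range(calls.shape[0])],
            [f"m{j}" for j in range(calls.shape[1])],
            calls,
            ploidy_mode=DOMINANT,
            het_flagged=set(het),
        )

    def test_het_then_maf_order(self):
        # 6 markers: m0 flagged, m1 rare (1/200 -> MAF .005), rest balanced
        n = 200
        calls = np.zeros((n, 6), dtype=int)
        calls[: n // 2, [2, 3, 4, 5]] = 1
        calls[0, 1] = 1
        gm = self._dominant(calls, het=["m0"])
        out = filter_dominant_markers(gm, min_maf=0.01)
        assert out.marker_ids == ["m2", "m3", "m4", "m5"]

    def test_no_flags_zero_maf_identity(self):
        calls = [[0, 1], [1, 0]]
        gm = self._dominant(calls)
        out = filter_dominant_markers(gm, min_maf=0.0)
        assert out.marker_ids == gm.marker_ids
        assert np.array_equal(out.calls, gm.calls)

    def test_requires_dominant(self, tiny_dosage):
        gm, _ = tiny_dosage
        with pytest.raises(ValueError):
            filter_dominant_markers(gm)


class TestThin:
    def test_count_and_order(self, separated_collection):
        gm, _, _ = separated_collection
        out = thin_markers(gm, 100, seed=5)
        assert out.n_markers == 100
        # order preserved: thinned ids are a subsequence of the originals
        it = iter(gm.marker_ids)
        assert all(m in it for m in out.marker_ids)

    def test_identity_when_enough(self, tiny_dosage):
        gm, _ = tiny_dosage
        assert thin_markers(gm, 10, seed=0) is gm

    def test_seed_determinism(self, separated_collection):
        gm, _, _ = separated_collection
        a = thin_markers(gm, 50, seed=9)
        b = thin_markers(gm, 50, seed=9)
        assert a.marker_ids == b.marker_ids


class TestImpute:
    def test_modal_fill_and_tie(self):
        calls = np.array(
            [[0, 0], [1, 0], [1, 1], [MISSING, 1], [MISSING, MISSING]]
        )
        gm = GenotypeMatrix(
            [f"a{i}" for i in range(5)], ["m0", "m1"], calls
        )
        out = impute_most_common(gm)
        assert out.calls[3, 0] == 1 and out.calls[4, 0] == 1  # clear mode
        assert out.calls[4, 1] == 0  # 2-2 tie -> lowest code
        assert not out.has_missing()

    def test_idempotent_and_identity(self, tiny_dosage):
        gm, _ = tiny_dosage
        once = impute_most_common(gm)
        twice = impute_most_common(once)
        assert np.array_equal(once.calls, twice.calls)
        # non-missing cells untouched
        mask = ~gm.missing_mask
        assert np.array_equal(once.calls[mask], gm.calls[mask])

    def test_all_missing_column_names_marker(self):
        calls = np.array([[0, MISSING], [1, MISSING]])
        gm = GenotypeMatrix(["a0", "a1"], ["ok", "void"], calls)
        with pytest.raises(ValueError, match="void"):
            impute_most_common(gm)


class TestAccessionMissingness:
    def test_high_missingness_accession_dropped(self):
        calls = np.array([[0, 1, 2], [MISSING, MISSING, 1], [0, 0, 0]])
        gm = GenotypeMatrix(["lowcov", "shallow", "deep"][::-1], ["m0", "m1", "m2"], calls)
        from speciesid.genotype_data import LabelSet, filter_accession_missingness

        labels = LabelSet({a: "A" for a in gm.accession_ids})
        out, out_labels = filter_accession_missingness(gm, labels, max_missing_rate=0.5)
        assert out.n_accessions == 2
        assert set(out_labels.labels) == set(out.accession_ids)


class TestInvariants:
    def test_alphabet_enforced(self):
        with pytest.raises(ValueError):
            GenotypeMatrix(["a"], ["m"], np.array([[3]]))
        with pytest.raises(ValueError):
            GenotypeMatrix(["a"], ["m"], np.array([[2]]), ploidy_mode=DOMINANT)

    def test_shape_and_duplicates(self):
        with pytest.raises(ValueError):
            GenotypeMatrix(["a", "a"], ["m"], np.array([[0], [1]]))
        with pytest.raises(ValueError):
            GenotypeMatrix(["a"], ["m", "m2"], np.array([[0]]))
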