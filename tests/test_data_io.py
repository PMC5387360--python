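"""Genome/profile reading, binarization, windows, neighbour contexts, splits."""

import gzip

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scmethyl import data_io
from scmethyl.data_io import (ConfigError, FormatError, InputError,
                              MethylationProfile, binarize, build_dataset,
                              extract_neighbors, extract_window, make_split,
                              one_hot, read_genome, read_profile,
                              write_profile)


class TestReadGenome:
    def test_reads_and_uppercases(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">chr1\nacgt\n>chr2\nNNTT\n")
        genome = read_genome(fa)
        assert genome == {"chr1": "ACGT", "chr2": "NNTT"}

    def test_missing_file(self, tmp_path):
        with pytest.raises(InputError):
            read_genome(tmp_path / "absent.fa")

    def test_duplicate_chromosomes(self, tmp_path):
        fa = tmp_path / "dup.fa"
        fa.write_text(">c\nAC\n>c\nGT\n")
        with pytest.raises((FormatError, InputError)):
            read_genome(fa)


class TestReadProfile:
    def _write(self, tmp_path, rows):
        path = tmp_path / "cell.tsv"
        path.write_text("\n".join("\t".join(map(str, r)) for r in rows) + "\n")
        return path

    def test_count_dialect_majority_call(self, tmp_path):
        # 3/4 methylated reads -> methylated; 2/4 tie -> unmethylated;
        # 3 total reads < min_reads=4 -> dropped
        path = self._write(tmp_path, [("1", 100, 3, 4), ("1", 200, 2, 4),
                                      ("1", 300, 3, 3)])
        prof = read_profile(path, min_reads=4)
        assert list(prof.positions["1"]) == [100, 200]
        assert list(prof.states["1"]) == [1, 0]

    def test_binary_dialect_passthrough(self, tmp_path):
        path = self._write(tmp_path, [("1", 5, 1), ("1", 9, 0)])
        prof = read_profile(path, min_reads=4)
        assert list(prof.states["1"]) == [1, 0]

    def test_binary_dialect_rejects_nonbinary_state(self, tmp_path):
        path = self._write(tmp_path, [("1", 5, 2)])
        with pytest.raises(FormatError):
            read_profile(path)

    def test_count_dialect_rejects_meth_over_total(self, tmp_path):
        path = self._write(tmp_path, [("1", 5, 5, 4)])
        with pytest.raises(FormatError):
            read_profile(path)

    def test_gzip_transparent(self, tmp_path):
        path = tmp_path / "cell.tsv.gz"
        with gzip.open(path, "wt") as fh:
            fh.write("1\t7\t1\n")
        prof = read_profile(path)
        assert prof.state_at("1", 7) == 1

    def test_roundtrip_binary_dialect(self, tmp_path, toy_profile):
        out = tmp_path / "rt.tsv"
        write_profile(toy_profile, out)
        back = read_profile(out, cell_id=toy_profile.cell_id)
        for chrom in toy_profile.chroms():
            assert np.array_equal(back.positions[chrom],
                                  toy_profile.positions[chrom])
            assert np.array_equal(back.states[chrom],
                                  toy_profile.states[chrom])

    @given(meth=st.integers(0, 30), extra=st.integers(0, 10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_binarization_monotone_in_meth_reads(self, meth, extra):
        total = meth + extra + 5
        assert binarize(meth, total) <= binarize(min(meth + 1, total), total)


class TestOneHot:
    def test_base_channels(self):
        assert list(one_hot("A")[0]) == [1, 0, 0, 0]
        assert list(one_hot("T")[0]) == [0, 1, 0, 0]
        assert list(one_hot("G")[0]) == [0, 0, 1, 0]
        assert list(one_hot("C")[0]) == [0, 0, 0, 1]

    def test_unknown_base_is_zero_row(self):
        assert one_hot("N").sum() == 0

    def test_one_hot_rows_sum_to_at_most_one(self):
        mat = one_hot("ACGTNRYacg")
        assert set(mat.sum(axis=1)) <= {0.0, 1.0}


class TestExtractWindow:
    genome = {"1": "ACGT"}

    def test_interior(self):
        win = extract_window(self.genome, "1", 2, 3)
        assert np.array_equal(win, one_hot("ACG"))

    def test_left_edge_pads_zero_rows(self):
        win = extract_window(self.genome, "1", 1, 3)
        assert win[0].sum() == 0
        assert np.array_equal(win[1:], one_hot("AC"))

    def test_row_count_always_l_win(self):
        for pos in (1, 2, 4):
            assert extract_window(self.genome, "1", pos, 7).shape == (7, 4)

    def test_even_window_rejected(self):
        with pytest.raises(ConfigError):
            extract_window(self.genome, "1", 2, 4)

    def test_missing_chromosome(self):
        with pytest.raises(KeyError):
            extract_window(self.genome, "9", 1, 3)


class TestExtractNeighbors:
    def test_single_neighbor_each_side(self):
        prof = MethylationProfile(cell_id="c")
        prof.positions["1"] = np.array([90, 110])
        prof.states["1"] = np.array([1, 0], dtype=np.uint8)
        x = extract_neighbors(prof, "1", 100, K=1, max_dist=100)
        assert np.allclose(x, [1, 0.10, 0, 0.10])

    def test_all_pad_when_no_observations(self):
        prof = MethylationProfile(cell_id="c")
        x = extract_neighbors(prof, "1", 100, K=1, max_dist=100)
        assert np.allclose(x, [0.5, 1.0, 0.5, 1.0])

    def test_length_is_4k(self, toy_profile):
        assert len(extract_neighbors(toy_profile, "1", 100, K=25,
                                     max_dist=1000)) == 100

    def test_target_site_excluded(self, toy_profile):
        # site 90 is observed with state 1; its own state must not appear
        # at distance zero
        x = extract_neighbors(toy_profile, "1", 90, K=2, max_dist=100)
        dists = x[1::2]
        assert 0.0 not in dists

    def test_distance_clipping(self, toy_profile):
        x = extract_neighbors(toy_profile, "1", 90, K=2, max_dist=10)
        assert x[1::2].max() <= 1.0

    def test_invalid_k(self, toy_profile):
        with pytest.raises(ConfigError):
            extract_neighbors(toy_profile, "1", 90, K=0, max_dist=10)

    @given(pos=st.integers(1, 500), k=st.integers(1, 8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_output_contract(self, pos, k):
        prof = MethylationProfile(cell_id="c")
        prof.positions["1"] = np.arange(10, 400, 37, dtype=np.int64)
        prof.states["1"] = (np.arange(len(prof.positions["1"])) % 2
                            ).astype(np.uint8)
        x = extract_neighbors(prof, "1", pos, K=k, max_dist=200)
        assert len(x) == 4 * k
        assert (x[1::2] >= 0).all() and (x[1::2] <= 1).all()


class TestMakeSplit:
    def test_default_odd_even(self):
        split = make_split([str(i) for i in range(1, 14)])
        assert "1" in split.train_chroms
        assert "2" in split.test_chroms
        assert "13" in split.val_chroms

    def test_chr_prefix_normalized(self):
        split = make_split(["chr1", "chr2", "chr13"])
        assert "chr1" in split.train_chroms
        assert "chr13" in split.val_chroms

    def test_custom_split_val_defaults_to_rest(self):
        split = make_split(["A", "B"], train={"A"}, test={"B"})
        assert split.val_chroms == frozenset()

    def test_overlapping_custom_sets_rejected(self):
        with pytest.raises(ConfigError):
            make_split(["A", "B"], train={"A"}, test={"A"})


class TestBuildDataset:
    def test_shapes_and_mask(self, micro_sim, micro_dataset):
        ds = micro_dataset
        N, T = ds.n_sites, ds.n_cells
        assert ds.windows.shape == (N, 101, 4)
        assert ds.contexts.shape == (N, T, 20)
        assert ds.y.shape == ds.o.shape == (N, T)
        # observed fraction should be near configured coverage
        assert abs(ds.o.mean() - 0.3) < 0.05

    def test_window_center_is_target_c(self, micro_dataset):
        # channel order ATGC: C is channel 3, G channel 2
        center = (micro_dataset.L_win - 1) // 2
        assert micro_dataset.windows[:, center, 3].all()
        assert micro_dataset.windows[:, center + 1, 2].all()

    def test_labels_match_profiles(self, micro_sim, micro_dataset):
        ds = micro_dataset
        profiles = sorted(micro_sim.profiles, key=lambda p: p.cell_id)
        for i in [0, len(ds.sites) // 2, len(ds.sites) - 1]:
            chrom, pos = ds.sites[i]
            for t, prof in enumerate(profiles):
                state = prof.state_at(chrom, pos)
                if state is None:
                    assert ds.o[i, t] == 0
                else:
                    assert ds.o[i, t] == 1 and ds.y[i, t] == state
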