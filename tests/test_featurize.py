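"""Windowed feature assembly, MSA-derived tracks and track validation."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import random_tracks
from nabind.featurize import (
    DEFAULT_SCHEMA, Channel, FeatureSchema, TrackSet, assemble_vector,
    conservation_from_msa, featurize_chain, load_tracks,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestConservationFromMsa:
    def test_fully_conserved_column_has_near_zero_entropy(self):
        msa = [(f"s{i}", "WWW") for i in range(50)]
        # the 1/20-per-symbol pseudocount leaves ~0.21 bits at depth 50
        cons, ent, n_align = conservation_from_msa(msa, 0)
        assert np.all(ent < 0.25)
        assert np.all(cons > 0.94)
        assert np.all(n_align == 50)

    def test_uniform_column_has_near_zero_conservation(self):
        msa = [(f"s{i}", c) for i, c in enumerate(AA)]
        cons, ent, _ = conservation_from_msa(msa, 0)
        assert cons[0] == pytest.approx(0.0, abs=1e-9)
        assert ent[0] == pytest.approx(math.log2(20))

    def test_half_and_half_column_approaches_one_bit(self):
        msa = [(f"s{i}", "A" if i < 250 else "C") for i in range(500)]
        cons, ent, _ = conservation_from_msa(msa, 0)
        assert ent[0] == pytest.approx(1.0, abs=0.05)
        assert cons[0] == pytest.approx(1 - 1 / math.log2(20), abs=0.01)

    def test_gapped_columns_skipped_for_query_and_counted_for_depth(self):
        msa = [("query", "A-C"), ("h1", "AAC"), ("h2", "-AC")]
        cons, ent, n_align = conservation_from_msa(msa, "query")
        assert len(cons) == 2            # query has two ungapped positions
        assert n_align.tolist() == [2, 3]

    def test_missing_query_is_an_error(self):
        with pytest.raises(ValueError):
            conservation_from_msa([("a", "AC")], "nope")


class TestLoadTracks:
    def _write(self, tmp_path, n, ss3_row=None):
        idx = np.arange(n)
        files = {}
        frames = {
            "conservation": {"conservation": np.linspace(0, 1, n)},
            "entropy": {"entropy": np.linspace(0, 4, n)},
            "n_align": {"n_align": np.full(n, 120.0)},
            "ss3": {"helix": np.full(n, 0.5), "strand": np.full(n, 0.25),
                    "other": np.full(n, 0.25)},
            "accessibility": {"rel_acc": np.linspace(0, 1, n),
                              "exposed": np.ones(n)},
            "disorder": {"disorder": np.linspace(0, 1, n)},
        }
        if ss3_row is not None:
            for j, col in enumerate(("helix", "strand", "other")):
                frames["ss3"][col] = np.full(n, ss3_row[j])
        for name, cols in frames.items():
            path = tmp_path / f"{name}.tsv"
            pd.DataFrame({"residue_index": idx, **cols}).to_csv(
                path, sep="\t", index=False)
            files[name] = path
        return files

    def test_valid_files_round_trip(self, tmp_path):
        tracks = load_tracks(self._write(tmp_path, 30), 30)
        assert len(tracks) == 30

    def test_row_count_mismatch_is_an_error(self, tmp_path):
        files = self._write(tmp_path, 29)
        with pytest.raises(ValueError, match="29 rows"):
            load_tracks(files, 30)

    def test_ss3_simplex_violation_rejected(self, tmp_path):
        files = self._write(tmp_path, 10, ss3_row=(0.2, 0.2, 0.2))
        with pytest.raises(ValueError, match="ss3"):
            load_tracks(files, 10)


class TestSchema:
    def test_default_schema_totals_246(self):
        assert DEFAULT_SCHEMA.total == 246

    def test_profile_windows_are_nine_and_structure_windows_seven(self):
        widths = {c.name: c.window for c in DEFAULT_SCHEMA.channels}
        assert widths["aa_onehot"] == widths["conservation"] == \
            widths["entropy"] == 9
        assert widths["ss3"] == widths["disorder"] == \
            widths["accessibility"] == 7

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            Channel("bad", 1, 4)

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "schema.yaml"
        DEFAULT_SCHEMA.to_yaml(path)
        loaded = FeatureSchema.from_yaml(path)
        assert loaded == DEFAULT_SCHEMA
        assert loaded.fingerprint == DEFAULT_SCHEMA.fingerprint


class TestAssembleVector:
    def test_vector_length_246_at_every_position(self):
        rng = np.random.default_rng(0)
        n = 50
        seq = "".join(rng.choice(list(AA), size=n))
        tracks = random_tracks(n, rng)
        fm = featurize_chain(seq, tracks)
        assert fm.values.shape == (n, 246)
        for i in (0, 1, n // 2, n - 1):
            assert len(assemble_vector(seq, tracks, DEFAULT_SCHEMA, i)) == 246

    def test_first_residue_left_slots_are_padding(self):
        rng = np.random.default_rng(1)
        n = 20
        seq = "".join(rng.choice(list(AA), size=n))
        tracks = random_tracks(n, rng)
        vec = assemble_vector(seq, tracks, DEFAULT_SCHEMA, 0)
        sl = DEFAULT_SCHEMA.channel_slice("conservation")
        window = vec[sl]                # 9 values, offsets -4..+4
        assert np.all(window[:4] == 0.0)
        assert window[4] == pytest.approx(tracks.conservation[0])
        onehot = vec[DEFAULT_SCHEMA.channel_slice("aa_onehot")].reshape(9, 20)
        assert np.all(onehot[:4] == 0.0)

    def test_out_of_range_index_is_an_error(self):
        rng = np.random.default_rng(2)
        tracks = random_tracks(5, rng)
        with pytest.raises(IndexError):
            assemble_vector("ACDEF", tracks, DEFAULT_SCHEMA, 5)


class TestWindowLocality:
    """Perturbing a track at offset d from residue i must reach i exactly
    when |d| is inside that channel's window."""

    def _features_at(self, tracks, seq, i):
        return featurize_chain(seq, tracks).values[i]

    @pytest.mark.parametrize("offset,ss3_changes,profile_changes", [
        (3, True, True),     # inside both windows
        (4, False, True),    # outside the 7-window, inside the 9-window
        (5, False, False),   # outside both
    ])
    def test_seven_and_nine_residue_spans(self, offset, ss3_changes,
                                          profile_changes):
        rng = np.random.default_rng(3)
        n, i = 31, 15
        seq = "".join(rng.choice(list(AA), size=n))
        tracks = random_tracks(n, np.random.default_rng(30))
        base = self._features_at(tracks, seq, i)

        bumped = random_tracks(n, np.random.default_rng(30))
        bumped.disorder[i + offset] = 1.0 - bumped.disorder[i + offset]
        bumped.conservation[i + offset] = 1.0 - bumped.conservation[i + offset]
        after = self._features_at(bumped, seq, i)

        ss3_sl = DEFAULT_SCHEMA.channel_slice("disorder")
        prof_sl = DEFAULT_SCHEMA.channel_slice("conservation")
        assert (not np.allclose(after[ss3_sl], base[ss3_sl])) == ss3_changes
        assert (not np.allclose(after[prof_sl], base[prof_sl])) == profile_changes

    def test_ss3_channel_equals_track_slice_window_seven(self):
        rng = np.random.default_rng(4)
        n, i = 30, 12
        seq = "".join(rng.choice(list(AA), size=n))
        tracks = random_tracks(n, rng)
        vec = featurize_chain(seq, tracks).values[i]
        block = vec[DEFAULT_SCHEMA.channel_slice("ss3")].reshape(7, 3)
        np.testing.assert_allclose(block, tracks.ss3[i - 3:i + 4])


class TestFeaturizeChain:
    def test_mask_follows_resolved_residues(self):
        from nabind.structure import LabeledChain

        rng = np.random.default_rng(5)
        n = 30
        seq = "".join(rng.choice(list(AA), size=n))
        mask = np.ones(n, bool)
        mask[[4, 9]] = False
        chain = LabeledChain("S", "A", seq, np.zeros(n, int), mask, "DNA")
        fm = featurize_chain(chain, random_tracks(n, rng))
        assert (~fm.mask).sum() == 2

    def test_masked_residue_still_feeds_neighbour_windows(self):
        from nabind.structure import LabeledChain

        rng = np.random.default_rng(6)
        n = 30
        seq = "".join(rng.choice(list(AA), size=n))
        tracks = random_tracks(n, rng)
        mask = np.ones(n, bool)
        mask[10] = False
        chain = LabeledChain("S", "A", seq, np.zeros(n, int), mask, "DNA")
        vec = featurize_chain(chain, tracks).values[11]
        window = vec[DEFAULT_SCHEMA.channel_slice("disorder")]
        assert window[2] == pytest.approx(tracks.disorder[10])

    def test_track_length_mismatch_is_an_error(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError):
            featurize_chain("ACDEF", random_tracks(6, rng))
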