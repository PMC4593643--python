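import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lncscan.annotation_io import Exon, GenomeSequence, TranscriptModel
from lncscan.conservation import ConservationTrack
from lncscan.features import (
    CANDIDATE_FEATURES,
    SELECTED_FEATURES,
    TRINUCLEOTIDES,
    FrameStopCounts,
    apply_scaler,
    assemble_features,
    avg_exon_length,
    count_stop_codons_by_frame,
    feature_table,
    fit_scaler,
    gc_content,
    stop_codon_std,
    trinucleotide_freqs,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=300)


class TestStopCodonCounts:
    @pytest.mark.parametrize(
        ("seq", "expected"),
        [
            ("TAATAATAA", (3, 0, 0)),
            ("CCCCCCCCC", (0, 0, 0)),
            ("ATGAAATAA", (1, 1, 0)),
            ("TA", (0, 0, 0)),
        ],
    )
    def test_examples(self, seq, expected):
        assert count_stop_codons_by_frame(seq) == expected

    @pytest.mark.parametrize(
        ("counts", "expected"),
        [
            ((2, 2, 2), 0.0),
            ((3, 0, 0), math.sqrt(2)),
            ((1, 1, 0), math.sqrt(2) / 3),
        ],
    )
    def test_population_std_examples(self, counts, expected):
        assert stop_codon_std(FrameStopCounts(*counts)) == pytest.approx(
            expected, abs=1e-12
        )

    @given(dna)
    def test_std_nonnegative_zero_iff_equal_counts(self, seq):
        counts = count_stop_codons_by_frame(seq)
        std = stop_codon_std(counts)
        assert std >= 0
        assert (std == 0) == (counts[0] == counts[1] == counts[2])

    @given(dna)
    def test_counts_bounded_by_codon_capacity(self, seq):
        counts = count_stop_codons_by_frame(seq)
        for frame in range(3):
            assert 0 <= counts[frame] <= max(0, (len(seq) - frame)) // 3


class TestTrinucleotideFreqs:
    def test_acgacg(self):
        freqs = trinucleotide_freqs("ACGACG")
        assert freqs["ACG"] == pytest.approx(0.5)
        assert freqs["CGA"] == pytest.approx(0.25)
        assert sum(v for k, v in freqs.items() if k not in ("ACG", "CGA")) == 0

    def test_no_tracked_trimer(self):
        assert all(v == 0 for v in trinucleotide_freqs("AAAAAA").values())

    def test_single_window(self):
        freqs = trinucleotide_freqs("TAG")
        assert freqs["TAG"] == 1.0

    def test_short_sequence_all_zero(self):
        assert all(v == 0 for v in trinucleotide_freqs("AC").values())

    def test_n_windows_count_in_denominator_only(self):
        # "ANG" window contributes to the denominator, matches nothing
        freqs = trinucleotide_freqs("ANGACG")
        assert freqs["ACG"] == pytest.approx(1 / 4)

    @given(dna.filter(lambda s: len(s) >= 3))
    def test_subset_of_full_overlapping_composition(self, seq):
        """Oracle: direct window counting over all 64 trimers sums to 1 for
        N-free sequences; the 14 reported values match their counts."""
        windows = [seq[i : i + 3] for i in range(len(seq) - 2)]
        full = {tri: windows.count(tri) / len(windows) for tri in set(windows)}
        assert sum(full.values()) == pytest.approx(1.0)
        freqs = trinucleotide_freqs(seq)
        for tri in TRINUCLEOTIDES:
            assert freqs[tri] == pytest.approx(full.get(tri, 0.0))


class TestGcContent:
    @pytest.mark.parametrize(
        ("seq", "expected"), [("ATGC", 0.5), ("GGCC", 1.0), ("ATNG", 0.25)]
    )
    def test_examples(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc_content("")


def test_avg_exon_length():
    model = TranscriptModel(
        "t", "g", "c", "+", [Exon("c", 1, 100, "+"), Exon("c", 201, 400, "+")]
    )
    assert avg_exon_length(model) == pytest.approx(150.0)
    single = TranscriptModel("t", "g", "c", "+", [Exon("c", 3, 9, "+")])
    assert avg_exon_length(single) == pytest.approx(7.0)


class TestAssembleFeatures:
    @pytest.fixture
    def orf_model_genome(self):
        genome = GenomeSequence({"c": "ATGAAATAA"})
        model = TranscriptModel("t", "g", "c", "+", [Exon("c", 1, 9, "+")])
        return model, genome

    def test_toy_single_exon_orf(self, orf_model_genome):
        model, genome = orf_model_genome
        vector = assemble_features(model, genome)
        assert vector["transcript_length"] == 9
        assert vector["exon_count"] == 1
        assert vector["stop_codon_std"] == pytest.approx(math.sqrt(2) / 3)
        assert vector["cds_percentage"] == 1.0
        assert set(vector) == set(CANDIDATE_FEATURES)

    def test_deterministic(self, orf_model_genome):
        model, genome = orf_model_genome
        assert assemble_features(model, genome) == assemble_features(model, genome)

    def test_consv_present_only_with_track(self, orf_model_genome):
        model, genome = orf_model_genome
        track = ConservationTrack({"c": {p: 0.5 for p in range(1, 10)}})
        with_track = assemble_features(model, genome, track)
        assert with_track["consv"] == pytest.approx(0.5)
        assert "consv" not in assemble_features(model, genome)

    def test_feature_table_columns_and_index(self, orf_model_genome):
        model, genome = orf_model_genome
        table = feature_table([model], genome)
        assert list(table.columns) == list(CANDIDATE_FEATURES)
        assert list(table.index) == ["t"]
        assert not table.isna().any().any()


def test_selected_feature_names():
    assert set(SELECTED_FEATURES) == {
        "transcript_length",
        "stop_codon_std",
        "cds_score",
        "exon_count",
        "avg_exon_length",
        "consv",
    }


class TestScaler:
    def test_endpoints_and_midpoint(self):
        train = pd.DataFrame({"f": [0.0, 10.0]})
        params = fit_scaler(train)
        out = apply_scaler(params, pd.DataFrame({"f": [0.0, 5.0, 10.0, 20.0]}))
        assert out["f"].tolist() == pytest.approx([-1.0, 0.0, 1.0, 3.0])

    def test_constant_column_maps_to_zero(self):
        train = pd.DataFrame({"f": [4.0, 4.0, 4.0]})
        params = fit_scaler(train)
        out = apply_scaler(params, pd.DataFrame({"f": [4.0, 99.0]}))
        assert out["f"].tolist() == [0.0, 0.0]

    def test_fit_requires_two_rows(self):
        with pytest.raises(ValueError):
            fit_scaler(pd.DataFrame({"f": [1.0]}))

    def test_column_mismatch_rejected(self):
        params = fit_scaler(pd.DataFrame({"a": [0.0, 1.0]}))
        with pytest.raises(ValueError, match="mismatch"):
            apply_scaler(params, pd.DataFrame({"b": [0.0]}))

    @given(
        st.lists(
            st.tuples(
                st.floats(-1e6, 1e6, allow_nan=False),
                st.floats(-1e6, 1e6, allow_nan=False),
            ),
            min_size=2,
            max_size=30,
        )
    )
    def test_training_matrix_scales_into_unit_box(self, rows):
        train = pd.DataFrame(rows, columns=["a", "b"])
        scaled = apply_scaler(fit_scaler(train), train)
        assert ((scaled >= -1.0 - 1e-9) & (scaled <= 1.0 + 1e-9)).all().all()
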