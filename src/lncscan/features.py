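"""Per-transcript candidate features and svm-scale-style feature scaling.

Three feature categories are computed from the spliced transcript sequence,
the predicted coding segment, and the gene structure, plus an optional mean
conservation score:

* sequence: 14 tri-nucleotide frequencies (overlapping windows, normalized
  by window count), the population standard deviation of stop-codon counts
  across the three translated frames, and GC content;
* coding segment: the CDS score, length and percentage from
  :func:`lncscan.cds.predict_cds`;
* gene structure: transcript length, exon count, average exon length.

The default model uses the six-feature subset ``SELECTED_FEATURES``:
transcript length, stop-codon standard deviation, CDS score, exon count,
average exon length, and mean conservation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import pandas as pd

from lncscan.annotation_io import GenomeSequence, TranscriptModel, spliced_sequence
from lncscan.cds import predict_cds
from lncscan.conservation import ConservationTrack, mean_conservation

logger = logging.getLogger(__name__)

#: The 14 tri-nucleotide attributes used as sequence-composition features.
TRINUCLEOTIDES = (
    "ACG", "CCG", "CGA", "CGC", "CGG", "CGT", "CTA",
    "GCG", "GGG", "GTA", "TAA", "TAC", "TAG", "TCG",
)

#: Fixed candidate-feature order (consv appended when a track is supplied).
CANDIDATE_FEATURES = TRINUCLEOTIDES + (
    "stop_codon_std",
    "gc_content",
    "cds_score",
    "cds_length",
    "cds_percentage",
    "transcript_length",
    "exon_count",
    "avg_exon_length",
)

#: The six features of the default classification model.
SELECTED_FEATURES = (
    "transcript_length",
    "stop_codon_std",
    "cds_score",
    "exon_count",
    "avg_exon_length",
    "consv",
)

#: Named feature subsets selectable in configuration.
FEATURE_SETS = {
    "selected_six": SELECTED_FEATURES,
    "candidates": CANDIDATE_FEATURES + ("consv",),
}

_STOPS = ("TAA", "TAG", "TGA")

#: Named per-transcript feature values, in CANDIDATE_FEATURES order.
FeatureVector = dict[str, float]


class FrameStopCounts(NamedTuple):
    """Stop-codon counts in the three translated frames."""

    frame0: int
    frame1: int
    frame2: int


def count_stop_codons_by_frame(seq: str) -> FrameStopCounts:
    """Count non-overlapping in-frame stop codons (TAA/TAG/TGA) per frame."""
    counts = []
    n = len(seq)
    for frame in range(3):
        counts.append(
            sum(1 for i in range(frame, n - 2, 3) if seq[i : i + 3] in _STOPS)
        )
    return FrameStopCounts(*counts)


def stop_codon_std(counts: FrameStopCounts) -> float:
    """Population standard deviation (divisor 3) of the three frame counts."""
    mean = sum(counts) / 3.0
    return math.sqrt(sum((c - mean) ** 2 for c in counts) / 3.0)


def trinucleotide_freqs(seq: str) -> dict[str, float]:
    """Frequencies of the 14 tracked trimers over overlapping windows.

    Each frequency is (occurrence count) / (L - 2); windows containing N
    count toward the denominator only.  Sequences shorter than 3 nt yield
    all zeros.
    """
    n_windows = len(seq) - 2
    if n_windows < 1:
        return {tri: 0.0 for tri in TRINUCLEOTIDES}
    return {tri: _count_overlapping(seq, tri) / n_windows for tri in TRINUCLEOTIDES}


def _count_overlapping(seq: str, pattern: str) -> int:
    count = 0
    pos = seq.find(pattern)
    while pos != -1:
        count += 1
        pos = seq.find(pattern, pos + 1)
    return count


def gc_content(seq: str) -> float:
    """(G + C) / length; N bases count in the denominator only."""
    if not seq:
        raise ValueError("gc_content of empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def avg_exon_length(model: TranscriptModel) -> float:
    """Transcript length divided by exon count, in nucleotides."""
    return model.length / model.exon_count


def assemble_features(
    model: TranscriptModel,
    genome: GenomeSequence,
    track: ConservationTrack | None = None,
) -> FeatureVector:
    """All candidate features for one transcript.

    The conservation feature ``consv`` is omitted (with a logged warning)
    when no track is supplied.  Deterministic for fixed inputs.
    """
    seq = spliced_sequence(model, genome)
    vector: FeatureVector = dict(trinucleotide_freqs(seq))
    vector["stop_codon_std"] = stop_codon_std(count_stop_codons_by_frame(seq))
    vector["gc_content"] = gc_content(seq)
    cds = predict_cds(seq)
    vector["cds_score"] = cds.score
    vector["cds_length"] = float(cds.cds_length)
    vector["cds_percentage"] = cds.cds_percentage
    vector["transcript_length"] = float(model.length)
    vector["exon_count"] = float(model.exon_count)
    vector["avg_exon_length"] = avg_exon_length(model)
    if track is not None:
        vector["consv"] = mean_conservation(model, track)
    else:
        logger.warning(
            "transcript %s: no conservation track supplied; consv omitted",
            model.transcript_id,
        )
    return vector


def feature_table(
    models: list[TranscriptModel],
    genome: GenomeSequence,
    track: ConservationTrack | None = None,
) -> pd.DataFrame:
    """Feature matrix with one row per transcript, indexed by transcript_id."""
    columns = CANDIDATE_FEATURES + (("consv",) if track is not None else ())
    rows = {m.transcript_id: assemble_features(m, genome, track) for m in models}
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(columns))
    frame.index.name = "transcript_id"
    return frame


@dataclass(frozen=True)
class ScalingParams:
    """Per-feature (min, max) learned from training data; target [-1, +1]."""

    limits: dict[str, tuple[float, float]]

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.limits)


def fit_scaler(matrix: pd.DataFrame) -> ScalingParams:
    """Learn per-feature min/max from a training feature matrix (>= 2 rows)."""
    if len(matrix) < 2:
        raise ValueError("scaler requires at least 2 training rows")
    limits = {
        name: (float(matrix[name].min()), float(matrix[name].max()))
        for name in matrix.columns
    }
    return ScalingParams(limits)


def apply_scaler(params: ScalingParams, matrix: pd.DataFrame) -> pd.DataFrame:
    """Map each feature linearly so the training min -> -1 and max -> +1.

    Values outside the training range extrapolate beyond +-1.  Features that
    were constant in training map to 0 everywhere.
    """
    if tuple(matrix.columns) != params.feature_names:
        raise ValueError(
            f"feature mismatch: scaler expects {params.feature_names}, "
            f"got {tuple(matrix.columns)}"
        )
    scaled = {}
    for name in matrix.columns:
        lo, hi = params.limits[name]
        col = matrix[name].astype(float)
        if hi == lo:
            scaled[name] = col * 0.0
        else:
            scaled[name] = -1.0 + 2.0 * (col - lo) / (hi - lo)
    return pd.DataFrame(scaled, index=matrix.index)


def write_feature_tsv(matrix: pd.DataFrame, path) -> None:
    """Write a feature matrix as TSV, first column transcript_id."""
    matrix.to_csv(path, sep="\t", index=True)


def to_svm_format(matrix: pd.DataFrame, labels: dict[str, int] | None, path) -> None:
    """Write sparse ``label index:value`` lines for SVM-tool interoperability.

    Feature indices are 1-based positions in the matrix column order; zero
    values are omitted.  ``labels`` maps transcript_id to an integer label
    (0 used when absent).
    """
    with open(path, "w") as fh:
        for tid, row in matrix.iterrows():
            label = labels.get(tid, 0) if labels else 0
            parts = [str(label)]
            for idx, value in enumerate(row, start=1):
                if value != 0.0:
                    parts.append(f"{idx}:{value:g}")
            fh.write(" ".join(parts) + "\n")
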