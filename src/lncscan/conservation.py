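"""Per-base conservation scores (PhastCons-like, in [0,1]) over exons.

The track is a sparse per-chromosome map of 1-based positions to scores;
positions absent from the track fall back to ``default_score`` (0 by default,
the conservative "unconserved" value — PhastCons tracks commonly omit
unalignable regions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from lncscan.annotation_io import TranscriptModel

logger = logging.getLogger(__name__)


class TrackParseError(ValueError):
    """A conservation track line could not be parsed or validated."""


@dataclass
class ConservationTrack:
    """Sparse map chrom -> {1-based position: score in [0,1]}."""

    scores: dict[str, dict[int, float]] = field(default_factory=dict)
    default_score: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.default_score <= 1.0:
            raise ValueError(f"default_score {self.default_score} outside [0,1]")

    def score(self, chrom: str, pos: int) -> float:
        return self.scores.get(chrom, {}).get(pos, self.default_score)


def _check_score(value: float, lineno: int) -> float:
    if not 0.0 <= value <= 1.0:
        raise TrackParseError(f"line {lineno}: score {value} outside [0,1]")
    return value


def read_track(path, default_score: float = 0.0) -> ConservationTrack:
    """Load a bedGraph (0-based half-open) or fixedStep WIG (1-based) track.

    The two dialects may be mixed in one file; ``track`` header lines are
    skipped.  Scores must lie in [0,1].
    """
    track = ConservationTrack(default_score=default_score)
    chrom_scores = track.scores
    wig_chrom: str | None = None
    wig_pos = 0
    wig_step = 1

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                wig_chrom = None
                continue
            if line.startswith("fixedStep"):
                params = dict(
                    part.split("=", 1) for part in line.split()[1:] if "=" in part
                )
                try:
                    wig_chrom = params["chrom"]
                    wig_pos = int(params["start"])
                    wig_step = int(params.get("step", 1))
                except (KeyError, ValueError):
                    raise TrackParseError(
                        f"line {lineno}: malformed fixedStep declaration"
                    ) from None
                chrom_scores.setdefault(wig_chrom, {})
                continue
            fields = line.split()
            if len(fields) == 1 and wig_chrom is not None:
                try:
                    value = float(fields[0])
                except ValueError:
                    raise TrackParseError(
                        f"line {lineno}: non-numeric fixedStep value"
                    ) from None
                chrom_scores[wig_chrom][wig_pos] = _check_score(value, lineno)
                wig_pos += wig_step
                continue
            if len(fields) != 4:
                raise TrackParseError(
                    f"line {lineno}: expected 4 bedGraph columns, got {len(fields)}"
                )
            chrom, start_s, end_s, value_s = fields
            try:
                start, end, value = int(start_s), int(end_s), float(value_s)
            except ValueError:
                raise TrackParseError(f"line {lineno}: malformed bedGraph fields") from None
            if end <= start:
                raise TrackParseError(
                    f"line {lineno}: empty or inverted interval {start}-{end}"
                )
            _check_score(value, lineno)
            per_chrom = chrom_scores.setdefault(chrom, {})
            # bedGraph is 0-based half-open; the track stores 1-based positions.
            for pos in range(start + 1, end + 1):
                per_chrom[pos] = value
            wig_chrom = None
    return track


def mean_conservation(model: TranscriptModel, track: ConservationTrack) -> float:
    """Base-weighted mean score over all exonic positions of a transcript."""
    if model.chrom not in track.scores:
        logger.warning(
            "transcript %s: chromosome %s absent from conservation track; "
            "using default score %g",
            model.transcript_id,
            model.chrom,
            track.default_score,
        )
    total = 0.0
    n = 0
    per_chrom = track.scores.get(model.chrom, {})
    for exon in model.exons:
        for pos in range(exon.start, exon.end + 1):
            total += per_chrom.get(pos, track.default_score)
            n += 1
    return total / n
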