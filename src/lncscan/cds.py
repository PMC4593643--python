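"""Coding-segment prediction on transcript sequences.

A transparent ORF scorer: every maximal ATG-to-stop open reading frame in the
three forward frames of the (already 5'->3' oriented) transcript sequence is
scored as

    score = ORF length (nt)
          + 25 if the start context is favorable (A or G three bases upstream
               of the ATG and G immediately after the ATG codon, both
               positions required to exist)
          + 25 if the ORF terminates at an in-frame stop codon

and the best-scoring ORF is reported with its length and the fraction of the
transcript it covers.  Long, well-anchored ORFs score high; the absolute
scale is arbitrary because the downstream classifier is trained on it.
Codons containing N never match ATG or a stop.
"""

from __future__ import annotations

from dataclasses import dataclass

START_CONTEXT_BONUS = 25.0
STOP_BONUS = 25.0
_STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class CdsPrediction:
    """Predicted coding segment, 0-based half-open on the transcript."""

    start: int
    end: int
    score: float
    cds_length: int
    cds_percentage: float


def enumerate_orfs(seq: str) -> list[tuple[int, int, bool]]:
    """All maximal ORFs in the three forward frames.

    Each ORF begins at an ATG and extends in frame to the first stop codon
    (inclusive), or to the last complete codon if no stop occurs
    (``has_stop`` False).  ATGs nested inside a reported ORF do not open a
    separate ORF.  Returns ``(start, end, has_stop)`` tuples with 0-based
    half-open coordinates, ordered by start position.
    """
    orfs: list[tuple[int, int, bool]] = []
    n = len(seq)
    for frame in range(3):
        i = frame
        while i + 3 <= n:
            if seq[i : i + 3] != "ATG":
                i += 3
                continue
            start = i
            j = i + 3
            has_stop = False
            while j + 3 <= n:
                codon = seq[j : j + 3]
                j += 3
                if codon in _STOPS:
                    has_stop = True
                    break
            orfs.append((start, j, has_stop))
            i = j
    orfs.sort()
    return orfs


def score_orf(seq: str, start: int, end: int, has_stop: bool) -> float:
    """Score one ORF under the length + context/stop bonus rule."""
    score = float(end - start)
    if (
        start >= 3
        and seq[start - 3] in "AG"
        and start + 3 < len(seq)
        and seq[start + 3] == "G"
    ):
        score += START_CONTEXT_BONUS
    if has_stop:
        score += STOP_BONUS
    return score


def predict_cds(seq: str) -> CdsPrediction:
    """Best-scoring ORF of a sequence, or an empty prediction if none.

    Ties in score are broken by longer ORF, then smaller start offset.
    """
    orfs = enumerate_orfs(seq)
    if not orfs:
        return CdsPrediction(0, 0, 0.0, 0, 0.0)
    best = max(
        orfs,
        key=lambda orf: (score_orf(seq, *orf), orf[1] - orf[0], -orf[0]),
    )
    start, end, has_stop = best
    length = end - start
    return CdsPrediction(
        start=start,
        end=end,
        score=score_orf(seq, start, end, has_stop),
        cds_length=length,
        cds_percentage=length / len(seq),
    )
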