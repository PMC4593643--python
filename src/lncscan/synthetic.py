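"""Self-contained synthetic fixtures: genome FASTA + GTFs + conservation.

The generator emulates the statistical contrast between protein-coding and
long non-coding transcripts that the classifier exploits, without any
external download:

* PCT-like transcripts are long (1-5 kb), multi-exon (4-12 exons), carry an
  embedded in-frame ATG...stop open reading frame of 100-400 codons with a
  favorable start context, and have high mean conservation (~0.7);
* LNCT-like transcripts are shorter (0.3-2 kb), have 1-3 exons, no ORF
  longer than 30 codons, and low mean conservation (~0.2).

Background base composition is uniform over A/C/G/T.  The designed spliced
sequence of every transcript is written back into the genome across its exon
boundaries (reverse-complemented for minus-strand loci), so splicing the
genome reconstitutes it exactly; gene loci never overlap.  Conservation is
drawn once per transcript (normal around the class mean, sd 0.1, clipped to
[0,1]) and held constant across its exons, which makes the expected mean
exonic conservation exactly checkable.  All randomness flows from one seeded
generator, so fixture output is byte-identical for a fixed config.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from lncscan.annotation_io import (
    Exon,
    TranscriptModel,
    reverse_complement,
    write_gtf,
)
from lncscan.cds import enumerate_orfs

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)
_G_CODONS = tuple(c for c in _NON_STOP_CODONS if c.startswith("G"))

_MIN_EXON_LEN = 20
_MAX_REPAIR_ROUNDS = 100


@dataclass
class SyntheticConfig:
    """Generation parameters; defaults encode the PCT/LNCT contrast.

    Per-class ORF policy: ``*_orf_codons`` (a (lo, hi) range, or None) embeds
    one ORF of that many codons; ``*_max_orf_codons`` (an int, or None) caps
    the longest ORF anywhere in the sequence.  The defaults give PCTs an
    embedded 100-400 codon ORF and LNCTs a 30-codon cap.  Setting both
    classes to identical parameters produces a no-signal null fixture.
    """

    n_pct: int = 100
    n_lnct: int = 100
    seed: int = 7
    pct_orf_codons: tuple[int, int] | None = (100, 400)
    pct_max_orf_codons: int | None = None
    lnct_orf_codons: tuple[int, int] | None = None
    lnct_max_orf_codons: int | None = 30
    pct_exon_count: tuple[int, int] = (4, 12)
    lnct_exon_count: tuple[int, int] = (1, 3)
    pct_transcript_length: tuple[int, int] = (1000, 5000)
    lnct_transcript_length: tuple[int, int] = (300, 2000)
    pct_consv_mean: float = 0.7
    lnct_consv_mean: float = 0.2
    consv_sd: float = 0.1
    intron_length: tuple[int, int] = (60, 500)
    intergenic_gap: tuple[int, int] = (200, 1000)
    minus_strand_prob: float = 0.5
    transcripts_per_chrom: int = 50

    def __post_init__(self) -> None:
        if self.n_pct < 0 or self.n_lnct < 0:
            raise ValueError("transcript counts must be >= 0")
        for rng_field in (
            "pct_exon_count",
            "lnct_exon_count",
            "pct_transcript_length",
            "lnct_transcript_length",
            "intron_length",
            "intergenic_gap",
        ):
            lo, hi = getattr(self, rng_field)
            if lo > hi or lo < 1:
                raise ValueError(f"{rng_field}: invalid range ({lo}, {hi})")
        for mean_field in ("pct_consv_mean", "lnct_consv_mean"):
            value = getattr(self, mean_field)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{mean_field} {value} outside [0,1]")

    def class_params(self, label: str) -> dict:
        prefix = "pct_" if label == "PCT" else "lnct_"
        return {
            "orf_codons": getattr(self, prefix + "orf_codons"),
            "max_orf_codons": getattr(self, prefix + "max_orf_codons"),
            "exon_count": getattr(self, prefix + "exon_count"),
            "transcript_length": getattr(self, prefix + "transcript_length"),
            "consv_mean": getattr(self, prefix + "consv_mean"),
        }


def null_config(**overrides) -> SyntheticConfig:
    """A no-signal config: both classes drawn from the PCT-like distribution."""
    cfg = SyntheticConfig(**overrides)
    cfg.lnct_orf_codons = cfg.pct_orf_codons
    cfg.lnct_max_orf_codons = cfg.pct_max_orf_codons
    cfg.lnct_exon_count = cfg.pct_exon_count
    cfg.lnct_transcript_length = cfg.pct_transcript_length
    cfg.lnct_consv_mean = cfg.pct_consv_mean
    return cfg


def _random_seq(rng: np.random.Generator, length: int) -> list[str]:
    return list(_BASES[rng.integers(0, 4, size=length)])


def _rand_range(rng: np.random.Generator, lohi: tuple[int, int]) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


def _embed_orf(
    rng: np.random.Generator, seq: list[str], n_codons: int
) -> None:
    """Write an ATG...stop ORF of ``n_codons`` codons (stop included) into
    ``seq`` at a random offset, with a favorable start context so the
    embedded ORF outscores any background ORF of equal length."""
    orf_len = 3 * n_codons
    max_start = len(seq) - orf_len - 1
    start = int(rng.integers(3, max_start + 1))
    codons = ["ATG"]
    codons.append(_G_CODONS[rng.integers(0, len(_G_CODONS))])
    for _ in range(n_codons - 3):
        codons.append(_NON_STOP_CODONS[rng.integers(0, len(_NON_STOP_CODONS))])
    codons.append(_STOPS[rng.integers(0, 3)])
    orf = "".join(codons)
    seq[start : start + orf_len] = list(orf)
    seq[start - 3] = "AG"[rng.integers(0, 2)]


def _cap_orfs(
    rng: np.random.Generator, seq: list[str], max_codons: int
) -> None:
    """Ensure no ORF exceeds ``max_codons`` codons by writing an in-frame
    stop at the cap boundary of each offender, re-scanning until clean."""
    limit_nt = 3 * max_codons
    for _ in range(_MAX_REPAIR_ROUNDS):
        text = "".join(seq)
        offenders = [
            (start, end) for start, end, _ in enumerate_orfs(text) if end - start > limit_nt
        ]
        if not offenders:
            return
        for start, _end in offenders:
            # make the cap'th codon a stop, so the ORF ends at exactly the cap
            pos = start + limit_nt - 3
            seq[pos : pos + 3] = list(_STOPS[rng.integers(0, 3)])
    raise RuntimeError(
        f"could not cap ORFs below {max_codons} codons after "
        f"{_MAX_REPAIR_ROUNDS} rounds; try a larger max_orf_codons"
    )


def _make_spliced_seq(
    rng: np.random.Generator, length: int, params: dict
) -> str:
    seq = _random_seq(rng, length)
    orf_range = params["orf_codons"]
    if orf_range is not None:
        lo, hi = orf_range
        # leave room for the ORF plus its upstream context
        hi = min(hi, (length - 7) // 3)
        if hi < lo:
            raise ValueError(
                f"transcript length {length} too short for a {lo}-codon ORF"
            )
        _embed_orf(rng, seq, int(rng.integers(lo, hi + 1)))
    if params["max_orf_codons"] is not None:
        _cap_orfs(rng, seq, params["max_orf_codons"])
    return "".join(seq)


def _split_exon_lengths(
    rng: np.random.Generator, total: int, k: int
) -> list[int]:
    base = min(_MIN_EXON_LEN, total // k)
    extra = rng.multinomial(total - k * base, [1.0 / k] * k)
    return [base + int(e) for e in extra]


def generate_fixture(config: SyntheticConfig, out_dir) -> dict:
    """Write genome.fa, pos.gtf, neg.gtf, consv.bedgraph, truth.tsv and
    manifest.json under ``out_dir``; returns the manifest dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # interleave classes so every chromosome carries both
    plan = [("PCT", i) for i in range(config.n_pct)] + [
        ("LNCT", i) for i in range(config.n_lnct)
    ]
    order = rng.permutation(len(plan))
    plan = [plan[i] for i in order]

    chromosomes: dict[str, list[str]] = {}
    models: dict[str, list[TranscriptModel]] = {"PCT": [], "LNCT": []}
    consv_lines: list[str] = []
    truth: list[tuple[str, str]] = []

    chrom_idx = 0
    cursor = 1
    chrom_seq: list[str] = []
    chrom_name = ""
    on_chrom = config.transcripts_per_chrom

    for label, idx in plan:
        if on_chrom >= config.transcripts_per_chrom:
            if chrom_seq:
                chromosomes[chrom_name] = chrom_seq
            chrom_idx += 1
            chrom_name = f"chr{chrom_idx}"
            chrom_seq = []
            cursor = 1
            on_chrom = 0
        params = config.class_params(label)
        tid = f"{label}_{idx:05d}"
        gid = f"gene_{tid}"

        length = _rand_range(rng, params["transcript_length"])
        k_max = min(params["exon_count"][1], max(1, length // _MIN_EXON_LEN))
        k_lo = min(params["exon_count"][0], k_max)
        k = int(rng.integers(k_lo, k_max + 1))
        exon_lengths = _split_exon_lengths(rng, length, k)
        strand = "-" if rng.random() < config.minus_strand_prob else "+"
        spliced = _make_spliced_seq(rng, length, params)

        # lay exons on the chromosome with intergenic gap + introns
        gap = _rand_range(rng, config.intergenic_gap)
        chrom_seq.extend(_random_seq(rng, gap))
        cursor += gap
        genomic = spliced if strand == "+" else reverse_complement(spliced)
        exons = []
        offset = 0
        for j, exon_len in enumerate(exon_lengths):
            if j > 0:
                intron = _rand_range(rng, config.intron_length)
                chrom_seq.extend(_random_seq(rng, intron))
                cursor += intron
            exons.append(Exon(chrom_name, cursor, cursor + exon_len - 1, strand))
            chrom_seq.extend(genomic[offset : offset + exon_len])
            cursor += exon_len
            offset += exon_len

        model = TranscriptModel(tid, gid, chrom_name, strand, exons)
        models[label].append(model)
        truth.append((tid, label))

        consv = float(np.clip(rng.normal(params["consv_mean"], config.consv_sd), 0, 1))
        for exon in exons:
            consv_lines.append(
                f"{chrom_name}\t{exon.start - 1}\t{exon.end}\t{consv:.4f}"
            )
        on_chrom += 1

    if chrom_seq:
        chromosomes[chrom_name] = chrom_seq

    genome_path = out_dir / "genome.fa"
    with open(genome_path, "w") as fh:
        for name, seq_list in chromosomes.items():
            fh.write(f">{name}\n")
            text = "".join(seq_list)
            for i in range(0, len(text), 80):
                fh.write(text[i : i + 80] + "\n")

    pos_path = out_dir / "pos.gtf"
    neg_path = out_dir / "neg.gtf"
    write_gtf(models["PCT"], pos_path)
    write_gtf(models["LNCT"], neg_path)

    consv_path = out_dir / "consv.bedgraph"
    with open(consv_path, "w") as fh:
        fh.write("\n".join(consv_lines) + ("\n" if consv_lines else ""))

    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("transcript_id\tlabel\n")
        for tid, label in truth:
            fh.write(f"{tid}\t{label}\n")

    manifest = {
        "seed": config.seed,
        "n_pct": config.n_pct,
        "n_lnct": config.n_lnct,
        "config": _jsonable(asdict(config)),
        "files": {
            "genome": genome_path.name,
            "pos_gtf": pos_path.name,
            "neg_gtf": neg_path.name,
            "conservation": consv_path.name,
            "truth": truth_path.name,
        },
        "out_dir": str(out_dir),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def truth_table(manifest: dict) -> list[tuple[str, str]]:
    """(transcript_id, label) rows of a generated fixture."""
    path = Path(manifest["out_dir"]) / manifest["files"]["truth"]
    if not path.exists():
        raise FileNotFoundError(f"truth table {path} missing")
    rows = []
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            tid, label = line.rstrip("\n").split("\t")
            rows.append((tid, label))
    return rows
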