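"""Synthetic labeled transcript datasets with planted coding signals.

Positives emulate bifunctional lncRNAs: an i.i.d. nucleotide
background at a chosen GC content carrying exactly one planted open
reading frame — a Kozak-like hexamer (default GCCATG, whose terminal
ATG is the start codon), a run of stop-free sense codons, and a single
stop codon. Negatives are the same background with no ORF longer than
half the planted minimum and with elevated stop-codon (TAA/TGA/TAG)
density, mimicking the stop-rich composition of non-coding sequence.

The generator exists so the classifier and the interpretability suite
can be exercised end to end without any external database: the signal
it plants (start codons, Kozak context, stop-codon depletion inside
ORFs) is exactly the signal the attention analyses are expected to
rediscover.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import LabeledDataset, NucleotideSequence, write_fasta

STOP_CODONS = ("TAA", "TGA", "TAG")
ALPHABET = np.array(list("ACGT"))


@dataclass
class SyntheticConfig:
    n_pos: int = 200
    n_neg: int = 200
    length_range: tuple[int, int] = (200, 1500)
    gc_content: float = 0.45
    kozak_motif: str = "GCCATG"
    orf_min_codons: int = 30
    neg_stop_boost: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must lie in (0, 1)")
        min_needed = 3 * self.orf_min_codons + 6
        if self.length_range[0] < min_needed:
            raise ValueError(
                f"minimum length {self.length_range[0]} too short for a "
                f"{self.orf_min_codons}-codon ORF (needs >= {min_needed} nt)"
            )
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range minimum exceeds maximum")
        if self.neg_stop_boost < 1:
            raise ValueError("neg_stop_boost must be >= 1")

    @property
    def nucleotide_probs(self) -> np.ndarray:
        gc = self.gc_content
        return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T


def _random_background(rng: np.random.Generator, length: int, probs: np.ndarray) -> np.ndarray:
    return rng.choice(4, size=length, p=probs)


def _codes(s: str) -> np.ndarray:
    return np.array(["ACGT".index(c) for c in s])


def _to_str(codes: np.ndarray) -> str:
    return "".join(ALPHABET[codes])


def _sense_codon(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    while True:
        c = rng.choice(4, size=3, p=probs)
        if _to_str(c) not in STOP_CODONS:
            return c


def _stop_for_negative(rng: np.random.Generator, prev_base: int | None) -> np.ndarray:
    """A stop codon that cannot fabricate a start codon at its boundary.

    Placing TGA directly after an A writes the trigram ATG into the
    sequence; negatives must differ from positives in stop density and
    ORF content, not in spurious start-codon content, so after an A
    only TAA/TAG are used.
    """
    choices = ("TAA", "TAG") if prev_base == 0 else STOP_CODONS
    return _codes(choices[rng.integers(len(choices))])


def _orf_spans(seq: str, min_codons: int) -> list[tuple[int, int]]:
    """0-based [start, end) spans of ATG..stop ORFs with >= min_codons sense codons."""
    spans = []
    L = len(seq)
    for frame in range(3):
        pos = frame
        while pos + 3 <= L:
            if seq[pos : pos + 3] == "ATG":
                q = pos + 3
                while q + 3 <= L and seq[q : q + 3] not in STOP_CODONS:
                    q += 3
                n_codons = (q - pos) // 3
                if q + 3 <= L and n_codons >= min_codons:
                    spans.append((pos, q + 3))
                pos = q + 3
            else:
                pos += 3
    return spans


def _disrupt_orfs(codes: np.ndarray, min_codons: int, rng: np.random.Generator) -> np.ndarray:
    """Insert stop codons mid-ORF until no ORF reaches min_codons."""
    for _ in range(200):  # convergence guard; each pass shortens some ORF
        spans = _orf_spans(_to_str(codes), min_codons)
        if not spans:
            return codes
        for start, end in spans:
            n_codons = (end - start) // 3 - 1
            mid = start + 3 * int(rng.integers(1, max(2, n_codons // 2 + 1)))
            prev = int(codes[mid - 1]) if mid > 0 else None
            codes[mid : mid + 3] = _stop_for_negative(rng, prev)
    raise RuntimeError("failed to disrupt ORFs (should not happen)")


def generate_dataset(config: SyntheticConfig) -> tuple[LabeledDataset, pd.DataFrame]:
    """Generate positives and negatives plus a ground-truth table.

    The truth table records, per sequence, the label and the planted
    ORF coordinates (1-based, inclusive; NA for negatives). Fully
    reproducible under the config seed.
    """
    rng = np.random.default_rng(config.seed)
    probs = config.nucleotide_probs
    kozak = _codes(config.kozak_motif)
    seqs: list[NucleotideSequence] = []
    labels: dict[str, int] = {}
    truth_rows = []

    for i in range(config.n_pos):
        sid = f"pos_{i + 1:04d}"
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        codes = _random_background(rng, length, probs)
        # planted ORF: kozak (ATG at its end), sense codons, one stop
        max_codons = (length - len(kozak) - 3) // 3 - 1
        n_codons = int(rng.integers(config.orf_min_codons,
                                    max(config.orf_min_codons + 1, min(max_codons, 3 * config.orf_min_codons))))
        insert_len = len(kozak) + 3 * n_codons + 3
        pos0 = int(rng.integers(0, length - insert_len + 1))
        piece = [kozak]
        for _ in range(n_codons):
            piece.append(_sense_codon(rng, probs))
        piece.append(_codes(STOP_CODONS[rng.integers(len(STOP_CODONS))]))
        codes[pos0 : pos0 + insert_len] = np.concatenate(piece)
        seq = _to_str(codes)
        orf_start = pos0 + len(kozak) - 3  # the ATG inside the kozak motif
        orf_end = pos0 + insert_len - 1
        seqs.append(NucleotideSequence(sid, seq))
        labels[sid] = 1
        truth_rows.append({"id": sid, "label": 1,
                           "orf_start": orf_start + 1, "orf_end": orf_end + 1})

    max_orf = max(1, config.orf_min_codons // 2)
    pA, pG, pT = probs[0], probs[2], probs[3]
    base_rate = pT * pA * (pA + 2 * pG)       # P(stop triplet) per position
    # Planted stops are AT-rich (mean GC 0.21 given the boundary rule);
    # draw the negative background GC-shifted so the finished sequence
    # still matches the configured composition — both classes must
    # differ in stop/ORF structure, not in GC.
    f_stop = 3.0 * (config.neg_stop_boost - 1.0) * base_rate
    stop_gc = pA * (1 / 6) + (1 - pA) * (2 / 9)
    gc_bg = min(0.99, max(0.01, (config.gc_content - f_stop * stop_gc) / (1 - f_stop)))
    neg_probs = np.array([(1 - gc_bg) / 2, gc_bg / 2, gc_bg / 2, (1 - gc_bg) / 2])
    for i in range(config.n_neg):
        sid = f"neg_{i + 1:04d}"
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        codes = _random_background(rng, length, neg_probs)
        # boost stop-codon density: plant extra stops at random codon slots
        n_extra = int(round((config.neg_stop_boost - 1.0) * base_rate * length))
        if n_extra > 0:
            starts = rng.choice(max(1, length - 3), size=n_extra, replace=False) \
                if length - 3 >= n_extra else np.arange(0, length - 3, 3)
            for s0 in starts:
                prev = int(codes[s0 - 1]) if s0 > 0 else None
                codes[s0 : s0 + 3] = _stop_for_negative(rng, prev)
        codes = _disrupt_orfs(codes, max_orf, rng)
        seqs.append(NucleotideSequence(sid, _to_str(codes)))
        labels[sid] = 0
        truth_rows.append({"id": sid, "label": 0, "orf_start": pd.NA, "orf_end": pd.NA})

    return LabeledDataset(seqs, labels), pd.DataFrame(truth_rows)


def write_dataset(dataset: LabeledDataset, truth: pd.DataFrame, outdir: str | Path) -> None:
    """Write positives.fasta, negatives.fasta, truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pos = [s for s in dataset.sequences if dataset.labels[s.id] == 1]
    neg = [s for s in dataset.sequences if dataset.labels[s.id] == 0]
    write_fasta(pos, outdir / "positives.fasta")
    write_fasta(neg, outdir / "negatives.fasta")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False, na_rep="NA")
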