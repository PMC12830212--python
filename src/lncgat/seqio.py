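"""Sequence input/output and tokenization.

Reads transcript sequences from FASTA, validates and normalizes the
alphabet (RNA -> DNA, case-folding), and segments sequences into
overlapping k-mers, which are the nodes of the downstream De Bruijn
graph. Also reads/writes the small tabular side files (labels,
predictions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Sentinel emitted by :func:`tokenize_kmers` for windows containing N.
#: Ambiguous windows must not create graph nodes or edges, but their
#: positions are kept so adjacency is never falsified across a gap.
SKIP = "skip"

_VALID = set("ACGTN")
_RNA_TABLE = str.maketrans("U", "T")


@dataclass(frozen=True)
class NucleotideSequence:
    """A validated transcript: identifier plus residues over {A,C,G,T,N}."""

    id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class LabeledDataset:
    """Sequences paired with binary labels (1 = bifunctional)."""

    sequences: list[NucleotideSequence]
    labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sequences]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sequence ids in dataset")
        missing = [i for i in ids if i not in self.labels]
        if missing:
            raise ValueError(f"sequences without labels: {missing[:5]}")
        for sid, lab in self.labels.items():
            if lab not in (0, 1):
                raise ValueError(f"label for {sid!r} must be 0 or 1, got {lab!r}")

    def subset(self, ids: Iterable[str]) -> "LabeledDataset":
        keep = set(ids)
        return LabeledDataset(
            [s for s in self.sequences if s.id in keep],
            {i: l for i, l in self.labels.items() if i in keep},
        )

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def label_vector(self) -> list[int]:
        return [self.labels[s.id] for s in self.sequences]


def normalize_sequence(raw: str) -> str:
    """Uppercase, map U->T, reject anything outside {A,C,G,T,U,N}.

    N is retained here; ambiguity is resolved at tokenization, where
    windows containing N become skip markers.
    """
    if not raw:
        raise ValueError("empty sequence")
    out = raw.upper().translate(_RNA_TABLE)
    for pos, ch in enumerate(out):
        if ch not in _VALID:
            raise ValueError(
                f"invalid character {raw[pos]!r} at position {pos} "
                "(expected A/C/G/T/U/N, case-insensitive)"
            )
    return out


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Parse a FASTA file into validated sequences, in file order.

    Ids are the first whitespace-delimited header token. Duplicate ids
    and malformed records raise; an empty file yields an empty list
    with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        raise ValueError(f"{path}: sequence data before first '>' header")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        logger.warning("FASTA file %s contains no records", path)
        return []
    seqs: list[NucleotideSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seqs.append(NucleotideSequence(rec.id, normalize_sequence(str(rec.seq))))
    return seqs


def write_fasta(seqs: Sequence[NucleotideSequence], path: str | Path, width: int = 60) -> None:
    """Write sequences to FASTA, wrapping at `width` columns."""
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def tokenize_kmers(seq: NucleotideSequence, k: int) -> list[str]:
    """Return the L-k+1 overlapping k-mer windows, 5'->3'.

    Windows containing N are replaced by the :data:`SKIP` sentinel so
    that downstream edge construction never spans an ambiguous base.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if seq.length < k:
        raise ValueError(
            f"sequence {seq.id!r} (length {seq.length}) shorter than k={k}"
        )
    res = seq.residues
    return [
        res[i : i + k] if "N" not in res[i : i + k] else SKIP
        for i in range(seq.length - k + 1)
    ]


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV `id<TAB>label`; a header row is optional."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    # tolerate a header line such as "id\tlabel"
    if not df.iloc[0, 1].strip().lstrip("+-").isdigit():
        df = df.iloc[1:]
    labels: dict[str, int] = {}
    for _, row in df.iterrows():
        sid, lab = row.iloc[0].strip(), int(row.iloc[1])
        if sid in labels:
            raise ValueError(f"duplicate id {sid!r} in label file")
        labels[sid] = lab
    return labels


def write_predictions(rows: Sequence[dict], path: str | Path) -> None:
    """Write a predictions table: id, probability, label (NA + reason allowed)."""
    df = pd.DataFrame(rows, columns=["id", "probability", "label", "reason"])
    df["reason"] = df["reason"].fillna("")
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
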