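"""Sequence input, normalization, and k-mer occurrence-position extraction.

A sequence ``S = s1 s2 ... sN`` over a finite alphabet is reduced, per k-mer
``x``, to the set of 1-based positions at which ``x`` occurs (overlaps
included).  These integer position sets are the 1-D point clouds on which all
downstream filtration invariants are computed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

DNA_ALPHABET: tuple[str, ...] = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SequenceRecord:
    """One named, normalized sequence (uppercase DNA; U already mapped to T)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record has an empty id")
        if not self.seq:
            raise ValueError(f"sequence record {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class KmerSpec:
    """Alphabet and word length defining the k-mer vocabulary.

    The alphabet order is significant: it fixes the lexicographic layout of
    the feature vector, so two runs with the same spec produce identically
    indexed representations.
    """

    alphabet: tuple[str, ...] = DNA_ALPHABET
    k: int = 1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValueError("alphabet symbols must be distinct")


@dataclass(frozen=True)
class PositionSet:
    """Strictly increasing 1-based occurrence positions of one k-mer."""

    kmer: str
    positions: tuple[int, ...]
    seq_id: str = ""

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)


def normalize_sequence(raw: str) -> str:
    """Uppercase and transcribe RNA to DNA (U -> T); other symbols kept verbatim.

    Ambiguity codes (N, R, Y, ...) are preserved here; windows containing them
    simply match no canonical k-mer later.
    """
    if not raw:
        raise ValueError("cannot normalize an empty sequence")
    return raw.upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into normalized records, in file order.

    Wrapped sequence lines are concatenated; whitespace is stripped by the
    parser.  Duplicate ids and empty records are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).strip()
        if not seq:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        records.append(SequenceRecord(id=rec.id, seq=normalize_sequence(seq)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_labels(path: str | Path, header: bool = False) -> dict[str, str]:
    """Read a two-column TSV (sequence id, class label) into a mapping."""
    df = pd.read_csv(path, sep="\t", header=0 if header else None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"label table {path} needs two columns (id, label)")
    ids, labels = df.iloc[:, 0], df.iloc[:, 1]
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValueError(f"duplicate id {dup!r} in label table {path}")
    return dict(zip(ids, labels))


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, lab in labels.items():
            fh.write(f"{sid}\t{lab}\n")


def enumerate_kmers(spec: KmerSpec) -> list[str]:
    """All ``|A|^k`` words in lexicographic order of the alphabet as given."""
    return ["".join(w) for w in itertools.product(spec.alphabet, repeat=spec.k)]


def kmer_positions(seq: str, kmer: str, k: int | None = None, seq_id: str = "") -> PositionSet:
    """1-based positions of every (possibly overlapping) occurrence of ``kmer``."""
    if k is None:
        k = len(kmer)
    if len(kmer) != k or k < 1:
        raise ValueError(f"kmer {kmer!r} does not have length k={k}")
    positions = tuple(
        i + 1 for i in range(len(seq) - k + 1) if seq[i : i + k] == kmer
    )
    return PositionSet(kmer=kmer, positions=positions, seq_id=seq_id)


def all_kmer_positions(seq: str, spec: KmerSpec, seq_id: str = "") -> dict[str, PositionSet]:
    """Position sets for every word in the vocabulary, in one pass over ``seq``.

    Windows containing symbols outside the alphabet match nothing.
    """
    k = spec.k
    hits: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        word = seq[i : i + k]
        hits.setdefault(word, []).append(i + 1)
    return {
        w: PositionSet(kmer=w, positions=tuple(hits.get(w, ())), seq_id=seq_id)
        for w in enumerate_kmers(spec)
    }
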