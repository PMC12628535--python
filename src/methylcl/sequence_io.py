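"""Reading, validating, padding and k-mer tokenizing fixed-length RNA windows.

Datasets for RNA-methylation site prediction come as balanced sets of short
windows (41 nt by default) centred on a candidate modification site; windows
shorter than the standard length are gap-padded with "-" at the 3' end.
This module turns such records into the token stream consumed by the
primary-view embedding backend: overlapping k-mers bracketed by [CLS]/[SEP],
indexed against a vocabulary of all 4^k k-mers plus five special tokens.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

from Bio import SeqIO

DEFAULT_LENGTH = 41
ALPHABET = set("ACGUT-")
SPECIAL_TOKENS = ("[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]")
VALID_K = (3, 4, 5, 6)


class SequenceValidationError(ValueError):
    """Raised when a record violates the alphabet or length contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """One labelled fixed-length RNA window.

    label 1 marks a window centred on a modified site, 0 an unmodified one.
    """

    id: str
    seq: str
    label: int

    def __post_init__(self):
        bad = set(self.seq) - ALPHABET
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r}: illegal characters {sorted(bad)}"
            )
        if self.label not in (0, 1):
            raise SequenceValidationError(
                f"record {self.id!r}: label must be 0 or 1, got {self.label!r}"
            )


@dataclass(frozen=True)
class TokenSequence:
    """k-mer tokens bracketed by [CLS]/[SEP] plus their vocabulary indices."""

    tokens: tuple
    ids: tuple
    k: int


def _check_k(k: int) -> None:
    if k not in VALID_K:
        raise ValueError(f"k must be one of {VALID_K}, got {k}")


def pad_sequence(seq: str, target_len: int = DEFAULT_LENGTH) -> str:
    """Gap-pad `seq` to `target_len` by appending '-' characters.

    Sequences longer than the target are an error: silent truncation would
    shift the window relative to the candidate site.
    """
    if len(seq) > target_len:
        raise ValueError(
            f"sequence of length {len(seq)} exceeds target length {target_len}"
        )
    return seq + "-" * (target_len - len(seq))


def build_vocab(k: int) -> dict:
    """Deterministic token -> id map: 5 special tokens then all 4^k k-mers.

    k-mers use the DNA alphabet (U is mapped to T before lookup), enumerated
    in lexicographic ACGT order; total size 4**k + 5.
    """
    _check_k(k)
    vocab = {tok: i for i, tok in enumerate(SPECIAL_TOKENS)}
    for i, kmer in enumerate(product("ACGT", repeat=k)):
        vocab["".join(kmer)] = len(SPECIAL_TOKENS) + i
    return vocab


def kmerize(seq: str, k: int, vocab: dict | None = None) -> TokenSequence:
    """Slide a width-k window (stride 1) over `seq` and bracket with [CLS]/[SEP].

    Output length is len(seq) - k + 3. U is read as T for vocabulary lookup;
    any k-mer containing a gap maps to [UNK].
    """
    _check_k(k)
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    bad = set(seq) - ALPHABET
    if bad:
        raise SequenceValidationError(f"illegal characters {sorted(bad)}")
    if vocab is None:
        vocab = build_vocab(k)
    seq = seq.upper()
    tokens = ["[CLS]"]
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        tokens.append("[UNK]" if "-" in kmer else kmer)
    tokens.append("[SEP]")
    # tokens keep the input alphabet; the vocabulary is DNA, so U reads as T
    ids = tuple(
        vocab[t if t in vocab else t.replace("U", "T")] for t in tokens
    )
    return TokenSequence(tokens=tuple(tokens), ids=ids, k=k)


def _parse_header(header: str) -> tuple[str, int]:
    """Label convention: FASTA id suffix '|1' / '|0'."""
    name, sep, tag = header.partition("|")
    if sep != "|" or tag not in ("0", "1"):
        raise SequenceValidationError(
            f"FASTA header {header!r} lacks a '|0' or '|1' label suffix"
        )
    return name, int(tag)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read labelled records from FASTA; labels encoded as '>id|label'."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        name, label = _parse_header(entry.id)
        records.append(SequenceRecord(id=name, seq=str(entry.seq).upper(), label=label))
    return records


def read_tsv(path: str | Path) -> list[SequenceRecord]:
    """Read two-column (label TAB sequence) records; ids are row numbers."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SequenceValidationError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            label_s, seq = parts
            if label_s not in ("0", "1"):
                raise SequenceValidationError(
                    f"{path}:{lineno}: label must be 0 or 1, got {label_s!r}"
                )
            records.append(
                SequenceRecord(id=f"row{lineno}", seq=seq.upper(), label=int(label_s))
            )
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}|{r.label}\n{r.seq}\n")


def write_tsv(records: list[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.label}\t{r.seq}\n")


def load_records(path: str | Path) -> list[SequenceRecord]:
    """Dispatch on extension: .fa/.fasta -> FASTA, .tsv/.txt -> two-column."""
    suffix = Path(path).suffix.lower()
    if suffix in (".fa", ".fasta", ".fna"):
        return read_fasta(path)
    return read_tsv(path)
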