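"""Sequence and interval primitives.

Nucleotide sequences are normalised to the 5-letter alphabet {A,C,G,T,N}:
lowercase is uppercased and IUPAC ambiguity codes other than N are mapped to N
(assemblies routinely contain R/Y/S/W/... positions that carry no usable signal
for homology mining). Internal coordinates are 0-based half-open throughout;
report writers convert to 1-based inclusive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger("chemomine")

NUC_ALPHABET = set("ACGTN")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*-")  # '-' permitted in aligned rows

_IUPAC_AMBIG = set("RYSWKMBDHVU")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Standard genetic code (NCBI table 1).
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(("TAA", "TAG", "TGA"))


class FastaFormatError(ValueError):
    """Raised on malformed FASTA input (empty record, duplicate id, junk)."""


def normalize_nuc(residues: str) -> str:
    """Uppercase and collapse non-ACGTN symbols (incl. gaps, IUPAC codes) to N."""
    up = residues.upper()
    if set(up) <= NUC_ALPHABET:
        return up
    ambig = {c for c in up if c in _IUPAC_AMBIG}
    if ambig:
        logger.warning("IUPAC ambiguity codes %s converted to N", sorted(ambig))
    return "".join(c if c in NUC_ALPHABET else "N" for c in up)


@dataclass(frozen=True)
class NucSequence:
    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"empty nucleotide sequence {self.id!r}")
        norm = normalize_nuc(self.residues)
        if norm != self.residues:
            object.__setattr__(self, "residues", norm)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ProtSequence:
    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"empty protein sequence {self.id!r}")
        up = self.residues.upper()
        bad = set(up) - AA_ALPHABET
        if bad:
            raise ValueError(f"invalid amino-acid symbols {sorted(bad)} in {self.id!r}")
        object.__setattr__(self, "residues", up)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named scaffold."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start},{self.end}) on {self.seq_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GapRun:
    interval: GenomicInterval
    length: int


def read_fasta(path, kind: str = "nuc"):
    """Read a multi-FASTA file.

    kind='nuc' yields NucSequence (normalised), kind='prot' yields ProtSequence.
    Record ids are the first whitespace-delimited token; duplicates are rejected.
    """
    path = Path(path)
    records = []
    seen = set()
    header = None
    chunks: list[str] = []
    ncls = {"nuc": NucSequence, "prot": ProtSequence}[kind]

    def flush():
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaFormatError(f"empty record {header!r} in {path}")
        parts = header.split(None, 1)
        rid = parts[0]
        desc = parts[1] if len(parts) > 1 else ""
        if rid in seen:
            raise FastaFormatError(f"duplicate id {rid!r} in {path}")
        seen.add(rid)
        if kind == "nuc":
            seq = seq.replace("-", "N")
        records.append(ncls(id=rid, residues=seq, description=desc))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FastaFormatError(f"header without id in {path}")
                chunks = []
            else:
                if header is None:
                    raise FastaFormatError(f"non-FASTA content in {path}: {line[:40]!r}")
                chunks.append(line.replace(" ", ""))
    flush()
    if not records:
        raise FastaFormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable, path, width: int = 60) -> None:
    """Write records as multi-FASTA wrapped at `width` columns."""
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.id}{desc}\n")
            res = rec.residues
            for i in range(0, len(res), width):
                fh.write(res[i : i + width] + "\n")


def revcomp(seq: NucSequence) -> NucSequence:
    return NucSequence(
        id=seq.id, residues=seq.residues.translate(_COMPLEMENT)[::-1],
        description=seq.description,
    )


def revcomp_str(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


def translate_str(residues: str, frame: int = 0) -> str:
    """Translate a +strand nucleotide string in the given frame (0..2).

    Codons containing N render X; stops render '*'.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0..2, got {frame}")
    out = []
    n = len(residues)
    for i in range(frame, n - 2, 3):
        codon = residues[i : i + 3]
        out.append(CODON_TABLE.get(codon, "X"))
    return "".join(out)


def translate(seq: NucSequence, frame: int = 0, strand: str = "+") -> ProtSequence:
    res = seq.residues if strand == "+" else revcomp_str(seq.residues)
    aa = translate_str(res, frame)
    if not aa:
        raise ValueError(f"sequence {seq.id!r} too short to translate in frame {frame}")
    return ProtSequence(id=f"{seq.id}|{strand}{frame}", residues=aa)


def find_gap_runs(seq: NucSequence, min_len: int = 1) -> list[GapRun]:
    """Maximal runs of N with length >= min_len, sorted by start."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    runs = []
    res = seq.residues
    i = 0
    n = len(res)
    while i < n:
        if res[i] == "N":
            j = i
            while j < n and res[j] == "N":
                j += 1
            if j - i >= min_len:
                runs.append(
                    GapRun(interval=GenomicInterval(seq.id, i, j, "+"), length=j - i)
                )
            i = j
        else:
            i += 1
    return runs
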