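"""Synthetic reference genomes and local sequence-context lookup.

Coordinates are 1-based and inclusive throughout the package, matching VCF
``POS``. A classification window that runs off a contig end or contains an
``N`` is *unavailable*: :func:`get_context` returns ``None`` for it and the
affected mutation is counted as unclassifiable rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ReferenceGenome",
    "generate_reference",
    "get_context",
    "read_fasta",
    "write_fasta",
]

_ALPHABET = frozenset("ACGTN")


@dataclass
class ReferenceGenome:
    """An ordered collection of named contig sequences over {A,C,G,T,N}."""

    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("genome must contain at least one contig")
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} has an empty sequence")
            extra = set(seq) - _ALPHABET
            if extra:
                raise ValueError(f"contig {name!r} contains non-ACGTN symbols: {sorted(extra)}")

    @property
    def contig_names(self) -> list[str]:
        return list(self.contigs)

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def sequence(self, contig: str) -> str:
        try:
            return self.contigs[contig]
        except KeyError:
            raise KeyError(f"unknown contig {contig!r}") from None

    def base(self, contig: str, pos: int) -> str:
        """Reference base at 1-based position ``pos``."""
        seq = self.sequence(contig)
        if not 1 <= pos <= len(seq):
            raise IndexError(f"position {pos} outside contig {contig!r} (length {len(seq)})")
        return seq[pos - 1]

    def slice(self, contig: str, start: int, end: int) -> str:
        """Reference bases on the 1-based inclusive interval [start, end]."""
        seq = self.sequence(contig)
        if start < 1 or end > len(seq) or start > end:
            raise IndexError(f"interval [{start},{end}] outside contig {contig!r}")
        return seq[start - 1 : end]

    def replace(self, contig: str, start: int, fragment: str) -> None:
        """Overwrite reference bases starting at 1-based ``start`` (in place)."""
        seq = self.sequence(contig)
        if start < 1 or start + len(fragment) - 1 > len(seq):
            raise IndexError("replacement fragment exceeds contig bounds")
        if set(fragment) - _ALPHABET:
            raise ValueError("fragment contains non-ACGTN symbols")
        self.contigs[contig] = seq[: start - 1] + fragment + seq[start - 1 + len(fragment) :]


def generate_reference(
    total_length: int,
    n_contigs: int = 1,
    gc_fraction: float = 0.41,
    seed: int = 0,
) -> ReferenceGenome:
    """Draw an i.i.d. random genome with the given GC content.

    Bases are sampled independently with P(G) = P(C) = ``gc_fraction``/2 and
    P(A) = P(T) = (1 - ``gc_fraction``)/2. Contig lengths partition
    ``total_length`` as evenly as possible. The same arguments always produce
    the same genome.
    """
    if total_length <= 0:
        raise ValueError("total_length must be positive")
    if n_contigs <= 0:
        raise ValueError("n_contigs must be positive")
    if total_length < n_contigs:
        raise ValueError("total_length must be at least n_contigs")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    base, rem = divmod(total_length, n_contigs)
    lengths = [base + (1 if i < rem else 0) for i in range(n_contigs)]
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    contigs: dict[str, str] = {}
    for i, length in enumerate(lengths, start=1):
        draws = rng.choice(4, size=length, p=p)
        contigs[f"chr{i}"] = alphabet[draws].tobytes().decode("ascii")
    return ReferenceGenome(contigs)


def get_context(genome: ReferenceGenome, contig: str, pos: int, flank: int = 1) -> str | None:
    """Reference window of length ``2*flank + 1`` centred on ``pos``.

    Returns ``None`` (an *unavailable* context) when the window would run off
    a contig end or contains an ``N``; raises for an unknown contig or a
    position outside the contig.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    seq = genome.sequence(contig)
    if not 1 <= pos <= len(seq):
        raise IndexError(f"position {pos} outside contig {contig!r} (length {len(seq)})")
    lo, hi = pos - flank, pos + flank
    if lo < 1 or hi > len(seq):
        return None
    window = seq[lo - 1 : hi]
    if "N" in window:
        return None
    return window


def read_fasta(path) -> ReferenceGenome:
    """Read a plain-text FASTA file; sequences are uppercased on read."""
    contigs: dict[str, str] = {}
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        if rec.id in contigs:
            raise ValueError(f"duplicate contig id {rec.id!r} in {path}")
        contigs[rec.id] = str(rec.seq).upper()
    if n == 0:
        raise ValueError(f"no FASTA records found in {path}")
    return ReferenceGenome(contigs)


def write_fasta(genome: ReferenceGenome, path, width: int = 60) -> None:
    """Write the genome as FASTA with ``width``-column line wrapping."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.contigs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
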