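"""Per-clone variant I/O and channel/count matrix I/O.

Variant calls enter the pipeline as plain VCF v4.x files, one per clone.
Genotype and quality fields are deliberately ignored: a passing record means
the clone carries the mutation (upstream caller thresholds are out of scope
here). Only records whose FILTER is ``PASS`` or ``.`` are accepted; the rest
are dropped with a logged reason. Indels are re-anchored and left-aligned
against the reference before classification, since VCF does not guarantee a
left-aligned representation and the indel channels depend on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .channels import ChannelAxis, axis_for_size
from .reference import ReferenceGenome

__all__ = [
    "MutationRecord",
    "read_vcf",
    "write_vcf",
    "left_align",
    "read_catalog",
    "read_matrix",
    "write_matrix",
]

log = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")


@dataclass(frozen=True, order=True)
class MutationRecord:
    """One variant call: SNV, anchored indel, or length-2 MNV (doublet).

    ``pos`` is the 1-based VCF POS. Insertions and deletions use the VCF
    anchored representation (``ref``/``alt`` share their first base). The
    identity key for all set logic is ``(contig, pos, ref, alt)`` — the
    carrying clone is deliberately not part of it.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    clone_id: str = ""

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if set(self.ref) - _ACGT or set(self.alt) - _ACGT:
            raise ValueError(f"ref/alt must be ACGT strings, got {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.pos < 1:
            raise ValueError("pos must be 1-based positive")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_insertion(self) -> bool:
        return len(self.ref) == 1 < len(self.alt) and self.alt[0] == self.ref

    @property
    def is_deletion(self) -> bool:
        return len(self.alt) == 1 < len(self.ref) and self.ref[0] == self.alt

    @property
    def is_mnv(self) -> bool:
        return len(self.ref) == len(self.alt) > 1

    @property
    def indel_length(self) -> int:
        """Length of the inserted/deleted fragment (0 for substitutions)."""
        return abs(len(self.alt) - len(self.ref))

    def with_clone(self, clone_id: str) -> "MutationRecord":
        return MutationRecord(self.contig, self.pos, self.ref, self.alt, clone_id)


def read_vcf(path, clone_id: str) -> list[MutationRecord]:
    """Read one clone's variant calls from a VCF v4.x file.

    Multi-allelic sites are split into one record per ALT. Symbolic alleles,
    breakends, non-ACGT alleles and non-passing FILTER values are dropped
    (each drop is logged at WARNING with its reason).
    """
    records: list[MutationRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for site in vcf:
            filters = list(site.filter.keys())
            if filters and filters != ["PASS"]:
                log.warning("%s:%s dropped: FILTER=%s", site.contig, site.pos, ",".join(filters))
                continue
            if site.alts is None:
                continue
            ref = (site.ref or "").upper()
            for alt in site.alts:
                alt = (alt or "").upper()
                if not ref or not alt or set(ref) - _ACGT or set(alt) - _ACGT:
                    log.warning(
                        "%s:%s dropped: unsupported allele %r>%r", site.contig, site.pos, ref, alt
                    )
                    continue
                if ref == alt:
                    log.warning("%s:%s dropped: ref==alt", site.contig, site.pos)
                    continue
                records.append(MutationRecord(site.contig, site.pos, ref, alt, clone_id))
    return records


def write_vcf(records, path, contig_lengths: dict[str, int]) -> None:
    """Write records as a minimal valid VCF v4.2 with ``##contig`` headers.

    Output is sorted by (contig order as given in ``contig_lengths``, pos).
    """
    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    order = {name: i for i, name in enumerate(contig_lengths)}
    for rec in records:
        if rec.contig not in order:
            raise ValueError(f"record on unknown contig {rec.contig!r}")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in sorted(records, key=lambda r: (order[r.contig], r.pos, r.ref, r.alt)):
            site = out.new_record(
                contig=rec.contig, start=rec.pos - 1, alleles=(rec.ref, rec.alt)
            )
            out.write(site)


def left_align(record: MutationRecord, genome: ReferenceGenome) -> MutationRecord:
    """Left-align an anchored insertion or deletion against the reference.

    Substitutions are returned unchanged. Raises if the record's REF does not
    match the reference sequence.
    """
    seq = genome.sequence(record.contig)
    if genome.slice(record.contig, record.pos, record.pos + len(record.ref) - 1) != record.ref:
        raise ValueError(
            f"REF mismatch at {record.contig}:{record.pos} "
            f"(record {record.ref!r} vs reference)"
        )
    if record.is_deletion:
        frag = record.ref[1:]
        i = record.pos  # 0-based index of first deleted base
        L = len(frag)
        while i >= 2 and seq[i - 1] == seq[i + L - 1]:
            i -= 1
        pos = i
        frag = seq[i : i + L]
        return MutationRecord(record.contig, pos, seq[pos - 1] + frag, seq[pos - 1], record.clone_id)
    if record.is_insertion:
        frag = record.alt[1:]
        pos = record.pos
        while pos >= 2 and frag[-1] == seq[pos - 1]:
            frag = seq[pos - 1] + frag[:-1]
            pos -= 1
        return MutationRecord(record.contig, pos, seq[pos - 1], seq[pos - 1] + frag, record.clone_id)
    return record


def read_matrix(path) -> pd.DataFrame:
    """Read a channels-by-samples TSV matrix into a DataFrame.

    Rows are reordered into the canonical channel order of the axis inferred
    from the row count; missing or unknown channel names are an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    axis = axis_for_size(len(df))
    return _canonicalize(df, axis)


def _canonicalize(df: pd.DataFrame, axis: ChannelAxis) -> pd.DataFrame:
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicated channel names: {dupes}")
    if df.columns.has_duplicates:
        raise ValueError("duplicated sample/signature names")
    missing = [c for c in axis.channels if c not in df.index]
    unknown = [c for c in df.index if c not in axis]
    if missing or unknown:
        raise ValueError(
            f"channel names do not match axis {axis.kind}: "
            f"missing {missing[:5]}, unknown {unknown[:5]}"
        )
    df = df.loc[list(axis.channels)]
    if (df.values < 0).any():
        raise ValueError("matrix contains negative entries")
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    """Write a channels-by-samples DataFrame as a canonical TSV matrix."""
    axis = axis_for_size(len(df))
    _canonicalize(df, axis).to_csv(path, sep="\t", index_label="MutationType")


def read_catalog(path):
    """Read a COSMIC-format signature catalog TSV.

    First column holds channel names; each remaining column is one signature.
    Channels are reordered canonically and each column is renormalized to sum
    exactly 1 (an error if a column sum is further than 1e-3 from 1).

    Returns a :class:`sigdissect.compare.SignatureCatalog`.
    """
    from .compare import SignatureCatalog

    df = pd.read_csv(path, sep="\t", index_col=0)
    axis = axis_for_size(len(df))
    df = _canonicalize(df, axis)
    sums = df.sum(axis=0)
    bad = sums[(sums - 1.0).abs() > 1e-3]
    if not bad.empty:
        raise ValueError(
            f"signature columns do not sum to 1 within 1e-3: {dict(bad.round(4))}"
        )
    values = df.values / sums.values
    return SignatureCatalog(axis, tuple(df.columns), np.asarray(values, dtype=float))
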