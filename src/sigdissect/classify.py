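"""Mutation classification onto the SBS96, DBS78 and ID83 channel axes.

Substitutions are strand-collapsed onto the pyrimidine: a purine-centred SNV
is reverse-complemented (context and alt alike) before naming, so e.g. a
G>T in context ``TGT`` and a C>A in context ``ACA`` land in the same
``A[C>A]A`` channel. Doublets are collapsed analogously onto the 78-channel
canonical set.

Doublet substitutions (DBS) are derived by merging two same-clone SNVs at
consecutive positions; runs of three or more consecutive substituted
positions are excluded from both the SBS and DBS spectra (and reported), so
no event is counted twice. Native length-2 MNV records from a VCF are
accepted directly as doublets.

Indels are classified on the COSMIC ID83 scheme: 1 bp events by the
pyrimidine-collapsed base and its homopolymer context, longer events by
tandem-repeat copy number or, failing that, microhomology with the flanking
sequence. The homopolymer length of a 1 bp deletion *includes* the deleted
base (channel suffix 0 means the run was just that base); the repeat count
of a 1 bp insertion counts only pre-existing adjacent copies.
"""

from __future__ import annotations

from dataclasses import dataclass

from .channels import DBS78, ID83, SBS96, ChannelAxis
from .reference import ReferenceGenome, get_context
from .variants import MutationRecord

__all__ = [
    "ClassifiedMutation",
    "classify_sbs",
    "classify_dbs",
    "classify_indel",
    "classify_record",
    "merge_adjacent",
    "reverse_complement",
    "MAX_INDEL_LENGTH",
]

MAX_INDEL_LENGTH = 50

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ClassifiedMutation:
    """A mutation assigned to a channel, or flagged unclassifiable."""

    record: MutationRecord
    axis: ChannelAxis | None
    channel: str | None
    reason: str | None = None  # set iff unclassifiable

    @property
    def is_classified(self) -> bool:
        return self.channel is not None

    @staticmethod
    def unclassifiable(record: MutationRecord, reason: str) -> "ClassifiedMutation":
        return ClassifiedMutation(record, None, None, reason)


def classify_sbs(record: MutationRecord, genome: ReferenceGenome) -> ClassifiedMutation:
    """Assign an SNV to its pyrimidine-centred trinucleotide channel."""
    if not record.is_snv:
        raise ValueError(f"classify_sbs needs an SNV, got {record.ref!r}>{record.alt!r}")
    base = genome.base(record.contig, record.pos)
    if base == "N":
        return ClassifiedMutation.unclassifiable(record, "reference_N")
    if base != record.ref:
        raise ValueError(
            f"REF mismatch at {record.contig}:{record.pos}: record {record.ref!r}, "
            f"reference {base!r} — wrong reference genome?"
        )
    context = get_context(genome, record.contig, record.pos, flank=1)
    if context is None:
        return ClassifiedMutation.unclassifiable(record, "context_unavailable")
    alt = record.alt
    if context[1] in "AG":
        context = reverse_complement(context)
        alt = reverse_complement(alt)
    channel = f"{context[0]}[{context[1]}>{alt}]{context[2]}"
    return ClassifiedMutation(record, SBS96, channel)


def classify_dbs(record: MutationRecord) -> ClassifiedMutation:
    """Assign a doublet substitution to its canonical DBS78 channel."""
    if len(record.ref) != 2 or len(record.alt) != 2:
        raise ValueError("classify_dbs needs length-2 ref and alt")
    if record.ref[0] == record.alt[0] or record.ref[1] == record.alt[1]:
        raise ValueError(
            f"doublet must change both bases, got {record.ref!r}>{record.alt!r}"
        )
    channel = f"{record.ref}>{record.alt}"
    if channel not in DBS78:
        channel = f"{reverse_complement(record.ref)}>{reverse_complement(record.alt)}"
    return ClassifiedMutation(record, DBS78, channel)


def merge_adjacent(
    records: list[MutationRecord],
) -> tuple[list[MutationRecord], list[MutationRecord], list[list[MutationRecord]]]:
    """Merge same-clone SNVs at consecutive positions into doublet records.

    Returns ``(doublets, isolated_snvs, excluded_runs)``: runs of exactly two
    consecutive substituted positions become one length-2 MNV record; runs of
    three or more are excluded entirely and returned for reporting; SNVs in
    no run pass through. Non-SNV input records are rejected.
    """
    for r in records:
        if not r.is_snv:
            raise ValueError("merge_adjacent expects SNV records only")
    by_contig: dict[str, list[MutationRecord]] = {}
    for r in records:
        by_contig.setdefault(r.contig, []).append(r)

    doublets: list[MutationRecord] = []
    isolated: list[MutationRecord] = []
    excluded: list[list[MutationRecord]] = []
    for contig in by_contig:
        recs = sorted(by_contig[contig], key=lambda r: r.pos)
        run: list[MutationRecord] = []
        for r in recs + [None]:  # type: ignore[list-item]
            if run and r is not None and r.pos == run[-1].pos + 1:
                run.append(r)
                continue
            if run:
                if len(run) == 1:
                    isolated.append(run[0])
                elif len(run) == 2:
                    a, b = run
                    doublets.append(
                        MutationRecord(contig, a.pos, a.ref + b.ref, a.alt + b.alt, a.clone_id)
                    )
                else:
                    excluded.append(run)
            run = [r] if r is not None else []
    return doublets, isolated, excluded


def _run_length(seq: str, start: int, base: str, step: int) -> int:
    """Number of consecutive ``base`` characters from 0-based ``start``."""
    n = 0
    i = start
    while 0 <= i < len(seq) and seq[i] == base:
        n += 1
        i += step
    return n


def _copies(seq: str, start: int, frag: str, step: int) -> int:
    """Full adjacent copies of ``frag`` in ``seq`` walking from ``start``."""
    L = len(frag)
    n = 0
    i = start
    while True:
        if step > 0:
            if i + L > len(seq) or seq[i : i + L] != frag:
                break
            i += L
        else:
            if i - L + 1 < 0 or seq[i - L + 1 : i + 1] != frag:
                break
            i -= L
        n += 1
    return n


def _microhomology(seq: str, del_start: int, frag: str) -> int:
    """Longest partial identity between a deleted fragment and its flanks.

    ``del_start`` is the 0-based index of the first deleted base. Checks the
    prefix of the fragment against the sequence just right of the deletion
    and its suffix against the sequence just left of it; returns the longer
    match, capped at len(frag) - 1.
    """
    L = len(frag)
    right = 0
    i = del_start + L
    while right < L - 1 and i + right < len(seq) and seq[i + right] == frag[right]:
        right += 1
    left = 0
    i = del_start - 1
    while left < L - 1 and i - left >= 0 and seq[i - left] == frag[L - 1 - left]:
        left += 1
    return max(left, right)


def classify_indel(record: MutationRecord, genome: ReferenceGenome) -> ClassifiedMutation:
    """Assign an anchored, left-aligned indel to its ID83 channel."""
    if record.is_snv or record.is_mnv:
        raise ValueError("classify_indel needs an insertion or deletion record")
    if not (record.is_insertion or record.is_deletion):
        return ClassifiedMutation.unclassifiable(record, "complex")
    seq = genome.sequence(record.contig)
    ref_slice = genome.slice(record.contig, record.pos, record.pos + len(record.ref) - 1)
    if ref_slice != record.ref:
        raise ValueError(
            f"REF mismatch at {record.contig}:{record.pos}: record {record.ref!r}, "
            f"reference {ref_slice!r}"
        )
    L = record.indel_length
    if L > MAX_INDEL_LENGTH:
        return ClassifiedMutation.unclassifiable(record, "too_long")
    frag = record.ref[1:] if record.is_deletion else record.alt[1:]
    if "N" in frag:
        return ClassifiedMutation.unclassifiable(record, "fragment_N")

    if record.is_deletion:
        start = record.pos  # 0-based index of first deleted base
        if L == 1:
            base = frag
            run = 1 + _run_length(seq, start + 1, base, +1) + _run_length(seq, start - 1, base, -1)
            named = base if base in "CT" else reverse_complement(base)
            channel = f"1:Del:{named}:{min(run, 6) - 1}"
        else:
            copies = _copies(seq, start + L, frag, +1) + _copies(seq, start - 1, frag, -1)
            size = min(L, 5)
            if copies >= 1:
                channel = f"{size}:Del:R:{min(copies, 5)}"
            else:
                mh = min(_microhomology(seq, start, frag), 5)
                channel = f"{size}:Del:M:{mh}" if mh >= 1 else f"{size}:Del:R:0"
    else:
        point = record.pos  # 0-based index of the base right of the insertion
        if L == 1:
            base = frag
            run = _run_length(seq, point, base, +1) + _run_length(seq, point - 1, base, -1)
            named = base if base in "CT" else reverse_complement(base)
            channel = f"1:Ins:{named}:{min(run, 5)}"
        else:
            copies = _copies(seq, point, frag, +1) + _copies(seq, point - 1, frag, -1)
            channel = f"{min(L, 5)}:Ins:R:{min(copies, 5)}"
    assert channel in ID83
    return ClassifiedMutation(record, ID83, channel)


def classify_record(record: MutationRecord, genome: ReferenceGenome) -> ClassifiedMutation:
    """Dispatch a record to the appropriate axis classifier."""
    if record.is_snv:
        return classify_sbs(record, genome)
    if record.is_mnv:
        if len(record.ref) == 2:
            if record.ref[0] != record.alt[0] and record.ref[1] != record.alt[1]:
                return classify_dbs(record)
            return ClassifiedMutation.unclassifiable(record, "partial_doublet")
        return ClassifiedMutation.unclassifiable(record, "complex")
    if record.is_insertion or record.is_deletion:
        return classify_indel(record, genome)
    return ClassifiedMutation.unclassifiable(record, "complex")
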