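"""End-to-end dissection: VCFs + manifest + FASTA -> signatures and matches.

Per joint-calling group the pipeline runs, in order: parental-variant
removal, colony-exclusive selection, adjacent-SNV merging into doublets,
classification onto SBS96/DBS78/ID83, per-clone counting, channel-wise
subtraction of the group's mean control spectrum, replicate averaging,
probability normalization, and cosine-similarity matching against any
reference catalogs supplied.

Every clone's records are accounted for exactly: input = parental-removed +
non-exclusive + classified (isolated SBS + merged doublet members + native
doublets + indels) + excluded-run members + unclassifiable. The per-clone
ledger is part of the run report and is checked by
:func:`check_conservation`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .channels import DBS78, ID83, SBS96
from .classify import classify_record, classify_sbs, merge_adjacent
from .compare import SIMILARITY_THRESHOLD, SignatureCatalog, match_catalog
from .groups import read_manifest, remove_parental, select_exclusive
from .reference import ReferenceGenome, read_fasta
from .spectra import (
    Spectrum,
    compound_signature,
    count_spectrum,
    mean_spectrum,
    spectra_to_frame,
    total_burden,
)
from .variants import MutationRecord, read_vcf, write_matrix

log = logging.getLogger(__name__)

__all__ = ["RunReport", "run_dissection", "check_conservation"]

_AXES = {"SBS96": SBS96, "DBS78": DBS78, "ID83": ID83}


@dataclass
class CloneLedger:
    """Exact per-clone accounting of every input record's fate."""

    clone_id: str
    group_id: str
    treatment: str
    n_input: int = 0
    n_parental_removed: int = 0
    n_nonexclusive: int = 0
    n_sbs: int = 0
    n_doublet_members: int = 0  # SNVs that were merged pairwise into doublets
    n_native_doublets: int = 0  # length-2 MNVs taken directly from the VCF
    n_excluded_run: int = 0  # SNVs in runs of >= 3 consecutive positions
    n_id: int = 0
    n_unclassifiable: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)

    @property
    def balanced(self) -> bool:
        accounted = (
            self.n_parental_removed + self.n_nonexclusive + self.n_sbs
            + self.n_doublet_members + self.n_native_doublets
            + self.n_excluded_run + self.n_id + self.n_unclassifiable
        )
        return accounted == self.n_input


@dataclass
class RunReport:
    """Self-contained audit record of one dissection run."""

    ledger: pd.DataFrame  # one row per clone (CloneLedger fields)
    burdens: pd.DataFrame  # one row per (treatment, axis): mean +- SD after subtraction
    signatures: dict[str, pd.DataFrame]  # axis kind -> channels x treatments
    spectra: dict[str, pd.DataFrame]  # axis kind -> raw channels x clones
    matches: pd.DataFrame  # treatment, axis, signature, similarity, flagged
    threshold: float
    subtract_order: str
    version: str = __version__
    unclassified_log: list[str] = field(default_factory=list)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.ledger.to_csv(out / "clone_ledger.tsv", sep="\t", index=False)
        self.burdens.to_csv(out / "burdens.tsv", sep="\t", index=False)
        for kind, df in self.spectra.items():
            if not df.empty:
                write_matrix(df, out / f"spectra_{kind}.tsv")
        for kind, df in self.signatures.items():
            if not df.empty:
                write_matrix(df, out / f"signatures_{kind}.tsv")
        if not self.matches.empty:
            self.matches.to_csv(out / "catalog_matches.tsv", sep="\t", index=False)
        meta = {
            "version": self.version,
            "threshold": self.threshold,
            "subtract_order": self.subtract_order,
            "conservation_ok": bool(check_conservation(self)),
            "unclassified": self.unclassified_log,
        }
        with open(out / "report.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)


def check_conservation(report: RunReport) -> bool:
    """True iff every clone's ledger row balances exactly."""
    df = report.ledger
    accounted = (
        df["n_parental_removed"] + df["n_nonexclusive"] + df["n_sbs"]
        + df["n_doublet_members"] + df["n_native_doublets"]
        + df["n_excluded_run"] + df["n_id"] + df["n_unclassifiable"]
    )
    return bool((accounted == df["n_input"]).all())


def _classify_clone(
    records: list[MutationRecord], genome: ReferenceGenome, ledger: CloneLedger,
    unclassified_log: list[str],
) -> dict[str, list]:
    """Split one clone's exclusive records into classified per-axis lists."""
    snvs, native_doublets, indels, classified = [], [], [], {"SBS96": [], "DBS78": [], "ID83": []}
    for r in records:
        if r.is_snv:
            snvs.append(r)
        elif r.is_mnv and len(r.ref) == 2 and r.ref[0] != r.alt[0] and r.ref[1] != r.alt[1]:
            native_doublets.append(r)
        else:
            indels.append(r)

    doublets, isolated, excluded = merge_adjacent(snvs)
    ledger.n_doublet_members += 2 * len(doublets)
    ledger.n_excluded_run += sum(len(run) for run in excluded)
    for run in excluded:
        log.info(
            "%s: excluded run of %d consecutive substitutions at %s:%d",
            ledger.clone_id, len(run), run[0].contig, run[0].pos,
        )

    for rec in isolated:
        cm = classify_sbs(rec, genome)
        if cm.is_classified:
            classified["SBS96"].append(cm)
            ledger.n_sbs += 1
        else:
            ledger.n_unclassifiable += 1
            unclassified_log.append(f"{ledger.clone_id} {rec.contig}:{rec.pos} {cm.reason}")
    for rec in doublets + native_doublets:
        cm = classify_record(rec, genome)
        if cm.is_classified:
            classified["DBS78"].append(cm)
            if rec in native_doublets:
                ledger.n_native_doublets += 1
        else:
            # merged doublets were already counted as members; rebook them
            if rec not in native_doublets:
                ledger.n_doublet_members -= 2
                ledger.n_unclassifiable += 2
            else:
                ledger.n_unclassifiable += 1
            unclassified_log.append(f"{ledger.clone_id} {rec.contig}:{rec.pos} {cm.reason}")
    for rec in indels:
        cm = classify_record(rec, genome)
        if cm.is_classified:
            classified["ID83"].append(cm)
            ledger.n_id += 1
        else:
            ledger.n_unclassifiable += 1
            unclassified_log.append(f"{ledger.clone_id} {rec.contig}:{rec.pos} {cm.reason}")
    return classified


def run_dissection(
    vcf_dir,
    fasta,
    manifest,
    parental_vcf=None,
    catalogs: dict[str, SignatureCatalog] | None = None,
    threshold: float = SIMILARITY_THRESHOLD,
    out_dir=None,
    subtract_order: str = "per-clone",
    exclusivity_scope: str = "group",
) -> RunReport:
    """Run the full dissection and (optionally) write all result tables.

    ``vcf_dir`` must contain one ``<clone_id>.vcf`` per manifest clone.
    Every group needs at least one control clone — without one the
    subtraction the analysis is built on is impossible, a hard error.
    """
    genome = read_fasta(fasta)
    groups = read_manifest(manifest)
    vcf_dir = Path(vcf_dir)
    parental: set = set()
    if parental_vcf is not None:
        parental = {r.key for r in read_vcf(parental_vcf, "_parental")}
    catalogs = catalogs or {}

    ledgers: list[CloneLedger] = []
    unclassified_log: list[str] = []
    all_spectra: dict[str, list[Spectrum]] = {k: [] for k in _AXES}
    burden_rows = []
    signature_cols: dict[str, dict[str, np.ndarray]] = {k: {} for k in _AXES}
    match_rows = []

    for group in groups:
        if not group.control_clones:
            raise ValueError(
                f"group {group.group_id!r} has no control clones; "
                "control subtraction is impossible"
            )
        raw: dict[str, list[MutationRecord]] = {}
        for clone in group.clone_ids:
            path = vcf_dir / f"{clone}.vcf"
            if not path.exists():
                raise FileNotFoundError(f"missing VCF for clone {clone!r}: {path}")
            raw[clone] = read_vcf(path, clone)

        deparented, removed = remove_parental(raw, parental)
        exclusive = select_exclusive(group, deparented, scope=exclusivity_scope)

        clone_spectra: dict[str, dict[str, Spectrum]] = {k: {} for k in _AXES}
        for clone in group.clone_ids:
            ledger = CloneLedger(clone, group.group_id, group.members[clone])
            ledger.n_input = len(raw[clone])
            ledger.n_parental_removed = removed[clone]
            ledger.n_nonexclusive = len(deparented[clone]) - len(exclusive[clone])
            classified = _classify_clone(exclusive[clone], genome, ledger, unclassified_log)
            for kind, axis in _AXES.items():
                spec = count_spectrum(classified[kind], axis, clone)
                clone_spectra[kind][clone] = spec
                all_spectra[kind].append(spec)
            ledgers.append(ledger)
            log.info(
                "%s: %d in, %d parental, %d shared, %d SBS, %d doublets, %d indels",
                clone, ledger.n_input, ledger.n_parental_removed, ledger.n_nonexclusive,
                ledger.n_sbs, ledger.n_doublet_members // 2 + ledger.n_native_doublets,
                ledger.n_id,
            )

        for treatment in group.treatments:
            t_clones = group.clones_of(treatment)
            c_clones = group.control_clones
            for kind in _AXES:
                t_spec = [clone_spectra[kind][c] for c in t_clones]
                c_spec = [clone_spectra[kind][c] for c in c_clones]
                sig, stats = compound_signature(
                    t_spec, c_spec, sample_id=treatment, order=subtract_order
                )
                # burdens subtract *totals* (treatment count minus mean control
                # count, per clone); the channel-wise clamped subtraction is
                # reserved for spectra, where clamping noise would otherwise
                # inflate low-burden treatments
                control_mean, _ = mean_spectrum(c_spec)
                control_total = total_burden(control_mean)
                per_clone = [total_burden(s) - control_total for s in t_spec]
                burden_rows.append({
                    "group_id": group.group_id, "treatment": treatment, "axis": kind,
                    "mean_burden": float(np.mean(per_clone)),
                    "sd_burden": float(np.std(per_clone, ddof=1)) if len(per_clone) > 1 else 0.0,
                    "control_mean_burden": control_total,
                    "clamped_channels": int(np.sum(stats["clamped_channels"])),
                })
                if not sig.is_zero:
                    signature_cols[kind][treatment] = sig.counts
                    if kind in catalogs:
                        for name, sim, flagged in match_catalog(sig, catalogs[kind], threshold):
                            match_rows.append({
                                "treatment": treatment, "axis": kind,
                                "signature": name, "similarity": sim, "flagged": flagged,
                            })

    report = RunReport(
        ledger=pd.DataFrame([l.as_dict() for l in ledgers]),
        burdens=pd.DataFrame(burden_rows),
        signatures={
            kind: pd.DataFrame(cols, index=list(_AXES[kind].channels))
            for kind, cols in signature_cols.items()
        },
        spectra={
            kind: spectra_to_frame(specs) if specs else pd.DataFrame()
            for kind, specs in all_spectra.items()
        },
        matches=pd.DataFrame(
            match_rows, columns=["treatment", "axis", "signature", "similarity", "flagged"]
        ),
        threshold=threshold,
        subtract_order=subtract_order,
        unclassified_log=unclassified_log,
    )
    if not check_conservation(report):  # pragma: no cover - internal invariant
        raise AssertionError("count conservation ledger does not balance")
    if out_dir is not None:
        report.write(out_dir)
    return report
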