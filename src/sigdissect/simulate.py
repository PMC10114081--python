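"""Synthetic clonal-expansion experiments with known ground truth.

The simulator generates the full input bundle the analysis pipeline
consumes — a random reference genome (FASTA), per-clone variant calls
(VCF), a group manifest (TSV) — plus the ground truth needed for recovery
testing: which mutations are parental, background or compound-induced, and
the exact channel distributions they were drawn from.

The generative model mirrors the study design it emulates: a parental
variant set shared by every clone; per-clone endogenous (background)
mutations, count ~ Poisson(~750 SBS per clone); and, in treatment clones,
compound-specific mutations, count ~ Poisson(per-compound burden), with
channels drawn from a per-compound signature. Burdens span the observed
range from a few hundred to tens of thousands of substitutions per clone.

Mutation placement is the inverse of classification: a channel is realized
at a uniformly chosen genomic site whose context reproduces that channel on
reclassification (a round-trip guarantee, verified at placement time). When
the genome lacks a required context — exotic tandem-repeat or microhomology
deletion channels on small genomes — a compatible context is embedded into
the reference first (logged); the FASTA is written only after all
placements, so analysis always sees the final reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .channels import DBS78, ID83, SBS96, ChannelAxis, axis_by_name
from .classify import classify_indel, classify_sbs, reverse_complement
from .compare import SignatureCatalog
from .groups import CONTROL_LABEL, CloneGroup, write_manifest
from .reference import ReferenceGenome, generate_reference, write_fasta
from .variants import MutationRecord, left_align, write_vcf

log = logging.getLogger(__name__)

__all__ = [
    "TreatmentSpec",
    "GroupSpec",
    "SimulationConfig",
    "SimulationTruth",
    "MutationPlacer",
    "place_mutation",
    "demo_signatures",
    "study_design",
    "simulate_experiment",
]

_MAX_TRIES = 2000


# ---------------------------------------------------------------------------
# packaged demo signatures

_IUPAC = {"N": "ACGT", "R": "AG", "Y": "CT", "A": "A", "C": "C", "G": "G", "T": "T"}


def _sbs_vector(weights: dict[str, float]) -> np.ndarray:
    """Expand pattern weights like ``{"R[T>C]N": 0.7}`` into a 96-vector.

    The 5' and 3' positions accept IUPAC codes N/R/Y; each pattern's weight
    is split equally over the channels it matches. Patterns are additive.
    """
    v = np.zeros(96)
    for pattern, w in weights.items():
        five, rest = pattern[0], pattern[1:]
        sub = rest[1:4]
        three = rest[5]
        matches = [
            SBS96.index(f"{f}[{sub}]{t}") for f in _IUPAC[five] for t in _IUPAC[three]
        ]
        v[matches] += w / len(matches)
    return v / v.sum()


def _named_vector(axis: ChannelAxis, weights: dict[str, float]) -> np.ndarray:
    v = np.zeros(len(axis))
    for channel, w in weights.items():
        v[axis.index(channel)] = w
    return v / v.sum()


def demo_signatures(kind: str) -> SignatureCatalog:
    """Packaged synthetic demo signatures for one channel axis.

    These are illustrative fixtures shaped qualitatively like the compound
    classes they are named after (a bulky-adduct C>A/C>T profile, an
    alkylation purine-5' T>C profile, a mixed-transversion profile, an
    oxidative C>A background) — synthetic stand-ins, not measured spectra.
    """
    if kind == "SBS96":
        vectors = {
            "flat": np.full(96, 1 / 96),
            "oxidative_like": _sbs_vector({"N[C>A]N": 0.60, "N[C>T]N": 0.15, "N[T>C]N": 0.10,
                                           "N[C>G]N": 0.05, "N[T>A]N": 0.05, "N[T>G]N": 0.05}),
            "bap_like": _sbs_vector({"C[C>A]N": 0.12, "G[C>A]N": 0.08, "N[C>A]N": 0.36,
                                     "N[C>T]N": 0.26, "N[C>G]N": 0.08, "N[T>A]N": 0.04,
                                     "N[T>C]N": 0.03, "N[T>G]N": 0.03}),
            "norharmane_like": _sbs_vector({"N[C>A]N": 0.48, "T[C>A]N": 0.08, "N[C>T]N": 0.30,
                                            "N[C>G]N": 0.04, "N[T>A]N": 0.03, "N[T>C]N": 0.04,
                                            "N[T>G]N": 0.03}),
            "mnng_like": _sbs_vector({"R[T>C]N": 0.68, "N[C>T]N": 0.22, "N[T>A]N": 0.03,
                                      "N[C>A]N": 0.03, "N[C>G]N": 0.02, "N[T>G]N": 0.02}),
            "nnk_acetate_like": _sbs_vector({"A[C>T]N": 0.13, "A[T>A]N": 0.13, "A[T>C]N": 0.13,
                                             "A[T>G]N": 0.13, "N[C>T]N": 0.08, "N[T>A]N": 0.08,
                                             "N[T>C]N": 0.08, "N[T>G]N": 0.08, "N[C>A]N": 0.08,
                                             "N[C>G]N": 0.08}),
        }
        axis = SBS96
    elif kind == "DBS78":
        vectors = {
            "flat_dbs": np.full(78, 1 / 78),
            "bap_like_dbs": _named_vector(DBS78, {"CC>AA": 0.55, "CC>TA": 0.30, "CC>TT": 0.05,
                                                  "TC>AA": 0.05, "CT>AA": 0.05}),
        }
        axis = DBS78
    elif kind == "ID83":
        vectors = {
            "flat_id": np.full(83, 1 / 83),
            "background_id": _named_vector(ID83, {"1:Del:T:2": 0.20, "1:Del:T:3": 0.20,
                                                  "1:Del:T:4": 0.10, "1:Ins:T:1": 0.15,
                                                  "1:Ins:T:2": 0.10, "1:Del:C:1": 0.15,
                                                  "1:Ins:C:1": 0.10}),
            "bap_like_id": _named_vector(ID83, {"1:Del:C:0": 0.22, "1:Del:C:1": 0.18,
                                                "1:Del:T:0": 0.15, "1:Del:T:1": 0.15,
                                                "1:Ins:T:0": 0.12, "1:Ins:T:1": 0.08,
                                                "2:Del:R:1": 0.05, "2:Del:M:1": 0.05}),
        }
        axis = ID83
    else:
        raise ValueError(f"unknown axis kind {kind!r}")
    names = tuple(vectors)
    return SignatureCatalog(axis, names, np.stack([vectors[n] for n in names], axis=1))


# ---------------------------------------------------------------------------
# configuration

@dataclass
class TreatmentSpec:
    """Burdens and signature mixtures for one compound condition."""

    name: str
    sbs_burden: float = 0.0
    sbs_mixture: dict[str, float] = field(default_factory=dict)
    dbs_burden: float = 0.0
    dbs_mixture: dict[str, float] = field(default_factory=dict)
    id_burden: float = 0.0
    id_mixture: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for burden, mixture, label in [
            (self.sbs_burden, self.sbs_mixture, "sbs"),
            (self.dbs_burden, self.dbs_mixture, "dbs"),
            (self.id_burden, self.id_mixture, "id"),
        ]:
            if burden < 0:
                raise ValueError(f"{label} burden must be non-negative")
            if burden > 0:
                if not mixture:
                    raise ValueError(f"{self.name}: {label}_burden > 0 needs a mixture")
                if abs(sum(mixture.values()) - 1.0) > 1e-9:
                    raise ValueError(f"{self.name}: {label} mixture weights must sum to 1")


@dataclass
class GroupSpec:
    group_id: str
    treatments: list[TreatmentSpec]


@dataclass
class SimulationConfig:
    """Full description of one synthetic clonal-expansion experiment."""

    groups: list[GroupSpec]
    genome_length: int = 5_000_000
    n_contigs: int = 2
    gc_fraction: float = 0.41
    clones_per_condition: int = 5
    background_sbs_burden: float = 750.0
    background_signature: str = "flat"  # "flat" or "oxidative_like", stated explicitly
    background_id_burden: float = 100.0
    background_id_signature: str = "background_id"
    background_dbs_burden: float = 0.0
    background_dbs_signature: str = "flat_dbs"
    n_parental_variants: int = 50
    dispersion: float | None = None  # variance/mean ratio; None => Poisson
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clones_per_condition < 1:
            raise ValueError("clones_per_condition must be >= 1")
        if min(self.background_sbs_burden, self.background_id_burden,
               self.background_dbs_burden) < 0:
            raise ValueError("burdens must be non-negative")
        if self.dispersion is not None and self.dispersion <= 1.0:
            raise ValueError("dispersion (variance/mean) must exceed 1; use None for Poisson")

    @staticmethod
    def from_yaml(path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        groups = [
            GroupSpec(g["group_id"], [TreatmentSpec(**t) for t in g["treatments"]])
            for g in raw.pop("groups")
        ]
        return SimulationConfig(groups=groups, **raw)

    def to_yaml(self, path) -> None:
        raw = {
            k: v for k, v in self.__dict__.items() if k != "groups"
        }
        raw["groups"] = [
            {"group_id": g.group_id, "treatments": [dict(t.__dict__) for t in g.treatments]}
            for g in self.groups
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def study_design(
    genome_length: int = 5_000_000,
    clones_per_condition: int = 5,
    background_sbs_burden: float = 750.0,
    burden_scale: float = 1.0,
    seed: int = 0,
) -> SimulationConfig:
    """The default three-group experiment layout.

    Three joint-calling groups with five clones per condition: group 1 pairs
    an alkylating-agent-like condition (700 SBS/clone) and a mixed-
    transversion condition (5500 SBS/clone) with their vehicle control;
    group 2 holds a weak mutagen (200 SBS/clone) and three non-mutagenic
    compounds (burden 0) plus control; group 3 holds the strong bulky-adduct
    mutagen (25 000 SBS/clone, with doublet and indel burdens) plus control.
    ``burden_scale`` scales every compound burden for cheaper test runs.
    """
    s = burden_scale
    groups = [
        GroupSpec("group1", [
            TreatmentSpec("MNNG_like", sbs_burden=700 * s, sbs_mixture={"mnng_like": 1.0}),
            TreatmentSpec("NNK_acetate_like", sbs_burden=5500 * s,
                          sbs_mixture={"nnk_acetate_like": 1.0}),
        ]),
        GroupSpec("group2", [
            TreatmentSpec("harmane_like"),
            TreatmentSpec("norharmane_like", sbs_burden=200 * s,
                          sbs_mixture={"norharmane_like": 1.0}),
            TreatmentSpec("naphthylamine_like"),
            TreatmentSpec("aminobiphenyl_like"),
        ]),
        GroupSpec("group3", [
            TreatmentSpec("BaP_like", sbs_burden=25000 * s, sbs_mixture={"bap_like": 1.0},
                          dbs_burden=0.6 * s, dbs_mixture={"bap_like_dbs": 1.0},
                          id_burden=800 * s, id_mixture={"bap_like_id": 1.0}),
        ]),
    ]
    return SimulationConfig(
        groups=groups,
        genome_length=genome_length,
        clones_per_condition=clones_per_condition,
        background_sbs_burden=background_sbs_burden,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# placement

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}


def _mixture_vector(mixture: dict[str, float], catalog: SignatureCatalog) -> np.ndarray:
    v = np.zeros(len(catalog.axis))
    for name, w in mixture.items():
        v += w * catalog.vector(name)
    return v / v.sum()


class UnsatisfiableChannelError(RuntimeError):
    """No genomic site (and no embeddable context) can realize the channel."""


class CollisionExhaustionError(RuntimeError):
    """The genome is too small for the requested mutation burden."""


class MutationPlacer:
    """Places channel-specified mutations on a genome, collision-free.

    One placer serves a whole experiment: the genome (and any embedded
    contexts) is shared across clones, while occupancy — the rule that no
    two mutations of one clone may overlap or sit on adjacent positions,
    unless a doublet is explicitly requested — is tracked per clone.
    Every placement is verified by reclassification before it is accepted.
    """

    def __init__(self, genome: ReferenceGenome, rng: np.random.Generator):
        self.genome = genome
        self.rng = rng
        self.occupied: dict[str, set[tuple[str, int]]] = {}
        self.locked: set[tuple[str, int]] = set()  # reference positions relied upon
        self.n_embedded = 0
        self._trinuc: dict[str, tuple[list[str], list[np.ndarray], np.ndarray]] | None = None
        self._runs: list[tuple[str, int, int, str]] | None = None  # (contig, start0, len, base)
        self._run_cache: dict[tuple, list] = {}

    # -- indexes ------------------------------------------------------------

    def _codes(self, seq: str) -> np.ndarray:
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        out = np.full(arr.shape, -100, dtype=np.int64)
        for b, c in _CODE.items():
            out[arr == ord(b)] = c
        return out

    def _build_trinuc_index(self) -> None:
        index: dict[int, list[tuple[str, np.ndarray]]] = {}
        for contig, seq in self.genome.contigs.items():
            if len(seq) < 3:
                continue
            codes = self._codes(seq)
            tri = codes[:-2] * 16 + codes[1:-1] * 4 + codes[2:]
            for code in range(64):
                centers = np.flatnonzero(tri == code) + 1  # 0-based center
                if centers.size:
                    index.setdefault(code, []).append((contig, centers))
        self._trinuc = {}
        for code, parts in index.items():
            contigs = [c for c, _ in parts]
            arrays = [a for _, a in parts]
            sizes = np.array([a.size for a in arrays])
            self._trinuc[code] = (contigs, arrays, np.cumsum(sizes))

    def _trinuc_sites(self, ctx: str) -> tuple[list[str], list[np.ndarray], np.ndarray] | None:
        if self._trinuc is None:
            self._build_trinuc_index()
        code = _CODE[ctx[0]] * 16 + _CODE[ctx[1]] * 4 + _CODE[ctx[2]]
        return self._trinuc.get(code)  # type: ignore[union-attr]

    def _build_run_index(self) -> None:
        runs = []
        for contig, seq in self.genome.contigs.items():
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            runs.append((contig, starts, ends - starts, arr[starts]))
        self._runs = runs

    def _candidate_runs(self, base: str, min_len: int, max_len: int | None):
        """Homopolymer runs of ``base`` (either strand) as a sampling pool:
        ``(contig names, per-contig start arrays, cumulative sizes)``."""
        key = (base, min_len, max_len)
        if key in self._run_cache:
            return self._run_cache[key]
        if self._runs is None:
            self._build_run_index()
        comp = reverse_complement(base)
        contigs, arrays = [], []
        for contig, starts, lengths, bases in self._runs:  # type: ignore[union-attr]
            mask = (
                ((bases == ord(base)) | (bases == ord(comp)))
                & (lengths >= min_len)
                & (starts >= 1)  # an anchor base must exist to the left
            )
            if max_len is not None:
                mask &= lengths <= max_len
            sel = starts[mask]
            if sel.size:
                contigs.append(contig)
                arrays.append(sel)
        if not contigs:
            pool = None
        else:
            pool = (contigs, arrays, np.cumsum([a.size for a in arrays]))
        self._run_cache[key] = pool
        return pool

    def _sample_pool(self, pool) -> tuple[str, int]:
        contigs, arrays, cum = pool
        j = int(self.rng.integers(cum[-1]))
        part = int(np.searchsorted(cum, j, side="right"))
        return contigs[part], int(arrays[part][j - (cum[part - 1] if part else 0)])

    # -- occupancy ----------------------------------------------------------

    def _footprint(self, record: MutationRecord) -> set[tuple[str, int]]:
        return {(record.contig, p) for p in range(record.pos, record.pos + len(record.ref))}

    def _free(self, clone: str, footprint: set[tuple[str, int]], pad: int = 1) -> bool:
        occ = self.occupied.setdefault(clone, set())
        padded = {(c, p + d) for c, p in footprint for d in range(-pad, pad + 1)}
        return not (padded & occ)

    def _commit(self, clone: str, record: MutationRecord, lock_margin: int) -> None:
        self.occupied.setdefault(clone, set()).update(self._footprint(record))
        lo = record.pos - lock_margin
        hi = record.pos + len(record.ref) + lock_margin
        self.locked.update((record.contig, p) for p in range(lo, hi + 1))

    def share_occupancy(self, src_clone: str, dst_clone: str) -> None:
        """Copy a clone's occupied sites into another (parental sharing)."""
        self.occupied.setdefault(dst_clone, set()).update(
            self.occupied.get(src_clone, set())
        )

    # -- embedding ----------------------------------------------------------

    def _embed(self, context: str) -> tuple[str, int]:
        """Write ``context`` into a clear stretch of reference; returns its
        contig and 0-based start. The region is locked afterwards."""
        margin = 12
        names = self.genome.contig_names
        lengths = np.array([len(self.genome.contigs[c]) for c in names], dtype=float)
        for _ in range(_MAX_TRIES):
            contig = names[int(self.rng.choice(len(names), p=lengths / lengths.sum()))]
            clen = len(self.genome.contigs[contig])
            if clen < len(context) + 2 * margin + 2:
                continue
            start = int(self.rng.integers(margin + 1, clen - len(context) - margin))
            zone = {(contig, p + 1) for p in range(start - margin, start + len(context) + margin)}
            if zone & self.locked:
                continue
            self.genome.replace(contig, start + 1, context)
            self.locked.update(zone)
            self.n_embedded += 1
            log.info("embedded %d bp context at %s:%d", len(context), contig, start + 1)
            return contig, start
        raise UnsatisfiableChannelError(
            f"no clear region to embed a {len(context)} bp context"
        )

    def _guard(self, *avoid: str) -> str:
        choices = [b for b in _BASES if b not in avoid]
        return choices[int(self.rng.integers(len(choices)))]

    # -- SBS ----------------------------------------------------------------

    def place_sbs(self, channel: str, clone: str) -> MutationRecord:
        """Place an SNV whose SBS96 classification is ``channel``."""
        five, sub, three = channel[0], channel[2:5], channel[6]
        ref_c, alt_c = sub[0], sub[2]
        fwd_ctx = five + ref_c + three
        orientations = [
            (fwd_ctx, alt_c),
            (reverse_complement(fwd_ctx), reverse_complement(alt_c)),
        ]
        pools = [(ctx, alt, self._trinuc_sites(ctx)) for ctx, alt in orientations]
        weights = np.array([0 if p is None else int(p[2][-1]) for _, _, p in pools], dtype=float)
        if weights.sum() == 0:
            raise UnsatisfiableChannelError(f"no site matches context of {channel}")
        for _ in range(_MAX_TRIES):
            k = int(self.rng.choice(2, p=weights / weights.sum()))
            ctx, alt, pool = pools[k]
            contigs, arrays, cum = pool  # type: ignore[misc]
            j = int(self.rng.integers(cum[-1]))
            part = int(np.searchsorted(cum, j, side="right"))
            center0 = int(arrays[part][j - (cum[part - 1] if part else 0)])
            contig = contigs[part]
            pos = center0 + 1
            rec = MutationRecord(contig, pos, ctx[1], alt, clone)
            if not self._free(clone, self._footprint(rec)):
                continue
            # embedded regions may have invalidated the index entry
            if self.genome.slice(contig, pos - 1, pos + 1) != ctx:
                continue
            cm = classify_sbs(rec, self.genome)
            if cm.channel != channel:  # pragma: no cover - defensive
                continue
            self._commit(clone, rec, lock_margin=2)
            return rec
        raise CollisionExhaustionError(f"could not place {channel} for clone {clone}")

    # -- DBS ----------------------------------------------------------------

    def place_dbs(self, channel: str, clone: str) -> tuple[MutationRecord, MutationRecord]:
        """Plant a true adjacent SNV pair realizing a DBS78 channel."""
        ref, alt = channel.split(">")
        orientations = [(ref, alt), (reverse_complement(ref), reverse_complement(alt))]
        for _ in range(_MAX_TRIES):
            r, a = orientations[int(self.rng.integers(2))]
            contig = self._random_contig()
            seq = self.genome.contigs[contig]
            if len(seq) < 6:
                continue
            start0 = int(self.rng.integers(2, len(seq) - 3))
            if seq[start0 : start0 + 2] != r:
                continue
            pos = start0 + 1
            rec1 = MutationRecord(contig, pos, r[0], a[0], clone)
            rec2 = MutationRecord(contig, pos + 1, r[1], a[1], clone)
            fp = self._footprint(rec1) | self._footprint(rec2)
            if not self._free(clone, fp):
                continue
            self._commit(clone, rec1, lock_margin=2)
            self._commit(clone, rec2, lock_margin=2)
            return rec1, rec2
        raise CollisionExhaustionError(f"could not place doublet {channel} for clone {clone}")

    def _random_contig(self) -> str:
        names = self.genome.contig_names
        lengths = np.array([len(self.genome.contigs[c]) for c in names], dtype=float)
        return names[int(self.rng.choice(len(names), p=lengths / lengths.sum()))]

    # -- indels -------------------------------------------------------------

    _UNITS = {2: "AC", 3: "ACG", 4: "ACGT", 5: "ACGTC", 6: "ACGTCA"}

    def place_id(self, channel: str, clone: str) -> MutationRecord:
        """Place an indel whose ID83 classification is ``channel``."""
        size_s, op, motif, count_s = channel.split(":")
        size, count = int(size_s), int(count_s)
        if size == 1:
            rec = self._place_1bp(op, motif, count, clone)
        elif motif == "R":
            rec = self._place_repeat(op, size, count, clone)
        else:
            rec = self._place_microhomology(size, count, clone)
        cm = classify_indel(rec, self.genome)
        if cm.channel != channel:  # pragma: no cover - defensive
            raise UnsatisfiableChannelError(
                f"placement for {channel} reclassified as {cm.channel}"
            )
        self._commit(clone, rec, lock_margin=40)
        return rec

    def _anchor_record(self, contig: str, first0: int, frag: str, op: str, clone: str
                       ) -> MutationRecord:
        """Build an anchored record; ``first0`` is the 0-based index of the
        first deleted base (Del) or of the base right of the insertion (Ins)."""
        seq = self.genome.contigs[contig]
        anchor = seq[first0 - 1]
        if op == "Del":
            return MutationRecord(contig, first0, anchor + frag, anchor, clone)
        return MutationRecord(contig, first0, anchor, anchor + frag, clone)

    def _try_site(self, rec: MutationRecord, channel_check: str, clone: str
                  ) -> MutationRecord | None:
        rec = left_align(rec, self.genome)
        if not self._free(clone, self._footprint(rec)):
            return None
        if classify_indel(rec, self.genome).channel != channel_check:
            return None
        return rec

    def _place_1bp(self, op: str, base: str, count: int, clone: str) -> MutationRecord:
        if op == "Del":
            lo, hi = (count + 1, count + 1) if count < 5 else (6, None)
            channel = f"1:Del:{base}:{count}"
        else:
            if count == 0:
                return self._place_1bp_ins_zero(base, clone)
            lo, hi = (count, count) if count < 5 else (5, None)
            channel = f"1:Ins:{base}:{count}"
        pool = self._candidate_runs(base, lo, hi)
        if pool is None:
            g = self._guard(base, reverse_complement(base))
            contig, start = self._embed(g + base * lo + g)
            pool = ([contig], [np.array([start + 1])], np.array([1]))
        for _ in range(_MAX_TRIES):
            contig, s0 = self._sample_pool(pool)
            # delete/insert at the run's left edge (0-based s0)
            run_base = self.genome.contigs[contig][s0]
            rec = self._anchor_record(contig, s0, run_base, op, clone)
            got = self._try_site(rec, channel, clone)
            if got is not None:
                return got
        raise CollisionExhaustionError(f"could not place {channel} for clone {clone}")

    def _place_1bp_ins_zero(self, base: str, clone: str) -> MutationRecord:
        channel = f"1:Ins:{base}:0"
        for _ in range(_MAX_TRIES):
            contig = self._random_contig()
            seq = self.genome.contigs[contig]
            first0 = int(self.rng.integers(2, len(seq) - 2))
            frag = base if self.rng.integers(2) else reverse_complement(base)
            rec = self._anchor_record(contig, first0, frag, "Ins", clone)
            got = self._try_site(rec, channel, clone)
            if got is not None:
                return got
        raise CollisionExhaustionError(f"could not place {channel} for clone {clone}")

    def _scan_probe(self, length: int) -> tuple[str, int, str] | None:
        contig = self._random_contig()
        seq = self.genome.contigs[contig]
        if len(seq) < length + 20:
            return None
        i = int(self.rng.integers(10, len(seq) - length - 10))
        frag = seq[i : i + length]
        if "N" in frag:
            return None
        return contig, i, frag

    def _place_repeat(self, op: str, size: int, count: int, clone: str) -> MutationRecord:
        channel = f"{size}:{op}:R:{count}"
        unit_len = size if size < 5 else 5
        # probe natural sites first; embed a constructed tandem array if the
        # genome has none
        for _ in range(400):
            probe = self._scan_probe(unit_len)
            if probe is None:
                continue
            contig, i, frag = probe
            if op == "Ins" and count == 0:
                # insert an arbitrary unit; almost no site has an adjacent copy
                frag = "".join(_BASES[int(b)] for b in self.rng.integers(4, size=unit_len))
            rec = self._anchor_record(contig, i, frag, op, clone)
            got = self._try_site(rec, channel, clone)
            if got is not None:
                return got
        if op == "Ins" and count == 0:
            raise UnsatisfiableChannelError(f"no insertion site free of copies for {channel}")
        unit = self._UNITS[unit_len]
        copies_in_ref = count + 1 if op == "Del" else count
        gl = self._guard(unit[-1])
        gr = self._guard(unit[0])
        context = gl + unit * copies_in_ref + gr
        contig, start = self._embed(context)
        # event at the array's left edge (0-based start + 1, just after the guard)
        rec = self._anchor_record(contig, start + 1, unit, op, clone)
        got = self._try_site(rec, channel, clone)
        if got is None:
            raise UnsatisfiableChannelError(f"embedded context failed for {channel}")
        return got

    def _place_microhomology(self, size: int, mh: int, clone: str) -> MutationRecord:
        channel = f"{size}:Del:M:{mh}"
        length = size if mh < size else mh + 1  # 5:Del:M:5 needs a 6+ bp event
        for _ in range(400):
            probe = self._scan_probe(length)
            if probe is None:
                continue
            contig, i, frag = probe
            rec = self._anchor_record(contig, i, frag, "Del", clone)
            got = self._try_site(rec, channel, clone)
            if got is not None:
                return got
        unit = self._UNITS[length]
        gl = self._guard(unit[-1])
        tail = self._guard(unit[mh % length])
        context = gl + unit + unit[:mh] + tail
        contig, start = self._embed(context)
        rec = self._anchor_record(contig, start + 1, unit, "Del", clone)
        got = self._try_site(rec, channel, clone)
        if got is None:
            raise UnsatisfiableChannelError(f"embedded context failed for {channel}")
        return got

    def place(self, channel: str, axis: ChannelAxis, clone: str):
        """Place one mutation of any axis; DBS returns the SNV pair."""
        if axis.kind == "SBS96":
            return self.place_sbs(channel, clone)
        if axis.kind == "DBS78":
            return self.place_dbs(channel, clone)
        if axis.kind == "ID83":
            return self.place_id(channel, clone)
        raise ValueError(f"unknown axis {axis.kind}")


def place_mutation(
    genome: ReferenceGenome, channel: str, axis: ChannelAxis, rng: np.random.Generator
):
    """One-shot placement of a single channel on a genome (round-trip safe).

    Convenience wrapper over :class:`MutationPlacer`; the genome may be
    modified in place if a context had to be embedded.
    """
    if channel not in axis:
        raise KeyError(f"{channel!r} is not a channel of {axis.kind}")
    placer = MutationPlacer(genome, rng)
    return placer.place(channel, axis, clone="_single")


# ---------------------------------------------------------------------------
# experiment simulation

@dataclass
class SimulationTruth:
    """Ground truth of one simulated experiment."""

    clone_table: pd.DataFrame  # clone_id, group_id, treatment, realized counts
    true_signatures: dict[str, dict[str, np.ndarray]]  # axis kind -> condition -> vector
    sources: dict[str, dict[tuple, str]]  # clone -> identity key -> source label
    n_embedded: int = 0

    def signature(self, kind: str, condition: str) -> np.ndarray:
        return self.true_signatures[kind][condition]


def _draw_count(rng: np.random.Generator, mean: float, dispersion: float | None) -> int:
    if mean <= 0:
        return 0
    if dispersion is None:
        return int(rng.poisson(mean))
    # negative binomial with variance = dispersion * mean
    p = 1.0 / dispersion
    n = mean * p / (1 - p)
    return int(rng.negative_binomial(n, p))


def simulate_experiment(
    config: SimulationConfig, out_dir
) -> tuple[Path, dict[str, Path], Path, Path, SimulationTruth]:
    """Generate a full experiment: FASTA, per-clone VCFs, manifest, truth.

    Returns ``(fasta, {clone: vcf}, manifest, parental_vcf, truth)``. The
    same config (seed included) always produces byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    genome = generate_reference(
        config.genome_length, config.n_contigs, config.gc_fraction,
        seed=int(rng.integers(2**31)),
    )
    placer = MutationPlacer(genome, rng)

    catalogs = {k: demo_signatures(k) for k in ("SBS96", "DBS78", "ID83")}
    bg_sbs = catalogs["SBS96"].vector(config.background_signature)
    bg_id = catalogs["ID83"].vector(config.background_id_signature)
    bg_dbs = catalogs["DBS78"].vector(config.background_dbs_signature)

    # parental variants: flat SNVs shared by every clone
    flat = catalogs["SBS96"].vector("flat")
    parental_records = [
        placer.place_sbs(SBS96.channels[int(rng.choice(96, p=flat))], "_parental")
        for _ in range(config.n_parental_variants)
    ]

    def draw_channels(vector: np.ndarray, axis: ChannelAxis, n: int) -> list[str]:
        idx = rng.choice(len(axis), size=n, p=vector)
        return [axis.channels[int(i)] for i in idx]

    clone_rows = []
    per_clone: dict[str, list[MutationRecord]] = {}
    sources: dict[str, dict[tuple, str]] = {}
    groups: list[CloneGroup] = []
    true_sigs: dict[str, dict[str, np.ndarray]] = {"SBS96": {}, "DBS78": {}, "ID83": {}}

    for gspec in config.groups:
        members: dict[str, str] = {}
        conditions = [(t.name, t) for t in gspec.treatments] + [(CONTROL_LABEL, None)]
        for cond_name, tspec in conditions:
            if tspec is not None:
                if tspec.sbs_burden > 0:
                    true_sigs["SBS96"][cond_name] = _mixture_vector(
                        tspec.sbs_mixture, catalogs["SBS96"])
                if tspec.dbs_burden > 0:
                    true_sigs["DBS78"][cond_name] = _mixture_vector(
                        tspec.dbs_mixture, catalogs["DBS78"])
                if tspec.id_burden > 0:
                    true_sigs["ID83"][cond_name] = _mixture_vector(
                        tspec.id_mixture, catalogs["ID83"])
            for i in range(1, config.clones_per_condition + 1):
                clone = f"{gspec.group_id}_{cond_name}_c{i}"
                members[clone] = cond_name if tspec is not None else CONTROL_LABEL
                placer.share_occupancy("_parental", clone)
                recs: list[MutationRecord] = [r.with_clone(clone) for r in parental_records]
                src = {r.key: "parental" for r in recs}

                def _add_sbs(vector, n, label):
                    for ch in draw_channels(vector, SBS96, n):
                        r = placer.place_sbs(ch, clone)
                        recs.append(r)
                        src[r.key] = label

                def _add_dbs(vector, n, label):
                    for ch in draw_channels(vector, DBS78, n):
                        r1, r2 = placer.place_dbs(ch, clone)
                        recs.extend([r1, r2])
                        src[r1.key] = src[r2.key] = label

                def _add_id(vector, n, label):
                    for ch in draw_channels(vector, ID83, n):
                        r = placer.place_id(ch, clone)
                        recs.append(r)
                        src[r.key] = label

                counts = {
                    "background_sbs": _draw_count(
                        rng, config.background_sbs_burden, config.dispersion),
                    "background_dbs": _draw_count(
                        rng, config.background_dbs_burden, config.dispersion),
                    "background_id": _draw_count(
                        rng, config.background_id_burden, config.dispersion),
                    "compound_sbs": 0, "compound_dbs": 0, "compound_id": 0,
                }
                _add_sbs(bg_sbs, counts["background_sbs"], "background")
                _add_dbs(bg_dbs, counts["background_dbs"], "background")
                _add_id(bg_id, counts["background_id"], "background")
                if tspec is not None:
                    counts["compound_sbs"] = _draw_count(rng, tspec.sbs_burden, config.dispersion)
                    counts["compound_dbs"] = _draw_count(rng, tspec.dbs_burden, config.dispersion)
                    counts["compound_id"] = _draw_count(rng, tspec.id_burden, config.dispersion)
                    if counts["compound_sbs"]:
                        _add_sbs(_mixture_vector(tspec.sbs_mixture, catalogs["SBS96"]),
                                 counts["compound_sbs"], "compound")
                    if counts["compound_dbs"]:
                        _add_dbs(_mixture_vector(tspec.dbs_mixture, catalogs["DBS78"]),
                                 counts["compound_dbs"], "compound")
                    if counts["compound_id"]:
                        _add_id(_mixture_vector(tspec.id_mixture, catalogs["ID83"]),
                                counts["compound_id"], "compound")
                per_clone[clone] = recs
                sources[clone] = src
                clone_rows.append({
                    "clone_id": clone, "group_id": gspec.group_id,
                    "treatment": members[clone],
                    "n_parental": len(parental_records), **counts,
                })
        groups.append(CloneGroup(gspec.group_id, members))

    # write outputs only after all placements (embedding edits the genome)
    fasta = out / "reference.fa"
    write_fasta(genome, fasta)
    lengths = genome.contig_lengths
    vcfs: dict[str, Path] = {}
    for clone, recs in per_clone.items():
        path = out / f"{clone}.vcf"
        write_vcf(recs, path, lengths)
        vcfs[clone] = path
    parental_vcf = out / "parental.vcf"
    write_vcf(parental_records, parental_vcf, lengths)
    manifest = out / "manifest.tsv"
    write_manifest(groups, manifest)

    clone_table = pd.DataFrame(clone_rows)
    clone_table.to_csv(out / "truth_clones.tsv", sep="\t", index=False)
    for kind, sigs in true_sigs.items():
        if sigs:
            axis = axis_by_name(kind)
            pd.DataFrame(sigs, index=list(axis.channels)).to_csv(
                out / f"truth_signatures_{kind}.tsv", sep="\t", index_label="MutationType")

    truth = SimulationTruth(clone_table, true_sigs, sources, placer.n_embedded)
    return fasta, vcfs, manifest, parental_vcf, truth
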