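"""Joint-calling groups and colony-exclusive variant selection.

Clonally expanded colonies are analysed in *groups*: each group holds the
clones that were variant-called together (treatment clones plus their
vehicle-control clones). Two filters turn raw per-clone calls into candidate
exposure-induced mutations:

1. **Parental removal** — variants already present in the clonal parental
   population are germline-like and removed from every clone.
2. **Colony exclusivity** — a variant is kept for a clone only if no other
   colony of the same calling group carries it. Shared variants are either
   pre-exposure or systematic artifacts, not single-cell mutagenesis events.

By default exclusivity is enforced against *all* colonies of the group,
controls included — the strictest census, and the one that best suppresses
shared artifacts. Restricting the census to clones of the same treatment is
available via ``scope="treatment"``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .variants import MutationRecord

__all__ = [
    "CloneGroup",
    "CONTROL_LABEL",
    "read_manifest",
    "write_manifest",
    "remove_parental",
    "select_exclusive",
]

CONTROL_LABEL = "control"

Key = tuple[str, int, str, str]


@dataclass
class CloneGroup:
    """One joint-calling group: clone -> treatment label, plus parental keys."""

    group_id: str
    members: dict[str, str]  # clone_id -> treatment label ("control" for vehicle)
    parental_variants: set[Key] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"group {self.group_id!r} needs at least 2 members")

    @property
    def clone_ids(self) -> list[str]:
        return list(self.members)

    @property
    def treatments(self) -> list[str]:
        """Distinct non-control treatment labels, in first-seen order."""
        seen: dict[str, None] = {}
        for label in self.members.values():
            if label != CONTROL_LABEL:
                seen.setdefault(label)
        return list(seen)

    @property
    def control_clones(self) -> list[str]:
        return [c for c, t in self.members.items() if t == CONTROL_LABEL]

    def clones_of(self, treatment: str) -> list[str]:
        return [c for c, t in self.members.items() if t == treatment]


def read_manifest(path) -> list[CloneGroup]:
    """Read a clone manifest TSV with columns clone_id, group_id, treatment."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"clone_id", "group_id", "treatment"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}, got {list(df.columns)}")
    if df["clone_id"].duplicated().any():
        dupes = df.loc[df["clone_id"].duplicated(), "clone_id"].tolist()
        raise ValueError(f"clones assigned to more than one group: {dupes}")
    groups = []
    for group_id, sub in df.groupby("group_id", sort=False):
        members = dict(zip(sub["clone_id"], sub["treatment"]))
        groups.append(CloneGroup(str(group_id), members))
    return groups


def write_manifest(groups: list[CloneGroup], path) -> None:
    rows = [
        {"clone_id": clone, "group_id": g.group_id, "treatment": label}
        for g in groups
        for clone, label in g.members.items()
    ]
    pd.DataFrame(rows, columns=["clone_id", "group_id", "treatment"]).to_csv(
        path, sep="\t", index=False
    )


def remove_parental(
    records: dict[str, list[MutationRecord]], parental: set[Key]
) -> tuple[dict[str, list[MutationRecord]], dict[str, int]]:
    """Drop every record whose identity key is in the parental set.

    Returns the filtered per-clone lists and the per-clone removed counts.
    An empty parental set is legal and leaves the input unchanged.
    """
    kept: dict[str, list[MutationRecord]] = {}
    removed: dict[str, int] = {}
    for clone, recs in records.items():
        kept[clone] = [r for r in recs if r.key not in parental]
        removed[clone] = len(recs) - len(kept[clone])
    return kept, removed


def select_exclusive(
    group: CloneGroup,
    records: dict[str, list[MutationRecord]],
    scope: str = "group",
) -> dict[str, list[MutationRecord]]:
    """Keep, per clone, only variants carried by no other colony in the census.

    ``scope="group"`` (default) counts every colony of the group as a carrier,
    controls and other treatments included; ``scope="treatment"`` restricts
    the census to colonies with the clone's own treatment label. A record is
    retained iff its identity key has exactly one carrier in its census.
    """
    if scope not in ("group", "treatment"):
        raise ValueError(f"scope must be 'group' or 'treatment', got {scope!r}")
    unknown = set(records) - set(group.members)
    if unknown:
        raise ValueError(f"clones not in group {group.group_id!r}: {sorted(unknown)}")

    # carriers per key: a clone carries a key at most once in the census
    def census(clone: str) -> Counter:
        if scope == "group":
            members = records.keys()
        else:
            label = group.members[clone]
            members = [c for c in records if group.members[c] == label]
        counts: Counter = Counter()
        for c in members:
            counts.update({r.key for r in records[c]})
        return counts

    if scope == "group":
        carriers = census(next(iter(records), ""))
        return {
            clone: [r for r in recs if carriers[r.key] == 1]
            for clone, recs in records.items()
        }
    out: dict[str, list[MutationRecord]] = {}
    for clone, recs in records.items():
        carriers = census(clone)
        out[clone] = [r for r in recs if carriers[r.key] == 1]
    return out
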