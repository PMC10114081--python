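"""Canonical mutation-classification channel axes.

Three fixed axes are supported, matching the COSMIC catalog conventions:

* **SBS96** — single-base substitutions, pyrimidine-centred, in trinucleotide
  context (6 substitution types x 16 flanking contexts), e.g. ``A[C>A]A``.
* **DBS78** — doublet-base substitutions, reverse-complement collapsed onto
  78 canonical ``NN>NN`` channels.
* **ID83** — small insertions/deletions binned by event size, homopolymer
  run length, tandem-repeat copy number and microhomology length,
  e.g. ``1:Del:T:3`` or ``4:Del:M:2``.

The channel names and their order are frozen in plain-text tables shipped
with the package; every spectrum, matrix and catalog in this package uses
these orders bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

__all__ = ["ChannelAxis", "SBS96", "DBS78", "ID83", "axis_by_name", "axis_for_size"]


def _load_table(name: str) -> tuple[str, ...]:
    text = resources.files("sigdissect.data").joinpath(name).read_text()
    return tuple(line for line in text.splitlines() if line)


@dataclass(frozen=True)
class ChannelAxis:
    """An ordered, fixed set of mutation channels."""

    kind: str
    channels: tuple[str, ...]
    _index: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(self.channels)})
        if len(self._index) != len(self.channels):
            raise ValueError(f"duplicate channel names on axis {self.kind}")

    def __len__(self) -> int:
        return len(self.channels)

    def __contains__(self, channel: str) -> bool:
        return channel in self._index

    def index(self, channel: str) -> int:
        try:
            return self._index[channel]
        except KeyError:
            raise KeyError(f"{channel!r} is not a channel of axis {self.kind}") from None


SBS96 = ChannelAxis("SBS96", _load_table("sbs96.txt"))
DBS78 = ChannelAxis("DBS78", _load_table("dbs78.txt"))
ID83 = ChannelAxis("ID83", _load_table("id83.txt"))

assert len(SBS96) == 96 and len(DBS78) == 78 and len(ID83) == 83

_BY_NAME = {"SBS96": SBS96, "DBS78": DBS78, "ID83": ID83}
_BY_SIZE = {96: SBS96, 78: DBS78, 83: ID83}


def axis_by_name(kind: str) -> ChannelAxis:
    try:
        return _BY_NAME[kind]
    except KeyError:
        raise ValueError(f"unknown channel axis {kind!r}; expected one of {sorted(_BY_NAME)}") from None


def axis_for_size(n: int) -> ChannelAxis:
    """Infer the axis from a vector length (96, 78 or 83)."""
    try:
        return _BY_SIZE[n]
    except KeyError:
        raise ValueError(f"no channel axis has {n} channels") from None
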