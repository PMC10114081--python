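"""Channel-count spectra: counting, control subtraction, aggregation.

The quantities mirror the clonal-expansion analysis: per-clone raw channel
counts; treatment counts with the mean vehicle-control spectrum subtracted
channel-wise (clamped at zero — counts cannot go negative); the mean +- SD
over the five biological replicates; and the probability-normalized
signature used for catalog comparison.

Subtraction is applied per treatment clone against the *mean* of the control
clones, before replicate averaging. With clamping the alternative order
(average the treatment clones first, then subtract) is not equivalent; it is
available via ``order="aggregate"`` in :func:`compound_signature`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .channels import ChannelAxis
from .classify import ClassifiedMutation

__all__ = [
    "Spectrum",
    "count_spectrum",
    "mean_spectrum",
    "subtract_control",
    "total_burden",
    "to_probability",
    "compound_signature",
    "spectra_to_frame",
]


@dataclass(frozen=True)
class Spectrum:
    """A count or probability vector over one canonical channel axis."""

    axis: ChannelAxis
    counts: np.ndarray
    sample_id: str
    kind: str = "raw_counts"  # raw_counts | control_subtracted | mean | probability

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (len(self.axis),):
            raise ValueError(
                f"spectrum length {counts.shape} does not match axis "
                f"{self.axis.kind} ({len(self.axis)})"
            )
        if (counts < 0).any():
            raise ValueError("spectrum counts must be non-negative")
        if self.kind == "raw_counts" and not np.allclose(counts, np.round(counts)):
            raise ValueError("raw counts must be integers")
        if self.kind == "probability" and counts.sum() > 0:
            if abs(counts.sum() - 1.0) > 1e-9:
                raise ValueError("probability spectrum must sum to 1 +- 1e-9")
        object.__setattr__(self, "counts", counts)

    @property
    def is_zero(self) -> bool:
        """True for the flagged all-zero state (empty signature)."""
        return bool(self.counts.sum() == 0)

    def __getitem__(self, channel: str) -> float:
        return float(self.counts[self.axis.index(channel)])


def count_spectrum(
    classified: list[ClassifiedMutation], axis: ChannelAxis, sample_id: str = ""
) -> Spectrum:
    """Tally classified mutations into a raw count spectrum."""
    counts = np.zeros(len(axis), dtype=float)
    for cm in classified:
        if not cm.is_classified:
            raise ValueError("count_spectrum accepts classified mutations only")
        if cm.axis is not axis:
            raise ValueError(f"mutation on axis {cm.axis.kind}, expected {axis.kind}")
        counts[axis.index(cm.channel)] += 1
    return Spectrum(axis, counts, sample_id, "raw_counts")


def _check_same_axis(spectra: list[Spectrum]) -> ChannelAxis:
    if not spectra:
        raise ValueError("need at least one spectrum")
    axis = spectra[0].axis
    for s in spectra[1:]:
        if s.axis is not axis:
            raise ValueError(f"axis mismatch: {s.axis.kind} vs {axis.kind}")
    return axis


def mean_spectrum(spectra: list[Spectrum], sample_id: str = "mean") -> tuple[Spectrum, np.ndarray]:
    """Element-wise mean over replicates, with the per-channel sample SD.

    SD uses the n-1 denominator and is all-zero when a single spectrum is
    given.
    """
    axis = _check_same_axis(spectra)
    stack = np.stack([s.counts for s in spectra])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(spectra) > 1 else np.zeros(len(axis))
    return Spectrum(axis, mean, sample_id, "mean"), sd


def subtract_control(treatment: Spectrum, control_mean: Spectrum) -> tuple[Spectrum, int]:
    """Channel-wise ``max(0, treatment - control)``; reports clamped channels.

    The clamp count is the number of channels where the difference was
    negative and forced to zero; a large count flags a treatment whose burden
    barely exceeds background.
    """
    if treatment.axis is not control_mean.axis:
        raise ValueError(
            f"axis mismatch: {treatment.axis.kind} vs {control_mean.axis.kind}"
        )
    diff = treatment.counts - control_mean.counts
    clamped = int((diff < 0).sum())
    out = Spectrum(treatment.axis, np.maximum(diff, 0.0), treatment.sample_id, "control_subtracted")
    return out, clamped


def total_burden(spectrum: Spectrum) -> float:
    """Total mutation count of the spectrum (sum over channels)."""
    return float(spectrum.counts.sum())


def to_probability(spectrum: Spectrum) -> Spectrum:
    """Normalize to relative channel frequencies summing to 1.

    An all-zero spectrum stays all-zero (flagged via ``Spectrum.is_zero``)
    rather than becoming NaN.
    """
    total = spectrum.counts.sum()
    if total == 0:
        return replace(spectrum, kind="probability")
    return Spectrum(spectrum.axis, spectrum.counts / total, spectrum.sample_id, "probability")


def compound_signature(
    treatment_spectra: list[Spectrum],
    control_spectra: list[Spectrum],
    sample_id: str = "",
    order: str = "per-clone",
) -> tuple[Spectrum, dict]:
    """Derive one compound's signature from its treatment and control clones.

    Default (``order="per-clone"``): subtract the control mean from each
    treatment clone, average the subtracted clones, then normalize to a
    probability spectrum. ``order="aggregate"`` averages the treatment clones
    first and subtracts once. Returns the signature plus a small stats dict
    (mean burden after subtraction, per-channel SD, clamped-channel counts).
    """
    if order not in ("per-clone", "aggregate"):
        raise ValueError(f"order must be 'per-clone' or 'aggregate', got {order!r}")
    control_mean, _ = mean_spectrum(control_spectra, "control_mean")
    if order == "per-clone":
        subtracted, clamps = zip(*(subtract_control(s, control_mean) for s in treatment_spectra))
        mean, sd = mean_spectrum(list(subtracted), sample_id)
    else:
        raw_mean, sd = mean_spectrum(treatment_spectra, sample_id)
        mean, clamp = subtract_control(raw_mean, control_mean)
        clamps = (clamp,)
    stats = {
        "burden": total_burden(mean),
        "sd": sd,
        "clamped_channels": list(clamps),
        "control_mean_burden": total_burden(control_mean),
    }
    return to_probability(mean), stats


def plot_spectrum(spectrum: Spectrum, path, title: str | None = None) -> None:
    """Export a spectrum as a simple channel bar plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(8, len(spectrum.axis) / 8), 3))
    ax.bar(range(len(spectrum.axis)), spectrum.counts, width=0.8)
    ax.set_xticks(range(len(spectrum.axis)))
    ax.set_xticklabels(spectrum.axis.channels, rotation=90, fontsize=4)
    ax.set_ylabel("probability" if spectrum.kind == "probability" else "count")
    ax.set_title(title or f"{spectrum.sample_id} ({spectrum.axis.kind})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def spectra_to_frame(spectra: list[Spectrum]) -> pd.DataFrame:
    """Stack spectra of one axis into a channels-by-samples DataFrame."""
    axis = _check_same_axis(spectra)
    return pd.DataFrame(
        {s.sample_id: s.counts for s in spectra}, index=list(axis.channels)
    )
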