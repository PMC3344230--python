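"""Flow-cytometric ploidy calling and spore-count reproduction typing.

Genome size is estimated from the ratio of the sample G1 peak to a co-run
calibration standard (default: a tetraploid tobacco standard of 20.08 pg).
In the hybrid complexes this package targets, sample/standard ratios fall
near 1.2, 1.8 and 2.4 for diploids, triploids and tetraploids — i.e. ratio
~ 0.6 x ploidy — so a nearest-reference rule with a non-overlapping
tolerance converts a ratio into a ploidy call.

Reproduction mode follows the classical sporangium rule for homosporous
ferns: sexual plants package 64 spores per sporangium, apogamous plants 32
or fewer; intermediate counts are never forced into either class.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.signal import find_peaks

#: reference sample/standard ratios and the ploidy each one implies
REFERENCE_RATIOS: dict[float, int] = {1.2: 2, 1.8: 3, 2.4: 4}
#: 4X calibration standard genome size, picograms
STANDARD_GENOME_PG = 20.08


class UnresolvableHistogramError(ValueError):
    """Raised when fewer than two G1 peaks can be resolved."""


@dataclass(frozen=True)
class FluorescenceHistogram:
    """A propidium-iodide fluorescence histogram (channel, count) pairs."""

    sample_id: str
    channels: tuple[float, ...]
    counts: tuple[int, ...]
    standard_id: str = "standard"

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(float(c) for c in self.channels))
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        if len(self.channels) != len(self.counts):
            raise ValueError("channels and counts differ in length")
        ch = np.asarray(self.channels)
        if len(ch) < 3 or not np.all(np.diff(ch) > 0):
            raise ValueError("channels must be strictly increasing")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if sum(self.counts) == 0:
            raise ValueError("histogram is empty")

    @classmethod
    def from_csv(cls, path: str | Path, sample_id: str | None = None,
                 standard_id: str = "standard") -> "FluorescenceHistogram":
        """Read a ``channel,count`` CSV (header required)."""
        channels: list[float] = []
        counts: list[int] = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or {"channel", "count"} - set(reader.fieldnames):
                raise ValueError(f"{path}: expected header 'channel,count'")
            for row in reader:
                channels.append(float(row["channel"]))
                counts.append(int(row["count"]))
        return cls(sample_id or Path(path).stem, tuple(channels), tuple(counts), standard_id)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["channel", "count"])
            for ch, ct in zip(self.channels, self.counts):
                writer.writerow([ch, ct])


@dataclass(frozen=True)
class PloidyCall:
    """Outcome of the nearest-reference ratio rule."""

    ratio: float
    genome_size_pg: float
    ploidy: int | Literal["uncalled"]
    sample_peak: float
    standard_peak: float
    standard_genome_pg: float = STANDARD_GENOME_PG


@dataclass(frozen=True)
class ReproductionCall:
    spore_counts: tuple[int, ...]
    mode: Literal["sexual", "apogamous", "indeterminate"]


def detect_g1_peaks(
    hist: FluorescenceHistogram,
    smoothing_window: int = 5,
    min_prominence_fraction: float = 0.10,
) -> list[float]:
    """Locate G1 peaks as channel positions of the smoothed histogram.

    The histogram counts are smoothed with a centred moving average and local
    maxima with prominence below ``min_prominence_fraction`` of the smoothed
    maximum are discarded (this removes G2 doublets and debris shoulders).

    Raises
    ------
    UnresolvableHistogramError
        If fewer than two qualifying peaks remain (standard + sample are
        expected in a co-run histogram).
    """
    counts = np.asarray(hist.counts, dtype=float)
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        smoothed = np.convolve(counts, kernel, mode="same")
    else:
        smoothed = counts
    prominence = min_prominence_fraction * smoothed.max()
    idx, _ = find_peaks(smoothed, prominence=prominence)
    peaks = sorted(hist.channels[i] for i in idx)
    if len(peaks) < 2:
        raise UnresolvableHistogramError(
            f"{hist.sample_id}: only {len(peaks)} peak(s) resolved; "
            "need standard + sample"
        )
    return peaks


def call_ploidy(
    sample_peak: float,
    standard_peak: float,
    standard_genome_pg: float = STANDARD_GENOME_PG,
    reference_ratios: dict[float, int] | None = None,
    tolerance: float = 0.15,
) -> PloidyCall:
    """Convert peak positions into genome size and a ploidy call.

    genome size = (sample/standard ratio) x standard genome size; ploidy is
    the reference ratio nearest to the observed ratio if within ``tolerance``
    (default 0.15, the maximal tolerance that keeps the 1.2/1.8/2.4
    references non-overlapping), else ``"uncalled"``.
    """
    if sample_peak <= 0 or standard_peak <= 0:
        raise ValueError("peak positions must be positive")
    refs = REFERENCE_RATIOS if reference_ratios is None else reference_ratios
    ratio = sample_peak / standard_peak
    genome = ratio * standard_genome_pg
    nearest = min(refs, key=lambda r: abs(ratio - r))
    ploidy: int | Literal["uncalled"]
    ploidy = refs[nearest] if abs(ratio - nearest) <= tolerance else "uncalled"
    return PloidyCall(ratio, genome, ploidy, sample_peak, standard_peak, standard_genome_pg)


def call_sample(
    hist: FluorescenceHistogram,
    standard_peak: float | None = None,
    smoothing_window: int = 5,
    min_prominence_fraction: float = 0.10,
    **ploidy_kwargs,
) -> PloidyCall:
    """Detect peaks and call ploidy for one co-run histogram.

    When ``standard_peak`` is not supplied, the lowest-channel qualifying
    peak is taken as the calibration standard (the 4X standard sits below
    the sample peaks whenever ratios are >= 1.2) and the most intense
    remaining peak as the sample G1 peak.
    """
    peaks = detect_g1_peaks(hist, smoothing_window, min_prominence_fraction)
    if standard_peak is None:
        standard = peaks[0]
        rest = peaks[1:]
    else:
        standard = standard_peak
        rest = [p for p in peaks if p != standard] or peaks
    counts = np.asarray(hist.counts, dtype=float)
    channels = np.asarray(hist.channels)
    heights = [counts[int(np.argmin(np.abs(channels - p)))] for p in rest]
    sample = rest[int(np.argmax(heights))]
    return call_ploidy(sample, standard, **ploidy_kwargs)


def classify_reproduction(
    spore_counts: Sequence[int],
    sexual_count: int = 64,
    apogamous_max: int = 32,
    slack: int = 0,
) -> ReproductionCall:
    """Classify reproduction mode from per-sporangium spore counts.

    Each sporangium is labelled sexual (count within ``slack`` of 64),
    apogamous (count <= 32), or indeterminate (the 33-63 gap, never observed
    in practice).  The plant-level mode is the majority label; ties give
    indeterminate.
    """
    counts = tuple(int(c) for c in spore_counts)
    if not counts:
        raise ValueError("no spore counts supplied")
    if any(c < 0 for c in counts):
        raise ValueError("spore counts must be >= 0")
    labels = []
    for c in counts:
        if abs(c - sexual_count) <= slack:
            labels.append("sexual")
        elif c <= apogamous_max:
            labels.append("apogamous")
        else:
            labels.append("indeterminate")
    tally = {m: labels.count(m) for m in set(labels)}
    best = max(tally.values())
    winners = [m for m, n in tally.items() if n == best]
    mode = winners[0] if len(winners) == 1 else "indeterminate"
    return ReproductionCall(counts, mode)
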