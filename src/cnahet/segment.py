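"""Piecewise-constant segmentation of log2-ratio profiles.

Breakpoints are found by penalized recursive binary splitting: within a
segment, the candidate split maximizing the reduction in residual sum of
squares (RSS) is accepted when the reduction exceeds a BIC-like penalty of
``penalty * sigma^2 * log(n)`` per breakpoint, where ``sigma`` is a robust
per-chromosome noise estimate (median absolute successive difference,
scaled).  A final bottom-up merge pass removes redundant breakpoints whose
removal costs less than the penalty, so noise-free piecewise-constant input
yields the minimal breakpoint set with zero residual.  Adaptive-weights
smoothing engines used elsewhere for this stage can be substituted via
:func:`import_segments`, which reads externally produced SEG files.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from cnahet.probes import FormatError, ProbeProfile

logger = logging.getLogger(__name__)

SEG_COLUMNS = ["Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean"]


@dataclass(frozen=True)
class Segment:
    """A constant-copy-number run of consecutive probes on one chromosome.

    Probe indices are within-chromosome and inclusive; bp coordinates are
    0-based half-open.
    """

    sample_id: str
    chromosome: str
    first_probe_index: int
    last_probe_index: int
    start_bp: int
    end_bp: int
    n_probes: int
    mean_log2: float

    def __post_init__(self) -> None:
        if self.n_probes != self.last_probe_index - self.first_probe_index + 1:
            raise ValueError("n_probes inconsistent with probe index range")
        if self.n_probes < 1:
            raise ValueError("segment must contain at least one probe")


@dataclass
class SegmentationParams:
    """Model-selection settings for the breakpoint search.

    ``penalty``: multiplier on ``sigma^2 * log(n)`` charged per breakpoint
    (2.0 approximates BIC for Gaussian noise).  ``min_seg_probes``: minimal
    probes per segment (1; the three-oligo rule belongs to calling, not
    segmentation).  ``max_breakpoints``: safety cap per chromosome.
    """

    penalty: float = 2.0
    min_seg_probes: int = 1
    max_breakpoints: int = 2000

    def __post_init__(self) -> None:
        if self.penalty <= 0:
            raise ValueError("penalty must be > 0")
        if self.min_seg_probes < 1:
            raise ValueError("min_seg_probes must be >= 1")


def estimate_noise_sd(values: np.ndarray) -> float:
    """Robust noise sd from median absolute successive differences.

    For i.i.d. Gaussian noise, ``diff`` has sd ``sigma * sqrt(2)`` and the
    median absolute value of a centered Gaussian is ``0.6745 * sd``; true
    copy-number steps are sparse in the diffs and barely move the median.
    """
    if len(values) < 2:
        return 0.0
    d = np.abs(np.diff(values))
    return float(np.median(d) / (math.sqrt(2.0) * 0.674489750196082))


def _split_gains(csum: np.ndarray, lo: int, hi: int, min_len: int) -> tuple[int, float]:
    """Best split of [lo, hi): returns (k, RSS reduction); leftmost on ties."""
    n = hi - lo
    if n < 2 * min_len:
        return -1, 0.0
    s = csum[hi] - csum[lo]
    ks = np.arange(lo + min_len, hi - min_len + 1)
    n1 = ks - lo
    n2 = n - n1
    s1 = csum[ks] - csum[lo]
    s2 = s - s1
    gains = s1 * s1 / n1 + s2 * s2 / n2 - s * s / n
    i = int(np.argmax(gains))
    return int(ks[i]), float(gains[i])


def _binary_segment(values: np.ndarray, params: SegmentationParams) -> list[int]:
    """Return sorted interior breakpoints (split indices) of ``values``."""
    n = len(values)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    sigma = estimate_noise_sd(values)
    threshold = max(params.penalty * sigma * sigma * math.log(max(n, 2)), 1e-12)

    breakpoints: list[int] = []
    stack = [(0, n)]
    while stack and len(breakpoints) < params.max_breakpoints:
        lo, hi = stack.pop()
        k, gain = _split_gains(csum, lo, hi, params.min_seg_probes)
        if k >= 0 and gain > threshold:
            breakpoints.append(k)
            stack.append((lo, k))
            stack.append((k, hi))
    breakpoints.sort()

    # bottom-up merge: drop breakpoints whose removal costs <= threshold
    changed = True
    while changed and breakpoints:
        changed = False
        bounds = [0] + breakpoints + [n]
        costs = []
        for i in range(1, len(bounds) - 1):
            a, b, c = bounds[i - 1], bounds[i], bounds[i + 1]
            s1 = csum[b] - csum[a]
            s2 = csum[c] - csum[b]
            n1, n2 = b - a, c - b
            cost = s1 * s1 / n1 + s2 * s2 / n2 - (s1 + s2) ** 2 / (n1 + n2)
            costs.append(cost)
        i = int(np.argmin(costs))
        if costs[i] <= threshold:
            del breakpoints[i]
            changed = True
    return breakpoints


def segment_chromosome(
    values: np.ndarray,
    params: SegmentationParams | None = None,
    sample_id: str = "",
    chromosome: str = "",
    starts: np.ndarray | None = None,
    ends: np.ndarray | None = None,
) -> list[Segment]:
    """Segment one chromosome's ordered log2 ratios into constant pieces.

    ``starts``/``ends`` give probe bp coordinates; when omitted, probe index
    stands in for position.  Deterministic: ties in RSS reduction break to
    the leftmost split.
    """
    params = params or SegmentationParams()
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot segment an empty chromosome")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite log2 ratios in segmentation input")
    if starts is None:
        starts = np.arange(len(values), dtype=np.int64)
    if ends is None:
        ends = starts + 1
    breakpoints = _binary_segment(values, params)
    bounds = [0] + breakpoints + [len(values)]
    segments = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        segments.append(
            Segment(
                sample_id=sample_id,
                chromosome=chromosome,
                first_probe_index=lo,
                last_probe_index=hi - 1,
                start_bp=int(starts[lo]),
                end_bp=int(ends[hi - 1]),
                n_probes=hi - lo,
                mean_log2=float(np.mean(values[lo:hi])),
            )
        )
    return segments


def segment_profile(
    profile: ProbeProfile, params: SegmentationParams | None = None
) -> list[Segment]:
    """Segment every chromosome of a cleaned profile; segments never span chromosomes."""
    params = params or SegmentationParams()
    segments: list[Segment] = []
    for chrom, group in profile.probes.groupby("chromosome", sort=False):
        values = group["log_ratio"].to_numpy()
        if values.size == 0:
            logger.info("%s: chromosome %s has no probes; skipped", profile.sample_id, chrom)
            continue
        segments.extend(
            segment_chromosome(
                values,
                params,
                sample_id=profile.sample_id,
                chromosome=str(chrom),
                starts=group["start"].to_numpy(),
                ends=group["end"].to_numpy(),
            )
        )
    return segments


def write_seg(segments: list[Segment], path: str | Path) -> None:
    """Write segments as a SEG-style TSV (1-based inclusive coordinates)."""
    rows = [
        (s.sample_id, s.chromosome, s.start_bp + 1, s.end_bp, s.n_probes, s.mean_log2)
        for s in segments
    ]
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.9f"
    )


def import_segments(
    path: str | Path, profiles: dict[str, ProbeProfile] | None = None
) -> list[Segment]:
    """Read a SEG file (own export, or external CBS/GLAD-style output).

    When matching probe profiles are supplied, probe counts and means are
    recomputed from probe data and validated; otherwise rows are accepted
    as-is with a provenance note.  Overlapping rows within one
    sample/chromosome are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing SEG column(s): {', '.join(missing)}")
    if (df["End"] < df["Start"]).any():
        bad = df[df["End"] < df["Start"]].iloc[0]
        raise FormatError(f"{path}: segment end < start on {bad['Chromosome']}")
    segments: list[Segment] = []
    for (sample, chrom), group in df.groupby(["Sample", "Chromosome"], sort=False):
        g = group.sort_values("Start")
        if (g["Start"].to_numpy()[1:] <= g["End"].to_numpy()[:-1]).any():
            raise FormatError(f"{path}: overlapping segments for {sample}/{chrom}")
        probe_idx = 0
        for _, row in g.iterrows():
            start0, end0 = int(row["Start"]) - 1, int(row["End"])
            n_probes = int(row["Num_Probes"])
            mean = float(row["Segment_Mean"])
            if profiles is not None and sample in profiles:
                probes = profiles[sample].probes
                mask = (
                    (probes["chromosome"].astype(str) == str(chrom))
                    & (probes["start"] >= start0)
                    & (probes["start"] < end0)
                )
                observed = probes.loc[mask, "log_ratio"].to_numpy()
                if len(observed) != n_probes:
                    raise FormatError(
                        f"{path}: {sample}/{chrom}:{row['Start']}-{row['End']} claims "
                        f"{n_probes} probes but profile has {len(observed)}"
                    )
                if observed.size and abs(float(np.mean(observed)) - mean) > 1e-6:
                    raise FormatError(
                        f"{path}: segment mean mismatch for {sample}/{chrom}:{row['Start']}"
                    )
            segments.append(
                Segment(
                    sample_id=str(sample),
                    chromosome=str(chrom),
                    first_probe_index=probe_idx,
                    last_probe_index=probe_idx + n_probes - 1,
                    start_bp=start0,
                    end_bp=end0,
                    n_probes=n_probes,
                    mean_log2=mean,
                )
            )
            probe_idx += n_probes
    if profiles is None:
        logger.info("%s: imported %d segments without probe-level validation", path, len(segments))
    return segments
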