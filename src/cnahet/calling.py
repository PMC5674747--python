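"""Gain/loss calling on segments and per-sample CNA accounting.

A segment becomes a copy-number alteration (CNA) call when it spans at least
three oligos, its mean absolute log2 ratio reaches 0.2, and its linear
sample/reference ratio exceeds 1.2 (gain) or falls below 0.8 (loss).  The
ratio thresholds (|log2| of 0.263 and 0.322) subsume the 0.2 prefilter; both
are applied literally because the upstream protocol states both rules.  No
distinction is made between low- and high-level events: every call is
``gain`` or ``loss``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cnahet.segment import Segment

logger = logging.getLogger(__name__)

GAIN, LOSS, NEUTRAL = 1, -1, 0
STATE_NAMES = {GAIN: "gain", LOSS: "loss", NEUTRAL: "neutral"}


@dataclass
class CallingParams:
    """CNA-calling thresholds.

    ``amplitude_only`` switches to the alternative reading in which
    ``|log2| >= min_abs_log2`` is the operative threshold and direction
    follows the sign (the ratio cutoffs then act as descriptions only).
    """

    min_probes: int = 3
    min_abs_log2: float = 0.2
    gain_ratio: float = 1.2
    loss_ratio: float = 0.8
    amplitude_only: bool = False
    include_sex_chromosomes: bool = True

    def __post_init__(self) -> None:
        if not (self.gain_ratio > 1 > self.loss_ratio > 0):
            raise ValueError("need gain_ratio > 1 > loss_ratio > 0")
        if self.min_probes < 1 or self.min_abs_log2 < 0:
            raise ValueError("min_probes >= 1 and min_abs_log2 >= 0 required")

    def segment_state(self, mean_log2: float) -> int:
        """State a segment's amplitude implies, ignoring the probe-count rule."""
        if abs(mean_log2) < self.min_abs_log2:
            return NEUTRAL
        if self.amplitude_only:
            return GAIN if mean_log2 > 0 else LOSS
        ratio = 2.0 ** mean_log2
        if ratio > self.gain_ratio:
            return GAIN
        if ratio < self.loss_ratio:
            return LOSS
        return NEUTRAL


@dataclass(frozen=True)
class CNACall:
    """A called gain or loss: a segment plus its state."""

    segment: Segment
    state: int  # GAIN or LOSS

    @property
    def state_name(self) -> str:
        return STATE_NAMES[self.state]


def call_segments(segments: list[Segment], params: CallingParams | None = None) -> list[CNACall]:
    """Apply the three-oligo, amplitude and ratio rules to produce CNA calls."""
    params = params or CallingParams()
    calls = []
    for seg in segments:
        if not params.include_sex_chromosomes and str(seg.chromosome) in ("X", "Y"):
            continue
        if seg.n_probes < params.min_probes:
            continue
        state = params.segment_state(seg.mean_log2)
        if state != NEUTRAL:
            calls.append(CNACall(seg, state))
    return calls


def sample_inclusion(
    segments_by_sample: dict[str, list[Segment]],
    calls_by_sample: dict[str, list[CNACall]],
    params: CallingParams | None = None,
) -> pd.DataFrame:
    """Flag samples whose every aberrant segment is too short to call.

    A sample with aberrant signal (segments whose amplitude would qualify)
    but zero surviving calls is excluded from all downstream analysis; a
    sample with no aberrant segment at all stays in with zero CNAs.
    Returns a DataFrame: SampleID, n_calls, n_aberrant_segments, included.
    """
    params = params or CallingParams()
    rows = []
    for sample, segments in segments_by_sample.items():
        n_aberrant = sum(1 for s in segments if params.segment_state(s.mean_log2) != NEUTRAL)
        n_calls = len(calls_by_sample.get(sample, []))
        included = n_calls > 0 or n_aberrant == 0
        if not included:
            logger.warning(
                "%s: %d aberrant segments, all spanning < %d oligos; excluded",
                sample, n_aberrant, params.min_probes,
            )
        rows.append((sample, n_calls, n_aberrant, included))
    return pd.DataFrame(rows, columns=["SampleID", "n_calls", "n_aberrant_segments", "included"])


def cna_counts(
    calls_by_sample: dict[str, list[CNACall]],
    sample_sheet: pd.DataFrame,
    included: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample and per-site CNA counts.

    Returns ``(per_sample, per_group)``.  Group medians use the midpoint
    convention for even group sizes (median of {2, 4} is 3.0).  Groups with
    no included sample are omitted with a notice.
    """
    meta = sample_sheet.set_index("SampleID")
    rows = []
    for sample in sample_sheet["SampleID"]:
        if included is not None and sample not in included:
            continue
        calls = calls_by_sample.get(sample, [])
        gains = sum(1 for c in calls if c.state == GAIN)
        losses = sum(1 for c in calls if c.state == LOSS)
        rows.append(
            (sample, meta.loc[sample, "PatientID"], meta.loc[sample, "Site"],
             gains, losses, gains + losses)
        )
    per_sample = pd.DataFrame(
        rows, columns=["SampleID", "PatientID", "Site", "gains", "losses", "total"]
    )
    group_rows = []
    for site in ("PT", "LNM", "OM"):
        g = per_sample[per_sample["Site"] == site]
        if g.empty:
            logger.info("no included samples for site %s; omitted from summary", site)
            continue
        group_rows.append(
            (
                site,
                len(g),
                float(np.median(g["total"])), int(g["total"].min()), int(g["total"].max()),
                float(np.median(g["gains"])), int(g["gains"].min()), int(g["gains"].max()),
                float(np.median(g["losses"])), int(g["losses"].min()), int(g["losses"].max()),
            )
        )
    per_group = pd.DataFrame(
        group_rows,
        columns=[
            "Site", "n",
            "median_total", "min_total", "max_total",
            "median_gains", "min_gains", "max_gains",
            "median_losses", "min_losses", "max_losses",
        ],
    )
    return per_sample, per_group


def calls_to_frame(calls: list[CNACall]) -> pd.DataFrame:
    """BED-like export table (1-based inclusive coordinates)."""
    rows = [
        (
            c.segment.sample_id, c.segment.chromosome,
            c.segment.start_bp + 1, c.segment.end_bp,
            c.state_name, c.segment.mean_log2, c.segment.n_probes,
        )
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=["Sample", "Chromosome", "Start", "End", "State", "Mean_log2", "Num_Probes"],
    )
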