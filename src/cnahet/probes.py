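"""Probe-table IO, QC filtering, log-base conversion and median centering.

Input files are TSV probe tables modeled on Feature Extraction exports:
one row per oligo with a log ratio and 0/1 QC flag columns.  Files carry
1-based inclusive coordinates; in memory everything is 0-based half-open.
The standard cleaning sequence is::

    profile = read_probe_table(path, sample_id)
    profile = apply_qc(profile, QCPolicy())
    profile = to_log2(profile)
    profile = median_center(profile)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cnahet.genome import chromosome_sort_key

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["ProbeName", "Chromosome", "Start", "End", "LogRatio"]

DEFAULT_FLAG_COLUMNS = [
    "gIsSaturated",
    "rIsSaturated",
    "gIsFeatNonUnifOL",
    "rIsFeatNonUnifOL",
]


class FormatError(ValueError):
    """Malformed probe table or segment file."""


@dataclass
class ProbeProfile:
    """One sample's ordered probe-level log-ratio profile.

    ``probes`` columns: probe_id, chromosome, start, end (0-based half-open),
    log_ratio.  ``ratio_base`` records the logarithm base of ``log_ratio``
    (10 as exported upstream, 2 after :func:`to_log2`).
    """

    sample_id: str
    probes: pd.DataFrame
    ratio_base: float = 10.0
    chrom_order: list[str] | None = None
    qc_applied: bool = False

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def log_ratios(self) -> np.ndarray:
        return self.probes["log_ratio"].to_numpy()

    def chromosomes(self) -> list[str]:
        """Chromosome names in profile order."""
        seen: list[str] = []
        for c in self.probes["chromosome"]:
            if not seen or seen[-1] != c:
                seen.append(c)
        return seen

    def values_by_chromosome(self) -> dict[str, np.ndarray]:
        return {
            c: g["log_ratio"].to_numpy()
            for c, g in self.probes.groupby("chromosome", sort=False)
        }


@dataclass
class QCPolicy:
    """Which probes to discard before analysis.

    ``flag_columns``: any listed 0/1 column equal to 1 removes the probe
    (saturation and feature-non-uniformity flags).  ``drop_zero_ratio``
    removes probes whose log ratio is exactly 0: the upstream extraction
    software sets the ratio to 0 when background exceeds signal, so exact
    zeros are sentinels, not measurements.
    """

    flag_columns: list[str] = field(default_factory=lambda: list(DEFAULT_FLAG_COLUMNS))
    drop_zero_ratio: bool = True
    drop_nonfinite: bool = True


def _sort_probes(df: pd.DataFrame, chrom_order: list[str] | None) -> pd.DataFrame:
    key = df["chromosome"].map(lambda c: chromosome_sort_key(c, chrom_order))
    out = df.assign(_key=key).sort_values(["_key", "start"], kind="mergesort")
    return out.drop(columns="_key").reset_index(drop=True)


def read_probe_table(
    path: str | Path,
    sample_id: str,
    column_map: dict[str, str] | None = None,
    chrom_order: list[str] | None = None,
) -> ProbeProfile:
    """Load a probe table TSV into a genomically sorted :class:`ProbeProfile`.

    A leading ``# ratio_base=<b>`` comment declares the log base (default 10,
    the upstream convention).  ``column_map`` renames columns of real
    Feature Extraction exports onto the expected schema, e.g.
    ``{"LogRatio": "gProcessedSignal_LogRatio"}``.
    """
    path = Path(path)
    ratio_base = 10.0
    with open(path) as fh:
        header_lines = 0
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            stripped = line[1:].strip()
            if stripped.startswith("ratio_base="):
                ratio_base = float(stripped.split("=", 1)[1])
    df = pd.read_csv(path, sep="\t", skiprows=header_lines)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    flags = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    probes = pd.DataFrame(
        {
            "probe_id": df["ProbeName"].astype(str),
            "chromosome": df["Chromosome"].astype(str),
            "start": df["Start"].astype(np.int64) - 1,  # to 0-based half-open
            "end": df["End"].astype(np.int64),
            "log_ratio": df["LogRatio"].astype(float),
        }
    )
    for c in flags:
        probes[c] = df[c]

    dup = probes.duplicated(subset=["probe_id", "chromosome", "start"])
    if dup.any():
        raise FormatError(
            f"{path}: duplicate probe id at same position, e.g. "
            f"{probes.loc[dup.idxmax(), 'probe_id']}"
        )
    sorted_probes = _sort_probes(probes, chrom_order)
    if not sorted_probes[["chromosome", "start"]].equals(probes[["chromosome", "start"]]):
        logger.info("%s: probe rows were not genomically sorted; sorted on load", path)
    return ProbeProfile(sample_id, sorted_probes, ratio_base, chrom_order)


def apply_qc(profile: ProbeProfile, policy: QCPolicy | None = None) -> ProbeProfile:
    """Drop flagged probes and zero-ratio sentinels; log removal counts."""
    policy = policy or QCPolicy()
    df = profile.probes
    keep = pd.Series(True, index=df.index)
    for col in policy.flag_columns:
        if col in df.columns:
            bad = df[col].astype(int) == 1
            keep &= ~bad
            if bad.any():
                logger.info("%s: removed %d probes with %s=1", profile.sample_id, int(bad.sum()), col)
    if policy.drop_zero_ratio:
        zero = df["log_ratio"] == 0.0
        removed_by_zero = zero & keep
        keep &= ~zero
        if removed_by_zero.any():
            logger.info(
                "%s: removed %d probes with log ratio exactly 0",
                profile.sample_id,
                int(removed_by_zero.sum()),
            )
    if policy.drop_nonfinite:
        keep &= np.isfinite(df["log_ratio"])
    out = df.loc[keep].reset_index(drop=True)
    if out.empty:
        logger.warning("%s: no probes retained after QC", profile.sample_id)
    return ProbeProfile(profile.sample_id, out, profile.ratio_base, profile.chrom_order, qc_applied=True)


def to_log2(profile: ProbeProfile) -> ProbeProfile:
    """Convert log ratios to base 2 (change of base); no-op if already log2."""
    if profile.ratio_base == 2:
        return profile
    if profile.ratio_base <= 0 or profile.ratio_base == 1:
        raise ValueError(f"unknown ratio base: {profile.ratio_base}")
    factor = 1.0 / math.log(2.0, profile.ratio_base)
    df = profile.probes.copy()
    df["log_ratio"] = df["log_ratio"] * factor
    return ProbeProfile(profile.sample_id, df, 2.0, profile.chrom_order, profile.qc_applied)


def median_center(profile: ProbeProfile) -> ProbeProfile:
    """Subtract the median log ratio over all retained probes.

    Centering replaces the median-centering step the segmentation engine
    would otherwise perform; the resulting profile has median 0.
    """
    if len(profile) == 0:
        raise ValueError(f"{profile.sample_id}: cannot center an empty profile")
    df = profile.probes.copy()
    df["log_ratio"] = df["log_ratio"] - float(np.median(df["log_ratio"]))
    return ProbeProfile(profile.sample_id, df, profile.ratio_base, profile.chrom_order, profile.qc_applied)


def profile_from_frame(
    table: pd.DataFrame,
    sample_id: str,
    ratio_base: float = 10.0,
    chrom_order: list[str] | None = None,
) -> ProbeProfile:
    """Build a profile from a file-layout DataFrame (1-based coords) without IO."""
    probes = pd.DataFrame(
        {
            "probe_id": table["ProbeName"].astype(str),
            "chromosome": table["Chromosome"].astype(str),
            "start": table["Start"].astype(np.int64) - 1,
            "end": table["End"].astype(np.int64),
            "log_ratio": table["LogRatio"].astype(float),
        }
    )
    for c in table.columns:
        if c not in REQUIRED_COLUMNS:
            probes[c] = table[c].to_numpy()
    return ProbeProfile(sample_id, _sort_probes(probes, chrom_order), ratio_base, chrom_order)


def clean_profile(
    path: str | Path,
    sample_id: str,
    policy: QCPolicy | None = None,
    column_map: dict[str, str] | None = None,
    chrom_order: list[str] | None = None,
) -> ProbeProfile:
    """read -> QC -> log2 -> median-center in one call."""
    profile = read_probe_table(path, sample_id, column_map, chrom_order)
    return median_center(to_log2(apply_qc(profile, policy)))


def write_profile(profile: ProbeProfile, path: str | Path) -> None:
    """Write a cleaned profile TSV (log2 values, 1-based inclusive coords)."""
    df = profile.probes
    out = pd.DataFrame(
        {
            "ProbeName": df["probe_id"],
            "Chromosome": df["chromosome"],
            "Start": df["start"] + 1,
            "End": df["end"],
            "LogRatio": df["log_ratio"],
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# ratio_base={int(profile.ratio_base)}\n")
        out.to_csv(fh, sep="\t", index=False, float_format="%.6f")
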