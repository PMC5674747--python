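"""Synthetic matched primary/metastasis aCGH cohort generator.

Emulates the structure of a pancreatic-cancer cohort in which every patient
contributes one primary tumor (PT), one to several lymph-node metastases
(LNM) and occasionally distant organ metastases (OM).  Each patient carries
*trunk* copy-number events shared by all of their samples (early clonal
ancestry) plus *private* events confined to a single sample (divergence
after dissemination).  Probe-level log ratios follow the standard two-color
mixture model

    log2 ratio = log2( (purity * CN + (1 - purity) * 2) / 2 )

with i.i.d. Gaussian noise, so tumor-cell purity attenuates amplitudes the
way stromal admixture does in real FFPE material.  Every event is recorded
in a ground-truth table, which makes the full downstream pipeline testable
without access to patient arrays.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cnahet.genome import GenomeModel

logger = logging.getLogger(__name__)

PROBE_TABLE_COLUMNS = [
    "ProbeName",
    "Chromosome",
    "Start",
    "End",
    "LogRatio",
    "gIsSaturated",
    "rIsSaturated",
    "gIsFeatNonUnifOL",
    "rIsFeatNonUnifOL",
]

QC_FLAG_COLUMNS = PROBE_TABLE_COLUMNS[5:]


def expected_log2(copy_number: int, purity: float) -> float:
    """Expected log2 ratio of a clone at integer copy number in an impure sample.

    ``log2((purity*CN + (1-purity)*2) / 2)``: the measured ratio mixes tumor
    DNA at ``CN`` copies with diploid contamination.  ``copy_number=0`` at
    ``purity=1`` gives ``-inf`` (complete loss of signal).
    """
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if copy_number < 0:
        raise ValueError(f"copy_number must be >= 0, got {copy_number}")
    mixture = purity * copy_number + (1.0 - purity) * 2.0
    return math.log2(mixture / 2.0) if mixture > 0 else -math.inf


@dataclass(frozen=True)
class ClonalEvent:
    """One simulated copy-number event.

    ``scope`` is ``"trunk"`` (present in every sample of the patient) or the
    id of the single sample carrying it.  Footprint is 0-based half-open.
    """

    patient: str
    scope: str
    chromosome: str
    start_bp: int
    end_bp: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError("event end must exceed start")
        if self.copy_number == 2:
            raise ValueError("a clonal event must change copy number (CN != 2)")
        if self.copy_number < 0:
            raise ValueError("copy number must be >= 0")

    @property
    def direction(self) -> str:
        return "gain" if self.copy_number > 2 else "loss"


@dataclass
class SimulationParams:
    """Cohort-level simulation settings.

    Ranges are inclusive ``(low, high)`` integer bounds.  Defaults mirror the
    target study design: 18 patients, 1 PT plus 1-5 LNM and 0-2 OM each, and
    a site gradient in private-event load (OM > LNM > PT) reflecting the
    higher alteration counts observed in metastases.  Event lengths are
    log-uniform between 2 and 40 Mb so that, on the default toy probe grid,
    every event spans dozens to hundreds of oligos.
    """

    n_patients: int = 18
    lnm_per_patient: tuple[int, int] = (1, 5)
    om_per_patient: tuple[int, int] = (0, 2)
    n_trunk_events: tuple[int, int] = (2, 6)
    n_private_events: tuple[int, int] = (1, 5)
    private_events_by_site: dict[str, tuple[int, int]] | None = field(
        default_factory=lambda: {"PT": (0, 3), "LNM": (1, 5), "OM": (2, 7)}
    )
    event_length_bp: tuple[float, float] = (2e6, 4e7)
    purity_range: tuple[float, float] = (0.6, 1.0)
    noise_sd: float = 0.1
    gain_fraction: float = 0.5
    gain_copy_numbers: tuple[tuple[int, ...], tuple[float, ...]] = ((3, 4, 5), (0.7, 0.2, 0.1))
    loss_copy_numbers: tuple[tuple[int, ...], tuple[float, ...]] = ((1, 0), (0.85, 0.15))
    qc_flag_fraction: float = 0.01
    zero_ratio_fraction: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("lnm_per_patient", "om_per_patient", "n_trunk_events", "n_private_events"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be a non-negative (low, high) range")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("purity_range must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.event_length_bp[0] <= 0 or self.event_length_bp[1] < self.event_length_bp[0]:
            raise ValueError("event_length_bp must be a positive (min, max) range")

    def private_range(self, site: str) -> tuple[int, int]:
        if self.private_events_by_site and site in self.private_events_by_site:
            return self.private_events_by_site[site]
        return self.n_private_events


@dataclass
class SimulatedCohort:
    """In-memory result of :func:`simulate_cohort`."""

    genome: GenomeModel
    params: SimulationParams
    sample_sheet: pd.DataFrame  # SampleID, PatientID, Site, FilePath
    truth: pd.DataFrame  # PatientID, SampleScope, Chromosome, Start, End, CN (0-based half-open)
    profiles: dict[str, pd.DataFrame]  # sample id -> probe table (file layout)
    events: list[ClonalEvent]

    def events_for_sample(self, sample_id: str) -> list[ClonalEvent]:
        patient = self.sample_sheet.set_index("SampleID").loc[sample_id, "PatientID"]
        return [
            e
            for e in self.events
            if e.patient == patient and e.scope in ("trunk", sample_id)
        ]


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def _draw_event(
    rng: np.random.Generator,
    genome: GenomeModel,
    params: SimulationParams,
    patient: str,
    scope: str,
    taken: list[tuple[str, int, int]],
    max_tries: int = 200,
) -> ClonalEvent | None:
    """Draw one event disjoint from ``taken`` footprints (rejection sampling).

    Disjointness keeps the per-probe ground truth single-valued and satisfies
    the no-partial-overlap constraint between trunk and private events.
    Returns None when no free slot is found.
    """
    names = genome.chrom_names
    lengths = np.array([genome.chrom_lengths[n] for n in names], dtype=float)
    weights = lengths / lengths.sum()
    log_lo, log_hi = np.log(params.event_length_bp[0]), np.log(params.event_length_bp[1])
    for _ in range(max_tries):
        chrom = names[int(rng.choice(len(names), p=weights))]
        chrom_len = genome.chrom_lengths[chrom]
        length = int(round(float(np.exp(rng.uniform(log_lo, log_hi)))))
        length = min(length, chrom_len - 1)
        start = int(rng.integers(0, chrom_len - length))
        end = start + length
        if any(c == chrom and _overlaps(start, end, s, e) for c, s, e in taken):
            continue
        if rng.random() < params.gain_fraction:
            cns, probs = params.gain_copy_numbers
        else:
            cns, probs = params.loss_copy_numbers
        cn = int(rng.choice(cns, p=np.asarray(probs) / np.sum(probs)))
        return ClonalEvent(patient, scope, chrom, start, end, cn)
    logger.warning("could not place a disjoint event for %s/%s; skipped", patient, scope)
    return None


def truth_probe_states(
    genome: GenomeModel, truth: pd.DataFrame, sample_id: str, patient_id: str
) -> dict[str, np.ndarray]:
    """Per-probe ground-truth state (+1 gain / -1 loss / 0 neutral) for one sample."""
    rows = truth[
        (truth["PatientID"] == patient_id)
        & (truth["SampleScope"].isin(["trunk", sample_id]))
    ]
    states: dict[str, np.ndarray] = {}
    for chrom in genome.chrom_names:
        pos = genome.probe_positions[chrom]
        state = np.zeros(len(pos), dtype=np.int8)
        for _, r in rows[rows["Chromosome"].astype(str) == chrom].iterrows():
            mask = (pos >= r["Start"]) & (pos < r["End"])
            state[mask] = 1 if r["CN"] > 2 else -1
        states[chrom] = state
    return states


def simulate_cohort(
    genome: GenomeModel,
    params: SimulationParams,
    out_dir: str | Path | None = None,
) -> SimulatedCohort:
    """Simulate a matched PT/LNM/OM cohort on the given probe grid.

    Returns the cohort in memory; when ``out_dir`` is given, additionally
    writes one probe table per sample (TSV, log10 ratios, Feature-Extraction
    style QC flag columns), ``sample_sheet.tsv`` and ``ground_truth.tsv``.
    Identical parameters (including seed) reproduce identical output.
    """
    rng = np.random.default_rng(params.seed)
    probe_table = genome.probe_table()
    pos_by_chrom = {c: genome.probe_positions[c] for c in genome.chrom_names}

    sheet_rows = []
    truth_rows = []
    events: list[ClonalEvent] = []
    profiles: dict[str, pd.DataFrame] = {}

    for p in range(params.n_patients):
        patient = f"case{p + 1:02d}"
        n_lnm = int(rng.integers(params.lnm_per_patient[0], params.lnm_per_patient[1] + 1))
        n_om = int(rng.integers(params.om_per_patient[0], params.om_per_patient[1] + 1))
        samples = [(f"{patient}_PT1", "PT")]
        samples += [(f"{patient}_LNM{i + 1}", "LNM") for i in range(n_lnm)]
        samples += [(f"{patient}_OM{i + 1}", "OM") for i in range(n_om)]

        trunk: list[ClonalEvent] = []
        taken: list[tuple[str, int, int]] = []
        n_trunk = int(rng.integers(params.n_trunk_events[0], params.n_trunk_events[1] + 1))
        for _ in range(n_trunk):
            ev = _draw_event(rng, genome, params, patient, "trunk", taken)
            if ev is not None:
                trunk.append(ev)
                taken.append((ev.chromosome, ev.start_bp, ev.end_bp))
        events.extend(trunk)
        truth_rows += [
            (patient, "trunk", e.chromosome, e.start_bp, e.end_bp, e.copy_number)
            for e in trunk
        ]

        for sample_id, site in samples:
            lo, hi = params.private_range(site)
            n_priv = int(rng.integers(lo, hi + 1))
            private: list[ClonalEvent] = []
            taken_s = list(taken)
            for _ in range(n_priv):
                ev = _draw_event(rng, genome, params, patient, sample_id, taken_s)
                if ev is not None:
                    private.append(ev)
                    taken_s.append((ev.chromosome, ev.start_bp, ev.end_bp))
            events.extend(private)
            truth_rows += [
                (patient, sample_id, e.chromosome, e.start_bp, e.end_bp, e.copy_number)
                for e in private
            ]

            purity = float(rng.uniform(*params.purity_range))
            log2 = np.zeros(genome.probes_total)
            offset = 0
            for chrom in genome.chrom_names:
                pos = pos_by_chrom[chrom]
                cn = np.full(len(pos), 2, dtype=np.int64)
                # trunk first, then private: disjoint by construction, but
                # later events win per probe if a placement fallback occurs
                for e in trunk + private:
                    if e.chromosome == chrom:
                        cn[(pos >= e.start_bp) & (pos < e.end_bp)] = e.copy_number
                mixture = purity * cn + (1.0 - purity) * 2.0
                with np.errstate(divide="ignore"):
                    log2[offset : offset + len(pos)] = np.log2(mixture / 2.0)
                offset += len(pos)
            if params.noise_sd > 0:
                log2 = log2 + rng.normal(0.0, params.noise_sd, size=log2.shape)

            table = probe_table.copy()
            # files carry 1-based inclusive coordinates and log10 ratios
            table["Start"] = table["Start"] + 1
            table["End"] = table["End"]
            table["LogRatio"] = log2 * math.log10(2.0)
            for col in QC_FLAG_COLUMNS:
                table[col] = 0
            n = len(table)
            n_flag = int(round(params.qc_flag_fraction * n))
            if n_flag:
                flagged = rng.choice(n, size=n_flag, replace=False)
                which = rng.integers(0, len(QC_FLAG_COLUMNS), size=n_flag)
                for idx, w in zip(flagged, which):
                    table.loc[idx, QC_FLAG_COLUMNS[w]] = 1
            n_zero = int(round(params.zero_ratio_fraction * n))
            if n_zero:
                zeroed = rng.choice(n, size=n_zero, replace=False)
                table.loc[zeroed, "LogRatio"] = 0.0  # background-exceeds-signal sentinel
            profiles[sample_id] = table[PROBE_TABLE_COLUMNS]
            sheet_rows.append((sample_id, patient, site, f"{sample_id}.tsv"))

    sample_sheet = pd.DataFrame(
        sheet_rows, columns=["SampleID", "PatientID", "Site", "FilePath"]
    )
    truth = pd.DataFrame(
        truth_rows, columns=["PatientID", "SampleScope", "Chromosome", "Start", "End", "CN"]
    )
    cohort = SimulatedCohort(genome, params, sample_sheet, truth, profiles, events)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> Path:
    """Write probe tables, sample sheet and ground truth under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sample_id, table in cohort.profiles.items():
        path = out / f"{sample_id}.tsv"
        with open(path, "w") as fh:
            fh.write("# ratio_base=10\n")
            table.to_csv(fh, sep="\t", index=False, float_format="%.6f")
    # FilePath stays relative to the sheet location, keeping cohorts relocatable
    cohort.sample_sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
    truth_file = cohort.truth.copy()
    truth_file["Start"] = truth_file["Start"] + 1  # 1-based inclusive in files
    truth_file.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    return out


def expected_pairwise_distance(
    truth: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    sample_a: str,
    sample_b: str,
    direction_aware: bool = True,
) -> float:
    """Noise-free asymmetric binary distance between two samples' true events.

    Applies the same region-level definition as the measured distance
    (pairwise breakpoint-union intervals, private / total aberrant elements)
    to the ground-truth event footprints; this is the recovery target the
    measured distance should approach as noise vanishes.  Returns ``nan``
    when neither sample carries any event.
    """
    from cnahet.heterogeneity import pair_distance_from_intervals

    meta = sample_sheet.set_index("SampleID")
    calls = {}
    for s in (sample_a, sample_b):
        patient = meta.loc[s, "PatientID"]
        rows = truth[
            (truth["PatientID"] == patient) & (truth["SampleScope"].isin(["trunk", s]))
        ]
        calls[s] = [
            (str(r["Chromosome"]), int(r["Start"]), int(r["End"]),
             1 if r["CN"] > 2 else -1)
            for _, r in rows.iterrows()
        ]
    return pair_distance_from_intervals(
        calls[sample_a], calls[sample_b], direction_aware=direction_aware
    )
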