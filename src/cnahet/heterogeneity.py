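"""Cross-sample harmonization, shared/private classification and distances.

Calls from different samples are made comparable by cutting the genome at
the union of all call breakpoints; each resulting *harmonized region* gets a
state per sample (gain / loss / neutral).  An aberration is *shared* when
two or more samples of the evaluated set carry it and *private* when exactly
one does.  The *asymmetric binary distance* between two samples is the
Jaccard-type ratio

    d(a, b) = (# aberrant elements private to one sample) /
              (# elements aberrant in at least one sample)

computed over the pair's own breakpoint-union regions (adjacent regions with
identical joint state are merged first, so unrelated samples' breakpoints do
not inflate counts).  Joint absences are ignored — hence "asymmetric binary"
in the 0/1 sense; the distance itself is symmetric in its arguments.  By
default an interval gained in one sample and lost in the other counts as two
distinct private elements (opposite dosage changes are different events); a
presence-only mode ignores direction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from cnahet.calling import GAIN, LOSS, NEUTRAL, STATE_NAMES, CNACall
from cnahet.genome import chromosome_sort_key

logger = logging.getLogger(__name__)

Interval = tuple[str, int, int, int]  # chromosome, start, end, state


class EmptySubsetError(ValueError):
    """Requested sample subset contains no defined distance pair."""


@dataclass
class CallMatrix:
    """Harmonized region x sample state matrix.

    ``regions``: DataFrame (chromosome, start, end), disjoint and sorted;
    ``states``: int8 array (n_regions, n_samples) with +1 gain, -1 loss,
    0 neutral; ``meta``: per-sample PatientID and Site, indexed by SampleID.
    """

    regions: pd.DataFrame
    states: np.ndarray
    samples: list[str]
    meta: pd.DataFrame | None = None

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id}") from None

    def sample_states(self, sample_id: str) -> np.ndarray:
        return self.states[:, self.sample_index(sample_id)]

    def subset(self, sample_ids: list[str]) -> "CallMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        meta = self.meta.loc[sample_ids] if self.meta is not None else None
        return CallMatrix(self.regions, self.states[:, idx], list(sample_ids), meta)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances in [0, 1]; NaN marks undefined pairs."""

    values: np.ndarray
    samples: list[str]
    meta: pd.DataFrame | None = None

    def get(self, a: str, b: str) -> float:
        i, j = self.samples.index(a), self.samples.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.samples)


@dataclass
class UTestResult:
    """Mann-Whitney U test outcome with the method actually used."""

    u_statistic: float
    p_value: float
    method: str  # "exact" | "normal-approximation-with-tie-correction" | "degenerate-ties"
    n1: int
    n2: int


def _as_intervals(calls) -> list[Interval]:
    out = []
    for c in calls:
        if isinstance(c, CNACall):
            out.append((str(c.segment.chromosome), c.segment.start_bp, c.segment.end_bp, c.state))
        else:
            chrom, start, end, state = c
            out.append((str(chrom), int(start), int(end), int(state)))
    return out


def _check_sample_consistency(sample: str, intervals: list[Interval]) -> None:
    by_chrom: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv[0], []).append(iv)
    for chrom, ivs in by_chrom.items():
        ivs = sorted(ivs, key=lambda x: x[1])
        for (_, s1, e1, st1), (_, s2, e2, st2) in zip(ivs, ivs[1:]):
            if s2 < e1 and st1 != st2:
                raise ValueError(
                    f"{sample}: conflicting overlapping calls on {chrom} "
                    f"({s1}-{e1} {STATE_NAMES[st1]} vs {s2}-{e2} {STATE_NAMES[st2]})"
                )


def harmonize(
    calls_by_sample: dict[str, list],
    sample_sheet: pd.DataFrame | None = None,
) -> CallMatrix:
    """Build the harmonized region x sample state matrix from per-sample calls.

    Regions are the intervals between consecutive breakpoints (union over all
    samples' call boundaries) that at least one call covers.  Each original
    call is exactly tiled by harmonized regions carrying its state, so the
    original call set is reconstructible per sample.
    """
    samples = list(calls_by_sample)
    intervals_by_sample = {s: _as_intervals(c) for s, c in calls_by_sample.items()}
    for s, ivs in intervals_by_sample.items():
        _check_sample_consistency(s, ivs)

    chroms = sorted(
        {iv[0] for ivs in intervals_by_sample.values() for iv in ivs},
        key=chromosome_sort_key,
    )
    region_rows = []
    state_rows = []
    for chrom in chroms:
        cuts = sorted(
            {iv[1] for ivs in intervals_by_sample.values() for iv in ivs if iv[0] == chrom}
            | {iv[2] for ivs in intervals_by_sample.values() for iv in ivs if iv[0] == chrom}
        )
        for start, end in zip(cuts, cuts[1:]):
            states = np.zeros(len(samples), dtype=np.int8)
            covered = False
            for j, s in enumerate(samples):
                for c, s0, e0, st in intervals_by_sample[s]:
                    if c == chrom and s0 < end and start < e0:
                        states[j] = st
                        covered = True
                        break
            if covered:
                region_rows.append((chrom, start, end))
                state_rows.append(states)
    regions = pd.DataFrame(region_rows, columns=["chromosome", "start", "end"])
    states = (
        np.vstack(state_rows) if state_rows else np.zeros((0, len(samples)), dtype=np.int8)
    )
    meta = None
    if sample_sheet is not None:
        meta = sample_sheet.set_index("SampleID").loc[samples, ["PatientID", "Site"]]
    return CallMatrix(regions, states, samples, meta)


def classify_shared_private(
    matrix: CallMatrix, sample_ids: list[str] | None = None
) -> pd.DataFrame:
    """Label every aberrant (region, direction) element shared or private.

    Within the evaluated sample set, an element carried by >= 2 samples is
    shared; carried by exactly one, private.  A region gained in one sample
    and lost in another yields two elements, one per direction.
    """
    sub = matrix if sample_ids is None else matrix.subset(sample_ids)
    rows = []
    for i in range(sub.n_regions):
        region = sub.regions.iloc[i]
        for direction, state in (("gain", GAIN), ("loss", LOSS)):
            carriers = [s for j, s in enumerate(sub.samples) if sub.states[i, j] == state]
            if carriers:
                rows.append(
                    (
                        region["chromosome"], region["start"], region["end"],
                        direction, len(carriers),
                        "shared" if len(carriers) >= 2 else "private",
                        ",".join(carriers),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["chromosome", "start", "end", "direction", "n_carriers", "label", "carriers"],
    )


def _merge_joint_runs(
    regions: pd.DataFrame, sa: np.ndarray, sb: np.ndarray
) -> list[tuple[int, int, int, float]]:
    """Merge genomically adjacent regions with identical joint state.

    Returns (state_a, state_b, run_count_is_1, length_bp) per merged element;
    merging keeps pair counts independent of other samples' breakpoints.
    """
    merged = []
    prev = None  # (chrom, end, sa, sb)
    for i in range(len(regions)):
        chrom = regions["chromosome"].iat[i]
        start, end = int(regions["start"].iat[i]), int(regions["end"].iat[i])
        a, b = int(sa[i]), int(sb[i])
        if (
            prev is not None
            and prev[0] == chrom
            and prev[1] == start
            and prev[2] == a
            and prev[3] == b
        ):
            merged[-1][3] += end - start
            prev = (chrom, end, a, b)
        else:
            merged.append([a, b, 1, end - start])
            prev = (chrom, end, a, b)
    return [(m[0], m[1], m[2], float(m[3])) for m in merged]


def _pair_distance(
    regions: pd.DataFrame,
    sa: np.ndarray,
    sb: np.ndarray,
    direction_aware: bool = True,
    length_weighted: bool = False,
) -> float:
    num = 0.0
    den = 0.0
    for a, b, _, length in _merge_joint_runs(regions, sa, sb):
        if a == NEUTRAL and b == NEUTRAL:
            continue  # joint absences never count
        w = length if length_weighted else 1.0
        if direction_aware:
            if a == b:
                den += w  # concordant element
            elif a != NEUTRAL and b != NEUTRAL:
                num += 2 * w  # opposite directions: two private elements
                den += 2 * w
            else:
                num += w
                den += w
        else:
            den += w
            if (a == NEUTRAL) != (b == NEUTRAL):
                num += w
    return num / den if den > 0 else float("nan")


def binary_distance(
    matrix: CallMatrix,
    sample_a: str,
    sample_b: str,
    direction_aware: bool = True,
    length_weighted: bool = False,
) -> float:
    """Asymmetric binary distance between two samples; NaN when undefined.

    Undefined means neither sample carries any aberration (denominator 0),
    mirroring the exclusion of call-free samples from subset means.
    """
    sa = matrix.sample_states(sample_a)
    sb = matrix.sample_states(sample_b)
    return _pair_distance(matrix.regions, sa, sb, direction_aware, length_weighted)


def pair_distance_from_intervals(
    intervals_a: list[Interval],
    intervals_b: list[Interval],
    direction_aware: bool = True,
    length_weighted: bool = False,
) -> float:
    """Distance between two raw interval sets (used for ground-truth targets)."""
    matrix = harmonize({"__a__": intervals_a, "__b__": intervals_b})
    return binary_distance(matrix, "__a__", "__b__", direction_aware, length_weighted)


def distance_matrix(
    matrix: CallMatrix,
    direction_aware: bool = True,
    length_weighted: bool = False,
) -> DistanceMatrix:
    """All pairwise distances; diagonal is 0 for samples with any aberration."""
    n = len(matrix.samples)
    values = np.full((n, n), np.nan)
    for i in range(n):
        if np.any(matrix.states[:, i] != NEUTRAL):
            values[i, i] = 0.0
        for j in range(i + 1, n):
            d = _pair_distance(
                matrix.regions, matrix.states[:, i], matrix.states[:, j],
                direction_aware, length_weighted,
            )
            values[i, j] = values[j, i] = d
    return DistanceMatrix(values, list(matrix.samples), matrix.meta)


@dataclass
class SubsetSummary:
    """Mean and range of distances over a named pair subset."""

    subset: str
    mean: float
    min: float
    max: float
    n_pairs: int
    pairs: pd.DataFrame = field(repr=False)  # sample_a, sample_b, distance


def _subset_pairs(dmat: DistanceMatrix, subset: str) -> list[tuple[str, str]]:
    if dmat.meta is None:
        raise ValueError("distance matrix has no sample metadata")
    meta = dmat.meta
    by_site = lambda s, site: meta.loc[s, "Site"] == site  # noqa: E731
    patient = lambda s: meta.loc[s, "PatientID"]  # noqa: E731
    pairs = []
    for a, b in itertools.combinations(dmat.samples, 2):
        if subset == "pt_vs_matched_lnm":
            ok = patient(a) == patient(b) and {meta.loc[a, "Site"], meta.loc[b, "Site"]} == {"PT", "LNM"}
        elif subset == "inter_case_lnm":
            ok = patient(a) != patient(b) and by_site(a, "LNM") and by_site(b, "LNM")
        elif subset == "matched_lnm_vs_om":
            ok = patient(a) == patient(b) and {meta.loc[a, "Site"], meta.loc[b, "Site"]} == {"LNM", "OM"}
        else:
            raise ValueError(f"unknown subset: {subset}")
        if ok:
            pairs.append((a, b))
    return pairs


def subset_mean_distance(
    dmat: DistanceMatrix, subset: str, patient: str | None = None
) -> SubsetSummary:
    """Mean, range and contributing pairs of distances for a named subset.

    Subsets: ``pt_vs_matched_lnm`` (each patient's PT against their own
    LNMs), ``inter_case_lnm`` (LNM pairs from different patients),
    ``matched_lnm_vs_om`` (within-patient LNM/OM pairs).  ``patient``
    restricts to one case.  Undefined (NaN) distances are dropped; an empty
    result raises :class:`EmptySubsetError`.
    """
    pairs = _subset_pairs(dmat, subset)
    if patient is not None:
        meta = dmat.meta
        pairs = [
            (a, b)
            for a, b in pairs
            if meta.loc[a, "PatientID"] == patient and meta.loc[b, "PatientID"] == patient
        ]
    rows = [(a, b, dmat.get(a, b)) for a, b in pairs]
    rows = [(a, b, d) for a, b, d in rows if np.isfinite(d)]
    if not rows:
        raise EmptySubsetError(f"no defined distance pairs in subset {subset!r}")
    df = pd.DataFrame(rows, columns=["sample_a", "sample_b", "distance"])
    d = df["distance"]
    return SubsetSummary(subset, float(d.mean()), float(d.min()), float(d.max()), len(df), df)


def per_case_distance_table(dmat: DistanceMatrix, subset: str = "pt_vs_matched_lnm") -> pd.DataFrame:
    """Per-patient mean and range of a subset's distances (Fig.-4-style table)."""
    if dmat.meta is None:
        raise ValueError("distance matrix has no sample metadata")
    rows = []
    for patient in pd.unique(dmat.meta["PatientID"]):
        try:
            s = subset_mean_distance(dmat, subset, patient=patient)
        except EmptySubsetError:
            continue
        rows.append((patient, s.n_pairs, s.mean, s.min, s.max))
    return pd.DataFrame(rows, columns=["PatientID", "n_pairs", "mean", "min", "max"])


def mann_whitney_u(values_a, values_b) -> UTestResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution (full enumeration over rank assignments) when
    n1 + n2 <= 20 and there are no ties; otherwise the normal approximation
    with continuity and tie correction.  Two groups with all values identical
    are maximally compatible with the null: p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    if np.all(combined == combined[0]):
        logger.info("Mann-Whitney on identical values: p = 1 by construction")
        return UTestResult(a.size * b.size / 2.0, 1.0, "degenerate-ties", a.size, b.size)
    if a.size + b.size <= 20 and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        method = "normal-approximation-with-tie-correction"
    return UTestResult(float(res.statistic), float(min(res.pvalue, 1.0)), method, a.size, b.size)
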