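"""Per-group penetrance and Fisher-exact enrichment of CNAs between groups.

For every harmonized region, the gain/loss/neutral composition of two sample
groups forms a 3x2 contingency table.  Conditional on the margins, the table
probability is multivariate hypergeometric; the exact two-sided p-value sums
the probabilities of all same-margin tables at most as probable as the
observed one (the standard r x c generalization of Fisher's test, computed
by full enumeration over the two free cells).  A region is reported as
enriched when p <= alpha (0.05) and the driving aberration is present in
more than 25% of the samples of the group where it is more frequent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from cnahet.calling import GAIN, LOSS, NEUTRAL
from cnahet.heterogeneity import CallMatrix

logger = logging.getLogger(__name__)

#: relative slack when comparing table probabilities (float safety)
_PROB_SLACK = 1e-7

_LGAMMA_CACHE: dict[int, np.ndarray] = {}


def _log_factorials(n: int) -> np.ndarray:
    """Cached ``gammaln(0..n+1)`` lookup (log factorials via lg[k+1] = log k!)."""
    size = 1 + (n // 256)  # grow in blocks so the cache stays small
    table = _LGAMMA_CACHE.get(size)
    if table is None:
        table = gammaln(np.arange(size * 256 + 2, dtype=float))
        _LGAMMA_CACHE[size] = table
    return table


@dataclass
class EnrichmentParams:
    """Significance and prevalence filters for enrichment reporting.

    ``min_prevalence`` is strict (> 0.25 means "more than a quarter of the
    samples").  ``prevalence_mode``: ``"max_group"`` evaluates prevalence in
    the group where the driving aberration is more frequent; ``"both"``
    requires it in both groups.  ``multiple_testing``: ``"none"`` reports raw
    p-values; ``"BH"`` applies Benjamini-Hochberg across regions.
    """

    alpha: float = 0.05
    min_prevalence: float = 0.25
    prevalence_mode: str = "max_group"
    multiple_testing: str = "none"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.min_prevalence < 1:
            raise ValueError("min_prevalence must be in [0, 1)")
        if self.prevalence_mode not in ("max_group", "both"):
            raise ValueError(f"unknown prevalence_mode: {self.prevalence_mode}")
        if self.multiple_testing not in ("none", "BH"):
            raise ValueError(f"unknown multiple_testing mode: {self.multiple_testing}")


@dataclass
class EnrichedRegion:
    """A (possibly band-merged) region enriched for one direction in one group."""

    chromosome: str
    start: int
    end: int
    direction: str  # "gain" | "loss"
    p_value: float
    enriched_in: str
    prevalence_a: float
    prevalence_b: float
    n_regions: int = 1
    genes: list[str] = field(default_factory=list)


def penetrance(matrix: CallMatrix, group: list[str]) -> pd.DataFrame:
    """Fraction of group samples gaining / losing each harmonized region."""
    if not group:
        raise ValueError("penetrance group must contain at least one sample")
    idx = [matrix.sample_index(s) for s in group]
    states = matrix.states[:, idx]
    out = matrix.regions.copy()
    out["frac_gain"] = (states == GAIN).mean(axis=1)
    out["frac_loss"] = (states == LOSS).mean(axis=1)
    return out


def fisher_exact_3x2(table) -> float:
    """Exact p-value of a 3x2 (gain/loss/neutral x two groups) table.

    Enumerates all non-negative integer tables with the observed margins;
    p is the total multivariate-hypergeometric probability of tables whose
    probability does not exceed the observed table's (within a small
    relative slack for floating-point safety).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (3, 2):
        raise ValueError(f"expected a 3x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("table counts must be non-negative")
    n = int(t.sum())
    if n == 0:
        raise ValueError("degenerate table: all counts zero")
    r = t.sum(axis=1)  # state margins
    c = t.sum(axis=0)  # group sizes
    lg = _log_factorials(n)
    r0, r1, r2 = int(r[0]), int(r[1]), int(r[2])
    c0 = int(c[0])

    # free cells: a = gain count in group A, b = loss count in group A
    a = np.arange(min(r0, c0) + 1)
    b = np.arange(min(r1, c0) + 1)
    la = lg[r0 + 1] - lg[a + 1] - lg[r0 - a + 1]
    lb = lg[r1 + 1] - lg[b + 1] - lg[r1 - b + 1]
    cc = c0 - a[:, None] - b[None, :]  # neutral count in group A
    valid = (cc >= 0) & (cc <= r2)
    cc_safe = np.clip(cc, 0, r2)
    logp = (la[:, None] + lb[None, :]) + (lg[r2 + 1] - lg[cc_safe + 1] - lg[r2 - cc_safe + 1])
    log_obs = (
        lg[r0 + 1] - lg[t[0, 0] + 1] - lg[r0 - t[0, 0] + 1]
        + lg[r1 + 1] - lg[t[1, 0] + 1] - lg[r1 - t[1, 0] + 1]
        + lg[r2 + 1] - lg[t[2, 0] + 1] - lg[r2 - t[2, 0] + 1]
    )
    log_norm = lg[n + 1] - lg[c0 + 1] - lg[n - c0 + 1]
    keep = valid & (logp <= log_obs + math.log1p(_PROB_SLACK))
    p = float(np.exp(logp[keep] - log_norm).sum())
    return min(p, 1.0)


def region_table(matrix: CallMatrix, region_index: int, group_a: list[str], group_b: list[str]) -> np.ndarray:
    """The 3x2 gain/loss/neutral table of one region for two groups."""
    out = np.zeros((3, 2), dtype=np.int64)
    for col, group in enumerate((group_a, group_b)):
        idx = [matrix.sample_index(s) for s in group]
        states = matrix.states[region_index, idx]
        out[0, col] = int((states == GAIN).sum())
        out[1, col] = int((states == LOSS).sum())
        out[2, col] = int((states == NEUTRAL).sum())
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def enriched_regions(
    matrix: CallMatrix,
    group_a: list[str],
    group_b: list[str],
    params: EnrichmentParams | None = None,
    label_a: str = "A",
    label_b: str = "B",
) -> list[EnrichedRegion]:
    """Regions whose gain/loss/neutral composition differs between groups.

    For each harmonized region the 3x2 Fisher test is computed; the *driving
    direction* is the state (gain or loss) with the largest between-group
    frequency difference, and the region is reported when p passes alpha and
    that direction's prevalence clears the filter.  Adjacent reported regions
    with identical direction and carrier sets are merged into bands.
    """
    params = params or EnrichmentParams()
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")

    idx_a = [matrix.sample_index(s) for s in group_a]
    idx_b = [matrix.sample_index(s) for s in group_b]
    n_regions = matrix.n_regions
    pvals = np.ones(n_regions)
    for i in range(n_regions):
        pvals[i] = fisher_exact_3x2(region_table(matrix, i, group_a, group_b))
    effective = _bh_adjust(pvals) if params.multiple_testing == "BH" else pvals

    hits: list[tuple] = []
    for i in range(n_regions):
        if effective[i] > params.alpha:
            continue
        sa = matrix.states[i, idx_a]
        sb = matrix.states[i, idx_b]
        best = None
        for direction, state in (("gain", GAIN), ("loss", LOSS)):
            fa = float((sa == state).mean())
            fb = float((sb == state).mean())
            diff = abs(fa - fb)
            if best is None or diff > best[0]:
                best = (diff, direction, state, fa, fb)
        _, direction, state, fa, fb = best
        enriched_in = label_a if fa >= fb else label_b
        if params.prevalence_mode == "both":
            ok = min(fa, fb) > params.min_prevalence
        else:
            ok = max(fa, fb) > params.min_prevalence
        if not ok:
            continue
        carriers = frozenset(
            s for s, st in zip(group_a + group_b, np.concatenate([sa, sb])) if st == state
        )
        region = matrix.regions.iloc[i]
        hits.append(
            (str(region["chromosome"]), int(region["start"]), int(region["end"]),
             direction, float(effective[i]), enriched_in, fa, fb, carriers)
        )

    # merge adjacent hits with identical direction and carrier set into bands
    merged: list[EnrichedRegion] = []
    prev_key = None
    for chrom, start, end, direction, p, enriched_in, fa, fb, carriers in hits:
        key = (chrom, direction, enriched_in, carriers)
        if (
            merged
            and prev_key is not None
            and key == prev_key[0]
            and start == prev_key[1]
        ):
            merged[-1].end = end
            merged[-1].n_regions += 1
            merged[-1].p_value = min(merged[-1].p_value, p)
        else:
            merged.append(
                EnrichedRegion(chrom, start, end, direction, p, enriched_in, fa, fb)
            )
        prev_key = (key, end)
    return merged


def load_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read a BED-style gene annotation (chrom, start, end, name; 0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2, 3], names=["chromosome", "start", "end", "name"],
    )
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: gene interval with end <= start")
    return df


def export_gene_list(
    regions: list[EnrichedRegion], annotation: pd.DataFrame
) -> pd.DataFrame:
    """Genes overlapping each enriched region by >= 1 bp, one row per (region, gene).

    The output is the upload table for downstream gene-ontology services;
    regions without overlapping genes are retained with an empty gene field.
    A gene spanning several enriched regions is listed under each.
    """
    rows = []
    for k, reg in enumerate(regions):
        region_id = f"{reg.chromosome}:{reg.start + 1}-{reg.end}_{reg.direction}"
        hits = annotation[
            (annotation["chromosome"].astype(str) == reg.chromosome)
            & (annotation["start"] < reg.end)
            & (annotation["end"] > reg.start)
        ]
        if hits.empty:
            rows.append((region_id, reg.chromosome, reg.start + 1, reg.end, reg.direction, ""))
        for _, g in hits.iterrows():
            rows.append((region_id, reg.chromosome, reg.start + 1, reg.end, reg.direction, g["name"]))
        regions[k].genes = list(hits["name"])
    return pd.DataFrame(
        rows, columns=["region_id", "chromosome", "start", "end", "direction", "gene"]
    )


def enrichment_report(
    regions: list[EnrichedRegion], comparison: str, label_a: str, label_b: str
) -> pd.DataFrame:
    """Flat report table: comparison, region, direction, per-group prevalence, p, genes."""
    rows = [
        (
            comparison, r.chromosome, r.start + 1, r.end, r.direction, r.enriched_in,
            r.prevalence_a, r.prevalence_b, r.p_value, r.n_regions, ";".join(r.genes),
        )
        for r in regions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "comparison", "chromosome", "start", "end", "direction", "enriched_in",
            f"prevalence_{label_a}", f"prevalence_{label_b}", "p_value", "n_regions", "genes",
        ],
    )
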