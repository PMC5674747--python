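"""End-to-end pipeline: QC -> segmentation -> calling -> distances -> enrichment.

Every stage reads and writes plain files under the run's output directory,
so any stage can be re-run in isolation from the previous stage's outputs.
A run manifest records the configuration hash, seed, package version,
per-stage row counts and a checksum of every output file; identical
configuration and inputs give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cnahet.calling import (
    GAIN,
    LOSS,
    CallingParams,
    CNACall,
    calls_to_frame,
    call_segments,
    cna_counts,
    sample_inclusion,
)
from cnahet.enrichment import (
    EnrichmentParams,
    enriched_regions,
    enrichment_report,
    export_gene_list,
    load_gene_annotation,
    penetrance,
)
from cnahet.heterogeneity import (
    EmptySubsetError,
    distance_matrix,
    harmonize,
    mann_whitney_u,
    per_case_distance_table,
    subset_mean_distance,
)
from cnahet.probes import QCPolicy, clean_profile, read_probe_table, write_profile
from cnahet.segment import (
    Segment,
    SegmentationParams,
    import_segments,
    segment_profile,
    write_seg,
)

logger = logging.getLogger(__name__)

SUBSETS = ["pt_vs_matched_lnm", "inter_case_lnm", "matched_lnm_vs_om"]
COMPARISONS = [("LNM", "PT"), ("OM", "PT"), ("OM", "LNM")]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending sample."""

    def __init__(self, stage: str, message: str, sample: str | None = None):
        self.stage = stage
        self.sample = sample
        where = f"[{stage}]" + (f" sample {sample}:" if sample else "")
        super().__init__(f"{where} {message}")


@dataclass
class PipelineConfig:
    """One run's inputs, parameters and output location."""

    sample_sheet: str
    outdir: str
    seed: int = 0
    annotation: str | None = None
    segments_file: str | None = None  # externally produced SEG file, skips segmentation
    column_map: dict | None = None
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    calling: CallingParams = field(default_factory=CallingParams)
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    direction_aware: bool = True
    length_weighted: bool = False
    figures: bool = True
    max_profile_figures: int = 6

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key, typ in (
            ("segmentation", SegmentationParams),
            ("calling", CallingParams),
            ("enrichment", EnrichmentParams),
        ):
            if isinstance(raw.get(key), dict):
                raw[key] = typ(**raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _read_sample_sheet(config: PipelineConfig) -> pd.DataFrame:
    path = Path(config.sample_sheet)
    if not path.exists():
        raise StageError("startup", f"sample sheet not found: {path}")
    sheet = pd.read_csv(path, sep="\t")
    required = ["SampleID", "PatientID", "Site", "FilePath"]
    missing = [c for c in required if c not in sheet.columns]
    if missing:
        raise StageError("startup", f"sample sheet missing column(s): {', '.join(missing)}")
    base = path.parent
    resolved = []
    for _, row in sheet.iterrows():
        p = Path(row["FilePath"])
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise StageError("startup", f"probe table not found: {p}", row["SampleID"])
        resolved.append(str(p))
    sheet = sheet.copy()
    sheet["FilePath"] = resolved
    return sheet


def stage_qc(config: PipelineConfig) -> dict[str, object]:
    """Read, QC-filter, convert to log2 and median-center every sample."""
    sheet = _read_sample_sheet(config)
    out = Path(config.outdir) / "cleaned"
    out.mkdir(parents=True, exist_ok=True)
    profiles = {}
    for _, row in sheet.iterrows():
        sample = row["SampleID"]
        try:
            profile = clean_profile(
                row["FilePath"], sample, QCPolicy(), column_map=config.column_map
            )
        except Exception as exc:  # noqa: BLE001 - re-tag with stage context
            raise StageError("qc", str(exc), sample) from exc
        write_profile(profile, out / f"{sample}.tsv")
        profiles[sample] = profile
    return profiles


def _load_cleaned(config: PipelineConfig, sheet: pd.DataFrame):
    out = Path(config.outdir) / "cleaned"
    profiles = {}
    for sample in sheet["SampleID"]:
        path = out / f"{sample}.tsv"
        if not path.exists():
            raise StageError("segment", f"cleaned profile missing (run qc first): {path}", sample)
        profiles[sample] = read_probe_table(path, sample)
    return profiles


def stage_segment(config: PipelineConfig, profiles=None) -> list[Segment]:
    """Segment every cleaned profile (or import external segments)."""
    if config.segments_file:
        segments = import_segments(config.segments_file)
    else:
        if profiles is None:
            profiles = _load_cleaned(config, _read_sample_sheet(config))
        segments = []
        for sample, profile in profiles.items():
            try:
                segments.extend(segment_profile(profile, config.segmentation))
            except Exception as exc:  # noqa: BLE001
                raise StageError("segment", str(exc), sample) from exc
    write_seg(segments, Path(config.outdir) / "segments.seg")
    return segments


def _segments_by_sample(segments: list[Segment]) -> dict[str, list[Segment]]:
    out: dict[str, list[Segment]] = {}
    for s in segments:
        out.setdefault(s.sample_id, []).append(s)
    return out


def _load_segments(config: PipelineConfig) -> list[Segment]:
    path = Path(config.outdir) / "segments.seg"
    if not path.exists():
        raise StageError("call", f"segments.seg missing (run segment first): {path}")
    return import_segments(path)


def stage_call(config: PipelineConfig, segments=None):
    """Call gains/losses, decide sample inclusion, summarize CNA counts."""
    if segments is None:
        segments = _load_segments(config)
    sheet = _read_sample_sheet(config)
    out = Path(config.outdir)
    by_sample = _segments_by_sample(segments)
    for sample in sheet["SampleID"]:
        by_sample.setdefault(sample, [])
    calls_by_sample = {
        s: call_segments(segs, config.calling) for s, segs in by_sample.items()
    }
    inclusion = sample_inclusion(by_sample, calls_by_sample, config.calling)
    included = set(inclusion.loc[inclusion["included"], "SampleID"])
    all_calls = [c for calls in calls_by_sample.values() for c in calls]
    calls_to_frame(all_calls).to_csv(out / "calls.tsv", sep="\t", index=False, float_format="%.9f")
    inclusion.to_csv(out / "inclusion.tsv", sep="\t", index=False)
    per_sample, per_group = cna_counts(calls_by_sample, sheet, included)
    per_sample.to_csv(out / "cna_per_sample.tsv", sep="\t", index=False)
    per_group.to_csv(out / "cna_per_group.tsv", sep="\t", index=False, float_format="%.6g")
    return calls_by_sample, inclusion


def _load_calls(config: PipelineConfig) -> tuple[dict[str, list[CNACall]], set[str]]:
    out = Path(config.outdir)
    calls_path = out / "calls.tsv"
    if not calls_path.exists():
        raise StageError("distance", f"calls.tsv missing (run call first): {calls_path}")
    df = pd.read_csv(calls_path, sep="\t")
    calls: dict[str, list[CNACall]] = {}
    for _, row in df.iterrows():
        n = int(row["Num_Probes"])
        seg = Segment(
            sample_id=str(row["Sample"]), chromosome=str(row["Chromosome"]),
            first_probe_index=0, last_probe_index=n - 1,
            start_bp=int(row["Start"]) - 1, end_bp=int(row["End"]),
            n_probes=n, mean_log2=float(row["Mean_log2"]),
        )
        calls.setdefault(seg.sample_id, []).append(
            CNACall(seg, GAIN if row["State"] == "gain" else LOSS)
        )
    inc = pd.read_csv(out / "inclusion.tsv", sep="\t")
    included = set(inc.loc[inc["included"], "SampleID"])
    return calls, included


def _build_matrix(config: PipelineConfig, calls_by_sample, included):
    sheet = _read_sample_sheet(config)
    keep = [s for s in sheet["SampleID"] if s in included]
    calls = {s: calls_by_sample.get(s, []) for s in keep}
    return harmonize(calls, sheet), sheet


def stage_distance(config: PipelineConfig, calls_by_sample=None, included=None):
    """Distance matrix, subset means, per-case table and subset comparisons."""
    if calls_by_sample is None or included is None:
        calls_by_sample, included = _load_calls(config)
    matrix, _ = _build_matrix(config, calls_by_sample, included)
    dmat = distance_matrix(matrix, config.direction_aware, config.length_weighted)
    out = Path(config.outdir)
    dmat.to_frame().to_csv(out / "distance_matrix.tsv", sep="\t", float_format="%.6f", na_rep="NA")

    summaries = {}
    rows = []
    for subset in SUBSETS:
        try:
            s = subset_mean_distance(dmat, subset)
        except EmptySubsetError:
            logger.info("subset %s is empty; omitted", subset)
            continue
        summaries[subset] = s
        rows.append((subset, s.mean, s.min, s.max, s.n_pairs))
    summary = pd.DataFrame(rows, columns=["subset", "mean", "min", "max", "n_pairs"])

    stats_rows = []
    if "pt_vs_matched_lnm" in summaries and "inter_case_lnm" in summaries:
        r = mann_whitney_u(
            summaries["pt_vs_matched_lnm"].pairs["distance"],
            summaries["inter_case_lnm"].pairs["distance"],
        )
        stats_rows.append(
            ("distance:pt_vs_matched_lnm|inter_case_lnm", r.u_statistic, r.p_value, r.method, r.n1, r.n2)
        )
    stats = pd.DataFrame(
        stats_rows, columns=["comparison", "U", "p_value", "method", "n1", "n2"]
    )
    summary.to_csv(out / "subset_summary.tsv", sep="\t", index=False, float_format="%.6f")
    stats.to_csv(out / "subset_tests.tsv", sep="\t", index=False, float_format="%.6g")
    per_case = per_case_distance_table(dmat)
    per_case.to_csv(out / "per_case_distance.tsv", sep="\t", index=False, float_format="%.6f")
    return dmat, summary, stats


def stage_enrich(config: PipelineConfig, calls_by_sample=None, included=None):
    """Per-site penetrance tracks and pairwise-group enrichment reports."""
    if calls_by_sample is None or included is None:
        calls_by_sample, included = _load_calls(config)
    matrix, sheet = _build_matrix(config, calls_by_sample, included)
    meta = sheet.set_index("SampleID")
    out = Path(config.outdir)
    groups = {
        site: [s for s in matrix.samples if meta.loc[s, "Site"] == site]
        for site in ("PT", "LNM", "OM")
    }
    for site, members in groups.items():
        if members:
            pen = penetrance(matrix, members)
            pen_out = pen.copy()
            pen_out["start"] = pen_out["start"] + 1
            pen_out.to_csv(out / f"penetrance_{site}.tsv", sep="\t", index=False, float_format="%.6f")

    annotation = load_gene_annotation(config.annotation) if config.annotation else None
    reports = []
    for a, b in COMPARISONS:
        if not groups[a] or not groups[b]:
            continue
        regs = enriched_regions(
            matrix, groups[a], groups[b], config.enrichment, label_a=a, label_b=b
        )
        if annotation is not None and regs:
            gene_table = export_gene_list(regs, annotation)
            gene_table.to_csv(
                out / f"gene_list_{a}_vs_{b}.tsv", sep="\t", index=False
            )
        rep = enrichment_report(regs, f"{a}_vs_{b}", a, b)
        rep.columns = [
            c.replace(f"prevalence_{a}", "prevalence_group_a").replace(
                f"prevalence_{b}", "prevalence_group_b"
            )
            for c in rep.columns
        ]
        reports.append(rep)
    reports = [r for r in reports if not r.empty]
    report = (
        pd.concat(reports, ignore_index=True)
        if reports
        else pd.DataFrame(
            columns=[
                "comparison", "chromosome", "start", "end", "direction", "enriched_in",
                "prevalence_group_a", "prevalence_group_b", "p_value", "n_regions", "genes",
            ]
        )
    )
    report.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    return matrix, report


def make_figures(config: PipelineConfig) -> list[Path]:
    """Penetrance tracks per site, per-sample profiles with calls, per-case distances.

    Follows the orange-gain / blue-loss convention.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(config.outdir)
    figdir = out / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for site in ("PT", "LNM", "OM"):
        path = out / f"penetrance_{site}.tsv"
        if not path.exists():
            logger.info("no penetrance track for %s; figure skipped", site)
            continue
        pen = pd.read_csv(path, sep="\t")
        fig, ax = plt.subplots(figsize=(10, 3))
        x = np.arange(len(pen))
        ax.bar(x, pen["frac_gain"], width=1.0, color="orange", label="gain")
        ax.bar(x, -pen["frac_loss"], width=1.0, color="steelblue", label="loss")
        ax.set_ylim(-1, 1)
        ax.set_xlabel("harmonized region (genome order)")
        ax.set_ylabel("penetrance")
        ax.set_title(f"Penetrance of gains/losses — {site}")
        ax.legend(loc="upper right")
        fig.tight_layout()
        fig.savefig(figdir / f"penetrance_{site}.png", dpi=110)
        plt.close(fig)
        written.append(figdir / f"penetrance_{site}.png")

    sheet = _read_sample_sheet(config)
    calls_df = pd.read_csv(out / "calls.tsv", sep="\t") if (out / "calls.tsv").exists() else None
    cleaned = Path(config.outdir) / "cleaned"
    for sample in sheet["SampleID"][: config.max_profile_figures]:
        path = cleaned / f"{sample}.tsv"
        if not path.exists():
            continue
        profile = read_probe_table(path, sample)
        fig, ax = plt.subplots(figsize=(10, 3))
        ax.plot(profile.log_ratios, ".", markersize=1.5, color="0.4")
        if calls_df is not None:
            sample_calls = calls_df[calls_df["Sample"] == sample]
            offsets = {}
            running = 0
            for chrom, g in profile.probes.groupby("chromosome", sort=False):
                offsets[str(chrom)] = (running, g["start"].to_numpy(), g["end"].to_numpy())
                running += len(g)
            for _, row in sample_calls.iterrows():
                chrom = str(row["Chromosome"])
                if chrom not in offsets:
                    continue
                base, starts, ends = offsets[chrom]
                lo = base + int(np.searchsorted(starts, row["Start"] - 1, side="left"))
                hi = base + int(np.searchsorted(starts, row["End"], side="left"))
                color = "orange" if row["State"] == "gain" else "steelblue"
                ax.axvspan(lo, hi, color=color, alpha=0.35)
        ax.set_xlabel("probe index (genome order)")
        ax.set_ylabel("log2 ratio")
        ax.set_title(sample)
        fig.tight_layout()
        fig.savefig(figdir / f"profile_{sample}.png", dpi=110)
        plt.close(fig)
        written.append(figdir / f"profile_{sample}.png")

    per_case_path = out / "per_case_distance.tsv"
    if per_case_path.exists():
        pc = pd.read_csv(per_case_path, sep="\t")
        if not pc.empty:
            fig, ax = plt.subplots(figsize=(8, 3.5))
            x = np.arange(len(pc))
            yerr = np.vstack([pc["mean"] - pc["min"], pc["max"] - pc["mean"]])
            ax.errorbar(x, pc["mean"], yerr=yerr, fmt="o", capsize=3, color="black")
            ax.set_xticks(x)
            ax.set_xticklabels(pc["PatientID"], rotation=90)
            ax.set_ylim(0, 1.05)
            ax.set_ylabel("binary distance (PT vs matched LNM)")
            fig.tight_layout()
            fig.savefig(figdir / "per_case_distance.png", dpi=110)
            plt.close(fig)
            written.append(figdir / "per_case_distance.png")
    return written


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write ``manifest.json``; returns the manifest."""
    t0 = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sheet = _read_sample_sheet(config)  # startup validation before any computation

    profiles = stage_qc(config)
    segments = stage_segment(config, profiles)
    calls_by_sample, inclusion = stage_call(config, segments)
    included = set(inclusion.loc[inclusion["included"], "SampleID"])
    dmat, summary, stats = stage_distance(config, calls_by_sample, included)
    matrix, report = stage_enrich(config, calls_by_sample, included)
    figures = make_figures(config) if config.figures else []

    counts = {
        "samples_in": int(len(sheet)),
        "samples_included": int(inclusion["included"].sum()),
        "samples_excluded": int((~inclusion["included"]).sum()),
        "segments": len(segments),
        "calls": int(sum(len(c) for c in calls_by_sample.values())),
        "harmonized_regions": int(matrix.n_regions),
        "distance_pairs_defined": int(np.isfinite(dmat.values).sum() - len(dmat.samples)) // 2,
        "enriched_regions": int(len(report)),
        "figures": len(figures),
    }
    files = sorted(
        str(p.relative_to(out))
        for p in out.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    from cnahet import __version__

    manifest = {
        "tool": "cnahet",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "stage_counts": counts,
        "outputs": {f: _sha256(out / f) for f in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline finished in %.1f s: %s", time.time() - t0, counts)
    return manifest
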