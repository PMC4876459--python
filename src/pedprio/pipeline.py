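"""End-to-end orchestration: segments -> filter cascade -> prioritization.

Reproduces the two complementary candidate-narrowing strategies of a
single-patient dominant exome study:

1. **IBD filtering** — restrict ultra-rare functional variants to
   regions shared IBD by the two patients, then exclude regions also
   shared by an unaffected sib and variants not carried by the second
   patient (the proband).
2. **Network prioritization** — rank all genes by random-walk-with-
   restart affinity to the seed (known disease) genes and keep the top
   fraction (20% by default).

The final candidate report is the intersection: surviving variants
whose gene also ranks in the top fraction.  Both survivor sets (with
and without sib exclusion) are always reported side by side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .intervals import (
    IbdTrack,
    RegionSet,
    call_ibd_segments,
    candidate_regions,
    read_ibd_table,
    write_bed,
)
from .network import (
    GeneNetwork,
    WalkParams,
    read_edge_list,
    rwr_scores,
    top_fraction,
)
from .variants import (
    CascadeConfig,
    FilterReport,
    VariantRecord,
    read_variant_table,
    run_cascade,
    write_variant_table,
)

__all__ = ["PipelineConfig", "CandidateReport", "validate_config", "run_all", "run_all_memory"]


@dataclass
class PipelineConfig:
    """All inputs, thresholds and outputs of one pipeline run."""

    ibd_path: str = ""
    variants_path: str = ""
    network_path: str = ""
    seeds_path: str = ""
    out_dir: str = "pedprio_out"

    patient_pair: tuple[str, str] = ("P1", "P2")
    sibs: tuple[str, ...] = ("P1_SIB", "P2_SIB")
    proband: str | None = "P1"

    ibd_threshold: float = 0.5
    frequency_threshold: float = 0.005
    gerp_min: float = 2.0
    restart: float = 0.5
    walk_tol: float = 1e-6
    top_fraction: float = 0.20
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "patient_pair" in data:
            data["patient_pair"] = tuple(data["patient_pair"])
        if "sibs" in data:
            data["sibs"] = tuple(data["sibs"])
        return cls(**data)


def validate_config(config: PipelineConfig, check_paths: bool = True) -> list[str]:
    """Return a list of problems (empty when the config is usable)."""
    errors = []
    if not 0.0 < config.restart <= 1.0:
        errors.append(f"restart probability {config.restart} outside (0, 1]")
    if not 0.0 < config.top_fraction <= 1.0:
        errors.append(f"top fraction {config.top_fraction} outside (0, 1]")
    if config.frequency_threshold < 0:
        errors.append("frequency threshold must be >= 0")
    if not 0.0 < config.ibd_threshold < 1.0:
        errors.append(f"IBD threshold {config.ibd_threshold} outside (0, 1)")
    if config.walk_tol <= 0:
        errors.append("walk tolerance must be > 0")
    if len(config.patient_pair) != 2 or config.patient_pair[0] == config.patient_pair[1]:
        errors.append("patient_pair must name two distinct samples")
    if check_paths:
        for name in ("ibd_path", "variants_path", "network_path", "seeds_path"):
            p = getattr(config, name)
            if not p:
                errors.append(f"missing input path: {name}")
            elif not Path(p).exists():
                errors.append(f"{name}: no such file {p!r}")
    return errors


@dataclass
class CandidateReport:
    """Final prioritized candidates plus full provenance."""

    rows: list[dict]
    shared_regions: RegionSet
    candidate_regions: RegionSet
    report_shared: FilterReport     # cascade restricted to patient-shared regions
    report_excluded: FilterReport   # + sib exclusion and proband carrier check
    top_genes: set[str]
    scores: dict[str, float]
    thresholds: dict

    def to_dataframe(self) -> pd.DataFrame:
        cols = [
            "gene", "chrom", "pos", "ref", "alt", "consequence", "gerp",
            "score", "network_rank", "network_percentile",
            "in_ibd_region", "sib_excluded_survivor", "proband_carrier",
        ]
        return pd.DataFrame(self.rows, columns=cols)

    def summary(self) -> str:
        lines = [
            "# Candidate report",
            "",
            f"- patient-pair shared regions: {len(self.shared_regions)} "
            f"({self.shared_regions.total_length()} bp)",
            f"- after sib exclusion: {len(self.candidate_regions)} "
            f"({self.candidate_regions.total_length()} bp)",
            f"- survivors in shared regions: {self.report_shared.n_survivors} variants "
            f"/ {len(self.report_shared.genes)} genes",
            f"- survivors after sib exclusion + carrier check: "
            f"{self.report_excluded.n_survivors} variants "
            f"/ {len(self.report_excluded.genes)} genes",
            f"- network top fraction: {len(self.top_genes)} genes",
            f"- final candidates: {len(self.rows)}",
            "",
            "| gene | variant | score | network rank |",
            "|---|---|---|---|",
        ]
        for r in self.rows:
            lines.append(
                f"| {r['gene']} | {r['chrom']}:{r['pos']} {r['ref']}>{r['alt']} "
                f"| {r['score']:.3e} | {r['network_rank']:.0f} |"
            )
        return "\n".join(lines) + "\n"


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return tuple(sorted((a, b)))  # type: ignore[return-value]


def run_all_memory(
    tracks: Sequence[IbdTrack],
    variants: Sequence[VariantRecord],
    network: GeneNetwork,
    seeds: Sequence[str],
    config: PipelineConfig,
) -> CandidateReport:
    """Run the full analysis on in-memory inputs (no files touched)."""
    errors = validate_config(config, check_paths=False)
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))

    by_pair = {t.pair: t for t in tracks}
    p1, p2 = config.patient_pair
    try:
        patient_track = by_pair[_pair_key(p1, p2)]
    except KeyError:
        raise ValueError(f"[segments] no IBD track for patient pair {p1},{p2}") from None
    sib_tracks = []
    for sib in config.sibs:
        try:
            sib_tracks.append(
                (by_pair[_pair_key(sib, p1)], by_pair[_pair_key(sib, p2)])
            )
        except KeyError:
            raise ValueError(
                f"[segments] sib {sib!r} needs tracks against both patients"
            ) from None

    shared = call_ibd_segments(patient_track, config.ibd_threshold)
    candidate = candidate_regions(patient_track, sib_tracks, config.ibd_threshold)

    report_shared = run_cascade(
        variants,
        CascadeConfig(
            frequency_threshold=config.frequency_threshold,
            gerp_min=config.gerp_min,
            regions=shared,
        ),
    )
    report_excluded = run_cascade(
        variants,
        CascadeConfig(
            frequency_threshold=config.frequency_threshold,
            gerp_min=config.gerp_min,
            regions=candidate,
            carrier_sample=config.proband,
        ),
    )

    sv = rwr_scores(
        network, seeds, WalkParams(restart=config.restart, tol=config.walk_tol)
    )
    scores = sv.as_dict()
    top = top_fraction(sv, config.top_fraction)

    # rank every network gene once for the report columns
    from scipy.stats import rankdata
    import numpy as np

    vals = np.asarray([scores[g] for g in network.nodes])
    ranks = dict(zip(network.nodes, rankdata(-vals, method="average")))
    n = network.n

    excluded_keys = {v.key for v in report_excluded.survivors}
    rows = []
    for v in report_shared.survivors:
        if v.gene not in top:
            continue
        if v.key not in excluded_keys:
            continue
        gt = v.genotypes.get(config.proband) if config.proband else None
        rows.append(
            {
                "gene": v.gene,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "consequence": v.consequence,
                "gerp": v.gerp,
                "score": scores.get(v.gene, 0.0),
                "network_rank": float(ranks.get(v.gene, n)),
                "network_percentile": float(ranks.get(v.gene, n)) / n,
                "in_ibd_region": True,
                "sib_excluded_survivor": True,
                "proband_carrier": None if gt is None else bool(gt >= 1),
            }
        )
    rows.sort(key=lambda r: (r["network_rank"], r["gene"], r["chrom"], r["pos"]))

    thresholds = {
        "ibd_threshold": config.ibd_threshold,
        "frequency_threshold": config.frequency_threshold,
        "gerp_min": config.gerp_min,
        "restart": config.restart,
        "walk_tol": config.walk_tol,
        "top_fraction": config.top_fraction,
        "seed": config.seed,
        "version": __version__,
    }
    return CandidateReport(
        rows=rows,
        shared_regions=shared,
        candidate_regions=candidate,
        report_shared=report_shared,
        report_excluded=report_excluded,
        top_genes=top,
        scores=scores,
        thresholds=thresholds,
    )


def run_all(config: PipelineConfig) -> CandidateReport:
    """Run the full analysis from files and write every artifact.

    Output tree under ``config.out_dir``::

        regions/   patient_shared.bed, candidate.bed
        variants/  survivors_shared.tsv, survivors_excluded.tsv, filter_report.json
        network/   scores.tsv
        report/    candidates.tsv, summary.md, run.json
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))

    try:
        tracks = read_ibd_table(config.ibd_path)
    except Exception as exc:
        raise RuntimeError(f"[segments] reading {config.ibd_path}: {exc}") from exc
    try:
        variants = read_variant_table(config.variants_path)
    except Exception as exc:
        raise RuntimeError(f"[filter] reading {config.variants_path}: {exc}") from exc
    try:
        network = read_edge_list(config.network_path)
        seeds = [
            s.strip()
            for s in Path(config.seeds_path).read_text().splitlines()
            if s.strip() and not s.startswith("#")
        ]
    except Exception as exc:
        raise RuntimeError(f"[prioritize] reading network/seeds: {exc}") from exc

    report = run_all_memory(tracks, variants, network, seeds, config)

    out = Path(config.out_dir)
    for sub in ("regions", "variants", "network", "report"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    write_bed(report.shared_regions, out / "regions" / "patient_shared.bed")
    write_bed(report.candidate_regions, out / "regions" / "candidate.bed")
    write_variant_table(
        report.report_shared.survivors, out / "variants" / "survivors_shared.tsv"
    )
    write_variant_table(
        report.report_excluded.survivors, out / "variants" / "survivors_excluded.tsv"
    )
    with open(out / "variants" / "filter_report.json", "w") as fh:
        json.dump(
            {
                "shared_regions": report.report_shared.to_dict(),
                "sib_excluded": report.report_excluded.to_dict(),
            },
            fh,
            indent=1,
        )
    with open(out / "network" / "scores.tsv", "w") as fh:
        fh.write("#gene\tscore\n")
        for g in sorted(report.scores, key=lambda g: (-report.scores[g], g)):
            fh.write(f"{g}\t{report.scores[g]:.12e}\n")
    report.to_dataframe().to_csv(out / "report" / "candidates.tsv", sep="\t", index=False)
    (out / "report" / "summary.md").write_text(report.summary())
    with open(out / "report" / "run.json", "w") as fh:
        json.dump(report.thresholds, fh, indent=1)
    return report
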