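"""End-to-end design flow: screen -> evaluate -> rank -> report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .editors import load_editors
from .io import (GenomeIndex, ReportRow, SnpTrack, TargetSite, read_genome,
                 read_sites, read_snp_track, write_report)
from .offtarget import default_cfd_table, load_cfd_table
from .ranking import (FEATURE_NAMES, GuideFeatures, GuideRanking,
                      OfftargetConfig, compute_features, rank_candidates)
from .reporting import summarize_failures, summarize_feasible_counts
from .screening import ScreeningOutcome, screen_site
from ._utils import percent

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    editor: str
    genome_path: str
    sites_path: str
    out_dir: str
    editors_path: str | None = None
    snp_vcf_path: str | None = None
    cfd_table_path: str | None = None
    max_mismatches: int = 4
    pam_policy: str = "strict"
    alpha: float = 0.05
    weak_max_significant: int = 1
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.__dict__, sort_keys=True)


@dataclass
class SiteResult:
    site: TargetSite
    outcome: ScreeningOutcome
    features: list[GuideFeatures] = field(default_factory=list)
    rankings: list[GuideRanking] = field(default_factory=list)


@dataclass
class DesignResult:
    sites: list[SiteResult]
    load_errors: list
    report_rows: list[ReportRow]


def run_design(config: RunConfig) -> DesignResult:
    """Run the full design pipeline and write report/summary files.

    Writes ``report.tsv`` (every site x candidate), ``summary.tsv``
    (category and failure tables), ``best_guides.tsv``, and the resolved
    ``run_config.yaml`` into the output directory.
    """
    registry = load_editors(Path(config.editors_path)
                            if config.editors_path else None)
    editor = registry.get(config.editor)
    genome = read_genome(config.genome_path)
    sites, load_errors = read_sites(config.sites_path, genome)
    for err in load_errors:
        logger.warning("skipped site %s (%s:%d): %s", err.site_id, err.chrom,
                       err.pos, err.reason)
    snp_track: SnpTrack | None = None
    if config.snp_vcf_path:
        snp_track = read_snp_track(config.snp_vcf_path)
    table = (load_cfd_table(config.cfd_table_path)
             if config.cfd_table_path else default_cfd_table())
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ot_cfg = OfftargetConfig(max_mm=config.max_mismatches,
                             pam_policy=config.pam_policy, table=table)

    results: list[SiteResult] = []
    rows: list[ReportRow] = []
    for site in sites:
        outcome = screen_site(site, editor, genome)
        res = SiteResult(site, outcome)
        if outcome.status == "failed":
            rows.append(ReportRow(site_id=site.site_id, status="failed",
                                  fail_reason=outcome.fail_reason))
        else:
            res.features = [compute_features(g, editor, genome, snp_track,
                                             ot_cfg)
                            for g in outcome.candidates]
            res.rankings = rank_candidates(outcome.candidates, res.features)
            for g, f, r in zip(outcome.candidates, res.features, res.rankings):
                rows.append(ReportRow(
                    site_id=site.site_id, status="editable", strand=g.strand,
                    protospacer=g.protospacer, pam=g.pam,
                    protospacer_start=g.protospacer_start,
                    protospacer_end=g.protospacer_end,
                    same_base_in_window=f.same_base_in_window,
                    gc_fraction=f.gc_fraction, repeat_count=f.repeat_count,
                    snp_count=f.snp_count, offtarget_score=f.offtarget_score,
                    per_feature_ranks=r.per_feature_ranks,
                    rra_score=r.rra_score, is_best=r.is_best))
        results.append(res)

    write_report(rows, out_dir / "report.tsv")
    _write_summary(results, out_dir / "summary.tsv")
    _write_best(rows, out_dir / "best_guides.tsv")
    (out_dir / "run_config.yaml").write_text(config.to_yaml())
    return DesignResult(results, load_errors, rows)


def _write_summary(results: list[SiteResult], destination: Path) -> None:
    outcomes = [r.outcome for r in results]
    lines = ["table\tkey\tcount\tpercent"]
    editable = [o for o in outcomes if o.status == "editable"]
    if editable:
        cat = summarize_feasible_counts(outcomes)
        for k, n in cat.counts.items():
            lines.append(f"feasible_gRNAs\t{k}\t{n}\t{cat.percentages[k]:.2f}")
        lines.append(f"feasible_gRNAs\ttotal_sites\t{cat.total_sites}\t")
        lines.append(f"feasible_gRNAs\ttotal_guides\t{cat.total_guides}\t")
    failed = [o.fail_reason for o in outcomes if o.status == "failed"]
    if failed:
        fail = summarize_failures(failed)
        for label, n in sorted(fail.counts.items()):
            lines.append(f"failures\t{label}\t{n}\t{fail.percentages[label]:.2f}")
        lines.append(f"failures\tno_PAM_or_window_pct\t\t{fail.pam_or_window_pct:.1f}")
    destination.write_text("\n".join(lines) + "\n")


def _write_best(rows: list[ReportRow], destination: Path) -> None:
    from .io import write_report
    write_report([r for r in rows if r.is_best], destination)
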