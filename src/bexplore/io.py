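"""Input/output: genomes, target sites, SNP tracks, GWAS tables, reports.

Coordinates are 1-based and inclusive everywhere at the interface, the VCF
convention. Target sites arrive either as a VCF (first ALT used) or as a
plain 4/5-column TSV (chrom, position, ref base, alt base[, site id]).
GWAS summary tables are TSVs with a named header; the per-phenotype case
fraction (phi) and effect-allele frequency (theta) are required columns
because the effect-scale conversion needs them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import DataError, FormatError

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: The five site-failure labels emitted by screening, bit-exact.
FAIL_BASE_MATCH = "base_match_error"
FAIL_NO_PAM = "no_PAM"
FAIL_WINDOW = "activity_window_error"
FAIL_HOMOPOLYMER = "continuous_identical_base_error"
FAIL_GC = "GC_ratio_error"
FAIL_LABELS = (FAIL_BASE_MATCH, FAIL_NO_PAM, FAIL_WINDOW, FAIL_HOMOPOLYMER, FAIL_GC)


# ---------------------------------------------------------------------------
# Genome

@dataclass
class GenomeIndex:
    """Uppercased in-memory genome keyed by chromosome name."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of the 1-based inclusive span [start, end]."""
        seq = self.sequences[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise DataError(
                f"span {chrom}:{start}-{end} outside chromosome (length {len(seq)})"
            )
        return seq[start - 1:end]

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)


_VALID = set("ACGTN")


def read_genome(fasta_source: Union[PathLike, TextIO]) -> GenomeIndex:
    """Read a FASTA into a :class:`GenomeIndex`.

    Records are uppercased; multi-line records are concatenated; any IUPAC
    ambiguity code other than N is mapped to N. Duplicate record names and
    empty files are format errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(fasta_source, "fasta"):
        if record.id in sequences:
            raise FormatError(f"duplicate FASTA record name {record.id!r}")
        seq = str(record.seq).upper()
        if not set(seq) <= _VALID:
            seq = "".join(c if c in _VALID else "N" for c in seq)
        sequences[record.id] = seq
    if not sequences:
        raise FormatError("FASTA contains no records")
    return GenomeIndex(sequences)


def write_genome(genome: GenomeIndex, destination: PathLike, width: int = 70) -> None:
    with open(destination, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Target sites

@dataclass(frozen=True)
class TargetSite:
    chrom: str
    pos: int            # 1-based
    ref_base: str
    alt_base: str
    site_id: str


@dataclass(frozen=True)
class SiteLoadError:
    """One rejected input site, with the reason it was rejected."""

    site_id: str
    chrom: str
    pos: int
    reason: str


def _is_vcf(path: Path) -> bool:
    name = path.name.lower()
    if name.endswith((".vcf", ".vcf.gz")):
        return True
    opener = open
    try:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            import gzip
            opener = gzip.open
        with opener(path, "rt") as fh:  # type: ignore[arg-type]
            first = fh.readline()
        return first.startswith("##fileformat=VCF")
    except OSError:
        return False


def read_sites(source: PathLike, genome: GenomeIndex
               ) -> tuple[list[TargetSite], list[SiteLoadError]]:
    """Read target sites from a VCF or a TSV and validate against the genome.

    Returns ``(sites, errors)``: sites whose reference base disagrees with
    the genome, fall outside their chromosome, or name an unknown
    chromosome are reported in ``errors`` rather than silently dropped.
    For multi-allelic VCF records the first ALT is used. TSV rows without
    an explicit id get the synthesized id ``"chrom:pos"``.
    """
    path = Path(source)
    raw: list[tuple[str, int, str, str, str]] = []
    if _is_vcf(path):
        from cyvcf2 import VCF
        for var in VCF(str(path)):
            alt = var.ALT[0] if var.ALT else ""
            sid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
            raw.append((var.CHROM, var.POS, var.REF.upper(), alt.upper(), sid))
    else:
        with open(path) as fh:
            for line_no, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise FormatError(
                        f"{path}:{line_no}: expected >= 4 tab-separated columns"
                    )
                chrom, pos_s, ref, alt = parts[:4]
                sid = parts[4] if len(parts) > 4 and parts[4] else f"{chrom}:{pos_s}"
                try:
                    pos = int(pos_s)
                except ValueError:
                    raise FormatError(
                        f"{path}:{line_no}: position {pos_s!r} is not an integer"
                    ) from None
                raw.append((chrom, pos, ref.upper(), alt.upper(), sid))

    sites: list[TargetSite] = []
    errors: list[SiteLoadError] = []
    for chrom, pos, ref, alt, sid in raw:
        if chrom not in genome.sequences:
            errors.append(SiteLoadError(sid, chrom, pos, "unknown chromosome"))
            continue
        if not (1 <= pos <= genome.lengths[chrom]):
            errors.append(SiteLoadError(sid, chrom, pos, "position outside chromosome"))
            continue
        genome_base = genome.base(chrom, pos)
        if len(ref) != 1 or ref != genome_base:
            errors.append(SiteLoadError(
                sid, chrom, pos,
                f"ref mismatch: file says {ref!r}, genome has {genome_base!r}"))
            continue
        if not alt or alt == ref or len(alt) != 1:
            errors.append(SiteLoadError(sid, chrom, pos, f"invalid alt {alt!r}"))
            continue
        sites.append(TargetSite(chrom, pos, ref, alt, sid))
    return sites, errors


# ---------------------------------------------------------------------------
# SNP track

class SnpTrack:
    """Background-SNP positions, queryable by genomic span."""

    def __init__(self, positions: dict[str, Sequence[int]]):
        self._pos = {c: np.asarray(sorted(p), dtype=np.int64)
                     for c, p in positions.items()}

    def count(self, chrom: str, start: int, end: int) -> int:
        """Number of SNPs with start <= pos <= end on ``chrom``."""
        pos = self._pos.get(chrom)
        if pos is None:
            return 0
        return int(np.searchsorted(pos, end, "right")
                   - np.searchsorted(pos, start, "left"))

    def __len__(self) -> int:
        return sum(len(p) for p in self._pos.values())


def read_snp_track(vcf_source: PathLike) -> SnpTrack:
    """Load SNP positions from a VCF into a :class:`SnpTrack`."""
    from cyvcf2 import VCF
    positions: dict[str, list[int]] = {}
    for var in VCF(str(Path(vcf_source))):
        positions.setdefault(var.CHROM, []).append(var.POS)
    return SnpTrack(positions)


# ---------------------------------------------------------------------------
# GWAS summary tables

@dataclass(frozen=True)
class GwasRecord:
    """One SNP-phenotype association row from a GWAS summary table."""

    snp_id: str
    chrom: str
    pos: int
    phenotype_id: str
    beta_obs: float     # allelic substitution effect, observed scale
    p_value: float
    phi: float          # proportion of cases in the sample
    theta: float        # effect-allele frequency in the sample
    effect_allele: str = ""


_GWAS_REQUIRED = ("snp_id", "chrom", "pos", "effect_allele",
                  "beta_obs", "p_value", "phi", "theta")


def read_gwas(source: PathLike, phenotype_id: str | None = None
              ) -> list[GwasRecord]:
    """Read one per-phenotype GWAS summary TSV.

    Requires a header naming the columns ``snp_id, chrom, pos,
    effect_allele, beta_obs, p_value, phi, theta`` (a ``phenotype_id``
    column is honoured if present; otherwise ``phenotype_id`` defaults to
    the file stem). Rows with phi or theta outside (0, 1) or p outside
    [0, 1] are rejected; the rejection count is logged as a warning.
    """
    path = Path(source)
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    missing = [c for c in _GWAS_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    default_pheno = phenotype_id if phenotype_id is not None else path.stem

    records: list[GwasRecord] = []
    n_rejected = 0
    for row in df.itertuples(index=False):
        phi, theta, p = float(row.phi), float(row.theta), float(row.p_value)
        if not (0.0 < phi < 1.0 and 0.0 < theta < 1.0 and 0.0 <= p <= 1.0) \
                or not math.isfinite(float(row.beta_obs)):
            n_rejected += 1
            continue
        pheno = str(getattr(row, "phenotype_id", default_pheno))
        records.append(GwasRecord(
            snp_id=str(row.snp_id), chrom=str(row.chrom), pos=int(row.pos),
            phenotype_id=pheno, beta_obs=float(row.beta_obs), p_value=p,
            phi=phi, theta=theta, effect_allele=str(row.effect_allele)))
    if n_rejected:
        logger.warning("%s: rejected %d row(s) with phi/theta outside (0,1) "
                       "or invalid p/beta", path, n_rejected)
    return records


def write_gwas(records: Iterable[GwasRecord], destination: PathLike) -> None:
    rows = [{
        "snp_id": r.snp_id, "chrom": r.chrom, "pos": r.pos,
        "phenotype_id": r.phenotype_id, "effect_allele": r.effect_allele,
        "beta_obs": r.beta_obs, "p_value": r.p_value,
        "phi": r.phi, "theta": r.theta,
    } for r in records]
    pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "phenotype_id",
                                "effect_allele", "beta_obs", "p_value",
                                "phi", "theta"]).to_csv(
        destination, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Design report

REPORT_COLUMNS = (
    "site_id", "status", "fail_reason", "strand", "protospacer", "pam",
    "protospacer_start", "protospacer_end",
    "same_base_in_window", "gc_fraction", "repeat_count", "snp_count",
    "offtarget_score",
    "rank_same_base_in_window", "rank_gc_fraction", "rank_repeat_count",
    "rank_snp_count", "rank_offtarget_score",
    "rra_score", "is_best",
)


@dataclass
class ReportRow:
    """One report line: a (site, candidate) pair, or a failed site."""

    site_id: str
    status: str                      # "editable" | "failed"
    fail_reason: str = ""
    strand: str = ""
    protospacer: str = ""
    pam: str = ""
    protospacer_start: int | None = None
    protospacer_end: int | None = None
    same_base_in_window: int | None = None
    gc_fraction: float | None = None
    repeat_count: int | None = None
    snp_count: int | None = None
    offtarget_score: float | None = None
    per_feature_ranks: dict[str, float] = field(default_factory=dict)
    rra_score: float | None = None
    is_best: bool | None = None


def write_report(results: Iterable[ReportRow], destination: PathLike) -> None:
    """Write the design report TSV: one row per (site x candidate).

    Failed sites emit a single row carrying the failure label and empty
    candidate fields; an empty result set yields a header-only file.
    """
    rows = []
    for r in results:
        if r.status not in ("editable", "failed"):
            raise DataError(f"site {r.site_id}: unknown status {r.status!r}")
        if r.fail_reason and r.fail_reason not in FAIL_LABELS:
            raise DataError(
                f"site {r.site_id}: unknown fail_reason {r.fail_reason!r}")
        rows.append({
            "site_id": r.site_id, "status": r.status,
            "fail_reason": r.fail_reason, "strand": r.strand,
            "protospacer": r.protospacer, "pam": r.pam,
            "protospacer_start": r.protospacer_start,
            "protospacer_end": r.protospacer_end,
            "same_base_in_window": r.same_base_in_window,
            "gc_fraction": r.gc_fraction,
            "repeat_count": r.repeat_count, "snp_count": r.snp_count,
            "offtarget_score": r.offtarget_score,
            "rank_same_base_in_window": r.per_feature_ranks.get("same_base_in_window"),
            "rank_gc_fraction": r.per_feature_ranks.get("gc_fraction"),
            "rank_repeat_count": r.per_feature_ranks.get("repeat_count"),
            "rank_snp_count": r.per_feature_ranks.get("snp_count"),
            "rank_offtarget_score": r.per_feature_ranks.get("offtarget_score"),
            "rra_score": r.rra_score,
            "is_best": r.is_best,
        })
    df = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    # nullable dtypes keep integer columns integral despite failed-site rows
    for col in ("protospacer_start", "protospacer_end", "same_base_in_window",
                "repeat_count", "snp_count"):
        df[col] = df[col].astype("Int64")
    df["is_best"] = df["is_best"].astype("boolean")
    df.to_csv(destination, sep="\t", index=False)
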