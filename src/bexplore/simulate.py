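"""Deterministic synthetic fixtures: genomes with planted sites, SNP
tracks, and GWAS tables with planted effects.

The generator is first-class, tested code: it is the ground truth against
which every other module is exercised. Each construct is engineered so
that screening *must* produce a known outcome:

* editable sites embed exactly ``multiplicity`` PAM-bearing placements
  inside the activity window (a contiguous block of planted PAMs) and no
  PAM anywhere else in the searchable range;
* failure sites embed the one defect their label names (wrong base, a
  PAM-free downstream, a PAM only outside the window, a 7-base run, or
  uniformly high GC) and nothing else.

Constructs live in segments wide enough to contain every base that can
influence a placement (protospacer + PAM on either side of the target),
padded with fixed bases, so the random background cannot alter outcomes.
The generator verifies each construct, and each planted off-target decoy,
against a direct brute-force check before emitting, resampling on the
rare clash; a spec that cannot be realised raises ``SpecError``.

One integer seed drives independent child streams for genome, SNP, and
GWAS draws (numpy ``default_rng`` with seed sequences), so outputs are
byte-identical across runs and platforms. PAM planting supports
NGG-family editors (the shipped BE3 and ABE7.10).

GWAS tables plant, per SNP, a chosen number of promotion and inhibition
associations: significant rows carry ``|beta_obs|`` equal to the effect
magnitude with the planted sign and P below alpha/10; null rows carry a
small zero-centred effect and P uniform above alpha. Defaults emulate a
PheWAS-style panel of 131 phenotypes with case fractions in (0.1, 0.5)
and allele frequencies in (0.1, 0.9).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .editors import BaseEditor, get_editor
from .errors import SpecError
from .io import (FAIL_BASE_MATCH, FAIL_GC, FAIL_HOMOPOLYMER, FAIL_NO_PAM,
                 FAIL_WINDOW, FAIL_LABELS, GenomeIndex, GwasRecord, PathLike,
                 TargetSite, write_genome, write_gwas)
from .offtarget import find_offtargets
from .screening import CandidateGuide
from ._seq import gc_count, iupac_match, max_identical_run, revcomp

_BASES = np.array(list("ACGT"))
_COMPL = {"A": "T", "C": "G", "G": "C", "T": "A"}

_MAX_TRIES = 500


# ---------------------------------------------------------------------------
# Specs

@dataclass(frozen=True)
class PlantedSite:
    editor: str = "BE3"
    outcome: str = "editable"       # "editable" or one of the five labels
    multiplicity: int = 1
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.outcome != "editable" and self.outcome not in FAIL_LABELS:
            raise SpecError(f"unknown planted outcome {self.outcome!r}")
        if self.multiplicity < 1:
            raise SpecError("multiplicity must be >= 1")


@dataclass(frozen=True)
class DecoySpec:
    source_site: int                # index into planted_sites
    mismatches: int


@dataclass(frozen=True)
class GwasSpec:
    n_snps: int = 20
    n_phenotypes: int = 131
    planted: tuple[tuple[int, int], ...] = ()   # per-SNP (promote, inhibit)
    effect: float = 0.05
    phi_range: tuple[float, float] = (0.1, 0.5)
    theta_range: tuple[float, float] = (0.1, 0.9)
    alpha: float = 0.05


@dataclass(frozen=True)
class PlantSpec:
    seed: int
    genome_length: int = 10_000
    chrom: str = "chr1"
    planted_sites: tuple[PlantedSite, ...] = ()
    decoys: tuple[DecoySpec, ...] = ()
    snp_density: float = 0.0
    guide_snps: dict[int, int] = field(default_factory=dict)
    gwas: GwasSpec | None = None


# ---------------------------------------------------------------------------
# Truth records

@dataclass
class SiteTruth:
    site_id: str
    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    editor: str
    strand: str
    expected_outcome: str           # "editable" or a failure label
    expected_candidates: int
    candidates: list[tuple[int, int, str, str]]  # (start, end, strand, protospacer)

    def as_target_site(self) -> TargetSite:
        return TargetSite(self.chrom, self.pos, self.ref_base,
                          self.alt_base, self.site_id)


@dataclass
class DecoyTruth:
    chrom: str
    start: int
    end: int
    strand: str
    mismatches: int
    source_site_id: str
    sequence: str


@dataclass
class GenomeTruth:
    chrom: str
    sites: list[SiteTruth]
    decoys: list[DecoyTruth]


# ---------------------------------------------------------------------------
# Local brute-force screen (the generator's self-check)

def _screen_local(seq: str, target_idx: int, editor: BaseEditor,
                  strand: str) -> tuple[str, list[tuple[int, str]]]:
    """Direct check of a construct: returns (outcome, [(p, protospacer)]).

    A literal translation of the screening rules, used only to verify
    constructs before they are emitted.
    """
    L, pat = editor.spacer_length, editor.pam_pattern
    P = len(pat)
    base = seq[target_idx]
    if strand == "+":
        if base != editor.target_base:
            return FAIL_BASE_MATCH, []
    else:
        if base != _COMPL[editor.target_base]:
            return FAIL_BASE_MATCH, []
    any_pam = False
    window_hits: list[tuple[int, str]] = []
    for p in range(1, L + 1):
        if strand == "+":
            start = target_idx - (p - 1)
            proto = seq[start:start + L]
            pam = seq[start + L:start + L + P]
        else:
            end = target_idx + (p - 1)          # 0-based inclusive
            start = end - L + 1
            if start < 0:
                continue
            proto = revcomp(seq[start:end + 1])
            pam_lo = start - P
            if pam_lo < 0:
                continue
            pam = revcomp(seq[pam_lo:start])
        if len(proto) < L or len(pam) < P or start < 0:
            continue
        if "N" in proto or "N" in pam:
            continue
        if proto[p - 1] != editor.target_base:
            continue
        if not iupac_match(pam, pat):
            continue
        any_pam = True
        if editor.window_start <= p <= editor.window_end:
            window_hits.append((p, proto))
    if not any_pam:
        return FAIL_NO_PAM, []
    if not window_hits:
        return FAIL_WINDOW, []
    kept = [(p, s) for p, s in window_hits if max_identical_run(s) <= 6]
    if not kept:
        return FAIL_HOMOPOLYMER, []
    kept = [(p, s) for p, s in kept
            if 30 * len(s) <= 100 * gc_count(s) <= 75 * len(s)]
    if not kept:
        return FAIL_GC, []
    return "editable", kept


# ---------------------------------------------------------------------------
# Construct builders (plus-strand; minus-strand constructs are the
# reverse complement of a plus-strand build)

def _rand_bases(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(_BASES, size=n))


def _no_gg_run(rng: np.random.Generator, n: int, prev: str = "") -> list[str]:
    """Random bases in which no G is ever followed by G."""
    out: list[str] = []
    for _ in range(n):
        choices = "ACT" if (out[-1] if out else prev) == "G" else "ACGT"
        out.append(str(rng.choice(list(choices))))
    return out


def _half_width(editor: BaseEditor) -> int:
    return editor.spacer_length + len(editor.pam_pattern)


def _plant_pams(seg: list[str], c: int, editor: BaseEditor,
                positions: list[int]) -> None:
    """Write NGG PAMs for the given protospacer positions of the target."""
    L = editor.spacer_length
    for p in positions:
        off = L - p + 1                 # PAM start offset from the target
        seg[c + off + 1] = "G"
        seg[c + off + 2] = "G"


def _build_segment(site: PlantedSite, editor: BaseEditor,
                   rng: np.random.Generator) -> tuple[list[str], list[tuple[int, str]]]:
    """One construct segment (target at the centre index) realising the
    intended outcome; verified with the local brute-force screen."""
    if "GG" not in editor.pam_pattern.upper() or len(editor.pam_pattern) != 3:
        raise SpecError("the fixture generator plants PAMs for NGG-family "
                        "editors only")
    hw = _half_width(editor)
    c = hw
    n = 2 * hw + 1
    L = editor.spacer_length
    win = list(range(editor.window_start, editor.window_end + 1))

    for _ in range(_MAX_TRIES):
        seg = _rand_bases(rng, n)
        seg[c] = editor.target_base
        seg[c + 1:] = _no_gg_run(rng, n - c - 1, prev=seg[c])

        if site.outcome == "editable":
            if site.multiplicity > len(win):
                raise SpecError(
                    f"multiplicity {site.multiplicity} exceeds the window "
                    f"size {len(win)} of editor {editor.name}")
            planted = win[:site.multiplicity]   # contiguous block
            _plant_pams(seg, c, editor, planted)
            expect = "editable"
        elif site.outcome == FAIL_BASE_MATCH:
            bad = {"C": "AT", "A": "CG"}[editor.target_base]
            seg[c] = str(rng.choice(list(bad)))
            expect = FAIL_BASE_MATCH
        elif site.outcome == FAIL_NO_PAM:
            expect = FAIL_NO_PAM
        elif site.outcome == FAIL_WINDOW:
            p_out = editor.window_end + 4
            if p_out > L:
                raise SpecError("no placement outside the window fits")
            _plant_pams(seg, c, editor, [p_out])
            expect = FAIL_WINDOW
        elif site.outcome == FAIL_HOMOPOLYMER:
            p = win[0] + 1 if len(win) > 1 else win[0]
            _plant_pams(seg, c, editor, [p])
            run_base = "A" if editor.target_base != "A" else "T"
            for d in range(2, 9):               # 7-base run inside the spacer
                seg[c + d] = run_base
            expect = FAIL_HOMOPOLYMER
        elif site.outcome == FAIL_GC:
            # high-GC alternating pattern across every window placement
            lo, hi = c - (L - 1), c + (L - editor.window_start)
            for i in range(max(0, lo), min(n, hi + 1)):
                seg[i] = "C" if (i - c) % 2 == 0 else "G"
            seg[c] = editor.target_base
            p = win[0] + 1 if len(win) > 1 else win[0]
            _plant_pams(seg, c, editor, [p])
            expect = FAIL_GC
        else:  # pragma: no cover - guarded by PlantedSite.__post_init__
            raise SpecError(site.outcome)

        outcome, kept = _screen_local("".join(seg), c, editor, "+")
        if outcome == expect and (
                expect != "editable" or len(kept) == site.multiplicity):
            return seg, kept
    raise SpecError(
        f"could not realise outcome {site.outcome!r} for editor "
        f"{editor.name} after {_MAX_TRIES} attempts")


def make_genome(spec: PlantSpec) -> tuple[GenomeIndex, GenomeTruth]:
    """Synthesize the genome and its truth table.

    Constructs are laid left to right with >= 12 bp of random background
    between them, flanked by 3 nt of fixed padding ("TAT") so adjacent
    background cannot complete a PAM; decoys are placed after all sites.
    """
    rng = np.random.default_rng([int(spec.seed), 0])
    chrom = spec.chrom
    pad = "TAT"

    pieces: list[str] = []
    cursor = 0

    def emit_background(n: int) -> None:
        nonlocal cursor
        if n > 0:
            pieces.append("".join(_rand_bases(rng, n)))
            cursor += n

    site_truths: list[SiteTruth] = []
    emit_background(12)
    planted_segments: list[tuple[PlantedSite, BaseEditor, list[tuple[int, str]], int]] = []
    for idx, psite in enumerate(spec.planted_sites):
        editor = get_editor(psite.editor)
        seg, kept = _build_segment(psite, editor, rng)
        c = _half_width(editor)
        if psite.strand == "-":
            seg = list(revcomp("".join(seg)))   # target stays at the centre
        piece = pad + "".join(seg) + pad
        target_pos = cursor + len(pad) + c + 1  # 1-based genomic position
        pieces.append(piece)
        cursor += len(piece)
        planted_segments.append((psite, editor, kept, target_pos, seg[c]))
        emit_background(12)

    # translate local placements into genomic candidate spans
    for idx, (psite, editor, kept, t, ref) in enumerate(planted_segments):
        L = editor.spacer_length
        if psite.outcome == FAIL_BASE_MATCH:
            alt = _COMPL[ref]
        elif psite.strand == "+":
            alt = editor.converted_base
        else:
            alt = _COMPL[editor.converted_base]
        cands: list[tuple[int, int, str, str]] = []
        for p, proto in kept:
            if psite.strand == "+":
                start = t - (p - 1)
            else:
                start = t - (L - p)
            cands.append((start, start + L - 1, psite.strand, proto))
        site_truths.append(SiteTruth(
            site_id=f"{chrom}:{t}", chrom=chrom, pos=t, ref_base=ref,
            alt_base=alt, editor=editor.name, strand=psite.strand,
            expected_outcome=psite.outcome, expected_candidates=len(cands),
            candidates=sorted(cands)))

    # decoys: mutated copies of a source site's first candidate
    decoy_truths: list[DecoyTruth] = []
    for dec in spec.decoys:
        src = site_truths[dec.source_site]
        if not src.candidates:
            raise SpecError(
                f"decoy source site {dec.source_site} has no candidates")
        start, end, strand, proto = src.candidates[0]
        seq = list(proto)
        if dec.mismatches > len(seq):
            raise SpecError("decoy mismatch count exceeds protospacer length")
        pos_choice = rng.choice(len(seq), size=dec.mismatches, replace=False)
        for i in pos_choice:
            seq[int(i)] = str(rng.choice([b for b in "ACGT" if b != seq[int(i)]]))
        decoy_seq = "".join(seq)
        piece = pad + decoy_seq + "TGG" + pad
        d_start = cursor + len(pad) + 1
        pieces.append(piece)
        cursor += len(piece)
        decoy_truths.append(DecoyTruth(
            chrom=chrom, start=d_start, end=d_start + len(decoy_seq) - 1,
            strand="+", mismatches=dec.mismatches,
            source_site_id=src.site_id, sequence=decoy_seq))
        emit_background(12)

    if cursor > spec.genome_length:
        raise SpecError(
            f"planted constructs need {cursor} bp but genome_length is "
            f"{spec.genome_length}")
    emit_background(spec.genome_length - cursor)

    for attempt in range(20):
        genome = GenomeIndex({chrom: "".join(pieces)})
        if _verify_decoys(genome, site_truths, decoy_truths):
            break
        # a background window collided with a planted query: redraw the
        # trailing background only (constructs are deterministic given rng
        # order, so truth is unchanged)
        pieces[-1] = "".join(_rand_bases(rng, len(pieces[-1])))
    else:  # pragma: no cover - p(collision) per attempt is ~1e-2 at 50 kb
        raise SpecError("could not place decoys without background collisions")

    return genome, GenomeTruth(chrom, site_truths, decoy_truths)


def _verify_decoys(genome: GenomeIndex, sites: list[SiteTruth],
                   decoys: list[DecoyTruth], budget: int = 4) -> bool:
    """Every tracked query's hit set within ``budget`` mismatches must be
    exactly its planted decoys (brute truth check)."""
    for site in sites:
        if not site.candidates:
            continue
        start, end, strand, proto = site.candidates[0]
        guide = CandidateGuide(site.site_id, strand, proto, "NGG",
                               start, end, 1, chrom=site.chrom)
        hits = find_offtargets(guide, genome, max_mm=budget, pam_policy="any")
        expected = {(d.start, d.end) for d in decoys
                    if d.source_site_id == site.site_id and d.mismatches <= budget}
        got = {(h.start, h.end) for h in hits
               if not _is_sibling(h.start, h.end, site)}
        if got != expected:
            return False
    return True


def _is_sibling(start: int, end: int, site: SiteTruth) -> bool:
    return any((start, end) == (s, e) for s, e, _, _ in site.candidates)


# ---------------------------------------------------------------------------
# SNP track

@dataclass
class SnpTruth:
    positions: list[int]
    per_guide_counts: dict[str, list[int]]   # site_id -> count per candidate


def make_snp_vcf(spec: PlantSpec, genome: GenomeIndex, truth: GenomeTruth,
                 destination: PathLike) -> SnpTruth:
    """Write a background-SNP VCF and return exact per-guide counts.

    ``spec.guide_snps`` plants an exact number of SNPs inside the first
    candidate span of the named site; density-driven background SNPs are
    kept out of all candidate spans so planted counts stay exact.
    """
    rng = np.random.default_rng([int(spec.seed), 1])
    chrom = truth.chrom
    seq = genome.sequences[chrom]
    n = len(seq)

    guide_spans = [(s, e) for site in truth.sites
                   for (s, e, _, _) in site.candidates]

    def in_any_span(pos: int) -> bool:
        return any(s <= pos <= e for s, e in guide_spans)

    positions: set[int] = set()
    for site_idx, count in sorted(spec.guide_snps.items()):
        site = truth.sites[site_idx]
        if not site.candidates:
            raise SpecError(f"guide_snps names site {site_idx}, which has "
                            "no candidates")
        s, e = site.candidates[0][:2]
        if count > e - s + 1:
            raise SpecError("more planted SNPs than bases in the guide span")
        chosen = rng.choice(np.arange(s, e + 1), size=count, replace=False)
        positions.update(int(p) for p in chosen)

    if spec.snp_density > 0:
        n_bg = rng.binomial(n, spec.snp_density)
        for pos in rng.integers(1, n + 1, size=n_bg):
            pos = int(pos)
            if not in_any_span(pos):
                positions.add(pos)

    ordered = sorted(positions)
    with open(destination, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={n}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, pos in enumerate(ordered, 1):
            ref = seq[pos - 1]
            if ref == "N":
                ref = "A"
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            fh.write(f"{chrom}\t{pos}\tsnp{i}\t{ref}\t{alt}\t.\t.\t.\n")

    per_guide = {
        site.site_id: [sum(1 for p in ordered if s <= p <= e)
                       for (s, e, _, _) in site.candidates]
        for site in truth.sites if site.candidates}
    return SnpTruth(ordered, per_guide)


# ---------------------------------------------------------------------------
# GWAS tables

@dataclass
class GwasFixture:
    records: list[GwasRecord]                       # all phenotypes pooled
    truth: dict[str, tuple[int, int]]               # snp -> (promote, inhibit)

    def by_phenotype(self) -> dict[str, list[GwasRecord]]:
        out: dict[str, list[GwasRecord]] = {}
        for r in self.records:
            out.setdefault(r.phenotype_id, []).append(r)
        return out


def make_gwas(spec: PlantSpec) -> GwasFixture:
    """Per-phenotype association rows with planted effect structure."""
    if spec.gwas is None:
        raise SpecError("PlantSpec has no gwas section")
    g = spec.gwas
    rng = np.random.default_rng([int(spec.seed), 2])
    planted = list(g.planted)
    while len(planted) < g.n_snps:
        planted.append((0, 0))
    for n_pro, n_inh in planted[:g.n_snps]:
        if n_pro + n_inh > g.n_phenotypes:
            raise SpecError("planted significant count exceeds n_phenotypes")

    phi = rng.uniform(*g.phi_range, size=g.n_phenotypes)
    records: list[GwasRecord] = []
    truth: dict[str, tuple[int, int]] = {}
    for i in range(g.n_snps):
        snp_id = f"snp{i + 1}"
        theta = float(rng.uniform(*g.theta_range))
        n_pro, n_inh = planted[i]
        assignment = rng.permutation(g.n_phenotypes)
        promote = set(assignment[:n_pro].tolist())
        inhibit = set(assignment[n_pro:n_pro + n_inh].tolist())
        for j in range(g.n_phenotypes):
            pheno = f"pheno{j + 1:03d}"
            if j in promote or j in inhibit:
                sign = 1.0 if j in promote else -1.0
                beta_obs = sign * g.effect
                p = float(rng.uniform(1e-8, g.alpha / 10))
            else:
                beta_obs = float(rng.normal(0.0, g.effect / 20))
                p = float(rng.uniform(g.alpha * 1.001, 1.0))
            records.append(GwasRecord(
                snp_id=snp_id, chrom="chr1", pos=1000 + 100 * i,
                phenotype_id=pheno, beta_obs=beta_obs, p_value=p,
                phi=float(phi[j]), theta=theta, effect_allele="A"))
        truth[snp_id] = (n_pro, n_inh)
    return GwasFixture(records, truth)


# ---------------------------------------------------------------------------
# Whole-fixture writer (the `bexplore simulate` backend)

def write_fixture(spec: PlantSpec, out_dir: PathLike) -> dict:
    """Write FASTA, site list, SNP VCF, GWAS TSVs, and truth tables.

    Returns the truth as a plain dict (also written to ``truth.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, truth = make_genome(spec)
    write_genome(genome, out / "genome.fa")
    with open(out / "sites.tsv", "w") as fh:
        for site in truth.sites:
            fh.write(f"{site.chrom}\t{site.pos}\t{site.ref_base}\t"
                     f"{site.alt_base}\t{site.site_id}\n")
    snp_truth = make_snp_vcf(spec, genome, truth, out / "snps.vcf")

    gwas_truth = {}
    if spec.gwas is not None:
        fixture = make_gwas(spec)
        gwas_dir = out / "gwas"
        gwas_dir.mkdir(exist_ok=True)
        for pheno, recs in fixture.by_phenotype().items():
            write_gwas(recs, gwas_dir / f"{pheno}.tsv")
        gwas_truth = {k: list(v) for k, v in fixture.truth.items()}

    payload = {
        "sites": [asdict(s) for s in truth.sites],
        "decoys": [asdict(d) for d in truth.decoys],
        "snp_positions": snp_truth.positions,
        "snp_per_guide_counts": snp_truth.per_guide_counts,
        "gwas_planted": gwas_truth,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1)
    return payload
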