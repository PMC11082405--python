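"""Pleiotropy profiling of candidate editing loci from GWAS summaries.

Case-control GWAS run on a linear (observed) scale report an effect
``beta_obs`` whose magnitude depends on the case fraction of the sample.
Before comparing effects across phenotypes we map each observed-scale
effect back to an allelic substitution effect ``beta`` with a
rational-function conversion in the case fraction ``phi`` and the
effect-allele frequency ``theta``:

    beta = beta_obs / D,
    D = phi(1-phi)
        + 0.5 (1-2 phi)(1-2 theta) beta_obs
        - (0.084 + 0.9 phi (1-2 phi)) theta(1-theta) phi(1-phi) beta_obs^2

For small effects this reduces to the familiar linear-scale rescaling
beta ~ beta_obs / (phi(1-phi)). The quadratic coefficient's grouping is
isolated in :func:`convert_beta` and switchable (see ``parse``), since
alternative groupings exist; the default is the one reproducing the
small-effect limit with the standard correction shape.

A SNP's pleiotropy profile counts, across phenotypes, significant
promotion (beta > 0, P < alpha) and inhibition (beta < 0, P < alpha)
associations, bins SNPs by pleiotropy strength (fewer than 10, 10-20,
more than 20 significant phenotypes), and screens for weakly pleiotropic
SNPs — the loci safest to edit when only one phenotype is intended.
"""

from __future__ import annotations

import logging
import math
import sys
from dataclasses import dataclass

import numpy as np

from .errors import BexploreError, NonConvertibleEffectError
from .io import GwasRecord
from ._utils import percent

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05

STRENGTH_BINS = ("<10", "10-20", ">20")


@dataclass(frozen=True)
class ConvertedEffect:
    beta: float
    beta_obs: float
    phi: float
    theta: float


@dataclass(frozen=True)
class PleiotropyProfile:
    snp_id: str
    n_phenotypes_tested: int
    n_significant: int
    n_promote: int
    n_inhibit: int
    strength_bin: str


def convert_beta(beta_obs: float, phi: float, theta: float,
                 parse: str = "rational") -> float:
    """Allelic substitution effect from an observed-scale effect.

    ``parse`` selects the algebraic grouping of the conversion:

    * ``"rational"`` (default): beta = beta_obs / D with D as in the
      module docstring — the trailing exponent read as D**-1. This is
      the grouping that yields the standard small-effect limit
      beta -> beta_obs / (phi(1-phi)).
    * ``"linear"``: beta = beta_obs * D - 1 (the exponent read as a
      literal "- 1" term); kept only for comparison, not recommended.

    Raises ``NonConvertibleEffectError`` when D <= 0 (the observed
    effect is outside the domain where the mapping is invertible).
    """
    if not (0.0 < phi < 1.0):
        raise BexploreError(f"phi must be in (0,1), got {phi}")
    if not (0.0 < theta < 1.0):
        raise BexploreError(f"theta must be in (0,1), got {theta}")
    d = (phi * (1.0 - phi)
         + 0.5 * (1.0 - 2.0 * phi) * (1.0 - 2.0 * theta) * beta_obs
         - (0.084 + 0.9 * phi * (1.0 - 2.0 * phi))
         * theta * (1.0 - theta) * phi * (1.0 - phi) * beta_obs ** 2)
    if parse == "rational":
        if d <= 0.0:
            raise NonConvertibleEffectError(beta_obs, phi, theta, d)
        return beta_obs / d
    if parse == "linear":
        return beta_obs * d - 1.0
    raise BexploreError(f"unknown parse {parse!r}")


def classify_association(beta: float, p_value: float,
                         alpha: float = DEFAULT_ALPHA) -> str:
    """'promotion' (beta>0, P<alpha), 'inhibition' (beta<0, P<alpha),
    else 'nonsignificant' (including beta == 0 at any P)."""
    if p_value < alpha:
        if beta > 0:
            return "promotion"
        if beta < 0:
            return "inhibition"
    return "nonsignificant"


def strength_bin(n_significant: int) -> str:
    if n_significant < 10:
        return "<10"
    if n_significant <= 20:
        return "10-20"
    return ">20"


def pleiotropy_profile(snp_id: str, gwas: list[GwasRecord],
                       alpha: float = DEFAULT_ALPHA) -> PleiotropyProfile:
    """Profile one SNP across its phenotype association records.

    Records whose observed effect cannot be converted are counted,
    logged, and excluded from the tested total.
    """
    records = [r for r in gwas if r.snp_id == snp_id]
    if not records:
        raise BexploreError(f"no GWAS records for SNP {snp_id!r}")
    n_promote = n_inhibit = n_tested = n_unconvertible = 0
    for rec in records:
        try:
            beta = convert_beta(rec.beta_obs, rec.phi, rec.theta)
        except NonConvertibleEffectError:
            n_unconvertible += 1
            continue
        n_tested += 1
        cls = classify_association(beta, rec.p_value, alpha)
        if cls == "promotion":
            n_promote += 1
        elif cls == "inhibition":
            n_inhibit += 1
    if n_unconvertible:
        logger.warning("SNP %s: %d record(s) had non-convertible effects "
                       "and were excluded", snp_id, n_unconvertible)
    n_sig = n_promote + n_inhibit
    return PleiotropyProfile(snp_id, n_tested, n_sig, n_promote, n_inhibit,
                             strength_bin(n_sig))


def bin_strength(profiles: list[PleiotropyProfile]
                 ) -> tuple[dict[str, int], dict[str, float]]:
    """Counts and percentages (half-up, 1 decimal) per strength bin."""
    if not profiles:
        raise BexploreError("bin_strength requires at least one profile")
    counts = {b: 0 for b in STRENGTH_BINS}
    for p in profiles:
        counts[p.strength_bin] += 1
    total = len(profiles)
    pct = {b: percent(c, total, 1) for b, c in counts.items()}
    return counts, pct


@dataclass(frozen=True)
class WeakPleiotropyCriteria:
    """A SNP is 'weakly pleiotropic' when its significant-phenotype count
    does not exceed ``max_significant``."""

    max_significant: int = 1


def screen_weak(profiles: list[PleiotropyProfile],
                criteria: WeakPleiotropyCriteria | None = None) -> list[str]:
    """SNP ids with at most ``criteria.max_significant`` significant
    phenotype associations, in input order."""
    crit = criteria or WeakPleiotropyCriteria()
    return [p.snp_id for p in profiles
            if p.n_significant <= crit.max_significant]


def qq_points(p_values: list[float]) -> list[tuple[float, float]]:
    """Quantile-quantile pairs on the -log10 scale.

    Observed P values are sorted ascending; the i-th expected quantile is
    (i - 0.5)/n. Zero P values are clamped to the smallest positive
    float with a warning.
    """
    if not p_values:
        return []
    tiny = sys.float_info.min
    clamped = []
    n_zero = 0
    for p in p_values:
        if not (0.0 <= p <= 1.0):
            raise BexploreError(f"P value {p} outside [0, 1]")
        if p == 0.0:
            n_zero += 1
            p = tiny
        clamped.append(p)
    if n_zero:
        logger.warning("clamped %d zero P value(s) to %.3g", n_zero, tiny)
    observed = np.sort(np.asarray(clamped))
    n = len(observed)
    expected = (np.arange(1, n + 1) - 0.5) / n
    return list(zip((-np.log10(expected)).tolist(),
                    (-np.log10(observed)).tolist()))
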