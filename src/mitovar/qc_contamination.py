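"""Sample-level quality control: swap detection, cross-contamination
estimation and polymorphism/back-mutation filters.

Tumor/normal mismatches are screened on a panel of common autosomal SNPs
(population minor allele frequency ~50%): at sites where the normal is
homozygous for the variant allele, a matched tumor should re-genotype as
homozygous, so the mismatch rate (N_het + N_wt) / (N_hom + N_het + N_wt)
is ~0 for matched pairs and rises toward the unrelated-pair expectation for
swaps; pairs above 0.1 are flagged.

Low-level cross-contamination depresses the variant-allele fraction at those
same homozygous sites, because a contaminating individual carries the
wild-type allele on about half of its chromosomes.  The contaminant fraction
is estimated as

    C = 2 * (sum(RC_wt) - Ne) / (sum(RD_hom) - Ne),   Ne = e * sum(RD_hom)

with sequencing error rate e (default 0.001), a Clopper-Pearson binomial 95%
CI, and a conservative per-sample VAF floor of 5x the CI upper bound applied
to somatic calls downstream (fixed 10% fallback when no estimate is
possible).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InsufficientDataError",
    "ContaminationEstimate",
    "genotype_mismatch_rate",
    "estimate_contamination",
    "polymorphism_qc",
    "SWAP_RATE_THRESHOLD",
    "FALLBACK_VAF_FLOOR",
]

SWAP_RATE_THRESHOLD = 0.1
FALLBACK_VAF_FLOOR = 0.10  # fixed conservative contamination threshold
DEFAULT_ERROR_RATE = 0.001
MIN_SITE_DEPTH = 10
MIN_HOM_VAF = 0.90


class InsufficientDataError(ValueError):
    """Too little data to compute the requested QC statistic."""


def genotype_mismatch_rate(
    n_hom: int, n_het: int, n_wt: int
) -> tuple[float, bool]:
    """Tumor/normal genotype mismatch rate and swap flag.

    rate = (N_het + N_wt) / (N_hom + N_het + N_wt); 0 is expected for a
    perfectly genotyped matched pair, ~0.5 for samples from different
    individuals; pairs with rate > 0.1 are treated as swapped.
    """
    total = n_hom + n_het + n_wt
    if total < 1:
        raise InsufficientDataError("no informative genotyped sites")
    rate = (n_het + n_wt) / total
    return rate, rate > SWAP_RATE_THRESHOLD


@dataclass(frozen=True)
class ContaminationEstimate:
    """Estimated contaminant fraction with its binomial confidence bounds."""

    C: float
    ci95: tuple[float, float]
    Ne_used: float
    vaf_floor: float
    n_sites: int


def _c_from_wt(rc_wt: float, rd: float, ne: float) -> float:
    c = 2.0 * (rc_wt - ne) / (rd - ne)
    return float(min(max(c, 0.0), 1.0))


def estimate_contamination(
    sites: pd.DataFrame,
    error_rate: float = DEFAULT_ERROR_RATE,
    min_depth: int = MIN_SITE_DEPTH,
    floor_multiplier: float = 5.0,
) -> ContaminationEstimate:
    """Estimate the contaminant fraction from homozygous-SNP read counts.

    ``sites`` needs columns ``RD_hom`` (Q20 depth) and ``RC_wt`` (wild-type
    reads); sites below ``min_depth`` are dropped.  Ne = error_rate * sum(RD)
    is the expected number of error reads, pooled over sites.  The 95% CI is
    Clopper-Pearson on sum(RC_wt) ~ Binomial(sum(RD), p) pushed through the
    estimator; the VAF floor is ``floor_multiplier`` x the CI upper bound.
    """
    use = sites[sites["RD_hom"] >= min_depth]
    rd = float(use["RD_hom"].sum())
    if rd <= 0:
        raise InsufficientDataError("no homozygous sites with sufficient depth")
    rc = float(use["RC_wt"].sum())
    ne = error_rate * rd
    if rd <= ne:
        raise InsufficientDataError("depth does not exceed the expected error count")
    c = _c_from_wt(rc, rd, ne)
    lo_p, hi_p = _clopper_pearson(int(rc), int(rd))
    ci = (_c_from_wt(lo_p * rd, rd, ne), _c_from_wt(hi_p * rd, rd, ne))
    return ContaminationEstimate(
        C=c, ci95=ci, Ne_used=ne, vaf_floor=floor_multiplier * ci[1], n_sites=int(len(use))
    )


def _clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
    hi = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return float(lo), float(hi)


def polymorphism_qc(
    somatic_calls: Iterable[tuple[int, str]],
    germline_calls: Iterable[tuple[int, str]],
    polymorphism_set: set[tuple[int, str]],
    reference_alleles: Optional[dict[int, str]] = None,
    max_known_somatic: int = 3,
    max_back_mutations: int = 2,
) -> dict:
    """Flag samples whose somatic calls look like contamination artefacts.

    Two indicators: (i) somatic calls matching known germline polymorphisms
    (``>= max_known_somatic`` flags the sample) and (ii) back mutations -
    apparent somatic changes reverting an inherited polymorphism to the
    reference allele (``>= max_back_mutations`` flags).  ``somatic_calls``
    and ``germline_calls`` are (position, alt) pairs; ``reference_alleles``
    maps positions to the reference base (needed to recognise reversions).
    """
    somatic = list(somatic_calls)
    germ_positions = {pos for pos, _ in germline_calls}
    known = sum(1 for call in somatic if call in polymorphism_set)
    back = 0
    if reference_alleles:
        for pos, alt in somatic:
            if pos in germ_positions and reference_alleles.get(pos) == alt:
                back += 1
    flagged = known >= max_known_somatic or back >= max_back_mutations
    return {
        "known_polymorphism_calls": known,
        "back_mutations": back,
        "flagged": flagged,
    }
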