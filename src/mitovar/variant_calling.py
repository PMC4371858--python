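"""Somatic variant filter chain and read-backed phasing for mtDNA.

Calls are made from tumor/normal Q20 allele-count pileups.  A candidate
substitution passes only if all of the following hold simultaneously:

* >= 4 unique variant reads, or >= 3 when the VAF is >= 20% (low-read rescue);
* VAF >= 3% (the heteroplasmy detection floor, which also excludes NuMT
  artefacts);
* strand filter: at most 90% of variant reads on one sequencing strand, or a
  bias-difference rescue when |perfect-match strand bias - mismatch strand
  bias| < 0.1 (regions where only one read orientation aligns);
* the position+allele is not one of the 13 recurrent alignment artefacts
  around the rCRS homopolymer tracts (302-316, 513-525) and the 3107N spacer;
* VAF above the per-sample contamination floor (5x the 95% upper bound of the
  estimated contaminant fraction, 10% fallback);
* the allele is absent or below germline level (VAF < 1%) in the matched
  normal.

Mutation pairs close enough to be spanned by single sequencing fragments are
phased from read-haplotype counts into co-clonal, sub-clonal or
different-strand configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .qc_contamination import FALLBACK_VAF_FLOOR

__all__ = [
    "CallParams",
    "SomaticVariant",
    "PhaseCall",
    "RCRS_BLACKLIST",
    "call_somatic",
    "phase_pair",
]

NUCLEOTIDES = "ACGT"

# Thirteen recurrent false-positive sites caused by misalignment around rCRS
# homopolymers (ACCCCCCCTCCCCC at 302-315, GCACACACACACC at 513-525) and the
# 3107N reference spacer, stored as (position, alt allele).
_BLACKLIST_NAMES = [
    "A302C", "C309T", "C311T", "C312T", "C313T", "G316C",
    "C514A", "A515G", "A523C", "C524G",
    "C3106A", "T3109C", "C3110A",
]
RCRS_BLACKLIST = frozenset((int(n[1:-1]), n[-1]) for n in _BLACKLIST_NAMES)


@dataclass(frozen=True)
class CallParams:
    """Filter-chain thresholds (defaults follow the standard scheme above)."""

    min_variant_reads: int = 4
    rescue_reads: int = 3
    rescue_vaf: float = 0.20
    min_vaf: float = 0.03
    strand_max_fraction: float = 0.90
    strand_bias_rescue_diff: float = 0.10
    normal_max_vaf: float = 0.01
    blacklist: frozenset = RCRS_BLACKLIST
    vaf_floor: float = FALLBACK_VAF_FLOOR


@dataclass
class SomaticVariant:
    """One candidate somatic substitution with its filter outcome."""

    sample: int
    position: int
    ref: str
    alt: str
    vaf: float
    variant_reads: int
    strand_split: tuple[int, int]  # variant reads (fwd, rev)
    rescue_tags: set = field(default_factory=set)
    filters_failed: set = field(default_factory=set)

    @property
    def passed(self) -> bool:
        return not self.filters_failed


def _site_counts(row) -> dict[str, tuple[int, int]]:
    return {b: (int(getattr(row, f"{b}_fwd")), int(getattr(row, f"{b}_rev"))) for b in NUCLEOTIDES}


def call_somatic(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    vaf_floor: Optional[float] = None,
    params: CallParams = CallParams(),
    keep_failed: bool = False,
) -> list[SomaticVariant]:
    """Apply the somatic filter chain to paired tumor/normal pileups.

    ``tumor``/``normal`` follow the pileup schema (sample, position, ref,
    per-allele per-strand Q20 counts).  ``vaf_floor`` is the per-sample 5x
    contamination bound from QC (``params.vaf_floor`` fallback when None).
    The VAF denominator is variant + reference Q20 reads.  Returns passing
    calls; with ``keep_failed`` every candidate is returned with its failed
    filters recorded.
    """
    if normal is None:
        raise ValueError("a matched normal pileup is required for somatic calling")
    floor = params.vaf_floor if vaf_floor is None else vaf_floor
    normal_lookup: dict[tuple[int, int], dict] = {}
    for row in normal.itertuples(index=False):
        normal_lookup[(int(row.sample), int(row.position))] = _site_counts(row)

    out: list[SomaticVariant] = []
    for row in tumor.itertuples(index=False):
        counts = _site_counts(row)
        refb = str(row.ref)
        ref_fwd, ref_rev = counts.get(refb, (0, 0))
        for alt in NUCLEOTIDES:
            if alt == refb:
                continue
            fwd, rev = counts[alt]
            var_reads = fwd + rev
            if var_reads == 0:
                continue
            denom = var_reads + ref_fwd + ref_rev
            vaf = var_reads / denom if denom else 0.0
            failed: set[str] = set()
            rescues: set[str] = set()

            if var_reads < params.min_variant_reads:
                if var_reads >= params.rescue_reads and vaf >= params.rescue_vaf:
                    rescues.add("low_read_rescue")
                else:
                    failed.add("min_reads")
            if vaf < params.min_vaf:
                failed.add("min_vaf")

            one_sided = max(fwd, rev) / var_reads if var_reads else 0.0
            if one_sided > params.strand_max_fraction:
                pm_total = ref_fwd + ref_rev
                if pm_total and var_reads:
                    pm_bias = ref_fwd / pm_total
                    mm_bias = fwd / var_reads
                    if abs(pm_bias - mm_bias) < params.strand_bias_rescue_diff:
                        rescues.add("strand_bias_rescue")
                    else:
                        failed.add("strand_filter")
                else:
                    failed.add("strand_filter")

            if (int(row.position), alt) in params.blacklist:
                failed.add("blacklist")
            if vaf <= floor:
                failed.add("contamination_floor")

            ncounts = normal_lookup.get((int(row.sample), int(row.position)))
            if ncounts is None:
                failed.add("no_normal")
            else:
                n_var = sum(ncounts[alt])
                n_ref = sum(ncounts.get(refb, (0, 0)))
                n_denom = n_var + n_ref
                n_vaf = n_var / n_denom if n_denom else 0.0
                if n_vaf >= params.normal_max_vaf:
                    failed.add("present_in_normal")

            variant = SomaticVariant(
                sample=int(row.sample),
                position=int(row.position),
                ref=refb,
                alt=alt,
                vaf=vaf,
                variant_reads=var_reads,
                strand_split=(fwd, rev),
                rescue_tags=rescues,
                filters_failed=failed,
            )
            if variant.passed or keep_failed:
                out.append(variant)
    return out


def variants_to_frame(variants: list[SomaticVariant]) -> pd.DataFrame:
    """Tabulate calls (one row per variant) for downstream analyses."""
    return pd.DataFrame(
        [
            {
                "sample": v.sample,
                "position": v.position,
                "ref": v.ref,
                "alt": v.alt,
                "vaf": v.vaf,
                "variant_reads": v.variant_reads,
                "rescue_tags": ",".join(sorted(v.rescue_tags)) or ".",
                "filters_failed": ",".join(sorted(v.filters_failed)) or "PASS",
            }
            for v in variants
        ],
        columns=[
            "sample", "position", "ref", "alt", "vaf",
            "variant_reads", "rescue_tags", "filters_failed",
        ],
    )


@dataclass
class PhaseCall:
    """Phasing classification of a nearby mutation pair."""

    classification: str  # different_strand | co_clonal | sub_clonal | unresolved
    subclonal_variant: Optional[int]  # 1 or 2 when sub_clonal
    counts: dict


def phase_pair(evidence: dict, min_phasing_reads: int = 2) -> PhaseCall:
    """Classify a pair of nearby variants from spanning-read haplotypes.

    ``evidence`` holds counts keyed wt1_wt2, subs1_wt2, wt1_subs2,
    subs1_subs2; a haplotype is considered observed when supported by at
    least ``min_phasing_reads`` reads.  Co-clonal: only wt1-wt2 and
    subs1-subs2 observed.  Different strand: subs1-wt2 and wt1-subs2
    observed but no subs1-subs2.  Sub-clonal: subs1-subs2 observed together
    with exactly one single-mutant haplotype (that haplotype's variant is the
    earlier, clonal one).  Anything else, including no spanning reads, is
    unresolved.
    """
    c = {k: int(evidence.get(k, 0)) for k in ("wt1_wt2", "subs1_wt2", "wt1_subs2", "subs1_subs2")}
    seen = {k for k, v in c.items() if v >= min_phasing_reads}
    both = "subs1_subs2" in seen
    only1 = "subs1_wt2" in seen
    only2 = "wt1_subs2" in seen

    if both and not only1 and not only2:
        cls, sub = "co_clonal", None
    elif not both and only1 and only2:
        cls, sub = "different_strand", None
    elif both and (only1 != only2):
        # subs1-wt2 present => variant 1 also exists alone => variant 2 arose
        # later on a subset of variant-1 genomes (variant 2 is subclonal).
        cls, sub = "sub_clonal", (2 if only1 else 1)
    else:
        cls, sub = "unresolved", None
    return PhaseCall(classification=cls, subclonal_variant=sub, counts=c)
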