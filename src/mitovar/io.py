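"""Readers/writers for variant tables (VCF v4.2 and flat TSV).

VCF records carry INFO keys VAF (variant allele fraction), CONSEQ
(consequence category) and GENE, and FILTER strings naming each failed
filter-chain rule.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd
import pysam

from .genome_model import MtReference

__all__ = ["write_variants_vcf", "read_variants_vcf", "write_variants_tsv", "read_variants_tsv"]

_FILTER_DESCRIPTIONS = {
    "min_reads": "Fewer than the minimum unique variant reads (no rescue)",
    "min_vaf": "Variant allele fraction below the detection threshold",
    "strand_filter": "More than 90% of variant reads on one strand, no bias rescue",
    "blacklist": "Recurrent alignment artefact site",
    "contamination_floor": "VAF below 5x the 95% upper contamination bound",
    "present_in_normal": "Allele present at germline level in the matched normal",
    "no_normal": "No matched normal pileup at this site",
}


def _vcf_header(ref: MtReference) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    header.contigs.add(ref.name, length=len(ref))
    header.info.add("VAF", 1, "Float", "Variant allele fraction in the tumor")
    header.info.add("CONSEQ", 1, "String", "Consequence category")
    header.info.add("GENE", 1, "String", "Containing gene")
    header.info.add("SAMPLE", 1, "String", "Sample identifier")
    for name, desc in _FILTER_DESCRIPTIONS.items():
        header.filters.add(name, None, None, desc)
    return header


def write_variants_vcf(df: pd.DataFrame, ref: MtReference, path) -> None:
    """Write a variant table (columns sample, position, ref, alt, vaf and
    optionally conseq, gene, filters_failed) as uncompressed VCF v4.2."""
    header = _vcf_header(ref)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in df.sort_values(["position", "sample"]).itertuples(index=False):
            rec = vcf.new_record(
                contig=ref.name,
                start=int(row.position) - 1,
                stop=int(row.position) - 1 + len(str(row.ref)),
                alleles=(str(row.ref), str(row.alt)),
            )
            rec.info["VAF"] = float(row.vaf)
            rec.info["SAMPLE"] = str(row.sample)
            if hasattr(row, "conseq") and isinstance(row.conseq, str):
                rec.info["CONSEQ"] = row.conseq
            if hasattr(row, "gene") and isinstance(row.gene, str):
                rec.info["GENE"] = row.gene
            failed = getattr(row, "filters_failed", "PASS")
            if failed in ("PASS", ".", "", None) or pd.isna(failed):
                rec.filter.add("PASS")
            else:
                for f in str(failed).split(","):
                    rec.filter.add(f)
            vcf.write(rec)


def read_variants_vcf(path) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            rows.append(
                {
                    "sample": rec.info.get("SAMPLE", "."),
                    "position": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0] if rec.alts else ".",
                    "vaf": float(rec.info.get("VAF", float("nan"))),
                    "conseq": rec.info.get("CONSEQ", None),
                    "gene": rec.info.get("GENE", None),
                    "filters_failed": ",".join(rec.filter.keys()) or "PASS",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["sample", "position", "ref", "alt", "vaf", "conseq", "gene", "filters_failed"],
    )


def write_variants_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
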