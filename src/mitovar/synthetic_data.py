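"""Synthetic data generation for the mtDNA somatic-mutation analysis.

Generates circular references with protein/tRNA/rRNA/D-loop features, somatic
variant cohorts drawn from a strand-asymmetric trinucleotide signature
(optionally with the inverted polarity of the Ori-b--O_H segment), allele-count
pileups with binomial sampling and sequencing error, SNP-panel data with
injectable cross-contamination and sample swaps, and read-haplotype evidence
for phasing.  Everything is deterministic under a fixed seed.

The default signature preset qualitatively mimics the somatic mtDNA process:
C>T with the pyrimidine on the H strand strongly enriched at NpCpG (~10x) and
T>C on the L strand enriched at NpTpC (~6x), with low rates elsewhere.  These
presets are illustrative generator settings, not calibrated estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .drift_wf import wf_absorption
from .genome_model import (
    GeneAnnotation,
    MtReference,
    NUCLEOTIDES,
    complement,
    reverse_complement,
    translate_codon,
)
from .signature import (
    STRANDS,
    SUBSTITUTIONS,
    class_index,
    classify_substitution,
    pyrimidine_contexts,
    segment_positions,
)

__all__ = [
    "ConfigurationError",
    "CohortTruth",
    "default_signature_rates",
    "simulate_reference",
    "simulate_cohort",
    "simulate_pileups",
    "simulate_snp_panel",
    "simulate_genotype_counts",
    "simulate_phasing_reads",
    "PILEUP_COLUMNS",
    "write_pileups",
    "read_pileups",
]


class ConfigurationError(ValueError):
    """Infeasible or inconsistent generator configuration."""


# ---------------------------------------------------------------------------
# Signature presets
# ---------------------------------------------------------------------------

def default_signature_rates() -> pd.Series:
    """Strand-asymmetric 192-class rate preset.

    Relative rates (arbitrary scale): C>T on the H strand at 1.0, boosted to
    10 in NpCpG contexts; T>C on the L strand at 1.0, boosted to 6 in NpTpC
    contexts; all other classes at a low background of 0.05.
    """
    idx = class_index(192)
    rates = pd.Series(0.05, index=idx, name="rate")
    for ctx in pyrimidine_contexts("C"):
        rates.loc[("C>T", "H", ctx)] = 10.0 if ctx[2] == "G" else 1.0
    for ctx in pyrimidine_contexts("T"):
        rates.loc[("T>C", "L", ctx)] = 6.0 if ctx[2] == "C" else 1.0
    return rates


def _as_rate_series(rates) -> pd.Series:
    idx = class_index(192)
    s = pd.Series(rates).reindex(idx)
    if s.isna().any():
        raise ConfigurationError("rate table must cover all 192 classes")
    if (s < 0).any():
        raise ConfigurationError("rates must be non-negative")
    return s.astype(float)


# ---------------------------------------------------------------------------
# Reference simulation
# ---------------------------------------------------------------------------

_STOPS = ("TAA", "TAG", "AGA", "AGG")  # vertebrate mitochondrial stop codons


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """Random open reading frame under the mitochondrial code: ATG start,
    no internal stop, TAA stop."""
    codons = ["ATG"]
    all_codons = ["".join(c) for c in __import__("itertools").product(NUCLEOTIDES, repeat=3)]
    sense_codons = [c for c in all_codons if c not in _STOPS]
    codons += list(rng.choice(sense_codons, size=max(n_codons - 2, 0)))
    codons.append("TAA")
    return "".join(codons)


def simulate_reference(
    length: int,
    gene_plan: Optional[dict[str, float]] = None,
    seed: Optional[int] = None,
    n_protein_genes: int = 2,
    n_trnas: int = 2,
    h_strand_protein: bool = True,
) -> tuple[MtReference, list[GeneAnnotation]]:
    """Build a random circular genome with annotated features.

    ``gene_plan`` maps feature types to genome-length proportions, e.g.
    ``{"protein": 0.6, "tRNA": 0.06, "rRNA": 0.1, "dloop": 0.08}`` (the
    default); proportions must sum to <= 1, the remainder is intergenic.
    The D-loop wraps the origin, mirroring the real mtDNA control region.
    Protein features get valid reading frames (ATG start, no internal stop);
    with ``h_strand_protein`` the last protein gene is encoded on the H
    strand, mimicking MT-ND6.
    """
    if length < 300:
        raise ConfigurationError("length must be >= 300")
    plan = dict(gene_plan or {"protein": 0.6, "tRNA": 0.06, "rRNA": 0.1, "dloop": 0.08})
    if any(p < 0 for p in plan.values()) or sum(plan.values()) > 1.0 + 1e-9:
        raise ConfigurationError("gene_plan proportions must be >= 0 and sum to <= 1")
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list(NUCLEOTIDES), size=length))
    annotations: list[GeneAnnotation] = []

    dloop_len = int(round(plan.get("dloop", 0.0) * length))
    if dloop_len >= 3:
        # centred on the origin: second half at the end, first half at the start
        half = dloop_len // 2
        start = length - half + 1 if half else 1
        end = dloop_len - half
        annotations.append(
            GeneAnnotation(gene="DLOOP", start=start, end=end, feature="dloop")
        )
    cursor = (annotations[0].end if annotations else 0) + 1

    def place(span: int) -> tuple[int, int]:
        nonlocal cursor
        start, end = cursor, cursor + span - 1
        if end > length - (dloop_len - dloop_len // 2):
            raise ConfigurationError("gene_plan does not fit in the genome")
        cursor = end + 2  # 1-bp spacer
        return start, end

    protein_total = int(plan.get("protein", 0.0) * length)
    if protein_total:
        per_gene = protein_total // max(n_protein_genes, 1)
        n_codons = per_gene // 3
        if n_codons < 3:
            raise ConfigurationError("protein proportion too small for an ORF")
        for i in range(n_protein_genes):
            start, end = place(n_codons * 3)
            strand = "H" if (h_strand_protein and i == n_protein_genes - 1) else "L"
            orf = _random_orf(rng, n_codons)
            placed = orf if strand == "L" else reverse_complement(orf)
            seq[start - 1 : end] = list(placed)
            annotations.append(
                GeneAnnotation(
                    gene=f"PG{i + 1}", start=start, end=end, feature="protein",
                    coding_strand=strand,
                )
            )
    rrna_len = int(plan.get("rRNA", 0.0) * length)
    if rrna_len >= 3:
        start, end = place(rrna_len)
        annotations.append(GeneAnnotation(gene="RNR1", start=start, end=end, feature="rRNA"))
    trna_total = int(plan.get("tRNA", 0.0) * length)
    if trna_total:
        per = max(trna_total // max(n_trnas, 1), 9)
        for i in range(n_trnas):
            start, end = place(per)
            mid = start + per // 2
            annotations.append(
                GeneAnnotation(
                    gene=f"TRN{i + 1}", start=start, end=end, feature="tRNA",
                    coding_strand="L" if i % 2 == 0 else "H",
                    anticodon_span=(mid, mid + 2),
                )
            )
    ref = MtReference(sequence="".join(seq), name=f"synthetic_mt_{length}")
    return ref, annotations


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortTruth:
    """Ground truth of a simulated somatic cohort."""

    variants: pd.DataFrame  # sample, position, ref, alt, vaf
    signature_rates: pd.Series
    contamination_levels: np.ndarray
    swap_pairs: list[tuple[int, int]]
    n_samples: int
    seed: Optional[int]

    def to_json(self, path) -> None:
        payload = {
            "n_samples": self.n_samples,
            "seed": self.seed,
            "contamination_levels": self.contamination_levels.tolist(),
            "swap_pairs": [list(p) for p in self.swap_pairs],
            "n_variants": int(len(self.variants)),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _site_alt_weights(
    ref: MtReference,
    rates: pd.Series,
    inverted: set[int],
    strand_model: str,
    annotation: Optional[Sequence[GeneAnnotation]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-(position, alt) sampling weights proportional to class rate."""
    n = len(ref)
    positions, alts, weights = [], [], []
    gene_strand: dict[int, str] = {}
    if strand_model == "transcriptional":
        if annotation is None:
            raise ConfigurationError("transcriptional bias model requires an annotation")
        for feat in annotation:
            if feat.feature in ("protein", "tRNA", "rRNA"):
                for p in feat.positions(n):
                    gene_strand.setdefault(p, feat.coding_strand)
    for pos in range(1, n + 1):
        b = ref.base(pos)
        if b == "N":
            continue
        for alt in NUCLEOTIDES:
            if alt == b:
                continue
            sub, strand, ctx = classify_substitution(
                ref, pos, alt, swap_strand=pos in inverted
            )
            if strand_model == "transcriptional":
                coding = gene_strand.get(pos)
                if coding is None:
                    continue
                # rate keyed by whether the pyrimidine is on the coding strand;
                # reuse the L/H axis of the table as coding/template.
                strand = "L" if strand == coding else "H"
            positions.append(pos)
            alts.append(alt)
            weights.append(rates.loc[(sub, strand, ctx)])
    return (
        np.asarray(positions, dtype=np.int64),
        np.asarray(alts, dtype=object),
        np.asarray(weights, dtype=float),
    )


def _draw_vaf(rng: np.random.Generator, vaf_model: tuple, size: int) -> np.ndarray:
    kind = vaf_model[0]
    if kind == "fixed":
        return np.full(size, float(vaf_model[1]))
    if kind == "uniform":
        lo, hi = float(vaf_model[1]), float(vaf_model[2])
        if not 0 < lo <= hi <= 1:
            raise ConfigurationError("uniform VAF bounds must satisfy 0 < lo <= hi <= 1")
        return rng.uniform(lo, hi, size)
    if kind == "drift":
        m, t = int(vaf_model[1]), int(vaf_model[2])
        out = np.empty(size)
        filled = 0
        while filled < size:
            batch = max(4 * (size - filled) * m, 64)
            x, _ = wf_absorption(
                m, 1, batch, seed=int(rng.integers(2**31 - 1)),
                horizon=np.full(batch, t), max_generations=t,
            )
            surv = x[x > 0] / m
            take = min(surv.size, size - filled)
            out[filled : filled + take] = surv[:take]
            filled += take
        return out
    raise ConfigurationError(f"unknown vaf_model {kind!r}")


def simulate_cohort(
    ref: MtReference,
    annotation: Optional[Sequence[GeneAnnotation]],
    signature_rates,
    n_samples: int,
    mutation_rate: float,
    vaf_model: tuple = ("uniform", 0.05, 1.0),
    dloop_inversion: bool = False,
    segment: Optional[tuple[int, int]] = None,
    strand_model: str = "replicative",
    contamination: float | Sequence[float] = 0.0,
    swap_pairs: Optional[list[tuple[int, int]]] = None,
    seed: Optional[int] = None,
) -> CohortTruth:
    """Draw a somatic variant cohort from a strand-resolved signature.

    Variant (position, alt) pairs are sampled with probability proportional
    to class rate x context opportunity; each sample receives a Poisson
    (``mutation_rate``) number of variants at distinct positions.  With
    ``dloop_inversion`` the H/L strand roles are swapped inside the circular
    ``segment`` (ori_b, o_h), emulating the reversed leading/lagging polarity
    there.  ``vaf_model`` is ("fixed", v), ("uniform", lo, hi) or
    ("drift", M, T) where drift VAFs are Wright-Fisher outcomes of single-copy
    mutants conditioned on survival.
    """
    rates = _as_rate_series(signature_rates)
    if mutation_rate < 0:
        raise ConfigurationError("mutation_rate must be >= 0")
    if mutation_rate > 0 and rates.sum() == 0:
        raise ConfigurationError("all-zero signature rates with positive mutation rate")
    inverted: set[int] = set()
    if dloop_inversion:
        if segment is None:
            raise ConfigurationError("dloop_inversion requires segment=(ori_b, o_h)")
        inverted = segment_positions(ref, *segment)
    rng = np.random.default_rng(seed)

    rows: list[tuple] = []
    if mutation_rate > 0:
        positions, alts, weights = _site_alt_weights(
            ref, rates, inverted, strand_model, annotation
        )
        total = weights.sum()
        if total == 0:
            raise ConfigurationError("no mutable site has positive rate")
        probs = weights / total
        counts = rng.poisson(mutation_rate, size=n_samples)
        for s, k in enumerate(counts):
            if k == 0:
                continue
            idx = rng.choice(probs.size, size=k, replace=True, p=probs)
            idx = pd.unique(idx)  # distinct sites within one sample
            vafs = _draw_vaf(rng, vaf_model, idx.size)
            for j, i in enumerate(idx):
                p = int(positions[i])
                rows.append((s, p, ref.base(p), alts[i], float(vafs[j])))
    variants = pd.DataFrame(
        rows, columns=["sample", "position", "ref", "alt", "vaf"]
    ).astype({"sample": int, "position": int})
    contam = np.broadcast_to(np.asarray(contamination, dtype=float), (n_samples,)).copy()
    if ((contam < 0) | (contam >= 1)).any():
        raise ConfigurationError("contamination levels must be in [0, 1)")
    return CohortTruth(
        variants=variants,
        signature_rates=rates,
        contamination_levels=contam,
        swap_pairs=list(swap_pairs or []),
        n_samples=n_samples,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Pileup simulation
# ---------------------------------------------------------------------------

PILEUP_COLUMNS = ["sample", "position", "ref"] + [
    f"{b}_{s}" for b in NUCLEOTIDES for s in ("fwd", "rev")
]


def simulate_pileups(
    truth: CohortTruth,
    ref: MtReference,
    depth: float,
    error_rate: float = 0.0,
    seed: Optional[int] = None,
    germline: Optional[pd.DataFrame] = None,
    positions: Optional[Sequence[int]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tumor and normal per-position allele-count pileups.

    Site depth is Poisson(``depth``); variant read counts are
    Binomial(site depth, VAF * (1 - contamination)); sequencing errors land
    uniformly on the three non-reference bases at ``error_rate`` per read;
    counts are split between sequencing strands binomially.  All counts are
    quality-filtered (Q>=20) tallies.  ``germline`` (columns position, alt,
    optional sample) adds homoplasmic polymorphisms shared by tumor and
    normal.  ``positions`` restricts output sites (default: whole genome).
    """
    if depth < 0:
        raise ConfigurationError("depth must be >= 0")
    if not 0 <= error_rate < 0.25:
        raise ConfigurationError("error_rate must be in [0, 0.25)")
    rng = np.random.default_rng(seed)
    if positions is None:
        positions = range(1, len(ref) + 1)
    positions = list(positions)
    if depth == 0:
        empty = pd.DataFrame(columns=PILEUP_COLUMNS)
        return empty, empty.copy()

    var_lookup: dict[tuple[int, int], list[tuple[str, float]]] = {}
    for row in truth.variants.itertuples(index=False):
        adj = row.vaf * (1.0 - truth.contamination_levels[row.sample])
        var_lookup.setdefault((row.sample, row.position), []).append((row.alt, adj))
    germ_lookup: dict[tuple[int, int], str] = {}
    if germline is not None:
        for row in germline.itertuples(index=False):
            samples = [int(row.sample)] if hasattr(row, "sample") else range(truth.n_samples)
            for s in samples:
                germ_lookup[(s, int(row.position))] = str(row.alt)

    def build(is_tumor: bool) -> pd.DataFrame:
        recs = []
        for s in range(truth.n_samples):
            for pos in positions:
                d = int(rng.poisson(depth))
                counts = {b: 0 for b in NUCLEOTIDES}
                refb = ref.base(pos)
                remaining = d
                germ_alt = germ_lookup.get((s, pos))
                site_ref = germ_alt or refb  # germline allele is the wild type here
                if is_tumor:
                    for alt, vaf in var_lookup.get((s, pos), []):
                        k = int(rng.binomial(remaining, min(vaf, 1.0))) if remaining else 0
                        counts[alt] += k
                        remaining -= k
                counts[site_ref] += remaining
                if error_rate > 0 and d:
                    for b in NUCLEOTIDES:
                        n_from = counts[b]
                        if not n_from:
                            continue
                        errs = rng.binomial(n_from, error_rate)
                        counts[b] -= errs
                        for _ in range(errs):
                            counts[rng.choice([x for x in NUCLEOTIDES if x != b])] += 1
                rec = [s, pos, refb]
                for b in NUCLEOTIDES:
                    fwd = int(rng.binomial(counts[b], 0.5)) if counts[b] else 0
                    rec += [fwd, counts[b] - fwd]
                recs.append(rec)
        return pd.DataFrame(recs, columns=PILEUP_COLUMNS)

    tumor = build(is_tumor=True)
    normal = build(is_tumor=False)
    return tumor, normal


def write_pileups(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_pileups(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# SNP panel (contamination / swap) simulation
# ---------------------------------------------------------------------------

def simulate_snp_panel(
    n_sites: int,
    depth: float,
    contamination: float,
    error_rate: float = 0.001,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Read counts at normal-homozygous common-SNP sites of one sample.

    The sample is homozygous for the variant allele at every panel site; a
    contaminant individual (common SNPs, minor allele fraction ~50%) carries
    the wild-type allele on average on half its chromosomes, so the expected
    wild-type read fraction is contamination / 2 plus sequencing error.
    Columns: site, RD_hom (Q20 depth), RC_wt (wild-type read count).
    """
    if not 0 <= contamination < 1:
        raise ConfigurationError("contamination must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rd = rng.poisson(depth, size=n_sites).astype(np.int64)
    # contaminant genotype at each site: hom-variant 25%, het 50%, hom-wt 25%
    wt_frac = rng.choice([0.0, 0.5, 1.0], p=[0.25, 0.5, 0.25], size=n_sites)
    p_wt = np.clip(contamination * wt_frac + error_rate, 0.0, 1.0)
    rc_wt = rng.binomial(rd, p_wt)
    return pd.DataFrame({"site": np.arange(1, n_sites + 1), "RD_hom": rd, "RC_wt": rc_wt})


def simulate_genotype_counts(
    n_sites: int,
    swapped: bool,
    genotyping_error: float = 0.0,
    seed: Optional[int] = None,
) -> dict[str, int]:
    """Tumor genotype tallies at normal-homozygous panel sites.

    For a matched pair every site should re-genotype as homozygous variant;
    for a swapped (unrelated) pair the tumor genotype follows Hardy-Weinberg
    at ~50% allele frequency.  Returns counts of hom / het / wt calls.
    """
    rng = np.random.default_rng(seed)
    if swapped:
        probs = [0.25, 0.5, 0.25]
    else:
        e = genotyping_error
        probs = [1 - e, e / 2, e / 2]
    draws = rng.choice(3, p=probs, size=n_sites)
    return {
        "N_hom": int((draws == 0).sum()),
        "N_het": int((draws == 1).sum()),
        "N_wt": int((draws == 2).sum()),
    }


# ---------------------------------------------------------------------------
# Phasing-read simulation
# ---------------------------------------------------------------------------

def simulate_phasing_reads(
    configuration: str,
    n_reads: int,
    positions: tuple[int, int] = (100, 200),
    fragment_span: int = 500,
    vaf1: float = 0.6,
    vaf2: float = 0.3,
    seed: Optional[int] = None,
) -> dict[str, int]:
    """Read-haplotype counts for two nearby variants.

    ``configuration`` selects the truth: 'co_clonal' (both substitutions on
    the same molecules), 'sub_clonal' (variant 2 on a subset of molecules
    carrying variant 1) or 'different_strand' (the two substitutions on
    disjoint molecules).  Returns counts keyed wt1_wt2, subs1_wt2, wt1_subs2,
    subs1_subs2.
    """
    if abs(positions[1] - positions[0]) > fragment_span:
        raise ConfigurationError("variant positions farther apart than the fragment span")
    if configuration not in ("co_clonal", "sub_clonal", "different_strand"):
        raise ConfigurationError(f"unknown configuration {configuration!r}")
    if not 0 < vaf2 <= vaf1 <= 1:
        raise ConfigurationError("require 0 < vaf2 <= vaf1 <= 1")
    rng = np.random.default_rng(seed)
    counts = {"wt1_wt2": 0, "subs1_wt2": 0, "wt1_subs2": 0, "subs1_subs2": 0}
    if configuration == "co_clonal":
        probs = {"subs1_subs2": vaf1, "wt1_wt2": 1 - vaf1}
    elif configuration == "sub_clonal":
        probs = {"subs1_subs2": vaf2, "subs1_wt2": vaf1 - vaf2, "wt1_wt2": 1 - vaf1}
    else:
        if vaf1 + vaf2 > 1:
            raise ConfigurationError("different_strand requires vaf1 + vaf2 <= 1")
        probs = {"subs1_wt2": vaf1, "wt1_subs2": vaf2, "wt1_wt2": 1 - vaf1 - vaf2}
    keys = [k for k, v in probs.items() if v > 0]
    draws = rng.choice(len(keys), p=np.array([probs[k] for k in keys]) / sum(probs[k] for k in keys), size=n_reads)
    for i, k in enumerate(keys):
        counts[k] = int((draws == i).sum())
    return counts
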