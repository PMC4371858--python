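"""Strand-resolved mutational signatures for mtDNA.

Somatic mtDNA substitutions show an extreme replicative strand asymmetry:
C>T transitions occur predominantly with the mutated cytosine on the heavy
(H) strand and T>C transitions with the mutated thymine on the light (L)
strand, and this polarity inverts inside the short segment between the
alternative replication origin Ori-b (~position 16,197 in human mtDNA) and
the heavy-strand origin O_H (~position 191) where leading/lagging roles swap.

Substitutions are represented pyrimidine-centric: each variant is assigned one
of the 6 pyrimidine substitution types (C>A, C>G, C>T, T>A, T>C, T>G) together
with the strand physically carrying the mutated pyrimidine.  With the
immediate 5' and 3' neighbours (read on the pyrimidine strand) this gives
192 = 6 x 16 x 2 strand-resolved trinucleotide classes.  Rates are counts
normalised by the number of occurrences of each context on each strand of the
circular reference ("opportunities").
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import (
    GeneAnnotation,
    MtReference,
    complement,
    reverse_complement,
    trinucleotide_context,
)

__all__ = [
    "SUBSTITUTIONS",
    "STRANDS",
    "pyrimidine_contexts",
    "SignatureTable",
    "StrandBiasSummary",
    "classify_substitution",
    "context_opportunities",
    "compute_signature",
    "strand_bias_summary",
    "signature_concordance",
    "strand_model_comparison",
    "dloop_segment_signature",
    "segment_positions",
    "cosine_similarity",
]

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
STRANDS = ("L", "H")
PYRIMIDINES = "CT"

# Default human Ori-b--O_H segment boundaries (inclusive on both sides).
DEFAULT_ORI_B = 16197
DEFAULT_O_H = 191


def pyrimidine_contexts(central: str) -> list[str]:
    """The 16 trinucleotide contexts with the given central pyrimidine."""
    return [a + central + b for a, b in itertools.product("ACGT", repeat=2)]


def class_index(n_classes: int = 192) -> pd.MultiIndex:
    """Canonical class index: (substitution, strand[, context])."""
    if n_classes == 12:
        return pd.MultiIndex.from_tuples(
            [(s, st) for s in SUBSTITUTIONS for st in STRANDS],
            names=["substitution", "strand"],
        )
    if n_classes == 192:
        rows = []
        for sub in SUBSTITUTIONS:
            for strand in STRANDS:
                for ctx in pyrimidine_contexts(sub[0]):
                    rows.append((sub, strand, ctx))
        return pd.MultiIndex.from_tuples(rows, names=["substitution", "strand", "context"])
    raise ValueError("n_classes must be 12 or 192")


def classify_substitution(
    ref: MtReference, position: int, alt: str, swap_strand: bool = False
) -> tuple[str, str, str]:
    """(substitution, pyrimidine strand, pyrimidine-strand context) of a
    single-base change at ``position`` with L-strand alternative ``alt``.

    ``swap_strand`` relabels L<->H (used when emulating the inverted
    replication polarity of the Ori-b--O_H segment).
    """
    b = ref.base(position)
    ctx_l = trinucleotide_context(ref, position, "L")
    if b in PYRIMIDINES:
        sub, strand, ctx = f"{b}>{alt}", "L", ctx_l
    else:
        sub, strand, ctx = f"{complement(b)}>{complement(alt)}", "H", reverse_complement(ctx_l)
    if swap_strand:
        strand = "H" if strand == "L" else "L"
    return sub, strand, ctx


def context_opportunities(ref: MtReference, positions: Optional[Iterable[int]] = None) -> pd.Series:
    """Occurrences of each pyrimidine-centred context per strand.

    For each position, the base is attributed to the strand on which it is a
    pyrimidine: an L-strand C or T counts toward (L, L-context); an L-strand
    A or G is a pyrimidine on the H strand and counts toward
    (H, reverse-complemented context).  Indexed by (strand, context).
    """
    counts: dict[tuple[str, str], int] = {}
    if positions is None:
        positions = range(1, len(ref) + 1)
    for pos in positions:
        b = ref.base(pos)
        if b == "N":
            continue
        ctx = trinucleotide_context(ref, pos, "L")
        if "N" in ctx:
            continue
        if b in PYRIMIDINES:
            key = ("L", ctx)
        else:
            key = ("H", reverse_complement(ctx))
        counts[key] = counts.get(key, 0) + 1
    idx = pd.MultiIndex.from_tuples(
        [(st, ctx) for st in STRANDS for c in PYRIMIDINES for ctx in pyrimidine_contexts(c)],
        names=["strand", "context"],
    )
    return pd.Series({k: counts.get(k, 0) for k in idx}, name="opportunity").reindex(idx)


@dataclass
class SignatureTable:
    """Strand-resolved mutation counts, opportunities and rates.

    ``table`` is indexed by (substitution, strand) for the 12-class model or
    (substitution, strand, context) for the 192-class model, with columns
    ``count``, ``opportunity`` and ``rate`` (= count / opportunity).
    """

    table: pd.DataFrame
    n_classes: int
    strand_model: str = "replicative"
    region: str = "whole_genome"

    @property
    def counts(self) -> pd.Series:
        return self.table["count"]

    @property
    def rates(self) -> pd.Series:
        return self.table["rate"]

    def total(self) -> int:
        return int(self.table["count"].sum())

    def to_tsv(self, path) -> None:
        self.table.reset_index().to_csv(path, sep="\t", index=False)


def _variant_class(
    ref: MtReference,
    annotation: Optional[Sequence[GeneAnnotation]],
    strand_model: str,
    position: int,
    alt: str,
) -> Optional[tuple[str, str, str]]:
    sub, strand, ctx = classify_substitution(ref, position, alt)
    if strand_model == "replicative":
        return sub, strand, ctx
    # transcriptional model: strand keyed to the coding strand of the
    # containing gene ('coding' when the mutated pyrimidine lies on the
    # mRNA-sense strand, 'template' otherwise); intergenic variants skipped.
    if annotation is None:
        raise ValueError("transcriptional strand model requires an annotation")
    n = len(ref)
    for feat in annotation:
        if feat.feature in ("protein", "tRNA", "rRNA") and feat.contains(position, n):
            label = "coding" if strand == feat.coding_strand else "template"
            return sub, label, ctx
    return None


def compute_signature(
    variants: pd.DataFrame,
    ref: MtReference,
    region: Optional[Iterable[int]] = None,
    strand_model: str = "replicative",
    n_classes: int = 192,
    annotation: Optional[Sequence[GeneAnnotation]] = None,
    region_label: str = "whole_genome",
    exclude_segment: Optional[tuple[int, int]] = None,
) -> SignatureTable:
    """Count substitutions per strand-resolved class and normalise by context
    opportunity.

    ``variants`` needs columns ``position``, ``ref`` and ``alt`` (single-base,
    L-strand representation).  ``region`` restricts both the counted variants
    and the opportunity tally to a set of positions (default: whole genome).
    ``exclude_segment`` = (ori_b, o_h) removes the origin segment, whose
    inverted replication polarity would otherwise dilute a whole-genome
    signature.  Under the transcriptional strand model the strand labels are
    'coding'/'template' relative to the containing gene and only genic
    variants/positions contribute.
    """
    if strand_model not in ("replicative", "transcriptional"):
        raise ValueError(f"unknown strand model {strand_model!r}")
    region_set = None if region is None else set(region)
    if exclude_segment is not None:
        base = region_set if region_set is not None else set(range(1, len(ref) + 1))
        region_set = base - segment_positions(ref, *exclude_segment)

    counts: dict[tuple, int] = {}
    for row in variants.itertuples(index=False):
        pos, alt = int(row.position), str(row.alt)
        if len(str(row.ref)) != 1 or len(alt) != 1:
            continue  # indels carry no trinucleotide class
        if region_set is not None and pos not in region_set:
            continue
        cls = _variant_class(ref, annotation, strand_model, pos, alt)
        if cls is None:
            continue
        sub, strand, ctx = cls
        key = (sub, strand, ctx) if n_classes == 192 else (sub, strand)
        counts[key] = counts.get(key, 0) + 1

    if strand_model == "replicative":
        positions = region_set
        opp = context_opportunities(ref, positions)
        strand_labels = STRANDS
    else:
        n = len(ref)
        opp_counts: dict[tuple[str, str], int] = {}
        for feat in annotation or []:
            if feat.feature not in ("protein", "tRNA", "rRNA"):
                continue
            for pos in feat.positions(n):
                if region_set is not None and pos not in region_set:
                    continue
                b = ref.base(pos)
                ctx = trinucleotide_context(ref, pos, "L")
                if b in PYRIMIDINES:
                    strand = "L"
                else:
                    strand, ctx = "H", reverse_complement(ctx)
                label = "coding" if strand == feat.coding_strand else "template"
                opp_counts[(label, ctx)] = opp_counts.get((label, ctx), 0) + 1
        strand_labels = ("coding", "template")
        idx = pd.MultiIndex.from_tuples(
            [
                (st, ctx)
                for st in strand_labels
                for c in PYRIMIDINES
                for ctx in pyrimidine_contexts(c)
            ],
            names=["strand", "context"],
        )
        opp = pd.Series({k: opp_counts.get(k, 0) for k in idx}, name="opportunity")

    rows = []
    for sub in SUBSTITUTIONS:
        for strand in strand_labels:
            for ctx in pyrimidine_contexts(sub[0]):
                rows.append((sub, strand, ctx, opp.loc[(strand, ctx)]))
    tbl = pd.DataFrame(rows, columns=["substitution", "strand", "context", "opportunity"])
    if n_classes == 192:
        tbl["count"] = [
            counts.get((s, st, c), 0)
            for s, st, c in zip(tbl["substitution"], tbl["strand"], tbl["context"])
        ]
        tbl = tbl.set_index(["substitution", "strand", "context"])
    else:
        tbl = tbl.groupby(["substitution", "strand"], sort=False)[["opportunity"]].sum()
        tbl["count"] = [counts.get(k, 0) for k in tbl.index]
    bad = (tbl["count"] > 0) & (tbl["opportunity"] == 0)
    if bad.any():
        raise ValueError(f"classes with observed mutations but zero opportunity: {tbl.index[bad].tolist()}")
    with np.errstate(invalid="ignore", divide="ignore"):
        tbl["rate"] = np.where(tbl["opportunity"] > 0, tbl["count"] / tbl["opportunity"], 0.0)
    return SignatureTable(
        table=tbl[["count", "opportunity", "rate"]],
        n_classes=n_classes,
        strand_model=strand_model,
        region=region_label,
    )


@dataclass
class StrandBiasSummary:
    """Per-substitution strand shares, composition ratios and rate folds."""

    table: pd.DataFrame  # index: substitution; columns below
    chi2_stat: float
    chi2_p: float


def strand_bias_summary(sig: SignatureTable) -> StrandBiasSummary:
    """Summarise the H/L strand asymmetry of a replicative signature.

    Per substitution type: ``h_share`` (fraction of mutations with the
    pyrimidine on the H strand), ``composition_ratio`` (opportunity L /
    opportunity H) and ``rate_fold`` (rate H / rate L).  These are linked by
    fold = (share/(1-share)) x composition ratio.  The chi-square statistic
    compares the 12 observed class counts to the expectation under a single
    uniform rate across classes (counts proportional to opportunities).
    """
    tbl = sig.table
    if sig.n_classes == 192:
        tbl = tbl.groupby(level=["substitution", "strand"], sort=False)[
            ["count", "opportunity"]
        ].sum()
    rows = []
    for sub in SUBSTITUTIONS:
        c_h, c_l = tbl.loc[(sub, "H"), "count"], tbl.loc[(sub, "L"), "count"]
        o_h, o_l = tbl.loc[(sub, "H"), "opportunity"], tbl.loc[(sub, "L"), "opportunity"]
        total = c_h + c_l
        share = c_h / total if total else np.nan
        comp = o_l / o_h if o_h else np.nan
        rate_h = c_h / o_h if o_h else np.nan
        rate_l = c_l / o_l if o_l else np.nan
        if total and c_h > 0 and o_h == 0:
            raise ValueError(f"zero opportunity with nonzero count for {sub} H")
        fold = rate_h / rate_l if rate_l else np.inf
        rows.append((sub, share, comp, fold, c_h, c_l, o_h, o_l))
    out = pd.DataFrame(
        rows,
        columns=[
            "substitution",
            "h_share",
            "composition_ratio",
            "rate_fold",
            "count_H",
            "count_L",
            "opportunity_H",
            "opportunity_L",
        ],
    ).set_index("substitution")
    observed = tbl["count"].to_numpy(dtype=float)
    opp = tbl["opportunity"].to_numpy(dtype=float)
    stat, p = signature_concordance(observed, opp)
    return StrandBiasSummary(table=out, chi2_stat=stat, chi2_p=p)


def signature_concordance(observed, background) -> tuple[float, float]:
    """Chi-square of observed class counts against expectation proportional
    to a background (opportunities, or a background signature's counts).

    Classes with zero background weight and zero observations are dropped.
    """
    observed = np.asarray(observed, dtype=float)
    background = np.asarray(background, dtype=float)
    keep = background > 0
    if (observed[~keep] > 0).any():
        raise ValueError("observed counts in classes with zero background weight")
    observed, background = observed[keep], background[keep]
    expected = background / background.sum() * observed.sum()
    stat, p = stats.chisquare(observed, expected)
    return float(stat), float(p)


def strand_model_comparison(
    variants: pd.DataFrame,
    ref: MtReference,
    annotation: Sequence[GeneAnnotation],
) -> dict[str, float]:
    """Chi-square discrimination between replicative and transcriptional
    strand models.

    Variants in H-coding genes are compared against the background signature
    of L-coding genes under each strand keying.  A replication-coupled
    process leaves the physical-strand (replicative) signature of H-coding
    genes identical to the background, so the replicative chi-square is low
    and the transcriptional one high; a transcription-coupled process gives
    the reverse.  Returns {'replicative': stat, 'transcriptional': stat};
    the lower statistic marks the better-fitting model.
    """
    n = len(ref)
    h_pos: set[int] = set()
    l_pos: set[int] = set()
    for feat in annotation:
        if feat.feature not in ("protein", "tRNA", "rRNA"):
            continue
        target = h_pos if feat.coding_strand == "H" else l_pos
        target.update(feat.positions(n))
    if not h_pos or not l_pos:
        raise ValueError("need genes coded on both strands to compare models")
    in_h = variants[variants["position"].map(lambda p: int(p) in h_pos)]
    in_l = variants[variants["position"].map(lambda p: int(p) in l_pos)]
    out: dict[str, float] = {}
    for model in ("replicative", "transcriptional"):
        sig_h = compute_signature(in_h, ref, region=h_pos, strand_model=model,
                                  n_classes=12, annotation=annotation)
        sig_l = compute_signature(in_l, ref, region=l_pos, strand_model=model,
                                  n_classes=12, annotation=annotation)
        # Haldane pseudocount keeps the expectation positive for classes the
        # background happens not to sample.
        bg_rate = np.where(
            sig_l.table["opportunity"] > 0,
            (sig_l.table["count"] + 0.5) / sig_l.table["opportunity"],
            0.0,
        )
        expected = bg_rate * sig_h.table["opportunity"].to_numpy(float)
        observed = sig_h.table["count"].to_numpy(float)
        stat, _ = signature_concordance(observed, expected)
        out[model] = stat
    return out


def segment_positions(ref: MtReference, ori_b: int = DEFAULT_ORI_B, o_h: int = DEFAULT_O_H) -> set[int]:
    """Positions of the circular Ori-b--O_H segment [ori_b..length] U [1..o_h].

    Boundary positions belong to the segment.
    """
    if not (1 <= o_h < ori_b <= len(ref)):
        raise ValueError("expected 1 <= o_h < ori_b <= genome length (segment wraps the origin)")
    inside = set(range(ori_b, len(ref) + 1)) | set(range(1, o_h + 1))
    if len(inside) >= len(ref):
        raise ValueError("degenerate segment covering the whole genome")
    return inside


def dloop_segment_signature(
    variants: pd.DataFrame,
    ref: MtReference,
    ori_b: int = DEFAULT_ORI_B,
    o_h: int = DEFAULT_O_H,
    n_classes: int = 12,
) -> tuple[SignatureTable, SignatureTable]:
    """Signatures inside vs outside the Ori-b--O_H segment.

    Inside this segment the leading/lagging replication roles of the two
    strands are swapped, so a replication-coupled process shows a
    strand-inverted signature there.
    """
    inside = segment_positions(ref, ori_b, o_h)
    outside = set(range(1, len(ref) + 1)) - inside
    sig_in = compute_signature(variants, ref, region=inside, n_classes=n_classes, region_label="ori_b_to_o_h")
    sig_out = compute_signature(variants, ref, region=outside, n_classes=n_classes, region_label="outside_segment")
    return sig_in, sig_out


def cosine_similarity(a, b) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))
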