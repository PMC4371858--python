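"""Circular mitochondrial genome model.

The mitochondrial genome is a small circular molecule with two complementary
strands of very different base composition: the guanine-rich heavy (H) strand
and the cytosine-rich light (L) strand.  Throughout this package the reference
sequence is recorded on the L strand; alleles, trinucleotide contexts and
codons on the H strand are obtained by complementing.  Coordinates are 1-based
inclusive, matching the community convention for naming variants (e.g. C309T),
and all position arithmetic wraps around the origin.

Protein-coding genes are translated with the vertebrate mitochondrial genetic
code (TGA = Trp, ATA = Met, AGA/AGG = stop).  A gene's ``coding_strand`` is the
strand whose sequence equals the mRNA sense sequence; in human mtDNA 12 of the
13 protein genes are encoded on the L strand and only MT-ND6 on the H strand.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "MtReference",
    "GeneAnnotation",
    "Consequence",
    "load_reference",
    "read_annotation",
    "write_annotation",
    "trinucleotide_context",
    "annotate_consequence",
    "classify_variant",
    "complement",
    "reverse_complement",
    "translate_codon",
    "MITO_CODE",
    "SEVERITY_ORDER",
]

NUCLEOTIDES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# NCBI translation table 2 (vertebrate mitochondrial)
MITO_CODE = CodonTable.unambiguous_dna_by_id[2]
_MITO_FORWARD = dict(MITO_CODE.forward_table)
_MITO_STOPS = frozenset(MITO_CODE.stop_codons)

SEVERITY_ORDER = [
    "frameshift",
    "nonsense",
    "stop_lost",
    "missense",
    "inframe_indel",
    "silent",
    "tRNA",
    "rRNA",
    "intergenic",
]
_SEVERITY_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}


class FormatError(ValueError):
    """Malformed input file or sequence."""


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Amino acid for ``codon`` under the vertebrate mitochondrial code.

    Returns ``'*'`` for stop codons.
    """
    codon = codon.upper()
    if codon in _MITO_STOPS:
        return "*"
    try:
        return _MITO_FORWARD[codon]
    except KeyError as exc:
        raise ValueError(f"not a translatable codon: {codon!r}") from exc


@dataclass(frozen=True)
class MtReference:
    """A circular mtDNA reference recorded on the L strand."""

    sequence: str
    name: str = "mtDNA"
    is_circular: bool = True

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 3:
            raise FormatError("reference must be at least 3 bp")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise FormatError(f"non-nucleotide characters in reference: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def wrap(self, position: int) -> int:
        """Map any integer position onto 1..length (circular arithmetic)."""
        return (position - 1) % len(self.sequence) + 1

    def base(self, position: int) -> str:
        """L-strand base at a 1-based position (wrapping circularly)."""
        return self.sequence[(position - 1) % len(self.sequence)]

    def fetch(self, start: int, end: int) -> str:
        """L-strand sequence from ``start`` to ``end`` inclusive, circular.

        ``end < start`` wraps through the origin.
        """
        n = len(self.sequence)
        span = (end - start) % n + 1
        return "".join(self.sequence[(start - 1 + i) % n] for i in range(span))

    def context(self, position: int, strand: str = "L") -> str:
        return trinucleotide_context(self, position, strand)


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated feature on the circular genome.

    ``start``/``end`` are 1-based inclusive; ``end < start`` means the feature
    wraps through the origin.  ``coding_strand`` is the strand carrying the
    mRNA-sense sequence ('L' or 'H'); it is meaningful for protein and RNA
    features.  ``anticodon_span`` (tRNA only) is the 1-based inclusive interval
    of the three anticodon bases.
    """

    gene: str
    start: int
    end: int
    feature: str  # protein | tRNA | rRNA | dloop | intergenic
    coding_strand: str = "L"
    frame_offset: int = 0
    anticodon_span: Optional[tuple[int, int]] = None

    def length(self, genome_length: int) -> int:
        return (self.end - self.start) % genome_length + 1

    def positions(self, genome_length: int) -> Iterator[int]:
        """All positions of the feature in 5'->3' order of the L strand."""
        n = self.length(genome_length)
        for i in range(n):
            yield (self.start - 1 + i) % genome_length + 1

    def contains(self, position: int, genome_length: int) -> bool:
        off = (position - self.start) % genome_length
        return off < self.length(genome_length)

    def in_anticodon(self, position: int, genome_length: int) -> bool:
        if self.anticodon_span is None:
            return False
        s, e = self.anticodon_span
        off = (position - s) % genome_length
        return off <= (e - s) % genome_length

    def sense_sequence(self, ref: MtReference) -> str:
        """mRNA-sense sequence of the feature (read on ``coding_strand``)."""
        seq = ref.fetch(self.start, self.end)
        return seq if self.coding_strand == "L" else reverse_complement(seq)

    def cds_index(self, position: int, genome_length: int) -> Optional[int]:
        """0-based index of ``position`` within the in-frame sense sequence.

        Returns None when the position falls before the frame offset.
        """
        if self.coding_strand == "L":
            off = (position - self.start) % genome_length
        else:
            off = (self.end - position) % genome_length
        idx = off - self.frame_offset
        return idx if idx >= 0 else None


@dataclass(frozen=True)
class Consequence:
    """Functional consequence of one variant in one feature."""

    category: str
    gene: Optional[str] = None
    codon_change: Optional[str] = None
    aa_change: Optional[str] = None
    anticodon_hit: bool = False

    @property
    def severity(self) -> int:
        return _SEVERITY_RANK[self.category]


def load_reference(path) -> MtReference:
    """Read a single-record FASTA into an :class:`MtReference`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    if len(records) > 1:
        raise FormatError(f"expected a single record, found {len(records)} in {path}")
    rec = records[0]
    return MtReference(sequence=str(rec.seq), name=rec.id)


ANNOTATION_COLUMNS = [
    "gene",
    "start",
    "end",
    "coding_strand",
    "feature",
    "frame_offset",
    "anticodon_start",
]


def read_annotation(path) -> list[GeneAnnotation]:
    """Read the bundled tab-separated annotation schema.

    Columns: gene, start, end, coding_strand, feature, frame_offset,
    anticodon_start (``.`` when absent; anticodon spans 3 bp).
    """
    out: list[GeneAnnotation] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "gene":
                continue
            gene, start, end, strand, feature, frame, anti = parts[:7]
            span = None
            if anti not in (".", ""):
                a = int(anti)
                span = (a, a + 2)
            out.append(
                GeneAnnotation(
                    gene=gene,
                    start=int(start),
                    end=int(end),
                    coding_strand=strand,
                    feature=feature,
                    frame_offset=int(frame),
                    anticodon_span=span,
                )
            )
    return out


def write_annotation(features: Sequence[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(ANNOTATION_COLUMNS) + "\n")
        for f in features:
            anti = str(f.anticodon_span[0]) if f.anticodon_span else "."
            fh.write(
                "\t".join(
                    [
                        f.gene,
                        str(f.start),
                        str(f.end),
                        f.coding_strand,
                        f.feature,
                        str(f.frame_offset),
                        anti,
                    ]
                )
                + "\n"
            )


def trinucleotide_context(ref: MtReference, position: int, strand: str = "L") -> str:
    """5'-base, base, 3'-base around ``position`` on the requested strand.

    On the L strand this is ``ref[pos-1], ref[pos], ref[pos+1]`` with circular
    wrapping; the H-strand context is its reverse complement.
    """
    if not 1 <= position <= len(ref):
        raise IndexError(f"position {position} out of range 1..{len(ref)}")
    ctx = ref.base(position - 1) + ref.base(position) + ref.base(position + 1)
    if strand == "L":
        return ctx
    if strand == "H":
        return reverse_complement(ctx)
    raise ValueError(f"strand must be 'L' or 'H', got {strand!r}")


def _protein_consequence(
    ref: MtReference, gene: GeneAnnotation, position: int, ref_allele: str, alt_allele: str
) -> Consequence:
    n = len(ref)
    idx = gene.cds_index(position, n)
    if idx is None:
        return Consequence(category="intergenic", gene=gene.gene)
    sense = gene.sense_sequence(ref)[gene.frame_offset :]
    codon_i, within = divmod(idx, 3)
    codon = sense[codon_i * 3 : codon_i * 3 + 3]
    if len(codon) < 3:  # trailing partial codon
        return Consequence(category="intergenic", gene=gene.gene)
    alt_sense = alt_allele if gene.coding_strand == "L" else complement(alt_allele)
    new_codon = codon[:within] + alt_sense + codon[within + 1 :]
    aa_old = translate_codon(codon)
    aa_new = translate_codon(new_codon)
    if aa_old == aa_new:
        category = "silent"
    elif aa_new == "*":
        category = "nonsense"
    elif aa_old == "*":
        category = "stop_lost"
    else:
        category = "missense"
    return Consequence(
        category=category,
        gene=gene.gene,
        codon_change=f"{codon}>{new_codon}",
        aa_change=f"{aa_old}{codon_i + 1}{aa_new}",
    )


def annotate_consequence(
    ref: MtReference,
    annotation: Iterable[GeneAnnotation],
    position: int,
    ref_allele: str,
    alt_allele: str,
) -> list[Consequence]:
    """Consequences of a variant in every containing feature.

    Substitutions in protein features are read through the gene's coding
    strand and translated with the vertebrate mitochondrial code.  Indels in
    protein features are classified as frameshift or inframe_indel by the
    length difference of the alleles.  A variant inside several overlapping
    features yields one consequence per feature; downstream analyses use the
    most severe (see :func:`classify_variant`).
    """
    n = len(ref)
    is_indel = len(ref_allele) != len(alt_allele)
    if not is_indel and ref.base(position) != ref_allele.upper():
        raise ValueError(
            f"reference allele mismatch at {position}: "
            f"expected {ref.base(position)}, got {ref_allele}"
        )
    out: list[Consequence] = []
    for feat in annotation:
        if not feat.contains(position, n):
            continue
        if feat.feature == "protein":
            if is_indel:
                shift = abs(len(ref_allele) - len(alt_allele)) % 3
                cat = "frameshift" if shift else "inframe_indel"
                out.append(Consequence(category=cat, gene=feat.gene))
            else:
                out.append(_protein_consequence(ref, feat, position, ref_allele, alt_allele))
        elif feat.feature == "tRNA":
            out.append(
                Consequence(
                    category="tRNA",
                    gene=feat.gene,
                    anticodon_hit=feat.in_anticodon(position, n),
                )
            )
        elif feat.feature == "rRNA":
            out.append(Consequence(category="rRNA", gene=feat.gene))
        else:  # dloop / intergenic features
            out.append(Consequence(category="intergenic", gene=feat.gene))
    if not out:
        out.append(Consequence(category="intergenic"))
    return out


def classify_variant(
    ref: MtReference,
    annotation: Iterable[GeneAnnotation],
    position: int,
    ref_allele: str,
    alt_allele: str,
) -> Consequence:
    """Most severe consequence of a variant over all containing features."""
    return min(
        annotate_consequence(ref, annotation, position, ref_allele, alt_allele),
        key=lambda c: c.severity,
    )


def enumerate_protein_changes(
    ref: MtReference, gene: GeneAnnotation
) -> Iterator[tuple[int, str, str, Consequence]]:
    """Yield (position, ref_allele, alt_allele, consequence) for every single
    base change in a protein feature, in frame."""
    n = len(ref)
    for position in gene.positions(n):
        if gene.cds_index(position, n) is None:
            continue
        b = ref.base(position)
        for alt in NUCLEOTIDES:
            if alt == b:
                continue
            yield position, b, alt, _protein_consequence(ref, gene, position, b, alt)
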