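"""Long-term sequence evolution under the mtDNA mutational signature.

A sequence evolved long enough under a fixed context-dependent substitution
process loses its hypermutable trinucleotides and converges to a stationary
composition.  Comparing that stationary state with the real mitochondrial
genome asks whether the somatic mutational signature alone can explain the
genome's base and codon content - either unconstrained, or constrained to
synonymous changes so that the encoded proteome is preserved
(mutation-selection equilibrium).

The simulator applies, per generation, a Poisson number of single-base
substitution events; each event picks a site with probability proportional to
its current context-dependent rate (rejection sampling, so only the three
sites whose context changed need updating per substitution) and an
alternative allele proportional to the class rates.  Under the synonymous
constraint, proposals that alter any protein's amino-acid sequence are
rejected.  Evolution stops when the total-variation distance between 3-mer
compositions sampled a window apart falls below a tolerance, or at a
generation cap.

Codon-usage skew statistics quantify the footprint of the same process in
real genomes: at third codon positions, T>C skew = (N_C - N_T)/(N_C + N_T)
and G>A skew = (N_A - N_G)/(N_A + N_G), with synonymous codon-pair ratios
(NNA:NNG, NNT:NNC) per codon family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import (
    GeneAnnotation,
    MtReference,
    NUCLEOTIDES,
    complement,
    translate_codon,
)

__all__ = [
    "EvolutionRun",
    "SkewReport",
    "evolve_sequence",
    "composition_correlation",
    "codon_skew",
    "kmer_frequencies",
    "codon_frequencies",
    "rate_lookup_tables",
]

_BASE_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}


def rate_lookup_tables(rates: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Compile a 192-class rate table into per-L-context lookup arrays.

    Returns ``(per_alt, total)`` where ``per_alt[c64, a]`` is the rate of the
    L-strand trinucleotide context with code ``c64`` mutating its central
    base to allele ``a`` and ``total[c64]`` the summed rate.  The class of a
    change is determined by its pyrimidine-strand representation, so both
    orientations are folded in here.
    """
    per_alt = np.zeros((64, 4))
    for i, ctx in enumerate("".join(t) for t in itertools.product(NUCLEOTIDES, repeat=3)):
        b = ctx[1]
        for alt in NUCLEOTIDES:
            if alt == b:
                continue
            if b in "CT":
                key = (f"{b}>{alt}", "L", ctx)
            else:
                rc = complement(ctx[2]) + complement(ctx[1]) + complement(ctx[0])
                key = (f"{complement(b)}>{complement(alt)}", "H", rc)
            per_alt[i, _BASE_INDEX[alt]] = float(rates.loc[key])
    return per_alt, per_alt.sum(axis=1)


def _context_codes(seq: np.ndarray) -> np.ndarray:
    """Code of the circular trinucleotide context at every site (base-4)."""
    left = np.roll(seq, 1)
    right = np.roll(seq, -1)
    return left * 16 + seq * 4 + right


@dataclass
class EvolutionRun:
    """Record of one sequence-evolution simulation."""

    initial_sequence: str
    final_sequence: str
    generations: int
    snapshots: list[tuple[int, np.ndarray]]  # (generation, 3-mer frequency vector)
    n_substitutions: int
    n_rejected: int
    constraint: str
    converged: bool
    seed: Optional[int]


def _trimer_freq(seq: np.ndarray) -> np.ndarray:
    codes = _context_codes(seq)
    return np.bincount(codes, minlength=64) / codes.size


def evolve_sequence(
    start: str | MtReference,
    rates: pd.Series,
    constraint: str = "none",
    annotation: Optional[Sequence[GeneAnnotation]] = None,
    events_per_generation: float = 10.0,
    max_generations: int = 200_000,
    stationarity_tol: float = 1e-3,
    snapshot_window: int = 100,
    seed: Optional[int] = None,
) -> EvolutionRun:
    """Evolve a circular sequence under a 192-class substitution process.

    ``start`` is a sequence string or reference.  ``rates`` is the 192-class
    strand-resolved table (relative scale; only ratios matter).  Under
    ``constraint='synonymous_only'`` (requires ``annotation``) proposals that
    change any protein feature's translation are rejected.  Stops when the
    total-variation distance between 3-mer compositions ``snapshot_window``
    generations apart drops below ``stationarity_tol``, or at
    ``max_generations``.
    """
    if constraint not in ("none", "synonymous_only"):
        raise ValueError("constraint must be 'none' or 'synonymous_only'")
    if constraint == "synonymous_only" and not annotation:
        raise ValueError("synonymous_only constraint requires an annotation")
    seq_str = start.sequence if isinstance(start, MtReference) else str(start).upper()
    seq = np.array([_BASE_INDEX[b] for b in seq_str], dtype=np.int8)
    n = seq.size
    per_alt, total = rate_lookup_tables(rates)

    if total.max() == 0:
        freq = _trimer_freq(seq)
        return EvolutionRun(seq_str, seq_str, 0, [(0, freq)], 0, 0, constraint, True, seed)

    protein_feats = [f for f in (annotation or []) if f.feature == "protein"]
    guard = _SynonymyGuard(protein_feats, seq_str, n) if constraint == "synonymous_only" else None

    rng = np.random.default_rng(seed)
    codes = _context_codes(seq)
    site_rate = total[codes]
    max_rate = total.max()

    snapshots = [(0, _trimer_freq(seq))]
    n_subs = n_rej = 0
    converged = False
    gen = 0
    while gen < max_generations:
        gen += 1
        total_rate = site_rate.sum()
        if total_rate <= 0:  # absorbing state: nothing left to mutate
            snapshots.append((gen, _trimer_freq(seq)))
            converged = True
            break
        # rejection sampling is O(1) per event while a fair fraction of sites
        # is mutable; fall back to exact categorical sampling once rare
        use_rejection = total_rate > 0.02 * n * max_rate
        for _ in range(rng.poisson(events_per_generation)):
            if use_rejection:
                while True:
                    pos = int(rng.integers(n))
                    if rng.random() * max_rate < site_rate[pos]:
                        break
            else:
                total_rate = site_rate.sum()
                if total_rate <= 0:
                    break
                pos = int(rng.choice(n, p=site_rate / total_rate))
            probs = per_alt[codes[pos]]
            tot = probs.sum()
            if tot == 0:
                continue
            alt = int(rng.choice(4, p=probs / tot))
            if guard is not None and not guard.is_synonymous(pos, alt):
                n_rej += 1
                continue
            seq[pos] = alt
            if guard is not None:
                guard.commit(pos, alt)
            n_subs += 1
            for p in ((pos - 1) % n, pos, (pos + 1) % n):
                codes[p] = seq[(p - 1) % n] * 16 + seq[p] * 4 + seq[(p + 1) % n]
                site_rate[p] = total[codes[p]]
        if gen % snapshot_window == 0:
            snapshots.append((gen, _trimer_freq(seq)))
            # Compare block-averaged compositions (last 5 snapshots vs the 5
            # before) to suppress finite-length sampling noise, which floors
            # the single-snapshot TV at about sqrt(64 / L).
            if len(snapshots) >= 10:
                recent = np.mean([f for _, f in snapshots[-5:]], axis=0)
                older = np.mean([f for _, f in snapshots[-10:-5]], axis=0)
                if 0.5 * np.abs(recent - older).sum() < stationarity_tol:
                    converged = True
                    break

    final = "".join(NUCLEOTIDES[i] for i in seq)
    return EvolutionRun(
        initial_sequence=seq_str,
        final_sequence=final,
        generations=gen,
        snapshots=snapshots,
        n_substitutions=n_subs,
        n_rejected=n_rej,
        constraint=constraint,
        converged=converged,
        seed=seed,
    )


class _SynonymyGuard:
    """Fast synonymous-change check against a set of protein features."""

    def __init__(self, features: Sequence[GeneAnnotation], seq: str, genome_length: int):
        self.n = genome_length
        self.seq = list(seq)
        # map position (0-based) -> list of (feature, cds index)
        self.hits: dict[int, list[tuple[GeneAnnotation, int]]] = {}
        for feat in features:
            for pos in feat.positions(genome_length):
                idx = feat.cds_index(pos, genome_length)
                if idx is not None:
                    self.hits.setdefault(pos - 1, []).append((feat, idx))

    def _codon(self, feat: GeneAnnotation, idx: int, override: Optional[tuple[int, str]] = None) -> str:
        codon_i = idx // 3
        bases = []
        for k in range(3):
            cds_idx = codon_i * 3 + k + feat.frame_offset
            if feat.coding_strand == "L":
                pos0 = (feat.start - 1 + cds_idx) % self.n
                b = self.seq[pos0]
                if override and pos0 == override[0]:
                    b = override[1]
            else:
                pos0 = (feat.end - 1 - cds_idx) % self.n
                b = self.seq[pos0]
                if override and pos0 == override[0]:
                    b = override[1]
                b = complement(b)
            bases.append(b)
        return "".join(bases)

    def is_synonymous(self, pos0: int, alt_idx: int) -> bool:
        alt = NUCLEOTIDES[alt_idx]
        for feat, idx in self.hits.get(pos0, []):
            old = self._codon(feat, idx)
            new = self._codon(feat, idx, override=(pos0, alt))
            try:
                if translate_codon(old) != translate_codon(new):
                    return False
            except ValueError:
                return False
        return True

    def commit(self, pos0: int, alt_idx: int) -> None:
        self.seq[pos0] = NUCLEOTIDES[alt_idx]


def kmer_frequencies(seq: str, k: int = 3) -> np.ndarray:
    """Circular k-mer frequency vector (lexicographic order) on the L strand."""
    if len(seq) < k:
        raise ValueError("sequence shorter than k")
    arr = np.array([_BASE_INDEX[b] for b in seq.upper()], dtype=np.int64)
    codes = np.zeros(arr.size, dtype=np.int64)
    for off in range(k):
        codes = codes * 4 + np.roll(arr, -off)
    return np.bincount(codes, minlength=4**k) / arr.size


def codon_frequencies(
    ref: MtReference | str, annotation: Sequence[GeneAnnotation]
) -> np.ndarray:
    """Frequency of each of the 64 codons over annotated protein features,
    read on each gene's coding strand."""
    if isinstance(ref, str):
        ref = MtReference(sequence=ref)
    counts = np.zeros(64)
    for feat in annotation:
        if feat.feature != "protein":
            continue
        sense = feat.sense_sequence(ref)[feat.frame_offset :]
        for i in range(0, len(sense) - 2, 3):
            codon = sense[i : i + 3]
            code = _BASE_INDEX[codon[0]] * 16 + _BASE_INDEX[codon[1]] * 4 + _BASE_INDEX[codon[2]]
            counts[code] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no codons found in the annotation")
    return counts / total


def composition_correlation(
    seq_a: str,
    seq_b: str,
    k: int = 3,
    mode: str = "kmer",
    annotation_a: Optional[Sequence[GeneAnnotation]] = None,
    annotation_b: Optional[Sequence[GeneAnnotation]] = None,
) -> float:
    """Pearson correlation between composition vectors of two sequences.

    ``mode='kmer'`` compares circular L-strand k-mer frequencies;
    ``mode='codon'`` compares codon frequencies over annotated protein
    features.
    """
    if mode == "kmer":
        fa, fb = kmer_frequencies(seq_a, k), kmer_frequencies(seq_b, k)
    elif mode == "codon":
        if annotation_a is None or annotation_b is None:
            raise ValueError("codon mode requires annotations for both sequences")
        fa = codon_frequencies(seq_a, annotation_a)
        fb = codon_frequencies(seq_b, annotation_b)
    else:
        raise ValueError("mode must be 'kmer' or 'codon'")
    if np.allclose(fa, fa[0]) or np.allclose(fb, fb[0]):
        raise ValueError("constant frequency vector: correlation undefined")
    return float(stats.pearsonr(fa, fb).statistic)


@dataclass
class SkewReport:
    """Third-codon-position base counts and skews per gene set."""

    counts: dict[str, int]  # N_A, N_C, N_G, N_T
    tc_skew: float
    ga_skew: float
    synonymous_pair_ratios: pd.DataFrame  # per codon family: NNA:NNG, NNT:NNC


def codon_skew(
    ref: MtReference,
    annotation: Sequence[GeneAnnotation],
    gene_set: Optional[Sequence[str]] = None,
) -> SkewReport:
    """Codon-usage skew over a set of protein genes.

    Counts third-position bases on the coding strand of each gene and
    computes T>C skew = (N_C - N_T)/(N_C + N_T) and G>A skew =
    (N_A - N_G)/(N_A + N_G), plus the frequency ratios of synonymous codon
    pairs NNA:NNG and NNT:NNC per codon-family prefix.  A genome shaped by
    sustained C_H>T_H (= G_L>A_L) and T_L>C_L pressure shows positive skews
    and strongly depleted NNG/NNT codons in L-strand genes.
    """
    feats = [f for f in annotation if f.feature == "protein"]
    if gene_set is not None:
        by_name = {f.gene: f for f in feats}
        missing = [g for g in gene_set if g not in by_name]
        if missing:
            raise ValueError(f"not protein genes in the annotation: {missing}")
        feats = [by_name[g] for g in gene_set]
    counts = {b: 0 for b in NUCLEOTIDES}
    family: dict[str, dict[str, int]] = {}
    for feat in feats:
        sense = feat.sense_sequence(ref)[feat.frame_offset :]
        for i in range(0, len(sense) - 2, 3):
            codon = sense[i : i + 3]
            counts[codon[2]] += 1
            family.setdefault(codon[:2], {b: 0 for b in NUCLEOTIDES})[codon[2]] += 1
    nc, nt = counts["C"], counts["T"]
    na, ng = counts["A"], counts["G"]
    tc = (nc - nt) / (nc + nt) if nc + nt else 0.0
    ga = (na - ng) / (na + ng) if na + ng else 0.0

    rows = []
    for prefix, c in sorted(family.items()):
        def _syn_ratio(x: str, y: str) -> float:
            try:
                same = translate_codon(prefix + x) == translate_codon(prefix + y)
            except ValueError:
                return np.nan
            if not same:
                return np.nan
            return c[x] / c[y] if c[y] else np.inf
        rows.append((prefix, c["A"], c["G"], c["T"], c["C"], _syn_ratio("A", "G"), _syn_ratio("T", "C")))
    fam = pd.DataFrame(
        rows, columns=["family", "NNA", "NNG", "NNT", "NNC", "ratio_A_G", "ratio_T_C"]
    ).set_index("family")
    return SkewReport(
        counts={f"N_{b}": counts[b] for b in NUCLEOTIDES},
        tc_skew=tc,
        ga_skew=ga,
        synonymous_pair_ratios=fam,
    )
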