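"""Context-dependent Poisson dN/dS inference and related selection tests.

The mutational process of mtDNA is strongly strand-asymmetric and context
dependent, so a naive missense/silent count ratio is confounded by sequence
composition.  Here the number of mutations of each strand-resolved class k
(12 classes, or 192 with the 5'/3' context) and consequence c is modelled as
a Poisson count

    N_syn,k ~ Poisson(r_k * L_syn,k)
    N_mis,k ~ Poisson(r_k * w_mis * L_mis,k)
    N_non,k ~ Poisson(r_k * w_non * L_non,k)

where L_c,k are opportunity counts (number of genomic single-base changes of
class k with consequence c, enumerated over all protein codons under the
vertebrate mitochondrial code) and the selection coefficients w are shared
across classes.  Rates and w are estimated by maximum likelihood (the rates
have a closed-form profile given w; w is optimised by coordinate-wise
hill-climbing on the profile log-likelihood), deviations from neutrality are
tested with likelihood-ratio tests, and confidence intervals come from the
profile likelihood.

Also here: the tRNA anticodon depletion test, mutation recurrence analyses
against uniform or signature-weighted null models, and VAF comparisons
between consequence groups (truncating mutations under negative selection
remain heteroplasmic, depressing their VAFs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .genome_model import (
    GeneAnnotation,
    MtReference,
    classify_variant,
    enumerate_protein_changes,
)
from .signature import class_index, classify_substitution

__all__ = [
    "OpportunityTable",
    "SelectionFit",
    "opportunity_counts",
    "observed_counts",
    "fit_dnds",
    "gene_dnds",
    "trna_anticodon_test",
    "recurrence_analysis",
    "recurrence_resample",
    "vaf_selection_test",
]

CONSEQUENCE_COLS = ("syn", "mis", "non", "stoploss")
_CATEGORY_TO_COL = {
    "silent": "syn",
    "missense": "mis",
    "nonsense": "non",
    "stop_lost": "stoploss",
}


@dataclass
class OpportunityTable:
    """Per-class counts of sites mutable to each consequence.

    ``table`` is indexed by substitution class (12- or 192-class) with
    columns L_syn, L_mis, L_non, L_stoploss.
    """

    table: pd.DataFrame
    model: int  # 12 or 192

    def totals(self) -> pd.Series:
        return self.table.sum(axis=1)


def _class_key(ref: MtReference, position: int, alt: str, model: int):
    sub, strand, ctx = classify_substitution(ref, position, alt)
    return (sub, strand, ctx) if model == 192 else (sub, strand)


def opportunity_counts(
    ref: MtReference,
    annotation: Sequence[GeneAnnotation],
    model: int = 192,
) -> OpportunityTable:
    """Enumerate and classify every single-base change in every protein codon.

    Each protein feature contributes 3 changes per in-frame site; a site in
    overlapping genes is counted once per gene.  Totals per class therefore
    equal 3 x (summed coding length).
    """
    if model not in (12, 192):
        raise ValueError("model must be 12 or 192")
    idx = class_index(model)
    tbl = pd.DataFrame(0, index=idx, columns=[f"L_{c}" for c in CONSEQUENCE_COLS])
    for feat in annotation:
        if feat.feature != "protein":
            continue
        if (feat.length(len(ref)) - feat.frame_offset) % 3 != 0:
            raise ValueError(f"protein feature {feat.gene} violates reading frame")
        for position, _refb, alt, cons in enumerate_protein_changes(ref, feat):
            col = _CATEGORY_TO_COL.get(cons.category)
            if col is None:
                continue
            tbl.loc[_class_key(ref, position, alt, model), f"L_{col}"] += 1
    return OpportunityTable(table=tbl, model=model)


def observed_counts(
    variants: pd.DataFrame,
    ref: MtReference,
    annotation: Sequence[GeneAnnotation],
    model: int = 192,
) -> pd.DataFrame:
    """Class-resolved observed mutation counts split by consequence.

    ``variants`` needs columns position, ref, alt; only single-base
    substitutions inside protein features contribute.  Indexed like the
    matching :class:`OpportunityTable`.
    """
    idx = class_index(model)
    out = pd.DataFrame(0, index=idx, columns=[f"N_{c}" for c in CONSEQUENCE_COLS])
    for row in variants.itertuples(index=False):
        if len(str(row.ref)) != 1 or len(str(row.alt)) != 1:
            continue
        cons = classify_variant(ref, annotation, int(row.position), str(row.ref), str(row.alt))
        col = _CATEGORY_TO_COL.get(cons.category)
        if col is None:
            continue
        out.loc[_class_key(ref, int(row.position), str(row.alt), model), f"N_{col}"] += 1
    return out


@dataclass
class SelectionFit:
    """Maximum-likelihood selection fit."""

    rates: pd.Series
    w_mis: Optional[float]
    w_non: Optional[float]
    loglik: float
    lrt_stat: float
    lrt_p: float
    ci_w_mis: Optional[tuple[float, float]]
    ci_w_non: Optional[tuple[float, float]]
    model: int


def _poisson_ll(n: np.ndarray, lam: np.ndarray) -> float:
    n = np.asarray(n, float)
    lam = np.asarray(lam, float)
    if ((lam == 0) & (n > 0)).any():
        return -np.inf
    ok = lam > 0
    return float(np.sum(n[ok] * np.log(lam[ok]) - lam[ok] - special.gammaln(n[ok] + 1)) - lam[~ok].sum())


class _DndsModel:
    """Profile log-likelihood machinery for the Poisson dN/dS model."""

    def __init__(self, observed, opp: OpportunityTable, targets, fold_stoploss=True):
        self.targets = tuple(targets)
        L = opp.table.copy()
        N = observed.copy()
        if fold_stoploss:
            L["L_mis"] = L["L_mis"] + L["L_stoploss"]
            N["N_mis"] = N["N_mis"] + N["N_stoploss"]
        cols = ["syn"] + [t[2:] for t in self.targets]  # 'w_mis' -> 'mis'
        self.cols = cols
        self.L = np.column_stack([L[f"L_{c}"].to_numpy(float) for c in cols])
        self.N = np.column_stack([N[f"N_{c}"].to_numpy(float) for c in cols])
        if self.N[:, 0].sum() == 0:
            raise ValueError("no synonymous observations: selection parameters unidentifiable")
        has_obs = self.N.sum(axis=1) > 0
        if ((self.L.sum(axis=1) == 0) & has_obs).any():
            raise ValueError("observed mutations in classes with zero opportunity")

    def profile_rates(self, w: np.ndarray) -> np.ndarray:
        wvec = np.concatenate([[1.0], w])
        denom = self.L @ wvec
        num = self.N.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, num / denom, 0.0)
        return r

    def loglik(self, w: np.ndarray) -> float:
        wvec = np.concatenate([[1.0], np.asarray(w, float)])
        r = self.profile_rates(np.asarray(w, float))
        lam = r[:, None] * self.L * wvec[None, :]
        return _poisson_ll(self.N, lam)


def _maximise_profile(model: _DndsModel, tol: float = 1e-8) -> tuple[np.ndarray, float]:
    """Coordinate-wise hill climbing on log-selection-coefficients.

    Each selection parameter is optimised in turn on the profile likelihood
    (rates profiled in closed form) until the log-likelihood improves by less
    than ``tol``; a deterministic multistart over a small grid of starting
    values guards against ridge-shaped likelihoods.
    """
    k = len(model.targets)
    best_w, best_ll = np.ones(k), -np.inf
    for start in (1.0, 0.25, 0.5, 2.0, 4.0):
        w = np.full(k, start)
        ll = model.loglik(w)
        for _ in range(200):
            improved = ll
            for j in range(k):
                def neg(logw, j=j):
                    wj = w.copy()
                    wj[j] = np.exp(logw)
                    return -model.loglik(wj)

                res = optimize.minimize_scalar(neg, bounds=(-9.0, 9.0), method="bounded",
                                               options={"xatol": 1e-10})
                w[j] = np.exp(res.x)
                ll = -res.fun
            if ll - improved < tol:
                break
        if ll > best_ll:
            best_w, best_ll = w.copy(), ll
    return best_w, best_ll


def _profile_ci(model: _DndsModel, w_hat: np.ndarray, ll_hat: float, j: int,
                alpha: float = 0.05) -> tuple[float, float]:
    """Profile-likelihood CI for selection parameter ``j`` (others re-optimised)."""
    crit = stats.chi2.ppf(1 - alpha, 1) / 2.0

    def profile_ll(wj: float) -> float:
        if len(w_hat) == 1:
            return model.loglik(np.array([wj]))
        # re-optimise the other coordinate(s)
        others = [i for i in range(len(w_hat)) if i != j]
        w = w_hat.copy()
        w[j] = wj

        def neg(logw):
            for i, lw in zip(others, np.atleast_1d(logw)):
                w[i] = np.exp(lw)
            return -model.loglik(w)

        res = optimize.minimize_scalar(neg, bounds=(-9.0, 9.0), method="bounded")
        return -res.fun

    def deficit(logw: float) -> float:
        return profile_ll(float(np.exp(logw))) - (ll_hat - crit)

    lw_hat = float(np.log(w_hat[j]))
    lo = lw_hat
    step = 0.25
    while deficit(lo) > 0 and lo > -9:
        lo -= step
    lower = np.exp(optimize.brentq(deficit, lo, lw_hat)) if lo > -9 else 0.0
    hi = lw_hat
    while deficit(hi) > 0 and hi < 9:
        hi += step
    upper = np.exp(optimize.brentq(deficit, lw_hat, hi)) if hi < 9 else np.inf
    return float(lower), float(upper)


def fit_dnds(
    observed: pd.DataFrame,
    opp: OpportunityTable,
    targets: Iterable[str] = ("w_mis",),
    fold_stoploss: bool = True,
    compute_ci: bool = True,
) -> SelectionFit:
    """Maximum-likelihood fit of class rates and selection coefficients.

    ``targets`` selects the fitted coefficients ('w_mis' and/or 'w_non');
    consequence classes without a fitted coefficient (other than synonymous)
    are excluded from the likelihood.  Stop-loss sites are folded into the
    missense class by default.  The LRT compares the fit against all targets
    fixed at 1 (chi-square, one df per coefficient).
    """
    targets = tuple(targets)
    if not targets or any(t not in ("w_mis", "w_non") for t in targets):
        raise ValueError("targets must be a non-empty subset of {'w_mis', 'w_non'}")
    model = _DndsModel(observed, opp, targets, fold_stoploss=fold_stoploss)
    w_hat, ll_hat = _maximise_profile(model)
    ll_null = model.loglik(np.ones(len(targets)))
    lrt = max(2.0 * (ll_hat - ll_null), 0.0)
    p = float(stats.chi2.sf(lrt, df=len(targets)))

    cis: dict[str, tuple[float, float]] = {}
    if compute_ci:
        for j, t in enumerate(targets):
            cis[t] = _profile_ci(model, w_hat, ll_hat, j)
    w_map = dict(zip(targets, w_hat))
    rates = pd.Series(model.profile_rates(w_hat), index=opp.table.index, name="rate")
    return SelectionFit(
        rates=rates,
        w_mis=w_map.get("w_mis"),
        w_non=w_map.get("w_non"),
        loglik=ll_hat,
        lrt_stat=lrt,
        lrt_p=p,
        ci_w_mis=cis.get("w_mis"),
        ci_w_non=cis.get("w_non"),
        model=opp.model,
    )


def gene_dnds(
    variants: pd.DataFrame,
    ref: MtReference,
    annotation: Sequence[GeneAnnotation],
    model: int = 12,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-gene dN/dS fits with Benjamini-Hochberg correction.

    Genes with no synonymous observation are reported with NaN estimates.
    """
    rows = []
    n = len(ref)
    for feat in annotation:
        if feat.feature != "protein":
            continue
        sub = variants[
            variants["position"].map(lambda p: feat.contains(int(p), n))
        ]
        opp = opportunity_counts(ref, [feat], model=model)
        try:
            obs = observed_counts(sub, ref, [feat], model=model)
            fit = fit_dnds(obs, opp, targets=("w_mis",), compute_ci=False)
            rows.append((feat.gene, len(sub), fit.w_mis, fit.lrt_p))
        except ValueError:
            rows.append((feat.gene, len(sub), np.nan, np.nan))
    out = pd.DataFrame(rows, columns=["gene", "n_variants", "w_mis", "p"]).set_index("gene")
    mask = out["p"].notna()
    out["q"] = np.nan
    if mask.any():
        out.loc[mask, "q"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    out["significant"] = out["q"] < fdr
    return out


def trna_anticodon_test(
    variants: pd.DataFrame,
    ref: MtReference,
    annotation: Sequence[GeneAnnotation],
    rates: pd.Series,
) -> tuple[int, float, float]:
    """Depletion test for substitutions in tRNA anticodon triplets.

    The expected anticodon hit count is the total number of tRNA
    substitutions redistributed over tRNA positions in proportion to their
    signature-weighted mutability (sum over alternative alleles of the
    192-class rate).  The p-value is the lower Poisson tail
    P(X <= observed | expected) - the probability of seeing this few or fewer
    anticodon hits under the mutational process alone.
    """
    n = len(ref)
    trnas = [f for f in annotation if f.feature == "tRNA"]
    if any(f.anticodon_span is None for f in trnas):
        raise ValueError("tRNA features must carry anticodon spans")
    weight_all = 0.0
    weight_anti = 0.0
    for feat in trnas:
        for pos in feat.positions(n):
            b = ref.base(pos)
            w = 0.0
            for alt in "ACGT":
                if alt == b:
                    continue
                w += float(rates.loc[classify_substitution(ref, pos, alt)])
            weight_all += w
            if feat.in_anticodon(pos, n):
                weight_anti += w
    in_trna = variants["position"].map(
        lambda p: any(f.contains(int(p), n) for f in trnas)
    )
    total = int(in_trna.sum())
    observed = int(
        variants.loc[in_trna, "position"]
        .map(lambda p: any(f.in_anticodon(int(p), n) for f in trnas))
        .sum()
    )
    if total == 0:
        return 0, 0.0, 1.0
    expected = total * weight_anti / weight_all if weight_all else 0.0
    p = float(stats.poisson.cdf(observed, expected)) if expected > 0 else 1.0
    return observed, expected, p


def _recurrence_count(positions: np.ndarray, samples: Optional[np.ndarray] = None) -> tuple[int, int]:
    """(number of recurrent mutations, number of recurrent positions).

    A mutation is recurrent when its position carries mutations in more than
    one sample (every sample distinct when ``samples`` is None).
    """
    if samples is None:
        uniq, counts = np.unique(positions, return_counts=True)
        rec = counts > 1
        return int(counts[rec].sum()), int(rec.sum())
    df = pd.DataFrame({"position": positions, "sample": samples}).drop_duplicates()
    counts = df.groupby("position").size()
    rec = counts[counts > 1]
    return int(rec.sum()), int(len(rec))


def recurrence_analysis(
    variants: pd.DataFrame,
    ref: MtReference,
    null_model: str = "uniform",
    n_sims: int = 1000,
    seed: Optional[int] = None,
    rates: Optional[pd.Series] = None,
) -> dict:
    """Observed vs chance recurrence of mutations across samples.

    Recurrent mutations are variants at positions mutated in more than one
    sample.  The null redistributes the same number of mutations over the
    genome, either uniformly or proportional to signature-weighted site
    mutability (``rates``: 192-class table), and the enrichment fold is
    observed / mean(null) with an empirical p-value.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    positions = variants["position"].to_numpy(int)
    samples = variants["sample"].to_numpy() if "sample" in variants else None
    n_rec, n_pos = _recurrence_count(positions, samples)
    n_total = len(positions)
    L = len(ref)
    if null_model == "uniform":
        probs = None
    elif null_model == "signature":
        if rates is None:
            raise ValueError("signature null model requires a rate table")
        w = np.zeros(L)
        for pos in range(1, L + 1):
            b = ref.base(pos)
            w[pos - 1] = sum(
                float(rates.loc[classify_substitution(ref, pos, alt)])
                for alt in "ACGT" if alt != b
            )
        probs = w / w.sum()
    else:
        raise ValueError("null_model must be 'uniform' or 'signature'")

    rng = np.random.default_rng(seed)
    null_rec = np.empty(n_sims)
    for i in range(n_sims):
        placed = rng.choice(L, size=n_total, replace=True, p=probs)
        null_rec[i], _ = _recurrence_count(placed)
    mean_null = float(null_rec.mean())
    fold = n_rec / mean_null if mean_null > 0 else (0.0 if n_rec == 0 else np.inf)
    p = float((1 + np.sum(null_rec >= n_rec)) / (n_sims + 1))
    return {
        "n_recurrent": n_rec,
        "n_positions": n_pos,
        "n_total": n_total,
        "null_mean": mean_null,
        "fold_enrichment": float(fold),
        "p": p,
    }


def recurrence_resample(
    variants: pd.DataFrame,
    groups: dict[str, pd.DataFrame],
    n_draw: int = 100,
    n_iter: int = 300,
    seed: Optional[int] = None,
) -> dict:
    """Compare recurrence between consequence groups by equal-size resampling.

    From each group, ``n_draw`` substitutions are repeatedly drawn without
    replacement and the recurrent mutations within the draw counted; a
    one-way ANOVA over the per-iteration counts tests for differences between
    the groups.
    """
    rng = np.random.default_rng(seed)
    per_group: dict[str, np.ndarray] = {}
    for name, df in groups.items():
        if len(df) < n_draw:
            raise ValueError(f"group {name!r} smaller than n_draw={n_draw}")
        positions = df["position"].to_numpy(int)
        samples = df["sample"].to_numpy() if "sample" in df else None
        counts = np.empty(n_iter, dtype=int)
        for i in range(n_iter):
            idx = rng.choice(len(positions), size=n_draw, replace=False)
            counts[i], _ = _recurrence_count(
                positions[idx], samples[idx] if samples is not None else None
            )
        per_group[name] = counts
    stat, p = stats.f_oneway(*per_group.values())
    return {
        "per_group_counts": per_group,
        "group_means": {k: float(v.mean()) for k, v in per_group.items()},
        "anova_stat": float(stat),
        "anova_p": float(p),
    }


def vaf_selection_test(groups: dict[str, Sequence[float]]) -> dict:
    """Mean VAF per consequence group and pairwise rank-sum tests.

    Negative selection on truncating mutations holds them back from
    homoplasmy, which shows as depressed VAFs relative to missense/silent
    groups.  Groups with fewer than 2 observations are excluded with a
    warning.  Tests are two-sided Wilcoxon rank-sum.
    """
    keep: dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        arr = np.asarray(list(vals), float)
        if arr.size < 2:
            warnings.warn(f"group {name!r} has fewer than 2 VAFs; excluded", stacklevel=2)
            continue
        keep[name] = arr
    if len(keep) < 2:
        raise ValueError("need at least 2 groups with >= 2 variants each")
    means = {k: float(v.mean()) for k, v in keep.items()}
    pvals: dict[tuple[str, str], float] = {}
    names = list(keep)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if np.array_equal(keep[a], keep[b]):
                pvals[(a, b)] = 1.0
            else:
                pvals[(a, b)] = float(stats.ranksums(keep[a], keep[b]).pvalue)
    return {"means": means, "pairwise_p": pvals}
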