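"""APOBEC-signature enrichment statistics.

The APOBEC3 cytidine deaminases preferentially mutate cytosine in a TCW
trinucleotide (W = A or T), producing C>T and C>G substitutions at TCW
centers (equivalently G>A / G>C at WGA on the opposite strand). This module
implements the per-sample enrichment analysis:

1. each substitution is classified APOBEC-signature or not by its
   trinucleotide context;
2. TCW-motif and cytosine availability are counted in the reference windows
   around the sample's mutations (both strands combined);
3. a Fisher exact test on the 2x2 table
   [[n_apobec, n_other], [n_tcw, n_c]] asks whether the sample carries more
   TCW-context mutations than its local sequence composition would give
   under context-blind mutagenesis;
4. Benjamini-Hochberg adjustment across the cohort; a sample is called
   APOBEC-mutated when q < 0.05 and odds ratio > 2 (strict);
5. for called samples, a conservative minimum estimate of APOBEC-induced
   mutations: the APOBEC-signature count in excess of the context-blind
   expectation; zero for uncalled samples.

96-channel trinucleotide spectra (pyrimidine-centric, COSMIC channel order)
are also computed here.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog_io import Mutation, MutationCatalog, ReferenceSequence

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Plus-strand trinucleotides whose center is an APOBEC target site:
#: TCW itself and its reverse complement WGA (center base G).
_TCW_PLUS = ("TCA", "TCT")
_WGA_PLUS = ("TGA", "AGA")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def classify_substitution(mutation: Mutation) -> bool:
    """True iff the substitution matches the APOBEC signature.

    Signature: C>T or C>G at a TCW center, or the strand-equivalent G>A or
    G>C at a WGA center. Mutations without a context, or with N in either
    immediate flank, are uncallable and return False.
    """
    tri = mutation.trinucleotide
    if tri is None or "N" in tri:
        return False
    five, ref, three = tri[0], mutation.ref, tri[2]
    if ref == "C":
        return mutation.alt in ("T", "G") and five == "T" and three in ("A", "T")
    if ref == "G":
        return mutation.alt in ("A", "C") and three == "A" and five in ("A", "T")
    return False


def is_callable(mutation: Mutation) -> bool:
    """Whether the mutation has a full non-N trinucleotide context."""
    tri = mutation.trinucleotide
    return tri is not None and "N" not in tri


@dataclass(frozen=True)
class ContextCounts:
    """TCW-motif and cytosine availability in a sample's context windows.

    ``n_tcw`` counts TCW occurrences on both strands (TCA/TCT plus TGA/AGA
    on the plus strand); ``n_c`` counts cytosines on both strands (C plus G
    bases). Both exclude the mutated position itself.
    """

    n_tcw: int
    n_c: int


def _window_counts(context: str, exclude_center: bool = True) -> tuple[int, int]:
    """Count (n_tcw, n_c) in one window string; center = mutated position."""
    center = len(context) // 2
    n_tcw = 0
    n_c = 0
    for i, base in enumerate(context):
        if exclude_center and i == center:
            continue
        if base in ("C", "G"):
            n_c += 1
            if 0 < i < len(context) - 1:
                tri = context[i - 1 : i + 2]
                if (base == "C" and tri in _TCW_PLUS) or (base == "G" and tri in _WGA_PLUS):
                    n_tcw += 1
    return n_tcw, n_c


def count_motifs_in_windows(
    mutations: Sequence[Mutation],
    collapse: bool = False,
    reference: ReferenceSequence | None = None,
    flank: int = 20,
) -> ContextCounts:
    """Count TCW motifs and C bases over a sample's context windows.

    By default windows are a multiset: a window is counted once per mutation
    and overlapping windows from nearby mutations contribute multiply. With
    ``collapse=True`` the genomic union of the windows is counted once
    (requires ``reference``). In both modes the mutated positions themselves
    are excluded, both as C/G bases and as motif centers.
    """
    if not collapse:
        n_tcw = n_c = 0
        for m in mutations:
            if m.context is None:
                raise ValueError(f"mutation at {m.chrom}:{m.pos} has no context attached")
            t, c = _window_counts(m.context)
            n_tcw += t
            n_c += c
        return ContextCounts(n_tcw, n_c)

    if reference is None:
        raise ValueError("collapse=True requires the reference sequence")
    mutated = {(m.chrom, m.pos) for m in mutations}
    intervals: dict[str, list[tuple[int, int]]] = {}
    for m in mutations:
        intervals.setdefault(m.chrom, []).append((m.pos - flank, m.pos + flank))
    n_tcw = n_c = 0
    for chrom, ivs in intervals.items():
        ivs.sort()
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            seq = reference.fetch(chrom, s, e)
            for i, base in enumerate(seq):
                pos = s + i
                if (chrom, pos) in mutated:
                    continue
                if base in ("C", "G"):
                    n_c += 1
                    if 0 < i < len(seq) - 1:
                        tri = seq[i - 1 : i + 2]
                        if (base == "C" and tri in _TCW_PLUS) or (base == "G" and tri in _WGA_PLUS):
                            n_tcw += 1
    return ContextCounts(n_tcw, n_c)


def fisher_enrichment_test(n_apobec: int, n_other: int, counts: ContextCounts) -> tuple[float, float]:
    """Two-sided Fisher exact test of mutation counts against context content.

    Returns ``(odds_ratio, p_value)`` for the table
    ``[[n_apobec, n_other], [n_tcw, n_c]]`` with the sample odds ratio
    ``(n_apobec * n_c) / (n_other * n_tcw)``; conventions: +inf when the
    denominator is zero with a nonzero numerator, 0 symmetrically, and an
    error when all four cells are zero.
    """
    a, b, c, d = n_apobec, n_other, counts.n_tcw, counts.n_c
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell in Fisher table")
    if a == b == c == d == 0:
        raise ValueError("all four Fisher cells are zero; odds ratio undefined")
    num, den = a * d, b * c
    if den == 0:
        odds = math.inf if num > 0 else math.nan
    else:
        odds = num / den
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds, float(p)


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


@dataclass
class EnrichmentResult:
    """Per-sample APOBEC enrichment call."""

    sample_id: str
    n_apobec: int
    n_other: int
    n_tcw: int
    n_c: int
    odds_ratio: float
    p_value: float
    q_value: float = math.nan
    is_apobec_mutated: bool = False
    min_estimate: float = 0.0
    n_uncallable: int = 0


def enrich_sample(
    sample_id: str,
    mutations: Sequence[Mutation],
    collapse: bool = False,
    reference: ReferenceSequence | None = None,
    flank: int = 20,
) -> EnrichmentResult:
    """Classify one sample's mutations and run the Fisher enrichment test."""
    n_apobec = sum(classify_substitution(m) for m in mutations)
    n_other = len(mutations) - n_apobec
    n_uncallable = sum(not is_callable(m) for m in mutations)
    counts = count_motifs_in_windows(mutations, collapse=collapse, reference=reference, flank=flank)
    odds, p = fisher_enrichment_test(n_apobec, n_other, counts)
    return EnrichmentResult(
        sample_id=sample_id,
        n_apobec=n_apobec,
        n_other=n_other,
        n_tcw=counts.n_tcw,
        n_c=counts.n_c,
        odds_ratio=odds,
        p_value=p,
        n_uncallable=n_uncallable,
    )


def minimum_apobec_estimate(
    result: EnrichmentResult, formula: str = "excess_over_context"
) -> float:
    """Minimum estimate of APOBEC-induced mutations for a classified sample.

    Zero for samples not called APOBEC-mutated. For called samples the
    default is the APOBEC-signature count in excess of the context-blind
    expectation, ``n_apobec - n_other * (n_tcw / n_c)``, floored at zero.
    ``formula="fraction_of_enrichment"`` instead scales the signature count
    by (1 - 1/odds_ratio).
    """
    if not result.is_apobec_mutated:
        return 0.0
    if result.n_c == 0:
        raise ValueError(f"sample {result.sample_id}: n_c == 0, context degenerate")
    if formula == "excess_over_context":
        est = result.n_apobec - result.n_other * (result.n_tcw / result.n_c)
    elif formula == "fraction_of_enrichment":
        est = result.n_apobec * (1.0 - 1.0 / result.odds_ratio) if result.odds_ratio > 0 else 0.0
    else:
        raise ValueError(f"unknown minimum-estimate formula {formula!r}")
    return float(min(max(est, 0.0), result.n_apobec))


def classify_cohort(
    results: Sequence[EnrichmentResult],
    alpha: float = 0.05,
    or_threshold: float = 2.0,
    min_estimate_formula: str = "excess_over_context",
) -> list[EnrichmentResult]:
    """Cohort-wide BH adjustment, classification, and minimum estimates.

    A sample is APOBEC-mutated iff q < alpha AND odds ratio > or_threshold,
    both strict. BH is applied across the whole cohort at once.
    """
    if not results:
        return []
    qs = benjamini_hochberg([r.p_value for r in results])
    out = []
    for r, q in zip(results, qs):
        called = q < alpha and r.odds_ratio > or_threshold
        r2 = replace(r, q_value=q, is_apobec_mutated=called)
        r2.min_estimate = minimum_apobec_estimate(r2, formula=min_estimate_formula)
        out.append(r2)
    return out


def enrich_catalog(
    catalog: MutationCatalog,
    alpha: float = 0.05,
    or_threshold: float = 2.0,
    collapse: bool = False,
    reference: ReferenceSequence | None = None,
    flank: int = 20,
    min_estimate_formula: str = "excess_over_context",
) -> pd.DataFrame:
    """Run the full enrichment analysis over every sample in a catalog."""
    results = [
        enrich_sample(sid, muts, collapse=collapse, reference=reference, flank=flank)
        for sid, muts in catalog.items()
    ]
    results = classify_cohort(results, alpha=alpha, or_threshold=or_threshold,
                              min_estimate_formula=min_estimate_formula)
    return results_to_frame(results)


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    cols = ["sample_id", "n_apobec", "n_other", "n_tcw", "n_c", "odds_ratio",
            "p_value", "q_value", "is_apobec_mutated", "min_estimate", "n_uncallable"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results], columns=cols)


# ---------------------------------------------------------------------------
# 96-channel trinucleotide spectrum

#: COSMIC channel order: substitution class (C>A, C>G, C>T, T>A, T>C, T>G)
#: major, then 5' base, then 3' base, each in A/C/G/T order.
SPECTRUM_CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{ref}>{alt}]{three}"
    for ref, alt in (("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G"))
    for five in "ACGT"
    for three in "ACGT"
)


def trinucleotide_spectrum(mutations: Iterable[Mutation]) -> pd.Series:
    """96-channel pyrimidine-centric mutation spectrum.

    Purine-reference mutations are reverse-complemented into the
    corresponding pyrimidine channel; mutations with N in an immediate
    flank (or no context) are excluded, so the channel sum equals the
    number of callable mutations.
    """
    counts: Counter[str] = Counter()
    for m in mutations:
        tri = m.trinucleotide
        if tri is None or "N" in tri:
            continue
        ref, alt = m.ref, m.alt
        if ref in ("A", "G"):
            tri = revcomp(tri)
            ref = ref.translate(COMPLEMENT)
            alt = alt.translate(COMPLEMENT)
        counts[f"{tri[0]}[{ref}>{alt}]{tri[2]}"] += 1
    return pd.Series([counts.get(ch, 0) for ch in SPECTRUM_CHANNELS],
                     index=list(SPECTRUM_CHANNELS), name="count", dtype=int)


def plot_spectrum(spectrum: pd.Series, ax=None, title: str | None = None):
    """Bar plot of a 96-channel spectrum, colored by substitution class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(14, 3.5))
    colors = {"C>A": "#03BCEE", "C>G": "#010101", "C>T": "#E32926",
              "T>A": "#CAC9C9", "T>C": "#A1CE63", "T>G": "#EBC6C4"}
    bar_colors = [colors[ch[2:5]] for ch in spectrum.index]
    ax.bar(range(len(spectrum)), spectrum.values, color=bar_colors)
    ax.set_xticks(range(len(spectrum)))
    ax.set_xticklabels(spectrum.index, rotation=90, fontsize=4)
    ax.set_ylabel("mutations")
    if title:
        ax.set_title(title)
    return ax
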