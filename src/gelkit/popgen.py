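"""Population-genetics statistics from gel-derived genotypes.

The presence/absence fingerprint is bridged to genotypes through a
user-supplied locus map (codominant mode: each band class is an allele,
classes grouped into loci; an individual showing one class at a locus is a
homozygote, two a heterozygote, more than two violates diploidy).  From the
genotype table the module computes allele and genotype frequencies, the
chi-square Hardy-Weinberg goodness-of-fit test, observed heterozygosity,
Nei gene diversity (expected heterozygosity), Botstein polymorphism
information content, and Nei/Wright F-statistics (FIS, FST, FIT) over
subpopulations, per locus and averaged over loci.

A dominant mode for RAPD-style data treats each band class as a biallelic
locus with a recessive null allele estimated as sqrt(band-absent fraction)
under Hardy-Weinberg; observed heterozygosity and the HWE test are
unavailable there.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GenotypeTable:
    """Codominant genotypes: individuals x loci, unordered allele pairs."""

    individuals: list
    subpops: dict  # individual -> subpopulation label
    loci: dict  # locus -> list of allele names
    genotypes: dict  # (individual, locus) -> (allele, allele) | None

    def __post_init__(self):
        if len(self.individuals) < 2 or len(self.loci) < 1:
            raise ValueError("need at least 2 individuals and 1 locus")
        for (ind, locus), gt in self.genotypes.items():
            if gt is None:
                continue
            for al in gt:
                if al not in self.loci[locus]:
                    raise ValueError(
                        f"allele {al!r} not in locus {locus!r} allele list")

    def subset(self, subpop=None) -> list:
        if subpop is None:
            return list(self.individuals)
        return [i for i in self.individuals if self.subpops.get(i) == subpop]

    def subpop_labels(self) -> list:
        seen = []
        for i in self.individuals:
            lab = self.subpops.get(i)
            if lab is not None and lab not in seen:
                seen.append(lab)
        return seen


def infer_genotypes(m, locus_map: dict, subpop_labels: dict | None = None
                    ) -> GenotypeTable:
    """Build a genotype table from a presence/absence matrix.

    `locus_map` maps each locus name to the class indices of its alleles.
    Per individual and locus: two present classes make a heterozygote, one a
    homozygote, none a missing genotype; three or more reject the diploid
    model and raise, naming the individual and locus.
    """
    samples = list(m.samples)
    entries = np.asarray(m.entries)
    values = m.class_values
    loci, genotypes = {}, {}
    for locus, class_indices in locus_map.items():
        alleles = [f"{values[ci]:g}" for ci in class_indices]
        loci[locus] = alleles
        for si, sample in enumerate(samples):
            present = [alleles[k] for k, ci in enumerate(class_indices)
                       if entries[ci, si]]
            if len(present) > 2:
                raise ValueError(
                    f"individual {sample!r} carries {len(present)} bands at "
                    f"locus {locus!r}; diploid genotypes allow at most 2")
            if len(present) == 0:
                genotypes[(sample, locus)] = None
            elif len(present) == 1:
                genotypes[(sample, locus)] = (present[0], present[0])
            else:
                genotypes[(sample, locus)] = tuple(sorted(present))
    return GenotypeTable(individuals=samples,
                         subpops=dict(subpop_labels or {}),
                         loci=loci, genotypes=genotypes)


def _nonmissing(g: GenotypeTable, locus, subset):
    return [(i, g.genotypes.get((i, locus))) for i in subset
            if g.genotypes.get((i, locus)) is not None]


def allele_frequencies(g: GenotypeTable, locus, subset=None) -> dict:
    """Gene-counting allele frequencies, missing genotypes excluded."""
    subset = g.subset() if subset is None else subset
    observed = _nonmissing(g, locus, subset)
    if not observed:
        raise ValueError(f"all genotypes missing at locus {locus!r}")
    counts = {}
    for _, (a1, a2) in observed:
        counts[a1] = counts.get(a1, 0) + 1
        counts[a2] = counts.get(a2, 0) + 1
    total = 2 * len(observed)
    return {al: counts.get(al, 0) / total for al in g.loci[locus]
            if counts.get(al, 0) > 0}


def genotype_counts(g: GenotypeTable, locus, subset=None) -> dict:
    subset = g.subset() if subset is None else subset
    counts = {}
    for _, gt in _nonmissing(g, locus, subset):
        counts[gt] = counts.get(gt, 0) + 1
    return counts


def hwe_test(g: GenotypeTable, locus, subset=None):
    """Chi-square goodness-of-fit test of Hardy-Weinberg proportions.

    Expected counts are ``n p_i^2`` for homozygotes and ``2 n p_i p_j`` for
    heterozygotes; ``df = k(k-1)/2`` for k observed alleles (genotype cells
    minus fitted allele frequencies).  Cells with expectation below 1 are
    pooled into the cell with the next-smallest expectation before summing,
    and a low-expected-count warning is emitted whenever any expectation is
    below 5.

    Returns ``(observed, expected, chi_square, df, p_value)`` with the two
    count dicts keyed by sorted allele pairs.
    """
    subset = g.subset() if subset is None else subset
    freqs = allele_frequencies(g, locus, subset)
    alleles = sorted(freqs)
    if len(alleles) < 2:
        raise ValueError(f"locus {locus!r} is monomorphic; HWE test undefined")
    observed = genotype_counts(g, locus, subset)
    n = sum(observed.values())
    expected = {}
    for i, a1 in enumerate(alleles):
        for a2 in alleles[i:]:
            if a1 == a2:
                expected[(a1, a2)] = n * freqs[a1] ** 2
            else:
                expected[(a1, a2)] = 2 * n * freqs[a1] * freqs[a2]
    obs = {gt: observed.get(gt, 0) for gt in expected}
    if min(expected.values()) < 5:
        warnings.warn(
            f"locus {locus!r}: expected genotype counts below 5; the "
            "chi-square approximation may be poor", UserWarning, stacklevel=2)
    # pool cells with E < 1 into the next-smallest-E cell
    pooled_obs = dict(obs)
    pooled_exp = dict(expected)
    while len(pooled_exp) > 1 and min(pooled_exp.values()) < 1:
        order = sorted(pooled_exp, key=lambda gt: pooled_exp[gt])
        smallest, target = order[0], order[1]
        pooled_exp[target] += pooled_exp.pop(smallest)
        pooled_obs[target] += pooled_obs.pop(smallest)
    chi_square = sum((pooled_obs[gt] - pooled_exp[gt]) ** 2 / pooled_exp[gt]
                     for gt in pooled_exp)
    k = len(alleles)
    df = k * (k - 1) // 2
    p_value = float(stats.chi2.sf(chi_square, df))
    return obs, expected, float(chi_square), df, p_value


def diversity_stats(g: GenotypeTable, locus, subset=None):
    """Observed/expected heterozygosity, homozygosity and PIC for one locus.

    He is Nei's gene diversity ``1 - sum p_i^2``; PIC is Botstein's
    ``1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2``.
    """
    subset = g.subset() if subset is None else subset
    freqs = allele_frequencies(g, locus, subset)
    observed = _nonmissing(g, locus, subset)
    n = len(observed)
    ho = sum(1 for _, (a1, a2) in observed if a1 != a2) / n
    p2 = sum(p ** 2 for p in freqs.values())
    he = 1.0 - p2
    pic = 1.0 - p2 - sum(2 * (freqs[a] ** 2) * (freqs[b] ** 2)
                         for a, b in combinations(sorted(freqs), 2))
    return ho, he, 1.0 - he, pic


@dataclass
class FStats:
    """Nei/Wright hierarchical F-statistics for one locus (or the average)."""

    hi: float
    hs: float
    ht: float
    fis: float
    fst: float
    fit: float


def _fstats_from_h(hi, hs, ht) -> FStats:
    fis = (hs - hi) / hs if hs > 0 else float("nan")
    fst = (ht - hs) / ht if ht > 0 else float("nan")
    fit = (ht - hi) / ht if ht > 0 else float("nan")
    return FStats(hi=hi, hs=hs, ht=ht, fis=fis, fst=fst, fit=fit)


def f_statistics(g: GenotypeTable) -> tuple[dict, FStats]:
    """Per-locus and averaged F-statistics over subpopulations.

    HI is the observed heterozygosity and HS the within-subpopulation gene
    diversity, both averaged over subpopulations weighted by their
    non-missing sample sizes; HT is the gene diversity of the pooled allele
    frequencies (the same weights).  FIS, FST and FIT follow as the usual
    heterozygosity deficits; the average over loci is the unweighted mean of
    per-locus values.  Loci where HS or HT vanish give NaN F-values rather
    than errors.
    """
    labels = g.subpop_labels()
    if len(labels) < 2:
        raise ValueError("F-statistics need at least 2 subpopulations")
    per_locus = {}
    for locus in g.loci:
        hi_sum = hs_sum = 0.0
        weight = 0
        pooled = {}
        informative = 0
        for lab in labels:
            subset = g.subset(lab)
            observed = _nonmissing(g, locus, subset)
            if not observed:
                continue
            informative += 1
            n = len(observed)
            ho, he, _, _ = diversity_stats(g, locus, subset)
            freqs = allele_frequencies(g, locus, subset)
            hi_sum += n * ho
            hs_sum += n * he
            for al, p in freqs.items():
                pooled[al] = pooled.get(al, 0.0) + n * p
            weight += n
        if informative < 2:
            continue
        hi = hi_sum / weight
        hs = hs_sum / weight
        ht = 1.0 - sum((c / weight) ** 2 for c in pooled.values())
        per_locus[locus] = _fstats_from_h(hi, hs, ht)
    if not per_locus:
        raise ValueError("no locus has data in at least 2 subpopulations")
    vals = list(per_locus.values())

    def _mean_defined(xs):
        xs = [x for x in xs if not np.isnan(x)]
        return float(np.mean(xs)) if xs else float("nan")

    avg = FStats(
        hi=float(np.mean([v.hi for v in vals])),
        hs=float(np.mean([v.hs for v in vals])),
        ht=float(np.mean([v.ht for v in vals])),
        fis=_mean_defined([v.fis for v in vals]),
        fst=_mean_defined([v.fst for v in vals]),
        fit=_mean_defined([v.fit for v in vals]),
    )
    return per_locus, avg


def locus_summary(g: GenotypeTable, subpop=None) -> pd.DataFrame:
    """Per-locus table: n, allele count, Ho, He, PIC, chi-square, df, p.

    Monomorphic loci report Ho/He/PIC with NaN for the (undefined) HWE test.
    """
    subset = g.subset(subpop)
    rows = []
    for locus in g.loci:
        try:
            freqs = allele_frequencies(g, locus, subset)
        except ValueError:
            continue
        observed = _nonmissing(g, locus, subset)
        ho, he, hom, pic = diversity_stats(g, locus, subset)
        if len(freqs) >= 2:
            _, _, chi2, df, p = hwe_test(g, locus, subset)
        else:
            chi2 = df = p = float("nan")
        rows.append({"locus": locus, "n": len(observed),
                     "n_alleles": len(freqs), "Ho": ho, "He": he,
                     "homozygosity": hom, "PIC": pic,
                     "chi_square": chi2, "df": df, "p_value": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dominant (RAPD-style) mode
# ---------------------------------------------------------------------------

def dominant_locus_stats(m) -> pd.DataFrame:
    """Treat each band class as a dominant biallelic locus.

    The null (band-absent) allele frequency is estimated as
    ``q = sqrt(absent fraction)`` assuming Hardy-Weinberg; He and PIC follow
    from the two-allele formulas.  Observed heterozygosity and the HWE test
    are undefined for dominant data and therefore not reported.
    """
    entries = np.asarray(m.entries)
    rows = []
    for ci, row in enumerate(entries):
        absent_frac = 1.0 - row.mean()
        q = math.sqrt(absent_frac)
        p = 1.0 - q
        he = 2 * p * q
        pic = 1.0 - (p ** 2 + q ** 2) - 2 * (p ** 2) * (q ** 2)
        rows.append({"class_value": m.class_values[ci], "p_band": p,
                     "q_null": q, "He": he, "PIC": pic})
    return pd.DataFrame(rows)
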