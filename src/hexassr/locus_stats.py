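"""Per-locus diversity indices for dosage-blind polyploid SSR data.

The panel mirrors the index set conventionally reported for SSR germplasm
fingerprints: allele count (An), Simpson's index of diversity (1-D),
evenness (Ev), rarefaction allelic richness (AR), Nei's unbiased gene
diversity (GD), observed heterozygosity (Ho), gametic heterozygosity (GH),
expected heterozygosity with dosage correction (Hs), effective number of
alleles (En) and the ratio R = En/An, with a per-class z-test flagging loci
whose R deviates from the class mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import pandas as pd
from scipy import stats as _sstats

from hexassr.genotypes import (
    AlleleFrequencySpectrum,
    AllelePhenotype,
    EstimationMode,
    GenotypeMatrix,
    MarkerClass,
    allele_frequencies,
    dosage_posterior,
)

__all__ = [
    "LocusStatistics",
    "simpson_diversity",
    "effective_alleles",
    "evenness",
    "allelic_richness",
    "gene_diversity",
    "observed_heterozygosity",
    "gametic_heterozygosity",
    "expected_heterozygosity",
    "r_ratio_test",
    "locus_panel",
    "panel_to_frame",
]


@dataclass
class LocusStatistics:
    """One row of the per-locus index panel."""

    locus: str
    an: int
    simpson_1mD: float
    ev: float
    ar: float
    gd: float
    ho: float
    gh: float
    hs: float
    en: float
    r: float
    z: float = math.nan
    p: float = math.nan

    @property
    def significance(self) -> str:
        """Star annotation for the R z-test (* p<0.05, ** p<0.01)."""
        if math.isnan(self.p):
            return ""
        if self.p < 0.01:
            return "**"
        if self.p < 0.05:
            return "*"
        return ""


def _sum_sq(spec: AlleleFrequencySpectrum) -> float:
    return sum(f * f for f in spec.frequency_values())


def simpson_diversity(spec: AlleleFrequencySpectrum) -> float:
    """Simpson's index of diversity, 1 - sum(p_i^2)."""
    return 1.0 - _sum_sq(spec)


def effective_alleles(spec: AlleleFrequencySpectrum) -> float:
    """Effective number of alleles En = 1 / sum(p_i^2).

    The number of equifrequent alleles that would give the same expected
    homozygosity; 1 <= En <= An with equality iff frequencies are uniform.
    """
    return 1.0 / _sum_sq(spec)


def evenness(spec: AlleleFrequencySpectrum) -> float:
    """Evenness Ev = [(1/lambda) - 1] / [exp(H) - 1].

    ``1/lambda`` is Stoddart and Taylor's index (the effective number of
    alleles) and ``H`` the Shannon diversity.  Both numerator and
    denominator count "effective types minus one", so Ev is 1 for uniform
    frequencies and decreases with skew.  Undefined (0/0) for a monomorphic
    locus; returns NaN there.
    """
    if spec.n_alleles < 2:
        return math.nan
    inv_lambda = effective_alleles(spec)
    shannon = -sum(f * math.log(f) for f in spec.frequency_values() if f > 0)
    return (inv_lambda - 1.0) / (math.exp(shannon) - 1.0)


def allelic_richness(spec: AlleleFrequencySpectrum, k: int) -> float:
    """Rarefaction allelic richness: expected alleles among k gene copies.

    Hypergeometric rarefaction: AR = sum_i [1 - C(N - N_i, k) / C(N, k)],
    the expected number of distinct alleles in a random subsample of ``k``
    of the ``N`` sampled gene copies.  Requires integer counts.
    """
    counts = []
    for c in spec.counts.values():
        ci = round(c)
        if abs(c - ci) > 1e-6:
            raise ValueError("rarefaction requires integer allele counts")
        counts.append(int(ci))
    n = sum(counts)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    denom = math.comb(n, k)
    return sum(1.0 - math.comb(n - ci, k) / denom for ci in counts)


def gene_diversity(spec: AlleleFrequencySpectrum) -> float:
    """Nei's unbiased gene diversity, N/(N-1) * (1 - sum(p_i^2))."""
    n = spec.n_copies
    if n < 2:
        raise ValueError("gene diversity needs at least 2 gene copies")
    return n / (n - 1.0) * (1.0 - _sum_sq(spec))


def observed_heterozygosity(gm: GenotypeMatrix, locus: str) -> float:
    """Fraction of non-missing samples showing >= 2 distinct alleles."""
    observed = [p for p in gm.column(locus) if not p.missing]
    if not observed:
        raise ValueError(f"locus {locus!r}: all calls missing")
    return sum(1 for p in observed if len(p) >= 2) / len(observed)


def _gh_for_dosage(dosage: Sequence[int], ploidy: int) -> float:
    pairs = math.comb(ploidy, 2)
    same = sum(math.comb(d, 2) for d in dosage)
    return 1.0 - same / pairs


def gametic_heterozygosity(
    gm: GenotypeMatrix,
    locus: str,
    mode: EstimationMode = EstimationMode.EM_DOSAGE,
) -> float:
    """Mean within-individual probability that two gene copies differ.

    For each individual, two of its ploidy allele copies are drawn without
    replacement; GH is the chance they carry different alleles, averaged
    over individuals.  Under unknown dosage the per-individual value is
    averaged over dosage completions: EM-posterior-weighted in
    ``EM_DOSAGE`` mode, or assuming equal (possibly fractional) dosage of
    the observed alleles in ``ONE_PER_PHENOTYPE`` mode.
    """
    mode = EstimationMode(mode)
    loc = gm.locus(locus)
    ploidy = loc.ploidy
    observed = [p for p in gm.column(locus) if not p.missing]
    if not observed:
        raise ValueError(f"locus {locus!r}: all calls missing")
    if mode is EstimationMode.ONE_PER_PHENOTYPE:
        vals = []
        pairs = ploidy * (ploidy - 1)
        for p in observed:
            d = ploidy / len(p)
            vals.append(1.0 - len(p) * d * (d - 1.0) / pairs)
        return sum(vals) / len(vals)
    freqs = allele_frequencies(gm, locus, EstimationMode.EM_DOSAGE).frequencies
    vals = []
    for p in observed:
        post = dosage_posterior(p, freqs, ploidy)
        vals.append(sum(w * _gh_for_dosage(d, ploidy) for d, w in post))
    return sum(vals) / len(vals)


def expected_heterozygosity(gm: GenotypeMatrix, locus: str) -> float:
    """Expected heterozygosity Hs with correction for missing dosage.

    Nei's unbiased gene diversity computed on the EM-dosage-corrected
    allele frequency spectrum (N = ploidy x non-missing samples).
    """
    spec = allele_frequencies(gm, locus, EstimationMode.EM_DOSAGE)
    return gene_diversity(spec)


def r_ratio_test(panel: list[LocusStatistics]) -> list[LocusStatistics]:
    """z-test of each locus' R = En/An against the panel (class) mean.

    z_i = (R_i - mean R) / sd(R) with the sample standard deviation
    (n - 1); two-sided p from the standard normal CDF.  Flags loci whose
    allele frequencies are unusually skewed (low R) or uniform (high R)
    for their marker class.
    """
    if len(panel) < 3:
        raise ValueError("R z-test needs at least 3 loci")
    rs = [row.r for row in panel]
    mean = sum(rs) / len(rs)
    var = sum((x - mean) ** 2 for x in rs) / (len(rs) - 1)
    if var <= 0:
        # all R identical: no deviation to test
        return [replace(row, z=0.0, p=1.0) for row in panel]
    sd = math.sqrt(var)
    out = []
    for row in panel:
        z = (row.r - mean) / sd
        p = 2.0 * _sstats.norm.sf(abs(z))
        out.append(replace(row, z=z, p=p))
    return out


def locus_panel(
    gm: GenotypeMatrix,
    class_filter: MarkerClass | str | None = None,
    k: int | None = None,
    gh_mode: EstimationMode = EstimationMode.EM_DOSAGE,
) -> list[LocusStatistics]:
    """Assemble the per-locus index panel for one marker class.

    ``k`` is the rarefaction size in gene copies; by default the smallest
    per-locus copy count within the class, so that every locus can be
    rarefied to a common depth despite missing data.  An, 1-D, Ev, AR, GD
    and En use dosage-agnostic (one-count-per-phenotype) frequencies; Hs
    (and GH by default) use the EM dosage correction.
    """
    if class_filter is None:
        names = gm.locus_names
    else:
        names = gm.loci_of_class(class_filter)
    if not names:
        raise ValueError(f"no loci of class {class_filter!r}")
    specs = {n: allele_frequencies(gm, n, EstimationMode.ONE_PER_PHENOTYPE) for n in names}
    if k is None:
        k = min(int(specs[n].n_copies) for n in names)
    rows: list[LocusStatistics] = []
    for n in names:
        spec = specs[n]
        en = effective_alleles(spec)
        rows.append(
            LocusStatistics(
                locus=n,
                an=spec.n_alleles,
                simpson_1mD=simpson_diversity(spec),
                ev=evenness(spec),
                ar=allelic_richness(spec, k),
                gd=gene_diversity(spec),
                ho=observed_heterozygosity(gm, n),
                gh=gametic_heterozygosity(gm, n, gh_mode),
                hs=expected_heterozygosity(gm, n),
                en=en,
                r=en / spec.n_alleles,
            )
        )
    if len(rows) >= 3:
        rows = r_ratio_test(rows)
    return rows


_COLUMNS = ["locus", "An", "1-D", "Ev", "AR", "GD", "Ho", "GH", "Hs", "En", "R", "z", "p"]


def panel_to_frame(panel: Sequence[LocusStatistics], mean_row: bool = True) -> pd.DataFrame:
    """Tabulate a panel, optionally appending the arithmetic-mean row."""
    records = [
        [row.locus, row.an, row.simpson_1mD, row.ev, row.ar, row.gd, row.ho, row.gh, row.hs, row.en, row.r, row.z, row.p]
        for row in panel
    ]
    df = pd.DataFrame(records, columns=_COLUMNS)
    if mean_row:
        means = df[_COLUMNS[1:]].mean(axis=0)
        df.loc[len(df)] = ["Mean", *means.tolist()]
    return df
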