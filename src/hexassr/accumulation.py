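"""Genotype-accumulation curves: marker discriminatory power by resampling.

For each subset size from 1 to L-1 loci, loci are repeatedly sampled
without replacement and the number of distinct multilocus genotypes (MLGs)
among the samples is counted, giving the distribution of discriminatory
power as markers are added.  The curve plateaus at the number of distinct
genotypes resolvable with the full panel (at most the sample count).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from hexassr.genotypes import GenotypeMatrix

__all__ = ["AccumulationResult", "count_mlg", "accumulation_curve", "accumulation_to_frame"]


@dataclass
class AccumulationResult:
    """MLG counts over resampled locus subsets of one size."""

    n_loci: int
    mlg_counts: np.ndarray

    @property
    def quartiles(self) -> tuple[float, float, float, float, float]:
        """Five-number summary (min, Q1, median, Q3, max)."""
        q = np.percentile(self.mlg_counts, [0, 25, 50, 75, 100])
        return tuple(float(x) for x in q)


def _phenotype_codes(gm: GenotypeMatrix, missing_as_equal: bool = True) -> np.ndarray:
    """Integer-encode each call; per locus, equal phenotypes share a code.

    Missing calls all map to one code when ``missing_as_equal`` (so two
    samples missing the same locus are not distinguished by it); otherwise
    each missing call gets a unique code (missing treated as "could be
    anything distinct", the anti-conservative extreme).
    """
    n, L = gm.n_samples, len(gm.loci)
    codes = np.zeros((n, L), dtype=np.int64)
    for j, loc in enumerate(gm.loci):
        seen: dict = {}
        next_unique = 0
        for i, row in enumerate(gm.calls):
            p = row[j]
            if p.missing and not missing_as_equal:
                key = ("__missing__", next_unique)
                next_unique += 1
            else:
                key = ("NA",) if p.missing else p.alleles
            codes[i, j] = seen.setdefault(key, len(seen))
    return codes


def count_mlg(
    gm: GenotypeMatrix,
    locus_subset: list[str] | None = None,
    missing_as_equal: bool = True,
) -> int:
    """Number of distinct multilocus genotypes over a locus subset."""
    if locus_subset is not None:
        if not locus_subset:
            raise ValueError("empty locus subset")
        gm = gm.subset_loci(locus_subset)
    codes = _phenotype_codes(gm, missing_as_equal)
    return int(np.unique(codes, axis=0).shape[0])


def accumulation_curve(
    gm: GenotypeMatrix,
    n_resamples: int = 10000,
    seed: int | None = None,
    missing_as_equal: bool = True,
) -> list[AccumulationResult]:
    """MLG-count distributions for locus subsets of size 1 .. L-1.

    Within each draw loci are sampled without replacement; the ``seed``
    makes the resampling reproducible.
    """
    L = len(gm.loci)
    if L < 2:
        raise ValueError("accumulation needs at least 2 loci")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    codes = _phenotype_codes(gm, missing_as_equal)
    n = codes.shape[0]
    # mixed-radix row hashing: all loci share base B, so a subset's rows can
    # be collapsed to single integers and counted by sorting
    base = int(codes.max()) + 1 if n else 1
    results: list[AccumulationResult] = []
    for size in range(1, L):
        use_hash = base**size < 2**62
        idx = np.empty((n_resamples, size), dtype=np.intp)
        for r in range(n_resamples):
            idx[r] = rng.choice(L, size=size, replace=False)
        if use_hash:
            weights = base ** np.arange(size, dtype=np.int64)
            # (n_samples, n_resamples, size) -> hash (n_resamples, n_samples)
            sub = codes[:, idx]  # n x R x size
            hashed = np.einsum("nrs,s->rn", sub, weights)
            hashed.sort(axis=1)
            counts = 1 + np.count_nonzero(np.diff(hashed, axis=1), axis=1)
        else:
            counts = np.array(
                [np.unique(codes[:, idx[r]], axis=0).shape[0] for r in range(n_resamples)]
            )
        results.append(AccumulationResult(n_loci=size, mlg_counts=counts.astype(int)))
    return results


def accumulation_to_frame(results: list[AccumulationResult]) -> pd.DataFrame:
    """Long-format table: n_loci, resample_index, mlg."""
    rows = []
    for res in results:
        for r, c in enumerate(res.mlg_counts):
            rows.append((res.n_loci, r, int(c)))
    return pd.DataFrame(rows, columns=["n_loci", "resample_index", "mlg"])
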