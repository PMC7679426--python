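"""Bruvo's genetic distance for dosage-blind polyploid microsatellites.

Alleles are expressed in repeat units (fragment size / motif length); the
distance between two alleles x and y is ``1 - 2**(-|x - y|)``, a geometric
kernel reflecting the stepwise mutation of microsatellites.  The distance
between two genotypes is the minimum, over all assignments of one
genotype's alleles to the other's, of the mean per-allele distance.

Dosage-blind phenotypes can show different numbers of alleles.  Four
models handle the size mismatch:

* ``INFINITE`` — missing alleles are virtual alleles infinitely far from
  everything (per-allele distance 1);
* ``GENOME_ADDITION`` — the smaller phenotype is augmented to the larger
  size with copies of its *own* alleles, every possible augmentation is
  scored (each with its own optimal assignment) and the scores averaged;
* ``GENOME_LOSS`` — the smaller phenotype is augmented with alleles from
  the *larger* phenotype, again averaging over all choices;
* ``COMBINATIONAL`` — the mean of the addition and loss model distances,
  appropriate when neither chromosome gain nor loss can be assumed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np

from hexassr.genotypes import AllelePhenotype, GenotypeMatrix, LocusDefinition

__all__ = ["BruvoModel", "DistanceMatrix", "repeat_numbers", "bruvo_pair", "bruvo_matrix"]


class BruvoModel(str, Enum):
    INFINITE = "infinite"
    GENOME_ADDITION = "genome_addition"
    GENOME_LOSS = "genome_loss"
    COMBINATIONAL = "combinational"


@dataclass
class DistanceMatrix:
    """Square symmetric labelled distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be exactly 0")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (off-diagonal) values, scipy condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        if sorted(labels) != sorted(self.labels):
            raise ValueError("label sets differ")
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels=list(labels), values=self.values[np.ix_(idx, idx)])

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        values = df.to_numpy(dtype=float)
        # symmetrize away round-tripping noise, keep the diagonal exact
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        return cls(labels=[str(c) for c in df.columns], values=values)

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for label, row in zip(self.labels, self.values):
                fh.write(label + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")


def repeat_numbers(pheno: AllelePhenotype, locus: LocusDefinition) -> tuple[float, ...]:
    """Allele sizes in repeat units (size / motif length)."""
    if pheno.missing:
        raise ValueError("missing phenotype has no repeat numbers")
    return tuple(a / locus.motif_length for a in pheno.alleles)


_PERM_CACHE: dict[int, np.ndarray] = {}


def _perms(k: int) -> np.ndarray:
    if k not in _PERM_CACHE:
        _PERM_CACHE[k] = np.array(list(itertools.permutations(range(k))), dtype=np.intp)
    return _PERM_CACHE[k]


def _min_mean_assignment(cost: np.ndarray) -> float:
    """Minimum over bijections of the mean per-allele distance.

    Exhaustive over the k! permutations (k <= 6 at hexaploid scale keeps
    this exact and fast); vectorized with a precomputed permutation table.
    """
    k = cost.shape[0]
    perms = _perms(k)
    totals = cost[np.arange(k), perms].sum(axis=1)
    return float(totals.min()) / k


def _allele_cost(xs: tuple[float, ...], ys: tuple[float, ...]) -> np.ndarray:
    xa = np.asarray(xs, dtype=float)
    ya = np.asarray(ys, dtype=float)
    return 1.0 - 2.0 ** (-np.abs(xa[:, None] - ya[None, :]))


def _weighted_fills(alleles: tuple[float, ...], slots: int):
    """Multiset fills of `slots` copies from `alleles`, with the number of
    ordered tuples realizing each multiset as weight."""
    for fill in itertools.combinations_with_replacement(alleles, slots):
        counts: dict[float, int] = {}
        for a in fill:
            counts[a] = counts.get(a, 0) + 1
        weight = math.factorial(slots)
        for c in counts.values():
            weight //= math.factorial(c)
        yield fill, weight


def _pair_distance(small: tuple[float, ...], large: tuple[float, ...], model: BruvoModel) -> float:
    m, n = len(small), len(large)
    if m == n:
        return _min_mean_assignment(_allele_cost(small, large))
    diff = n - m
    if model is BruvoModel.INFINITE:
        cost = np.ones((n, n))
        cost[:, :m] = _allele_cost(large, small)
        return _min_mean_assignment(cost)
    if model is BruvoModel.COMBINATIONAL:
        add = _pair_distance(small, large, BruvoModel.GENOME_ADDITION)
        loss = _pair_distance(small, large, BruvoModel.GENOME_LOSS)
        return (add + loss) / 2.0
    source = small if model is BruvoModel.GENOME_ADDITION else large
    base = _allele_cost(large, small)  # n x m, reused across fills
    fills = list(_weighted_fills(source, diff))
    costs = np.empty((len(fills), n, n))
    weights = np.empty(len(fills))
    for fi, (fill, w) in enumerate(fills):
        costs[fi, :, :m] = base
        costs[fi, :, m:] = _allele_cost(large, fill)
        weights[fi] = w
    perms = _perms(n)
    # advanced indices broadcast to (P, n); result (F, P, n)
    totals = costs[:, np.arange(n), perms].sum(axis=2)
    mins = totals.min(axis=1) / n
    return float((weights * mins).sum() / weights.sum())


_pair_cache: dict[tuple, float] = {}


def bruvo_pair(
    a: AllelePhenotype,
    b: AllelePhenotype,
    locus: LocusDefinition,
    model: BruvoModel = BruvoModel.COMBINATIONAL,
    strict: bool = False,
) -> float:
    """Bruvo distance between two phenotypes at one locus; NaN if either is
    a no-call.

    ``strict`` errors (instead of proceeding with fractional repeat
    numbers) when the two phenotypes' sizes are not congruent modulo the
    motif, i.e. when binning failed to place them on a common grid.
    """
    model = BruvoModel(model)
    if a.missing or b.missing:
        return math.nan
    if strict:
        residues = {s % locus.motif_length for s in a.alleles + b.alleles}
        if len(residues) > 1:
            raise ValueError(
                f"locus {locus.name!r}: allele sizes not on a common "
                f"{locus.motif_length}-bp grid (residues {sorted(residues)})"
            )
    ra = repeat_numbers(a, locus)
    rb = repeat_numbers(b, locus)
    if len(ra) > len(rb):
        ra, rb = rb, ra
    key = (ra, rb, model)
    if key not in _pair_cache:
        if len(_pair_cache) > 300_000:
            _pair_cache.clear()
        _pair_cache[key] = _pair_distance(ra, rb, model)
    return _pair_cache[key]


def bruvo_matrix(
    gm: GenotypeMatrix,
    model: BruvoModel = BruvoModel.COMBINATIONAL,
    loci: list[str] | None = None,
) -> DistanceMatrix:
    """Pairwise Bruvo distances: mean over loci of per-locus distances.

    Loci at which either member of a pair is a no-call are dropped from
    that pair's mean; a pair with no comparable locus is an error.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    names = loci if loci is not None else gm.locus_names
    if not names:
        raise ValueError("no loci selected")
    columns = [(gm.locus(n), gm.column(n)) for n in names]
    n = gm.n_samples
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            total, used = 0.0, 0
            for loc, col in columns:
                d = bruvo_pair(col[i], col[j], loc, model)
                if not math.isnan(d):
                    total += d
                    used += 1
            if used == 0:
                raise ValueError(
                    f"samples {gm.sample_ids[i]!r} and {gm.sample_ids[j]!r} "
                    "share no comparable locus"
                )
            values[i, j] = values[j, i] = total / used
    return DistanceMatrix(labels=list(gm.sample_ids), values=values)
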