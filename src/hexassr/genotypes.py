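"""Domain types, genotype-table IO, allele binning and frequency estimation.

Polyploid microsatellite genotypes are *dosage-blind*: capillary
electrophoresis reveals which allele sizes are present at a locus in an
individual but not how many chromosomal copies carry each allele.  An
individual's call is therefore an :class:`AllelePhenotype` — the set of
distinct allele sizes observed (1 to ploidy of them) — and any statistic
that needs allele *frequencies* must either count each observed allele once
per individual (``ONE_PER_PHENOTYPE``) or integrate over the unobserved
dosage (``EM_DOSAGE``, an expectation-maximization estimator assuming
alleles are drawn independently from the population frequencies).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger("hexassr")

__all__ = [
    "MarkerClass",
    "EstimationMode",
    "LocusDefinition",
    "AllelePhenotype",
    "GenotypeMatrix",
    "AlleleFrequencySpectrum",
    "read_genotypes",
    "write_genotypes",
    "read_locus_definitions",
    "write_locus_definitions",
    "bin_alleles",
    "allele_frequencies",
    "dosage_posterior",
]


class MarkerClass(str, Enum):
    """Origin of the SSR: transcribed (EST) or anonymous genomic sequence."""

    EST = "EST"
    GENOMIC = "genomic"


class EstimationMode(str, Enum):
    """How allele frequencies are estimated from dosage-blind phenotypes."""

    ONE_PER_PHENOTYPE = "one_per_phenotype"
    EM_DOSAGE = "em_dosage"


@dataclass(frozen=True)
class LocusDefinition:
    """An SSR locus: name, repeat-motif length in bp, marker class, ploidy."""

    name: str
    motif_length: int
    marker_class: MarkerClass = MarkerClass.GENOMIC
    ploidy: int = 6

    def __post_init__(self) -> None:
        if not 1 <= int(self.motif_length):
            raise ValueError(f"motif_length must be >= 1, got {self.motif_length}")
        if self.ploidy < 2 or self.ploidy % 2:
            raise ValueError(f"ploidy must be even and >= 2, got {self.ploidy}")
        object.__setattr__(self, "motif_length", int(self.motif_length))
        object.__setattr__(self, "ploidy", int(self.ploidy))
        object.__setattr__(self, "marker_class", MarkerClass(self.marker_class))


@dataclass(frozen=True)
class AllelePhenotype:
    """Distinct allele sizes (bp) observed in one individual at one locus.

    Dosage is not recorded; a hexaploid showing two sizes may carry them in
    dosage 1:5 through 5:1.  ``missing`` marks a no-call.
    """

    alleles: tuple[int, ...] = ()
    missing: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", tuple(int(a) for a in self.alleles))
        if self.missing:
            if self.alleles:
                raise ValueError("missing phenotype cannot carry alleles")
            return
        if not self.alleles:
            raise ValueError("non-missing phenotype needs at least one allele")
        if any(b <= a for a, b in zip(self.alleles, self.alleles[1:])):
            raise ValueError(f"alleles must be strictly increasing, got {self.alleles}")

    @classmethod
    def from_sizes(cls, sizes: Iterable[int], ploidy: int | None = None) -> "AllelePhenotype":
        distinct = tuple(sorted({int(s) for s in sizes}))
        if ploidy is not None and len(distinct) > ploidy:
            raise ValueError(f"{len(distinct)} distinct alleles exceed ploidy {ploidy}")
        return cls(alleles=distinct)

    @classmethod
    def no_call(cls) -> "AllelePhenotype":
        return cls(alleles=(), missing=True)

    def __len__(self) -> int:
        return len(self.alleles)


@dataclass
class GenotypeMatrix:
    """Samples x loci table of dosage-blind allele phenotypes."""

    sample_ids: list[str]
    loci: list[LocusDefinition]
    calls: list[list[AllelePhenotype]]

    def __post_init__(self) -> None:
        if len(self.calls) != len(self.sample_ids):
            raise ValueError("row count does not match sample_ids")
        for row in self.calls:
            if len(row) != len(self.loci):
                raise ValueError("column count does not match loci")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        names = [loc.name for loc in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names")
        for row, sid in zip(self.calls, self.sample_ids):
            for pheno, loc in zip(row, self.loci):
                if not pheno.missing and len(pheno) > loc.ploidy:
                    raise ValueError(
                        f"sample {sid!r}, locus {loc.name!r}: "
                        f"{len(pheno)} alleles exceed ploidy {loc.ploidy}"
                    )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def locus_names(self) -> list[str]:
        return [loc.name for loc in self.loci]

    def locus(self, name: str) -> LocusDefinition:
        for loc in self.loci:
            if loc.name == name:
                return loc
        raise KeyError(f"unknown locus {name!r}")

    def locus_index(self, name: str) -> int:
        for i, loc in enumerate(self.loci):
            if loc.name == name:
                return i
        raise KeyError(f"unknown locus {name!r}")

    def column(self, name: str) -> list[AllelePhenotype]:
        j = self.locus_index(name)
        return [row[j] for row in self.calls]

    def subset_loci(self, names: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.locus_index(n) for n in names]
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            loci=[self.loci[j] for j in idx],
            calls=[[row[j] for j in idx] for row in self.calls],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return GenotypeMatrix(
            sample_ids=list(sample_ids),
            loci=list(self.loci),
            calls=[list(self.calls[i]) for i in idx],
        )

    def loci_of_class(self, marker_class: MarkerClass | str) -> list[str]:
        mc = MarkerClass(marker_class)
        return [loc.name for loc in self.loci if loc.marker_class is mc]


@dataclass
class AlleleFrequencySpectrum:
    """Allele counts at one locus; ``counts[a] / n_copies`` are frequencies.

    Under ``ONE_PER_PHENOTYPE`` each distinct allele observed in a sample
    contributes one count, so ``n_copies`` is the total number of distinct
    per-sample allele observations.  Under ``EM_DOSAGE`` counts are expected
    gene-copy counts and ``n_copies`` equals ploidy x non-missing samples.
    """

    locus: str
    counts: dict[int, float]
    n_copies: float
    estimation_mode: EstimationMode

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("empty allele spectrum")
        if any(c <= 0 for c in self.counts.values()):
            raise ValueError("allele counts must be positive")
        total = sum(self.counts.values())
        if not math.isclose(total, self.n_copies, rel_tol=0, abs_tol=1e-6):
            raise ValueError(f"counts sum {total} != n_copies {self.n_copies}")

    @property
    def n_alleles(self) -> int:
        return len(self.counts)

    @property
    def frequencies(self) -> dict[int, float]:
        return {a: c / self.n_copies for a, c in self.counts.items()}

    def frequency_values(self) -> list[float]:
        return [c / self.n_copies for c in self.counts.values()]


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

ALLELE_SEP = "/"


def _parse_cell(text: str, locus: LocusDefinition, sample: str, na_token: str) -> AllelePhenotype:
    text = text.strip()
    if text == na_token or text in ("", "NA", "na"):
        return AllelePhenotype.no_call()
    sizes: list[int] = []
    for token in text.split(ALLELE_SEP):
        token = token.strip()
        try:
            sizes.append(int(token))
        except ValueError as exc:
            raise ValueError(
                f"sample {sample!r}, locus {locus.name!r}: non-integer allele {token!r}"
            ) from exc
    distinct = sorted(set(sizes))
    if len(distinct) < len(sizes):
        logger.warning(
            "sample %r, locus %r: duplicate allele sizes in cell %r collapsed "
            "(dosage-blind format stores distinct sizes)",
            sample,
            locus.name,
            text,
        )
    if len(distinct) > locus.ploidy:
        raise ValueError(
            f"sample {sample!r}, locus {locus.name!r}: "
            f"{len(distinct)} alleles exceed ploidy {locus.ploidy}"
        )
    return AllelePhenotype(alleles=tuple(distinct))


def read_locus_definitions(path: str | Path) -> list[LocusDefinition]:
    """Read a locus metadata CSV: name,motif_length,marker_class,ploidy."""
    loci: list[LocusDefinition] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"name", "motif_length", "marker_class"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"locus metadata must have columns {sorted(required)}")
        for row in reader:
            loci.append(
                LocusDefinition(
                    name=row["name"].strip(),
                    motif_length=int(row["motif_length"]),
                    marker_class=MarkerClass(row["marker_class"].strip()),
                    ploidy=int(row.get("ploidy") or 6),
                )
            )
    return loci


def write_locus_definitions(loci: Sequence[LocusDefinition], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "motif_length", "marker_class", "ploidy"])
        for loc in loci:
            writer.writerow([loc.name, loc.motif_length, loc.marker_class.value, loc.ploidy])


def read_genotypes(path: str | Path, loci_meta: str | Path, na_token: str = "") -> GenotypeMatrix:
    """Read a wide genotype CSV (``sample,<locus1>,...``; alleles "/"-joined).

    Every locus column must appear in the metadata table; cells equal to
    ``na_token`` (default: empty) are no-calls.
    """
    loci = read_locus_definitions(loci_meta)
    by_name = {loc.name: loc for loc in loci}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError("empty genotype file") from None
        if not header or header[0] != "sample":
            raise ValueError('genotype CSV header must start with "sample"')
        locus_names = header[1:]
        unknown = [n for n in locus_names if n not in by_name]
        if unknown:
            raise ValueError(f"unknown locus column(s): {unknown}")
        ordered = [by_name[n] for n in locus_names]
        sample_ids: list[str] = []
        calls: list[list[AllelePhenotype]] = []
        for row in reader:
            if not row:
                continue
            sample = row[0]
            cells = row[1:]
            if len(cells) != len(ordered):
                raise ValueError(f"sample {sample!r}: expected {len(ordered)} cells")
            sample_ids.append(sample)
            calls.append(
                [_parse_cell(c, loc, sample, na_token) for c, loc in zip(cells, ordered)]
            )
    return GenotypeMatrix(sample_ids=sample_ids, loci=ordered, calls=calls)


def write_genotypes(gm: GenotypeMatrix, path: str | Path, na_token: str = "") -> None:
    """Write the wide genotype CSV; round-trips with :func:`read_genotypes`."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample"] + gm.locus_names)
        for sid, row in zip(gm.sample_ids, gm.calls):
            cells = [
                na_token if p.missing else ALLELE_SEP.join(str(a) for a in p.alleles)
                for p in row
            ]
            writer.writerow([sid] + cells)


# ---------------------------------------------------------------------------
# Allele-size binning
# ---------------------------------------------------------------------------


def bin_alleles(
    raw_sizes: Sequence[float],
    locus: LocusDefinition,
    resolution: float = 1.0,
) -> dict[float, int]:
    """Snap fractional fragment sizes onto a common repeat-motif grid.

    Fragment-analysis software reports fractional basepair sizes; true
    alleles of one SSR differ by whole repeat motifs, i.e. lie on a grid
    ``offset + motif_length * k``.  The grid offset is chosen by exhaustive
    search (0.1 bp steps over one motif period) to minimize the mean
    absolute displacement of the raw sizes, subject to every displacement
    being within the instrumental ``resolution`` (default +/- 1 bp).  Ties
    go to the smaller offset.

    Returns a mapping from each raw size to its integer binned size.

    Raises ``ValueError`` listing the offending sizes when no grid offset
    keeps all displacements within the resolution.
    """
    if not raw_sizes:
        return {}
    if any(r <= 0 for r in raw_sizes):
        raise ValueError("raw sizes must be positive")
    motif = locus.motif_length
    raws = sorted(set(float(r) for r in raw_sizes))

    # candidate keys: (mean |displacement|, mean signed displacement, offset)
    # -- ties in the absolute displacement go to the grid that on balance
    # rounds sizes down, then to the smaller offset
    best: tuple[float, float, float] | None = None
    best_map: dict[float, int] | None = None
    n_steps = int(round(motif / 0.1))
    for step in range(n_steps):
        offset = round(step * 0.1, 10)
        mapping: dict[float, int] = {}
        displacements: list[float] = []
        feasible = True
        for r in raws:
            k = round((r - offset) / motif)
            binned = offset + motif * k
            disp = abs(r - binned)
            if disp >= resolution - 1e-9:
                # a peak displaced by the full instrumental resolution is
                # indistinguishable from the neighbouring grid point
                feasible = False
                break
            snapped = int(round(binned))
            if abs(binned - snapped) > 1e-6:
                # offset grid not on integers; integer sizes require an
                # integer-compatible offset
                feasible = False
                break
            mapping[r] = snapped
            displacements.append(binned - r)
        if not feasible:
            continue
        mean_abs = sum(abs(d) for d in displacements) / len(displacements)
        mean_signed = sum(displacements) / len(displacements)
        key = (round(mean_abs, 9), round(mean_signed, 9), offset)
        if best is None or key < best:
            best = key
            best_map = mapping
    if best_map is None:
        # report which sizes are unbinnable under the best unconstrained grid
        bad = _unbinnable_sizes(raws, motif, resolution)
        raise ValueError(
            f"no {motif}-bp grid places all sizes within +/-{resolution} bp; "
            f"offending sizes: {bad}"
        )
    return best_map


def _unbinnable_sizes(raws: list[float], motif: int, resolution: float) -> list[float]:
    """Sizes inconsistent with the grid anchored at the first raw size."""
    anchor = raws[0]
    bad = []
    for r in raws:
        k = round((r - anchor) / motif)
        if abs(r - (anchor + motif * k)) > resolution + 1e-9:
            bad.append(r)
    return bad or raws


# ---------------------------------------------------------------------------
# Allele frequency estimation
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _compositions(total: int, parts: int) -> tuple[tuple[int, ...], ...]:
    """All tuples of `parts` positive integers summing to `total`."""
    if parts == 1:
        return ((total,),)
    out = []
    for first in range(1, total - parts + 2):
        for rest in _compositions(total - first, parts - 1):
            out.append((first,) + rest)
    return tuple(out)


@lru_cache(maxsize=None)
def _multinomial(counts: tuple[int, ...]) -> int:
    n = sum(counts)
    num = math.factorial(n)
    for c in counts:
        num //= math.factorial(c)
    return num


def dosage_posterior(
    pheno: AllelePhenotype,
    frequencies: Mapping[int, float],
    ploidy: int,
) -> list[tuple[tuple[int, ...], float]]:
    """Posterior over dosage completions of a phenotype, given frequencies.

    A dosage completion assigns each observed allele at least one of the
    ``ploidy`` gene copies.  Assuming copies are independent draws from the
    population frequencies, the posterior weight of dosage ``d`` is
    proportional to ``multinomial(d) * prod_a f_a^d_a``.  Returns
    ``[(dosage_tuple, weight), ...]`` aligned with ``pheno.alleles``;
    weights sum to 1.
    """
    if pheno.missing:
        raise ValueError("missing phenotype has no dosage posterior")
    alleles = pheno.alleles
    m = len(alleles)
    if m > ploidy:
        raise ValueError("more observed alleles than gene copies")
    freqs = [max(float(frequencies.get(a, 0.0)), 1e-300) for a in alleles]
    weights = []
    doses = _compositions(ploidy, m)
    for d in doses:
        w = float(_multinomial(d))
        for f, di in zip(freqs, d):
            w *= f**di
        weights.append(w)
    total = sum(weights)
    if total <= 0:
        # numerically degenerate; fall back to uniform over completions
        weights = [1.0] * len(doses)
        total = float(len(doses))
    return [(d, w / total) for d, w in zip(doses, weights)]


def _one_per_phenotype_counts(phenos: list[AllelePhenotype]) -> dict[int, float]:
    counts: dict[int, float] = {}
    for p in phenos:
        if p.missing:
            continue
        for a in p.alleles:
            counts[a] = counts.get(a, 0.0) + 1.0
    return counts


def _em_frequencies(
    phenos: list[AllelePhenotype],
    ploidy: int,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> dict[int, float]:
    """EM over dosage completions; deterministic init at per-phenotype counts."""
    observed = [p for p in phenos if not p.missing]
    counts = _one_per_phenotype_counts(observed)
    total = sum(counts.values())
    freqs = {a: c / total for a, c in counts.items()}
    for _ in range(max_iter):
        expected: dict[int, float] = {a: 0.0 for a in freqs}
        for p in observed:
            for d, w in dosage_posterior(p, freqs, ploidy):
                for a, di in zip(p.alleles, d):
                    expected[a] += w * di
        n_total = ploidy * len(observed)
        new = {a: e / n_total for a, e in expected.items()}
        delta = max(abs(new[a] - freqs[a]) for a in freqs)
        freqs = new
        if delta < tol:
            break
    return freqs


def allele_frequencies(
    gm: GenotypeMatrix,
    locus: str,
    mode: EstimationMode = EstimationMode.ONE_PER_PHENOTYPE,
) -> AlleleFrequencySpectrum:
    """Estimate the allele frequency spectrum at one locus.

    ``ONE_PER_PHENOTYPE`` counts each distinct allele observed in a sample
    once (the dosage-agnostic convention); ``EM_DOSAGE`` returns expected
    gene-copy counts under the EM dosage model, scaled so that the copies
    sum to ploidy x (non-missing samples).
    """
    mode = EstimationMode(mode)
    loc = gm.locus(locus)
    phenos = gm.column(locus)
    observed = [p for p in phenos if not p.missing]
    if not observed:
        raise ValueError(f"locus {locus!r}: all calls missing")
    if mode is EstimationMode.ONE_PER_PHENOTYPE:
        counts = _one_per_phenotype_counts(observed)
        n = sum(counts.values())
        return AlleleFrequencySpectrum(
            locus=locus, counts=counts, n_copies=n, estimation_mode=mode
        )
    freqs = _em_frequencies(observed, loc.ploidy)
    n = loc.ploidy * len(observed)
    counts = {a: f * n for a, f in freqs.items() if f * n > 0}
    return AlleleFrequencySpectrum(locus=locus, counts=counts, n_copies=n, estimation_mode=mode)
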