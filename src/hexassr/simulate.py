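"""Synthetic clonal hexaploid SSR germplasm with known generative truth.

The generator emulates a germplasm fingerprinting design: a collection of
clonally propagated hexaploid varieties, each sampled as two plants, typed
at a small panel of EST-derived SSRs (few alleles) and genomic SSRs (many
alleles).  Per locus an allele pool on the repeat-motif grid receives
Dirichlet frequencies; each variety draws its six gene copies from the
pool; clone mates copy the variety genotype apart from rare one-motif
stepwise mutations; scoring is dosage-blind (distinct sizes only) with a
small no-call fraction.  The generative truth (frequencies, dosages,
clone map) is returned for validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from hexassr.genotypes import (
    AllelePhenotype,
    EstimationMode,
    GenotypeMatrix,
    LocusDefinition,
    MarkerClass,
    allele_frequencies,
)

__all__ = ["SimulationConfig", "SimulationTruth", "simulate", "truth_check"]


@dataclass
class SimulationConfig:
    """Generative parameters for the synthetic germplasm.

    Defaults mirror the reference design: 44 varieties x 2 plants,
    hexaploid, 5 EST-SSRs with 6-12 alleles and 5 genomic SSRs with 14-26
    alleles.  ``dirichlet_concentration`` < 1 skews the allele spectra so
    the effective allele number stays well below the allele count
    (realistic R = En/An around 0.2-0.6); ``clonal_mutation_rate`` is the
    per-locus chance that a clone mate carries a single +/-1-motif
    stepwise mutation; ``missing_rate`` is the per-call no-call chance.
    """

    n_varieties: int = 44
    plants_per_variety: int = 2
    ploidy: int = 6
    n_est_loci: int = 5
    est_allele_range: tuple[int, int] = (6, 12)
    n_gssr_loci: int = 5
    gssr_allele_range: tuple[int, int] = (14, 26)
    est_motif_length: int = 3
    gssr_motif_length: int = 2
    dirichlet_concentration: float = 0.3
    clonal_mutation_rate: float = 0.02
    missing_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.est_allele_range, self.gssr_allele_range):
            if not 1 <= lo <= hi:
                raise ValueError("allele ranges must be positive and ordered")
        for rate in (self.clonal_mutation_rate, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.ploidy < 2 or self.ploidy % 2:
            raise ValueError("ploidy must be even and >= 2")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")


@dataclass
class SimulationTruth:
    """Generative record: what the estimators should recover."""

    frequencies: dict[str, dict[int, float]]
    variety_dosages: dict[str, dict[str, tuple[int, ...]]]  # locus -> variety -> copies
    clone_map: dict[str, str]  # sample id -> variety id
    config: SimulationConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "frequencies": {
                loc: {str(a): f for a, f in freqs.items()}
                for loc, freqs in self.frequencies.items()
            },
            "variety_dosages": {
                loc: {v: list(copies) for v, copies in per_var.items()}
                for loc, per_var in self.variety_dosages.items()
            },
            "clone_map": self.clone_map,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self.config).items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _simulate_locus(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    name: str,
    marker_class: MarkerClass,
    motif: int,
    allele_range: tuple[int, int],
) -> tuple[LocusDefinition, dict[int, float], dict[str, tuple[int, ...]], list[AllelePhenotype]]:
    pool_size = int(rng.integers(allele_range[0], allele_range[1] + 1))
    base = int(rng.integers(100, 251))
    base -= base % motif  # anchor the pool on the motif grid
    sizes = [base + motif * i for i in range(pool_size)]
    freqs = rng.dirichlet(np.full(pool_size, cfg.dirichlet_concentration))
    # guard against numerically zero categories, which would make the pool
    # smaller than requested in expectation
    freqs = np.maximum(freqs, 1e-9)
    freqs = freqs / freqs.sum()

    locus = LocusDefinition(name=name, motif_length=motif, marker_class=marker_class, ploidy=cfg.ploidy)
    dosages: dict[str, tuple[int, ...]] = {}
    column: list[AllelePhenotype] = []
    for v in range(cfg.n_varieties):
        vid = f"V{v + 1:02d}"
        copies = tuple(
            int(sizes[i]) for i in rng.choice(pool_size, size=cfg.ploidy, p=freqs)
        )
        dosages[vid] = tuple(sorted(copies))
        for plant in range(cfg.plants_per_variety):
            plant_copies = list(copies)
            if rng.random() < cfg.clonal_mutation_rate:
                which = int(rng.integers(cfg.ploidy))
                step = motif if rng.random() < 0.5 else -motif
                plant_copies[which] = max(motif, plant_copies[which] + step)
            if rng.random() < cfg.missing_rate:
                column.append(AllelePhenotype.no_call())
            else:
                column.append(AllelePhenotype.from_sizes(plant_copies, cfg.ploidy))
    return locus, {int(s): float(f) for s, f in zip(sizes, freqs)}, dosages, column


def simulate(cfg: SimulationConfig) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Draw one synthetic germplasm panel; byte-reproducible given the seed."""
    rng = np.random.default_rng(cfg.seed)
    loci: list[LocusDefinition] = []
    columns: list[list[AllelePhenotype]] = []
    frequencies: dict[str, dict[int, float]] = {}
    variety_dosages: dict[str, dict[str, tuple[int, ...]]] = {}

    plan = [
        (f"EST{i + 1:03d}", MarkerClass.EST, cfg.est_motif_length, cfg.est_allele_range)
        for i in range(cfg.n_est_loci)
    ] + [
        (f"GSSR{i + 1:03d}", MarkerClass.GENOMIC, cfg.gssr_motif_length, cfg.gssr_allele_range)
        for i in range(cfg.n_gssr_loci)
    ]
    for name, mclass, motif, arange_ in plan:
        locus, freqs, dosages, column = _simulate_locus(rng, cfg, name, mclass, motif, arange_)
        loci.append(locus)
        columns.append(column)
        frequencies[name] = freqs
        variety_dosages[name] = dosages

    sample_ids = [
        f"V{v + 1:02d}_{chr(ord('a') + plant)}"
        for v in range(cfg.n_varieties)
        for plant in range(cfg.plants_per_variety)
    ]
    clone_map = {sid: sid.split("_")[0] for sid in sample_ids}
    calls = [[columns[j][i] for j in range(len(loci))] for i in range(len(sample_ids))]
    gm = GenotypeMatrix(sample_ids=sample_ids, loci=loci, calls=calls)
    truth = SimulationTruth(
        frequencies=frequencies,
        variety_dosages=variety_dosages,
        clone_map=clone_map,
        config=cfg,
    )
    return gm, truth


def truth_check(gm: GenotypeMatrix, truth: SimulationTruth) -> dict:
    """Compare panel estimates against the generative truth.

    Per locus: the realized allele count vs the pool size, the EM-dosage
    expected heterozygosity vs the true gene diversity of the generative
    frequencies, and the estimated vs true effective allele number.  Also
    reports the fraction of clone pairs with identical phenotypes at every
    non-missing locus.
    """
    from hexassr.locus_stats import effective_alleles, expected_heterozygosity

    report: dict = {"loci": {}, "clone_pairs": {}}
    for loc in gm.loci:
        freqs = truth.frequencies[loc.name]
        true_sumsq = sum(f * f for f in freqs.values())
        spec = allele_frequencies(gm, loc.name, EstimationMode.ONE_PER_PHENOTYPE)
        em_spec = allele_frequencies(gm, loc.name, EstimationMode.EM_DOSAGE)
        report["loci"][loc.name] = {
            "pool_size": len(freqs),
            "realized_an": spec.n_alleles,
            "true_gene_diversity": 1.0 - true_sumsq,
            "estimated_hs": expected_heterozygosity(gm, loc.name),
            "true_en": 1.0 / true_sumsq,
            "estimated_en": effective_alleles(em_spec),
        }
    # clone fidelity: identical phenotypes across all comparable loci
    by_variety: dict[str, list[int]] = {}
    for i, sid in enumerate(gm.sample_ids):
        by_variety.setdefault(truth.clone_map[sid], []).append(i)
    total, identical = 0, 0
    for members in by_variety.values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                ra, rb = gm.calls[members[a]], gm.calls[members[b]]
                comparable = [
                    (pa, pb) for pa, pb in zip(ra, rb) if not pa.missing and not pb.missing
                ]
                if not comparable:
                    continue
                total += 1
                if all(pa.alleles == pb.alleles for pa, pb in comparable):
                    identical += 1
    report["clone_pairs"] = {
        "n_compared": total,
        "identical_fraction": identical / total if total else float("nan"),
    }
    return report
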