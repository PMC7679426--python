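"""Shared fixtures: hand-built genotype matrices and the published
per-locus reference panels used for arithmetic-reproduction checks."""

from __future__ import annotations

import pytest

from hexassr.genotypes import AllelePhenotype, GenotypeMatrix, LocusDefinition, MarkerClass

# Published per-locus index panels for a hexaploid plum germplasm
# fingerprint (44 varieties; 5 EST-SSRs, 5 genomic SSRs).  Columns:
# An, 1-D, Ev, AR, GD, Ho, GH, Hs, En, R.  Used as *input* data for
# arithmetic summary checks (means, CVs, ratios).
EST_PANEL = {
    "EPPISF001": (12, 0.82, 0.73, 11.07, 0.79, 0.99, 0.66, 0.81, 5.15, 0.43),
    "EPPISF004": (11, 0.73, 0.62, 10.24, 0.67, 1.00, 0.66, 0.58, 2.36, 0.21),
    "EPPISF027": (8, 0.70, 0.71, 7.67, 0.66, 1.00, 0.65, 0.65, 2.77, 0.35),
    "ES4": (6, 0.75, 0.83, 6.00, 0.72, 0.98, 0.47, 0.69, 3.14, 0.52),
    "ES5": (11, 0.71, 0.55, 10.88, 0.65, 0.78, 1.00, 0.97, 2.90, 0.26),
}
GSSR_PANEL = {
    "BPPCT004": (17, 0.90, 0.80, 15.49, 0.89, 1.00, 0.88, 0.88, 8.25, 0.49),
    "BPPCT014": (26, 0.92, 0.70, 24.13, 0.91, 0.94, 0.59, 0.85, 6.24, 0.24),
    "BPPCT028": (14, 0.77, 0.54, 14.00, 0.74, 0.73, 1.00, 1.00, 2.45, 0.17),
    "PS12A02": (21, 0.92, 0.80, 19.27, 0.91, 1.00, 0.72, 0.91, 10.42, 0.47),
    "UDP98409": (18, 0.89, 0.76, 16.72, 0.88, 1.00, 0.59, 0.85, 6.30, 0.35),
}
PANEL_COLUMNS = ("An", "1-D", "Ev", "AR", "GD", "Ho", "GH", "Hs", "En", "R")


def panel_column(panel: dict, name: str) -> list[float]:
    j = PANEL_COLUMNS.index(name)
    return [row[j] for row in panel.values()]


@pytest.fixture
def hexaploid_locus() -> LocusDefinition:
    return LocusDefinition("LOC1", motif_length=3, marker_class=MarkerClass.EST, ploidy=6)


def make_matrix(cells: dict[str, list[tuple[int, ...] | None]], loci=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from {locus: [per-sample allele tuples]}.

    ``None`` marks a no-call; loci default to hexaploid trinucleotide EST
    markers.
    """
    names = list(cells)
    n = len(next(iter(cells.values())))
    if loci is None:
        loci = [
            LocusDefinition(name, motif_length=3, marker_class=MarkerClass.EST, ploidy=6)
            for name in names
        ]
    calls = []
    for i in range(n):
        row = []
        for name in names:
            alleles = cells[name][i]
            if alleles is None:
                row.append(AllelePhenotype.no_call())
            else:
                row.append(AllelePhenotype.from_sizes(alleles))
        calls.append(row)
    return GenotypeMatrix(
        sample_ids=[f"s{i + 1}" for i in range(n)], loci=loci, calls=calls
    )
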