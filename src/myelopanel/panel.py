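"""Bundled description of the 54-gene targeted myeloid panel.

The panel targets genes recurrently mutated in myeloid neoplasms: complete
coding exons of 15 genes and exonic hotspots of 39 genes.  Chromosome
assignments are real (hg-style names) so that X-linked hemizygosity in male
cases is modelled correctly, but the per-gene coordinates used by the
synthetic cohort are synthetic integers, not genome positions.
"""

from __future__ import annotations

from dataclasses import dataclass

# gene -> chromosome. Full-exon genes first, then hotspot genes.
_PANEL_CHROMS = {
    # complete coding exons
    "BCOR": "chrX", "BCORL1": "chrX", "CDKN2A": "chr9", "CEBPA": "chr19",
    "CUX1": "chr7", "DNMT3A": "chr2", "ETV6": "chr12", "EZH2": "chr7",
    "KDM6A": "chrX", "IKZF1": "chr7", "PHF6": "chrX", "RAD21": "chr8",
    "RUNX1": "chr21", "STAG2": "chrX", "ZRSR2": "chrX",
    # exonic hotspots
    "ABL1": "chr9", "ASXL1": "chr20", "ATRX": "chrX", "BRAF": "chr7",
    "CALR": "chr19", "CBL": "chr11", "CBLB": "chr3", "CBLC": "chr19",
    "CSF3R": "chr1", "FBXW7": "chr4", "FLT3": "chr13", "GATA1": "chrX",
    "GATA2": "chr3", "GNAS": "chr20", "HRAS": "chr11", "IDH1": "chr2",
    "IDH2": "chr15", "JAK2": "chr9", "JAK3": "chr19", "KIT": "chr4",
    "KRAS": "chr12", "KMT2A": "chr11", "MPL": "chr1", "MYD88": "chr3",
    "NOTCH1": "chr9", "NPM1": "chr5", "NRAS": "chr1", "PDGFRA": "chr4",
    "PTEN": "chr10", "PTPN11": "chr12", "SETBP1": "chr18", "SF3B1": "chr2",
    "SMC1A": "chrX", "SMC3": "chr10", "SRSF2": "chr17", "TET2": "chr4",
    "TP53": "chr17", "U2AF1": "chr21", "WT1": "chr11",
}

#: Span of each gene's synthetic target interval (positions are 1-based).
GENE_SPAN = 20_000


@dataclass(frozen=True)
class PanelGene:
    name: str
    chrom: str
    start: int  # synthetic 1-based start of the targeted interval
    end: int

    @property
    def x_linked(self) -> bool:
        return self.chrom == "chrX"


def _build_panel():
    genes = {}
    for i, (name, chrom) in enumerate(sorted(_PANEL_CHROMS.items())):
        start = 1_000_000 * (i + 1) + 1
        genes[name] = PanelGene(name, chrom, start, start + GENE_SPAN - 1)
    return genes


#: name -> PanelGene for all 54 panel genes, in alphabetical order.
PANEL_GENES = _build_panel()

GENE_NAMES = tuple(PANEL_GENES)

X_LINKED_GENES = frozenset(g.name for g in PANEL_GENES.values() if g.x_linked)

assert len(PANEL_GENES) == 54
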