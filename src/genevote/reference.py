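"""Published worked-example loci: GWAS susceptibility SNPs for type 2
diabetes and obesity together with the nearby candidate genes reported
from the cross-tissue expression screen, with NCBI-style 1-based
coordinates (GRCh37 era).

These few records are the package's built-in demonstration input for
the ±1 Mb window screen: every listed gene lies within 1 Mb of its
listed SNP(s), and the reported differential-expression percentages let
the screen thresholds (>40% for T2DM, >50% for obesity) be exercised
without any expression data.
"""
from __future__ import annotations

from .types import GeneInterval, SnpRecord

# T2DM arm: SNP-proximal candidate genes and their susceptibility SNPs
T2DM_GENES: list[GeneInterval] = [
    GeneInterval("HIBADH", "chr7", 27_565_059, 27_702_620),
    GeneInterval("TMBIM4", "chr12", 66_530_717, 66_563_807),
]
T2DM_SNPS: list[SnpRecord] = [
    SnpRecord("rs864745", "chr7", 28_180_556),
    SnpRecord("rs849134", "chr7", 28_196_222),
    SnpRecord("rs1531343", "chr12", 66_174_894),
]
# reported differential-expression percentages of the genes above
T2DM_PERCENTAGES: dict[str, float] = {"HIBADH": 42.9, "TMBIM4": 42.9}

# Obesity arm
OBESITY_GENES: list[GeneInterval] = [
    GeneInterval("NCKAP5L", "chr12", 50_184_929, 50_222_208),
    GeneInterval("SP1", "chr12", 53_773_979, 53_810_230),
    GeneInterval("ITGA5", "chr12", 54_789_045, 54_813_050),
    GeneInterval("TOMM5", "chr9", 37_588_410, 37_592_636),
    GeneInterval("HSP90AB1", "chr6", 44_214_849, 44_221_614),
    GeneInterval("BAP1", "chr3", 52_435_024, 52_444_009),
    GeneInterval("GRB14", "chr2", 165_349_323, 165_478_360),
]
OBESITY_SNPS: list[SnpRecord] = [
    SnpRecord("rs7132908", "chr12", 50_263_148),
    SnpRecord("rs1443512", "chr12", 54_342_684),
    SnpRecord("rs16933812", "chr9", 36_969_205),
    SnpRecord("rs6905288", "chr6", 43_758_873),
    SnpRecord("rs6784615", "chr3", 52_506_426),
    SnpRecord("rs10195252", "chr2", 165_513_091),
]
OBESITY_PERCENTAGES: dict[str, float] = {
    "NCKAP5L": 63.6, "SP1": 63.6, "ITGA5": 58.3, "TOMM5": 57.1,
    "HSP90AB1": 55.6, "BAP1": 50.0, "GRB14": 50.0,
}
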