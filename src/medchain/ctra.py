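"""The conserved transcriptional response to adversity (CTRA) indicator set.

A fixed 53-gene leukocyte expression signature: 19 pro-inflammatory
transcripts expected to be up-regulated under chronic adversity, and 34
transcripts expected to be down-regulated (31 type-I interferon response
genes and 3 antibody-synthesis genes).
"""

from __future__ import annotations

#: Pro-inflammatory indicator transcripts (up-regulated component).
CTRA_UP: tuple[str, ...] = (
    "IL1A", "IL1B", "IL6", "IL8", "TNF",
    "PTGS1", "PTGS2",
    "FOS", "FOSB", "FOSL1", "FOSL2",
    "JUN", "JUNB", "JUND",
    "NFKB1", "NFKB2", "REL", "RELA", "RELB",
)

#: Type-I interferon response indicator transcripts (down-regulated component).
CTRA_IFN: tuple[str, ...] = (
    "GBP1", "IFI16", "IFI27", "IFI27L1", "IFI27L2", "IFI30", "IFI35",
    "IFI44", "IFI44L", "IFI6", "IFIH1",
    "IFIT1", "IFIT1L", "IFIT2", "IFIT3", "IFIT5",
    "IFITM1", "IFITM2", "IFITM3", "IFITM4P", "IFITM5",
    "IFNB1", "IRF2", "IRF7", "IRF8",
    "MX1", "MX2", "OAS1", "OAS2", "OAS3", "OASL",
)

#: Antibody-synthesis indicator transcripts (down-regulated component).
CTRA_AB: tuple[str, ...] = ("IGJ", "IGLL1", "IGLL3")

#: The full 53-member CTRA indicator gene list.
CTRA_GENES: tuple[str, ...] = CTRA_UP + CTRA_IFN + CTRA_AB

assert len(CTRA_GENES) == 53
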