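"""Published reference data for the early-CRC metastasis signature.

The 44-probe prognostic signature for metachronous metastasis in early
colorectal carcinoma was discovered on Agilent Whole Human Genome 4x44K
arrays (45 tumors: 33 non-recurrent, 12 later-metastasizing).  Of the 44
probes, 30 carry a gene symbol; 14 of the symbol-bearing genes are
annotated to the GO term "immune system process" (GO:0002376) and form
the immune signature used by the below-median-count classifier.

This module ships those published facts as plain constants so the
enrichment utilities and classifier fixtures can run without any array
download.  The 14 symbol-less probe identifiers of the published table
are not public; they are represented here by clearly synthetic
placeholder ids (``A_SYN_P??``) — only their count and their lack of a
symbol matter to any computation.
"""

from __future__ import annotations

# gene symbol -> designated Agilent probe, for the 14 immune-signature genes
IMMUNE_SIGNATURE_PROBES: dict[str, str] = {
    "BNIP3": "A_23_P138635",
    "CCL18": "A_23_P55270",
    "CD74": "A_23_P70095",
    "CD86": "A_24_P131589",
    "CXCL11": "A_23_P125278",
    "CXCL9": "A_23_P18452",
    "HLA-DMA": "A_23_P42306",
    "HLA-DPB1": "A_23_P258769",
    "HLA-DRB4": "A_24_P370472",
    "HLA-DRB5": "A_23_P31006",
    "IDO1": "A_23_P112026",
    "IGHA1": "A_24_P92683",
    "IGLL1": "A_24_P83102",
    "ORM1": "A_23_P169494",
}

IMMUNE_SIGNATURE_GENES: tuple[str, ...] = tuple(sorted(IMMUNE_SIGNATURE_PROBES))

# The 30 symbol-bearing probes of the published 44-probe signature.
# (probe id, gene symbol); symbols repeat where several probes map to one gene.
SIGNATURE_PROBE_ANNOTATION: tuple[tuple[str, str], ...] = (
    ("A_23_P138635", "BNIP3"),
    ("A_23_P55270", "CCL18"),
    ("A_23_P70095", "CD74"),
    ("A_24_P131589", "CD86"),
    ("A_24_P510357", "CKAP2"),
    ("A_23_P125278", "CXCL11"),
    ("A_23_P18452", "CXCL9"),
    ("A_23_P254944", "GSTT1"),
    ("A_23_P42306", "HLA-DMA"),
    ("A_23_P258769", "HLA-DPB1"),
    ("A_24_P370472", "HLA-DRB4"),
    ("A_23_P31006", "HLA-DRB5"),
    ("A_23_P112026", "IDO1"),
    ("A_23_P119943", "IGFBP2"),
    ("A_23_P158817", "IGHG1"),
    ("A_24_P92683", "IGHA1"),
    ("A_24_P204727", "IGHG1"),
    ("A_24_P315941", "IGHG1"),
    ("A_23_P21249", "IGHG1"),
    ("A_24_P519504", "IGL@"),
    ("A_24_P83102", "IGLL1"),
    ("A_23_P76249", "KRT6B"),
    ("A_23_P1691", "MMP1"),
    ("A_23_P169494", "ORM1"),
    ("A_23_P213508", "PCSK1"),
    ("A_24_P174793", "PCSK1"),
    ("A_23_P149517", "PIGR"),
    ("A_24_P844984", "PIGR"),
    ("A_23_P1962", "RARRES3"),
    ("A_23_P81898", "UBD"),
) + tuple((f"A_SYN_P{i:02d}", "") for i in range(1, 15))  # 14 symbol-less placeholders


# Anchor rows of the published GO over-representation table for the signature:
# (term id, term name, p-value, odds ratio, expected count, overlap a, term size K).
# The selection size n and universe size N were not printed; they are
# reconstructible by integer grid search from the Expected and Odds-ratio
# columns (see enrichment.reconstruct_table_params).
GO_ENRICHMENT_ANCHORS: tuple[dict, ...] = (
    {
        "term_id": "GO:0006955",
        "term_name": "Immune response",
        "pvalue": 1.4e-12,
        "odds_ratio": 31.69,
        "expected": 1.04,
        "count": 13,
        "size": 620,
    },
    {
        "term_id": "GO:0002376",
        "term_name": "Immune system process",
        "pvalue": 4.6e-12,
        "odds_ratio": 26.94,
        "expected": 1.47,
        "count": 14,
        "size": 874,
    },
    {
        "term_id": "GO:0002504",
        "term_name": (
            "Antigen processing and presentation of peptide or "
            "polysaccharide antigen via MHC class II"
        ),
        "pvalue": 1.8e-08,
        "odds_ratio": 208.89,
        "expected": 0.03,
        "count": 4,
        "size": 18,
    },
    {
        "term_id": "GO:0019882",
        "term_name": "Antigen processing and presentation",
        "pvalue": 3.5e-08,
        "odds_ratio": 73.05,
        "expected": 0.10,
        "count": 5,
        "size": 58,
    },
)
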