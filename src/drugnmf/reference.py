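"""Curated reference lists from the published GSE5258 PC3 drug study.

These are small published artifacts of the original analysis of the PC3
drug-induced expression compendium (GEO accession GSE5258, GPL96 platform):
the 30-gene lists each feature-selection method produced, the enriched KEGG
pathway lists per cluster at ranks 2 and 3, the rank-2 drug cluster
memberships, and the reported drug-drug interactions with their common
target genes.  They serve as worked-example inputs for the set-overlap and
interaction-mapping utilities; none of them is required by the algorithms
themselves.

Gene symbols are transcribed as printed (a handful of published entries are
probe ids without a symbol, kept verbatim).
"""

from __future__ import annotations

import pandas as pd

from .interactions import InteractionEdge, edges_from_frame

# 30 genes selected by feature selection via concave minimization (fsv),
# normal vs tumor PC3 samples.  Parenthesized aliases in the published list
# are reduced to the primary symbol; repeated symbols are kept as printed.
FSV_GENES_PC3: list[str] = [
    "TPT1", "COX6A1", "ACTB", "ACTB", "CCDC72", "RPL7",
    "ACTG1", "RPS2", "RPL38", "GAPDH", "S100A6", "EEF1A1",
    "RPS10", "HUWE1", "GAPDH", "RPS18", "ACTB", "FTHP1",
    "RPLP0", "HSPA1A", "ACTG1", "ALDOA", "RPL3", "ALDOA",
    "RPL24", "RPL11", "ODC1", "UBC", "ACTG1", "RPS24",
]

# 30 genes selected by the Fisher discriminant score on the same contrast.
FISHER_GENES_PC3: list[str] = [
    "RPL11", "CCNT1", "EIF4H", "UBE2L6", "SLC36A1", "RPL23",
    "MUC6", "KLHL24", "RPL3", "TNXA", "RPL30", "CAMLG",
    "216138_at", "DES", "HADHA", "ANKRD1", "FGF16", "POLG2",
    "207756_at", "TBCD", "RPL9", "NEBL", "HTR5A", "UBB",
    "RPS18", "RPL32", "217709_at", "LRP2BP", "RPLP0", "EEF1DP5",
]

# Enriched KEGG pathways per cluster from the rank-2 clustering of all genes.
RANK2_PATHWAYS_PC3: dict[int, list[str]] = {
    1: [
        "HSA00531_GLYCOSAMINOGLYCAN_DEGRADATION",
        "HSA00910_NITROGEN_METABOLISM",
        "HSA04950_MATURITY_ONSET_DIABETES_OF_THE_YOUNG",
        "HSA00565_ETHER_LIPID_METABOLISM",
        "HSA04080_NEUROACTIVE_LIGAND_RECEPTOR_INTERACTION",
        "HSA04742_TASTE_TRANSDUCTION",
    ],
    2: [
        "HSA00040_PENTOSE_AND_GLUCURONATE_INTERCONVERSIONS",
        "HSA03050_PROTEASOME",
        "HSA03010_RIBOSOME",
        "HSA03060_PROTEIN_EXPORT",
        "HSA00680_METHANE_METABOLISM",
        "HSA00062_FATTY_ACID_ELONGATION_IN_MITOCHONDRIA",
    ],
}

# Enriched pathways per cluster from the rank-3 clustering.
RANK3_PATHWAYS_PC3: dict[int, list[str]] = {
    1: [
        "HSA00563_GLYCOSYLPHOSPHATIDYLINOSITOL_ANCHOR_BIOSYNTHESIS",
        "HSA00531_GLYCOSAMINOGLYCAN_DEGRADATION",
        "HSA00910_NITROGEN_METABOLISM",
        "HSA04614_RENIN_ANGIOTENSIN_SYSTEM",
        "HSA00565_ETHER_LIPID_METABOLISM",
    ],
    2: [
        "HSA00602_GLYCOSPHINGOLIPID_BIOSYNTHESIS_NEO_LACTOSERIES",
        "HSA04060_CYTOKINE_CYTOKINE_RECEPTOR_INTERACTION",
        "HSA00430_TAURINE_AND_HYPOTAURINE_METABOLISM",
        "HSA04740_OLFACTORY_TRANSDUCTION",
        "HSA04940_TYPE_I_DIABETES_MELLITUS",
    ],
    3: [
        "HSA03010_RIBOSOME",
        "HSA00040_PENTOSE_AND_GLUCURONATE_INTERCONVERSIONS",
        "HSA03060_PROTEIN_EXPORT",
        "HSA03050_PROTEASOME",
        "HSA00720_REDUCTIVE_CARBOXYLATE_CYCLE",
    ],
}

# Rank-2 drug cluster memberships (all-gene clustering; unique drugs).
RANK2_DRUG_CLUSTERS_PC3: dict[str, int] = {
    # cluster 1
    "LY-294002": 1, "rosiglitazone": 1, "troglitazone": 1,
    "17-allylamino-geldanamycin": 1, "valproic acid": 1,
    "sodium phenylbutyrate": 1, "novobiocin": 1, "fasudil": 1,
    "diclofenac": 1, "15-delta prostaglandin J2": 1, "tretinoin": 1,
    "trichostatin A": 1, "monorden": 1, "TTNPB": 1, "indomethacin": 1,
    "tetraethylenepentamine": 1, "rofecoxib": 1, "copper sulfate": 1,
    "celecoxib": 1, "imatinib": 1, "pirinixic acid": 1,
    # cluster 2
    "fulvestrant": 2, "genistein": 2, "alpha-estradiol": 2, "monastrol": 2,
    "mercaptopurine": 2, "butirosin": 2, "estradiol": 2,
    "docosahexaenoic acid ethyl ester": 2, "U0125": 2, "resveratrol": 2,
    "splitomicin": 2, "dimethyloxalylglycine": 2, "HNMPA-(AM)3": 2,
    "butein": 2, "fisetin": 2, "4,5-dianilinophthalimide": 2,
    "deferoxamine": 2,
}

# Reported drug-drug interactions with common target genes
# (STITCH / DrugBank evidence as summarized by the study).
_EDGE_ROWS: list[tuple[str, str, str]] = [
    ("estradiol", "rosiglitazone", "RETN"),
    ("estradiol", "valproic acid", "CYP19A1,ESR1,ESR2,PTGS1"),
    ("estradiol", "diclofenac", "PTGS2,CYP2A6"),
    ("estradiol", "tretinoin", "RARA,AR,ESR1,ESR2,HSD17B1"),
    ("estradiol", "genistein", "AR,ESR1,ESR2,SHBG,CYP19A1"),
    ("estradiol", "fisetin", "AR"),
    ("estradiol", "resveratrol", "ESR1,ESR2,CYP19A1"),
    ("estradiol", "fulvestrant", "AR,ESR1,ESR2"),
    ("estradiol", "alpha-estradiol", "ESR1,ESR2,CYP19A1,PRL"),
    ("valproic acid", "diclofenac", "ABCB1,CYP3A4,CYP2C19,CYP2C9"),
    ("valproic acid", "tretinoin", ""),
    ("valproic acid", "rosiglitazone", "LEP"),
    ("valproic acid", "sodium phenylbutyrate", ""),
    ("tretinoin", "diclofenac", "PTGS1,PTGS2,PPARG"),
    ("tretinoin", "rosiglitazone", "PTGS2,PPARG,RXRA"),
    ("celecoxib", "diclofenac", "PTGS1,PTGS2,CYP2C9,VEGFA"),
    ("celecoxib", "rofecoxib", "PTGS1,PTGS2"),
    ("celecoxib", "indomethacin", "PTGS1,PTGS2"),
    ("rofecoxib", "indomethacin", "PTGS1,PTGS2"),
    ("troglitazone", "rosiglitazone", "PPARA,RXRA,UCP2,RETN,LEP,CD36"),
]


def pc3_reference_edges() -> list[InteractionEdge]:
    """The reported PC3 drug-interaction edges as validated edge objects."""
    frame = pd.DataFrame(_EDGE_ROWS, columns=["drug_a", "drug_b", "common_genes"])
    frame["source"] = "stitch"
    return edges_from_frame(frame)


def pc3_drug_clusters() -> dict[str, frozenset[int]]:
    """Rank-2 drug cluster memberships in drug_cluster_map's output form."""
    return {d: frozenset({c}) for d, c in RANK2_DRUG_CLUSTERS_PC3.items()}
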