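"""Published reference values for the eight-rhizotoxin rice root study.

These are transcribed from the published integrative analysis of rice
root transcriptomes under eight rhizotoxins (Cu, As(V), Cd, Hg, Cr, V,
ferulic acid, juglone): the per-stress differential-expression count
table, the promoter-motif enrichment percentages for GSR versus
background promoters, and the qPCR fold inductions of the cadmium
biomarker candidate (a phosphoenolpyruvate carboxylase kinase,
LOC_Os02g41580 / OsPPCK2) under combined-metal panels.

They serve two purposes: the count table is the input for the summary
arithmetic-identity checks, and the motif/biomarker values parameterize
worked examples and screens.  Note two arithmetic slips in the printed
count table: the Cd row's uniquely-regulated count (39) differs from its
uniquely-up + uniquely-down (17 + 20 = 37), and the Cr row's DEG count
(2498) differs from its up + down (1801 + 688 = 2489).  They are kept as
printed; identity checks skip those two cells.
"""

from __future__ import annotations

import pandas as pd

#: Per-stress counts as printed: DEGs, up, down, uniquely regulated / up / down.
PER_STRESS_COUNTS = pd.DataFrame(
    {
        "DEGs":          [2666, 4675, 2577, 4029, 2498, 3869, 2476, 3033],
        "up_regulated":  [1768, 2527, 1836, 2101, 1801, 2486, 1742, 2055],
        "down_regulated": [898, 2148,  741, 1928,  688, 1383,  734,  978],
        "uniquely_regulated": [22, 340, 39, 53, 16, 75, 23, 23],
        "uniquely_up":   [12, 64, 17, 31, 9, 62, 18, 6],
        "uniquely_down": [10, 276, 20, 22, 7, 13, 5, 17],
    },
    index=pd.Index(["Cu", "As(V)", "Cd", "Hg", "Cr", "V", "FA", "juglone"],
                   name="stress"),
)

#: Global pattern-class counts (identical in every per-stress row).
GLOBAL_CLASS_COUNTS = {
    "generally_up_GSR": 539,
    "generally_down": 38,
    "background_genes": 530,
    "low_regulated": 66,
}

#: Printed non-redundant totals (Sum row).
NONREDUNDANT_TOTALS = {
    "DEGs": 8737,
    "up_regulated": 4696,
    "down_regulated": 4476,
    "uniquely_regulated": 591,
    "uniquely_up": 219,
    "uniquely_down": 370,
    "generally_regulated": 577,
}

#: Rows of the printed count table whose DEGs = up + down identity holds
#: (Cr is excluded: 1801 + 688 = 2489, printed 2498).
CONSISTENT_DEG_ROWS = ("Cu", "As(V)", "Cd", "Hg", "V", "FA", "juglone")

#: Rows where uniquely_regulated = uniquely_up + uniquely_down holds
#: (Cd is excluded: 17 + 20 = 37, printed 39).
CONSISTENT_UNIQUE_ROWS = ("Cu", "As(V)", "Hg", "Cr", "V", "FA", "juglone")

#: Promoter-motif enrichment in 1 kb upstream regions, GSR vs background
#: promoters: per-gene presence percentages and permutation p-values.
MOTIF_ENRICHMENT = pd.DataFrame(
    {
        "motif": ["TTGACY", "BACGTGKM", "CGCGTT", "SCGCGCS"],
        "name": ["W-box", "ABRE-like", "RWRE", "CGCG box"],
        "pct_gsr": [51.54, 19.71, 12.53, 31.83],
        "pct_background": [31.38, 13.36, 6.07, 21.86],
        "p_value": [0.0, 0.0146, 0.0004, 0.0],
    }
).set_index("motif")

#: Metal/metalloid stressors used in the combined-stress panels.
PANEL_METALS = ("As(V)", "Cd", "Hg", "Cu", "Cr")

#: qPCR fold inductions of the Cd biomarker candidate under the five
#: leave-one-out combined panels (each panel = 4 of the 5 metals).  The
#: per-panel attribution of the Cd-containing folds is not printed; only
#: the multiset matters for the specificity ratio.
CD_BIOMARKER_PANEL_FOLDS_WITH_CD = (17.0, 23.0, 81.0, 165.0)
CD_BIOMARKER_PANEL_FOLD_WITHOUT_CD = 3.3

#: Single-stress qPCR induction of the candidate under Cd at 3 h.
CD_BIOMARKER_SINGLE_CD_FOLD = 9.0
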