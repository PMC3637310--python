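"""Packaged worked-example fixture: estrogen-responsive probe fold changes.

Published fold changes (treatment/control) for the strongly
estradiol-responsive probe sets on the Affymetrix HG-U133 Plus 2.0 array in
MCF-7 cells, for the reference estradiol treatment (E2, 0.1 uM) and the two
upper query doses (SH = 2.56 mg/ml, SM = 0.256 mg/ml). 36 up-regulated and
8 down-regulated rows as printed, values to two decimals. The source text
describes a 45-probe set with 9 down-regulated probes, but only 8 down rows
were printed; this fixture carries exactly the 44 printed rows.
"""

from __future__ import annotations

# (probe_id, gene_symbol, description, fc_e2, fc_sh, fc_sm, direction)
TABLE1_ROWS: list[tuple[str, str, str, float, float, float, str]] = [
    ("237460_x_at", "C14orf182", "chromosome 14 open reading frame 182", 13.77, 6.29, 1.18, "up"),
    ("228554_at", "PGR", "progesterone receptor", 12.10, 2.83, 1.72, "up"),
    ("205862_at", "GREB1", "growth regulation by estrogen in breast cancer 1", 10.87, 5.08, 2.37, "up"),
    ("206115_at", "EGR3", "early growth response 3", 10.69, 10.70, 1.65, "up"),
    ("235004_at", "RBM24", "RNA binding motif protein 24", 10.23, 6.07, 1.57, "up"),
    ("1557277_a_at", "", "", 8.71, 2.08, 1.32, "up"),
    ("231120_x_at", "PKIB", "protein kinase (cAMP-dependent, catalytic) inhibitor beta", 7.96, 2.29, 1.27, "up"),
    ("219525_at", "SLC47A1", "solute carrier family 47, member 1", 7.93, 2.22, 1.40, "up"),
    ("205440_s_at", "NPY1R", "neuropeptide Y receptor Y1", 7.08, 2.81, 1.84, "up"),
    ("44790_s_at", "C13orf18", "chromosome 13 open reading frame 18", 7.08, 2.97, 2.59, "up"),
    ("213906_at", "MYBL1", "v-myb myeloblastosis viral oncogene homolog (avian)-like 1", 6.78, 1.26, 1.29, "up"),
    ("220038_at", "SGK3", "serum/glucocorticoid regulated kinase family, member 3", 6.63, 1.79, 1.51, "up"),
    ("222921_s_at", "HEY2", "hairy/enhancer-of-split related with YRPW motif 2", 6.11, 2.88, 1.59, "up"),
    ("228241_at", "AGR3", "anterior gradient homolog 3 (Xenopus laevis)", 6.08, 2.55, 1.84, "up"),
    ("204798_at", "MYB", "v-myb myeloblastosis viral oncogene homolog (avian)", 5.96, 2.37, 1.92, "up"),
    ("227627_at", "SGK3", "serum/glucocorticoid regulated kinase family, member 3", 5.83, 1.69, 1.54, "up"),
    ("208018_s_at", "HCK", "hemopoietic cell kinase", 5.77, 1.33, 1.02, "up"),
    ("239777_at", "C14orf182", "chromosome 14 open reading frame 182", 5.63, 3.29, 1.27, "up"),
    ("207886_s_at", "CALCR", "calcitonin receptor", 5.38, 2.59, 1.86, "up"),
    ("232306_at", "CDH26", "cadherin 26", 5.37, 3.51, 1.94, "up"),
    ("219743_at", "HEY2", "hairy/enhancer-of-split related with YRPW motif 2", 5.30, 1.83, 1.37, "up"),
    ("208305_at", "PGR", "progesterone receptor", 5.22, 1.69, 1.10, "up"),
    ("223551_at", "PKIB", "protein kinase (cAMP-dependent, catalytic) inhibitor beta", 5.18, 2.13, 1.42, "up"),
    ("211421_s_at", "RET", "ret proto-oncogene", 4.98, 1.54, 1.19, "up"),
    ("205326_at", "RAMP3", "receptor (G protein-coupled) activity modifying protein 3", 4.67, 2.35, 1.87, "up"),
    ("244745_at", "RERG", "RAS-like, estrogen-regulated, growth inhibitor", 4.61, 1.43, 1.51, "up"),
    ("237334_at", "", "", 4.55, 2.25, 1.34, "up"),
    ("219702_at", "PLAC1", "placenta-specific 1", 4.45, 2.02, 1.09, "up"),
    ("223201_s_at", "TMEM164", "transmembrane protein 164", 4.44, 1.68, 1.23, "up"),
    ("219825_at", "CYP26B1", "cytochrome P450, family 26, subfamily B, polypeptide 1", 4.42, 1.26, 1.19, "up"),
    ("224428_s_at", "CDCA7", "cell division cycle associated 7", 4.39, 1.11, 1.45, "up"),
    ("209687_at", "CXCL12", "chemokine (C-X-C motif) ligand 12", 4.31, 1.77, 1.29, "up"),
    ("242064_at", "SDK2", "sidekick homolog 2 (chicken)", 4.25, 1.48, 0.99, "up"),
    ("219985_at", "HS3ST3A1", "heparan sulfate (glucosamine) 3-O-sulfotransferase 3A1", 4.17, 2.01, 1.40, "up"),
    ("220486_x_at", "TMEM164", "transmembrane protein 164", 4.09, 1.64, 1.22, "up"),
    ("201739_at", "SGK1", "serum/glucocorticoid regulated kinase 1", 4.01, 1.86, 1.29, "up"),
    ("242943_at", "ST8SIA4", "ST8 alpha-N-acetyl-neuraminide alpha-2,8-sialyltransferase 4", 0.31, 0.40, 0.85, "down"),
    ("202948_at", "IL1R1", "interleukin 1 receptor, type I", 0.32, 0.40, 0.78, "down"),
    ("229354_at", "AHRR", "aryl-hydrocarbon receptor repressor", 0.33, 0.83, 0.80, "down"),
    ("230261_at", "ST8SIA4", "ST8 alpha-N-acetyl-neuraminide alpha-2,8-sialyltransferase 4", 0.36, 0.41, 0.88, "down"),
    ("230836_at", "ST8SIA4", "ST8 alpha-N-acetyl-neuraminide alpha-2,8-sialyltransferase 4", 0.37, 0.35, 0.88, "down"),
    ("228176_at", "EDG3", "endothelial differentiation, sphingolipid G-protein-coupled receptor, 3", 0.38, 0.67, 0.95, "down"),
    ("205749_at", "CYP1A1", "cytochrome P450, family 1, subfamily A, polypeptide 1", 0.38, 1.76, 0.97, "down"),
    ("213413_at", "BG434174", "STON1", 0.39, 0.27, 0.63, "down"),
]
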