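"""Reference values from the colorectal MSRE methylation study.

Per-gene, per-group mean +/- SD methylation percentages for the 55 genes the
study reported as hypermethylated in at least one group, the printed per-group
hypermethylation prevalences for the top genes, cohort group sizes, KRAS/BRAF
mutation counts, and the RFLP assay fragment map.  These numbers parameterize
the synthetic-cohort generator and anchor the table-reconstruction tests; they
are study-reported summaries, not raw data.
"""

from __future__ import annotations

# Histological groups, in canonical (reporting) order.
GROUPS: tuple[str, ...] = ("Y", "N", "CN", "F", "LGD", "HGD", "CRC", "MCRC", "UCi", "UCa")

# Cohort sizes per group (biopsy samples).
GROUP_SIZES: dict[str, int] = {
    "Y": 5, "N": 5, "CN": 5, "F": 5,
    "LGD": 17, "HGD": 6, "CRC": 17, "MCRC": 7,
    "UCi": 4, "UCa": 4,
}

# Non-metastatic tumor groups pooled in the "Tumors (n = 40)" column.
TUMOR_GROUPS: tuple[str, ...] = ("LGD", "HGD", "CRC")

# Ten-gene hypermethylation signature (>= 85% of pooled tumor samples).
SIGNATURE_GENES: tuple[str, ...] = (
    "SFRP1", "SST", "BNC1", "MAL", "SLIT2",
    "SFRP2", "SLIT3", "ALDH1A3", "TMEFF2", "WIF1",
)

# Printed gene classes:
#   A - commonly methylated in >95% of all samples,
#   B - methylated in all tumorous groups including MCRC,
#   C - methylated only in LGD, HGD and stage I-III CRC,
#   D - individually methylated in certain groups.
GENE_CLASSES: dict[str, tuple[str, ...]] = {
    "A": ("BAGE", "CCNA1", "H19", "MAGEA1", "MSX1", "PTGIS", "RUNX3", "SPARC", "UGT1A1"),
    "B": ("BNC1", "SST"),
    "C": (
        "ADAMTS1", "ALDH1A3", "ALX4", "CDH13", "DKK2", "DKK3", "GALR2", "HLTF",
        "hsa-mir-342", "LRRC3B", "MAL", "NID1", "OPCML", "PAX2", "PCDH10", "PDLIM4",
        "RBP1", "RPRM", "SFRP1", "SFRP2", "SLC16A12", "SLIT2", "SLIT3", "TAC1",
        "TMEFF2", "UCHL1", "VIM", "WIF1",
    ),
    "D": (
        "DAB2IP", "HS3ST2", "IGFBP3", "WT1", "CALCA", "MCC", "BMP3", "CHFR",
        "DACT2", "EYA2", "NKX2", "SFRP5", "SLC5A8", "TFAP2C", "WNT5A", "WRN",
    ),
}

# Mean +/- SD methylation percent per gene, columns in GROUPS order:
# (Y, N, CN, F, LGD, HGD, CRC, MCRC, UCi, UCa) as (mean, sd) pairs.
GROUP_MOMENTS: dict[str, tuple[tuple[float, float], ...]] = {
    # class A
    "BAGE": ((97.39, 1.32), (76.0, 15.83), (79.72, 11.97), (66.2, 21.11), (95.43, 3.35),
             (93.46, 8.09), (82.52, 18.2), (90.0, 11.83), (76.65, 5.61), (78.4, 7.83)),
    "CCNA1": ((2.75, 1.48), (30.76, 23.14), (24.74, 10.49), (18.17, 10.12), (67.1, 23.44),
              (61.99, 17.72), (43.94, 9.66), (33.46, 9.6), (23.7, 20.65), (8.96, 4.12)),
    "H19": ((47.91, 2.89), (46.33, 5.82), (37.36, 7.5), (37.17, 11.42), (33.95, 13.46),
            (38.72, 15.54), (44.16, 17.53), (42.35, 4.89), (40.96, 12.74), (46.39, 6.27)),
    "MAGEA1": ((98.18, 1.14), (73.73, 13.92), (86.44, 9.69), (90.08, 4.23), (79.14, 33.83),
               (61.85, 44.1), (76.63, 25.96), (90.23, 13.21), (63.94, 15.08), (80.93, 7.84)),
    "MSX1": ((13.9, 3.3), (17.26, 3.96), (20.2, 10.87), (15.66, 5.46), (66.64, 24.29),
             (57.98, 14.36), (46.63, 17.95), (29.4, 7.3), (34.95, 17.57), (20.57, 4.08)),
    "PTGIS": ((22.95, 13.09), (43.84, 10.57), (49.64, 4.72), (43.29, 10.54), (79.98, 17.71),
              (79.14, 17.34), (59.71, 15.84), (56.29, 18.53), (44.67, 20.47), (39.43, 11.62)),
    "RUNX3": ((34.95, 11.62), (42.96, 12.45), (38.94, 7.53), (37.9, 10.99), (71.33, 21.56),
              (69.82, 12.09), (58.52, 13.82), (52.39, 9.39), (41.59, 13.79), (56.96, 5.15)),
    "SPARC": ((21.42, 8.49), (42.08, 10.87), (42.86, 6.75), (38.97, 11.28), (65.02, 19.86),
              (49.02, 33.01), (46.86, 15.24), (45.43, 6.01), (31.75, 17.67), (31.34, 15.04)),
    "UGT1A1": ((84.15, 6.49), (51.13, 3.28), (86.53, 8.32), (85.75, 5.88), (91.49, 9.46),
               (89.29, 10.02), (94.9, 4.69), (81.26, 22.83), (47.49, 3.42), (58.42, 3.94)),
    # class B
    "BNC1": ((2.02, 1.0), (16.37, 17.49), (11.67, 8.14), (8.71, 5.11), (63.95, 24.45),
             (53.8, 17.43), (31.99, 14.53), (20.15, 3.63), (12.84, 10.01), (7.83, 3.86)),
    "SST": ((3.56, 1.96), (12.07, 10.84), (11.99, 5.51), (8.35, 6.42), (35.57, 23.77),
            (49.74, 23.41), (30.98, 14.29), (15.53, 8.99), (7.42, 5.09), (6.99, 3.88)),
    # class C
    "ADAMTS1": ((0.56, 0.66), (0.37, 0.34), (0.49, 0.75), (0.52, 0.39), (19.38, 29.92),
                (43.26, 35.45), (18.18, 19.41), (1.23, 0.87), (0.83, 0.57), (0.15, 0.57)),
    "ALDH1A3": ((0.75, 0.45), (4.12, 3.32), (3.77, 1.9), (2.82, 1.69), (53.95, 38.12),
                (74.36, 18.83), (37.22, 23.74), (6.73, 2.64), (3.61, 2.74), (2.62, 1.19)),
    "ALX4": ((0.72, 0.59), (0.69, 0.57), (0.8, 0.84), (0.72, 0.2), (33.94, 35.79),
             (51.47, 41.78), (27.76, 26.83), (1.26, 1.04), (1.34, 0.98), (0.94, 0.42)),
    "CDH13": ((1.6, 0.92), (1.23, 0.85), (3.93, 3.82), (2.47, 0.98), (32.79, 34.53),
              (33.47, 27.99), (25.75, 25.35), (3.7, 2.82), (2.42, 2.64), (3.08, 1.56)),
    "DKK2": ((4.21, 0.93), (8.6, 4.47), (5.09, 3.25), (4.13, 0.99), (39.93, 25.97),
             (46.7, 17.31), (31.54, 18.05), (7.04, 2.99), (11.13, 13.86), (9.11, 4.77)),
    "DKK3": ((1.61, 1.45), (1.95, 0.52), (2.02, 2.76), (1.31, 0.19), (21.04, 28.46),
             (32.3, 32.37), (23.36, 19.79), (4.76, 5.03), (2.89, 2.56), (1.9, 1.03)),
    "GALR2": ((2.24, 1.02), (2.2, 1.65), (3.71, 2.38), (2.18, 0.51), (37.63, 33.64),
              (50.16, 29.88), (25.88, 24.27), (5.79, 4.12), (4.6, 2.73), (4.33, 2.42)),
    "HLTF": ((5.06, 1.44), (5.39, 1.79), (4.45, 1.34), (4.78, 1.51), (19.71, 15.27),
             (33.01, 27.9), (18.36, 15.74), (8.17, 4.72), (6.35, 7.34), (8.91, 4.6)),
    "hsa-mir-342": ((0.53, 0.5), (1.18, 1.61), (2.82, 2.98), (2.14, 3.09), (42.73, 22.86),
                    (17.71, 27.98), (21.27, 16.69), (3.81, 3.23), (0.39, 0.33), (0.4, 0.27)),
    "LRRC3B": ((1.44, 0.93), (3.59, 3.61), (1.96, 1.2), (1.1, 0.66), (26.39, 12.0),
               (35.55, 24.78), (12.68, 10.04), (4.94, 1.81), (3.1, 2.77), (2.14, 1.34)),
    "MAL": ((1.03, 0.49), (2.65, 3.28), (3.71, 4.06), (1.75, 0.83), (51.79, 30.94),
            (41.39, 30.32), (37.14, 18.83), (10.21, 9.15), (1.38, 0.99), (1.49, 0.63)),
    "NID1": ((1.26, 0.83), (1.43, 0.64), (1.52, 1.52), (1.13, 0.23), (26.86, 29.06),
             (24.35, 29.84), (19.33, 19.46), (2.28, 2.12), (2.55, 1.6), (1.78, 0.92)),
    "OPCML": ((2.49, 1.05), (9.96, 11.52), (13.03, 11.34), (7.13, 3.54), (47.01, 19.98),
              (38.1, 12.77), (20.62, 15.2), (12.54, 3.24), (8.74, 10.68), (4.79, 1.95)),
    "PAX2": ((1.16, 0.5), (0.81, 0.65), (1.19, 1.04), (1.26, 1.02), (26.5, 34.37),
             (42.74, 37.46), (19.97, 19.1), (1.23, 1.33), (1.49, 1.73), (0.99, 0.53)),
    "PCDH10": ((1.53, 0.52), (3.44, 1.4), (3.98, 1.89), (3.4, 1.24), (44.79, 29.1),
               (57.28, 35.04), (21.77, 18.49), (7.43, 5.2), (7.73, 10.11), (3.65, 1.8)),
    "PDLIM4": ((2.75, 0.99), (12.22, 11.22), (7.14, 3.09), (7.48, 4.1), (40.94, 39.99),
               (77.39, 20.48), (28.69, 21.67), (12.48, 7.97), (13.24, 8.87), (7.05, 3.16)),
    "RBP1": ((1.18, 0.52), (1.44, 0.81), (3.08, 2.29), (1.15, 0.45), (42.22, 39.03),
             (39.55, 38.0), (20.34, 13.8), (3.88, 4.7), (1.57, 1.79), (1.9, 0.86)),
    "RPRM": ((2.19, 0.95), (2.97, 1.62), (4.38, 1.87), (2.81, 0.66), (25.62, 28.93),
             (26.88, 33.0), (21.41, 19.23), (10.25, 6.48), (8.4, 6.9), (4.76, 1.26)),
    "SFRP1": ((0.52, 0.36), (4.95, 4.69), (4.95, 4.62), (3.12, 2.48), (60.66, 25.27),
              (54.93, 30.99), (31.67, 16.36), (7.56, 2.1), (8.16, 12.89), (3.23, 2.91)),
    "SFRP2": ((1.79, 1.26), (1.55, 0.99), (2.33, 2.39), (2.27, 0.64), (48.49, 34.63),
              (51.63, 30.57), (27.49, 14.35), (5.26, 4.52), (2.51, 1.82), (2.5, 0.72)),
    "SLC16A12": ((0.85, 0.94), (0.89, 0.63), (1.64, 1.67), (0.92, 0.23), (25.78, 29.43),
                 (41.5, 39.64), (21.53, 21.37), (2.24, 1.3), (4.04, 4.44), (1.76, 0.94)),
    "SLIT2": ((1.68, 0.89), (2.58, 2.0), (6.93, 8.21), (4.05, 1.89), (58.58, 32.95),
              (47.79, 29.48), (26.32, 17.86), (9.12, 3.4), (6.85, 6.02), (4.06, 1.87)),
    "SLIT3": ((0.61, 0.3), (2.49, 2.81), (1.36, 1.02), (1.25, 0.43), (38.44, 30.9),
              (41.46, 22.63), (27.08, 21.36), (5.78, 8.52), (4.93, 5.52), (1.39, 0.56)),
    "TAC1": ((2.2, 1.63), (6.0, 4.42), (4.73, 2.38), (8.9, 8.73), (22.51, 27.98),
             (30.17, 16.38), (18.84, 19.05), (15.36, 10.11), (15.39, 14.47), (6.13, 2.19)),
    "TMEFF2": ((1.36, 0.71), (1.23, 1.07), (1.93, 1.69), (1.46, 1.05), (45.87, 31.23),
               (53.79, 40.26), (25.27, 17.33), (7.5, 7.49), (2.73, 4.09), (1.94, 0.63)),
    "UCHL1": ((2.83, 1.21), (2.68, 2.3), (2.07, 2.23), (2.43, 0.04), (29.26, 35.0),
              (57.78, 34.35), (23.29, 17.5), (6.27, 6.03), (2.24, 1.62), (3.79, 1.9)),
    "VIM": ((1.54, 0.65), (0.65, 0.5), (0.89, 0.99), (0.84, 0.88), (40.03, 34.38),
            (46.53, 40.81), (27.35, 22.14), (3.32, 3.86), (2.0, 1.63), (1.92, 1.27)),
    "WIF1": ((2.63, 1.62), (8.14, 6.78), (13.75, 8.8), (8.59, 5.34), (44.27, 30.0),
             (49.89, 40.45), (30.32, 21.16), (19.1, 16.62), (16.22, 20.39), (4.61, 3.89)),
    # class D
    "DAB2IP": ((1.12, 0.35), (1.35, 0.18), (0.8, 0.4), (0.59, 0.21), (20.01, 26.99),
               (27.52, 23.65), (8.7, 7.24), (6.33, 10.34), (2.81, 0.49), (0.73, 0.25)),
    "HS3ST2": ((1.35, 0.6), (1.36, 0.12), (1.16, 1.02), (0.81, 0.03), (31.13, 36.33),
               (29.69, 26.42), (13.45, 12.23), (1.88, 1.55), (3.28, 1.01), (0.78, 0.16)),
    "IGFBP3": ((0.23, 0.32), (0.22, 0.26), (0.3, 0.29), (0.29, 0.21), (11.03, 15.37),
               (22.92, 30.86), (11.98, 18.37), (0.5, 0.5), (1.0, 1.18), (0.47, 0.2)),
    "WT1": ((0.44, 0.25), (0.73, 0.56), (0.97, 1.07), (0.4, 0.34), (22.06, 31.12),
            (31.78, 31.99), (12.99, 19.58), (1.18, 1.15), (1.78, 1.86), (0.85, 0.84)),
    "CALCA": ((8.37, 1.09), (8.78, 2.71), (8.22, 4.01), (13.57, 11.74), (8.72, 4.24),
              (30.74, 27.13), (18.92, 14.32), (12.29, 5.2), (14.52, 9.31), (18.07, 3.38)),
    "MCC": ((4.74, 1.71), (2.78, 1.19), (2.89, 1.87), (2.12, 0.93), (11.99, 14.96),
            (34.09, 28.85), (17.38, 15.11), (6.87, 6.61), (3.61, 2.91), (5.87, 3.14)),
    "BMP3": ((0.17, 0.23), (0.12, 0.02), (0.18, 0.26), (0.07, 0.02), (8.65, 18.27),
             (31.09, 30.12), (9.46, 13.85), (0.21, 0.27), (0.27, 0.07), (0.07, 0.01)),
    "CHFR": ((0.46, 0.09), (0.41, 0.23), (0.3, 0.16), (0.35, 0.08), (6.83, 11.39),
             (20.56, 27.57), (5.4, 6.1), (0.25, 0.53), (0.42, 0.74), (0.28, 0.18)),
    "DACT2": ((0.67, 0.17), (0.75, 0.39), (1.26, 1.02), (1.17, 0.6), (4.23, 6.02),
              (33.62, 31.64), (6.41, 11.25), (1.82, 1.69), (2.14, 1.89), (2.3, 0.64)),
    "EYA2": ((2.06, 0.96), (0.55, 0.5), (1.16, 1.46), (1.0, 0.27), (3.6, 5.86),
             (30.98, 37.86), (10.84, 16.92), (1.4, 1.37), (2.24, 1.47), (2.07, 1.0)),
    "NKX2": ((0.78, 0.62), (0.88, 0.48), (0.68, 0.72), (0.55, 0.12), (6.82, 8.83),
             (34.85, 41.31), (6.17, 10.95), (1.26, 0.67), (1.83, 0.56), (1.2, 0.42)),
    "SFRP5": ((2.51, 1.58), (2.61, 1.93), (1.12, 1.21), (0.95, 0.36), (15.57, 27.23),
              (15.35, 10.84), (9.24, 10.4), (2.09, 1.36), (2.95, 0.8), (3.3, 1.86)),
    "SLC5A8": ((0.85, 0.44), (3.42, 3.73), (2.69, 1.75), (3.58, 1.29), (12.15, 13.15),
               (34.12, 42.53), (11.46, 19.21), (4.59, 3.11), (2.24, 0.81), (3.52, 1.01)),
    "TFAP2C": ((2.43, 1.06), (0.99, 1.19), (1.1, 1.37), (0.63, 0.42), (12.47, 19.71),
               (26.11, 38.62), (7.27, 15.74), (1.78, 2.38), (1.9, 0.9), (3.16, 1.47)),
    "WNT5A": ((0.37, 0.38), (0.05, 0.07), (0.03, 0.03), (0.0, 0.0), (0.75, 2.19),
              (21.44, 31.86), (0.8, 2.17), (0.18, 0.35), (0.17, 0.32), (0.05, 0.1)),
    "WRN": ((1.75, 0.79), (1.51, 0.16), (3.55, 1.01), (3.68, 1.03), (2.82, 1.89),
            (19.17, 16.27), (5.7, 7.5), (2.41, 1.22), (3.73, 1.14), (1.24, 0.59)),
}

PANEL_GENES: tuple[str, ...] = tuple(GROUP_MOMENTS)

# Printed per-group "Methylated cases (%)" for the ten signature genes
# (columns: LGD, HGD, CRC, pooled tumors, MCRC).
TOP10_PREVALENCE: dict[str, dict[str, float]] = {
    "SFRP1":   {"LGD": 100, "HGD": 100, "CRC": 94, "TU": 97.5, "MCRC": 0},
    "SST":     {"LGD": 94,  "HGD": 100, "CRC": 94, "TU": 95.0, "MCRC": 57},
    "BNC1":    {"LGD": 100, "HGD": 100, "CRC": 88, "TU": 95.0, "MCRC": 57},
    "MAL":     {"LGD": 100, "HGD": 83,  "CRC": 88, "TU": 92.5, "MCRC": 14},
    "SLIT2":   {"LGD": 100, "HGD": 100, "CRC": 82, "TU": 92.5, "MCRC": 0},
    "SFRP2":   {"LGD": 82,  "HGD": 100, "CRC": 94, "TU": 90.0, "MCRC": 0},
    "SLIT3":   {"LGD": 94,  "HGD": 100, "CRC": 76, "TU": 87.5, "MCRC": 14},
    "ALDH1A3": {"LGD": 88,  "HGD": 100, "CRC": 76, "TU": 85.0, "MCRC": 0},
    "TMEFF2":  {"LGD": 94,  "HGD": 83,  "CRC": 76, "TU": 85.0, "MCRC": 14},
    "WIF1":    {"LGD": 88,  "HGD": 83,  "CRC": 82, "TU": 85.0, "MCRC": 29},
}

# Printed normal-group prevalences for the ten signature genes (columns: Y, N,
# CN, F, UCi, UCa).
TOP10_NORMAL_PREVALENCE: dict[str, dict[str, float]] = {
    "SFRP1":   {"Y": 0, "N": 0,  "CN": 0,  "F": 0,  "UCi": 25, "UCa": 0},
    "SST":     {"Y": 0, "N": 40, "CN": 40, "F": 20, "UCi": 0,  "UCa": 0},
    "BNC1":    {"Y": 0, "N": 40, "CN": 20, "F": 20, "UCi": 25, "UCa": 0},
    "MAL":     {"Y": 0, "N": 0,  "CN": 0,  "F": 0,  "UCi": 0,  "UCa": 0},
    "SLIT2":   {"Y": 0, "N": 0,  "CN": 20, "F": 0,  "UCi": 25, "UCa": 0},
    "SFRP2":   {"Y": 0, "N": 0,  "CN": 0,  "F": 0,  "UCi": 0,  "UCa": 0},
    "SLIT3":   {"Y": 0, "N": 0,  "CN": 0,  "F": 0,  "UCi": 0,  "UCa": 0},
    "ALDH1A3": {"Y": 0, "N": 0,  "CN": 0,  "F": 0,  "UCi": 0,  "UCa": 0},
    "TMEFF2":  {"Y": 0, "N": 0,  "CN": 0,  "F": 0,  "UCi": 0,  "UCa": 0},
    "WIF1":    {"Y": 0, "N": 20, "CN": 20, "F": 0,  "UCi": 20, "UCa": 0},
}

# Pooled tumor penetrance (%) for the 17 top genes of the single-gene
# comparison table (columns: N, LGD, HGD, CRC, TU; TU pooled n = 40).
TOP17_PREVALENCE: dict[str, dict[str, float]] = {
    "SFRP1":   {"N": 0,  "LGD": 100, "HGD": 100, "CRC": 94, "TU": 97.5},
    "SST":     {"N": 18, "LGD": 94,  "HGD": 100, "CRC": 94, "TU": 95.0},
    "BNC1":    {"N": 18, "LGD": 100, "HGD": 100, "CRC": 88, "TU": 95.0},
    "MAL":     {"N": 0,  "LGD": 100, "HGD": 83,  "CRC": 88, "TU": 92.5},
    "SLIT2":   {"N": 7,  "LGD": 100, "HGD": 100, "CRC": 82, "TU": 92.5},
    "SFRP2":   {"N": 0,  "LGD": 82,  "HGD": 100, "CRC": 94, "TU": 90.0},
    "SLIT3":   {"N": 0,  "LGD": 94,  "HGD": 100, "CRC": 76, "TU": 87.5},
    "ALDH1A3": {"N": 0,  "LGD": 88,  "HGD": 100, "CRC": 76, "TU": 85.0},
    "TMEFF2":  {"N": 0,  "LGD": 94,  "HGD": 83,  "CRC": 76, "TU": 85.0},
    "WIF1":    {"N": 11, "LGD": 88,  "HGD": 83,  "CRC": 82, "TU": 85.0},
    "PCDH10":  {"N": 4,  "LGD": 88,  "HGD": 83,  "CRC": 76, "TU": 82.5},
    "PDLIM4":  {"N": 11, "LGD": 82,  "HGD": 100, "CRC": 76, "TU": 82.5},
    "VIM":     {"N": 0,  "LGD": 82,  "HGD": 83,  "CRC": 76, "TU": 80.0},
    "GALR2":   {"N": 0,  "LGD": 76,  "HGD": 100, "CRC": 71, "TU": 77.5},
    "DKK2":    {"N": 7,  "LGD": 88,  "HGD": 100, "CRC": 59, "TU": 77.5},
    "OPCML":   {"N": 14, "LGD": 94,  "HGD": 83,  "CRC": 59, "TU": 77.5},
    "UCHL1":   {"N": 0,  "LGD": 65,  "HGD": 83,  "CRC": 82, "TU": 75.0},
}

# KRAS/BRAF mutation counts per reporting group.  "N" pools all twenty normal
# samples (Y + N + CN + F); "Total" pools LGD + HGD + CRC.
MUTATION_COUNTS: dict[str, dict[str, int]] = {
    "N":     {"n": 20, "KRAS_c12": 0, "KRAS_c13": 0, "BRAF_V600E": 0},
    "LGD":   {"n": 17, "KRAS_c12": 4, "KRAS_c13": 0, "BRAF_V600E": 3},
    "HGD":   {"n": 6,  "KRAS_c12": 1, "KRAS_c13": 0, "BRAF_V600E": 1},
    "CRC":   {"n": 17, "KRAS_c12": 4, "KRAS_c13": 1, "BRAF_V600E": 0},
    "Total": {"n": 40, "KRAS_c12": 9, "KRAS_c13": 1, "BRAF_V600E": 4},
}

# Mutagenic PCR-RFLP fragment map: amplicon length and the diagnostic fragment
# produced from the wild-type vs. mutant allele after digestion
# (BstNI for codon 12, BglI for codon 13).
RFLP_ASSAYS: dict[str, dict[str, int]] = {
    "KRAS_c12": {"amplicon": 162, "wt_fragment": 113, "mut_fragment": 142},
    "KRAS_c13": {"amplicon": 174, "wt_fragment": 165, "mut_fragment": 125},
}
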