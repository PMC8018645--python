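"""Published summary tables from a multisite carrot metabolite trial.

A three-year French trial quantified 86 metabolites (sugars, acids,
carotenoids, polyphenols, polyacetylenes, terpenoids, phenylpropanoids,
6-methoxymellein) in 16 commercial carrot varieties: year 1 across three
locations with two blocks, then a five-variety subset across twenty
environments (ten locations × two years) with three blocks.  The raw
per-sample measurements were not released, but the printed summary tables
are sufficient to exercise this package's summary arithmetic on real
numbers: the variance partition, the PCA triangle areas, the per-variety
amplitude summaries, and the per-compound Pearson-residual sums of the
plasticity screen.

These tables are worked-example *inputs*; nothing in the package's own
estimators depends on them.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "carrot_permanova_partition",
    "carrot_pca_areas",
    "carrot_amplitude_summary",
    "carrot_residual_sums",
]


def carrot_permanova_partition() -> pd.DataFrame:
    """Printed PERMANOVA partition (Bray–Curtis, 86 metabolites, 96 samples).

    Rows are the sequential terms; columns DF and SumsOfSqs are the printed
    inputs, the printed MeanSqs/R2/F/p are kept for comparison.  Note the
    printed interaction MeanSqs (0.0267) is inconsistent with its own
    SS/DF = 0.02616, which the printed F-ratio (3.2085 × residual MS)
    confirms; the SS and DF columns are the authoritative ones.
    """
    return pd.DataFrame(
        {
            "DF": [2, 15, 30, 48],
            "SumsOfSqs": [0.7479, 3.394, 0.7848, 0.3914],
            "MeanSqs_printed": [0.3740, 0.2263, 0.0267, 0.0082],
            "R2_printed": [0.14063, 0.6382, 0.14758, 0.07359],
            "F_printed": [45.8619, 27.7502, 3.2085, None],
        },
        index=pd.Index(
            ["Locations", "Varieties", "Varieties:Locations", "Residuals"], name="term"
        ),
    )


def carrot_pca_areas() -> pd.DataFrame:
    """Printed per-variety PCA triangle areas (raw and inertia-weighted)."""
    data = {
        "Vi8": (18.40, 20.32), "Mae": (16.45, 18.21), "Yuk": (15.16, 16.75),
        "Cro": (11.36, 12.40), "Vi4": (10.81, 11.86), "Swt": (9.51, 10.68),
        "Bol": (5.65, 6.33), "Luc": (5.39, 5.95), "Rom": (5.15, 5.60),
        "Dor": (4.79, 5.23), "Ext": (4.18, 4.60), "Ver": (3.78, 4.21),
        "Pho": (2.74, 3.02), "Ner": (2.72, 2.96), "Mor": (0.95, 1.07),
        "Rod": (0.40, 0.44),
    }
    df = pd.DataFrame(data, index=["area", "weighted_area"]).T
    df.index.name = "variety"
    return df


def carrot_amplitude_summary() -> pd.DataFrame:
    """Printed per-variety amplitude summaries over 51 shared compounds.

    Columns: sum of amplitudes, printed mean, printed sd; 16 varieties,
    three environments, year 1.
    """
    data = {
        "Vi8": (103.8, 2.04, 1.28), "Luc": (102.2, 2.00, 1.24),
        "Cro": (101.9, 2.00, 1.13), "Mae": (95.7, 1.88, 0.91),
        "Ver": (94.2, 1.85, 1.21), "Yuk": (93.1, 1.83, 1.19),
        "Bol": (92.9, 1.82, 1.05), "Rod": (91.7, 1.80, 1.33),
        "Vi4": (89.4, 1.75, 1.02), "Pho": (75.4, 1.48, 0.93),
        "Mor": (75.2, 1.47, 1.01), "Ner": (73.2, 1.44, 0.87),
        "Swt": (72.9, 1.43, 1.23), "Ext": (72.8, 1.43, 1.07),
        "Rom": (72.0, 1.41, 1.06), "Dor": (68.2, 1.34, 0.90),
    }
    df = pd.DataFrame(data, index=["sum", "mean_printed", "sd_printed"]).T
    df.index.name = "variety"
    df.attrs["n_compounds"] = 51
    return df


def carrot_residual_sums() -> pd.DataFrame:
    """Printed |Pearson residual| summaries per compound (5 varieties, 20 envs).

    39 compounds accumulated by all five varieties; columns: compound name,
    sum, printed mean and sd of the five absolute residuals.
    """
    rows = [
        ("PP2", "myristicin", 4.14, 0.83, 1.01),
        ("S6", "D-germacrene", 4.13, 0.83, 0.95),
        ("T2", "beta-pinene", 4.12, 0.82, 1.18),
        ("S10", "alpha-bisabolene", 4.12, 0.82, 1.12),
        ("PP1", "elemicin", 3.90, 0.78, 0.96),
        ("6MM", "6-methoxymellein", 3.71, 0.74, 0.88),
        ("S1", "beta-elemene", 3.67, 0.73, 0.88),
        ("T15", "cis-beta-ocimene", 3.59, 0.72, 0.99),
        ("T3", "sabinene", 3.31, 0.66, 0.94),
        ("T5", "beta-myrcene", 3.08, 0.62, 0.71),
        ("T18", "unknown-T18", 3.06, 0.61, 0.77),
        ("T1", "alpha-pinene", 2.99, 0.60, 0.76),
        ("FaDOAc", "falcarindiol-acetate", 2.88, 0.58, 0.74),
        ("S5", "(E)-beta-farnesene", 2.77, 0.55, 0.69),
        ("T16", "trans-beta-ocimene", 2.64, 0.53, 0.72),
        ("S2", "beta-caryophyllene", 2.62, 0.52, 0.65),
        ("S11", "bisabolol", 2.53, 0.51, 0.61),
        ("acar", "alpha-carotene", 2.37, 0.47, 0.65),
        ("T17", "unknown-T17", 2.36, 0.47, 0.64),
        ("S4", "alpha-humulene", 2.21, 0.44, 0.61),
        ("S9", "gamma-bisabolene", 2.05, 0.41, 0.55),
        ("FaDOH", "falcarindiol", 1.98, 0.40, 0.50),
        ("T14", "beta-phellandrene", 1.95, 0.39, 0.56),
        ("FaOH", "falcarinol", 1.94, 0.39, 0.45),
        ("SAC", "sucrose", 1.93, 0.39, 0.45),
        ("T7", "gamma-terpinene", 1.79, 0.36, 0.44),
        ("S13", "unknown-S13", 1.78, 0.36, 0.49),
        ("T8", "p-cymene", 1.77, 0.35, 0.42),
        ("CIT", "citric acid", 1.76, 0.35, 0.44),
        ("T6", "limonene", 1.72, 0.34, 0.43),
        ("lut", "lutein", 1.60, 0.32, 0.47),
        ("S7", "beta-bisabolene", 1.59, 0.32, 0.45),
        ("GLU", "glucose", 1.52, 0.30, 0.35),
        ("T9", "alpha-terpinolene", 1.48, 0.30, 0.40),
        ("T4", "alpha-phellandrene", 1.41, 0.28, 0.40),
        ("Bcar", "beta-carotene", 1.39, 0.28, 0.38),
        ("MAL", "malic acid", 1.33, 0.27, 0.41),
        ("FRU", "fructose", 0.97, 0.19, 0.27),
        ("S3", "beta-farnesene", 0.96, 0.19, 0.24),
    ]
    df = pd.DataFrame(
        rows, columns=["code", "compound", "sum", "mean_printed", "sd_printed"]
    ).set_index("code")
    df.attrs["n_varieties"] = 5
    return df
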