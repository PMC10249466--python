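"""Small built-in reference tables.

``gut_taxa_damping_fit`` is a previously reported multivariable fit of the
top ten gut microbiota (ALR-transformed 16S rDNA abundances) against baseline
tissue damping G in obese mice with allergic airway disease.  The printed
coefficient / standard-error / t / p columns are internally consistent Wald
statistics with 10 residual degrees of freedom, which makes the table a handy
desk check for the package's OLS summary machinery: ``t = beta / SE`` and
``p = t_pvalue(t, 10)`` must reproduce the printed columns to their printed
precision.
"""

from __future__ import annotations

import pandas as pd

#: residual degrees of freedom implied by the printed t -> p pairs
GUT_TAXA_DAMPING_DF = 10

_ROWS = [
    # predictor taxon, beta, SE, t, p
    ("Akkermansia", -0.0437, 0.1263, -0.3458, 0.7366),
    ("Lachnospiraceae_uncl", -0.9433, 0.3871, -2.4371, 0.0350),
    ("Lactococcus", 0.2902, 0.2813, 1.0318, 0.3265),
    ("Romboutsia", 0.2511, 0.1320, 1.9021, 0.0863),
    ("Bacteroides", 0.3176, 0.2730, 1.1633, 0.2717),
    ("Dubosiella", 0.0250, 0.1055, 0.2366, 0.8177),
    ("Colidextribacter", -0.3699, 0.3380, -1.0946, 0.2994),
    ("Oscillospiraceae_uncl", 0.4111, 0.1594, 2.5791, 0.0275),
    ("Oscillospiraceae_Uncltrd", 0.2683, 0.2026, 1.3242, 0.2149),
    ("Lachnoclostridium", 0.3364, 0.2051, 1.6406, 0.1320),
]


def gut_taxa_damping_fit() -> pd.DataFrame:
    """Coefficient table of the gut-taxa -> baseline tissue damping model."""
    return pd.DataFrame(_ROWS, columns=["predictor", "beta", "se", "t", "p"])
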