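"""Fixed population parameters used for ascertainment correction.

The disease (schizophrenia) side of the bivariate model is never estimated
from ascertained twin data.  Its variance components are held at
meta-analytic point estimates and its liability threshold at the value
implied by a 1% lifetime prevalence; the implied MZ and DZ twin liability
correlations follow as h2 + c2 and 0.5*h2 + c2.
"""

#: Additive-genetic variance proportion of schizophrenia liability.
SZ_H2 = 0.81
#: Common-environmental variance proportion of schizophrenia liability.
SZ_C2 = 0.11
#: Unique-environmental variance proportion of schizophrenia liability.
SZ_E2 = 0.08

#: MZ twin correlation of schizophrenia liability, h2 + c2.
R_SZ_MZ = 0.92
#: DZ twin correlation of schizophrenia liability, 0.5*h2 + c2.
R_SZ_DZ = 0.515

#: Lifetime population prevalence fixing the liability threshold.
PREVALENCE = 0.01

#: Default number of ordinal classes for the quantitative trait.
N_BV_CATEGORIES = 5
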