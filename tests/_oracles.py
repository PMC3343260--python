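"""Independent brute-force oracles used by several test modules."""

import numpy as np

from twinace import threshold_from_prevalence
from twinace._mvnorm import bvn_cdf, bvn_rect_prob


def tetrachoric_grid_ml(df, prevalence, step=1e-3):
    """Brute-force ML of the 2x2 tetrachoric correlation.

    Thresholds sit at the disease prevalence and the observed binary-trait
    margin (its ML under the 2x2 table); the correlation is scanned on a
    grid.  Entirely independent of the package's optimizer and integrator
    (closed-form bivariate probabilities only).
    """
    t_sz = threshold_from_prevalence(prevalence)
    t_bv = -threshold_from_prevalence((df["bv_cat"] == 2).mean())
    n11 = int(((df["affected"] == 1) & (df["bv_cat"] == 2)).sum())
    n10 = int(((df["affected"] == 1) & (df["bv_cat"] == 1)).sum())
    n01 = int(((df["affected"] == 0) & (df["bv_cat"] == 2)).sum())
    n00 = int(((df["affected"] == 0) & (df["bv_cat"] == 1)).sum())

    def loglik(r):
        p11 = bvn_rect_prob(r, (t_sz, t_bv), (np.inf, np.inf))
        p10 = bvn_rect_prob(r, (t_sz, -np.inf), (np.inf, t_bv))
        p01 = bvn_rect_prob(r, (-np.inf, t_bv), (t_sz, np.inf))
        p00 = bvn_cdf(t_sz, t_bv, r)
        return (n11 * np.log(p11) + n10 * np.log(p10)
                + n01 * np.log(p01) + n00 * np.log(p00))

    grid = np.arange(-0.99, 0.99 + step / 2, step)
    return float(grid[np.argmax([loglik(r) for r in grid])])
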