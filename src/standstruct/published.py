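"""Published per-plot reference values from the original field survey.

The 12-plot Chihuahua-spruce (Picea chihuahuana) community survey that this
pipeline re-implements published its plot-level stand parameters and the
Monte-Carlo tail probabilities of the Clark-Evans index per plot.  Those
printed values are inputs to the tally operations (how many plots read
clustering / CSR / regularity at the 0.01/0.99 rule) and to internal
consistency checks of the stand-parameter formulas; they are not outputs of
this package.

All tables are keyed by the survey's plot codes.
"""

from __future__ import annotations

import pandas as pd

PLOT_CODES = ("TN", "RC", "CV", "TY", "TR", "VN",
              "LQ", "PPR", "QD", "CB", "SJ", "LP")

#: Stand parameters of the 12 plots, all species ("total") and the focal
#: spruce ("pch"): stems/ha (N), basal area m^2/ha (G), quadratic mean
#: diameter cm (dg).
STAND_PARAMETERS = pd.DataFrame(
    {
        "N_total": [304, 348, 328, 232, 356, 260, 432, 152, 532, 352, 360, 364],
        "N_pch": [132, 44, 88, 112, 48, 108, 140, 92, 92, 44, 48, 96],
        "G_total": [19.0, 20.2, 18.1, 18.5, 13.7, 18.1, 27.8, 16.6, 23.3,
                    21.8, 15.2, 22.9],
        "G_pch": [14.3, 5.6, 6.2, 10.6, 2.5, 11.5, 13.3, 8.2, 5.6, 2.1,
                  1.7, 10.7],
        "dg_total": [28.2, 27.2, 26.5, 31.9, 22.1, 29.8, 28.1, 37.3, 23.6,
                     28.1, 23.2, 28.3],
        "dg_pch": [37.2, 40.1, 30.0, 34.8, 25.8, 36.9, 34.8, 33.6, 27.9,
                   24.7, 21.0, 37.7],
    },
    index=pd.Index(PLOT_CODES, name="code"),
)

#: Clark-Evans tail probabilities 1 - P(Z >= CE) per plot, all tree species.
CE_TAIL_ALL_SPECIES = pd.Series(
    [0.0011, 0.0017, 0.0042, 0.0412, 0.0063, 0.1890,
     0.1988, 0.8792, 0.0164, 0.1762, 0.3701, 0.3781],
    index=pd.Index(PLOT_CODES, name="code"), name="ce_tail",
)

#: Same tail for the suppressed stratum (all species): the smaller trees
#: holding the lower half of the stand basal area.
CE_TAIL_SUPPRESSED_ALL = pd.Series(
    [0.0060, 0.0000, 0.0047, 0.0196, 0.0002, 0.1152,
     0.0482, 0.3142, 0.0001, 0.1421, 0.4779, 0.1763],
    index=pd.Index(PLOT_CODES, name="code"), name="ce_tail",
)

#: Same tail for the suppressed stratum of the focal spruce only.
CE_TAIL_SUPPRESSED_PCH = pd.Series(
    [0.0373, 0.0020, 0.0011, 0.0156, 0.0030, 0.1290,
     0.2633, 0.6979, 0.2225, 0.8322, 0.1135, 0.2467],
    index=pd.Index(PLOT_CODES, name="code"), name="ce_tail",
)
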