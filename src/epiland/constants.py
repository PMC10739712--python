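"""Shared numeric constants of the analysis.

All function values are log10 fold-changes relative to the wild-type
genotype, so thresholds are expressed in log10 units.
"""

import math

#: Significance threshold tau = log10(1.5): an effect is significant when its
#: magnitude exceeds a 1.5-fold change, the median replicate error (2 SD) of
#: the compiled dataset.
TAU = math.log10(1.5)

#: Additional spread bins used when summarising heterogeneity (5- and 10-fold).
FOLD_BINS = (1.5, 5.0, 10.0)

#: Fraction of values at the logistic bounds above which a landscape is
#: considered degenerate (binary-collapsed) after global-epistasis correction.
DEGENERACY_FRACTION = 0.90

#: Relative clamp width used when inverting the logistic: values outside
#: (L, U) are moved to L + delta / U - delta with delta = CLAMP_DELTA * (U - L).
CLAMP_DELTA = 1e-6
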