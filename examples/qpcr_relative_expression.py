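"""Relative gene expression from qPCR cycle thresholds.

Fold change over the housekeeping gene (18S rRNA) is 2^(Ct_ref − Ct_target):
a target amplifying 3 cycles earlier than the reference is 8-fold enriched.
"""

import pandas as pd

import osteochip as oc

ct = pd.DataFrame(
    {
        "gene": ["IL6", "IL8", "MMP13", "ACAN"],
        "ct_reference": [15.0, 15.0, 15.0, 15.0],
        "ct_target": [12.0, 13.5, 18.0, 15.0],
    }
)
table = oc.io.qpcr_table(ct)
print(table.to_string(index=False))
# fold_change > 1 means the target is more abundant than the housekeeping
# reference; < 1 means less abundant (e.g. suppressed matrix genes).
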