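"""Comparative-Ct analysis of a simulated toxin-feeding experiment.

Simulates replicate qPCR measurements for four genes whose true fold changes
(treated vs control gut tissue, normalized to a reference transcript) are
known, then runs the Pfaffl ratio and replicate t-test per gene and time
point.  A gene is flagged when it is significant at alpha = 0.05 AND changes
at least 2-fold.
"""

import pandas as pd

from serprot.expression import analyze_ct_table
from serprot.synth import CtDesign, synth_ct

times = (2.0, 6.0, 12.0, 24.0)
design = CtDesign(
    fold={
        "up4x": {t: 4.0 for t in times},
        "up2x": {t: 2.0 for t in times},
        "flat": {t: 1.0 for t in times},
        "down4x": {t: 0.25 for t in times},
    },
    sigma=0.3,
    n_replicates=3,
    seed=11,
)
records = synth_ct(design)
df = pd.DataFrame([r.__dict__ for r in records])
results = analyze_ct_table(df)

pd.set_option("display.float_format", lambda v: f"{v:.3f}")
print(results.to_string(index=False))
print("\n'ratio' is the treated/control fold (1 = no change); with both")
print("amplification efficiencies at 2.0 it equals 2^(-ddCt).  The 4-fold genes")
print("are flagged at essentially every time point, the flat gene almost never.")
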