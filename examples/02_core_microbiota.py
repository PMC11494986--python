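"""Classify genomes as MfA/LfA and select core members from a count matrix.

A genome is MfA ("most frequently appeared") when detected in a strict
majority of samples — at least 6 of 11 here — and a core member when it is
MfA with mean relative abundance above 0.01% of total reads.
"""

import numpy as np
import pandas as pd

from flocprofiler import AbundanceMatrix, build_profile, mapping_rate

samples = [f"S{i:02d}" for i in range(11)]
total = 10_000_000  # 10 million PE reads per metagenome

counts = pd.DataFrame(
    {
        # detected everywhere at ~0.3% -> MfA, core
        "MAG_core": [30_000] * 11,
        # detected in 8 samples but only ~0.004% -> MfA, below the core threshold
        "MAG_thin": [400] * 8 + [0] * 3,
        # abundant but only in 4 samples -> LfA despite 2% abundance
        "MAG_bloom": [200_000] * 4 + [0] * 7,
    },
    index=samples,
).T

matrix = AbundanceMatrix(counts.astype(np.int64), pd.Series(total, index=samples))
profile = build_profile(matrix)

print(profile.frame.round(4))
print()
print("core members:", sorted(profile.core_set()))
per_sample, means = mapping_rate(matrix)
print(f"mean mapping rate: {means['all']:.3f}% of reads per sample")
# Only MAG_core satisfies both rules: majority detection AND mean RA > 0.01%.
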