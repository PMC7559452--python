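"""Estimate smORF expression from weighted probe-set signals.

Probe-set signals are log2-scale (RMA-level). The smORF expression is
E = log2 median(w_i * 2^RMA_i) over its annotations with weight > 0.1:
the signals are unlogged, scaled by the fraction of the probe set the smORF
owns, summarised, and relogged.
"""

import pandas as pd

from smorfpred import ProbeSetAnnotation, estimate_smorf_expression

signals = pd.DataFrame(
    {"sample1": [1.0, 2.0, 9.0], "sample2": [4.0, 3.5, 6.0]},
    index=["psA", "psB", "psC"],
)
annotations = [
    ProbeSetAnnotation("psA", "smorf_x", 0.5),
    ProbeSetAnnotation("psB", "smorf_x", 1.0),
    ProbeSetAnnotation("psC", "smorf_x", 0.1),  # at the threshold: removed
    ProbeSetAnnotation("psC", "smorf_y", 0.05),  # all below: unquantifiable
]

expr, unquantifiable = estimate_smorf_expression(signals, annotations)
print(expr.round(5))
print(f"unquantifiable smORFs: {unquantifiable}")

# sample1: E = log2 median(0.5*2^1, 1.0*2^2) = log2 2.5 = 1.32193 -- the
# psC annotation (w = 0.1) is excluded by the strict w > 0.1 rule, and
# smorf_y, with no surviving annotation, is reported instead of emitted
# as missing values.
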