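"""Small bundled reference tables.

``QPCR_VALIDATION_LOG2FC`` is a published cross-platform validation
panel from a porcine muscle study of divergent intramuscular-fat
groups: 15 genes with log2 fold-change (high over low group) estimated
independently by RNA-seq and by qPCR.  It is the canonical worked input
for :func:`rifnet.qpcr.lin_ccc`.
"""

from __future__ import annotations

import pandas as pd

QPCR_VALIDATION_LOG2FC = pd.DataFrame(
    [
        ("ADIPOQ", 1.31, 1.33),
        ("ATF3", -1.17, -1.22),
        ("CNOT10", -0.25, -0.14),
        ("DCAF5", -0.26, 0.04),
        ("DNAJA1", -0.57, -0.53),
        ("EGR1", -1.64, -1.71),
        ("ELOVL6", 1.50, 0.83),
        ("FASN", 2.54, 1.19),
        ("FOS", -1.67, -1.65),
        ("GPHN", -0.05, -0.10),
        ("ITGB6", 0.12, -0.18),
        ("PFKFB3", -1.10, -0.67),
        ("PLIN1", 1.39, 1.51),
        ("SCD", 1.55, 1.58),
        ("SPP1", -1.62, -1.57),
    ],
    columns=["gene", "log2fc_rnaseq", "log2fc_qpcr"],
).set_index("gene")
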