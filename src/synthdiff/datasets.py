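"""Small bundled datasets for worked examples.

The validation panel covers ten E. coli MG1655 genes whose synthesis was
attempted by polymerase cycling assembly: for each gene it records the
ensemble predictor's call, the Synthesis Success Calculator (SSC) baseline
call, the experimentally observed outcome, and the DNAWorks complexity
score reported for the same construct. It is the standard worked example
for the metrics module.
"""

from __future__ import annotations

import pandas as pd

_PANEL_ROWS = [
    # gene, dnaworks_score, method, ssc, experiment
    ("ygiD", 6.485, "EASY", "HARD", "HARD"),
    ("yghX", 6.756, "EASY", "HARD", "EASY"),
    ("insD-1", 4.512, "EASY", "HARD", "EASY"),
    ("ydgJ", 6.5, "HARD", "EASY", "HARD"),
    ("waaJ", 54.875, "HARD", "EASY", "HARD"),
    ("wbbH", 64.955, "HARD", "HARD", "HARD"),
    ("fabR", 6.084, "EASY", "EASY", "EASY"),
    ("yhiL", 41.894, "HARD", "EASY", "HARD"),
    ("ycbJ", 9.622, "EASY", "EASY", "EASY"),
    ("ypfJ", 6.625, "EASY", "HARD", "HARD"),
]


def load_validation_panel() -> pd.DataFrame:
    """The 10-gene E. coli synthesis validation panel.

    Columns: ``dnaworks_score`` (complexity score of an independent design
    tool; informational only), ``method`` (this predictor's call), ``ssc``
    (SSC baseline call), ``experiment`` (observed outcome). Index: gene
    symbol.
    """
    df = pd.DataFrame(
        _PANEL_ROWS,
        columns=["gene", "dnaworks_score", "method", "ssc", "experiment"],
    )
    return df.set_index("gene")
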