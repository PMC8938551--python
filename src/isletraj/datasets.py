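"""Published aggregate tables used as fixed test inputs.

The trajectory-by-outcome contingency tables below are the printed
cohort composition (six groups: undiagnosed and diagnosed participants
of trajectories TR1-TR3) over sex and HLA-DR risk category.  They are
aggregate counts from the published study table, usable without access
to the protected individual-level data.
"""

from __future__ import annotations

import numpy as np

from .stats import ContingencyTable

GROUPS = ["UD-TR1", "UD-TR2", "UD-TR3", "D-TR1", "D-TR2", "D-TR3"]


def trajectory_sex_table() -> ContingencyTable:
    """Sex by trajectory/outcome group (2 x 6)."""
    return ContingencyTable(
        row_labels=["Male", "Female"],
        col_labels=list(GROUPS),
        counts=np.array([
            [283, 145, 409, 155, 146, 52],
            [200, 112, 353, 101, 127, 62],
        ]),
    )


def trajectory_hla_table(include_unknown: bool = False) -> ContingencyTable:
    """HLA-DR category by trajectory/outcome group.

    By default the sparse "Unknown" category is excluded, giving the
    4 x 6 table on which the association test is run.
    """
    rows = ["DR3/4", "DR4/X", "DR3/X", "DRX/X"]
    counts = [
        [73, 48, 141, 93, 106, 41],
        [298, 140, 421, 139, 138, 55],
        [70, 23, 85, 15, 19, 16],
        [42, 45, 112, 9, 10, 2],
    ]
    if include_unknown:
        rows = rows + ["Unknown"]
        counts = counts + [[0, 1, 3, 0, 0, 0]]
    return ContingencyTable(
        row_labels=rows, col_labels=list(GROUPS), counts=np.array(counts)
    )
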