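#!/usr/bin/env python
"""Recompute the published panel percentages from the printed confusion counts.

The clinical study reports sensitivity/specificity/accuracy/error per
comparison together with the underlying confusion counts; this driver
verifies that the percentages follow exactly from those counts under the
neurofibroma-positive convention.
"""

from pathlib import Path

import pandas as pd

from serds.classify import REFERENCE_CONFUSIONS, binary_metrics

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for panel, counts in REFERENCE_CONFUSIONS.items():
        m = binary_metrics(**counts)
        rows.append({"comparison": f"neurofibroma vs {panel}", **counts,
                     **{k: round(v, 1) for k, v in m.items()}})
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "reference_metrics.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print(f"table -> {RESULTS / 'reference_metrics.tsv'}")


if __name__ == "__main__":
    main()
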