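#!/usr/bin/env python
"""Form SERDS difference spectra and quantify fluorescence suppression.

For every locus of the default cohort: average the 50 repeats per
excitation, z-score both means, subtract.  The broad fluorescence
background (identical at both excitations) cancels; the Raman features
survive as derivative-shaped doublets.  Suppression is quantified as the
ratio of the smooth (median-filtered) component's magnitude in the mean
spectrum vs the difference spectrum, both on z-score scale.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from serds import core, pipeline, synthetic

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 0


def smooth_magnitude(values: np.ndarray) -> float:
    """Magnitude of the broad (>> Raman linewidth) component."""
    return float(np.abs(median_filter(values, size=101)).max())


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cohort = synthetic.generate_cohort(synthetic.CohortConfig(seed=SEED))
    rows = []
    for pair in cohort:
        mean_a = core.mean_block(pair.block_a)
        diff = pipeline.difference_for_pair(pair)
        rows.append({
            "locus": pair.locus_id,
            "label": pair.label,
            "smooth_mag_mean_z": smooth_magnitude(core.zscore(mean_a.values)),
            "smooth_mag_diff": smooth_magnitude(diff.values),
        })
    table = pd.DataFrame(rows)
    table["suppression_factor"] = (table["smooth_mag_mean_z"]
                                   / table["smooth_mag_diff"])
    table.to_csv(RESULTS / "serds_suppression.tsv", sep="\t", index=False)

    print(f"loci processed: {len(table)}")
    print("broad-background magnitude (z-score units): "
          f"mean spectrum median {table['smooth_mag_mean_z'].median():.2f}, "
          f"difference median {table['smooth_mag_diff'].median():.3f}")
    print(f"median suppression factor: {table['suppression_factor'].median():.0f}x")
    print(f"table -> {RESULTS / 'serds_suppression.tsv'}")


if __name__ == "__main__":
    main()
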