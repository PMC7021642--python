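"""Inter-hemispheric balance model of the ITI marker.

Partial correlation between the log marker at each of the 54 lateral
electrodes and clinical improvement, controlling for the homologous
contralateral electrode; parametric two-tailed tests (df = n - 3) with
Benjamini-Hochberg FDR over the 54 channels. Also compares the explained
variance of the single-channel (FC4) model with the dual-channel
{FC4, FC3} regression.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, study_cohort  # noqa: E402
marker_table = __import__("importlib").import_module("03_marker_map").marker_table  # noqa: E402

from rtmseeg import spectral  # noqa: E402


def main() -> None:
    cohort = study_cohort()
    marker = marker_table(cohort)
    clin = cohort.clinical.set_index("subject")
    real = clin.index[clin["group"] == "Real"]
    x = np.log(marker.loc[real])
    imp = clin.loc[real, "improvement_t"]

    bal = spectral.interhemispheric_balance(x, imp, cohort.montage)
    bal.to_csv(RESULTS / "04_interhemispheric_balance.csv", index=False)
    b = bal.set_index("channel")
    print("inter-hemispheric balance model (54 lateral channels, BH-FDR):")
    print(f"  partial r at FC4 (controlling FC3) = {b.loc['FC4', 'r_partial']:.2f}"
          f"  q = {b.loc['FC4', 'q']:.4f}")
    print(f"  partial r at FC3 (controlling FC4) = {b.loc['FC3', 'r_partial']:.2f}"
          f"  q = {b.loc['FC3', 'q']:.4f}")
    print(f"  significant channels: {int(bal['significant'].sum())}")

    r2 = spectral.dual_channel_r2(x, imp, "FC4", cohort.montage)
    gain = 100 * (r2["r2_dual"] - r2["r2_single"])
    print(f"  single-channel r^2 = {100 * r2['r2_single']:.1f}%, "
          f"dual-channel R^2 = {100 * r2['r2_dual']:.1f}% "
          f"(gain {gain:.1f} points)")


if __name__ == "__main__":
    main()
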