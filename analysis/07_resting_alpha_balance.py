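"""Resting-state alpha inter-hemispheric balance model.

Partial correlations between resting alpha power at the eight prefrontal
channels most implicated by the treatment (FC4, FC2, F4, F2 and left
homologues) and clinical improvement, each controlling for its mirror
channel, FDR-corrected over the eight. The planted asymmetry coupling
predicts negative partial correlations on the right and positive on the
left: subjects with less right-dominant resting alpha improve more.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, study_cohort  # noqa: E402

from rtmseeg import preprocess as pre, spectral  # noqa: E402
from rtmseeg.pipeline import extract_iti_like_rest  # noqa: E402


def main() -> None:
    cohort = study_cohort()
    clin = cohort.clinical.set_index("subject")
    real = clin.index[clin["group"] == "Real"]
    rows = {}
    for sid in real:
        rest = pre.apply_average_reference(
            extract_iti_like_rest(cohort.rest_recording(sid)))
        rows[sid] = spectral.epochs_band_power(rest, (spectral.ALPHA,))["Alpha"]
    tab = pd.DataFrame(rows).T
    tab.columns = cohort.montage.channel_names

    bal = spectral.resting_alpha_balance(
        np.log(tab), clin.loc[real, "improvement_t"], cohort.montage)
    bal.to_csv(RESULTS / "07_resting_alpha_balance.csv", index=False)

    print("resting alpha balance model (8 prefrontal channels, BH-FDR):")
    for _, r in bal.iterrows():
        star = " *" if r["significant"] else ""
        print(f"  {r['channel']:<4} | {r['pair']:<4}  partial r = "
              f"{r['r_partial']:+.2f}  q = {r['q']:.3f}{star}")


if __name__ == "__main__":
    main()
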