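"""Power dynamics within the inter-train interval at FC4.

Alpha and low-gamma power per 2 s ITI segment, expressed as a ratio to the
first post-train segment, averaged over the Real group; a two-way
repeated-measures ANOVA (segment x band) tests the signature divergence:
train-evoked gamma decays across the interval while alpha stays flat.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, study_cohort  # noqa: E402

from rtmseeg import preprocess as pre, spectral  # noqa: E402


def main() -> None:
    cohort = study_cohort()
    clin = cohort.clinical.set_index("subject")
    real = clin.index[clin["group"] == "Real"]
    eps = {}
    for sid in real:
        iti = pre.extract_iti_epochs(cohort.treatment_recording(sid))
        eps[sid] = pre.apply_average_reference(iti).pick_channels(("FC4",))

    dyn = spectral.iti_dynamics(eps, channel="FC4")
    dyn["ratios"].to_csv(RESULTS / "05_iti_dynamics.csv", index=False)
    dyn["summary"].to_csv(RESULTS / "05_iti_dynamics_summary.csv", index=False)
    dyn["anova"].to_csv(RESULTS / "05_iti_dynamics_anova.csv", index=False)

    print("ITI power dynamics at FC4, ratio to segment 1 (Real group):")
    for band in ("LowGamma", "Alpha"):
        s = dyn["summary"][dyn["summary"]["band"] == band].sort_values("segment")
        prof = "  ".join(f"{v:.2f}" for v in s["mean"])
        print(f"  {band:<9} {prof}")
    an = dyn["anova"]
    inter = an[an["Source"].str.contains(r"\*")].iloc[0]
    print(f"segment x band interaction: F = {inter['F']:.2f}, "
          f"p = {inter['p_unc']:.3g}")


if __name__ == "__main__":
    main()
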