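"""TEP component contrasts: treatment effects on cortical excitability.

Averages the single-pulse TEP per subject and session, extracts mean
amplitudes over the N45/P60/N75/N100/P180 time windows of interest, and
tests Time x Group effects on post-minus-pre change scores: a one-way
F interaction screen across the three arms followed by the Real-vs-Sham
independent-t decomposition, both cluster-corrected. The generator plants
a post-treatment N75 reduction in the Real group only.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, SEED, STUDY_CONFIG, study_cohort  # noqa: E402

from rtmseeg import preprocess as pre, tep  # noqa: E402


def main() -> None:
    cohort = study_cohort()
    clin = cohort.clinical.set_index("subject")
    groups = clin["group"]

    amp = {}
    for phase in ("pre", "post"):
        sets = {}
        for sid in cohort.subject_ids:
            rec = cohort.tep_recording(sid, phase)
            sets[sid] = pre.apply_average_reference(pre.extract_tep_epochs(rec))
        tabs = tep.component_amplitude_table(sets)
        for name, t in tabs.items():
            t.columns = list(cohort.montage.channel_names)
        amp[phase] = tabs

    res = tep.tep_contrast(amp["pre"], amp["post"], groups,
                           cohort.montage.adjacency,
                           n_perm=STUDY_CONFIG.n_perm, seed=SEED)
    rows = []
    print("TEP Time x Group contrasts per component TOI "
          f"({STUDY_CONFIG.cohort.n_tep_pulses} pulses/session):")
    for name, r in res.items():
        pair = r["pairwise"]
        best = min((c.p_mc for c in pair.clusters), default=float("nan"))
        sig = pair.significant_channels()
        rows.append({"component": name, "best_cluster_p": best,
                     "n_significant_channels": len(sig)})
        print(f"  {name:<5} best Real-vs-Sham cluster p = {best:.4f}; "
              f"{len(sig)} significant channels")
        if name == "N75" and sig:
            print(f"        N75 cluster channels: {sorted(sig)}")
    pd.DataFrame(rows).to_csv(RESULTS / "08_tep_contrasts.csv", index=False)


if __name__ == "__main__":
    main()
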