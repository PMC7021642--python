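"""Clinical outcome layer: mixed ANOVA, effect sizes, responder rates.

Time (pre/post) x Group (Real/AC/Sham) mixed ANOVA on the total-symptom
t-scores, Bonferroni-corrected per-group post-hocs, partial eta squared,
Cohen's d of the Real group's improvement against each control arm, and
the >= 25%-reduction responder rule with Fisher exact contrasts.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, study_cohort  # noqa: E402

from rtmseeg import stats  # noqa: E402


def main() -> None:
    cohort = study_cohort()
    clin = cohort.clinical.set_index("subject")
    groups = clin["group"].to_numpy()

    res = stats.mixed_anova(
        clin.rename(columns={"pre_t": "pre", "post_t": "post"}), groups)
    res["anova"].to_csv(RESULTS / "02_clinical_anova.csv", index=False)
    res["posthoc"].to_csv(RESULTS / "02_clinical_posthoc.csv", index=False)

    print("mixed ANOVA (time x group) on CAARS-style total symptom t-scores:")
    for _, r in res["anova"].iterrows():
        print(f"  {r['effect']:<13} F({r['df1']:.0f},{r['df2']:.0f}) = "
              f"{r['F']:6.2f}  p = {r['p']:.4g}  eta_p^2 = {r['eta_p_sq']:.2f}")
    print("post-hoc pre-vs-post per group (Bonferroni):")
    for _, r in res["posthoc"].iterrows():
        print(f"  {r['group']:<5} mean change {r['mean_change']:6.2f}  "
              f"p_c = {r['p_bonferroni']:.4g}  eta_p^2 = {r['eta_p_sq']:.2f}")

    chg = clin.groupby("group")["improvement_t"].agg(["mean", "std", "count"])
    for other in ("Sham", "AC"):
        d = stats.cohens_d(chg.loc["Real", "mean"], chg.loc["Real", "std"],
                           chg.loc["Real", "count"], chg.loc[other, "mean"],
                           chg.loc[other, "std"], chg.loc[other, "count"])
        print(f"Cohen's d (improvement, Real vs {other}): {d:.2f}")

    flags, _ = stats.classify_responders(clin["pre_raw"], clin["post_raw"])
    resp = pd.DataFrame({"group": clin["group"], "responder": flags})
    rates = resp.groupby("group")["responder"].agg(["sum", "count"])
    rates["rate_pct"] = 100 * rates["sum"] / rates["count"]
    rates.to_csv(RESULTS / "02_responder_rates.csv")
    print("responder rates (>= 25% raw-score reduction):")
    for g, r in rates.iterrows():
        print(f"  {g:<5} {int(r['sum'])}/{int(r['count'])} = {r['rate_pct']:.1f}%")
    for other in ("Sham", "AC"):
        a, b = int(rates.loc["Real", "sum"]), int(rates.loc["Real", "count"] - rates.loc["Real", "sum"])
        c, d = int(rates.loc[other, "sum"]), int(rates.loc[other, "count"] - rates.loc[other, "sum"])
        p, _ = stats.fisher_exact(a, b, c, d)
        print(f"  Fisher exact Real vs {other}: p = {p:.3f}")


if __name__ == "__main__":
    main()
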