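"""End-to-end orchestration: simulate -> preprocess -> analyze -> report.

``run_simulate`` writes a synthetic cohort to disk (recordings as npz with a
JSON sidecar, clinical table and ground truth as CSV/JSON, and a manifest
with per-file checksums so determinism is verifiable). ``run_analyze``
executes the full analysis battery on a cohort — in memory or from disk —
per reference scheme, writing tidy CSV tables and a machine-readable
``summary.json``. ``run_report`` renders the results bundle as a plain-text
report with per-channel value listings for topographic plotting.

Every random element (cohort synthesis, permutation tests) derives from the
seeds recorded in the configuration and the summary, so a logged run can be
reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import spectral, stats, tep
from .montage import Montage, default_montage
from .preprocess import (EpochSet, Recording, apply_average_reference,
                         apply_csd, extract_iti_epochs, extract_tep_epochs,
                         first_segment)
from .simulate import Cohort, CohortConfig, generate_cohort

logger = logging.getLogger("rtmseeg")

__all__ = ["PipelineConfig", "run_simulate", "run_analyze", "run_report",
           "load_cohort"]

ANALYSES = ("clinical", "marker_map", "interhemispheric", "dynamics",
            "rest_treatment", "resting_alpha_balance", "tep_contrast",
            "responders")


@dataclass(frozen=True)
class PipelineConfig:
    """Run-level settings layered over the cohort configuration."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    references: tuple[str, ...] = ("AVR",)      # subset of {"AVR", "CSD"}
    n_perm: int = 1000
    alpha_cf: float = 0.05
    fdr_q: float = 0.05
    analysis_seed: int = 0
    log_marker: bool = True
    invert_marker: bool = False
    dynamics_channel: str = "FC4"
    balance_channel: str = "FC4"

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=1, default=str)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        cohort = d.pop("cohort", {})
        for key in ("n_per_group", "group_gamma_scale", "marker_seg_window"):
            if key in cohort:
                cohort[key] = tuple(cohort[key])
        d["references"] = tuple(d.get("references", ("AVR",)))
        return cls(cohort=CohortConfig(**cohort), **d)


# --------------------------------------------------------------------------
# simulate
# --------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _save_recording(rec: Recording, path: Path) -> None:
    onsets = np.array([e[0] for e in rec.events])
    durations = np.array([e[1] for e in rec.events])
    labels = np.array([e[2] for e in rec.events])
    np.savez_compressed(
        path, data=rec.data.astype(np.float32), sfreq=rec.sfreq,
        ch_names=np.array(rec.ch_names), onsets=onsets, durations=durations,
        labels=labels,
        artifact_mask=(rec.artifact_mask if rec.artifact_mask is not None
                       else np.zeros(0, bool)))


def _load_recording(path: Path, subject: str, session: str) -> Recording:
    with np.load(path) as z:
        mask = z["artifact_mask"]
        events = [(float(o), float(d), str(l))
                  for o, d, l in zip(z["onsets"], z["durations"], z["labels"])]
        return Recording(z["data"].astype(float), float(z["sfreq"]),
                         tuple(str(c) for c in z["ch_names"]), events,
                         artifact_mask=(mask if mask.size else None),
                         subject=subject, session=session)


def run_simulate(config: PipelineConfig | CohortConfig, out_dir: str | Path,
                 write_recordings: bool = True) -> Path:
    """Generate a cohort and write it to ``out_dir``; returns the directory."""
    cohort_cfg = config.cohort if isinstance(config, PipelineConfig) else config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(cohort_cfg)
    cohort.clinical.to_csv(out / "clinical.csv", index=False)
    cohort.ground_truth.to_frame().to_csv(out / "ground_truth.csv", index=False)
    (out / "ground_truth.json").write_text(json.dumps({
        "planted_r_fc4": cohort.ground_truth.planted_r_fc4,
        "planted_r_log_ratio": cohort.ground_truth.planted_r_log_ratio,
        "planted_r2_dual": cohort.ground_truth.planted_r2_dual,
    }, indent=1))
    (out / "config.json").write_text(
        json.dumps(dataclasses.asdict(cohort_cfg), indent=1))
    (out / "montage.tsv").write_text(cohort.montage.to_table())
    files = ["clinical.csv", "ground_truth.csv", "ground_truth.json",
             "config.json", "montage.tsv"]
    if write_recordings:
        rec_dir = out / "recordings"
        rec_dir.mkdir(exist_ok=True)
        for sid in cohort.subject_ids:
            for session, maker in (
                    ("rest", cohort.rest_recording),
                    ("treatment", cohort.treatment_recording)):
                p = rec_dir / f"{sid}_{session}.npz"
                _save_recording(maker(sid), p)
                files.append(str(p.relative_to(out)))
            for phase in ("pre", "post"):
                p = rec_dir / f"{sid}_tep_{phase}.npz"
                _save_recording(cohort.tep_recording(sid, phase), p)
                files.append(str(p.relative_to(out)))
    manifest = {"seed": cohort_cfg.seed,
                "files": {f: _sha256(out / f) for f in files}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("cohort written to %s (seed=%d)", out, cohort_cfg.seed)
    return out


class DiskCohort:
    """Cohort interface backed by a ``run_simulate`` output directory."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        manifest = self.path / "manifest.json"
        if not manifest.exists():
            raise FileNotFoundError(f"no cohort manifest in {self.path}")
        self.config = CohortConfig(**{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in json.loads((self.path / "config.json").read_text()).items()})
        self.clinical = pd.read_csv(self.path / "clinical.csv")
        self.montage = Montage.from_table((self.path / "montage.tsv").read_text())
        self.ground_truth = json.loads(
            (self.path / "ground_truth.json").read_text())

    @property
    def subject_ids(self) -> list[str]:
        return self.clinical["subject"].tolist()

    def _rec(self, name: str, subject: str, session: str) -> Recording:
        return _load_recording(self.path / "recordings" / name, subject, session)

    def rest_recording(self, sid: str) -> Recording:
        return self._rec(f"{sid}_rest.npz", sid, "rest")

    def treatment_recording(self, sid: str) -> Recording:
        return self._rec(f"{sid}_treatment.npz", sid, "treatment")

    def tep_recording(self, sid: str, phase: str = "pre") -> Recording:
        return self._rec(f"{sid}_tep_{phase}.npz", sid, f"tep_{phase}")


def load_cohort(path: str | Path) -> DiskCohort:
    return DiskCohort(path)


# --------------------------------------------------------------------------
# analyze
# --------------------------------------------------------------------------

def _reference(epochs: EpochSet, scheme: str, montage: Montage) -> EpochSet:
    if scheme == "AVR":
        return apply_average_reference(epochs)
    if scheme == "CSD":
        return apply_csd(epochs, montage)
    raise ValueError(f"unknown reference scheme {scheme!r}")


def _subject_tables(cohort, montage: Montage, scheme: str,
                    bands=(spectral.ALPHA, spectral.LOW_GAMMA),
                    dynamics_channel: str = "FC4",
                    dynamics_subjects: set[str] | None = None):
    """Per-subject band powers: first-ITI-segment (treatment) and rest.

    Full ITI epoch sets are retained only at the dynamics channel (and only
    for ``dynamics_subjects``) to keep memory flat in the cohort size.
    """
    iti_rows, rest_rows = {}, {}
    iti_epochs = {}
    for sid in cohort.subject_ids:
        rec = cohort.treatment_recording(sid)
        iti = extract_iti_epochs(rec)
        ref_iti = _reference(iti, scheme, montage)
        seg1 = first_segment(ref_iti)
        bp = spectral.epochs_band_power(seg1, bands)
        iti_rows[sid] = {(b.name, ch): bp[b.name][i]
                         for b in bands
                         for i, ch in enumerate(montage.channel_names)}
        if dynamics_subjects is None or sid in dynamics_subjects:
            iti_epochs[sid] = ref_iti.pick_channels((dynamics_channel,))
        rest = _reference(
            extract_iti_like_rest(cohort.rest_recording(sid)), scheme, montage)
        bpr = spectral.epochs_band_power(rest, bands)
        rest_rows[sid] = {(b.name, ch): bpr[b.name][i]
                          for b in bands
                          for i, ch in enumerate(montage.channel_names)}
    iti_tab = pd.DataFrame(iti_rows).T
    rest_tab = pd.DataFrame(rest_rows).T
    iti_tab.columns = pd.MultiIndex.from_tuples(iti_tab.columns)
    rest_tab.columns = pd.MultiIndex.from_tuples(rest_tab.columns)
    return iti_tab, rest_tab, iti_epochs


def extract_iti_like_rest(recording: Recording,
                          epoch_len: float = 2.0) -> EpochSet:
    """Chop a resting recording into consecutive 2 s epochs (rest condition)."""
    sf = recording.sfreq
    n = int(round(epoch_len * sf))
    k = recording.data.shape[1] // n
    data = recording.data[:, :k * n].reshape(len(recording.ch_names), k, n)
    return EpochSet(np.transpose(data, (1, 0, 2)), sf,
                    tuple(recording.ch_names), "rest",
                    subject=recording.subject, session=recording.session)


def _cluster_to_jsonable(res: stats.ClusterResult) -> dict:
    return {
        "threshold": res.threshold, "n_perm": res.n_perm, "design": res.design,
        "clusters": [{"channels": list(c.channels), "mass": c.mass,
                      "p_mc": c.p_mc} for c in res.clusters],
        "significant_channels": sorted(res.significant_channels()),
    }


def run_analyze(cohort: Cohort | DiskCohort | str | Path,
                out_dir: str | Path,
                config: PipelineConfig | None = None) -> dict:
    """Run the full analysis battery; returns (and writes) the summary dict.

    Produces, per reference scheme: the marker map and its cluster-corrected
    outcome correlation (Real group), the inter-hemispheric balance table,
    ITI power dynamics, rest-vs-treatment band-power correlations per group,
    the resting-alpha balance model, and TEP Time x Group contrasts; plus
    the reference-independent clinical layer (mixed ANOVA, effect sizes,
    responder rates, Fisher tests).
    """
    if isinstance(cohort, (str, Path)):
        cohort = load_cohort(cohort)
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "pipeline_config.json").write_text(config.to_json())
    montage = cohort.montage
    clin = cohort.clinical.set_index("subject")
    groups = clin["group"]
    improvement = clin["improvement_t"]
    summary: dict = {"seed": config.analysis_seed, "references": {}}

    # ---- clinical layer (reference independent) ----
    anova = stats.mixed_anova(clin.rename(columns={"pre_t": "pre",
                                                   "post_t": "post"}),
                              groups.to_numpy())
    anova["anova"].to_csv(out / "clinical_anova.csv", index=False)
    anova["posthoc"].to_csv(out / "clinical_posthoc.csv", index=False)
    flags, _ = stats.classify_responders(clin["pre_raw"], clin["post_raw"])
    resp = pd.DataFrame({"group": groups, "responder": flags})
    rates = resp.groupby("group")["responder"].agg(["sum", "count"])
    rates["rate_pct"] = 100 * rates["sum"] / rates["count"]
    rates.to_csv(out / "responder_rates.csv")
    fisher = {}
    for other in ("Sham", "AC"):
        a = int(rates.loc["Real", "sum"])
        b = int(rates.loc["Real", "count"]) - a
        c = int(rates.loc[other, "sum"])
        d = int(rates.loc[other, "count"]) - c
        p, orat = stats.fisher_exact(a, b, c, d)
        fisher[f"real_vs_{other.lower()}"] = {"p": p, "odds_ratio": orat,
                                              "table": [[a, b], [c, d]]}
    chg = clin.groupby("group")["improvement_t"].agg(["mean", "std", "count"])
    d_sham = stats.cohens_d(chg.loc["Real", "mean"], chg.loc["Real", "std"],
                            chg.loc["Real", "count"], chg.loc["Sham", "mean"],
                            chg.loc["Sham", "std"], chg.loc["Sham", "count"])
    d_ac = stats.cohens_d(chg.loc["Real", "mean"], chg.loc["Real", "std"],
                          chg.loc["Real", "count"], chg.loc["AC", "mean"],
                          chg.loc["AC", "std"], chg.loc["AC", "count"])
    summary["clinical"] = {
        "anova": anova["anova"].to_dict("records"),
        "posthoc": anova["posthoc"].to_dict("records"),
        "mean_improvement": chg["mean"].to_dict(),
        "responder_rate_pct": rates["rate_pct"].to_dict(),
        "fisher": fisher,
        "cohens_d_real_vs_sham": d_sham,
        "cohens_d_real_vs_ac": d_ac,
    }

    real_ids = clin.index[groups == "Real"].tolist()

    for scheme in config.references:
        logger.info("analyzing under %s reference", scheme)
        ref_sum: dict = {}
        iti_tab, rest_tab, iti_epochs = _subject_tables(
            cohort, montage, scheme, dynamics_channel=config.dynamics_channel,
            dynamics_subjects=set(real_ids))

        alpha_iti = iti_tab["Alpha"]
        gamma_iti = iti_tab["LowGamma"]
        if scheme == "CSD":  # CSD band powers are positive by construction too
            alpha_iti = alpha_iti.clip(lower=np.finfo(float).tiny)
        marker = spectral.compute_marker(alpha_iti, gamma_iti,
                                         invert=config.invert_marker)
        marker.to_csv(out / f"marker_{scheme}.csv")

        mreal = marker.loc[real_ids]
        imp_real = improvement.loc[real_ids]
        cmap = spectral.marker_outcome_map(
            mreal, imp_real, montage, n_perm=config.n_perm,
            seed=config.analysis_seed, alpha_cf=config.alpha_cf,
            log_transform=config.log_marker)
        cmap.to_frame().to_csv(out / f"marker_outcome_map_{scheme}.csv",
                               index=False)
        ref_sum["marker_outcome"] = _cluster_to_jsonable(cmap)
        ref_sum["marker_outcome"]["r_fc4"] = float(
            cmap.statistic.get(config.balance_channel, np.nan))

        x = np.log(mreal) if config.log_marker else mreal
        balance = spectral.interhemispheric_balance(
            x, imp_real, montage, q=config.fdr_q)
        balance.to_csv(out / f"interhemispheric_{scheme}.csv", index=False)
        r2 = spectral.dual_channel_r2(x, imp_real, config.balance_channel,
                                      montage)
        ref_sum["interhemispheric"] = {
            "r_partial_fc4": float(
                balance.set_index("channel").loc[config.balance_channel,
                                                 "r_partial"]),
            "n_significant": int(balance["significant"].sum()),
            **{k: float(v) for k, v in r2.items()},
        }

        dyn = spectral.iti_dynamics(
            {sid: iti_epochs[sid] for sid in real_ids},
            channel=config.dynamics_channel)
        dyn["ratios"].to_csv(out / f"iti_dynamics_{scheme}.csv", index=False)
        dyn["anova"].to_csv(out / f"iti_dynamics_anova_{scheme}.csv",
                            index=False)
        inter = dyn["anova"][dyn["anova"]["Source"].str.contains(r"\*")]
        ref_sum["dynamics"] = {
            "interaction_p": float(inter["p_unc"].iloc[0]) if len(inter) else None,
            "gamma_profile": dyn["summary"][
                dyn["summary"]["band"] == "LowGamma"]["mean"].tolist(),
            "alpha_profile": dyn["summary"][
                dyn["summary"]["band"] == "Alpha"]["mean"].tolist(),
        }

        rt = {}
        for band in ("Alpha", "LowGamma"):
            for gname in ("Real", "AC", "Sham"):
                gids = clin.index[groups == gname]
                r = spectral.rest_treatment_correlation(
                    rest_tab[band].loc[gids], iti_tab[band].loc[gids])
                r.to_csv(out / f"rest_treatment_{band}_{gname}_{scheme}.csv")
                rt[f"{band}_{gname}"] = float(
                    r.get(config.balance_channel, np.nan))
        ref_sum["rest_treatment_r_fc4"] = rt

        rab = spectral.resting_alpha_balance(
            rest_tab["Alpha"].loc[real_ids], imp_real, montage,
            q=config.fdr_q, log_transform=config.log_marker)
        rab.to_csv(out / f"resting_alpha_balance_{scheme}.csv", index=False)
        rab_i = rab.set_index("channel")
        ref_sum["resting_alpha_balance"] = {
            "r_partial_fc4": float(rab_i.loc["FC4", "r_partial"]),
            "r_partial_fc3": float(rab_i.loc["FC3", "r_partial"]),
        }
        summary["references"][scheme] = ref_sum

    # ---- TEP layer (raw reference; component amplitudes) ----
    amp_pre, amp_post = {}, {}
    for phase, store in (("pre", amp_pre), ("post", amp_post)):
        sets = {}
        for sid in cohort.subject_ids:
            rec = cohort.tep_recording(sid, phase)
            sets[sid] = apply_average_reference(extract_tep_epochs(rec))
        tabs = tep.component_amplitude_table(sets)
        for name, tab in tabs.items():
            tab.columns = list(montage.channel_names)
            store[name] = tab
    contrasts = tep.tep_contrast(amp_pre, amp_post, groups, montage.adjacency,
                                 n_perm=config.n_perm,
                                 seed=config.analysis_seed,
                                 alpha_cf=config.alpha_cf)
    tep_sum = {}
    for name, res in contrasts.items():
        res["pairwise"].to_frame().to_csv(
            out / f"tep_contrast_{name}_real_vs_sham.csv", index=False)
        tep_sum[name] = {
            "interaction": _cluster_to_jsonable(res["interaction"]),
            "real_vs_sham": _cluster_to_jsonable(res["pairwise"]),
        }
    summary["tep"] = tep_sum

    (out / "summary.json").write_text(json.dumps(summary, indent=1,
                                                 default=float))
    return summary


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------

def run_report(results_dir: str | Path, out_path: str | Path | None = None) -> str:
    """Render a results bundle as a deterministic plain-text report."""
    results = Path(results_dir)
    summary_file = results / "summary.json"
    if not summary_file.exists():
        raise FileNotFoundError(f"missing {summary_file}; run the analysis first")
    summary = json.loads(summary_file.read_text())
    lines = ["rtmseeg analysis report", "=" * 60]

    clin = summary.get("clinical")
    if clin:
        lines.append("\n[clinical outcome]")
        for row in clin["anova"]:
            lines.append(f"  {row['effect']:<14} F({row['df1']},{row['df2']}) = "
                         f"{row['F']:.2f}  p = {row['p']:.4g}  "
                         f"eta_p^2 = {row['eta_p_sq']:.2f}")
        for g, m in clin["mean_improvement"].items():
            rate = clin["responder_rate_pct"][g]
            lines.append(f"  {g:<5} mean improvement {m:5.2f} t-points, "
                         f"responders {rate:.1f}%")
        for name, f in clin["fisher"].items():
            lines.append(f"  Fisher {name}: p = {f['p']:.3f}")
        lines.append(f"  Cohen's d Real vs Sham = "
                     f"{clin['cohens_d_real_vs_sham']:.2f}, "
                     f"vs AC = {clin['cohens_d_real_vs_ac']:.2f}")
    else:
        lines.append("\n[clinical outcome] MISSING")

    for scheme, ref in summary.get("references", {}).items():
        lines.append(f"\n[{scheme} reference]")
        mo = ref.get("marker_outcome", {})
        lines.append(f"  marker-outcome r(FC4) = {mo.get('r_fc4', float('nan')):.3f}; "
                     f"{len(mo.get('significant_channels', []))} channels in "
                     f"significant clusters")
        ih = ref.get("interhemispheric", {})
        lines.append(f"  balance model: partial r(FC4) = "
                     f"{ih.get('r_partial_fc4', float('nan')):.3f}; "
                     f"single r^2 = {100 * ih.get('r2_single', float('nan')):.1f}%, "
                     f"dual R^2 = {100 * ih.get('r2_dual', float('nan')):.1f}%")
        dyn = ref.get("dynamics", {})
        lines.append(f"  dynamics interaction p = {dyn.get('interaction_p')}")
        rab = ref.get("resting_alpha_balance", {})
        lines.append(f"  resting alpha balance: r(FC4) = "
                     f"{rab.get('r_partial_fc4', float('nan')):.3f}, "
                     f"r(FC3) = {rab.get('r_partial_fc3', float('nan')):.3f}")

    tep_sum = summary.get("tep", {})
    if tep_sum:
        lines.append("\n[TEP contrasts]")
        for name, res in tep_sum.items():
            sig = res["real_vs_sham"]["clusters"]
            best = min((c["p_mc"] for c in sig), default=None)
            lines.append(f"  {name}: best Real-vs-Sham cluster p = {best}")

    # per-channel listings for topographic rendering
    for csv in sorted(results.glob("marker_outcome_map_*.csv")):
        lines.append(f"\n[topography] {csv.name}")
        df = pd.read_csv(csv)
        for _, row in df.iterrows():
            lines.append(f"  {row['channel']:<5} {row['statistic']:+.4f}")

    text = "\n".join(lines) + "\n"
    out_path = Path(out_path) if out_path else results / "report.txt"
    out_path.write_text(text)
    return text
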