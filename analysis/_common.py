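"""Shared configuration for the numbered analysis scripts.

One trial-sized synthetic cohort (n = 15/14/14) drives all analyses. The
EEG is synthesised at 250 Hz with 12 stimulation trains per treatment
session — enough first-ITI-segment epochs for stable band powers while
keeping each script's runtime to tens of seconds; the generator's
protocol defaults (40 trains, 500 Hz) remain available for full-scale runs.
Recordings are regenerated deterministically from the seed on demand, so
nothing heavier than CSV tables ever lands in results/.
"""

from pathlib import Path

from rtmseeg import CohortConfig, PipelineConfig, generate_cohort

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
COHORT_DIR = RESULTS / "cohort"

SEED = 2026

STUDY_CONFIG = PipelineConfig(
    cohort=CohortConfig(
        n_per_group=(15, 14, 14), seed=SEED, sfreq=250.0,
        n_trains=12, rest_dur=60.0, n_tep_pulses=50,
    ),
    n_perm=1000,
    analysis_seed=SEED,
)


def study_cohort():
    RESULTS.mkdir(exist_ok=True)
    return generate_cohort(STUDY_CONFIG.cohort)
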