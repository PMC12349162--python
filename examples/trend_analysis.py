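"""Track interface parameters over an hour-long session, per electrode type.

Generates a small cohort (3 subjects, all four electrode types), fits
the interface circuit at every time point, takes the median trajectory
across subjects, and classifies each parameter's trend. Dry tattoo
electrodes show the drying interface: R0 up, C0 down; the wet Ag/AgCl
reference shows R0 slightly down.
"""

import zskin
from zskin.fitting import FitConfig
from zskin.temporal import cohort_trends, fit_session

sessions, _ = zskin.generate_cohort(n_subjects=3, seed=2)
model0 = zskin.make_model("model0")

trajectories = {
    key: fit_session(series, model0, FitConfig(n_starts=20, rng_seed=0))[1]
    for key, series in sessions.items()
}

print(f"{'electrode':>10} {'parameter':>10} {'trend':>11} {'change over 60 min':>19}")
for t in cohort_trends(trajectories):
    print(f"{t.electrode_type:>10} {t.parameter:>10} {t.trend:>11} {t.relative_change:>+18.1%}")

print("\nR0/C0 are the interface resistance and capacitance of the first")
print("parallel segment; trends are least-squares slopes of the median")
print("trajectory with a 5 % relative-change floor for 'flat'.")
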