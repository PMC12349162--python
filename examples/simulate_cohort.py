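"""Generate a synthetic measurement campaign and look at the raw spectra.

Six subjects x four electrode types, six sweeps over one hour each.
Prints the 20 Hz magnitude per electrode type at the start and end of
the session: dry (tattoo) electrodes drift up, the wet Ag/AgCl
reference drifts down.
"""

import numpy as np

import zskin

sessions, truths = zskin.generate_cohort(seed=1)

print(f"{len(sessions)} sessions ({len({k[0] for k in sessions})} subjects x 4 electrode types)")
print(f"{'electrode':>10} {'|Z(20 Hz)| t=0':>16} {'t=60 min':>12}  direction")
for etype in ("gold", "silver", "pedot_pss", "agagcl"):
    start = [sessions[(s, etype)].spectra[0].magnitudes[0] for s in ("S1", "S2", "S3", "S4", "S5", "S6")]
    end = [sessions[(s, etype)].spectra[-1].magnitudes[0] for s in ("S1", "S2", "S3", "S4", "S5", "S6")]
    m0, m1 = np.median(start) / 1e3, np.median(end) / 1e3
    print(f"{etype:>10} {m0:>13.1f} kR {m1:>9.1f} kR  {'up' if m1 > m0 else 'down'}")

print("\nMagnitudes sit in the tens of kilo-ohms at 20 Hz, the level at which")
print("both tattoo and pre-gelled electrodes support biopotential acquisition.")
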