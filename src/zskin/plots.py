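"""Minimal diagnostic Bode plot helper."""

from __future__ import annotations

import numpy as np

from .spectra import ImpedanceSpectrum


def bode_plot(s: ImpedanceSpectrum, fitted: np.ndarray | None = None, path=None):
    """Magnitude/phase Bode panels of a spectrum, optionally with a model overlay.

    ``fitted`` is a complex impedance array on the spectrum's grid.
    Saves to ``path`` if given, else returns the figure.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, (ax_m, ax_p) = plt.subplots(2, 1, sharex=True, figsize=(6, 6))
    ax_m.loglog(s.frequencies, s.magnitudes, "o", ms=3, label="data")
    ax_p.semilogx(s.frequencies, np.degrees(s.phases), "o", ms=3, label="data")
    if fitted is not None:
        ax_m.loglog(s.frequencies, np.abs(fitted), "-", label="fit")
        ax_p.semilogx(s.frequencies, np.degrees(np.angle(fitted)), "-", label="fit")
    ax_m.set_ylabel("|Z| (ohm)")
    ax_p.set_ylabel("phase (deg)")
    ax_p.set_xlabel("frequency (Hz)")
    ax_m.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
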