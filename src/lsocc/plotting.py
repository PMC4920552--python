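"""Optional matplotlib rendering of tuning curves."""
from __future__ import annotations

from .tuning import TuningCurve

_XLABEL = {
    "mtf": "Modulation frequency (Hz)",
    "phase": "Phase difference (deg)",
    "ild": "Contralateral level (dB)",
}


def plot_tuning_curve(curve: TuningCurve, ax=None, **kwargs):
    """Plot rate versus the curve's independent variable.

    Requires matplotlib (``pip install lsocc[plot]``).  Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.x, curve.rate, marker=".", **kwargs)
    ax.set_xlabel(_XLABEL.get(curve.kind, curve.kind))
    ax.set_ylabel("Output rate (spikes/s)")
    return ax
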