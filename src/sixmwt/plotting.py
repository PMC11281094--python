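"""Optional static plots: the SC×SL frailty map and a cadence spectrum."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .frailty import FRAIL, NON_FRAIL, PRE_FRAIL
from .types import AnalysisConfig

_COLORS = {FRAIL: "tab:red", PRE_FRAIL: "tab:blue", NON_FRAIL: "tab:green"}


def plot_distribution_map(
    df: pd.DataFrame,
    path: str,
    config: Optional[AnalysisConfig] = None,
    sl_col: str = "sl",
    sc_col: str = "sc",
    category_col: str = "category",
) -> None:
    """Scatter the cohort on the SC×SL plane with the four-range cutoff lines."""
    config = config or AnalysisConfig()
    fig, ax = plt.subplots(figsize=(6, 5))
    for cat, sub in df.groupby(category_col):
        ax.scatter(sub[sc_col], sub[sl_col], label=str(cat),
                   color=_COLORS.get(cat, "tab:gray"), alpha=0.8)
    ax.axvline(config.cut_sc, ls="--", color="k", lw=1)
    ax.axhline(config.cut_sl, ls="--", color="k", lw=1)
    ax.set_xlabel("step cadence SC [step/s]")
    ax.set_ylabel("stride length SL [m/step]")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_cadence_spectrum(
    y_motion: np.ndarray, fs: float, path: str,
    config: Optional[AnalysisConfig] = None,
) -> None:
    """Amplitude spectrum of one straight walk's vertical motion."""
    from scipy import fft as sp_fft

    config = config or AnalysisConfig()
    y = np.asarray(y_motion, dtype=float)
    y = (y - y.mean()) * np.hanning(len(y))
    n = sp_fft.next_fast_len(max(len(y), int(np.ceil(fs / config.freq_resolution))))
    spec = np.abs(sp_fft.rfft(y, n))
    freqs = sp_fft.rfftfreq(n, 1.0 / fs)
    fig, ax = plt.subplots(figsize=(6, 4))
    m = freqs <= config.cadence_band[1] * 1.5
    ax.plot(freqs[m], spec[m])
    ax.axvspan(*config.cadence_band, alpha=0.15, color="tab:orange")
    ax.set_xlabel("frequency [Hz]")
    ax.set_ylabel("|FFT| [a.u.]")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
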