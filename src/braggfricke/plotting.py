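"""Diagnostic figures: absorbance vs time per fibre, and G / ELF vs depth.

Cosmetic output only; nothing here is relied on numerically.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_absorbance", "plot_yield_profile"]


def plot_absorbance(records, fibres=None, ax=None):
    """Absorbance time series for a selection of fibres (default: all)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for rec in records:
        if fibres is not None and rec.fibre not in fibres:
            continue
        ax.plot(rec.times, rec.absorbance, lw=0.9, label=f"fibre {rec.fibre}")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("absorbance at 304 nm")
    if fibres is not None and len(fibres) <= 8:
        ax.legend(frameon=False, fontsize=8)
    return ax


def plot_yield_profile(profile, ax=None, show_elf=True):
    """G(Fe3+) per fibre vs depth, with the aligned ELF on a twin axis."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    g = profile.g_molecules_per_100ev
    ax.plot(profile.depth_mm, g, "o-", color="tab:red", label="G(Fe$^{3+}$)")
    if profile.band_lo is not None:
        f = g / np.where(profile.g_mol_per_j != 0, profile.g_mol_per_j, np.nan)
        ax.fill_between(
            profile.depth_mm,
            profile.band_lo * f,
            profile.band_hi * f,
            color="tab:red",
            alpha=0.2,
            label="alignment band",
        )
    ax.set_xlabel("depth in sample (mm)")
    ax.set_ylabel("G(Fe$^{3+}$) (molecules / 100 eV)")
    if show_elf:
        ax2 = ax.twinx()
        ax2.plot(profile.depth_mm, profile.elf, "k-", lw=1.0, label="ELF")
        ax2.set_ylabel("ELF (MeV/mm)")
    ax.legend(frameon=False, fontsize=8, loc="upper left")
    return ax
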