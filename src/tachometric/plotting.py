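"""Figures: tachometric panels with a chance band and a Bayes-factor strip."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .inference import chance_band

__all__ = ["plot_tachometric"]

_COLORS = {"congruent": "#2166ac", "incongruent": "#b2182b"}


def _color(name: str) -> str:
    return _COLORS["incongruent" if name.startswith("incongruent") else "congruent"]


def plot_tachometric(report: dict, curves: dict, out_dir) -> list[Path]:
    """One two-row figure per group: smoothed curve with the binomial chance
    band (top) and decadal-log Bayes factors per 100-ms bin (bottom).

    For SOA groups, dashed vertical lines mark flanker onset (rPT = -SOA)
    and target onset (rPT = 0). The values behind every panel are exported
    alongside the images by the pipeline (curves.csv / bayes_factors.csv).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, curve in sorted(curves.items()):
        band = chance_band(curve, p0=report["provenance"]["config"]["chance_level"])
        fig, (ax, axb) = plt.subplots(
            2, 1, figsize=(7, 5.5), sharex=True,
            gridspec_kw={"height_ratios": [3, 1]})
        ok = np.isfinite(band.half_width)
        ax.fill_between(curve.grid_ms[ok], band.lower[ok], band.upper[ok],
                        color="0.85", label="95% chance band")
        ax.axhline(band.p0, color="0.4", lw=0.8)
        ax.plot(curve.grid_ms, curve.p_smooth, color=_color(name), lw=1.8,
                label=name)
        if "@soa" in name:
            soa = int(name.split("@soa")[1])
            if soa > 0:
                ax.axvline(-soa, ls="--", color="0.3", lw=0.9)  # flanker onset
            ax.axvline(0, ls="--", color="0.3", lw=0.9)         # target onset
        ax.set_ylim(0, 1)
        ax.set_ylabel("proportion correct")
        ax.set_title(f"tachometric function — {name}")
        ax.legend(loc="lower right", fontsize=8)

        bf = pd.DataFrame(report["groups"][name]["bayes_factors"])
        mid = (bf["bin_start_ms"] + bf["bin_end_ms"]) / 2
        for col, sign, color in (("log10_bf_above", 1, "#2166ac"),
                                 ("log10_bf_below", -1, "#b2182b")):
            vals = pd.to_numeric(bf[col], errors="coerce")
            axb.bar(mid, sign * vals.clip(-50, 50), width=80, color=color,
                    alpha=0.7)
        axb.axhline(0, color="0.4", lw=0.8)
        axb.set_xlabel("raw processing time (ms)")
        axb.set_ylabel(r"$\pm\log_{10}$ BF")
        fig.tight_layout()
        path = out / f"tachometric_{name.replace('@', '_')}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
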