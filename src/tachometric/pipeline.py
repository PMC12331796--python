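"""End-to-end analysis orchestration.

One call runs the whole scheme the three experiments share: filter trials,
bin and smooth per condition (and per SOA level when the data contain more
than one), compute restricted minima with bootstrap SEs, run both
permutation tests, derive the chance band and its exceedance intervals, and
tabulate per-100-ms-bin Bayes factors. Everything is driven by a single
master seed that expands into fixed per-stage seeds, so a report is
byte-identical across reruns of the same config.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import inference
from .curves import add_rpt, bin_accuracy, filter_trials, smooth_curve
from .io import config_hash, jsonify, write_report

__all__ = ["AnalysisConfig", "run_analysis", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Expand a master seed into a stage seed below 2**31.

    Fixed scheme: the stage name is CRC32-hashed and mixed with the master
    seed through a SeedSequence, so adding or reordering stages never
    shifts another stage's stream.
    """
    tag = zlib.crc32(stage.encode())
    ss = np.random.SeedSequence([int(master_seed), tag])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class AnalysisConfig:
    """Settings for one experiment analysis.

    ``span``/``degree`` control the curve smoother; ``restriction_ms`` is
    the lower rPT bound for minima (responses earlier than that are
    pre-stimulus); ``n_perm``/``n_boot`` are resampling depths; the Bayes
    factors use ``bf_bin_width_ms`` bins and a logistic prior of scale
    ``bf_prior_scale`` on the log-odds.
    """

    span: float = 0.2
    degree: int = 2
    count_weighted: bool = False
    restriction_ms: float = 0.0
    n_perm: int = 1000
    n_boot: int = 1000
    bf_bin_width_ms: int = 100
    bf_prior_scale: float = 0.5
    chance_level: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.span <= 1):
            raise ValueError("span must be in (0, 1]")
        if self.restriction_ms < -200 or self.restriction_ms > 1000:
            raise ValueError("restriction_ms outside the rPT window")
        for name in ("n_perm", "n_boot", "bf_bin_width_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def _groups(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split by congruency, and additionally by SOA when several levels
    are present (the asymmetry experiment is analyzed per SOA level)."""
    soas = sorted(records["soa_ms"].dropna().unique())
    out: dict[str, pd.DataFrame] = {}
    for cong in ("congruent", "incongruent"):
        sub = records.loc[records["congruency"] == cong]
        if len(soas) > 1:
            for soa in soas:
                out[f"{cong}@soa{int(soa)}"] = sub.loc[sub["soa_ms"] == soa]
        else:
            out[cong] = sub
    return {k: v for k, v in out.items() if len(v)}


def run_analysis(records: pd.DataFrame, config: AnalysisConfig,
                 out_dir: str | Path | None = None,
                 make_figures: bool = True) -> dict:
    """Run the full analysis scheme on a trial table.

    Returns the report tree; when ``out_dir`` is given, also writes
    ``report.json``, the per-group curve table ``curves.csv``, the Bayes
    factor table ``bayes_factors.csv`` and (optionally) figures.
    """
    if records.empty:
        raise ValueError("empty trial table")
    records = add_rpt(records)
    filtered, counts = filter_trials(records)
    if filtered.empty:
        raise ValueError("no trials remain after filtering")
    cfg = config.to_dict()
    report: dict = {
        "provenance": {"config": cfg, "config_hash": config_hash(cfg),
                       "seed": config.seed, "exclusions": counts},
        "groups": {}, "comparisons": {},
    }
    groups = _groups(filtered)
    if not groups:
        raise ValueError("no congruent/incongruent groups found "
                         "(check the congruency column)")
    smooth_kw = dict(span=config.span, degree=config.degree,
                     count_weighted=config.count_weighted)
    curves: dict[str, object] = {}
    curve_rows, bf_rows = [], []
    for name, grp in sorted(groups.items()):
        curve = smooth_curve(bin_accuracy(grp), condition=name, **smooth_kw)
        curves[name] = curve
        mstat = inference.curve_minimum(curve, config.restriction_ms)
        se = inference.bootstrap_min_se(
            grp, n_boot=config.n_boot, seed=stage_seed(config.seed, f"boot:{name}"),
            restriction_ms=config.restriction_ms, **smooth_kw)
        vs_chance = inference.perm_test_min_vs_chance(
            grp, n_perm=config.n_perm, seed=stage_seed(config.seed, f"chance:{name}"),
            restriction_ms=config.restriction_ms, p0=config.chance_level,
            span=config.span, degree=config.degree,
            count_weighted=config.count_weighted)
        band = inference.chance_band(curve, p0=config.chance_level)
        exceed = inference.band_exceedance(curve, band)
        bf = inference.bayes_factors(grp, bin_width_ms=config.bf_bin_width_ms,
                                     prior_scale=config.bf_prior_scale,
                                     p0=config.chance_level)
        report["groups"][name] = {
            "n_trials": int(len(grp)),
            "minimum": {"value": mstat.min_value,
                        "argmin_rpt_ms": mstat.argmin_rpt_ms,
                        "restriction_ms": mstat.restriction_ms,
                        "bootstrap_se": se},
            "vs_chance": {"p_value": vs_chance.p_value,
                          "observed_min": vs_chance.observed,
                          "n_perm": vs_chance.n_permutations,
                          "sidedness": vs_chance.sidedness,
                          "seed": vs_chance.seed},
            "band_exceedance": exceed,
            "bayes_factors": jsonify(bf),
        }
        cf = curve.to_frame()
        cf["band_half_width"] = band.half_width
        curve_rows.append(cf)
        bf.insert(0, "condition", name)
        bf_rows.append(bf)

    # between-condition minima comparisons, one per SOA level
    soa_suffixes = sorted({n.split("@", 1)[1] for n in groups if "@" in n}) or [""]
    for suf in soa_suffixes:
        a = f"incongruent@{suf}" if suf else "incongruent"
        b = f"congruent@{suf}" if suf else "congruent"
        if a in groups and b in groups:
            res = inference.perm_test_min_diff(
                groups[a], groups[b], n_perm=config.n_perm,
                seed=stage_seed(config.seed, f"diff:{suf or 'all'}"),
                restriction_ms=config.restriction_ms, **smooth_kw)
            report["comparisons"][f"incongruent_vs_congruent{('@' + suf) if suf else ''}"] = {
                "observed_min_diff": res.observed, "p_value": res.p_value,
                "n_perm": res.n_permutations, "sidedness": res.sidedness,
                "seed": res.seed, "n_redrawn": res.n_redrawn}
    # asymmetry contrast: incongruent minima across the two SOA levels
    if len(soa_suffixes) == 2 and all(f"incongruent@{s}" in groups for s in soa_suffixes):
        s0, s1 = soa_suffixes
        res = inference.perm_test_min_diff(
            groups[f"incongruent@{s1}"], groups[f"incongruent@{s0}"],
            n_perm=config.n_perm, seed=stage_seed(config.seed, "diff:soa"),
            restriction_ms=config.restriction_ms, **smooth_kw)
        report["comparisons"][f"incongruent_{s1}_vs_{s0}"] = {
            "observed_min_diff": res.observed, "p_value": res.p_value,
            "n_perm": res.n_permutations, "sidedness": res.sidedness,
            "seed": res.seed, "n_redrawn": res.n_redrawn}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(report, out / "report.json")
        pd.concat(curve_rows, ignore_index=True).to_csv(
            out / "curves.csv", index=False)
        pd.concat(bf_rows, ignore_index=True).to_csv(
            out / "bayes_factors.csv", index=False)
        if make_figures:
            from .plotting import plot_tachometric
            plot_tachometric(report, curves, out)
    return report
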