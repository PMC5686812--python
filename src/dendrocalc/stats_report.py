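"""Normality-routed two-group statistics and tidy report tables.

Routing mirrors common practice in the imaging literature: each sample is
tested for normality with a Kolmogorov–Smirnov-type test; if both samples
pass (p > alpha), a two-tailed Student's t-test is used (paired or unpaired
by design), otherwise the Mann-Whitney U test (unpaired) or the Wilcoxon
signed-rank test (paired).  Significance level alpha = 0.05.  Results always
carry mean ± s.e.m. per group.

The plain KS test against a Normal with parameters estimated from the same
sample is anticonservative, so the default normality test is the
Lilliefors-corrected version (``ks_mode="lilliefors"``); the uncorrected
test is selectable with ``ks_mode="plain"`` for fidelity to SPSS-style
one-sample KS output.  No multiple-testing correction is applied by default;
Benjamini–Hochberg is available on the comparisons table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from ._util import config_hash


@dataclass
class ComparisonResult:
    metric: str
    group_labels: tuple[str, str]
    n: tuple[int, int]
    normality_p: tuple[float, float]
    test_used: Literal["t-test", "Mann-Whitney", "Wilcoxon signed-rank"]
    statistic: float
    p_value: float
    means: tuple[float, float]
    sems: tuple[float, float]
    effect_direction: Literal["increase", "decrease", "none"]
    paired: bool
    alpha: float = 0.05
    warnings_: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha


def _normality_p(x: np.ndarray, ks_mode: str) -> float:
    if np.ptp(x) == 0:
        return 0.0  # degenerate: certainly not Normal-with-spread
    if ks_mode == "lilliefors":
        return float(lilliefors(x, dist="norm")[1])
    if ks_mode == "plain":
        return float(stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).pvalue)
    raise ValueError(f"unknown ks_mode {ks_mode!r}")


def route_and_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    paired: bool = False,
    metric: str = "",
    group_labels: tuple[str, str] = ("A", "B"),
    alpha: float = 0.05,
    ks_mode: Literal["lilliefors", "plain"] = "lilliefors",
) -> ComparisonResult:
    """KS-route two samples to a t-test or a rank test and run it."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs n >= 3")
    if paired and a.size != b.size:
        raise ValueError("paired design requires equal sample sizes")

    warns: list[str] = []
    pa, pb = _normality_p(a, ks_mode), _normality_p(b, ks_mode)
    if paired and np.all(a == b):
        # degenerate paired design: no differences at all; neither the
        # t-test nor the signed-rank statistic is defined
        return ComparisonResult(
            metric=metric,
            group_labels=group_labels,
            n=(a.size, b.size),
            normality_p=(pa, pb),
            test_used="Wilcoxon signed-rank",
            statistic=0.0,
            p_value=1.0,
            means=(float(a.mean()), float(b.mean())),
            sems=(float(stats.sem(a)), float(stats.sem(b))),
            effect_direction="none",
            paired=True,
            alpha=alpha,
            warnings_=["all paired differences zero; test undefined, p set to 1"],
        )
    zero_var = np.ptp(a) == 0 or np.ptp(b) == 0
    if zero_var:
        warns.append("zero-variance sample; routed to nonparametric test")
    normal = (pa > alpha) and (pb > alpha) and not zero_var

    if normal:
        test_used = "t-test"
        res = stats.ttest_rel(a, b) if paired else stats.ttest_ind(a, b)
        statistic, p = float(res.statistic), float(res.pvalue)
    elif paired:
        test_used = "Wilcoxon signed-rank"
        d = a - b
        if np.all(d == 0):
            warns.append("all paired differences zero; Wilcoxon undefined, p set to 1")
            statistic, p = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                n_eff = int(np.count_nonzero(d))
                how = "exact" if n_eff <= 20 and not _has_ties(np.abs(d[d != 0])) else "approx"
                res = stats.wilcoxon(
                    a, b, zero_method="wilcox", correction=(how == "approx"), method=how
                )
            statistic, p = float(res.statistic), float(res.pvalue)
    else:
        test_used = "Mann-Whitney"
        n_small = max(a.size, b.size) <= 20
        method = "exact" if n_small and not _has_ties(np.concatenate([a, b])) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        statistic, p = float(res.statistic), float(res.pvalue)

    ma, mb = float(a.mean()), float(b.mean())
    direction = "none" if ma == mb else ("increase" if mb > ma else "decrease")
    return ComparisonResult(
        metric=metric,
        group_labels=group_labels,
        n=(a.size, b.size),
        normality_p=(pa, pb),
        test_used=test_used,  # type: ignore[arg-type]
        statistic=statistic,
        p_value=float(min(max(p, 0.0), 1.0)),
        means=(ma, mb),
        sems=(float(stats.sem(a)), float(stats.sem(b))),
        effect_direction=direction,  # type: ignore[arg-type]
        paired=paired,
        alpha=alpha,
        warnings_=warns,
    )


def _has_ties(x: np.ndarray) -> bool:
    return np.unique(x).size < x.size


def comparisons_frame(results: Sequence[ComparisonResult], bh_correct: bool = False) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "metric": [r.metric for r in results],
            "group_a": [r.group_labels[0] for r in results],
            "group_b": [r.group_labels[1] for r in results],
            "n_a": [r.n[0] for r in results],
            "n_b": [r.n[1] for r in results],
            "normality_p_a": [r.normality_p[0] for r in results],
            "normality_p_b": [r.normality_p[1] for r in results],
            "test_used": [r.test_used for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "mean_a": [r.means[0] for r in results],
            "mean_b": [r.means[1] for r in results],
            "sem_a": [r.sems[0] for r in results],
            "sem_b": [r.sems[1] for r in results],
            "effect_direction": [r.effect_direction for r in results],
            "paired": [r.paired for r in results],
        }
    )
    if bh_correct and len(df):
        df["p_adj_bh"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# report bundle


def events_frame(events) -> pd.DataFrame:
    """Tidy per-event table from CalciumTransient records."""
    return pd.DataFrame(
        {
            "roi_id": [e.roi_id for e in events],
            "trial": [e.trial for e in events],
            "onset_frame": [e.onset_frame for e in events],
            "offset_frame": [e.offset_frame for e in events],
            "duration_s": [e.duration_s for e in events],
            "peak_dff": [e.peak_dff for e in events],
            "integrated_activity": [e.integrated_activity for e in events],
            "prolonged": [e.prolonged for e in events],
            "large_amplitude": [e.large_amplitude for e in events],
        }
    )


def summaries_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "roi_id": [s.roi_id for s in summaries],
            "state": [s.state for s in summaries],
            "n_events": [s.n_events for s in summaries],
            "frequency_per_min": [s.frequency_per_min for s in summaries],
            "mean_duration_s": [s.mean_duration_s for s in summaries],
            "total_duration_s": [s.total_duration_s for s in summaries],
            "mean_peak": [s.mean_peak for s in summaries],
            "total_integrated_activity_per_min": [
                s.total_integrated_activity_per_min for s in summaries
            ],
            "minutes_observed": [s.minutes_observed for s in summaries],
        }
    )


def first_third_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "spine_id": [r.spine_id for r in records],
            "dendrite_id": [r.dendrite_id for r in records],
            "trial": [r.trial for r in records],
            "peak_pre": [r.peak_pre for r in records],
            "peak_post": [r.peak_post for r in records],
            "middle_duration_class": [r.middle_duration_class for r in records],
            "primary": [r.primary for r in records],
        }
    )


_SCHEMAS = {
    "events": [
        "roi_id", "trial", "onset_frame", "offset_frame", "duration_s",
        "peak_dff", "integrated_activity", "prolonged", "large_amplitude",
    ],
    "summaries": [
        "roi_id", "state", "n_events", "frequency_per_min", "mean_duration_s",
        "total_duration_s", "mean_peak", "total_integrated_activity_per_min",
        "minutes_observed",
    ],
}


def figure_tables(
    events=None,
    summaries=None,
    comparisons: Sequence[ComparisonResult] = (),
    dendrite_fractions: dict | None = None,
    first_third=None,
    size_change: pd.DataFrame | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Assemble one tidy table per figure-panel family plus a manifest.

    Empty inputs yield empty but schema-valid tables, so downstream writers
    never see missing columns.
    """
    ev = events_frame(events) if events else pd.DataFrame(columns=_SCHEMAS["events"])
    sm = (
        summaries_frame(summaries)
        if summaries
        else pd.DataFrame(columns=_SCHEMAS["summaries"])
    )
    tables = {
        "events": ev,
        "activity_summaries": sm,
        "comparisons": comparisons_frame(list(comparisons)),
        "dendrite_fractions": pd.DataFrame(
            [{"predicate": k, "fraction": v} for k, v in (dendrite_fractions or {}).items()]
        ),
        "first_third": first_third_frame(first_third) if first_third else pd.DataFrame(
            columns=[
                "spine_id", "dendrite_id", "trial", "peak_pre", "peak_post",
                "middle_duration_class", "primary",
            ]
        ),
        "size_change": size_change if size_change is not None else pd.DataFrame(
            columns=["spine_id", "ratio_session0", "ratio_session1", "size_change"]
        ),
    }
    manifest = {
        "config_hash": config_hash(config or {}),
        "seed": seed,
        "tables": {k: int(len(v)) for k, v in tables.items()},
    }
    return {"tables": tables, "manifest": manifest}


def write_report(bundle: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in bundle["tables"].items():
        df.to_csv(out / f"{name}.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(bundle["manifest"], indent=1))


def plot_distributions(bundle: dict, out_dir: str | Path) -> list[Path]:
    """Basic histograms of per-event duration and peak by ROI group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ev = bundle["tables"]["events"]
    paths = []
    if len(ev):
        for col in ("duration_s", "peak_dff"):
            fig, ax = plt.subplots(figsize=(4, 3))
            ax.hist(ev[col], bins=30, color="steelblue")
            ax.set_xlabel(col)
            ax.set_ylabel("transients")
            fig.tight_layout()
            p = out / f"dist_{col}.png"
            fig.savefig(p, dpi=100)
            plt.close(fig)
            paths.append(p)
    return paths
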