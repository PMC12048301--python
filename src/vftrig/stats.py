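"""Statistical battery and summary reporting.

Normality screening (Shapiro-Wilk at alpha = 0.05) routes two-group
comparisons to a t test or its rank-based equivalent; three or more groups
go to Kruskal-Wallis with Holm-Sidak-adjusted pairwise comparisons; 2x2
contingency tables use the two-sided Fisher exact test.  Narrative
summaries round means to one decimal and percentages to integers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

NORMALITY_ALPHA = 0.05


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    groups: list
    pairwise: pd.DataFrame | None = None
    warnings: list = field(default_factory=list)


def _is_normal(x: np.ndarray) -> bool:
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sps.shapiro(x).pvalue >= NORMALITY_ALPHA


def choose_test(samples: dict, paired: bool = False) -> TestResult:
    """Run the appropriate comparison for the given groups.

    ``samples`` maps group label -> 1-D array.  Two groups: t-type test if
    every group passes Shapiro-Wilk, else Wilcoxon signed-rank (paired) or
    rank-sum (unpaired).  More than two groups: Kruskal-Wallis with
    Holm-Sidak-adjusted pairwise rank-sum comparisons.
    """
    labels = list(samples)
    arrays = [np.asarray(samples[k], dtype=float) for k in labels]
    notes = []
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    small = any(len(a) < 3 for a in arrays)
    if small:
        notes.append("group with n < 3: defaulting to rank-based test")
    if len(arrays) == 2:
        a, b = arrays
        normal = (not small) and _is_normal(a) and _is_normal(b)
        if normal:
            if paired:
                res = sps.ttest_rel(a, b)
                name = "paired t test"
            else:
                res = sps.ttest_ind(a, b)
                name = "unpaired t test"
        else:
            if paired:
                res = sps.wilcoxon(a, b)
                name = "Wilcoxon signed rank"
            else:
                res = sps.mannwhitneyu(a, b, alternative="two-sided")
                name = "Wilcoxon rank sum"
        return TestResult(
            test_name=name, statistic=float(res.statistic),
            p_value=float(res.pvalue), groups=labels, warnings=notes,
        )
    res = sps.kruskal(*arrays)
    rows = []
    raw = []
    pairs = [(i, j) for i in range(len(arrays)) for j in range(i + 1, len(arrays))]
    for i, j in pairs:
        pr = sps.mannwhitneyu(arrays[i], arrays[j], alternative="two-sided")
        raw.append(pr.pvalue)
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "statistic": float(pr.statistic), "p_raw": float(pr.pvalue)})
    adj = holm_sidak(np.array(raw))
    for row, p in zip(rows, adj):
        row["p_adjusted"] = float(p)
    return TestResult(
        test_name="Kruskal-Wallis + Holm-Sidak pairwise",
        statistic=float(res.statistic), p_value=float(res.pvalue),
        groups=labels, pairwise=pd.DataFrame(rows), warnings=notes,
    )


def holm_sidak(pvals: np.ndarray) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values."""
    if len(pvals) == 0:
        return np.asarray(pvals, dtype=float)
    return multipletests(pvals, method="holm-sidak")[1]


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative integers.

    Sums hypergeometric probabilities (margins fixed) of all tables no more
    probable than the observed one; a zero margin yields p = 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("table entries must be non-negative integers")
        t = t.astype(int)
    if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def gradient_comparison(
    trigger_sites, nontrigger_sites
) -> dict:
    """Trigger vs nontrigger gradient summary (means, SDs, rank-sum p)."""
    if not trigger_sites or not nontrigger_sites:
        raise ValueError("both site groups must be non-empty")
    out = {"n_trigger": len(trigger_sites), "n_nontrigger": len(nontrigger_sites)}
    for kind in ("apd", "rt"):
        attr = f"{kind}_gradient_ms_mm"
        a = np.array([getattr(s, attr) for s in trigger_sites])
        b = np.array([getattr(s, attr) for s in nontrigger_sites])
        if np.allclose(a.mean(), b.mean()) and np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0
        elif len(a) >= 2 and len(b) >= 2:
            p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        else:
            p = np.nan
        out[f"{kind}_trigger_mean"] = float(a.mean())
        out[f"{kind}_trigger_sd"] = float(a.std(ddof=1)) if len(a) > 1 else 0.0
        out[f"{kind}_trigger_max"] = float(a.max())
        out[f"{kind}_nontrigger_mean"] = float(b.mean())
        out[f"{kind}_nontrigger_sd"] = float(b.std(ddof=1)) if len(b) > 1 else 0.0
        out[f"{kind}_nontrigger_max"] = float(b.max())
        out[f"{kind}_p_ranksum"] = p
    return out


def summarize_value(x: float, kind: str = "mean") -> str:
    """Narrative rounding: means to one decimal, percentages to integers."""
    if kind == "percent":
        return f"{x:.0f}%"
    if kind == "count":
        return f"{x:.0f}"
    return f"{x:.1f}"


def render_report(
    study_tables: dict,
    out_path=None,
    title: str = "Synthetic VF-trigger study report",
) -> str:
    """Deterministic Markdown report assembled from upstream tables.

    ``study_tables`` may contain: ``config`` (dict echo), ``seeds`` (list),
    ``episode_summary`` (DataFrame), ``gradient_comparison`` (dict),
    ``trigger_reports`` (list of dicts), ``incidence`` (dict with keys
    control/lesioned counts), ``version`` (str).
    """
    lines = [f"# {title}", ""]
    if "version" in study_tables:
        lines += [f"Software version: {study_tables['version']}", ""]
    if "seeds" in study_tables:
        lines += [f"Seeds: {study_tables['seeds']}", ""]
    inc = study_tables.get("incidence")
    if inc is not None:
        n_c, k_c = inc.get("control_n", 0), inc.get("control_vf", 0)
        n_l, k_l = inc.get("lesion_n", 0), inc.get("lesion_vf", 0)
        lines += ["## Incidence of spontaneous VF", ""]
        lines += [
            f"- control: {k_c}/{n_c} preparations with >= 1 spontaneous VF",
            f"- lesioned: {k_l}/{n_l} preparations with >= 1 spontaneous VF",
        ]
        if n_c and n_l:
            p = fisher_exact([[k_c, n_c - k_c], [k_l, n_l - k_l]])
            lines.append(f"- Fisher exact two-sided p = {p:.3g}")
        lines.append("")
    es = study_tables.get("episode_summary")
    if es is not None and len(es):
        lines += ["## Episode summary", "", es.to_markdown(index=False), ""]
    gc = study_tables.get("gradient_comparison")
    if gc is not None:
        lines += [
            "## Local gradients at trigger vs nontrigger sites", "",
            f"- APD80 gradient: {gc['apd_trigger_mean']:.1f} +/- "
            f"{gc['apd_trigger_sd']:.1f} ms/mm (trigger, n={gc['n_trigger']}) vs "
            f"{gc['apd_nontrigger_mean']:.1f} +/- {gc['apd_nontrigger_sd']:.1f} "
            f"ms/mm (nontrigger, n={gc['n_nontrigger']}); p = {gc['apd_p_ranksum']:.3g}",
            f"- RT gradient: {gc['rt_trigger_mean']:.1f} +/- {gc['rt_trigger_sd']:.1f}"
            f" ms/mm vs {gc['rt_nontrigger_mean']:.1f} +/- "
            f"{gc['rt_nontrigger_sd']:.1f} ms/mm; p = {gc['rt_p_ranksum']:.3g}",
            "",
        ]
    trs = study_tables.get("trigger_reports")
    if trs:
        lines += ["## Trigger origins", ""]
        df = pd.DataFrame(trs)
        lines += [df.to_markdown(index=False), ""]
    cfg = study_tables.get("config")
    if cfg is not None:
        import json

        lines += ["## Configuration echo", "", "```json",
                  json.dumps(cfg, indent=1, default=str), "```", ""]
    text = "\n".join(lines)
    if out_path is not None:
        from pathlib import Path

        Path(out_path).write_text(text)
    return text
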