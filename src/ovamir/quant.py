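"""Relative-expression statistics for the validation assays.

qPCR: Livak 2^-ddCt quantification of miRNA abundance against the U6
snRNA endogenous control, with a paired t-test on per-individual dCt
between stages (unpaired Welch fallback, flagged, when individuals are
not matched across stages).

Dual luciferase: per-well firefly/renilla ratios scaled to the
negative-control mean, one-way ANOVA across mimic groups within each
reporter construct, then per-mimic two-sided t-tests against the
negative control with Holm correction (correction configurable off).

Input tables are tidy TSV-style DataFrames:

* Ct table: individual, stage, target, rep, ct   (one row per technical
  replicate; U6 rows required for every individual x stage)
* luciferase table: construct, mimic, rep, firefly, renilla
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = ["RelativeExpression", "ddct", "luciferase_ratios"]


@dataclass
class RelativeExpression:
    """2^-ddCt summary for one miRNA in one stage contrast."""

    mirna: str
    stage: str
    reference_stage: str
    n: int
    per_individual_fold: pd.Series
    fold_mean: float
    fold_se: float
    t_stat: float
    p_value: float
    paired: bool
    significant: bool


def _collapse_tech(records: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates -> one Ct per (individual, stage, target)."""
    required = {"individual", "stage", "target", "ct"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    bad = records[(records.ct <= 0) | (records.ct > 40)]
    if len(bad):
        raise ValueError(f"{len(bad)} Ct values outside (0, 40]")
    return (records.groupby(["individual", "stage", "target"], as_index=False)
            .ct.mean())


def ddct(records: pd.DataFrame, reference_stage: str = "GV",
         control: str = "U6", alpha: float = 0.05
         ) -> list[RelativeExpression]:
    """Livak relative quantification against an endogenous control.

    dCt = Ct_miRNA - Ct_control per (individual, stage); ddCt subtracts
    the mean reference-stage dCt; fold = 2^-ddCt.  Samples without a
    control measurement are excluded (logged).  The test compares dCt
    between stages: paired t when individuals are matched, Welch
    otherwise (flagged in the result).  A contrast with zero variance in
    the paired differences degenerates to t=0, p=1.
    """
    flat = _collapse_tech(records)
    ctrl = flat[flat.target == control].set_index(["individual", "stage"]).ct
    if ctrl.empty:
        raise ValueError(f"no {control!r} rows in the Ct table")
    mirnas = flat[flat.target != control]
    out: list[RelativeExpression] = []
    for (mirna,), sub in mirnas.groupby(["target"]):
        d = sub.set_index(["individual", "stage"]).ct
        dct = {}
        for (ind, stage), ct in d.items():
            key = (ind, stage)
            if key not in ctrl.index:
                log.warning("sample %s/%s lacks %s; excluded", ind, stage, control)
                continue
            dct[key] = ct - ctrl.loc[key]
        dct = pd.Series(dct).rename_axis(["individual", "stage"])
        stages = sorted(dct.index.get_level_values("stage").unique())
        if reference_stage not in stages:
            raise ValueError(f"reference stage {reference_stage!r} absent for {mirna}")
        ref = dct.xs(reference_stage, level="stage")
        for stage in stages:
            if stage == reference_stage:
                continue
            test = dct.xs(stage, level="stage")
            common = sorted(set(test.index) & set(ref.index))
            paired = len(common) == len(test) == len(ref) and len(common) >= 2
            if paired:
                # matched individuals: each serves as its own reference,
                # cancelling per-individual baselines exactly
                ddct_i = test.loc[common] - ref.loc[common]
            else:
                ddct_i = test - ref.mean()
            fold = np.power(2.0, -ddct_i)
            if paired:
                diff = test.loc[common].to_numpy() - ref.loc[common].to_numpy()
                sd = np.std(diff, ddof=1)
                if sd < 1e-10 and abs(diff.mean()) < 1e-10:
                    t, p = 0.0, 1.0
                elif sd < 1e-10:
                    t, p = (np.inf * np.sign(diff.mean()), 0.0)
                else:
                    t, p = stats.ttest_rel(test.loc[common], ref.loc[common])
            else:
                log.warning("unmatched individuals for %s (%s vs %s): Welch test",
                            mirna, stage, reference_stage)
                t, p = stats.ttest_ind(test, ref, equal_var=False)
            n = len(test)
            se = float(fold.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            out.append(RelativeExpression(
                mirna=mirna, stage=stage, reference_stage=reference_stage,
                n=n, per_individual_fold=fold, fold_mean=float(fold.mean()),
                fold_se=se, t_stat=float(t), p_value=float(p), paired=paired,
                significant=bool(p < alpha)))
    return out


def relative_expression_frame(results: list[RelativeExpression]) -> pd.DataFrame:
    return pd.DataFrame([{
        "mirna": r.mirna, "stage": r.stage, "reference": r.reference_stage,
        "n": r.n, "fold_mean": r.fold_mean, "fold_se": r.fold_se,
        "t_stat": r.t_stat, "p_value": r.p_value, "paired": r.paired,
        "significant": r.significant} for r in results])


# --------------------------------------------------------------------------
# dual luciferase
# --------------------------------------------------------------------------

def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def luciferase_ratios(records: pd.DataFrame, nc_mimic: str = "NC",
                      alpha: float = 0.05, holm: bool = True
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize dual-luciferase readings and test mimic effects.

    Per well, ratio = firefly/renilla; ratios are scaled so the
    negative-control mean is 1 within each construct.  Within each
    construct a one-way ANOVA runs across all mimic groups, followed by
    per-mimic two-sided t-tests versus the negative control (Holm
    correction unless ``holm=False``).  Wells with non-positive signals
    are rejected with a logged message.  Returns (per-well normalized
    table, per-group stats table).
    """
    required = {"construct", "mimic", "rep", "firefly", "renilla"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"luciferase table missing columns: {sorted(missing)}")
    bad = records[(records.firefly <= 0) | (records.renilla <= 0)]
    for _, row in bad.iterrows():
        log.warning("rejected well %s/%s rep %s: non-positive signal",
                    row.construct, row.mimic, row.rep)
    ok = records.drop(bad.index).copy()
    ok["ratio"] = ok.firefly / ok.renilla
    tables = []
    stats_rows = []
    for construct, sub in ok.groupby("construct"):
        counts = sub.groupby("mimic").size()
        if (counts < 2).any():
            raise ValueError(f"construct {construct!r}: every mimic needs >= 2 "
                             f"replicates")
        if nc_mimic not in counts.index:
            raise ValueError(f"construct {construct!r}: no {nc_mimic!r} wells")
        nc_mean = sub.loc[sub.mimic == nc_mimic, "ratio"].mean()
        sub = sub.assign(normalized=sub.ratio / nc_mean)
        tables.append(sub)
        groups = [g.normalized.to_numpy() for _, g in sub.groupby("mimic")]
        if all(np.allclose(g, groups[0].mean()) for g in groups):
            f_stat, anova_p = 0.0, 1.0
        else:
            f_stat, anova_p = stats.f_oneway(*groups)
        nc_vals = sub.loc[sub.mimic == nc_mimic, "normalized"].to_numpy()
        mimics = [m for m in sorted(sub.mimic.unique()) if m != nc_mimic]
        pvals = []
        for m in mimics:
            vals = sub.loc[sub.mimic == m, "normalized"].to_numpy()
            if np.std(vals, ddof=1) == 0 and np.std(nc_vals, ddof=1) == 0:
                p = 1.0 if np.isclose(vals.mean(), nc_vals.mean()) else 0.0
                t = 0.0
            else:
                t, p = stats.ttest_ind(vals, nc_vals)
            pvals.append((m, float(t), float(p), float(vals.mean())))
        raw = np.array([p for _, _, p, _ in pvals]) if pvals else np.array([])
        adj = _holm(raw) if (holm and len(raw)) else raw
        for (m, t, p, mean_ratio), pa in zip(pvals, adj):
            stats_rows.append({
                "construct": construct, "mimic": m, "mean_ratio": mean_ratio,
                "anova_F": float(f_stat), "anova_p": float(anova_p),
                "t_stat": t, "p_value": p, "p_adjusted": float(pa),
                "significant": bool(pa < alpha)})
    table = pd.concat(tables, ignore_index=True)
    return table, pd.DataFrame(stats_rows)
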