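"""Recovery metrics of called enhancer classes against planted truth."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["match_to_truth", "recovery_metrics"]

UP_LIKE = ("up", "de_novo_gained")
DOWN_LIKE = ("down", "de_novo_lost")


def match_to_truth(called: pd.DataFrame, truth: pd.DataFrame) -> pd.Series:
    """Planted class for each called region (>= 1 bp overlap with a truth
    region; NaN when none). Truth regions are assumed disjoint."""
    out = np.full(len(called), None, dtype=object)
    for chrom, t in truth.groupby("chrom"):
        t = t.sort_values("start")
        t_start = t["start"].to_numpy()
        t_end = t["end"].to_numpy()
        t_cls = t["class"].to_numpy()
        mask = (called["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        c_start = called.loc[mask, "start"].to_numpy()
        c_end = called.loc[mask, "end"].to_numpy()
        idx = np.searchsorted(t_end, c_start, side="right")
        ok = idx < len(t_start)
        hit = np.zeros(len(c_start), dtype=bool)
        hit[ok] = t_start[idx[ok]] < c_end[ok]
        vals = np.full(len(c_start), None, dtype=object)
        vals[hit] = t_cls[idx[hit]]
        out[mask] = vals
    return pd.Series(out, index=called.index, name="planted_class")


def recovery_metrics(called: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Sensitivity and false-discovery rate of directional calls.

    A planted differential enhancer counts as recovered when some called
    region overlapping it carries a class of the same direction; a
    directional call on a planted unaffected enhancer is a false discovery.
    """
    call_cls = called["class"]
    call_up = call_cls.isin(UP_LIKE).to_numpy()
    call_down = call_cls.isin(DOWN_LIKE).to_numpy()

    recovered = set()
    false_calls = 0
    n_directional = int(call_up.sum() + call_down.sum())
    # map each called region back to its truth row for per-truth recovery
    matched = match_to_truth(called, truth.assign(
        **{"class": np.arange(len(truth))}))
    for i in range(len(called)):
        t_idx = matched.iloc[i]
        if t_idx is None:
            if call_up[i] or call_down[i]:
                false_calls += 1
            continue
        planted_cls = truth["class"].iloc[int(t_idx)]
        if call_up[i]:
            if planted_cls in UP_LIKE:
                recovered.add(int(t_idx))
            else:
                false_calls += 1
        elif call_down[i]:
            if planted_cls in DOWN_LIKE:
                recovered.add(int(t_idx))
            else:
                false_calls += 1
    n_planted_diff = int(truth["class"].isin(UP_LIKE + DOWN_LIKE).sum())
    sensitivity = len(recovered) / n_planted_diff if n_planted_diff else np.nan
    fdr = false_calls / n_directional if n_directional else 0.0
    return {
        "sensitivity": sensitivity,
        "fdr": fdr,
        "n_planted_differential": n_planted_diff,
        "n_directional_calls": n_directional,
    }
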