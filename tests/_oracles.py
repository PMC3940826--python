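"""Independent brute-force oracles used by the unit and acceptance suites."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def wilcoxon_enumeration_p(diffs: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p by enumerating all 2^n sign assignments.

    Zero differences are dropped and ties mid-ranked, mirroring the test's
    definition but computed by full enumeration (feasible for n <= ~14).
    Returns (W+ observed, p).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(bool)
    w_all = signs @ ranks
    p_le = np.mean(w_all <= w_obs + 1e-9)
    p_ge = np.mean(w_all >= w_obs - 1e-9)
    return w_obs, float(min(1.0, 2.0 * min(p_le, p_ge)))


def daily_totals_by_hand(day_rows, composition_indexed, nutrients) -> dict[str, float]:
    """Per-item python re-summation of one participant-day's nutrients."""
    out = {n: 0.0 for n in nutrients}
    for _, r in day_rows.iterrows():
        rec = composition_indexed.loc[r["food_code"]]
        for n in nutrients:
            out[n] += r["amount"] * rec[n] / 100.0
    return out
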