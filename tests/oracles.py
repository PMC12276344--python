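"""Independent re-implementations used as oracles.

These deliberately avoid the package's own code paths: classification rules
are re-evaluated inequality by inequality, matching by a repeated
global-minimum search, confusion counts by a plain tally, and the Kaplan-
Meier product-limit by hand on sorted times.
"""

from __future__ import annotations

import numpy as np


def classify_oracle(evafs: list[float | None], baseline_evaf: float | None,
                    abs_rise: float = 0.01):
    """Per-sample rule evaluation from raw eVAF values (None = undetected).

    Returns a list of dicts mirroring the sample-call fields, with the
    first entry the baseline (rise fields None there).
    """
    out = []
    prior = None
    for i, e in enumerate(evafs):
        eff = 0.0 if e is None else e
        row = {"cleared": e is None}
        if baseline_evaf is not None and baseline_evaf > 0:
            ratio = eff / baseline_evaf
            row["ratio"] = ratio
            row["response"] = ratio < 0.10
            for thr in (0.75, 0.50, 0.25, 0.10):
                row[f"rel_{thr}"] = ratio >= thr
        else:
            row.update({"ratio": None, "response": None})
        if i == 0 or prior is None:
            row.update({"rise_any": None, "rise_abs": None})
        else:
            delta = eff - prior
            row["rise_any"] = delta > 0
            row["rise_abs"] = delta > abs_rise
        if baseline_evaf and i > 0:
            row["combined"] = bool(row.get("rise_abs")) or row["rel_0.5"]
        prior = eff
        out.append(row)
    return out


def greedy_match_oracle(sample_days: list[int], scan_days: list[int],
                        window: int) -> set[tuple[int, int]]:
    """Repeated global-minimum |gap| one-to-one assignment (greedy order)."""
    free_s = set(range(len(sample_days)))
    free_c = set(range(len(scan_days)))
    matched = set()
    while True:
        best = None
        for i in sorted(free_s):
            for j in sorted(free_c):
                gap = abs(scan_days[j] - sample_days[i])
                if gap > window:
                    continue
                key = (gap, scan_days[j], sample_days[i])
                if best is None or key < best[0]:
                    best = (key, i, j)
        if best is None:
            return matched
        _, i, j = best
        matched.add((i, j))
        free_s.discard(i)
        free_c.discard(j)


def confusion_oracle(calls: list[bool], refs: list[bool]):
    tp = sum(c and r for c, r in zip(calls, refs))
    fp = sum(c and not r for c, r in zip(calls, refs))
    fn = sum((not c) and r for c, r in zip(calls, refs))
    tn = sum((not c) and (not r) for c, r in zip(calls, refs))
    return tp, fp, fn, tn


def km_oracle(durations: np.ndarray, events: np.ndarray):
    """Hand-rolled product-limit estimate: (event_times, survival)."""
    order = np.argsort(durations, kind="stable")
    durations, events = durations[order], events[order]
    times, surv = [], []
    s = 1.0
    n = len(durations)
    i = 0
    while i < n:
        t = durations[i]
        d = int(sum(events[(durations == t)]))
        at_risk = int(sum(durations >= t))
        if d > 0:
            s *= 1.0 - d / at_risk
            times.append(float(t))
            surv.append(s)
        i = int(np.searchsorted(durations, t, side="right"))
    return np.array(times), np.array(surv)


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """1 - 6*sum(d^2)/(n(n^2-1)); valid without ties."""
    rx = np.argsort(np.argsort(x))
    ry = np.argsort(np.argsort(y))
    d = rx - ry
    n = len(x)
    return 1.0 - 6.0 * float(np.sum(d * d)) / (n * (n * n - 1))
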