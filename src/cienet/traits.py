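"""Derive per-mouse drinking traits from daily intake records.

Weekly baseline means b1-b6, per-CIE-cycle means t1-t4, and absolute /
percent change of each cycle mean versus the baseline reference. These
trait vectors are what gene and module expression is correlated against.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BASELINE_PHASES = [f"baseline_w{w}" for w in range(1, 7)]
CYCLE_PHASES = [f"cie_c{c}" for c in range(1, 5)]
TRAIT_COLUMNS = (
    [f"b{w}" for w in range(1, 7)]
    + [f"t{c}" for c in range(1, 5)]
    + [f"abs_change_{c}" for c in range(1, 5)]
    + [f"pct_change_{c}" for c in range(1, 5)]
)


def derive_traits(record: pd.DataFrame, baseline: str = "mean") -> pd.DataFrame:
    """Per-mouse trait table from a long drinking record.

    Parameters
    ----------
    record
        Columns mouse_id, session, phase, intake_gkg. Phases must be the six
        baseline weeks and four CIE cycles; each phase a mouse appears in
        must have at least one session.
    baseline
        Reference used for the change measures: ``"mean"`` (mean of the six
        weekly baseline means, default) or ``"lastweek"`` (b6 only).

    Returns a DataFrame with mouse_id, b1-b6, t1-t4, abs_change_1..4 (g/kg),
    pct_change_1..4 (%), and ``pct_defined`` (False where baseline is 0, in
    which case percent change is reported as 0 and should be ignored).
    """
    if baseline not in ("mean", "lastweek"):
        raise ValueError("baseline must be 'mean' or 'lastweek'")
    needed = {"mouse_id", "phase", "intake_gkg"}
    if not needed.issubset(record.columns):
        raise ValueError(f"drinking record missing columns {needed - set(record.columns)}")
    known = set(BASELINE_PHASES) | set(CYCLE_PHASES)
    bad = set(record["phase"]) - known
    if bad:
        raise ValueError(f"unknown phase labels: {sorted(bad)}")

    means = (
        record.groupby(["mouse_id", "phase"], sort=False)["intake_gkg"]
        .mean()
        .unstack("phase")
    )
    missing = [ph for ph in BASELINE_PHASES + CYCLE_PHASES if ph not in means.columns]
    if missing:
        raise ValueError(f"phases with no sessions: {missing}")
    if means.isna().any().any():
        who = means.index[means.isna().any(axis=1)].tolist()
        raise ValueError(f"mice with a phase lacking sessions: {who}")

    out = pd.DataFrame({"mouse_id": means.index})
    for w, ph in enumerate(BASELINE_PHASES, start=1):
        out[f"b{w}"] = means[ph].to_numpy()
    for c, ph in enumerate(CYCLE_PHASES, start=1):
        out[f"t{c}"] = means[ph].to_numpy()

    if baseline == "mean":
        base = out[[f"b{w}" for w in range(1, 7)]].mean(axis=1).to_numpy()
    else:
        base = out["b6"].to_numpy()

    defined = base > 0
    for c in range(1, 5):
        tc = out[f"t{c}"].to_numpy()
        out[f"abs_change_{c}"] = tc - base
        pct = np.zeros_like(tc)
        np.divide(100.0 * (tc - base), base, out=pct, where=defined)
        out[f"pct_change_{c}"] = pct
    out["pct_defined"] = defined
    return out.reset_index(drop=True)
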