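"""Relative transcript quantification by the ddCt method, and RIP enrichment.

Per replicate, dCt = Ct_target - Ct_reference normalizes out input amounts via
a housekeeping reference (e.g. HPRT mRNA or 18S rRNA); ddCt is the
replicate-paired difference of dCt between a condition and its control, and
the fold change is 2^-ddCt (amplification efficiency fixed at 100%).
Replicates are aggregated on the log scale — fold = 2^(-mean ddCt), the
geometric mean of per-replicate folds — with the SEM of per-replicate log2
folds as the error estimate.  Significance is a two-tailed paired t-test on
the per-replicate dCt pairs at alpha = 0.1.

RNA-immunoprecipitation (RIP) enrichment compares elution-over-input Ct
differences between the specific antibody and control beads:

    enrichment = 2^-[(Ct_ELU,ab - Ct_INP,ab) - (Ct_ELU,beads - Ct_INP,beads)]
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CT_COLUMNS",
    "FoldChange",
    "delta_delta_ct",
    "rip_enrichment",
    "read_ct_csv",
]

CT_COLUMNS = [
    "target", "reference_flag", "condition", "replicate", "fraction",
    "antibody", "ct",
]

DEFAULT_ALPHA = 0.1


@dataclass
class FoldChange:
    target: str
    condition_vs_control: str
    fold: float
    log2_fold: float
    sem: float
    p_value: float  # nan when < 2 replicates or zero variance
    significant: bool
    n_replicates: int
    note: str = ""


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if not np.isfinite(table["ct"]).all():
        raise ValueError("all Ct values must be finite")
    key = ["target", "condition", "replicate", "fraction", "antibody"]
    if table.duplicated(subset=key).any():
        raise ValueError("duplicate (target, condition, replicate, fraction, antibody)")
    return table


def _ct_lookup(table, target, condition, fraction="total", antibody="none"):
    sel = table[
        (table["target"] == target)
        & (table["condition"] == condition)
        & (table["fraction"] == fraction)
        & (table["antibody"] == antibody)
    ]
    return dict(zip(sel["replicate"], sel["ct"]))


def delta_delta_ct(
    table: pd.DataFrame,
    target: str,
    reference: str,
    condition: str,
    control_condition: str,
    alpha: float = DEFAULT_ALPHA,
) -> FoldChange:
    """ddCt fold change of ``target`` (vs ``reference`` gene) between a
    condition and its control, aggregated over paired replicates.

    With fewer than 2 shared replicates, or zero variance across replicates,
    the fold is still reported and the p-value is NaN with a note.
    """
    table = _validate(table)
    t_cond = _ct_lookup(table, target, condition)
    t_ctrl = _ct_lookup(table, target, control_condition)
    r_cond = _ct_lookup(table, reference, condition)
    r_ctrl = _ct_lookup(table, reference, control_condition)
    reps = sorted(set(t_cond) & set(t_ctrl) & set(r_cond) & set(r_ctrl))
    if not reps:
        raise ValueError("no replicate measured in both conditions for target and reference")
    dct_cond = np.array([t_cond[r] - r_cond[r] for r in reps])
    dct_ctrl = np.array([t_ctrl[r] - r_ctrl[r] for r in reps])
    ddct = dct_cond - dct_ctrl
    log2_fold = float(-np.mean(ddct))
    fold = float(2.0 ** log2_fold)
    sem = float(np.std(ddct, ddof=1) / math.sqrt(len(ddct))) if len(ddct) > 1 else float("nan")
    note = ""
    if len(reps) < 2:
        p = float("nan")
        note = "p-value unavailable: fewer than 2 paired replicates"
    elif np.allclose(np.std(ddct, ddof=1), 0.0):
        p = float("nan")
        note = ("p-value undefined at zero replicate variance "
                "(differences identical to machine precision)")
    else:
        p = float(stats.ttest_rel(dct_cond, dct_ctrl).pvalue)
    return FoldChange(
        target=target,
        condition_vs_control=f"{condition} vs {control_condition}",
        fold=fold, log2_fold=log2_fold, sem=sem, p_value=p,
        significant=bool(np.isfinite(p) and p < alpha),
        n_replicates=len(reps), note=note,
    )


def rip_enrichment(
    table: pd.DataFrame,
    target: str,
    antibody: str = "flag",
    control_antibody: str = "beads",
    condition: str | None = None,
) -> FoldChange:
    """Fold enrichment of a transcript in the antibody IP over control beads,
    each normalized to its input (INP) fraction; aggregated as in
    :func:`delta_delta_ct`.  Adding a constant to all Cts of a replicate
    (plate shift) cancels exactly.
    """
    table = _validate(table)
    if condition is not None:
        table = table[table["condition"] == condition]

    def lut(frac, ab):
        sel = table[
            (table["target"] == target)
            & (table["fraction"] == frac)
            & (table["antibody"] == ab)
        ]
        return dict(zip(sel["replicate"], sel["ct"]))

    elu_ab, inp_ab = lut("ELU", antibody), lut("INP", antibody)
    elu_ct, inp_ct = lut("ELU", control_antibody), lut("INP", control_antibody)
    if not inp_ab or not inp_ct:
        raise ValueError("missing INP (input) Ct values for enrichment normalization")
    reps = sorted(set(elu_ab) & set(inp_ab) & set(elu_ct) & set(inp_ct))
    if not reps:
        raise ValueError("no replicate with complete ELU/INP measurements")
    d_ab = np.array([elu_ab[r] - inp_ab[r] for r in reps])
    d_ct = np.array([elu_ct[r] - inp_ct[r] for r in reps])
    ddct = d_ab - d_ct
    log2_fold = float(-np.mean(ddct))
    sem = float(np.std(ddct, ddof=1) / math.sqrt(len(ddct))) if len(ddct) > 1 else float("nan")
    if len(reps) > 1 and not np.allclose(np.std(ddct, ddof=1), 0.0):
        p = float(stats.ttest_rel(d_ab, d_ct).pvalue)
    else:
        p = float("nan")
    return FoldChange(
        target=target,
        condition_vs_control=f"{antibody} vs {control_antibody}",
        fold=float(2.0 ** log2_fold), log2_fold=log2_fold, sem=sem,
        p_value=p, significant=bool(np.isfinite(p) and p < DEFAULT_ALPHA),
        n_replicates=len(reps),
    )


def read_ct_csv(path) -> pd.DataFrame:
    return _validate(pd.read_csv(path))
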