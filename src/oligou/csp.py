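"""Amide chemical-shift-perturbation (CSP) mapping between free and bound states.

Combined amide CSP per residue, from assigned 1H-15N HSQC peak lists:

    csp = sqrt((w_HN * d_HN)^2 + (w_N * d_N)^2)

with the conventional nucleus weights w_HN = 1 and w_N = 0.154 that place 15N
shifts on the 1H scale.  Peaks that vanish from the bound spectrum
(intermediate-exchange broadening) are recorded with the sentinel CSP of 1.0
ppm and excluded from the threshold statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PeakList",
    "CSPProfile",
    "combined_csp",
    "call_perturbed",
    "read_peaklist_csv",
    "write_profile_csv",
    "DEFAULT_W_HN",
    "DEFAULT_W_N",
    "DISAPPEARED_CSP",
]

DEFAULT_W_HN = 1.0
DEFAULT_W_N = 0.154
#: sentinel assigned to peaks lost to exchange broadening on binding
DISAPPEARED_CSP = 1.0


@dataclass
class PeakList:
    """Assigned amide peaks: residue number -> (delta_HN ppm, delta_N ppm)."""

    entries: dict[int, tuple[float, float]]
    state_label: str = ""

    def __post_init__(self) -> None:
        for res, (h, n) in self.entries.items():
            if not (math.isfinite(h) and math.isfinite(n)):
                raise ValueError(f"non-finite shift for residue {res}")


@dataclass
class CSPProfile:
    per_residue: dict[int, float]
    disappeared: set[int] = field(default_factory=set)
    w_HN: float = DEFAULT_W_HN
    w_N: float = DEFAULT_W_N


def combined_csp(
    free: PeakList,
    bound: PeakList,
    w_HN: float = DEFAULT_W_HN,
    w_N: float = DEFAULT_W_N,
) -> CSPProfile:
    """Per-residue combined CSP between a free and a bound peak list.

    Residues present in both lists get the weighted-quadrature CSP; residues
    present only in the free list are recorded as disappeared with CSP 1.0;
    residues appearing only in the bound list are skipped with a warning
    (they cannot be matched without the free-state assignment).
    """
    if free.state_label and free.state_label == bound.state_label:
        raise ValueError("free and bound peak lists carry the same state label")
    if w_HN <= 0 or w_N <= 0:
        raise ValueError("weights must be positive")
    common = set(free.entries) & set(bound.entries)
    if not common and free.entries:
        raise ValueError("no residues shared between free and bound lists")
    extra = set(bound.entries) - set(free.entries)
    if extra:
        warnings.warn(
            f"{len(extra)} residues present only in the bound list were skipped",
            stacklevel=2,
        )
    per: dict[int, float] = {}
    gone: set[int] = set()
    for res in sorted(free.entries):
        h_f, n_f = free.entries[res]
        if res in bound.entries:
            h_b, n_b = bound.entries[res]
            per[res] = math.hypot(w_HN * (h_b - h_f), w_N * (n_b - n_f))
        else:
            per[res] = DISAPPEARED_CSP
            gone.add(res)
    return CSPProfile(per_residue=per, disappeared=gone, w_HN=w_HN, w_N=w_N)


def call_perturbed(
    profile: CSPProfile,
    method: str = "mean_sd",
    n_sd: float = 1.0,
) -> set[int]:
    """Call significantly perturbed residues.

    Default rule: CSP > mean + ``n_sd``*SD, with mean/SD computed over measured
    residues only (the 1.0-ppm sentinel of disappeared peaks would otherwise
    inflate the threshold).  Disappeared residues are always in the called set.
    An all-zero profile returns the empty set.
    """
    if not profile.per_residue:
        raise ValueError("empty CSP profile")
    if method != "mean_sd":
        raise ValueError(f"unknown method {method!r}")
    measured = {
        r: v for r, v in profile.per_residue.items() if r not in profile.disappeared
    }
    called = set(profile.disappeared)
    if measured:
        vals = np.array(list(measured.values()))
        thr = vals.mean() + n_sd * vals.std(ddof=1) if len(vals) > 1 else np.inf
        if np.any(vals > 0):
            called |= {r for r, v in measured.items() if v > thr}
    return called


def read_peaklist_csv(path, state_label: str = "") -> PeakList:
    """Read `residue,aa,delta_HN_ppm,delta_N_ppm` (the `aa` column is optional)."""
    df = pd.read_csv(path)
    entries = {
        int(row["residue"]): (float(row["delta_HN_ppm"]), float(row["delta_N_ppm"]))
        for _, row in df.iterrows()
    }
    if len(entries) != len(df):
        raise ValueError("duplicate residue numbers in peak list")
    return PeakList(entries=entries, state_label=state_label)


def write_profile_csv(profile: CSPProfile, path) -> None:
    rows = [
        {"residue": r, "csp_ppm": v, "disappeared": r in profile.disappeared}
        for r, v in sorted(profile.per_residue.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
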