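"""Label-free top-3 protein quantification and the oligo(U) enrichment filter.

Peptide-spectrum matches are first filtered (q-value < 1%, rank 1, at least
6 residues), each protein's abundance per sample is the mean area of its three
most intense peptides ("top-3 quantification"), and a protein is called
enriched on the U30 bait when its U30/control area ratio is at least
``fold_min`` in at least ``min_replicates`` paired replicates.  A protein
detected on the bait but absent from the paired control is EXCLUSIVE, which
counts as passing; absence is always represented explicitly (NaN), never as a
zero area, so no fold is ever a division by zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EXCLUSIVE",
    "EnrichmentCall",
    "filter_peptides",
    "top3_area",
    "build_quant_matrix",
    "enrichment_filter",
    "overlap_report",
]

PEPTIDE_COLUMNS = ["protein_id", "peptide_seq", "q_value", "rank", "area", "sample_id"]

#: sentinel fold for bait-detected / control-absent replicates
EXCLUSIVE = "EXCLUSIVE"


@dataclass
class EnrichmentCall:
    protein_id: str
    per_replicate_fold: list  # float, EXCLUSIVE, or nan when bait-absent
    n_passing: int
    passed: bool
    exclusive: bool  # at least one passing replicate was control-absent


def filter_peptides(
    records: pd.DataFrame,
    q_max: float = 0.01,
    rank_required: int = 1,
    min_len: int = 6,
) -> pd.DataFrame:
    """Keep peptides with q_value strictly below ``q_max`` (the "< 1%" rule),
    search rank equal to ``rank_required`` and sequence length >= ``min_len``."""
    missing = [c for c in ("q_value", "rank", "peptide_seq") if c not in records]
    if missing:
        raise ValueError(f"peptide table missing columns: {missing}")
    keep = (
        (records["q_value"] < q_max)
        & (records["rank"] == rank_required)
        & (records["peptide_seq"].str.len() >= min_len)
    )
    return records.loc[keep].reset_index(drop=True)


def top3_area(areas: Sequence[float]) -> tuple[float, bool]:
    """Mean of the three largest peptide areas for one protein in one sample.

    With fewer than three peptides the mean of all available areas is returned
    and the result is flagged low-evidence.  No peptides -> not detected
    (``(nan, False)``).
    """
    vals = sorted((float(a) for a in areas), reverse=True)
    if not vals:
        return float("nan"), False
    top = vals[:3]
    return sum(top) / len(top), len(vals) < 3


def build_quant_matrix(peptides: pd.DataFrame) -> pd.DataFrame:
    """Protein x sample matrix of top-3 areas from a filtered peptide table.

    Missing (protein, sample) combinations are NaN = not detected.
    """
    rows = []
    for (prot, sample), grp in peptides.groupby(["protein_id", "sample_id"]):
        area, _ = top3_area(grp["area"])
        rows.append({"protein_id": prot, "sample_id": sample, "area": area})
    if not rows:
        return pd.DataFrame()
    return (
        pd.DataFrame(rows)
        .pivot(index="protein_id", columns="sample_id", values="area")
    )


def enrichment_filter(
    matrix: pd.DataFrame,
    u30_samples: Sequence[str],
    ctrl_samples: Sequence[str],
    fold_min: float = 5.0,
    min_replicates: int = 2,
) -> list[EnrichmentCall]:
    """Call bait-enriched proteins from a protein x sample area matrix.

    ``u30_samples`` and ``ctrl_samples`` are paired by position (replicate r of
    the bait against replicate r of the control).  Per replicate the fold is
    area_U30/area_ctrl; bait detected with control absent is EXCLUSIVE and
    passes; bait absent never passes.  A protein passes overall when at least
    ``min_replicates`` replicates pass (fold >= fold_min, inclusive, per the
    at-least-five-fold rule).
    """
    if len(u30_samples) != len(ctrl_samples):
        raise ValueError("u30 and control sample lists must pair one-to-one")
    for s in list(u30_samples) + list(ctrl_samples):
        if s not in matrix.columns:
            raise ValueError(f"sample {s!r} absent from the quant matrix")
    calls = []
    for prot, row in matrix.iterrows():
        folds: list = []
        n_pass = 0
        any_exclusive = False
        for u, c in zip(u30_samples, ctrl_samples):
            a_u, a_c = row[u], row[c]
            if pd.isna(a_u):
                folds.append(float("nan"))
            elif pd.isna(a_c):
                folds.append(EXCLUSIVE)
                n_pass += 1
                any_exclusive = True
            else:
                f = a_u / a_c
                folds.append(f)
                if f >= fold_min:
                    n_pass += 1
        calls.append(EnrichmentCall(
            protein_id=str(prot), per_replicate_fold=folds,
            n_passing=n_pass, passed=n_pass >= min_replicates,
            exclusive=any_exclusive,
        ))
    return calls


def overlap_report(
    passed: set[str],
    reference_list: set[str],
    id_mapping: dict[str, str] | None = None,
) -> tuple[int, int, list[str]]:
    """Overlap of a passed-protein set with a reference list of gene symbols.

    Symbols are compared case-insensitively after applying the optional
    ``id_mapping`` (e.g. accession -> symbol).  Returns
    ``(n_passed, n_overlap, sorted overlapping symbols)``.
    """
    def norm(s: str) -> str:
        s = (id_mapping or {}).get(s, s)
        return s.strip().upper()

    a = {norm(s) for s in passed}
    b = {norm(s) for s in reference_list}
    inter = sorted(a & b)
    return len(a), len(inter), inter


def calls_to_frame(calls: list[EnrichmentCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "protein_id": c.protein_id,
            "folds": ";".join(
                f if isinstance(f, str) else f"{f:.4g}" for f in c.per_replicate_fold
            ),
            "n_passing": c.n_passing,
            "passed": c.passed,
            "exclusive": c.exclusive,
        })
    return pd.DataFrame(rows)
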