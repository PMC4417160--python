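"""Seeded synthetic-data generators for every pipeline stage.

Each generator draws from its own ``numpy.random.default_rng(seed)`` stream —
no global state — so the same (arguments, seed) always produce byte-identical
output, and setting the noise/jitter level to zero produces exact model
values.  The generators emit the already-reduced tables and coordinates each
analysis stage consumes (titration tables, assigned peak lists, coordinate
ensembles, a toy genome with annotated features, replicate quantification
tables, Ct tables); they do not simulate raw spectra, chromatograms or reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .csp import PeakList
from .ensemble import StructureEnsemble
from .isotherm import TitrationSeries, predict_anisotropy
from .motifs import (
    Feature,
    FeatureSet,
    Window,
    normalize_motif,
    reverse_complement,
)

__all__ = [
    "GeneratorConfig",
    "gen_titration",
    "gen_peaklists",
    "gen_ensemble",
    "gen_genome",
    "gen_quant_tables",
    "gen_ct_table",
    "gen_rip_table",
    "QuantSim",
]


@dataclass
class GeneratorConfig:
    """Stage-agnostic generator settings used by the pipeline runner."""

    seed: int = 0
    noise_sd: float = 0.0
    n_items: int = 10
    planted_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_items < 1:
            raise ValueError("n_items must be positive")


def gen_titration(
    kd_uM: float,
    r_free: float,
    r_bound: float,
    rna_total_uM: float,
    protein_concs: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    rna_label: str = "UUUUUUU",
) -> TitrationSeries:
    """Simulate a labeled-RNA anisotropy titration.

    Anisotropy at each point is the ligand-depletion model value plus i.i.d.
    Gaussian noise of SD ``noise_sd`` (anisotropy units).
    """
    if kd_uM <= 0 or rna_total_uM <= 0:
        raise ValueError("kd_uM and rna_total_uM must be positive")
    if r_bound == r_free:
        raise ValueError("r_bound must differ from r_free")
    p = np.asarray(protein_concs, dtype=float)
    if not np.all(np.isfinite(p)) or np.any(p < 0):
        raise ValueError("protein concentrations must be finite and non-negative")
    rng = np.random.default_rng(seed)
    r = predict_anisotropy(p, rna_total_uM, kd_uM, r_free, r_bound, "depletion")
    if noise_sd > 0:
        r = r + rng.normal(0.0, noise_sd, size=len(p))
    return TitrationSeries(
        rna_label=rna_label, rna_total_uM=rna_total_uM,
        points=list(zip(p.tolist(), np.asarray(r).tolist())),
    )


def gen_peaklists(
    n_residues: int,
    perturbed: Mapping[int, tuple[float, float]] | None = None,
    disappeared: Iterable[int] = (),
    seed: int = 0,
    noise_ppm: tuple[float, float] = (0.0, 0.0),
) -> tuple[PeakList, PeakList]:
    """Free/bound amide peak-list pair with planted perturbations.

    The free list has random but realistic amide shifts (1H in 7.5-9.5 ppm,
    15N in 105-130 ppm).  The bound list equals the free list shifted by the
    planted (dHN, dN) deltas for ``perturbed`` residues; ``disappeared``
    residues are dropped from the bound list; all other residues move only by
    the optional per-nucleus Gaussian ``noise_ppm``.
    """
    perturbed = dict(perturbed or {})
    disappeared = set(disappeared)
    residues = set(range(1, n_residues + 1))
    if not set(perturbed) <= residues or not disappeared <= residues:
        raise ValueError("perturbed/disappeared residues out of range")
    if set(perturbed) & disappeared:
        raise ValueError("perturbed and disappeared residue sets must be disjoint")
    rng = np.random.default_rng(seed)
    free = {
        r: (float(rng.uniform(7.5, 9.5)), float(rng.uniform(105.0, 130.0)))
        for r in sorted(residues)
    }
    sd_h, sd_n = noise_ppm
    bound = {}
    for r, (h, n) in free.items():
        if r in disappeared:
            continue
        dh, dn = perturbed.get(r, (0.0, 0.0))
        jh = rng.normal(0.0, sd_h) if sd_h > 0 else 0.0
        jn = rng.normal(0.0, sd_n) if sd_n > 0 else 0.0
        bound[r] = (h + dh + jh, n + dn + jn)
    return (
        PeakList(entries=free, state_label="free"),
        PeakList(entries=bound, state_label="bound"),
    )


def _reference_chain(n_residues: int) -> tuple[list[tuple[str, int]], np.ndarray]:
    """Synthetic backbone trace: CA atoms on a helix-like curve with N, C, O
    placed at fixed local offsets (non-collinear by construction)."""
    atoms = []
    xyz = []
    turn = np.deg2rad(100.0)
    for i in range(1, n_residues + 1):
        th = turn * i
        ca = np.array([2.3 * np.cos(th), 2.3 * np.sin(th), 1.5 * i])
        offsets = {
            "N": ca + np.array([-1.2, 0.5, -0.4]),
            "CA": ca,
            "C": ca + np.array([1.2, 0.5, 0.4]),
            "O": ca + np.array([1.4, 1.6, 0.6]),
            "CB": ca + np.array([-0.5, -1.3, 0.3]),
        }
        for name, pos in offsets.items():
            atoms.append((name, i))
            xyz.append(pos)
    return atoms, np.array(xyz)


def gen_ensemble(
    n_models: int,
    n_residues: int,
    jitter_A: float = 0.0,
    seed: int = 0,
    ss_regions: Sequence[tuple[int, int]] | None = None,
) -> StructureEnsemble:
    """Jittered coordinate ensemble around one reference chain.

    Each model is the reference chain plus i.i.d. Gaussian displacement of SD
    ``jitter_A`` per coordinate, followed by an arbitrary rigid rotation and
    translation so downstream superposition is genuinely exercised.
    """
    from scipy.spatial.transform import Rotation

    if n_models < 2:
        raise ValueError("an ensemble needs at least 2 models")
    if jitter_A < 0:
        raise ValueError("jitter_A must be non-negative")
    rng = np.random.default_rng(seed)
    atoms, ref = _reference_chain(n_residues)
    models = []
    for _ in range(n_models):
        xyz = ref.copy()
        if jitter_A > 0:
            xyz = xyz + rng.normal(0.0, jitter_A, size=xyz.shape)
        rot = Rotation.random(rng=rng).as_matrix()
        trans = rng.uniform(-50.0, 50.0, size=3)
        models.append(xyz @ rot.T + trans)
    if ss_regions is None and n_residues >= 8:
        third = n_residues // 3
        ss_regions = [(2, 1 + third), (n_residues - third, n_residues - 1)]
    return StructureEnsemble(atoms, np.array(models), ss_regions=ss_regions)


def _scan_extra_occurrences(seq: str, motif: str, planted_at: int | None) -> list[int]:
    k = len(motif)
    return [
        i for i in range(len(seq) - k + 1)
        if seq[i:i + k] == motif and i != planted_at
    ]


def gen_genome(
    n_features: int,
    chrom_len: int,
    motif: str | None = "TTTTT",
    offset_nt: int = 10,
    strand_mix: float = 0.5,
    seed: int = 0,
    feature_len: int = 150,
    window: Window = Window(),
    chrom: str = "chr1",
) -> tuple[str, FeatureSet]:
    """Toy genome (FASTA text) plus features with a planted downstream motif.

    Features are placed non-overlapping, with full window clearance from each
    other and from the chromosome ends.  Each feature gets the motif planted
    starting exactly ``offset_nt`` downstream of its 3' end on its own strand
    (a fraction ``strand_mix`` of the features lies on the minus strand, where
    the planted copy appears reverse-complemented in the plus-strand FASTA).
    Background bases are i.i.d. uniform over A,C,G,T; any accidental extra
    occurrence of the motif inside a feature's scored window is resampled
    away, so construction-based positional counts are exact.  Pass
    ``motif=None`` for a background-only genome with no planting.
    """
    m = normalize_motif(motif) if motif is not None else None
    k = len(m) if m else 0
    clearance = window.upstream_nt + window.downstream_nt + k
    pitch = feature_len + 2 * clearance
    if chrom_len < n_features * pitch + clearance:
        raise ValueError(
            f"chrom_len too small: need >= {n_features * pitch + clearance}"
        )
    if m is not None and not (-window.upstream_nt <= offset_nt
                              <= window.downstream_nt - k):
        raise ValueError("offset_nt places the motif outside the scored window")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seq = rng.integers(0, 4, size=chrom_len)

    feats = []
    n_minus = int(round(strand_mix * n_features))
    for i in range(n_features):
        lo = clearance + i * pitch + int(rng.integers(0, clearance // 2 + 1))
        strand = "-" if i < n_minus else "+"
        feats.append(Feature(chrom=chrom, start=lo, end=lo + feature_len,
                             strand=strand, name=f"feat{i + 1}"))
    order = rng.permutation(n_features)
    feats = [feats[i] for i in order]

    seq_list = [bases[b] for b in seq]
    planted_spans = []
    if m is not None:
        for f in feats:
            if f.strand == "+":
                g0 = f.end + offset_nt
                for j, c in enumerate(m):
                    seq_list[g0 + j] = c
                planted_spans.append((f, g0))
            else:
                g0 = f.start - offset_nt - k
                rc = reverse_complement(m)
                for j, c in enumerate(rc):
                    seq_list[g0 + j] = c
                planted_spans.append((f, g0))
        # resample accidental extra copies within each scored window
        protected = {
            pos for _, g0 in planted_spans for pos in range(g0, g0 + k)
        }
        for f, g0 in planted_spans:
            if f.strand == "+":
                w0, w1 = f.end - window.upstream_nt, f.end + window.downstream_nt
            else:
                w0, w1 = f.start - window.downstream_nt, f.start + window.upstream_nt
            target = m if f.strand == "+" else reverse_complement(m)
            for _ in range(1000):
                region = "".join(seq_list[w0:w1])
                extras = [
                    w0 + i for i in _scan_extra_occurrences(region, target, g0 - w0)
                ]
                if not extras:
                    break
                for st in extras:
                    mutable = [p for p in range(st, st + k) if p not in protected]
                    p = mutable[int(rng.integers(0, len(mutable)))]
                    alts = [b for b in "ACGT" if b != seq_list[p]]
                    seq_list[p] = alts[int(rng.integers(0, 3))]
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError("could not de-collide background motif copies")

    fasta_seq = "".join(seq_list)
    lines = [f">{chrom}"]
    for i in range(0, chrom_len, 60):
        lines.append(fasta_seq[i:i + 60])
    return "\n".join(lines) + "\n", FeatureSet(feats)


@dataclass
class QuantSim:
    """Simulated protein x sample top-3 area matrix with ground truth."""

    matrix: pd.DataFrame
    u30_samples: list[str]
    ctrl_samples: list[str]
    enriched: set[str]


def gen_quant_tables(
    n_proteins: int,
    enriched: Iterable[str | int],
    fold_range: tuple[float, float] = (5.0, 20.0),
    n_replicates: int = 3,
    dropout_rate: float = 0.0,
    seed: int = 0,
) -> QuantSim:
    """Replicate bait/control quantification tables with planted enrichment.

    Planted-enriched proteins have bait/control area ratios drawn uniformly
    from ``fold_range`` in every replicate; background proteins have ratios in
    [0.5, 2].  With probability ``dropout_rate`` an enriched protein's control
    area is set missing in a replicate, turning that replicate into an
    exclusive (bait-only) detection.  ``enriched`` may contain protein ids
    (``"P0003"``) or 1-based indices.
    """
    if not 0 <= dropout_rate <= 1:
        raise ValueError("dropout_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = [f"P{i + 1:04d}" for i in range(n_proteins)]
    enr = {e if isinstance(e, str) else f"P{e:04d}" for e in enriched}
    if not enr <= set(ids):
        raise ValueError("enriched ids outside the generated protein set")
    u30 = [f"U30_r{r + 1}" for r in range(n_replicates)]
    ctrl = [f"ctrl_r{r + 1}" for r in range(n_replicates)]
    data = {}
    for pid in ids:
        base = float(10 ** rng.uniform(5.0, 8.0))
        row = {}
        for r in range(n_replicates):
            c_area = base * float(rng.lognormal(0.0, 0.2))
            if pid in enr:
                fold = float(rng.uniform(*fold_range))
            else:
                fold = float(rng.uniform(0.5, 2.0))
            row[u30[r]] = c_area * fold
            if pid in enr and rng.random() < dropout_rate:
                row[ctrl[r]] = np.nan
            else:
                row[ctrl[r]] = c_area
        data[pid] = row
    matrix = pd.DataFrame.from_dict(data, orient="index")[u30 + ctrl]
    matrix.index.name = "protein_id"
    matrix.columns.name = "sample_id"
    return QuantSim(matrix=matrix, u30_samples=u30, ctrl_samples=ctrl,
                    enriched=enr)


def gen_ct_table(
    targets: Sequence[str],
    conditions: Sequence[str],
    true_log2_fc: Mapping[str, float] | float = 0.0,
    ct_noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    reference: str = "18S",
) -> pd.DataFrame:
    """Ct table with planted per-target log2 fold changes.

    Ct = baseline - log2(expression) + noise.  The first condition is the
    control (fold change 0 by definition); the reference gene has fold change
    0 in every condition.  Fraction is 'total' and antibody 'none' throughout.
    """
    if len(conditions) < 2:
        raise ValueError("need a control plus at least one test condition")
    rng = np.random.default_rng(seed)
    if not isinstance(true_log2_fc, Mapping):
        true_log2_fc = {t: float(true_log2_fc) for t in targets}
    rows = []
    control = conditions[0]
    baselines = {t: float(rng.uniform(18.0, 28.0)) for t in targets}
    baselines[reference] = float(rng.uniform(10.0, 15.0))
    for gene in list(targets) + [reference]:
        for cond in conditions:
            lfc = 0.0
            if gene != reference and cond != control:
                lfc = float(true_log2_fc.get(gene, 0.0))
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                rows.append({
                    "target": gene,
                    "reference_flag": gene == reference,
                    "condition": cond,
                    "replicate": rep,
                    "fraction": "total",
                    "antibody": "none",
                    "ct": baselines[gene] - lfc + noise,
                })
    return pd.DataFrame(rows)


def gen_rip_table(
    targets: Sequence[str],
    true_log2_enrichment: Mapping[str, float] | float = 0.0,
    ct_noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    antibody: str = "flag",
    control_antibody: str = "beads",
) -> pd.DataFrame:
    """RIP Ct table (INP/ELU fractions for antibody and control beads) with a
    planted log2 enrichment of the antibody IP over beads, input-normalized."""
    rng = np.random.default_rng(seed)
    if not isinstance(true_log2_enrichment, Mapping):
        true_log2_enrichment = {t: float(true_log2_enrichment) for t in targets}
    rows = []
    for gene in targets:
        base_inp = float(rng.uniform(18.0, 25.0))
        base_elu = base_inp + float(rng.uniform(2.0, 6.0))  # beads background
        for rep in range(1, n_replicates + 1):
            for ab in (antibody, control_antibody):
                shift = true_log2_enrichment.get(gene, 0.0) if ab == antibody else 0.0
                for frac, ct0 in (("INP", base_inp), ("ELU", base_elu - shift)):
                    noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                    rows.append({
                        "target": gene,
                        "reference_flag": False,
                        "condition": "RIP",
                        "replicate": rep,
                        "fraction": frac,
                        "antibody": ab,
                        "ct": ct0 + noise,
                    })
    return pd.DataFrame(rows)
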