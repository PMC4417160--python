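"""End-to-end pipeline runner over a plain-text (YAML) config.

Each stage either loads the input paths named in its config block or, with a
``simulate:`` block, generates them via :mod:`oligou.synthetic`.  All
randomness flows from one global seed through per-stage derived seeds
(``global_seed + fixed stage offset``, so adding a stage never reshuffles the
others).  Every output file is recorded with a SHA-256 checksum; rerunning the
same config reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import csp as csp_mod
from . import ensemble as ens_mod
from . import isotherm as iso_mod
from . import motifs as motif_mod
from . import pulldown as pd_mod
from . import qpcr as qpcr_mod
from . import synthetic as syn

log = logging.getLogger("oligou.pipeline")

STAGE_ORDER = ["titration", "csp", "ensemble", "motifs", "pulldown", "qpcr"]
_STAGE_SEED_OFFSET = {name: 1000 * (i + 1) for i, name in enumerate(STAGE_ORDER)}


@dataclass
class RunReport:
    seed: int
    version: str
    stages: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "version": self.version, "stages": self.stages},
            indent=2,
        )

    def to_markdown(self) -> str:
        lines = [f"# Pipeline run (seed {self.seed}, oligou {self.version})", ""]
        for name, info in self.stages.items():
            lines.append(f"## {name}")
            for key, val in info.get("summary", {}).items():
                lines.append(f"- {key}: {val}")
            for path, digest in info.get("outputs", {}).items():
                lines.append(f"- output `{path}` sha256 `{digest[:12]}`")
            lines.append("")
        return "\n".join(lines)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def demo_config(seed: int = 0) -> dict:
    """All-simulate config exercising every stage without any input files."""
    return {
        "seed": seed,
        "stages": {
            "titration": {"simulate": {
                "kd_uM": 60.0, "r_free": 0.05, "r_bound": 0.20,
                "rna_total_uM": 7.1, "noise_sd": 0.002,
                "protein_concs": [0, 2, 5, 10, 20, 40, 60, 90, 130, 200, 300, 400],
            }},
            "csp": {"simulate": {
                "n_residues": 90,
                "perturbed": {13: [0.25, 1.2], 40: [0.15, 0.8],
                              52: [0.30, 1.5], 81: [0.12, 0.6]},
                "disappeared": [14, 53],
            }},
            "ensemble": {"simulate": {
                "n_models": 20, "n_residues": 30, "jitter_A": 0.4,
            }},
            "motifs": {"simulate": {
                "n_features": 20, "chrom_len": 80000, "motif": "UUUUU",
                "offset_nt": 10, "strand_mix": 0.5,
            }},
            "pulldown": {"simulate": {
                "n_proteins": 200, "n_enriched": 15,
                "fold_range": [5.0, 20.0], "n_replicates": 3,
                "dropout_rate": 0.1,
            }},
            "qpcr": {"simulate": {
                "targets": ["U1", "U2", "U11", "U12", "PROMPT"],
                "conditions": ["siCTRL", "siRBM7"],
                "true_log2_fc": 1.5, "ct_noise_sd": 0.15, "n_replicates": 3,
            }},
        },
    }


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    if "stages" not in cfg or not isinstance(cfg["stages"], dict):
        raise ValueError("config must contain a 'stages' mapping")
    unknown = set(cfg["stages"]) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages in config: {sorted(unknown)}")
    for name, block in cfg["stages"].items():
        if "simulate" not in block:
            for key, val in block.items():
                if key.endswith(("_path", "_file")) and not Path(val).exists():
                    raise FileNotFoundError(
                        f"stage {name!r}: input path {val!r} does not exist"
                    )


# ------------------------------------------------------------------ stages

def _run_titration(block, outdir: Path, seed: int) -> tuple[dict, dict]:
    if "simulate" in block:
        sim = dict(block["simulate"])
        series = syn.gen_titration(
            kd_uM=sim["kd_uM"], r_free=sim["r_free"], r_bound=sim["r_bound"],
            rna_total_uM=sim["rna_total_uM"],
            protein_concs=sim["protein_concs"],
            noise_sd=sim.get("noise_sd", 0.0), seed=seed,
        )
    else:
        series = iso_mod.read_titration_csv(block["titration_path"])
    fit = iso_mod.fit_kd(series, model=block.get("model", "depletion"))
    fit_path = outdir / "titration_fit.json"
    fit_path.write_text(fit.to_json())
    curve_path = outdir / "titration_normalized.csv"
    if fit.converged:
        norm = iso_mod.normalize_isotherm(series, fit)
        pd.DataFrame({
            "protein_total_uM": series.protein_uM,
            "anisotropy": series.anisotropy,
            "normalized": norm,
        }).to_csv(curve_path, index=False)
    summary = {"kd_uM": round(fit.kd_uM, 4), "converged": fit.converged}
    return summary, {"fit": fit_path, "curve": curve_path}


def _run_csp(block, outdir: Path, seed: int) -> tuple[dict, dict]:
    if "simulate" in block:
        sim = dict(block["simulate"])
        perturbed = {int(k): tuple(v) for k, v in sim.get("perturbed", {}).items()}
        free, bound = syn.gen_peaklists(
            n_residues=sim["n_residues"], perturbed=perturbed,
            disappeared=sim.get("disappeared", ()), seed=seed,
        )
    else:
        free = csp_mod.read_peaklist_csv(block["free_path"], "free")
        bound = csp_mod.read_peaklist_csv(block["bound_path"], "bound")
    profile = csp_mod.combined_csp(free, bound)
    called = csp_mod.call_perturbed(profile)
    out = outdir / "csp_profile.csv"
    csp_mod.write_profile_csv(profile, out)
    summary = {"n_residues": len(profile.per_residue),
               "n_called": len(called),
               "called": sorted(called)}
    return summary, {"profile": out}


def _run_ensemble(block, outdir: Path, seed: int) -> tuple[dict, dict]:
    if "simulate" in block:
        sim = dict(block["simulate"])
        ens = syn.gen_ensemble(
            n_models=sim["n_models"], n_residues=sim["n_residues"],
            jitter_A=sim.get("jitter_A", 0.0), seed=seed,
        )
        pdb_path = outdir / "ensemble.pdb"
        ens_mod.write_pdb_ensemble(ens, pdb_path)
    else:
        pdb_path = Path(block["pdb_path"])
        ens = ens_mod.read_pdb_ensemble(pdb_path)
    reports = {
        sel: ens_mod.ensemble_rmsd(ens, selection=sel, regions="ss")
        for sel in ("backbone", "heavy")
    }
    out = outdir / "ensemble_rmsd.json"
    out.write_text(json.dumps({
        sel: {"mean_A": r.mean_A, "sd_A": r.sd_A, "n_pairs": r.n_pairs}
        for sel, r in reports.items()
    }, indent=2))
    summary = {
        f"rmsd_{sel}_A": f"{r.mean_A:.3f} +/- {r.sd_A:.3f}"
        for sel, r in reports.items()
    }
    outputs = {"rmsd": out}
    if "simulate" in block:
        outputs["pdb"] = pdb_path
    return summary, outputs


def _run_motifs(block, outdir: Path, seed: int) -> tuple[dict, dict]:
    window = motif_mod.Window(
        upstream_nt=block.get("upstream_nt", 200),
        downstream_nt=block.get("downstream_nt", 600),
    )
    if "simulate" in block:
        sim = dict(block["simulate"])
        fasta_text, feats = syn.gen_genome(
            n_features=sim["n_features"], chrom_len=sim["chrom_len"],
            motif=sim.get("motif", "TTTTT"),
            offset_nt=sim.get("offset_nt", 10),
            strand_mix=sim.get("strand_mix", 0.5), seed=seed, window=window,
        )
        fa_path = outdir / "genome.fa"
        fa_path.write_text(fasta_text)
        bed_path = outdir / "features.bed"
        motif_mod.write_bed6(feats, bed_path)
        genome = motif_mod.read_fasta(fa_path)
        motif = sim.get("motif", "TTTTT")
    else:
        genome = motif_mod.read_fasta(block["genome_path"])
        feats = motif_mod.read_bed6(block["features_path"])
        motif = block.get("motif", "UUUUU")
    feats = motif_mod.filter_nonoverlapping(feats)
    windows = motif_mod.extract_windows(genome, feats, window)
    profile = motif_mod.positional_profile(windows, motif, window)
    ranking = motif_mod.rank_kmers(windows, k=len(motif_mod.normalize_motif(motif)))
    prof_path = outdir / "motif_profile.csv"
    profile.to_frame().to_csv(prof_path, index=False)
    rank_path = outdir / "kmer_ranking.csv"
    ranking.to_frame().to_csv(rank_path, index=False)
    peak = int(profile.positions[int(np.argmax(profile.counts))])
    summary = {"n_features": len(feats), "peak_position": peak,
               "peak_count": int(profile.counts.max()),
               "motif_rank": ranking.rank(motif)}
    outputs = {"profile": prof_path, "ranking": rank_path}
    if "simulate" in block:
        outputs.update({"genome": fa_path, "features": bed_path})
    return summary, outputs


def _run_pulldown(block, outdir: Path, seed: int) -> tuple[dict, dict]:
    if "simulate" in block:
        sim = dict(block["simulate"])
        rng = np.random.default_rng(seed)
        ids = rng.choice(sim["n_proteins"], size=sim["n_enriched"], replace=False)
        quant = syn.gen_quant_tables(
            n_proteins=sim["n_proteins"],
            enriched={int(i) + 1 for i in ids},
            fold_range=tuple(sim.get("fold_range", (5.0, 20.0))),
            n_replicates=sim.get("n_replicates", 3),
            dropout_rate=sim.get("dropout_rate", 0.0), seed=seed,
        )
        matrix, u30, ctrl = quant.matrix, quant.u30_samples, quant.ctrl_samples
    else:
        peptides = pd.read_csv(block["peptides_path"])
        sheet = pd.read_csv(block["samples_path"])
        kept = pd_mod.filter_peptides(peptides)
        matrix = pd_mod.build_quant_matrix(kept)
        u30 = sheet.loc[sheet["condition"] == "U30", "sample_id"].tolist()
        ctrl = sheet.loc[sheet["condition"] == "control", "sample_id"].tolist()
    calls = pd_mod.enrichment_filter(
        matrix, u30, ctrl,
        fold_min=block.get("fold_min", 5.0),
        min_replicates=block.get("min_replicates", 2),
    )
    mat_path = outdir / "protein_matrix.csv"
    matrix.to_csv(mat_path)
    call_path = outdir / "enrichment_calls.csv"
    pd_mod.calls_to_frame(calls).to_csv(call_path, index=False)
    n_pass = sum(c.passed for c in calls)
    summary = {"n_proteins": len(calls), "n_passed": n_pass}
    if "simulate" in block:
        recovered = {c.protein_id for c in calls if c.passed} == quant.enriched
        summary["planted_recovered_exactly"] = bool(recovered)
    return summary, {"matrix": mat_path, "calls": call_path}


def _run_qpcr(block, outdir: Path, seed: int) -> tuple[dict, dict]:
    if "simulate" in block:
        sim = dict(block["simulate"])
        table = syn.gen_ct_table(
            targets=sim["targets"], conditions=sim["conditions"],
            true_log2_fc=sim.get("true_log2_fc", 0.0),
            ct_noise_sd=sim.get("ct_noise_sd", 0.0),
            n_replicates=sim.get("n_replicates", 3), seed=seed,
        )
        targets, conditions, reference = sim["targets"], sim["conditions"], "18S"
    else:
        table = qpcr_mod.read_ct_csv(block["ct_path"])
        reference = block["reference"]
        conditions = [block["control_condition"]] + list(block["conditions"])
        targets = [t for t in table["target"].unique() if t != reference]
    rows = []
    for target in targets:
        for cond in conditions[1:]:
            fc = qpcr_mod.delta_delta_ct(
                table, target, reference, cond, conditions[0]
            )
            rows.append({
                "target": fc.target, "comparison": fc.condition_vs_control,
                "fold": fc.fold, "log2_fold": fc.log2_fold, "sem": fc.sem,
                "p_value": fc.p_value, "significant": fc.significant,
            })
    out = outdir / "fold_changes.csv"
    df = pd.DataFrame(rows)
    df.to_csv(out, index=False)
    summary = {"n_comparisons": len(df),
               "n_significant": int(df["significant"].sum())}
    return summary, {"fold_changes": out}


_RUNNERS = {
    "titration": _run_titration,
    "csp": _run_csp,
    "ensemble": _run_ensemble,
    "motifs": _run_motifs,
    "pulldown": _run_pulldown,
    "qpcr": _run_qpcr,
}


def run_pipeline(config: dict, outdir) -> RunReport:
    """Run all configured stages in order; abort naming the failing stage."""
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    report = RunReport(seed=seed, version=__version__)
    for name in STAGE_ORDER:
        if name not in config["stages"]:
            continue
        stage_dir = outdir / name
        stage_dir.mkdir(exist_ok=True)
        stage_seed = seed + _STAGE_SEED_OFFSET[name]
        log.info("running stage %s (seed %d)", name, stage_seed)
        try:
            summary, outputs = _RUNNERS[name](
                config["stages"][name], stage_dir, stage_seed
            )
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        report.stages[name] = {
            "seed": stage_seed,
            "summary": summary,
            "outputs": {
                str(p.relative_to(outdir)): _sha256(p) for p in outputs.values()
            },
        }
    (outdir / "report.json").write_text(report.to_json())
    (outdir / "report.md").write_text(report.to_markdown())
    return report
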