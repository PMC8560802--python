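"""Config-driven orchestration of the full analysis on synthetic data.

``run_all`` executes simulate -> preprocess -> (coherence | markers ->
interface rule -> MIA | NMF | signatures) as toggled in the run
configuration, writing every intermediate as TSV and a JSON run report
with versions, derived seeds, and output hashes.  Each stochastic stage
receives its own seed derived from the global seed and the stage name, so
toggling one stage never perturbs another's randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import GeneSetCollection
from .io import write_cell_dataset, write_gene_list, write_gmt, write_spot_dataset
from .markers import cluster_correlation, interface_enriched_genes, ranksum_markers
from .mia import mia_map
from .nmf import estimate_rank, factor_spot_scores, nmf_fit, top_factor_genes
from .preprocess import QCParams, normalize_dataset, qc_filter
from .signatures import (
    build_interface_signature,
    classify_by_signature,
    module_score,
    score_correlation,
)
from .spatialcoh import coherence_screen
from .synthio import SynthConfig, generate_cells, generate_gene_sets, generate_spatial

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    mixed = np.random.SeedSequence([global_seed & 0x7FFFFFFF, zlib.crc32(stage.encode())])
    return int(mixed.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Toggles and parameters for one end-to-end run."""

    out_dir: str = "interface_atlas_run"
    seed: int = 0
    simulate: dict = field(default_factory=dict)  # SynthConfig overrides
    stages: dict = field(
        default_factory=lambda: {
            "coherence": True,
            "markers": True,
            "mia": True,
            "nmf": True,
            "signatures": True,
        }
    )
    qc: dict = field(default_factory=dict)  # QCParams overrides
    coherence: dict = field(default_factory=lambda: {"n_reps": 100, "n_random_sets": 50, "set_size": 30})
    nmf_params: dict = field(
        default_factory=lambda: {"rank": 3, "n_restarts": 5, "survey": None, "n_runs": 10}
    )
    signatures_params: dict = field(default_factory=lambda: {"alpha": 0.05})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_all(config: RunConfig) -> dict:
    """Execute all toggled stages; returns (and writes) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed, "stages": {}, "outputs": {}}

    def _fail(stage: str, exc: Exception):
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # ----- simulate ---------------------------------------------------
    sim_seed = stage_seed(config.seed, "simulate")
    try:
        synth = SynthConfig(**{"seed": sim_seed, **config.simulate})
        spots, spot_truth = generate_spatial(synth)
        cells, cell_truth = generate_cells(synth, "cell")
        nuclei, _ = generate_cells(synth, "nucleus")
    except Exception as exc:  # noqa: BLE001
        _fail("simulate", exc)
    write_spot_dataset(spots, out / "spatial")
    write_cell_dataset(cells, out / "cells")
    write_cell_dataset(nuclei, out / "nuclei")
    with open(out / "synth_config.yaml", "w") as fh:
        yaml.safe_dump(synth.to_dict(), fh, sort_keys=True)
    truth_df = pd.DataFrame(
        {"spot": list(spot_truth.region_of_spot), "region": list(spot_truth.region_of_spot.values())}
    )
    _write_tsv(truth_df, out / "ground_truth_regions.tsv", index=False)
    report["stages"]["simulate"] = {
        "seed": sim_seed,
        "n_spots": spots.n_spots,
        "n_cells": cells.n_cells,
        "n_nuclei": nuclei.n_cells,
    }

    # ----- preprocess -------------------------------------------------
    try:
        qc_params = QCParams(**config.qc)
        cells_f, rep_c = qc_filter(cells, qc_params)
        nuc_params = QCParams(**{"max_umi": 1_000_000, **config.qc})
        nuclei_f, rep_n = qc_filter(nuclei, nuc_params)
        norm_spots = normalize_dataset(spots)
        norm_cells = normalize_dataset(cells_f)
        norm_nuclei = normalize_dataset(nuclei_f)
    except Exception as exc:  # noqa: BLE001
        _fail("preprocess", exc)
    report["stages"]["preprocess"] = {"cells_qc": rep_c.to_dict(), "nuclei_qc": rep_n.to_dict()}

    # ----- coherence --------------------------------------------------
    if config.stages.get("coherence", True):
        seed = stage_seed(config.seed, "coherence")
        try:
            coh_cfg = config.coherence
            gene_sets = generate_gene_sets(
                spot_truth,
                n_random_sets=coh_cfg.get("n_random_sets", 50),
                set_size=coh_cfg.get("set_size", 30),
                seed=seed,
            )
            tumor_mask = spots.cluster_of_spot == "tumor"
            coh = coherence_screen(
                norm_spots.subset_obs(tumor_mask),
                spots.coords[tumor_mask],
                gene_sets,
                n_reps=coh_cfg.get("n_reps", 100),
                seed=seed,
            )
        except Exception as exc:  # noqa: BLE001
            _fail("coherence", exc)
        _write_tsv(coh, out / "coherence.tsv")
        write_gmt(out / "gene_sets.gmt", gene_sets)
        report["stages"]["coherence"] = {
            "seed": seed,
            "n_sets": len(gene_sets),
            "n_evaluated": int(coh["evaluated"].sum()),
        }

    # ----- markers + interface rule + cluster correlation -------------
    marker_tables = {}
    if config.stages.get("markers", True) or config.stages.get("mia", True) or config.stages.get(
        "signatures", True
    ):
        try:
            labels = spots.cluster_of_spot
            t_all = ranksum_markers(norm_spots, labels, "interface", "rest")
            t_tum = ranksum_markers(norm_spots, labels, "tumor", "rest")
            t_mus = ranksum_markers(norm_spots, labels, "muscle", "rest")
            marker_tables = {"interface": t_all, "tumor": t_tum, "muscle": t_mus}
        except Exception as exc:  # noqa: BLE001
            _fail("markers", exc)

    if config.stages.get("markers", True):
        try:
            calls = interface_enriched_genes(
                marker_tables["interface"], marker_tables["tumor"], marker_tables["muscle"]
            )
            rmat, pmat, order = cluster_correlation(norm_spots, spots.cluster_of_spot, n_var=500)
        except Exception as exc:  # noqa: BLE001
            _fail("markers", exc)
        _write_tsv(marker_tables["interface"].table, out / "markers_interface.tsv")
        calls_df = pd.DataFrame(
            [
                {
                    "gene": c.gene,
                    "direction": c.direction,
                    "fc_interface": c.fc_interface,
                    "fc_tumor": c.fc_tumor,
                    "fc_muscle": c.fc_muscle,
                    "p_adj": c.p_adj,
                }
                for c in calls
            ]
        )
        _write_tsv(calls_df, out / "interface_gene_calls.tsv", index=False)
        _write_tsv(rmat, out / "cluster_correlation_r.tsv")
        report["stages"]["markers"] = {
            "n_up_calls": int((calls_df["direction"] == "up").sum()) if len(calls_df) else 0,
            "n_down_calls": int((calls_df["direction"] == "down").sum()) if len(calls_df) else 0,
            "dendrogram_order": list(map(str, order)),
        }

    # ----- MIA --------------------------------------------------------
    if config.stages.get("mia", True):
        try:
            state_tables = {
                s: ranksum_markers(norm_cells, cells_f.cluster_of_cell, s, "rest")
                for s in sorted(set(cells_f.cluster_of_cell))
            }
            alpha = config.signatures_params.get("alpha", 0.05)
            state_sets = GeneSetCollection(
                sets={s: t.significant_up(alpha) for s, t in state_tables.items()},
                universe=list(map(str, cells_f.gene_ids)),
            )
            region_sets = GeneSetCollection(
                sets={r: t.significant_up(alpha) for r, t in marker_tables.items()},
                universe=list(map(str, spots.gene_ids)),
            )
            background = sorted(set(map(str, spots.gene_ids)) & set(map(str, cells_f.gene_ids)))
            mia_res = mia_map(state_sets, region_sets, background)
        except Exception as exc:  # noqa: BLE001
            _fail("mia", exc)
        _write_tsv(mia_res.to_long(), out / "mia.tsv", index=False)
        report["stages"]["mia"] = {"background_size": mia_res.background_size}

    # ----- NMF --------------------------------------------------------
    if config.stages.get("nmf", True):
        seed = stage_seed(config.seed, "nmf")
        try:
            me_mask = np.isin(spots.cluster_of_spot, ["interface", "muscle"])
            me_norm = norm_spots.subset_obs(me_mask)
            nmf_cfg = config.nmf_params
            # factorize expression above the per-gene microenvironment mean,
            # clamped at zero, so factors capture programs rather than
            # overall expression level
            from .nmf import clamp_negatives

            centered = clamp_negatives(
                me_norm.values - me_norm.values.mean(axis=0, keepdims=True)
            )
            fit = nmf_fit(
                centered,
                rank=nmf_cfg.get("rank", 3),
                seed=seed,
                spot_ids=me_norm.obs_ids,
                gene_ids=me_norm.gene_ids,
                n_restarts=nmf_cfg.get("n_restarts", 5),
            )
            scores = factor_spot_scores(fit)
            survey = None
            if nmf_cfg.get("survey"):
                survey = estimate_rank(
                    centered,
                    nmf_cfg["survey"],
                    n_runs=nmf_cfg.get("n_runs", 10),
                    seed=seed,
                )
        except Exception as exc:  # noqa: BLE001
            _fail("nmf", exc)
        _write_tsv(
            pd.DataFrame(fit.W, index=me_norm.obs_ids.astype(str)), out / "nmf_W.tsv"
        )
        _write_tsv(
            pd.DataFrame(fit.H, columns=me_norm.gene_ids.astype(str)), out / "nmf_H.tsv"
        )
        _write_tsv(
            pd.DataFrame(scores, index=me_norm.obs_ids.astype(str)), out / "nmf_spot_scores.tsv"
        )
        for f in range(fit.rank):
            write_gene_list(out / f"nmf_factor{f}_top_genes.txt", top_factor_genes(fit, f))
        if survey is not None:
            _write_tsv(survey.table, out / "nmf_rank_survey.tsv")
        report["stages"]["nmf"] = {
            "seed": seed,
            "rank": fit.rank,
            "n_iter": len(fit.objective_trace),
            "suggested_rank": None if survey is None else survey.suggested_rank,
        }

    # ----- signatures -------------------------------------------------
    if config.stages.get("signatures", True):
        seed = stage_seed(config.seed, "signatures")
        try:
            alpha = config.signatures_params.get("alpha", 0.05)
            t_cells = ranksum_markers(
                norm_cells,
                _merge_interface_labels(cells_f.cluster_of_cell),
                "interface",
                "rest",
            )
            t_nuclei = ranksum_markers(
                norm_nuclei,
                _merge_interface_labels(nuclei_f.cluster_of_cell),
                "interface",
                "rest",
            )
            signature = build_interface_signature(
                [marker_tables["interface"], t_cells, t_nuclei], alpha=alpha
            )
            sig_score = module_score(
                norm_cells, cell_truth.interface_program, seed=seed, set_name="interface_program"
            )
            classified = classify_by_signature(sig_score)
            iface_cells = [
                str(c)
                for c, s in zip(cells_f.cell_ids, cells_f.cluster_of_cell)
                if str(s).startswith("interface")
            ]
            both = cell_truth.ets_genes + cell_truth.ets_targets
            ets_score = module_score(
                norm_cells,
                cell_truth.ets_genes,
                seed=seed + 1,
                set_name="ets",
                control_exclude=both,
            )
            tgt_score = module_score(
                norm_cells,
                cell_truth.ets_targets,
                seed=seed + 2,
                set_name="ets_targets",
                control_exclude=both,
            )
            r, p = score_correlation(ets_score, tgt_score, subset=iface_cells)
        except Exception as exc:  # noqa: BLE001
            _fail("signatures", exc)
        write_gene_list(out / "interface_signature.txt", signature.genes)
        _write_tsv(
            pd.DataFrame(
                {"score": sig_score.scores, "interface_like": classified}
            ),
            out / "module_scores.tsv",
        )
        report["stages"]["signatures"] = {
            "seed": seed,
            "signature_size": len(signature.genes),
            "ets_target_correlation_r": r,
            "ets_target_correlation_p": p,
            "n_classified_interface": int(classified.sum()),
        }

    # ----- report -----------------------------------------------------
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "run_report.json":
            report["outputs"][str(path.relative_to(out))] = _sha256(path)
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _merge_interface_labels(labels) -> np.ndarray:
    """Collapse interface_* states to one 'interface' cluster label."""
    return np.array(
        ["interface" if str(l).startswith("interface") else str(l) for l in labels],
        dtype=object,
    )
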