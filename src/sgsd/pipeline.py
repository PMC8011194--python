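"""Config-driven orchestration: QC -> subsample -> clustering -> per-cluster
diversity, differentiation, SGS, dispersal and selfing, with CSV outputs and
a JSON run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import apply_admixture_threshold, select_k
from .diversity import diversity_summary
from .differentiation import differentiation_result
from .genotype_io import (
    GenotypeTable,
    detect_duplicates,
    filter_min_typed_loci,
    grid_subsample,
    pairwise_distances,
    read_genotypes,
)
from .mating_system import selfing_with_jackknife
from .sgs_dispersal import (
    density_scenarios,
    estimate_sigma_g,
    kinship_distance_analysis,
    loiselle_kinship,
)

logger = logging.getLogger("sgsd.pipeline")


@dataclass
class PipelineConfig:
    """Declarative description of a full analysis run (YAML round-trippable)."""

    input_path: str
    input_format: str = "csv"
    coord_system: str = "planar"
    output_dir: str = "sgsd_run"
    seed: int = 0
    # QC
    min_typed_fraction: float = 0.6
    dedupe: bool = True
    grid_cell_size: Optional[float] = None     # degrees; None disables
    grid_max_per_cell: int = 3
    # clustering
    run_clustering: bool = True
    k_max: int = 10
    n_starts: int = 20
    admixture_threshold: float = 0.8
    # diversity
    rarefaction_k: Optional[int] = None
    n_perm: int = 10000
    # SGS / dispersal
    fn_radius: float = 100.0
    range_factor: float = 20.0
    jackknife: bool = True
    density_per_ha: dict = field(default_factory=dict)  # group -> adults/ha
    de_fractions: list = field(default_factory=lambda: [0.5, 0.25, 0.1])
    mu: Optional[float] = None
    # selfing
    run_selfing: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def stage_seed(global_seed: int, stage: str) -> int:
    """Independent per-stage seed derived by hashing the stage name."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:8], "big") % (2**63)


def _float_fmt(df: pd.DataFrame) -> str:
    return df.to_csv(index=False, float_format="%.6g", lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis chain; returns the run directory.

    Stage failures are recorded in the manifest; later independent stages
    still run. Outputs: ``table1.csv`` (per-group diversity + Sp + selfing),
    ``table2.csv`` (FST below / RST above the diagonal), ``sgs_curves.csv``,
    ``dispersal.csv``, ``clusters.csv``, ``manifest.json``, ``run.log``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest = {
        "sgsd_version": __version__,
        "seed": config.seed,
        "stages": {},
        "errors": {},
    }

    def record(stage, n_in, n_out, t0):
        manifest["stages"][stage] = {
            "n_in": n_in,
            "n_out": n_out,
            "n_removed": n_in - n_out,
            "seconds": round(time.time() - t0, 3),
        }
        logger.info("%s: %d -> %d (%.2fs)", stage, n_in, n_out, time.time() - t0)

    try:
        t0 = time.time()
        table = read_genotypes(
            config.input_path, config.input_format, config.coord_system
        )
        record("import", table.n_samples, table.n_samples, t0)

        t0 = time.time()
        n_in = table.n_samples
        table = filter_min_typed_loci(table, config.min_typed_fraction)
        record("min_typed_filter", n_in, table.n_samples, t0)

        if config.dedupe:
            t0 = time.time()
            n_in = table.n_samples
            dups = detect_duplicates(table)
            drop = {p.sample_2 for p in dups}
            if drop:
                keep = [i for i, s in enumerate(table.sample_ids) if s not in drop]
                table = table.subset(keep)
            record("dedupe", n_in, table.n_samples, t0)

        if config.grid_cell_size:
            t0 = time.time()
            n_in = table.n_samples
            table = grid_subsample(
                table,
                cell_size=config.grid_cell_size,
                max_per_cell=config.grid_max_per_cell,
                seed=stage_seed(config.seed, "grid_subsample"),
            )
            record("grid_subsample", n_in, table.n_samples, t0)
    except Exception as exc:  # import/QC failure is fatal
        manifest["errors"]["qc"] = str(exc)
        _write_manifest(out, manifest)
        logger.removeHandler(handler)
        raise

    if config.run_clustering:
        try:
            t0 = time.time()
            sel = select_k(
                table,
                k_max=config.k_max,
                n_starts=config.n_starts,
                seed=stage_seed(config.seed, "clustering"),
            )
            fit = sel.assignments[sel.chosen_K - 1]
            table, unassigned = apply_admixture_threshold(
                table, fit, config.admixture_threshold
            )
            qdf = pd.DataFrame(fit.q, columns=[f"q{k}" for k in range(fit.K)])
            qdf.insert(0, "sample_id", fit.sample_ids)
            qdf["assigned_group"] = [g if g is not None else "" for g in table.groups]
            (out / "clusters.csv").write_text(_float_fmt(qdf))
            kdf = pd.DataFrame({"K": sel.ks, "AIC": sel.scores})
            (out / "k_selection.csv").write_text(_float_fmt(kdf))
            record("clustering", table.n_samples, table.n_samples - len(unassigned), t0)
            manifest["chosen_K"] = sel.chosen_K
            manifest["n_unassigned"] = len(unassigned)
        except Exception as exc:
            manifest["errors"]["clustering"] = str(exc)

    groups = table.group_labels()
    analysis_groups = [None] + groups  # None = "ALL"

    # ---------------------------------------------------------- diversity
    rows = []
    try:
        t0 = time.time()
        for g in analysis_groups:
            sub = table if g is None else table.select_group(g)
            if sub.n_samples < 2:
                continue
            s = diversity_summary(
                sub,
                k=config.rarefaction_k,
                n_perm=config.n_perm,
                seed=stage_seed(config.seed, f"fi:{g}"),
            )
            rows.append(
                {
                    "group": "ALL" if g is None else g,
                    "n": s.n, "NAe": s.NAe, "AR_k": s.AR_k, "He": s.He,
                    "Ho": s.Ho, "Fi": s.Fi, "Fi_p": s.Fi_p,
                }
            )
        record("diversity", table.n_samples, table.n_samples, t0)
    except Exception as exc:
        manifest["errors"]["diversity"] = str(exc)

    # ----------------------------------------------------- differentiation
    if len(groups) >= 2:
        try:
            t0 = time.time()
            diff = differentiation_result(
                table, groups, n_perm=config.n_perm,
                seed=stage_seed(config.seed, "differentiation"),
            )
            # Table-2 layout: FST below diagonal, RST above
            mat = np.where(
                np.tri(len(groups), k=-1, dtype=bool), diff.FST, diff.RST
            )
            np.fill_diagonal(mat, 0.0)
            t2 = pd.DataFrame(mat, columns=groups)
            t2.insert(0, "group", groups)
            (out / "table2.csv").write_text(_float_fmt(t2))
            pdf = pd.DataFrame(diff.pRST_p, columns=groups)
            pdf.insert(0, "group", groups)
            (out / "prst_pvalues.csv").write_text(_float_fmt(pdf))
            record("differentiation", len(groups), len(groups), t0)
        except Exception as exc:
            manifest["errors"]["differentiation"] = str(exc)

    # ----------------------------------------------------------------- SGS
    sgs_rows, curve_rows, disp_rows, selfing_rows = [], [], [], []
    for g in analysis_groups:
        label = "ALL" if g is None else g
        sub = table if g is None else table.select_group(g)
        if sub.n_samples < 10:
            continue
        try:
            t0 = time.time()
            kin = loiselle_kinship(sub)
            dist = pairwise_distances(sub)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = kinship_distance_analysis(
                    kin, dist,
                    n_perm=config.n_perm,
                    seed=stage_seed(config.seed, f"sgs:{label}"),
                    jackknife=config.jackknife,
                    fn_radius=config.fn_radius,
                )
            sgs_rows.append(
                {
                    "group": label, "n": sub.n_samples, "b_log": res.b_log,
                    "F1": res.F1, "Fn": res.Fn, "Sp": res.Sp,
                    "Sp_SE": res.Sp_SE, "perm_p": res.perm_p,
                }
            )
            for c in range(res.class_bounds.size):
                lo = 0.0 if c == 0 else res.class_bounds[c - 1]
                curve_rows.append(
                    {
                        "group": label,
                        "class_lower_m": lo,
                        "class_upper_m": res.class_bounds[c],
                        "mean_distance_m": res.class_mean_distance[c],
                        "mean_Fij": res.class_mean_fij[c],
                        "n_pairs": res.class_pair_counts[c],
                    }
                )
            record(f"sgs:{label}", sub.n_samples, sub.n_samples, t0)

            D = config.density_per_ha.get(label)
            if D:
                for sc in density_scenarios(D, config.de_fractions):
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        est = estimate_sigma_g(
                            kin, dist,
                            De=sc["De_per_m2"],
                            range_factor=config.range_factor,
                            fn_radius=config.fn_radius,
                            mu=config.mu,
                            De_scenario=sc["fraction"],
                        )
                    disp_rows.append(
                        {
                            "group": label,
                            "De_fraction": sc["fraction"],
                            "De_per_ha": sc["De_per_ha"],
                            "sigma_g_m": est.sigma_g,
                            "Nb": est.Nb,
                            "converged": est.converged,
                            "iterations": est.iterations,
                            "Fn": est.Fn,
                        }
                    )
        except Exception as exc:
            manifest["errors"][f"sgs:{label}"] = str(exc)

        if config.run_selfing and g is not None:
            try:
                est = selfing_with_jackknife(sub)
                selfing_rows.append(
                    {
                        "group": label, "g2": est.g2, "s_hat": est.s_hat,
                        "SE": est.SE, "n_loci": est.n_loci,
                        "significant": est.significant,
                    }
                )
            except Exception as exc:
                manifest["errors"][f"selfing:{label}"] = str(exc)

    sgs_df = pd.DataFrame(sgs_rows)
    selfing_df = pd.DataFrame(selfing_rows)
    if rows:
        t1 = pd.DataFrame(rows)
        if not sgs_df.empty:
            t1 = t1.merge(sgs_df[["group", "Sp", "Sp_SE"]], on="group", how="left")
        if not selfing_df.empty:
            t1 = t1.merge(
                selfing_df[["group", "s_hat", "SE"]].rename(
                    columns={"s_hat": "SR", "SE": "SR_SE"}
                ),
                on="group", how="left",
            )
        (out / "table1.csv").write_text(_float_fmt(t1))
    if curve_rows:
        (out / "sgs_curves.csv").write_text(_float_fmt(pd.DataFrame(curve_rows)))
    if disp_rows:
        (out / "dispersal.csv").write_text(_float_fmt(pd.DataFrame(disp_rows)))
    if selfing_rows:
        (out / "selfing.csv").write_text(_float_fmt(selfing_df))

    manifest["final_n_samples"] = table.n_samples
    manifest["groups"] = ["ALL"] + [str(g) for g in groups]
    _write_manifest(out, manifest)
    logger.removeHandler(handler)
    handler.close()
    return out


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
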