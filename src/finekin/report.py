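"""Pipeline orchestration and per-population report tables.

Runs diversity -> FSGS -> sPCA -> admixture -> heterogeneity on a joined
dataset and writes four TSV tables mirroring the standard per-population
summary layouts: diversity (table3), FSGS parameters (table4), gene-pool
differentiation (table5) and cyto-nuclear / altitude associations
(table6), plus a manifest with every parameter used.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import admixture as adm
from . import diversity as div
from . import fsgs as fs
from . import heterogeneity as het
from .data_model import AltitudeClasses, GenotypeMatrix, HaplotypeSet, SpatialFrame
from .spca import build_network, g_l_tests
from .spca import spca as run_spca

__all__ = ["RunConfig", "run_pipeline", "significance_stars"]


def significance_stars(p: float | None) -> str:
    if p is None or not np.isfinite(p):
        return "nd"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 1
    n_perm: int = 10_000
    n_classes: int = 5
    k_grid: tuple[int, ...] = (1, 2, 3)
    n_reps: int = 3
    burnin: int = 2_000
    iters: int = 10_000
    thresholds: tuple[float, ...] = (0.5, 0.875)
    rarefaction_individuals: int = 34
    network_k: int = 10
    population: str = "pop"
    extra: dict = field(default_factory=dict)


def run_pipeline(
    cfg: RunConfig,
    g: GenotypeMatrix,
    s: SpatialFrame,
    h: HaplotypeSet | None = None,
) -> dict[str, Path]:
    """Execute every analysis stage in order and write the report bundle.

    Returns the mapping of table name to written path. Identical configs
    (same seeds) give byte-identical bundles.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    stage = "diversity"
    try:
        summary = div.diversity_summary(
            g,
            h,
            rarefaction_individuals=cfg.rarefaction_individuals,
            n_perm=cfg.n_perm,
            seed=cfg.seed,
        )
        t3 = pd.DataFrame(
            [
                {
                    "population": cfg.population,
                    "n_nuc": summary.n_individuals,
                    "SSR": summary.n_loci,
                    "A": round(summary.mean_alleles, 1),
                    "A_R": round(summary.allelic_richness, 2),
                    "A_R_sd": round(summary.allelic_richness_sd, 2),
                    "H_E": round(summary.he, 3),
                    "H_E_se": round(summary.he_se, 3),
                    "F_IS": f"{summary.fis:.3f}{significance_stars(summary.fis_p)}",
                    "F_IS_star": round(summary.fis_star, 3),
                    "hap": summary.hap_count,
                    "A_Rp": None
                    if summary.hap_richness is None
                    else round(summary.hap_richness, 2),
                    "h": None
                    if summary.hap_diversity is None
                    else round(summary.hap_diversity, 3),
                }
            ]
        )
        written["table3"] = out / "table3.tsv"
        t3.to_csv(written["table3"], sep="\t", index=False)

        stage = "fsgs"
        scheme = fs.build_distance_classes(s, cfg.n_classes)
        kin = fs.loiselle_kinship(g)
        corr = fs.correlogram(kin, s, scheme, n_perm=cfg.n_perm, seed=cfg.seed)
        plastid_sp = plastid_b = None
        if h is not None:
            try:
                pcorr = fs.plastid_fsgs(h, s, scheme, n_perm=cfg.n_perm, seed=cfg.seed)
                plastid_sp = f"{pcorr.sp:.4f}{significance_stars(pcorr.p_slope)}"
                plastid_b = round(pcorr.b, 4)
            except ValueError:
                plastid_sp = plastid_b = "nc"

        stage = "spca"
        net = build_network(s, "knn", k=cfg.network_k)
        spca_res = run_spca(g, net, s)
        gl = g_l_tests(g, net, n_perm=min(cfg.n_perm, 999), seed=cfg.seed)

        t4 = pd.DataFrame(
            [
                {
                    "population": cfg.population,
                    "n_nuc": g.n_individuals,
                    "DC": scheme.n_classes,
                    "first_DC": round(float(scheme.upper_bounds[0]), 1),
                    "F_ij1": round(corr.f1, 3),
                    "Sp": f"{corr.sp:.4f}{significance_stars(corr.p_slope)}",
                    "b": round(corr.b, 4),
                    "b_se": round(corr.b_se, 4),
                    "eig_sPCA": f"{spca_res.eig_spca:.3f}{significance_stars(gl.g_p)}",
                    "plastid_Sp": plastid_sp,
                    "plastid_b": plastid_b,
                }
            ]
        )
        written["table4"] = out / "table4.tsv"
        t4.to_csv(written["table4"], sep="\t", index=False)
        corr_df = pd.DataFrame(
            {
                "upper_bound_m": corr.class_bounds,
                "mean_Fij": corr.class_mean_f,
                "jackknife_se": corr.class_jackknife_se,
                "envelope_low": corr.envelope_low,
                "envelope_high": corr.envelope_high,
            }
        )
        written["correlogram"] = out / "correlogram.tsv"
        corr_df.to_csv(written["correlogram"], sep="\t", index=False)

        stage = "admixture"
        results_by_k = {
            k: adm.align_replicates(
                adm.run_admixture(
                    g,
                    k,
                    burnin=cfg.burnin,
                    iters=cfg.iters,
                    n_reps=cfg.n_reps,
                    seed=cfg.seed + k,
                )
            )
            for k in cfg.k_grid
        }
        ksel = adm.select_k(results_by_k)
        best_k = ksel.best_by_l
        best = results_by_k[best_k][0]
        qdf = pd.DataFrame(
            best.q, columns=[f"GP{j + 1}" for j in range(best.k)]
        )
        qdf.insert(0, "id", g.individual_ids)
        written["q_matrix"] = out / "q_matrix.tsv"
        qdf.to_csv(written["q_matrix"], sep="\t", index=False)
        ksel_df = pd.DataFrame(
            {
                "K": ksel.k_values,
                "L_K": [ksel.l_mean[k] for k in ksel.k_values],
                "sd": [ksel.l_sd[k] for k in ksel.k_values],
                "delta_K": [ksel.delta_k.get(k, np.nan) for k in ksel.k_values],
            }
        )
        written["k_selection"] = out / "k_selection.tsv"
        ksel_df.to_csv(written["k_selection"], sep="\t", index=False)

        stage = "heterogeneity"
        row5: dict = {"population": cfg.population, "K": best_k}
        for thr, tag in zip(cfg.thresholds, ("Q50", "Q87")):
            if best_k >= 2:
                labels, pct = adm.assign_gene_pools(best, thr)
                row5[f"PI{tag[1:]}"] = round(pct, 1)
                try:
                    diff = het.fst_among_pools(
                        g, labels, n_perm=min(cfg.n_perm, 999), seed=cfg.seed
                    )
                    row5[f"F_ST_{tag}"] = (
                        f"{diff.fst:.3f}{significance_stars(diff.p)}"
                    )
                except ValueError:
                    row5[f"F_ST_{tag}"] = "nd"
            else:
                row5[f"PI{tag[1:]}"] = "nd"
                row5[f"F_ST_{tag}"] = "nd"
        written["table5"] = out / "table5.tsv"
        pd.DataFrame([row5]).to_csv(written["table5"], sep="\t", index=False)

        score1 = spca_res.scores[:, 0]
        row6: dict = {"population": cfg.population}
        if h is not None:
            labs = np.array([x if x is not None else "NA" for x in h.labels])
            try:
                a = het.anova_scores(score1, labs)
                row6["P_hap"] = significance_stars(a.p)
                for j, (grp, m) in enumerate(sorted(a.group_means.items())[:3]):
                    row6[f"sPCA_hap{j + 1}"] = f"{m:.3f} ({grp})"
            except ValueError:
                row6["P_hap"] = "nc"
        if s.altitude is not None:
            ac = AltitudeClasses.from_altitudes(s.altitude)
            try:
                a = het.anova_scores(score1, ac.class_index)
                row6["P_alt"] = significance_stars(a.p)
                for j, (grp, m) in enumerate(sorted(a.group_means.items())):
                    row6[f"sPCA_alt{j + 1}"] = round(m, 3)
            except ValueError:
                row6["P_alt"] = "nc"
        written["table6"] = out / "table6.tsv"
        pd.DataFrame([row6]).to_csv(written["table6"], sep="\t", index=False)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    manifest = {k: str(v) for k, v in written.items()}
    cfg_json = json.dumps(asdict(cfg), sort_keys=True, default=str)
    manifest["config"] = json.loads(cfg_json)
    manifest["config_hash"] = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]
    written["manifest"] = out / "manifest.json"
    written["manifest"].write_text(json.dumps(manifest, indent=2, default=str))
    return written
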