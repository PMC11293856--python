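"""End-to-end orchestration: synth -> associate -> fit -> project -> cluster -> respond.

Each stage writes its outputs plus a JSON manifest (parameters, seed,
SHA-256 of every output file) into the run directory. On re-entry a stage
whose manifest verifies against the files on disk is loaded instead of
recomputed; a missing or tampered output triggers recomputation of that
stage and everything after it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from . import io as admio
from .adm import discretize_states, fit_cadm, fit_radm
from .association import all_pairs_rho, alpha_decompose, bootstrap_fdr_thresholds
from .community import cluster_signatures, stack_copresence
from .compositional import clr_transform, filter_by_occurrence, impute_zeros
from .config import RunConfig
from .projection import mask_to_observed_range, project_cadm, project_radm
from .synthetic import (
    SyntheticSpec,
    generate_abundances,
    generate_env,
    generate_future_grids,
    generate_grid,
    generate_sample_sites,
)
from .temporal import (
    Trajectory,
    classify_response,
    filter_persistent,
    fit_slopes,
    summarize_groups,
)

__all__ = ["run_pipeline"]

log = logging.getLogger("admkit.pipeline")

DEFAULT_YEARS = [2015] + list(range(2020, 2101, 10))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _manifest_ok(out_dir: Path, stage: str) -> bool:
    mf = out_dir / f"manifest_{stage}.json"
    if not mf.exists():
        return False
    manifest = json.loads(mf.read_text())
    for rel, digest in manifest.get("outputs", {}).items():
        f = out_dir / rel
        if not f.exists() or _sha256(f) != digest:
            log.info("stage %s: output %s missing or modified; recomputing", stage, rel)
            return False
    return True


def _write_manifest(out_dir: Path, stage: str, params: dict, outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "params": params,
        "outputs": {str(p.relative_to(out_dir)): _sha256(p) for p in outputs},
    }
    (out_dir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=1, default=str))


def run_pipeline(
    config: RunConfig,
    out_dir,
    spec: SyntheticSpec | None = None,
    years: list[int] | None = None,
    resume: bool = True,
) -> dict:
    """Run all stages on a synthetic world; returns the key result objects."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    years = DEFAULT_YEARS if years is None else list(years)
    if spec is None:
        spec = SyntheticSpec(seed=config.seed)
    config.to_toml(out_dir / "config.toml")
    results: dict = {"out_dir": out_dir}

    # ---- synth -------------------------------------------------------
    abund_p = out_dir / "abundance.tsv"
    meta_p = out_dir / "metadata.tsv"
    env_p = out_dir / "env.tsv"
    truth_p = out_dir / "ground_truth.tsv"
    grid_ps = [out_dir / f"grid_{y}.tsv" for y in years]
    if resume and _manifest_ok(out_dir, "synth"):
        log.info("synth: manifest verified, loading outputs")
        table = admio.read_abundance_tsv(abund_p, meta_p)
        env = admio.read_env_tsv(env_p)
        truth = pd.read_csv(truth_p, sep="\t").to_dict("records")
        grids = [admio.read_grid(p, time_label=str(y)) for p, y in zip(grid_ps, years)]
    else:
        meta = generate_sample_sites(spec)
        env = generate_env(spec, meta)
        table, truth = generate_abundances(spec, env, meta)
        base = generate_grid(spec, time_label=str(years[0]))
        grids = generate_future_grids(spec, base, years)
        admio.write_abundance_tsv(table, abund_p, meta_p)
        admio.write_env_tsv(env, env_p)
        pd.DataFrame(truth).to_csv(truth_p, sep="\t", index=False)
        for p, g in zip(grid_ps, grids):
            admio.write_grid(g, p)
        _write_manifest(out_dir, "synth", {"spec": str(spec), "years": years},
                        [abund_p, meta_p, env_p, truth_p, *grid_ps])
    results.update(table=table, env=env, ground_truth=truth, grids=grids)

    # ---- associate ---------------------------------------------------
    filtered = filter_by_occurrence(table, config.min_occurrence)
    imputed = impute_zeros(filtered, config.impute_factor)
    clr = clr_transform(imputed)
    assoc = all_pairs_rho(clr)
    t_neg, t_pos = bootstrap_fdr_thresholds(
        clr, n_boot=config.n_boot, fdr_level=config.fdr_level,
        seed=config.seed, observed=assoc,
    )
    assoc = assoc.with_thresholds(t_neg, t_pos, config.fdr_level)
    assoc_p = out_dir / "associations.tsv"
    admio.write_associations_tsv(assoc, assoc_p)
    _write_manifest(out_dir, "associate", {
        "min_occurrence": config.min_occurrence, "impute_factor": config.impute_factor,
        "fdr_level": config.fdr_level, "n_boot": config.n_boot, "seed": config.seed,
        "t_neg": t_neg, "t_pos": t_pos,
    }, [assoc_p])
    log.info("associate: %d pairs, %d significant (t_neg=%.2f, t_pos=%.2f)",
             len(assoc.pairs), int(assoc.significant.sum()), t_neg, t_pos)
    results.update(clr=clr, associations=assoc, filtered_table=filtered)

    # ---- fit ---------------------------------------------------------
    models_dir = out_dir / "models"
    models_dir.mkdir(exist_ok=True)
    sig_pos = [
        p for p, s in zip(assoc.pairs, assoc.sign) if s == "positive"
    ]
    cadms, radms, rows = {}, {}, []
    for pair in sig_pos:
        states = discretize_states(filtered, pair)
        counts = np.unique(states.states, return_counts=True)[1]
        if counts.size < 2 or counts.min() < 2:
            log.info("fit: pair %s has degenerate co-occurrence states; skipped", pair)
            continue
        cadm = fit_cadm(states, env, config.learner, seed=config.seed,
                        cv_folds=config.cv_folds, n_estimators=config.n_estimators)
        alpha = alpha_decompose(clr.column(pair[0]), clr.column(pair[1]),
                                pair=pair, sample_ids=clr.sample_ids)
        radm = fit_radm(alpha, env, config.learner, seed=config.seed,
                        cv_folds=config.cv_folds, n_estimators=config.n_estimators)
        if cadm.performance["cv_value"] < config.performance_floor:
            log.info("fit: pair %s cADM below performance floor; skipped", pair)
            continue
        if not np.isnan(radm.performance["cv_value"]) and radm.performance["cv_value"] < config.r2_floor:
            log.info("fit: pair %s rADM below R^2 floor; skipped", pair)
            continue
        cadms[pair], radms[pair] = cadm, radm
        joblib.dump({"cadm": cadm, "radm": radm, "format_version": 1},
                    models_dir / f"{pair[0]}__{pair[1]}.joblib")
        rows.append({
            "taxon_j": pair[0], "taxon_k": pair[1],
            "cadm_balanced_accuracy": cadm.performance["cv_value"],
            "radm_r2": radm.performance["cv_value"],
            "learner": cadm.learner, "seed": config.seed,
        })
    manifest_p = out_dir / "models_manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest_p, sep="\t", index=False)
    _write_manifest(out_dir, "fit", {"learner": config.learner, "cv_folds": config.cv_folds,
                                     "n_estimators": config.n_estimators, "seed": config.seed},
                    [manifest_p])
    log.info("fit: %d of %d significant positive pairs retained", len(cadms), len(sig_pos))
    results.update(cadms=cadms, radms=radms)

    # ---- project -----------------------------------------------------
    masked = [mask_to_observed_range(g, env, config.mask_q_lo, config.mask_q_hi)
              for g in grids]
    proj_rows = []
    cadm_projections = {}  # (pair, year) -> ProjectionResult
    for grid, year in zip(masked, years):
        for pair in cadms:
            pc = project_cadm(cadms[pair], grid)
            pr = project_radm(radms[pair], grid)
            cadm_projections[(pair, year)] = pc
            proj_rows.append({
                "taxon_j": pair[0], "taxon_k": pair[1], "year": year,
                "copresence_proportion": pc.copresence_proportion,
                "rho_star": pr.rho_star_global,
            })
    proj_p = out_dir / "projections.tsv"
    proj_df = pd.DataFrame(proj_rows)
    proj_df.to_csv(proj_p, sep="\t", index=False, float_format="%.15g")
    _write_manifest(out_dir, "project", {"mask_q": [config.mask_q_lo, config.mask_q_hi],
                                         "years": years}, [proj_p])
    log.info("project: %d cells valid of %d at base year", masked[0].n_valid, masked[0].n_cells)
    results.update(projections=proj_df, masked_grids=masked)

    # ---- cluster -----------------------------------------------------
    pairs_order = list(cadms)
    base_year = years[0]
    cluster_labels = {}
    if pairs_order:
        stacked = stack_copresence([cadm_projections[(p, base_year)] for p in pairs_order])
        k_max = min(config.k_max, stacked.shape[0] - 1)
        if k_max >= config.k_min:
            cr = cluster_signatures(stacked, range(config.k_min, k_max + 1), seed=config.seed)
            cluster_labels = {f"{p[0]}__{p[1]}": int(l) for p, l in zip(pairs_order, cr.labels)}
            results["clusters"] = cr
            log.info("cluster: chose k=%d", cr.chosen_k)
    cluster_p = out_dir / "clusters.tsv"
    pd.DataFrame(
        {"association_id": list(cluster_labels), "cluster": list(cluster_labels.values())}
    ).to_csv(cluster_p, sep="\t", index=False)
    _write_manifest(out_dir, "cluster", {"k_range": [config.k_min, config.k_max]}, [cluster_p])

    # ---- respond -----------------------------------------------------
    trajectories = []
    for pair in pairs_order:
        sub = proj_df[(proj_df.taxon_j == pair[0]) & (proj_df.taxon_k == pair[1])]
        sub = sub.sort_values("year")
        if sub.copresence_proportion.isna().any():
            continue
        trajectories.append(Trajectory(
            association_id=f"{pair[0]}__{pair[1]}",
            years=sub.year.to_numpy(),
            copresence_proportion=sub.copresence_proportion.to_numpy(),
            rho_star=sub.rho_star.to_numpy(),
        ))
    persistent = filter_persistent(trajectories, config.min_copresence) if trajectories else []
    slopes, diags = {}, {}
    for t in persistent:
        sc, sr, d = fit_slopes(t)
        slopes[t.association_id] = (sc, sr)
        diags[t.association_id] = d
    classifications = (
        classify_response(slopes, config.band_fraction, config.band_mode, diags)
        if slopes else []
    )
    resp_p = out_dir / "responses.tsv"
    pd.DataFrame(
        [{"association_id": c.association_id, "slope_c": c.slope_c,
          "slope_r": c.slope_r, "group": c.group, **c.diagnostics}
         for c in classifications]
    ).to_csv(resp_p, sep="\t", index=False, float_format="%.15g")
    _write_manifest(out_dir, "respond", {"band_fraction": config.band_fraction,
                                         "min_copresence": config.min_copresence}, [resp_p])
    results["responses"] = classifications
    if classifications:
        results["group_counts"] = summarize_groups(classifications)
        log.info("respond: %d persistent associations classified", len(classifications))
    return results
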