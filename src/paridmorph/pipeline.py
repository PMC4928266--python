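"""End-to-end study orchestration.

``run_pipeline`` ingests (or simulates) a complete dataset — linear
measurements, beak landmark configurations, a phylogeny and range tables —
and runs every analysis stage in order: per-trait ANOVA, body CVA and
species-mean PCA, Procrustes superimposition with sliding semilandmarks,
Procrustes ANOVA, shape CVA and PCA, phylomorphospace projection,
phylogenetic-signal tests (Blomberg's K and Pagel's λ, optionally with a
designated outlier species excluded), interspecific PGLS and intraspecific
OLS altitude regressions, and partial Mantel tests of morphological distance
against geographic and altitudinal range-overlap distances controlling for
phylogeny. Every table is written as a labelled CSV plus one JSON provenance
file; fixed seeds make the whole bundle byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import data_io, morphostats, overlap, phylo, superimposition
from .data_io import MEASUREMENT_TRAITS
from .synthetic_data import SimulationConfig, generate_study

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "describe"]

ALL_STAGES = (
    "anova",
    "body_cva",
    "body_pca",
    "superimposition",
    "procrustes_anova",
    "shape_cva",
    "shape_pca",
    "phylomorphospace",
    "signal",
    "regressions",
    "mantel",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs (file paths or a simulation), stage switches and seeds."""

    measurements_path: str | None = None
    landmarks_path: str | None = None
    tree_path: str | None = None
    ranges_path: str | None = None
    overlap_path: str | None = None
    simulation: SimulationConfig | None = None
    output_dir: str = "results"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    exclude_species: tuple[str, ...] = ()
    intraspecific_species: str | None = None  # default: best-sampled species
    mantel_permutations: int = 10_000
    signal_permutations: int = 999
    slide_criterion: str = "procrustes"
    phylomorphospace_axes: tuple[int, int] = (1, 2)

    def __post_init__(self) -> None:
        paths = [self.measurements_path, self.landmarks_path, self.tree_path]
        has_paths = any(p is not None for p in paths)
        if has_paths == (self.simulation is not None):
            raise ValueError(
                "exactly one of input paths or a simulation must be given"
            )
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulation is not None:
        study = generate_study(cfg.simulation)
        return study.measurements, study.configurations, study.tree, study.ranges
    measurements = data_io.read_measurements(cfg.measurements_path)
    configurations = data_io.read_tps(cfg.landmarks_path)
    tree = data_io.read_newick(cfg.tree_path)
    ranges = None
    if cfg.ranges_path and cfg.overlap_path:
        ranges = data_io.read_ranges(cfg.ranges_path, cfg.overlap_path)
    # configurations from raw TPS may lack species labels; fill from ids
    by_id = {m.specimen_id: m.species for m in measurements}
    for c in configurations:
        if not c.species and c.specimen_id in by_id:
            c.species = by_id[c.specimen_id]
    return measurements, configurations, tree, ranges


def _check_consistency(measurements, configurations, tree, ranges) -> None:
    meas_sp = {m.species for m in measurements}
    tree_sp = set(tree.tip_labels)
    missing = sorted(meas_sp - tree_sp)
    if missing:
        raise PipelineError(
            "ingest", f"species absent from the tree: {missing}"
        )
    conf_sp = {c.species for c in configurations if c.species}
    bad = sorted(conf_sp - tree_sp)
    if bad:
        raise PipelineError("ingest", f"landmark species absent from tree: {bad}")
    if ranges is not None:
        range_sp = {r.species for r in ranges}
        bad = sorted(meas_sp - range_sp)
        if bad:
            raise PipelineError("ingest", f"species missing range data: {bad}")


def run_pipeline(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run all requested stages; returns the tables and writes the bundle."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    measurements, configurations, tree, ranges = _load_inputs(cfg)
    _check_consistency(measurements, configurations, tree, ranges)
    rng = np.random.default_rng(cfg.seed)
    subseed = {
        name: int(s)
        for name, s in zip(
            ("procrustes_anova", "signal", "mantel"),
            rng.integers(0, 2**31 - 1, size=3),
        )
    }
    tables: dict[str, pd.DataFrame] = {}
    stages = set(cfg.stages)

    frame = data_io.measurements_frame(measurements)
    species_col = frame["species"]
    traits = frame[list(MEASUREMENT_TRAITS)]
    log_traits = morphostats.log_transform(traits)
    logger.info("ingest: %d measurement records, %d configurations, %d tips",
                len(measurements), len(configurations), tree.n_tips)

    # ----- traditional morphometrics ----------------------------------
    if "anova" in stages:
        rows = []
        for t in MEASUREMENT_TRAITS:
            res = morphostats.one_way_anova(log_traits[t], species_col)
            rows.append(
                {"trait": t, "F": res.F, "df_between": res.df_between,
                 "df_within": res.df_within, "p": res.p}
            )
        tables["anova_traits"] = pd.DataFrame(rows)

    complete = log_traits.dropna()
    complete_sp = species_col.loc[complete.index]
    if "body_cva" in stages:
        try:
            res = morphostats.cva(complete, complete_sp)
        except ValueError as exc:
            raise PipelineError("body_cva", str(exc))
        tables["body_cva_mahalanobis"] = res.mahalanobis.to_frame()
        tables["body_cva_scores"] = res.canonical_scores.assign(
            species=complete_sp
        )

    body_pca_scores = None
    sp_means = morphostats.species_means(log_traits, species_col)
    if "body_pca" in stages:
        std_means = morphostats.standardize(sp_means)
        res = morphostats.pca(std_means, mode="covariance")
        tables["body_pca_scores"] = res.scores
        tables["body_pca_loadings"] = res.loadings
        tables["body_pca_variance"] = pd.DataFrame(
            {"component": res.scores.columns,
             "variance_fraction": res.variance_fraction}
        )
        body_pca_scores = res.scores

    # ----- geometric morphometrics ------------------------------------
    aligned = None
    tangent = None
    shape_pca_scores = None
    if stages & {"superimposition", "procrustes_anova", "shape_cva",
                 "shape_pca", "phylomorphospace", "signal", "mantel",
                 "regressions"}:
        try:
            aligned = superimposition.gpa(configurations)
            if aligned.semi_mask.any() and cfg.slide_criterion != "none":
                aligned = superimposition.slide_semilandmarks(
                    aligned, criterion=cfg.slide_criterion
                )
        except (ValueError, superimposition.ConvergenceError) as exc:
            raise PipelineError("superimposition", str(exc))
        tangent = superimposition.tangent_project(aligned)
        coord_cols = [
            f"{ax}{i + 1}" for i in range(aligned.n_points) for ax in ("x", "y")
        ]
        tangent_df = pd.DataFrame(
            tangent, index=list(aligned.specimen_ids), columns=coord_cols
        )
        shape_species = pd.Series(list(aligned.species), index=tangent_df.index)
        if "superimposition" in stages:
            flat = pd.DataFrame(
                aligned.flat(), index=list(aligned.specimen_ids),
                columns=coord_cols,
            )
            flat.insert(0, "species", list(aligned.species))
            flat.insert(1, "centroid_size", aligned.centroid_sizes)
            tables["aligned_shapes"] = flat

    if "procrustes_anova" in stages:
        shape_res, size_res = morphostats.procrustes_anova(
            tangent, aligned.centroid_sizes, list(aligned.species),
            seed=subseed["procrustes_anova"],
        )
        tables["procrustes_anova"] = pd.DataFrame(
            [
                {"effect": "shape", "F": shape_res.F,
                 "df_between": shape_res.df_between,
                 "df_within": shape_res.df_within, "p": shape_res.p},
                {"effect": "size", "F": size_res.F,
                 "df_between": size_res.df_between,
                 "df_within": size_res.df_within, "p": size_res.p},
            ]
        )

    if "shape_cva" in stages:
        try:
            res = morphostats.cva(tangent_df, shape_species)
        except ValueError as exc:
            raise PipelineError("shape_cva", str(exc))
        tables["shape_cva_mahalanobis"] = res.mahalanobis.to_frame()

    mean_shapes = None
    if stages & {"shape_pca", "phylomorphospace", "signal", "regressions"}:
        mean_shapes = morphostats.species_means(tangent_df, shape_species)
        res = morphostats.pca(mean_shapes, mode="covariance")
        shape_pca_scores = res.scores
        if "shape_pca" in stages:
            tables["shape_pca_scores"] = res.scores
            tables["shape_pca_loadings"] = res.loadings
            tables["shape_pca_variance"] = pd.DataFrame(
                {"component": res.scores.columns,
                 "variance_fraction": res.variance_fraction}
            )

    if "phylomorphospace" in stages:
        a, b = cfg.phylomorphospace_axes
        axes = [f"PC{a}", f"PC{b}"]
        avail = [ax for ax in axes if ax in shape_pca_scores.columns]
        if len(avail) < 2:
            axes = list(shape_pca_scores.columns[:2])
        nodes, edges = phylo.phylomorphospace(tree, shape_pca_scores[axes])
        tables["phylomorphospace_nodes"] = nodes
        tables["phylomorphospace_edges"] = edges

    # ----- comparative analyses ----------------------------------------
    if stages & {"signal", "regressions", "mantel"}:
        log_weight = sp_means["body_weight"]
        size_corrected = morphostats.size_correct(
            sp_means.drop(columns=["body_weight"]), log_weight
        )

    if "signal" in stages:
        tables["signal"] = _signal_table(
            cfg, tree, sp_means, size_corrected, body_pca_scores,
            shape_pca_scores, subseed["signal"],
        )

    if "regressions" in stages:
        tables["regressions"] = _regression_table(
            cfg, tree, frame, log_traits, species_col, sp_means,
            body_pca_scores, shape_pca_scores, ranges,
        )

    if "mantel" in stages:
        if ranges is None:
            raise PipelineError("mantel", "range tables are required")
        tables["mantel"] = _mantel_table(
            cfg, tree, complete, complete_sp, tangent_df, shape_species,
            ranges, subseed["mantel"],
        )

    # ----- write bundle -------------------------------------------------
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=not isinstance(df.index, pd.RangeIndex))
    provenance = {
        "package": "paridmorph",
        "version": __version__,
        "seed": cfg.seed,
        "stage_seeds": subseed,
        "config": _jsonable(asdict(cfg)),
        "n_measurements": len(measurements),
        "n_configurations": len(configurations),
        "n_species": tree.n_tips,
        "tables": sorted(tables),
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return tables


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _signal_table(cfg, tree, sp_means, size_corrected, body_pca_scores,
                  shape_pca_scores, seed) -> pd.DataFrame:
    """K and λ for log traits, size-corrected traits and PC scores, on the
    full species set and with each configured exclusion."""
    datasets = [("all", tree, None)]
    for sp in cfg.exclude_species:
        datasets.append((f"excl_{sp}", tree.without_tips([sp]), sp))
    traitsets: list[tuple[str, pd.DataFrame]] = [("log", sp_means),
                                                 ("size_corrected", size_corrected)]
    if body_pca_scores is not None:
        traitsets.append(("body_pc", body_pca_scores.iloc[:, :3]))
    if shape_pca_scores is not None:
        traitsets.append(("shape_pc", shape_pca_scores.iloc[:, :3]))
    rng = np.random.default_rng(seed)
    rows = []
    for ds_name, ds_tree, dropped in datasets:
        tips = ds_tree.tip_labels
        for set_name, table in traitsets:
            sub = table.loc[[t for t in table.index if t in tips]]
            for col in sub.columns:
                trait = sub[col].to_dict()
                k_res = phylo.blomberg_k(
                    ds_tree, trait, n_perm=cfg.signal_permutations,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                l_res = phylo.pagel_lambda(ds_tree, trait)
                rows.append(
                    {"dataset": ds_name, "trait_set": set_name, "trait": col,
                     "K": k_res.estimate, "K_p": k_res.p,
                     "lambda": l_res.estimate, "lambda_p": l_res.p}
                )
    return pd.DataFrame(rows)


def _regression_table(cfg, tree, frame, log_traits, species_col, sp_means,
                      body_pca_scores, shape_pca_scores, ranges) -> pd.DataFrame:
    rows = []
    # interspecific: PGLS of species means on altitudinal midpoints
    if ranges is not None:
        mid = {r.species: (r.alt_min + r.alt_max) / 2.0 for r in ranges}
        targets: list[tuple[str, pd.Series]] = [
            (t, sp_means[t]) for t in sp_means.columns
        ]
        if body_pca_scores is not None:
            targets.append(("body_PC1", body_pca_scores["PC1"]))
        if shape_pca_scores is not None:
            targets.append(("shape_PC1", shape_pca_scores["PC1"]))
        alt = {sp: mid[sp] for sp in tree.tip_labels}
        for name, series in targets:
            res = phylo.pgls(series.to_dict(), alt, tree)
            rows.append(
                {"level": "interspecific", "trait": name, "method": "PGLS",
                 "slope": res.slope, "stderr": res.slope_se,
                 "intercept": res.intercept, "t": res.t, "p": res.p}
            )
    # intraspecific: OLS within the best-sampled (or designated) species
    target_sp = cfg.intraspecific_species
    if target_sp is None:
        target_sp = species_col.value_counts().idxmax()
    mask = (species_col == target_sp) & frame["altitude"].notna()
    if mask.sum() >= 3:
        alt_ind = frame.loc[mask, "altitude"]
        for t in MEASUREMENT_TRAITS:
            y = log_traits.loc[mask, t]
            if y.notna().sum() < 3:
                continue
            res = morphostats.ols_regression(y, alt_ind)
            rows.append(
                {"level": f"intraspecific:{target_sp}", "trait": t,
                 "method": "OLS", "slope": res.slope, "stderr": res.stderr,
                 "intercept": res.intercept, "t": np.nan, "p": res.p}
            )
    return pd.DataFrame(rows)


def _mantel_table(cfg, tree, complete, complete_sp, tangent_df, shape_species,
                  ranges, seed) -> pd.DataFrame:
    order = tuple(tree.tip_labels)
    body = morphostats.cva(complete, complete_sp).mahalanobis.reindex(order)
    beak = morphostats.cva(tangent_df, shape_species).mahalanobis.reindex(order)
    geo = overlap.overlap_distance_matrix(ranges).reindex(order)
    alt = overlap.altitudinal_overlap_distance(ranges).reindex(order)
    phy = overlap.phylogenetic_distance_matrix(tree).reindex(order)
    rng = np.random.default_rng(seed)
    rows = []
    for m_name, M in (("body", body), ("beak", beak)):
        for d_name, D in (("geographic", geo), ("altitudinal", alt)):
            res = overlap.partial_mantel(
                M, D, phy, n_perm=cfg.mantel_permutations,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            rows.append(
                {"morphology": m_name, "distance": d_name, "r": res.r,
                 "p": res.p, "n_permutations": res.n_permutations}
            )
    return pd.DataFrame(rows)


def describe(output_dir) -> str:
    """One-page text summary of a report bundle's headline numbers."""
    outdir = Path(output_dir)
    if not outdir.is_dir() or not any(outdir.glob("*.csv")):
        raise FileNotFoundError(f"no report bundle in {output_dir}")
    lines = [f"Report bundle: {outdir}"]

    def table(name):
        path = outdir / f"{name}.csv"
        return pd.read_csv(path) if path.exists() else None

    t = table("body_pca_variance")
    if t is not None:
        vf = t["variance_fraction"].to_numpy()
        lines.append(
            f"Body PCA: PC1 {vf[0] * 100:.2f}% / PC2 {vf[1] * 100:.2f}% of variance"
        )
    t = table("shape_pca_variance")
    if t is not None:
        vf = t["variance_fraction"].to_numpy()
        lines.append(
            f"Shape PCA: first 3 PCs {vf[:3].sum() * 100:.2f}% of variance"
        )
    t = table("anova_traits")
    if t is not None:
        for _, r in t.iterrows():
            lines.append(
                f"ANOVA {r['trait']}: F({int(r['df_between'])},"
                f"{int(r['df_within'])}) = {r['F']:.2f}, p = {r['p']:.3g}"
            )
    t = table("procrustes_anova")
    if t is not None:
        for _, r in t.iterrows():
            lines.append(
                f"Procrustes ANOVA {r['effect']}: F({int(r['df_between'])},"
                f"{int(r['df_within'])}) = {r['F']:.2f}, p = {r['p']:.3g}"
            )
    t = table("signal")
    if t is not None:
        sig = t[(t["K_p"] < 0.05) | (t["lambda_p"] < 0.05)]
        lines.append(
            f"Phylogenetic signal: {len(sig)}/{len(t)} trait tests significant"
        )
    t = table("mantel")
    if t is not None:
        for _, r in t.iterrows():
            lines.append(
                f"Partial Mantel {r['morphology']} x {r['distance']}: "
                f"r = {r['r']:.3f}, p = {r['p']:.4g}"
            )
    missing = [
        n for n in ("body_pca_variance", "procrustes_anova", "mantel", "signal")
        if not (outdir / f"{n}.csv").exists()
    ]
    for n in missing:
        logger.warning("table %s missing; summary is partial", n)
    return "\n".join(lines)
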