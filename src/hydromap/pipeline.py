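"""End-to-end orchestration: simulate/load -> signal -> familystats -> cwm ->
cluster -> interpolate -> crossval -> mess.

A run is described by a single declarative config (YAML on disk, a nested
dict in memory): either a ``simulate`` block (SimConfig fields) or an
``inputs`` block (paths to a Newick tree, trait CSV, inventory CSV and ASCII
rasters), a ``stages`` list of toggles, per-stage parameter blocks, an output
directory and a global seed. Every number in every output table can be traced
back through the run manifest, which records the config snapshot, derived
stage seeds, output checksums and timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import (
    InvalidArgumentError,
    PipelineDependencyError,
    PipelineValidationError,
)
from .gridio import AsciiGrid, GridSpec
from .phylosignal import (
    Phylogeny,
    blomberg_k,
    node_randomisation,
    permutation_test,
    prune_to_overlap,
)
from .simulate import SimConfig, simulate_bundle
from .traitstats import (
    choose_transformation,
    fabaceae_contrast,
    family_anova_tukey,
    nested_anova,
    select_nested_subset,
)
from .cwm import compute_cwm_table, gapfill_validation
from .geo import (
    IdwParams,
    constrained_ward,
    fold_averaged_surface,
    loocv_search,
    mess,
    select_alpha,
    spatial_cv,
)

log = logging.getLogger("hydromap")

STAGE_ORDER = (
    "signal",
    "familystats",
    "cwm",
    "cluster",
    "interpolate",
    "crossval",
    "mess",
)
STAGE_DEPS = {
    "cluster": ("cwm",),
    "interpolate": ("cwm", "cluster"),
    "crossval": ("cwm", "cluster", "interpolate"),
    "mess": ("cwm",),
}


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    seed: int = 0
    outdir: str = "hydromap_out"
    simulate: dict | None = None  # SimConfig field overrides
    inputs: dict | None = None  # paths: tree, traits, inventories, rasters{}
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))
    signal: dict = field(default_factory=dict)
    familystats: dict = field(default_factory=dict)
    cwm: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    interpolate: dict = field(default_factory=dict)
    crossval: dict = field(default_factory=dict)
    mess: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunManifest:
    """Reproducibility record written at the end of a run."""

    config: dict
    version: str
    stage_seeds: dict
    checksums: dict  # relative output path -> sha256
    timings: dict  # stage -> seconds
    completed: list[str]
    failed_stage: str | None = None

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seeds(seed: int) -> dict:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGE_ORDER) + 1)
    out = {"simulate": int(children[0].generate_state(1)[0] % (2**31 - 1))}
    for name, child in zip(STAGE_ORDER, children[1:]):
        out[name] = int(child.generate_state(1)[0] % (2**31 - 1))
    return out


# ---------------------------------------------------------------------------
# validation


def validate_inputs(config: RunConfig):
    """Schema and cross-reference checks; returns (errors, warnings).

    Errors are hard violations (missing columns, positive psi50, unreadable
    files); warnings cover recoverable oddities (inventory families absent
    from the trait table — the plot-mean gap-fill may still resolve them).
    Collection is exhaustive, not fail-fast.
    """
    errors: list[str] = []
    warnings_: list[str] = []
    if (config.simulate is None) == (config.inputs is None):
        errors.append("config must provide exactly one of 'simulate' or 'inputs'")
        return errors, warnings_
    if config.simulate is not None:
        try:
            SimConfig(seed=config.seed, **config.simulate)
        except Exception as exc:
            errors.append(f"simulate block invalid: {exc}")
        return errors, warnings_

    paths = config.inputs
    tree = traits = inventories = None
    for key in ("tree", "traits", "inventories"):
        if key not in paths:
            errors.append(f"inputs missing path: {key}")
        elif not Path(paths[key]).exists():
            errors.append(f"inputs.{key} does not exist: {paths[key]}")
    if errors:
        return errors, warnings_
    try:
        tree = Phylogeny.from_newick_file(paths["tree"])
    except Exception as exc:
        errors.append(f"tree unreadable: {exc}")
    try:
        traits = pd.read_csv(paths["traits"])
        need = {"species", "genus", "family", "site", "psi50"}
        missing = need - set(traits.columns)
        if missing:
            errors.append(f"trait table missing columns: {sorted(missing)}")
        elif (traits["psi50"] >= 0).any():
            errors.append(
                "trait table has non-negative psi50 values; psi50 is a "
                "negative water potential in MPa"
            )
        if traits is not None and "genus" in traits and "family" in traits:
            multi = traits.groupby("genus")["family"].nunique()
            bad = multi[multi > 1].index.tolist()
            if bad:
                errors.append(f"genera mapped to multiple families: {bad}")
    except Exception as exc:
        errors.append(f"trait table unreadable: {exc}")
    try:
        inventories = pd.read_csv(paths["inventories"])
        need = {"plot_id", "species", "genus", "family", "basal_area"}
        missing = need - set(inventories.columns)
        if missing:
            errors.append(f"inventory missing columns: {sorted(missing)}")
        elif (inventories["basal_area"] <= 0).any():
            errors.append("inventory has non-positive basal areas")
    except Exception as exc:
        errors.append(f"inventory unreadable: {exc}")
    for name, rpath in (paths.get("rasters") or {}).items():
        try:
            AsciiGrid.read(rpath)
        except Exception as exc:
            errors.append(f"raster {name!r} unreadable: {exc}")
    if tree is not None and traits is not None and "genus" in traits:
        tips = {t.casefold() for t in tree.tip_labels}
        genera = {str(g).casefold() for g in traits["genus"].unique()}
        overlap = tips & genera
        if len(overlap) < 3:
            errors.append(
                f"only {len(overlap)} genera shared between tree and traits"
            )
        elif len(overlap) < len(genera):
            warnings_.append(
                f"{len(genera) - len(overlap)} trait genera not in tree (dropped)"
            )
    if inventories is not None and traits is not None and "family" in traits:
        inv_fams = {str(f).casefold() for f in inventories["family"].unique()}
        known = {str(f).casefold() for f in traits["family"].unique()}
        orphan = inv_fams - known
        if orphan:
            warnings_.append(
                f"{len(orphan)} inventory families without trait coverage "
                "(gap-fill may still resolve via plot mean)"
            )
    return errors, warnings_


# ---------------------------------------------------------------------------
# run


def _load_study(config: RunConfig, seeds: dict):
    """Materialise tree/traits/inventories/rasters from either source."""
    if config.simulate is not None:
        sim = SimConfig(seed=seeds["simulate"], **config.simulate)
        bundle = simulate_bundle(sim)
        return bundle.tree, bundle.traits, bundle.inventories, bundle.rasters
    paths = config.inputs
    tree = Phylogeny.from_newick_file(paths["tree"])
    traits = pd.read_csv(paths["traits"])
    inventories = pd.read_csv(paths["inventories"])
    rasters = {
        name: AsciiGrid.read(p) for name, p in (paths.get("rasters") or {}).items()
    }
    return tree, traits, inventories, rasters


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in dependency order and write the manifest.

    Each stage reads only the declared upstream artifacts and writes CSV/ASC
    files under ``outdir``; the manifest (config snapshot, seeds, checksums,
    timings) is written last. A stage failure stops the run but still writes
    a manifest recording partial completion.
    """
    errors, warns = validate_inputs(config)
    for w in warns:
        log.warning(w)
    if errors:
        raise PipelineValidationError(errors)
    enabled = [s for s in STAGE_ORDER if s in config.stages]
    unknown = set(config.stages) - set(STAGE_ORDER)
    if unknown:
        raise InvalidArgumentError(f"unknown stages: {sorted(unknown)}")
    for s in enabled:
        missing = [d for d in STAGE_DEPS.get(s, ()) if d not in enabled]
        if missing:
            raise PipelineDependencyError(
                f"stage {s!r} requires {missing} (artifact missing from run)"
            )
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        stage_seeds=seeds,
        checksums={},
        timings={},
        completed=[],
    )
    artifacts: dict[str, object] = {}
    tree, traits, inventories, rasters = _load_study(config, seeds)
    if config.simulate is not None:
        tree_path = out / "tree.nwk"
        tree_path.write_text(tree.to_newick() + "\n")
        traits.to_csv(out / "traits.csv", index=False)
        inventories.to_csv(out / "inventories.csv", index=False)

    def _run_stage(name, fn):
        t0 = time.perf_counter()
        log.info("stage %s: seed=%s", name, seeds[name])
        try:
            fn()
        except Exception:
            manifest.failed_stage = name
            manifest.write(out / "manifest.json")
            raise
        manifest.timings[name] = round(time.perf_counter() - t0, 3)
        manifest.completed.append(name)

    # -- stages ----------------------------------------------------------
    def stage_signal():
        p = config.signal
        genus_means = traits.groupby("genus")["psi50"].mean().to_dict()
        ptree, sub, dropped = prune_to_overlap(tree, genus_means)
        if dropped:
            log.info("signal: dropped %d unmatched genera", len(dropped))
        transformation = p.get("transformation", "auto")
        if transformation == "auto":
            choice = choose_transformation(np.array(list(sub.values())))
            transformation = choice.transformation
            log.info("signal: %s", choice.trace)
        res = permutation_test(
            ptree,
            sub,
            n_permutations=int(p.get("n_permutations", 1000)),
            seed=seeds["signal"],
            transformation=transformation,
        )
        nodes = node_randomisation(
            ptree,
            sub,
            n_permutations=int(p.get("n_permutations", 1000)),
            alpha=float(p.get("alpha", 0.05)),
            tail=p.get("tail", "upper"),
            seed=seeds["signal"],
            transformation=transformation,
        )
        pd.DataFrame(
            [
                {
                    "k": res.k,
                    "p_value": res.p_value,
                    "significant": res.significant,
                    "n_genera": res.n_genera,
                    "n_permutations": res.n_permutations,
                    "transformation": res.transformation,
                }
            ]
        ).to_csv(out / "signal_k.csv", index=False)
        pd.DataFrame(
            {
                "node_id": nodes.node_ids,
                "observed": nodes.observed,
                "null_rank": nodes.null_rank,
                "p_value": nodes.p_values,
                "flagged": nodes.flagged,
            }
        ).to_csv(out / "signal_nodes.csv", index=False)
        artifacts["signal"] = res

    def stage_familystats():
        p = config.familystats
        sub = select_nested_subset(traits)
        nested = nested_anova(sub, transformation=p.get("transformation", "sqrt"))
        tab = nested.terms.copy()
        tab.loc["residual"] = [nested.residual_ss, nested.residual_df, np.nan, np.nan]
        tab.to_csv(out / "nested_anova.csv")
        fam = family_anova_tukey(traits, min_sites=int(p.get("min_sites", 3)))
        fam.tukey.to_csv(out / "family_tukey.csv", index=False)
        pd.DataFrame(
            sorted(fam.letters.items()), columns=["family", "letters"]
        ).to_csv(out / "family_letters.csv", index=False)
        rows = []
        contrast_family = p.get("contrast_family")
        if contrast_family is None:
            # default: the most record-rich family (Fabaceae analogue)
            contrast_family = traits["family"].value_counts().index[0]
        scopes = [None] + sorted(traits.get("forest_type", pd.Series()).unique())
        for ft in scopes:
            try:
                r = fabaceae_contrast(traits, forest_type=ft, family=contrast_family)
            except Exception as exc:
                log.info("familystats: contrast skipped for %s (%s)", ft, exc)
                continue
            rows.append(
                {
                    "forest_type": ft or "all",
                    "family": contrast_family,
                    "W": r.w,
                    "p_value": r.p_value,
                    "n_family": r.n_a,
                    "n_other": r.n_b,
                    "mean_family": r.mean_a,
                    "sd_family": r.sd_a,
                    "mean_other": r.mean_b,
                    "sd_other": r.sd_b,
                }
            )
        pd.DataFrame(rows).to_csv(out / "family_contrast.csv", index=False)
        artifacts["familystats"] = nested

    def stage_cwm():
        p = config.cwm
        table = compute_cwm_table(
            inventories,
            traits,
            coverage_threshold=float(p.get("coverage_threshold", 0.60)),
            mean_mode=p.get("mean_mode", "record"),
        )
        table.to_csv(out / "cwm.csv", index=False)
        try:
            val = gapfill_validation(inventories, traits)
            pd.DataFrame([val]).to_csv(out / "gapfill_validation.csv", index=False)
        except Exception as exc:
            log.info("cwm: gap-fill validation skipped (%s)", exc)
        artifacts["cwm"] = table

    def _plot_features():
        table: pd.DataFrame = artifacts["cwm"]
        feats = {"cwm_psi50": table["cwm_psi50"].to_numpy()}
        for name, grid in rasters.items():
            feats[name] = grid.sample(table["x_km"], table["y_km"])
        return table, feats

    def stage_cluster():
        p = config.cluster
        table, feats = _plot_features()
        F = np.column_stack(list(feats.values()))
        if p.get("standardize", True):
            sd = F.std(axis=0)
            sd[sd == 0] = 1.0
            F = (F - F.mean(axis=0)) / sd
        D0 = np.sqrt(((F[:, None, :] - F[None, :, :]) ** 2).sum(axis=2))
        xy = table[["x_km", "y_km"]].to_numpy()
        D1 = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
        k = int(p.get("k", 5))
        alpha = p.get("alpha")
        if alpha is None:
            alpha, curves = select_alpha(
                D0, D1, k=k, q0_tolerance=float(p.get("q0_tolerance", 0.1))
            )
            curves.to_csv(out / "cluster_alpha_curves.csv", index=False)
            log.info("cluster: selected alpha=%.2f", alpha)
        sol = constrained_ward(D0, D1, alpha=float(alpha), k=k)
        table = table.copy()
        table["cluster"] = sol.labels
        table.to_csv(out / "cwm_clustered.csv", index=False)
        pd.DataFrame(
            [{"alpha": sol.alpha, "k": sol.k, "q0": sol.q0, "q1": sol.q1}]
        ).to_csv(out / "cluster_summary.csv", index=False)
        artifacts["cluster"] = sol

    def stage_interpolate():
        p = config.interpolate
        table: pd.DataFrame = artifacts["cwm"]
        sol = artifacts["cluster"]
        xy = table[["x_km", "y_km"]].to_numpy()
        vals = table["cwm_psi50"].to_numpy()
        params, trace = loocv_search(
            xy,
            vals,
            idp_grid=p.get("idp_grid"),
            nmax_grid=p.get("nmax_grid"),
            n_refine_steps=int(p.get("n_refine_steps", 3)),
        )
        trace.to_csv(out / "idw_search_trace.csv", index=False)
        log.info("interpolate: idp=%.3f nmax=%d", params.idp, params.nmax)
        if rasters:
            ref = next(iter(rasters.values()))
            spec = ref.spec
        else:
            cell = float(p.get("cell_size", 25.0))
            spec = GridSpec.from_extent(
                (
                    xy[:, 0].min(), xy[:, 1].min(),
                    xy[:, 0].max(), xy[:, 1].max(),
                ),
                cell,
            )
        surface = fold_averaged_surface(
            xy,
            vals,
            sol.labels,
            params,
            spec,
            smooth_window=int(p.get("smooth_window", 9)),
            training=p.get("training", "complement"),
        )
        surface.to_ascii().write(out / "cwm_surface.asc")
        artifacts["idw_params"] = params
        artifacts["surface"] = surface

    def stage_crossval():
        table: pd.DataFrame = artifacts["cwm"]
        sol = artifacts["cluster"]
        xy = table[["x_km", "y_km"]].to_numpy()
        vals = table["cwm_psi50"].to_numpy()
        report = spatial_cv(
            xy, vals, sol.labels, artifacts["idw_params"],
            surface=artifacts.get("surface"),
        )
        report.predictions.to_csv(out / "crossval_predictions.csv", index=False)
        summary = pd.DataFrame(
            [
                {"fold": f, "rmse": r}
                for f, r in sorted(report.fold_rmse.items())
            ]
            + [{"fold": "pooled", "rmse": report.pooled_rmse}]
        )
        summary["vecv"] = report.vecv
        summary.to_csv(out / "crossval_summary.csv", index=False)
        if report.cluster_agreement is not None:
            report.cluster_agreement.to_csv(
                out / "cluster_agreement.csv", index=False
            )
        artifacts["crossval"] = report

    def stage_mess():
        if not rasters:
            raise InvalidArgumentError("mess stage needs environmental rasters")
        table: pd.DataFrame = artifacts["cwm"]
        reference = {
            name: grid.sample(table["x_km"], table["y_km"])
            for name, grid in rasters.items()
        }
        query = {name: grid.values for name, grid in rasters.items()}
        layer = mess(reference, query)
        ref_grid = next(iter(rasters.values()))
        AsciiGrid(
            values=layer.scores,
            xll=ref_grid.xll,
            yll=ref_grid.yll,
            cell_size=ref_grid.cell_size,
        ).write(out / "mess.asc")
        frac_inside = float(np.mean(layer.scores >= 0))
        pd.DataFrame(
            [{"fraction_within_envelope": frac_inside,
              "n_cells": layer.scores.size}]
        ).to_csv(out / "mess_summary.csv", index=False)
        artifacts["mess"] = layer

    stage_fns = {
        "signal": stage_signal,
        "familystats": stage_familystats,
        "cwm": stage_cwm,
        "cluster": stage_cluster,
        "interpolate": stage_interpolate,
        "crossval": stage_crossval,
        "mess": stage_mess,
    }
    for name in enabled:
        _run_stage(name, stage_fns[name])
    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest.checksums[f.name] = _sha256(f)
    manifest.write(out / "manifest.json")
    return manifest
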