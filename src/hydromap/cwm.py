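"""Plot-level community-weighted mean psi50 via taxonomic gap-filling.

Forest-inventory stems rarely have a direct psi50 measurement; values are
imputed down the taxonomic hierarchy: a species mean when the species was
measured, else the genus mean, else the family mean, else the basal-area
weighted mean of the stems already resolved within the same plot. The
community-weighted mean (CWM) then weights each stem's trait value by its
share of plot basal area.

Two quality controls accompany the imputation: the *coverage filter* keeps
only plots whose dicot basal area is at least 60 % in families present in the
trait database, and the *gap-fill validation* regresses family-filled CWMs
against species-level CWMs on the plots where species data exist.

Inventories are tidy DataFrames with columns ``plot_id, x_km, y_km, species,
genus, family, basal_area, dicot``; trait tables follow the schema of
:mod:`hydromap.traitstats`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientDataError,
    InvalidArgumentError,
    UndefinedCoverageError,
    UnfillablePlotError,
)

__all__ = [
    "CwmRecord",
    "trait_means",
    "gap_fill",
    "coverage_filter",
    "community_weighted_mean",
    "compute_cwm_table",
    "gapfill_validation",
]

FILL_LEVELS = ("species", "genus", "family", "plot_mean")

INVENTORY_COLUMNS = ("plot_id", "species", "genus", "family", "basal_area")


def _norm(s: pd.Series) -> pd.Series:
    """Exact name matching after case/whitespace normalisation."""
    return s.astype(str).str.strip().str.casefold()


def _check_inventory(inventory: pd.DataFrame) -> None:
    missing = [c for c in INVENTORY_COLUMNS if c not in inventory.columns]
    if missing:
        raise InvalidArgumentError(f"inventory missing columns: {missing}")
    if (inventory["basal_area"] <= 0).any():
        raise InvalidArgumentError("basal areas must be > 0")


@dataclass
class CwmRecord:
    """One plot's community-weighted mean and its imputation provenance."""

    plot_id: str
    cwm_psi50: float
    total_basal_area: float
    coverage_fraction: float | None
    fill_profile: dict[str, float]  # basal-area fraction resolved per level


def trait_means(
    traits: pd.DataFrame, mode: str = "record"
) -> tuple[dict, dict, dict]:
    """Species, genus and family mean psi50 lookup tables.

    ``mode='record'`` averages raw species-site records at each level;
    ``mode='species'`` first collapses to species means, then averages those
    (mean of means) for genus and family. Keys are normalised names.
    """
    if mode not in ("record", "species"):
        raise InvalidArgumentError(f"unknown trait-mean mode {mode!r}")
    t = traits.copy()
    t["species_n"] = _norm(t["species"])
    t["genus_n"] = _norm(t["genus"])
    t["family_n"] = _norm(t["family"])
    species = t.groupby("species_n")["psi50"].mean().to_dict()
    if mode == "record":
        genus = t.groupby("genus_n")["psi50"].mean().to_dict()
        family = t.groupby("family_n")["psi50"].mean().to_dict()
    else:
        sp = t.groupby(["family_n", "genus_n", "species_n"])["psi50"].mean().reset_index()
        genus = sp.groupby("genus_n")["psi50"].mean().to_dict()
        family = sp.groupby("family_n")["psi50"].mean().to_dict()
    return species, genus, family


def gap_fill(
    inventory: pd.DataFrame,
    traits: pd.DataFrame,
    mean_mode: str = "record",
    plot_mean_weighted: bool = True,
) -> pd.DataFrame:
    """Assign every stem a psi50 and a provenance level.

    Resolution order per stem: species mean, genus mean, family mean, then
    the plot mean of the stems already resolved at a finer level (basal-area
    weighted by default). Returns the inventory with ``psi50_filled`` and
    ``fill_level`` columns; a plot where nothing resolves at any taxonomic
    level raises :class:`UnfillablePlotError`.
    """
    _check_inventory(inventory)
    sp_mean, gen_mean, fam_mean = trait_means(traits, mean_mode)
    out = inventory.copy()
    sp = _norm(out["species"]).map(sp_mean)
    gen = _norm(out["genus"]).map(gen_mean)
    fam = _norm(out["family"]).map(fam_mean)
    filled = sp.copy()
    level = pd.Series(
        np.where(sp.notna(), "species", None), index=out.index, dtype=object
    )
    level[filled.isna() & gen.notna()] = "genus"
    filled = filled.fillna(gen)
    level[filled.isna() & fam.notna()] = "family"
    filled = filled.fillna(fam)
    out["psi50_filled"] = filled
    out["fill_level"] = level
    # plot-mean fallback from records resolved at finer levels
    for plot_id, grp in out.groupby("plot_id", sort=False):
        open_idx = grp.index[grp["psi50_filled"].isna()]
        if len(open_idx) == 0:
            continue
        resolved = grp.dropna(subset=["psi50_filled"])
        if resolved.empty:
            raise UnfillablePlotError(
                f"plot {plot_id!r}: no record resolvable at any taxonomic level"
            )
        if plot_mean_weighted:
            pm = float(
                np.average(
                    resolved["psi50_filled"], weights=resolved["basal_area"]
                )
            )
        else:
            pm = float(resolved["psi50_filled"].mean())
        out.loc[open_idx, "psi50_filled"] = pm
        out.loc[open_idx, "fill_level"] = "plot_mean"
    return out


def coverage_filter(
    inventory: pd.DataFrame,
    traits: pd.DataFrame,
    threshold: float = 0.60,
) -> pd.DataFrame:
    """Per-plot dicot family coverage against the trait database.

    Coverage is the fraction of *dicot* basal area belonging to families
    present in the trait table; a plot passes when coverage >= ``threshold``.
    Monocots are excluded from both numerator and denominator. A plot with
    zero dicot basal area has undefined coverage and raises.
    """
    _check_inventory(inventory)
    if "dicot" not in inventory.columns:
        raise InvalidArgumentError("inventory needs a dicot flag column")
    fams = set(_norm(traits["family"]))
    inv = inventory.copy()
    inv["_fam"] = _norm(inv["family"])
    rows = []
    for plot_id, grp in inv.groupby("plot_id", sort=False):
        dic = grp[grp["dicot"].astype(bool)]
        total = float(dic["basal_area"].sum())
        if total <= 0:
            raise UndefinedCoverageError(
                f"plot {plot_id!r} has zero dicot basal area"
            )
        covered = float(dic.loc[dic["_fam"].isin(fams), "basal_area"].sum())
        cov = covered / total
        rows.append(
            {"plot_id": plot_id, "coverage": cov, "passed": cov >= threshold}
        )
    return pd.DataFrame(rows)


def community_weighted_mean(filled_plot: pd.DataFrame) -> CwmRecord:
    """CWM of one gap-filled plot: sum(BA_i * psi_i) / sum(BA_i)."""
    if filled_plot.empty:
        raise InvalidArgumentError("empty plot")
    if "psi50_filled" not in filled_plot.columns:
        raise InvalidArgumentError("plot not gap-filled (no psi50_filled column)")
    ba = filled_plot["basal_area"].to_numpy(dtype=float)
    total = float(ba.sum())
    if total <= 0:
        raise InvalidArgumentError("plot total basal area is zero")
    psi = filled_plot["psi50_filled"].to_numpy(dtype=float)
    cwm = float(np.dot(ba, psi) / total)
    profile = {
        lvl: float(ba[(filled_plot["fill_level"] == lvl).to_numpy()].sum() / total)
        for lvl in FILL_LEVELS
    }
    pid = str(filled_plot["plot_id"].iloc[0])
    return CwmRecord(
        plot_id=pid,
        cwm_psi50=cwm,
        total_basal_area=total,
        coverage_fraction=None,
        fill_profile=profile,
    )


def compute_cwm_table(
    inventory: pd.DataFrame,
    traits: pd.DataFrame,
    coverage_threshold: float = 0.60,
    mean_mode: str = "record",
    apply_filter: bool = True,
) -> pd.DataFrame:
    """Inventory + traits -> per-plot CWM table with coverage and provenance.

    Plots failing the dicot-family coverage filter are dropped when
    ``apply_filter``. Output columns: plot_id, x_km, y_km, cwm_psi50,
    coverage, plus ``frac_<level>`` fill-profile columns.
    """
    cov = coverage_filter(inventory, traits, coverage_threshold)
    keep = set(cov.loc[cov["passed"], "plot_id"]) if apply_filter else set(
        cov["plot_id"]
    )
    filled = gap_fill(inventory[inventory["plot_id"].isin(keep)], traits, mean_mode)
    cov_map = cov.set_index("plot_id")["coverage"].to_dict()
    rows = []
    for plot_id, grp in filled.groupby("plot_id", sort=False):
        rec = community_weighted_mean(grp)
        row = {
            "plot_id": rec.plot_id,
            "cwm_psi50": rec.cwm_psi50,
            "coverage": cov_map[plot_id],
            "total_basal_area": rec.total_basal_area,
        }
        for c in ("x_km", "y_km"):
            if c in grp.columns:
                row[c] = float(grp[c].iloc[0])
        for lvl in FILL_LEVELS:
            row[f"frac_{lvl}"] = rec.fill_profile[lvl]
        rows.append(row)
    if not rows:
        raise InsufficientDataError("no plot passed the coverage filter")
    return pd.DataFrame(rows)


def gapfill_validation(
    inventory: pd.DataFrame,
    traits: pd.DataFrame,
    min_species_fraction: float = 0.8,
) -> dict:
    """Degrade species-resolved plots to family means and compare CWMs.

    For plots where at least ``min_species_fraction`` of basal area resolves
    at species level, the species-level CWM is recomputed after replacing
    every species value by its family mean (simulating the gap-fill), and the
    two CWM sets are compared by ordinary least squares. Returns r2, slope,
    intercept, p_value and n_plots.
    """
    sp_mean, _, fam_mean = trait_means(traits)
    inv = inventory.copy()
    inv["_sp"] = _norm(inv["species"]).map(sp_mean)
    inv["_fam"] = _norm(inv["family"]).map(fam_mean)
    x_true, y_filled = [], []
    for _, grp in inv.groupby("plot_id", sort=False):
        ba = grp["basal_area"].to_numpy(dtype=float)
        have_sp = grp["_sp"].notna().to_numpy()
        if ba[have_sp].sum() < min_species_fraction * ba.sum():
            continue
        sub = grp[have_sp & grp["_fam"].notna()]
        if sub.empty:
            continue
        w = sub["basal_area"].to_numpy(dtype=float)
        x_true.append(float(np.average(sub["_sp"], weights=w)))
        y_filled.append(float(np.average(sub["_fam"], weights=w)))
    if len(x_true) < 3:
        raise InsufficientDataError(
            f"only {len(x_true)} plots with species-level support; need >= 3"
        )
    fit = stats.linregress(x_true, y_filled)
    return {
        "r2": float(fit.rvalue**2),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "p_value": float(fit.pvalue),
        "n_plots": len(x_true),
    }
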