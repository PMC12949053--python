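"""Group-comparison statistics on the species-by-site psi50 table.

Covers the taxonomic variance decomposition (nested ANOVA family/genus/
species with sequential sums of squares), family-level one-way ANOVA with
Tukey HSD and a compact letter display, rank-sum contrasts of Fabaceae vs
non-Fabaceae (overall and within forest types), and the data-driven choice of
normalising transformation (none / sqrt / cbrt of the absolute trait, guided
by Shapiro-Wilk).

The trait table is a tidy DataFrame with columns ``species, genus, family,
order, site, forest_type, psi50`` (psi50 in MPa, strictly negative) plus any
auxiliary trait columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateDataError,
    EmptySubsetError,
    InsufficientDataError,
    InvalidArgumentError,
    SaturatedModelError,
)
from .phylosignal import apply_transformation

__all__ = [
    "AnovaResult",
    "RankTestResult",
    "TransformationChoice",
    "select_nested_subset",
    "nested_anova",
    "family_anova_tukey",
    "wilcoxon_rank_sum",
    "fabaceae_contrast",
    "choose_transformation",
]

REQUIRED_COLUMNS = ("species", "genus", "family", "site", "psi50")


def _check_table(table: pd.DataFrame, extra=()) -> None:
    missing = [c for c in (*REQUIRED_COLUMNS, *extra) if c not in table.columns]
    if missing:
        raise InvalidArgumentError(f"trait table missing columns: {missing}")


@dataclass
class AnovaResult:
    """Sequential ANOVA table plus, for the one-way variant, Tukey output."""

    terms: pd.DataFrame  # index = term name; columns: ss, df, F, p
    residual_ss: float
    residual_df: int
    transformation: str = "none"
    tukey: pd.DataFrame | None = None  # pairwise: group1, group2, meandiff, p_adj
    letters: dict[str, str] | None = None  # compact letter display
    group_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_ss(self) -> float:
        return float(self.terms["ss"].sum() + self.residual_ss)


@dataclass
class RankTestResult:
    """Two-sample rank-sum test in the W (rank-sum minus minimum) convention."""

    w: float
    p_value: float
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    method: str  # 'exact' or 'normal-approx'


@dataclass
class TransformationChoice:
    transformation: str
    shapiro: dict[str, tuple[float, float]]  # transform -> (W, p)
    threshold: float

    @property
    def trace(self) -> str:
        steps = ", ".join(
            f"{t}: W={w:.4f} p={p:.4g}" for t, (w, p) in self.shapiro.items()
        )
        return f"candidates [{steps}] -> chose {self.transformation!r}"


# ---------------------------------------------------------------------------
# replication subset for the nested ANOVA


def select_nested_subset(table: pd.DataFrame) -> pd.DataFrame:
    """Keep only taxa with enough replication for the nested ANOVA.

    A genus qualifies when it has more than one species or its records span
    more than one site; a family qualifies when it contains at least two
    qualifying genera or its records span more than one site. Records are
    kept when both their genus and family qualify.
    """
    _check_table(table)
    g = table.groupby("genus")
    genus_ok = set(
        g.filter(
            lambda d: d["species"].nunique() > 1 or d["site"].nunique() > 1
        )["genus"]
    )
    fam_site = table.groupby("family")["site"].nunique()
    fam_genus_ok = (
        table[table["genus"].isin(genus_ok)].groupby("family")["genus"].nunique()
    )
    family_ok = set(fam_site[fam_site > 1].index) | set(
        fam_genus_ok[fam_genus_ok >= 2].index
    )
    out = table[table["genus"].isin(genus_ok) & table["family"].isin(family_ok)]
    if out.empty:
        raise EmptySubsetError("replication filter removed every record")
    return out.reset_index(drop=True)


def nested_anova(table: pd.DataFrame, transformation: str = "sqrt") -> AnovaResult:
    """Sequential (Type-I) nested ANOVA: family, genus in family, species in genus.

    The response is the transformed absolute psi50. Each term's F uses the
    residual mean square as denominator, the convention whose degrees of
    freedom match a family term with (number of families - 1) df.
    """
    _check_table(table)
    if table["family"].nunique() < 2:
        raise InsufficientDataError("need >= 2 families for the nested ANOVA")
    bad = table.groupby("genus")["family"].nunique()
    if (bad > 1).any():
        raise InvalidArgumentError(
            f"taxonomy inconsistent: genera in multiple families: "
            f"{bad[bad > 1].index.tolist()}"
        )
    df = table.copy()
    df["y"] = apply_transformation(df["psi50"].to_numpy(), transformation)
    # Because taxonomy is strictly nested (species in genus in family), each
    # successive model in the Type-I chain is a plain group-mean model, and
    # its residual SS is the within-group SS at that level.
    df["_sp"] = df["family"].astype(str) + "/" + df["genus"].astype(str) + "/" + df[
        "species"
    ].astype(str)
    df["_gen"] = df["family"].astype(str) + "/" + df["genus"].astype(str)

    def _within_ss(col):
        return float(
            df.groupby(col)["y"].transform("mean").rsub(df["y"]).pow(2).sum()
        )

    rss0 = float(((df["y"] - df["y"].mean()) ** 2).sum())
    rss_fam = _within_ss("family")
    rss_gen = _within_ss("_gen")
    rss_sp = _within_ss("_sp")
    n = len(df)
    n_fam = df["family"].nunique()
    n_gen = df["_gen"].nunique()
    n_sp = df["_sp"].nunique()
    resid_df = n - n_sp
    if resid_df <= 0:
        raise SaturatedModelError("no residual degrees of freedom")
    resid_ms = rss_sp / resid_df
    rows = []
    for name, ss, dfree in (
        ("family", rss0 - rss_fam, n_fam - 1),
        ("genus_in_family", rss_fam - rss_gen, n_gen - n_fam),
        ("species_in_genus", rss_gen - rss_sp, n_sp - n_gen),
    ):
        if dfree <= 0:
            rows.append({"ss": max(ss, 0.0), "df": dfree, "F": np.nan, "p": np.nan})
            continue
        f = (ss / dfree) / resid_ms if resid_ms > 0 else np.inf
        rows.append(
            {"ss": max(ss, 0.0), "df": dfree, "F": f,
             "p": float(stats.f.sf(f, dfree, resid_df))}
        )
    terms = pd.DataFrame(
        rows, index=["family", "genus_in_family", "species_in_genus"]
    )
    return AnovaResult(
        terms=terms,
        residual_ss=rss_sp,
        residual_df=resid_df,
        transformation=transformation,
        group_counts={
            "families": int(df["family"].nunique()),
            "genera": int(df["genus"].nunique()),
            "species": int(df["species"].nunique()),
        },
    )


# ---------------------------------------------------------------------------
# family-level one-way ANOVA + Tukey HSD


def _compact_letter_display(groups: list[str], distinct: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different; ``distinct``
    holds unordered pairs that must not share any letter.
    """
    letter_sets: list[set[str]] = [set(groups)]
    for a, b in distinct:
        new_sets = []
        for s in letter_sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb subsets
        letter_sets = []
        for s in sorted(new_sets, key=len, reverse=True):
            if not any(s <= t for t in letter_sets):
                letter_sets.append(s)
    letter_sets.sort(key=lambda s: min(groups.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for i, s in enumerate(letter_sets):
        for g in groups:
            if g in s:
                out[g] += alphabet[i % len(alphabet)]
    return out


def family_anova_tukey(
    table: pd.DataFrame,
    min_sites: int = 3,
    transformation: str = "none",
    alpha: float = 0.05,
) -> AnovaResult:
    """One-way ANOVA across widely occurring families with Tukey HSD.

    Families occurring in fewer than ``min_sites`` distinct sites are dropped
    before testing (the wide-occurrence filter). All family pairs are compared
    with the studentized-range (Tukey HSD) correction and summarised as a
    compact letter display at ``alpha``.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    _check_table(table)
    sites = table.groupby("family")["site"].nunique()
    keep = set(sites[sites >= min_sites].index)
    sub = table[table["family"].isin(keep)]
    if sub["family"].nunique() < 2:
        raise InsufficientDataError(
            f"fewer than 2 families occur in >= {min_sites} sites"
        )
    y = apply_transformation(sub["psi50"].to_numpy(), transformation)
    fam = sub["family"].to_numpy()
    groups = sorted(set(fam))
    samples = [y[fam == g] for g in groups]
    if any(len(s) < 2 for s in samples) or np.ptp(y) == 0:
        raise DegenerateDataError("a family has < 2 records or data are constant")
    # sequential one-way decomposition
    grand = y.mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b = len(groups) - 1
    df_w = len(y) - len(groups)
    if df_w <= 0:
        raise SaturatedModelError("no residual degrees of freedom")
    f_stat = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f_stat, df_b, df_w))
    terms = pd.DataFrame(
        {"ss": [ss_between], "df": [df_b], "F": [f_stat], "p": [p]},
        index=["family"],
    )
    hsd = pairwise_tukeyhsd(y, fam, alpha=alpha)
    tukey = pd.DataFrame(
        hsd.summary().data[1:], columns=[c.strip() for c in hsd.summary().data[0]]
    )
    tukey = tukey.rename(columns={"p-adj": "p_adj"})
    distinct = {
        tuple(sorted((str(r["group1"]), str(r["group2"]))))
        for _, r in tukey.iterrows()
        if bool(r["reject"])
    }
    letters = _compact_letter_display(groups, distinct)
    return AnovaResult(
        terms=terms,
        residual_ss=float(ss_within),
        residual_df=df_w,
        transformation=transformation,
        tukey=tukey,
        letters=letters,
        group_counts={g: int((fam == g).sum()) for g in groups},
    )


# ---------------------------------------------------------------------------
# rank-sum tests


def wilcoxon_rank_sum(group_a, group_b, exact_limit: int = 400) -> RankTestResult:
    """Two-sided two-sample rank-sum test.

    The statistic is ``W = rank-sum(group_a) - n_a (n_a + 1) / 2`` with
    midranks for ties (the Mann-Whitney U of the first group, the convention
    in which R reports W). The p-value is exact (enumeration) when there are
    no ties and ``n_a * n_b <= exact_limit``, otherwise a normal approximation
    with tie-corrected variance and a 0.5 continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidArgumentError("both groups must be non-empty")
    n_a, n_b = len(a), len(b)
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    w = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)
    has_ties = len(np.unique(combined)) < len(combined)
    if not has_ties and n_a * n_b <= exact_limit:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        p = float(res.pvalue)
        method = "exact"
    else:
        mu = n_a * n_b / 2.0
        n = n_a + n_b
        _, counts = np.unique(combined, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
        var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (w - mu - 0.5 * np.sign(w - mu)) / np.sqrt(var)
            p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
        method = "normal-approx"
    return RankTestResult(
        w=w,
        p_value=p,
        n_a=n_a,
        n_b=n_b,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)) if n_a > 1 else 0.0,
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)) if n_b > 1 else 0.0,
        method=method,
    )


def fabaceae_contrast(
    table: pd.DataFrame,
    forest_type: str | None = None,
    family: str = "Fabaceae",
) -> RankTestResult:
    """Rank-sum contrast of one family (first group) against all others.

    Operates on species-site psi50 records on the original MPa scale,
    optionally restricted to one forest type; group means and SDs are
    reported in MPa.
    """
    _check_table(table)
    sub = table
    if forest_type is not None:
        if "forest_type" not in table.columns:
            raise InvalidArgumentError("table has no forest_type column")
        sub = table[table["forest_type"] == forest_type]
    a = sub.loc[sub["family"] == family, "psi50"].to_numpy()
    b = sub.loc[sub["family"] != family, "psi50"].to_numpy()
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError(
            f"empty partition for family={family!r}, forest_type={forest_type!r}"
        )
    return wilcoxon_rank_sum(a, b)


# ---------------------------------------------------------------------------
# transformation choice


def choose_transformation(
    values, threshold: float = 0.05
) -> TransformationChoice:
    """Pick the mildest transform that normalises ``abs(values)``.

    Tries none, sqrt, cbrt in that order on the absolute values, running
    Shapiro-Wilk on each; returns the first whose p-value reaches
    ``threshold``, else the one with the largest p-value. The cube root is
    the escalation used when a square root cannot tame the right skew.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("need at least 3 values")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant values; normality undefined")
    report: dict[str, tuple[float, float]] = {}
    for t in ("none", "sqrt", "cbrt"):
        y = apply_transformation(np.abs(x), t)
        stat_w, p = stats.shapiro(y)
        report[t] = (float(stat_w), float(p))
        if p >= threshold:
            return TransformationChoice(t, report, threshold)
    best = max(report, key=lambda t: report[t][1])
    return TransformationChoice(best, report, threshold)
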