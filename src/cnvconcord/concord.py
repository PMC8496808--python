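"""Inter-species / inter-platform log2 hit ratios, platform call sets,
their correlations and intersections, and the group-difference tests.

Orientation convention: every inter-species ratio is species-A over
species-B; positive values are species-A-biased. Inter-platform ratios
are long-read over short-read within one species; positive values are
long-read-biased (the signature of a family collapsed in the short-read
assembly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .arraynorm import CallThreshold
from .exceptions import DataError, InsufficientDataError

PLATFORMS = ("acgh", "longread", "shortread")
PLATFORM_PAIRS = (("acgh", "longread"), ("acgh", "shortread"), ("longread", "shortread"))
#: the seven regions of a three-set Venn over (acgh, longread, shortread)
VENN_REGIONS = (
    "acgh_only",
    "longread_only",
    "shortread_only",
    "acgh_longread",
    "acgh_shortread",
    "longread_shortread",
    "all",
)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    t: float
    df: int
    p: float

    def as_dict(self) -> dict:
        return {"r": self.r, "t": self.t, "df": self.df, "p": self.p}


def interspecies_hit_ratio(table: pd.DataFrame, platform: str) -> pd.Series:
    """log2(species-A count / species-B count) within one platform."""
    col_a, col_b = {"longread": ("a_long", "b_long"), "shortread": ("a_short", "b_short")}[
        platform
    ]
    if (table[col_a] < 1).any() or (table[col_b] < 1).any():
        raise DataError("zero hit count reached ratio stage; apply filter_universal first")
    return pd.Series(
        np.log2(table[col_a] / table[col_b]), index=table.index, name=f"hit_{platform}"
    )


def interplatform_hit_ratio(table: pd.DataFrame, species: str) -> pd.Series:
    """log2(long-read count / short-read count) within one species."""
    col_l, col_s = {"a": ("a_long", "a_short"), "b": ("b_long", "b_short")}[species]
    if (table[col_l] < 1).any() or (table[col_s] < 1).any():
        raise DataError("zero hit count reached ratio stage; apply filter_universal first")
    return pd.Series(
        np.log2(table[col_l] / table[col_s]),
        index=table.index,
        name=f"interplatform_{species}",
    )


def build_ratio_table(hit_table: pd.DataFrame, acgh: pd.Series) -> pd.DataFrame:
    """Combine aggregated aCGH ratios with the four hit ratios.

    Restricted to probes present in both inputs (the universal hit set).
    Columns: acgh, hit_longread, hit_shortread, interplatform_a,
    interplatform_b.
    """
    common = hit_table.index.intersection(acgh.index)
    sub = hit_table.loc[common]
    return pd.DataFrame(
        {
            "acgh": acgh.loc[common],
            "hit_longread": interspecies_hit_ratio(sub, "longread"),
            "hit_shortread": interspecies_hit_ratio(sub, "shortread"),
            "interplatform_a": interplatform_hit_ratio(sub, "a"),
            "interplatform_b": interplatform_hit_ratio(sub, "b"),
        }
    )


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with t statistic and two-sided p on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise InsufficientDataError("need at least 3 observations for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataError("correlation undefined: zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        t = float(np.sign(r) * np.inf)
        p = 0.0
    else:
        t = float(r * np.sqrt(df / (1.0 - r * r)))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationResult(r=r, t=t, df=df, p=p)


def _ratio_column(platform: str) -> str:
    return "acgh" if platform == "acgh" else f"hit_{platform}"


def _neutral_mask(ratio_table: pd.DataFrame, platform: str, threshold: float) -> pd.Series:
    col = _ratio_column(platform)
    if platform == "acgh":
        return ratio_table[col].abs() <= threshold
    return ratio_table[col] == 0  # integer-count ratios: 0 is the only neutral value


def concordance_matrix(
    ratio_table: pd.DataFrame,
    mode: str = "all_multicopy",
    threshold: CallThreshold | float = CallThreshold(),
) -> dict[tuple[str, str], CorrelationResult]:
    """All three platform-pair correlations of inter-species ratios.

    ``mode="nonneutral_pair"`` drops, per pair, the probes neutral in
    both plotted platforms (aCGH neutral: |ratio| <= threshold; hit
    platforms: ratio exactly 0) before correlating.
    """
    if mode not in ("all_multicopy", "nonneutral_pair"):
        raise DataError(f"unknown mode {mode!r}")
    mag = threshold.magnitude if isinstance(threshold, CallThreshold) else float(threshold)
    out = {}
    for p1, p2 in PLATFORM_PAIRS:
        sub = ratio_table
        if mode == "nonneutral_pair":
            keep = ~(_neutral_mask(sub, p1, mag) & _neutral_mask(sub, p2, mag))
            sub = sub[keep]
        if len(sub) < 3:
            raise InsufficientDataError(f"fewer than 3 probes left for pair {(p1, p2)}")
        out[(p1, p2)] = pearson(sub[_ratio_column(p1)], sub[_ratio_column(p2)])
    return out


def build_call_sets(
    ratio_table: pd.DataFrame, threshold: CallThreshold | float = CallThreshold()
) -> dict[str, dict[str, set]]:
    """Species-biased probe sets per platform.

    Hit platforms: species-A-biased where the inter-species hit ratio is
    > 0, species-B-biased where < 0. aCGH: biased only beyond the
    +/-threshold near-neutral filter.
    """
    mag = threshold.magnitude if isinstance(threshold, CallThreshold) else float(threshold)
    sets: dict[str, dict[str, set]] = {}
    for platform in PLATFORMS:
        col = ratio_table[_ratio_column(platform)]
        cut = mag if platform == "acgh" else 0.0
        sets[platform] = {
            "a": set(col.index[col > cut]),
            "b": set(col.index[col < -cut]),
        }
    return sets


def _venn_counts(a: set, l: set, s: set) -> dict[str, int]:
    return {
        "acgh_only": len(a - l - s),
        "longread_only": len(l - a - s),
        "shortread_only": len(s - a - l),
        "acgh_longread": len((a & l) - s),
        "acgh_shortread": len((a & s) - l),
        "longread_shortread": len((l & s) - a),
        "all": len(a & l & s),
    }


def venn_sets(call_sets: dict, direction: str) -> dict[str, set]:
    """Membership sets of the seven Venn regions for one bias direction."""
    a = call_sets["acgh"][direction]
    l = call_sets["longread"][direction]
    s = call_sets["shortread"][direction]
    return {
        "acgh_only": a - l - s,
        "longread_only": l - a - s,
        "shortread_only": s - a - l,
        "acgh_longread": (a & l) - s,
        "acgh_shortread": (a & s) - l,
        "longread_shortread": (l & s) - a,
        "all": a & l & s,
    }


def intersect_sets(
    call_sets: dict,
    genic_ids: set | None = None,
    probe_to_gene: dict | None = None,
) -> dict:
    """Euler region counts per bias direction.

    Always reports all-probe counts; with ``genic_ids`` adds genic-only
    probe counts, and with ``probe_to_gene`` adds gene-level counts
    (gene biased iff >= 1 of its probes is).
    """
    out: dict = {}
    for direction in ("a", "b"):
        a = call_sets["acgh"][direction]
        l = call_sets["longread"][direction]
        s = call_sets["shortread"][direction]
        entry = {"probes": _venn_counts(a, l, s)}
        if genic_ids is not None:
            entry["genic_probes"] = _venn_counts(a & genic_ids, l & genic_ids, s & genic_ids)
        if probe_to_gene is not None:
            gsets = gene_calls(call_sets, probe_to_gene)
            entry["genes"] = _venn_counts(
                gsets["acgh"][direction], gsets["longread"][direction], gsets["shortread"][direction]
            )
        out[direction] = entry
    return out


def gene_calls(call_sets: dict, probe_to_gene: dict) -> dict[str, dict[str, set]]:
    """Lift probe call sets to genes: a gene is called for a platform and
    direction iff at least one of its probes is; intergenic probes (not
    in the map, or mapped to "") never contribute."""
    for probe, gene in probe_to_gene.items():
        if isinstance(gene, (list, tuple, set)):
            raise DataError(f"probe {probe!r} mapped to more than one gene")
    out: dict[str, dict[str, set]] = {}
    for platform, dirs in call_sets.items():
        out[platform] = {}
        for direction, probes in dirs.items():
            out[platform][direction] = {
                probe_to_gene[p] for p in probes if probe_to_gene.get(p)
            }
    return out


def kruskal_wallis(groups: list) -> tuple[float, int, float]:
    """Rank-based Kruskal-Wallis H with tie correction; chi-square p on k-1 df.

    Degenerate all-identical data returns (0, k-1, 1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise InsufficientDataError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, len(groups) - 1, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), len(groups) - 1, float(p)


def anova_tukey(values_by_group: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA plus all-pairs Tukey HSD (Tukey-Kramer for unequal n).

    Returns {"F", "p", "df_between", "df_within", "tukey": DataFrame with
    group1, group2, meandiff, p_adj}. Degenerate zero-variance input
    yields F = 0 and all adjusted p = 1.
    """
    names = list(values_by_group)
    groups = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise InsufficientDataError("need >= 2 groups with >= 2 members each")
    pooled = np.concatenate(groups)
    k, n = len(groups), len(pooled)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    if np.all(pooled == pooled[0]):
        tukey = pd.DataFrame(
            [
                {"group1": names[i], "group2": names[j], "meandiff": 0.0, "p_adj": 1.0}
                for i, j in pairs
            ]
        )
        return {"F": 0.0, "p": 1.0, "df_between": k - 1, "df_within": n - k, "tukey": tukey}
    f, p = stats.f_oneway(*groups)
    res = stats.tukey_hsd(*groups)
    rows = []
    for i, j in pairs:
        rows.append(
            {
                "group1": names[i],
                "group2": names[j],
                "meandiff": float(groups[i].mean() - groups[j].mean()),
                "p_adj": float(res.pvalue[i, j]),
            }
        )
    return {
        "F": float(f),
        "p": float(p),
        "df_between": k - 1,
        "df_within": n - k,
        "tukey": pd.DataFrame(rows),
    }
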