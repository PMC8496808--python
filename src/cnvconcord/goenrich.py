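"""Fisher-exact GO term enrichment with Benjamini-Hochberg FDR.

For each term the 2x2 table is (term in gene, term not in gene) x
(test set, background minus test); the default test is one-sided
over-representation (hypergeometric upper tail). Genes with no
annotation stay in the denominators unless ``annotated_only`` is set.
The annotation map is flat (no GO-graph propagation); pre-propagated
maps are accepted as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DataError, InsufficientDataError

logger = logging.getLogger(__name__)


def enrich(
    test_genes,
    background_genes,
    annotation: pd.DataFrame,
    fdr_cutoff: float = 0.05,
    two_sided: bool = False,
    annotated_only: bool = False,
) -> pd.DataFrame:
    """Per-term enrichment of ``test_genes`` against ``background_genes``.

    ``annotation`` has columns gene_id, term_id, term_name, category.
    Returns one row per term with n_test, n_rest, pct_test, pct_bg, p,
    fdr and a significance flag at ``fdr_cutoff``, sorted by p.
    """
    test = set(test_genes)
    background = set(background_genes)
    if not test <= background:
        raise DataError("test set must be a subset of the background set")
    if not test:
        raise InsufficientDataError("empty test set")
    ann = annotation[annotation["gene_id"].isin(background)]
    if annotated_only:
        annotated = set(ann["gene_id"])
        test = test & annotated
        background = background & annotated
        if not test:
            raise InsufficientDataError("no annotated genes in the test set")
    rest = background - test
    n_test, n_rest = len(test), len(rest)
    M = n_test + n_rest

    rows = []
    for (term_id, term_name, category), sub in ann.groupby(
        ["term_id", "term_name", "category"], sort=True
    ):
        carriers = set(sub["gene_id"])
        a = len(carriers & test)
        k_rest = len(carriers & rest)
        K = a + k_rest
        if two_sided:
            table = [[a, n_test - a], [k_rest, n_rest - k_rest]]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        else:
            p = float(stats.hypergeom.sf(a - 1, M, K, n_test))
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "category": category,
                "n_test": a,
                "n_rest": k_rest,
                "pct_test": 100.0 * a / n_test,
                "pct_bg": 100.0 * k_rest / n_rest if n_rest else 0.0,
                "p": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "category", "n_test", "n_rest", "pct_test", "pct_bg", "p"],
    )
    if len(out):
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["fdr"] < fdr_cutoff
        out = out.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
    else:
        out["fdr"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


@dataclass(frozen=True)
class Contrast:
    name: str
    test: frozenset
    background: frozenset


def build_contrasts(
    gene_call_sets_by_species: dict[str, dict[str, set]],
    all_genes,
) -> list[Contrast]:
    """Enumerate the enrichment contrasts over platform combinations.

    For each species (bias direction): the seven Venn regions of the
    three platform gene sets, each against the union of that species'
    detected gains; plus the union of all gains from any platform or
    species against all annotated genes. Empty test sets are skipped
    with a log notice.
    """
    all_genes = set(all_genes)
    contrasts: list[Contrast] = []
    union_all: set = set()
    for species, platform_sets in gene_call_sets_by_species.items():
        sets = {p: set(platform_sets[p]) for p in platform_sets}
        union = set().union(*sets.values())
        union_all |= union
        region_defs = _venn_region_sets(sets)
        for region, members in region_defs.items():
            if not members:
                logger.info("skipping empty contrast %s/%s", species, region)
                continue
            contrasts.append(
                Contrast(f"{species}:{region}", frozenset(members), frozenset(union))
            )
    if union_all:
        contrasts.append(
            Contrast("all_gains_vs_annotation", frozenset(union_all), frozenset(all_genes))
        )
    else:
        logger.info("skipping empty contrast all_gains_vs_annotation")
    return contrasts


def _venn_region_sets(sets: dict[str, set]) -> dict[str, set]:
    names = list(sets)
    if len(names) != 3:
        raise DataError("expected exactly three platform sets")
    a, b, c = (sets[n] for n in names)
    return {
        f"{names[0]}_only": a - b - c,
        f"{names[1]}_only": b - a - c,
        f"{names[2]}_only": c - a - b,
        f"{names[0]}_{names[1]}": (a & b) - c,
        f"{names[0]}_{names[2]}": (a & c) - b,
        f"{names[1]}_{names[2]}": (b & c) - a,
        "all": a & b & c,
    }


def run_contrasts(
    contrasts: list[Contrast],
    annotation: pd.DataFrame,
    fdr_cutoff: float = 0.05,
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """Run :func:`enrich` for every contrast; returns name -> result table."""
    return {
        c.name: enrich(c.test, c.background, annotation, fdr_cutoff=fdr_cutoff, **kwargs)
        for c in contrasts
    }
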