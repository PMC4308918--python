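"""Target-set term enrichment and group-level Fisher aggregation.

Each miRNA's predicted target genes are tested for term over-representation
(one-sided hypergeometric; a pluggable stand-in for model-based enrichment
methods — externally computed per-miRNA enrichment flags are accepted
through the same interface).  To ask whether a *category* of miRNAs (e.g.
those up-regulated in tumors) collectively enriches a term, a two-sided
Fisher exact test compares the in-category vs out-of-category counts of
miRNAs enriching the term, BH-corrected across terms (significant at
q < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .diffexp import bh_adjust


@dataclass
class TermEnrichment:
    term_id: str
    mirna_id: str
    n_targets_in_term: int
    n_targets: int
    n_universe_in_term: int
    n_universe: int
    p_value: float
    enriched: bool
    term_name: str = ""


@dataclass
class GroupTermTest:
    term_id: str
    category: str
    a: int  # in category, term enriched
    b: int  # in category, not enriched
    c: int  # out of category, enriched
    d: int  # out of category, not enriched
    p_value: float
    q_value: float = float("nan")


def term_enrich(
    target_genes: set[str],
    term_sets: dict[str, set[str]],
    universe: set[str],
    mirna_id: str = "",
    p_max: float = 0.05,
    bh: bool = False,
    term_names: dict[str, str] | None = None,
) -> list[TermEnrichment]:
    """One-sided hypergeometric over-representation per term.

    Term gene sets are intersected with the universe; p is the upper-tail
    probability of drawing at least the observed overlap when sampling
    ``len(targets)`` genes without replacement.
    """
    if not universe:
        raise ValueError("empty universe")
    extra = target_genes - universe
    if extra:
        raise ValueError(f"target genes outside universe: {sorted(extra)[:5]}")
    n_universe = len(universe)
    n_targets = len(target_genes)
    results = []
    for term_id, genes in term_sets.items():
        in_univ = genes & universe
        overlap = len(target_genes & in_univ)
        # P(X >= overlap), X ~ Hypergeom(N=n_universe, K=len(in_univ), n=n_targets)
        p = float(stats.hypergeom.sf(overlap - 1, n_universe, len(in_univ), n_targets))
        results.append(
            TermEnrichment(
                term_id=term_id,
                mirna_id=mirna_id,
                n_targets_in_term=overlap,
                n_targets=n_targets,
                n_universe_in_term=len(in_univ),
                n_universe=n_universe,
                p_value=min(p, 1.0),
                enriched=False,
                term_name=(term_names or {}).get(term_id, ""),
            )
        )
    if bh:
        q = bh_adjust([r.p_value for r in results])
        for r, qv in zip(results, q):
            r.enriched = qv < p_max
    else:
        for r in results:
            r.enriched = r.p_value < p_max
    return results


def fisher_group_term(
    enrichment_flags: pd.Series,
    category_flags: pd.Series,
    term_id: str = "",
    category: str = "",
) -> GroupTermTest:
    """Two-sided Fisher exact test on the 2x2 table of
    (miRNA in category) x (miRNA enriches the term)."""
    enr = enrichment_flags.astype(bool)
    cat = category_flags.loc[enr.index].astype(bool)
    if cat.all() or (~cat).all():
        raise ValueError("need miRNAs both in and out of the category")
    a = int((cat & enr).sum())
    b = int((cat & ~enr).sum())
    c = int((~cat & enr).sum())
    d = int((~cat & ~enr).sum())
    _odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return GroupTermTest(term_id=term_id, category=category, a=a, b=b, c=c, d=d, p_value=float(p))


def group_term_tests(
    enrichment_by_term: pd.DataFrame,
    category_flags: pd.Series,
    category: str = "",
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Fisher aggregation for every term, BH-corrected across terms.

    ``enrichment_by_term`` is a boolean miRNA x term matrix of per-miRNA
    enrichment flags.  Returns one row per term with the 2x2 counts, p, q and
    the q < q_max significance call.
    """
    rows = []
    for term_id in enrichment_by_term.columns:
        t = fisher_group_term(
            enrichment_by_term[term_id], category_flags, term_id=term_id, category=category
        )
        rows.append(t)
    df = pd.DataFrame(
        {
            "term_id": [t.term_id for t in rows],
            "category": category,
            "a": [t.a for t in rows],
            "b": [t.b for t in rows],
            "c": [t.c for t in rows],
            "d": [t.d for t in rows],
            "p_value": [t.p_value for t in rows],
        }
    )
    df["q_value"] = bh_adjust(df["p_value"].to_numpy()) if len(df) else []
    df["significant"] = df["q_value"] < q_max
    return df


def read_gmt(path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read GMT-style term sets: term_id <tab> term_name <tab> gene1 <tab> ..."""
    term_sets: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            term_sets[parts[0]] = {g for g in parts[2:] if g}
            term_names[parts[0]] = parts[1]
    return term_sets, term_names
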