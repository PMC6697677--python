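"""Flat gene-set enrichment of network mRNAs against an array background.

Over-representation is scored per annotation term by fold enrichment,
(k/n) / (K/N) for k query hits among n query genes against K term members in
a background of N, with a one-sided exact hypergeometric (Fisher) p-value or
an optional Pearson chi-square.  Terms with zero query hits are omitted from
the emitted family (and hence from the BH FDR), matching common annotation
servers.  Top terms are ranked within each namespace by descending fold
enrichment among terms with p < 0.05 and FDR < 0.05.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

NAMESPACES = ("BP", "MF", "CC", "pathway")

RESULT_COLUMNS = [
    "term_id", "term_name", "namespace", "k", "n", "K", "N",
    "fold_enrichment", "p_value", "fdr",
]


@dataclasses.dataclass(frozen=True)
class AnnotationTerm:
    term_id: str
    term_name: str
    namespace: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"term {self.term_id!r} has no members")
        if self.namespace not in NAMESPACES:
            raise ValueError(f"namespace {self.namespace!r} not in {NAMESPACES}")


@dataclasses.dataclass(frozen=True)
class AnnotationCollection:
    terms: tuple[AnnotationTerm, ...]

    def __post_init__(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate term ids")

    def __len__(self) -> int:
        return len(self.terms)


def read_gmt(path: str | Path) -> AnnotationCollection:
    """Read a GMT file (term_id <TAB> namespace <TAB> member ids...).

    The GMT description column is used to carry the namespace; values outside
    {BP, MF, CC, pathway} fall back to ``pathway`` with a logged note.
    """
    terms = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has fewer than 3 fields")
            term_id, desc = fields[0], fields[1]
            ns = desc if desc in NAMESPACES else "pathway"
            if ns != desc:
                logger.info("%s: line %d namespace %r -> 'pathway'", path, lineno, desc)
            members = frozenset(f for f in fields[2:] if f)
            terms.append(AnnotationTerm(term_id, term_id, ns, members))
    return AnnotationCollection(tuple(terms))


def write_gmt(collection: AnnotationCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in collection.terms:
            fh.write("\t".join([t.term_id, t.namespace, *sorted(t.members)]) + "\n")


def enrich(
    query_mrnas,
    collection: AnnotationCollection,
    background,
    method: str = "fisher",
) -> pd.DataFrame:
    """Score every annotation term with >= 1 query hit.

    ``query_mrnas`` must be a subset of ``background``; term members outside
    the background are not counted.  Fisher p-values are one-sided
    over-representation tails of the hypergeometric distribution; ``chisq``
    uses Pearson's chi-square on the 2x2 hit table.  BH FDR is computed over
    the emitted terms only.
    """
    if method not in ("fisher", "chisq"):
        raise ValueError("method must be 'fisher' or 'chisq'")
    background = set(background)
    query = set(query_mrnas)
    offenders = query - background
    if offenders:
        raise ValueError(f"query ids not in background: {sorted(offenders)[:10]}")
    n = len(query)
    N = len(background)
    rows = []
    n_zero = 0
    for term in collection.terms:
        members = term.members & background
        K = len(members)
        k = len(query & members)
        if k == 0:
            n_zero += 1
            continue
        fold = (k / n) / (K / N) if n and K else 0.0
        if method == "fisher":
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        else:
            table = np.array([[k, n - k], [K - k, N - K - (n - k)]], dtype=float)
            if table.min() < 0 or 0 in table.sum(axis=0) or 0 in table.sum(axis=1):
                p = 1.0
            else:
                p = float(stats.chi2_contingency(table, correction=False)[1])
        rows.append(
            {
                "term_id": term.term_id,
                "term_name": term.term_name,
                "namespace": term.namespace,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "fold_enrichment": fold,
                "p_value": p,
            }
        )
    if n_zero:
        logger.info("enrich: %d terms with zero query hits omitted", n_zero)
    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out[RESULT_COLUMNS].sort_values(
        ["namespace", "p_value", "term_id"], ignore_index=True
    )


def top_terms(
    results: pd.DataFrame,
    per_namespace: int = 5,
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Top terms per namespace by descending fold enrichment.

    Only terms significant at both thresholds are ranked; ties in fold
    enrichment break by ascending p, then term id.  Namespaces with fewer
    than ``per_namespace`` significant terms return what they have.
    """
    if results.empty:
        return results.copy()
    sig = results[(results["p_value"] < p_threshold) & (results["fdr"] < fdr_threshold)]
    ranked = sig.sort_values(
        ["namespace", "fold_enrichment", "p_value", "term_id"],
        ascending=[True, False, True, True],
    )
    return ranked.groupby("namespace", group_keys=False).head(per_namespace).reset_index(drop=True)
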