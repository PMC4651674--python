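"""Singular enrichment analysis of a protein list against a background.

For each GO term the over-representation of the query list in the
background is scored by the one-sided hypergeometric upper tail
(equivalently a one-sided Fisher exact test), with Benjamini–Hochberg
control across the tested terms.  Annotations are assumed already
propagated to ancestor terms by the provider; no GO-DAG traversal is
performed here, so an un-propagated annotation file will understate
high-level terms.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GOAnnotation

DEFAULT_MIN_TERM_SIZE = 5


def enrich(
    query_ids: Iterable[str],
    annotations: Sequence[GOAnnotation],
    background_ids: Iterable[str],
    min_term_size: int = DEFAULT_MIN_TERM_SIZE,
    include_unannotated: bool = False,
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``query_ids`` within ``background_ids``.

    The background population defaults to the annotated accessions of the
    supplied background (unannotated proteins carry no information for
    any term and would dilute every test); ``include_unannotated=True``
    keeps them in the population size.  Terms with fewer than
    ``min_term_size`` background hits are not tested.

    Returns a DataFrame sorted by ascending p with the columns
    ``term_id``, ``ontology``, ``description``, ``n_input``,
    ``n_background``, ``p_value``, ``fdr``.
    """
    query = set(query_ids)
    background = set(background_ids)
    stray = sorted(query - background)
    if stray:
        raise ValueError(f"query id(s) not in background: {stray[:10]}")

    term_hits: dict[str, set[str]] = {}
    term_meta: dict[str, tuple[str, str]] = {}
    annotated: set[str] = set()
    for ann in annotations:
        if ann.accession not in background:
            continue
        annotated.add(ann.accession)
        term_hits.setdefault(ann.term_id, set()).add(ann.accession)
        term_meta.setdefault(ann.term_id, (ann.ontology, ann.description))

    if include_unannotated:
        population = background
    else:
        population = annotated
    N = len(population)
    effective_query = query & population
    n = len(effective_query)

    rows = []
    for term, hits in term_hits.items():
        K = len(hits)
        if K < min_term_size:
            continue
        k = len(hits & effective_query)
        # P(X >= k) drawing n from N with K successes
        p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        ontology, description = term_meta[term]
        rows.append(
            {
                "term_id": term,
                "ontology": ontology,
                "description": description,
                "n_input": k,
                "n_background": K,
                "p_value": min(p, 1.0),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "term_id", "ontology", "description",
                "n_input", "n_background", "p_value", "fdr",
            ]
        )
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    df = df.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    return df
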