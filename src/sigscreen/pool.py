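"""Marker-pool assembly: merge candidate gene sets from multiple sources
into a single pool with queryable per-gene provenance, and summarize how
the sources overlap.

Pool genes are treated as biologically vetted downstream: the background
SNR filter never removes them (see :mod:`sigscreen.snr`).
"""

from __future__ import annotations

from itertools import combinations

import pandas as pd

from .datatypes import GeneSetCollection


def merge_markers(*collections: GeneSetCollection) -> GeneSetCollection:
    """Merge gene-set collections into one pooled set.

    The pool is the union of all member genes in input order (first
    occurrence wins).  Provenance records every source set each gene came
    from.  Merging is idempotent: merging a merged pool with itself
    returns the same pool and provenance.
    """
    if not collections:
        raise ValueError("need at least one collection")
    if all(len(c) == 0 or not any(c.sets.values()) for c in collections):
        raise ValueError("all collections are empty")
    pooled: dict[str, None] = {}
    provenance: dict[str, list[str]] = {}
    for coll in collections:
        for set_name, members in coll.sets.items():
            for g in members:
                pooled.setdefault(g)
                sources = provenance.setdefault(g, [])
                # carry through existing provenance when merging a merged pool
                gene_sources = coll.provenance.get(g, [set_name])
                for src in gene_sources if set_name == "pool" else [set_name]:
                    if src not in sources:
                        sources.append(src)
    genes = list(pooled)
    return GeneSetCollection(
        sets={"pool": genes},
        descriptions={"pool": "merged marker pool"},
        provenance=provenance,
    )


def overlap_summary(collection: GeneSetCollection) -> pd.DataFrame:
    """Tabulate every non-empty intersection region of the collection.

    Mirrors an UpSet-style decomposition: each row is an exclusive region
    (genes in exactly that combination of sets) with its gene count.
    Region counts sum to the size of the union.
    """
    if len(collection) < 2:
        raise ValueError("overlap summary needs at least 2 sets")
    names = list(collection.sets)
    membership = {
        g: frozenset(n for n in names if g in collection.sets[n])
        for g in collection.all_genes()
    }
    rows = []
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            region = frozenset(combo)
            genes = sorted(g for g, m in membership.items() if m == region)
            if genes:
                rows.append(
                    {
                        "sets": "&".join(combo),
                        "degree": k,
                        "count": len(genes),
                        "genes": ",".join(genes),
                    }
                )
    return pd.DataFrame(rows, columns=["sets", "degree", "count", "genes"])
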