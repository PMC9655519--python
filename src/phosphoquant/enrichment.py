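"""Hypergeometric over-representation analysis against GMT gene sets."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .io import DataError, GeneSetCollection
from .diffstats import bh_adjust


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int  # overlap with the hit list
    set_size: int  # members present in the universe
    n_hits: int
    n_universe: int
    p: float
    q: float
    overlap: tuple[str, ...]


def ora_hypergeometric(
    hits, universe, sets: GeneSetCollection
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test of each gene set against the hit list.

    Identifiers are case-normalized (upper). The universe defaults to the
    quantified features of the comparison, so pass exactly that background;
    hits must be a subset of it.  Set sizes count only members present in
    the universe.  Results carry BH-adjusted q across all sets and come
    sorted by (p, set name).
    """
    uni = {str(g).upper() for g in universe}
    hit = {str(g).upper() for g in hits}
    if not uni:
        raise DataError("empty universe")
    if not hit:
        raise DataError("empty hit list")
    stray = hit - uni
    if stray:
        raise DataError(
            f"{len(stray)} hit genes are not in the universe, e.g. "
            f"{sorted(stray)[:3]}"
        )
    N, n = len(uni), len(hit)
    names, ps, rows = [], [], []
    for name, members in sets:
        mem = {m.upper() for m in members} & uni
        K = len(mem)
        overlap = tuple(sorted(mem & hit))
        k = len(overlap)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        p = min(p, 1.0)
        names.append(name)
        ps.append(p)
        rows.append((name, k, K, overlap))
    qs = bh_adjust(ps)
    results = [
        EnrichmentResult(
            set_name=name, k=k, set_size=K, n_hits=n, n_universe=N,
            p=p, q=float(q), overlap=overlap,
        )
        for (name, k, K, overlap), p, q in zip(rows, ps, qs)
    ]
    results.sort(key=lambda r: (r.p, r.set_name))
    return results


def enrichment_to_tsv(results, path) -> None:
    frame = pd.DataFrame(
        [
            (r.set_name, r.k, r.set_size, r.n_hits, r.n_universe, r.p, r.q,
             ";".join(r.overlap))
            for r in results
        ],
        columns=["set_name", "k", "set_size", "n_hits", "n_universe", "p", "q",
                 "overlap"],
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
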