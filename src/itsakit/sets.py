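"""Fisher's-exact gene-set enrichment and disease-gene interrogation.

Enrichment is the one-sided (over-representation) Fisher exact test on
the 2x2 table of target-list membership against annotation-set
membership within a background universe, with Benjamini-Hochberg
q-values across the tested sets.  The default background is the
quality-filtered protein list of the experiment, not the whole
annotation: the assay can only call what it detects.

Disease interrogation is plain set algebra: union of per-database gene
lists and the Venn partition of called targets against that union.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSetCollection, normalize_symbol

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntersectionResult:
    """Venn partition of two symbol sets."""

    a_only: frozenset[str]
    shared: frozenset[str]
    b_only: frozenset[str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "a_only": len(self.a_only),
            "shared": len(self.shared),
            "b_only": len(self.b_only),
        }


def union_gene_sets(lists: Iterable[Iterable[str]]) -> frozenset[str]:
    """Case-normalized deduplicated union across gene lists."""
    lists = list(lists)
    if not lists:
        raise ValueError("need at least one gene list")
    out: set[str] = set()
    for lst in lists:
        out.update(normalize_symbol(g) for g in lst)
    return frozenset(out)


def intersect_targets(a: Iterable[str], b: Iterable[str]) -> IntersectionResult:
    sa = frozenset(normalize_symbol(g) for g in a)
    sb = frozenset(normalize_symbol(g) for g in b)
    return IntersectionResult(a_only=sa - sb, shared=sa & sb, b_only=sb - sa)


def hypergeom_tail(k, N, K, n):
    """P(X >= k) for X ~ Hypergeometric(N, K, n); vectorized.

    This is the one-sided (greater) Fisher exact p-value of the 2x2
    table (k, n-k; K-k, N-n-K+k).
    """
    k = np.asarray(k)
    return stats.hypergeom.sf(k - 1, np.asarray(N), np.asarray(K), np.asarray(n))


def fisher_enrichment(
    targets: Iterable[str],
    background: Iterable[str],
    collection: GeneSetCollection,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Over-representation of each annotation set among the targets.

    Targets outside the background are dropped (logged); each set's
    members are intersected with the background before testing.  Rows
    with overlap below ``min_overlap`` are skipped.  Columns: set_name,
    k, n, K, N, odds_ratio, p_value, q_value; sorted by p_value.
    """
    bg = frozenset(normalize_symbol(g) for g in background)
    if not bg:
        raise ValueError("background is empty")
    tg = frozenset(normalize_symbol(g) for g in targets)
    outside = tg - bg
    if outside:
        logger.info("dropping %d target symbols outside the background", len(outside))
        tg &= bg
    N, n = len(bg), len(tg)

    rows = []
    for gs in collection:
        members = gs.members & bg
        if not members:
            logger.warning("set %r empty after background intersection; skipped", gs.name)
            continue
        K = len(members)
        k = len(members & tg)
        if k < min_overlap:
            continue
        p = float(hypergeom_tail(k, N, K, n))
        a, b, c, d = k, n - k, K - k, N - n - K + k
        odds = math_inf_safe(a, b, c, d)
        rows.append((gs.name, k, n, K, N, odds, p))

    df = pd.DataFrame(
        rows, columns=["set_name", "k", "n", "K", "N", "odds_ratio", "p_value"]
    )
    if len(df):
        df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values("p_value", kind="stable").reset_index(drop=True)
    else:
        df["q_value"] = pd.Series(dtype=float)
    return df


def math_inf_safe(a: int, b: int, c: int, d: int) -> float:
    """Odds ratio (a*d)/(b*c) with the conventional 0 and +inf limits."""
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)
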