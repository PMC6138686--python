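"""Hypergeometric Index (HyI) scoring of phenotype-locus associations.

For a phenotype node A and a locus node B in one variant-class
subnetwork, let

    N = patients in the subnetwork,
    K = patients annotated with the phenotype (degree of A),
    n = patients at the locus (degree of B),
    k = patients shared by A and B,

and p = P(X >= k) the upper tail of the hypergeometric distribution with
population N, K successes and n draws.  The Hypergeometric Index is

    HyI = -log10(p),

so HyI >= 2.0 corresponds to p <= 0.01, the significance threshold used
throughout.  A widely prevalent phenotype (large K) yields low HyI at
any single locus; a phenotype concentrated in the patients of one locus
scores high — the index rewards specificity.

Auxiliary parameters: *penetrance* = 100*k/n, the share of patients at
the locus expressing the phenotype; *% max* = a pair's HyI as a
percentage of the best HyI that phenotype reaches at any locus of the
subnetwork.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy.stats import hypergeom as _hypergeom

from .network import TripartiteNetwork

#: HyI ceiling absorbing p-value underflow.
HYI_CEILING = 300.0

#: Default significance threshold: HyI >= 2.0, i.e. p <= 0.01.
DEFAULT_THRESHOLD = 2.0

LN10 = math.log(10.0)


@dataclass(frozen=True)
class AssociationScore:
    """Scored phenotype-locus pair with counts and auxiliary parameters."""

    phenotype: str
    locus_id: str
    N: int
    K: int
    n: int
    k: int
    p_value: float
    hyi: float
    penetrance: float
    pct_max: float
    significant: bool
    p_bh: float = float("nan")  # Benjamini-Hochberg adjusted, supplementary


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail probability P(X >= k), X ~ Hypergeom(N, K, n).

    Computed in log space for numerical safety.  Arguments must satisfy
    0 <= k <= min(K, n) and K, n <= N.
    """
    _check_counts(N, K, n, k)
    return float(math.exp(_log_tail(N, K, n, k)))


def _check_counts(N: int, K: int, n: int, k: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(
            f"invalid hypergeometric counts N={N}, K={K}, n={n}, k={k}"
        )


def _log_tail(N: int, K: int, n: int, k: int) -> float:
    if k == 0:
        return 0.0
    return float(_hypergeom.logsf(k - 1, N, K, n))


def hyi(p: float, ceiling: float = HYI_CEILING) -> float:
    """Minus log10 of a probability, capped at ``ceiling``."""
    if not (0.0 < p <= 1.0):
        raise ValueError(f"probability out of (0, 1]: {p}")
    return min(-math.log10(p), ceiling)


def penetrance(k: int, n: int) -> float:
    """Percentage of patients at the locus expressing the phenotype."""
    if n <= 0:
        raise ValueError("locus with no patients")
    if not (1 <= k <= n):
        raise ValueError(f"invalid penetrance counts k={k}, n={n}")
    return 100.0 * k / n


def pct_max(score: float, best: float) -> float:
    """A pair's HyI as a percentage of the phenotype's best HyI."""
    if best <= 0.0:
        raise ValueError("best HyI must be positive")
    if not (0.0 < score <= best):
        raise ValueError(f"score {score} out of (0, {best}]")
    return 100.0 * score / best


def is_significant(p_value: float, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """Significance call: p <= 10^(-threshold) (p <= 0.01 at the default)."""
    return p_value <= 10.0 ** (-threshold)


def score_all(
    net: TripartiteNetwork,
    threshold: float = DEFAULT_THRESHOLD,
    include_k0: bool = False,
) -> list[AssociationScore]:
    """Score every connected phenotype-locus pair of a subnetwork.

    Pairs with no shared patient (k = 0) cannot be significant and are
    skipped unless ``include_k0``.  ``pct_max`` is computed once all loci
    of a phenotype are scored; pairs whose phenotype never reaches a
    positive HyI report pct_max = 100 by convention (their best is 0).
    Ordering is deterministic: phenotype id, then locus position.
    """
    N = net.n_population
    locus_order = sorted(
        net.loci.values(), key=lambda l: (l.interval.chrom, l.interval.start)
    )

    raw: list[tuple[str, str, int, int, int, float, float]] = []
    for term in sorted(net.pheno_edges):
        term_patients = net.pheno_edges[term]
        K = len(term_patients)
        for locus in locus_order:
            n = len(locus.patient_ids)
            k = len(term_patients & locus.patient_ids)
            if k == 0 and not include_k0:
                continue
            logp = _log_tail(N, K, n, k)
            p = max(math.exp(logp), 10.0 ** (-HYI_CEILING))
            h = min(-logp / LN10, HYI_CEILING)
            raw.append((term, locus.locus_id, K, n, k, p, h))

    best: dict[str, float] = {}
    for term, _, _, _, _, _, h in raw:
        best[term] = max(best.get(term, 0.0), h)

    bh = _benjamini_hochberg([r[5] for r in raw])
    scores: list[AssociationScore] = []
    for (term, lid, K, n, k, p, h), q in zip(raw, bh):
        b = best[term]
        scores.append(AssociationScore(
            phenotype=term,
            locus_id=lid,
            N=N, K=K, n=n, k=k,
            p_value=p,
            hyi=h,
            penetrance=100.0 * k / n if n else 0.0,
            pct_max=100.0 * h / b if b > 0.0 else 100.0,
            significant=is_significant(p, threshold),
            p_bh=q,
        ))
    return scores


def _benjamini_hochberg(pvals: Sequence[float]) -> list[float]:
    """BH step-up adjustment; supplementary output, never gates reports."""
    m = len(pvals)
    if m == 0:
        return []
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


def scores_to_frame(
    scores: Sequence[AssociationScore], net: TripartiteNetwork
) -> pd.DataFrame:
    """Flatten scores into the associations table (bit-stable columns)."""
    rows = []
    for s in scores:
        locus = net.loci[s.locus_id]
        rows.append({
            "phenotype_id": s.phenotype,
            "phenotype_name": net.phenotype_names.get(s.phenotype, ""),
            "locus_id": s.locus_id,
            "chrom": locus.interval.chrom,
            "start": locus.interval.start,
            "end": locus.interval.end,
            "N": s.N, "K": s.K, "n": s.n, "k": s.k,
            "p_value": s.p_value,
            "hyi": s.hyi,
            "penetrance": s.penetrance,
            "pct_max": s.pct_max,
            "significant": s.significant,
            "p_bh": s.p_bh,
        })
    columns = ["phenotype_id", "phenotype_name", "locus_id", "chrom", "start",
               "end", "N", "K", "n", "k", "p_value", "hyi", "penetrance",
               "pct_max", "significant", "p_bh"]
    return pd.DataFrame(rows, columns=columns)
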