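"""Paired differential expression and cross-cancer signature selection.

Per cancer, each gene is tested with a two-sided paired t-test on the
within-patient tumor minus normal log2 differences, P-values are adjusted by
Benjamini-Hochberg within the cancer, and fold change is the geometric-mean
ratio ``2**mean(log2 difference)``.  A gene enters the signature when it is
significant with the same direction of change in at least ``min_cancers``
cancer types (default four at adjusted P < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import PairedCohort
from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "SelectionRule",
    "paired_t_test",
    "bh_adjust",
    "fold_change",
    "de_test_cohort",
    "de_test_cohorts",
    "select_common_de",
    "complement_pool",
    "term_enrichment",
]


@dataclass(frozen=True)
class SelectionRule:
    """Cross-cancer selection rule for the signature.

    A gene qualifies when >= ``min_cancers`` cancers show adjusted
    P < ``alpha`` with a shared direction.  With ``require_accordant`` off,
    direction is ignored.  ``forbid_discordant`` additionally disqualifies
    genes that are significant in the opposite direction anywhere (a stricter
    reading of "accordant"; off by default).
    """

    alpha: float = 0.05
    min_cancers: int = 4
    require_accordant: bool = True
    forbid_discordant: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")
        if self.min_cancers < 1:
            raise ValidationError("min_cancers must be >= 1")


def paired_t_test(cohort: PairedCohort, gene_id: str) -> tuple[float, int, float, str]:
    """Two-sided paired t-test for one gene: tumor vs normal.

    Returns ``(t, df, p_raw, direction)`` where ``t = mean(d)/(sd(d)/sqrt(n))``
    on the within-patient differences d, df = n - 1, and direction is ``up``
    when t > 0, ``down`` when t < 0, ``none`` at t == 0 exactly.
    """
    if gene_id not in cohort.expression.index:
        raise ValidationError(f"gene {gene_id!r} not in cohort {cohort.cancer!r}")
    d = cohort.differences().loc[gene_id].to_numpy(dtype=float)
    n = d.size
    if n < 2:
        raise InsufficientDataError("paired t-test needs >= 2 complete pairs")
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise DegenerateDataError("zero variance of paired differences")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    direction = "up" if t > 0 else ("down" if t < 0 else "none")
    return float(t), n - 1, float(p), direction


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(cohort: PairedCohort, gene_id: str) -> float:
    """Geometric-mean tumor/normal ratio: ``2**mean(paired log2 difference)``."""
    if gene_id not in cohort.expression.index:
        raise ValidationError(f"gene {gene_id!r} not in cohort {cohort.cancer!r}")
    d = cohort.differences().loc[gene_id].to_numpy(dtype=float)
    if d.size < 1:
        raise InsufficientDataError("fold change needs >= 1 pair")
    return float(2.0 ** d.mean())


def de_test_cohort(cohort: PairedCohort) -> pd.DataFrame:
    """Paired t-test + BH + fold change for every gene of one cohort.

    Vectorized across genes; BH is applied within the cohort (per-cancer
    scope).  Genes with zero difference variance get NaN statistics and are
    excluded from the BH family.
    """
    diffs = cohort.differences().to_numpy(dtype=float)
    n = diffs.shape[1]
    if n < 2:
        raise InsufficientDataError("paired t-test needs >= 2 complete pairs")
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    ok = sd > 0
    t = np.full(len(mean), np.nan)
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p = np.full_like(t, np.nan)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n - 1)
    p_adj = np.full_like(t, np.nan)
    if ok.any():
        p_adj[ok] = bh_adjust(p[ok])
    direction = np.where(t > 0, "up", np.where(t < 0, "down", "none"))
    return pd.DataFrame(
        {
            "gene": cohort.expression.index,
            "cancer": cohort.cancer,
            "t": t,
            "p_raw": p,
            "p_adj": p_adj,
            "direction": direction,
            "fold_change": 2.0 ** mean,
        }
    )


def de_test_cohorts(cohorts: Iterable[PairedCohort]) -> pd.DataFrame:
    """Stack :func:`de_test_cohort` over several cancers."""
    frames = [de_test_cohort(c) for c in cohorts]
    if not frames:
        raise ValidationError("no cohorts given")
    return pd.concat(frames, ignore_index=True)


def select_common_de(
    results: pd.DataFrame,
    rule: SelectionRule = SelectionRule(),
    restrict_to: Iterable[str] | None = None,
) -> set[str]:
    """Apply the cross-cancer accordant-direction selection rule.

    ``results`` is the long table from :func:`de_test_cohorts` (columns
    ``gene``, ``cancer``, ``p_adj``, ``direction``).  A gene is selected iff
    some direction d has adjusted P < alpha with direction d in at least
    ``min_cancers`` cancers.  ``restrict_to`` limits the candidate genes
    (e.g. to a curated interacting-gene universe).
    """
    n_cancers = results["cancer"].nunique()
    if n_cancers < rule.min_cancers:
        raise ValidationError(
            f"rule needs >= {rule.min_cancers} cancers, results have {n_cancers}"
        )
    df = results
    if restrict_to is not None:
        allowed = set(restrict_to)
        df = df[df["gene"].isin(allowed)]
    sig = df[(df["p_adj"] < rule.alpha) & df["p_adj"].notna()]
    selected: set[str] = set()
    for gene, sub in sig.groupby("gene", sort=False):
        counts = sub["direction"].value_counts()
        up = int(counts.get("up", 0))
        down = int(counts.get("down", 0))
        if rule.require_accordant:
            if rule.forbid_discordant and up > 0 and down > 0:
                continue
            if max(up, down) >= rule.min_cancers:
                selected.add(gene)
        else:
            if up + down >= rule.min_cancers:
                selected.add(gene)
    return selected


def complement_pool(all_selected: set[str], signature_universe: set[str]) -> set[str]:
    """Selected genes outside the curated interacting-gene universe.

    This is the "other cancer-related genes" pool used as the reference
    null pool in the pooled resampling test.
    """
    return set(all_selected) - set(signature_universe)


def term_enrichment(
    gene_set: Iterable[str],
    term_gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided Fisher's exact enrichment of ``gene_set`` in each term.

    For each term the 2x2 table (in gene_set x in term) over ``universe`` is
    tested with the one-sided (greater) Fisher's exact test; P-values are
    BH-adjusted across terms.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty gene universe")
    genes = set(gene_set)
    if not genes <= universe:
        raise ValidationError("gene_set must be a subset of the universe")
    rows = []
    for term, members in term_gene_sets.items():
        members = set(members) & universe
        a = len(genes & members)
        b = len(genes - members)
        c = len(members - genes)
        d = len(universe) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"term": term, "n_overlap": a, "odds_ratio": odds, "p_raw": p})
    out = pd.DataFrame(rows, columns=["term", "n_overlap", "odds_ratio", "p_raw"])
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy()) if len(out) else []
    return out
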