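"""Contingency tests for categorical trait associations.

Covers Fisher's exact test on 2x2 tables (virus-virus, virus-population,
virus-origin), a margin-conditional exact/Monte-Carlo test for larger r x c
tables (e.g. PCR genotype by abundance level), and a pairwise co-occurrence
screen with Benjamini-Hochberg correction. Two-sided p-values follow the
probability-mass rule: the summed probability of all margin-fixed tables no
more probable than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from ._rng import child_rng
from .types import ValidationError, VirusStatus

__all__ = ["FisherResult", "fisher_2x2", "rxc_exact", "cooccurrence_screen"]


@dataclass
class FisherResult:
    p_value: float
    odds_ratio: float  # sample odds ratio (ad/bc), inf/nan for zero cells
    conditional_odds_ratio: float | None
    degenerate: bool  # a margin was zero; p = 1 by convention


def _as_table(table) -> np.ndarray:
    t = np.asarray(table)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValidationError("contingency table must be at least 2x2")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValidationError("counts must be integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise ValidationError("counts must be non-negative")
    return t


def fisher_2x2(table, conditional_or: bool = False) -> FisherResult:
    """Two-sided Fisher's exact test for a 2x2 table.

    Any zero margin makes the table degenerate: p = 1 by convention, with
    the flag set. The sample odds ratio (ad/bc) is always reported; the
    conditional maximum-likelihood odds ratio on request.
    """
    t = _as_table(table)
    if t.shape != (2, 2):
        raise ValidationError("fisher_2x2 needs a 2x2 table")
    a, b = t[0]
    c, d = t[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sample_or = float(np.divide(a * d, b * c)) if b * c else (np.inf if a * d else np.nan)
    if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
        return FisherResult(1.0, sample_or, None, degenerate=True)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    cond = None
    if conditional_or:
        cond = float(stats.contingency.odds_ratio(t, kind="conditional").statistic)
    return FisherResult(float(p), sample_or, cond, degenerate=False)


def _log_table_prob(t: np.ndarray) -> float:
    """Log multivariate hypergeometric probability of a margin-fixed table."""
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    n = t.sum()
    return float(
        gammaln(r + 1).sum()
        + gammaln(c + 1).sum()
        - gammaln(n + 1)
        - gammaln(t + 1).sum()
    )


def _enumerate_tables(rows: np.ndarray, cols: np.ndarray):
    """Yield all non-negative integer tables with the given margins."""
    nr, nc = len(rows), len(cols)

    def fill(row_idx: int, remaining_cols: np.ndarray, acc: list[np.ndarray]):
        if row_idx == nr - 1:
            if (remaining_cols >= 0).all():
                yield np.array(acc + [remaining_cols])
            return
        target = rows[row_idx]

        def cells(ci: int, left: int, row: list[int]):
            if ci == nc - 1:
                if 0 <= left <= remaining_cols[ci]:
                    yield row + [left]
                return
            for v in range(min(left, remaining_cols[ci]) + 1):
                yield from cells(ci + 1, left - v, row + [v])

        for row in cells(0, target, []):
            row_arr = np.array(row)
            yield from fill(row_idx + 1, remaining_cols - row_arr, acc + [row_arr])

    yield from fill(0, cols.copy(), [])


def rxc_exact(table, n_mc: int = 9999, seed: int = 0, exact_max_n: int = 30) -> float:
    """Margin-conditional exact test for an r x c table.

    For small tables (total count <= ``exact_max_n``) all margin-fixed
    tables are enumerated and the p-value is the exact probability mass of
    tables no more probable than the observed one. Larger tables use a
    seeded Monte Carlo over margin-fixed tables (label-permutation
    sampling) with the add-one estimator, so p stays in (0, 1].
    """
    t = _as_table(table)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    n = int(t.sum())
    if n == 0:
        return 1.0
    obs = _log_table_prob(t)
    tol = 1e-9
    if n <= exact_max_n:
        p = 0.0
        for cand in _enumerate_tables(rows, cols):
            lp = _log_table_prob(cand)
            if lp <= obs + tol:
                p += np.exp(lp)
        return float(min(p, 1.0))
    if n_mc < 1000:
        raise ValidationError("n_mc must be >= 1000 for the Monte Carlo path")
    rng = child_rng(seed, "rxc_exact")
    row_labels = np.repeat(np.arange(len(rows)), rows)
    col_labels = np.repeat(np.arange(len(cols)), cols)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(col_labels)
        cand = np.zeros_like(t)
        np.add.at(cand, (row_labels, perm), 1)
        if _log_table_prob(cand) <= obs + tol:
            hits += 1
    return float((1 + hits) / (1 + n_mc))


def cooccurrence_screen(
    statuses: list[VirusStatus],
    pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Pairwise presence/absence association screen across a cohort.

    Builds a 2x2 table for each requested virus pair from the presence
    calls, tests each with Fisher's exact test, and adjusts the p-values
    with Benjamini-Hochberg across the screen.
    """
    present: dict[str, dict[str, bool]] = {}
    for s in statuses:
        present.setdefault(s.virus, {})[s.strain_id] = s.present
    rows = []
    for va, vb in pairs:
        if va not in present or vb not in present:
            raise ValidationError(f"no presence calls for pair ({va}, {vb})")
        shared = sorted(set(present[va]) & set(present[vb]))
        a = np.array([present[va][s] for s in shared])
        b = np.array([present[vb][s] for s in shared])
        tab = np.array(
            [
                [int((a & b).sum()), int((a & ~b).sum())],
                [int((~a & b).sum()), int((~a & ~b).sum())],
            ]
        )
        res = fisher_2x2(tab)
        rows.append(
            {
                "virus_a": va,
                "virus_b": vb,
                "n_both": tab[0, 0],
                "n_a_only": tab[0, 1],
                "n_b_only": tab[1, 0],
                "n_neither": tab[1, 1],
                "odds_ratio": res.odds_ratio,
                "p_value": res.p_value,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = stats.false_discovery_control(df["p_value"], method="bh")
    return df
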