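"""Phylogenetic conservation scoring and the rank tests built on it.

Conservation of a genomic window is summarized by a rate multiplier omega:
the factor by which all branch lengths of a fixed neutral tree must be
scaled to maximize the Jukes-Cantor likelihood of the window's alignment
columns (one shared omega per window).  omega < 1 means fewer substitutions
than the neutral expectation, i.e. conservation; omega = 0 is the boundary
optimum for a window with no substitutions at all.

The estimator uses Felsenstein pruning under JC69, treats gaps and Ns as
missing data, skips columns with fewer than two informative taxa or gaps in
more than half the taxa, and maximizes the likelihood by bounded 1-D search
on [0, omega_max].  All downstream comparisons are ordinal (rank-sum and
signed-rank tests), for which this single-parameter summary suffices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .intervals import GenomicInterval

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class ConservationScore:
    interval: GenomicInterval | None
    omega: float
    n_sites: int
    flagged: bool = False  # True when no usable columns remained


def _encode(rows: dict[str, str]) -> dict[str, np.ndarray]:
    out = {}
    for taxon, seq in rows.items():
        out[taxon] = np.array([_BASE_CODE.get(b, -1) for b in seq.upper()], dtype=np.int8)
    return out


def _usable_columns(coded: dict[str, np.ndarray], max_gap_frac: float = 0.5) -> np.ndarray:
    mat = np.stack(list(coded.values()))
    informative = (mat >= 0).sum(axis=0)
    return (informative >= 2) & (informative >= mat.shape[0] * (1.0 - max_gap_frac))


def _prune_loglik(tree, coded: dict[str, np.ndarray], omega: float, cols: np.ndarray) -> float:
    """Total JC69 log-likelihood of the selected columns at rate multiplier omega."""
    ncol = int(cols.sum())

    def partial(clade) -> np.ndarray:
        if clade.is_terminal():
            codes = coded[clade.name][cols]
            L = np.ones((ncol, 4))
            known = codes >= 0
            L[known] = 0.0
            L[np.nonzero(known)[0], codes[known]] = 1.0
            return L
        L = np.ones((ncol, 4))
        for child in clade.clades:
            Lc = partial(child)
            t = (child.branch_length or 0.0) * omega
            e = np.exp(-4.0 / 3.0 * t)
            p_same = 0.25 + 0.75 * e
            p_diff = 0.25 - 0.25 * e
            total = Lc.sum(axis=1, keepdims=True)
            L *= p_diff * total + (p_same - p_diff) * Lc
        return L

    root_L = partial(tree.root)
    site_lik = 0.25 * root_L.sum(axis=1)
    return float(np.log(np.clip(site_lik, 1e-300, None)).sum())


def count_substitutions(rows: dict[str, str]) -> int:
    """Minimum evidence of change: columns where informative taxa disagree."""
    coded = _encode(rows)
    mat = np.stack(list(coded.values()))
    n_sub = 0
    for col in mat.T:
        bases = col[col >= 0]
        if len(bases) >= 2 and len(np.unique(bases)) > 1:
            n_sub += 1
    return n_sub


def estimate_omega(
    rows: dict[str, str],
    tree,
    interval: GenomicInterval | None = None,
    omega_max: float = 10.0,
    tol: float = 1e-6,
) -> ConservationScore:
    """ML rate multiplier for one alignment block on a fixed tree.

    ``rows`` maps taxon name (matching the tree's leaf names) to its aligned
    sequence; ``tree`` is a Bio.Phylo tree with branch lengths.
    """
    leaves = {leaf.name for leaf in tree.get_terminals()}
    rows = {t: s for t, s in rows.items() if t in leaves}
    if len(rows) < 2:
        return ConservationScore(interval, float("nan"), 0, flagged=True)
    coded = _encode(rows)
    cols = _usable_columns(coded)
    n_used = int(cols.sum())
    if n_used == 0:
        return ConservationScore(interval, float("nan"), 0, flagged=True)

    # with zero observed substitutions the likelihood is maximized at the
    # omega = 0 boundary exactly
    mat = np.stack([coded[t][cols] for t in coded])
    any_sub = False
    for col in mat.T:
        bases = col[col >= 0]
        if len(np.unique(bases)) > 1:
            any_sub = True
            break
    if not any_sub:
        return ConservationScore(interval, 0.0, n_used)

    res = optimize.minimize_scalar(
        lambda w: -_prune_loglik(tree, coded, w, cols),
        bounds=(0.0, omega_max),
        method="bounded",
        options={"xatol": tol},
    )
    return ConservationScore(interval, float(res.x), n_used)


def jc_distance(p_mismatch: float) -> float:
    """Jukes-Cantor distance from an observed mismatch proportion."""
    if p_mismatch >= 0.75:
        return float("inf")
    return -0.75 * np.log(1.0 - 4.0 / 3.0 * p_mismatch)


# ---------------------------------------------------------------------------
# rank tests


def compare_site_conservation(
    omega_correlated: list[float],
    omega_uncorrelated: list[float],
    omega_upstream: list[float] | None = None,
    omega_correlated_paired: list[float] | None = None,
) -> dict:
    """Conservation contrasts between site classes.

    Rank-sum (Mann-Whitney, two-sided) compares the omega of sites on
    reverse-correlated pairs with the other predicted sites; the paired
    signed-rank test compares each correlated site with its own length-
    matched control 100 bp upstream (``omega_upstream`` aligned with
    ``omega_correlated``).  Reports p-values and the direction of each
    effect (negative median difference = correlated sites more conserved).
    """
    corr = np.asarray(omega_correlated, dtype=float)
    uncorr = np.asarray(omega_uncorrelated, dtype=float)
    report: dict = {
        "n_correlated": len(corr),
        "n_uncorrelated": len(uncorr),
    }
    if len(corr) and len(uncorr):
        stat, p = stats.mannwhitneyu(corr, uncorr, alternative="two-sided")
        report["ranksum_p"] = float(p)
        report["median_correlated"] = float(np.median(corr))
        report["median_uncorrelated"] = float(np.median(uncorr))
    if omega_upstream is not None and len(omega_upstream):
        up = np.asarray(omega_upstream, dtype=float)
        paired = (
            np.asarray(omega_correlated_paired, dtype=float)
            if omega_correlated_paired is not None
            else corr
        )
        if len(up) != len(paired):
            raise ValueError("upstream controls must pair 1:1 with their sites")
        corr = paired
        diffs = corr - up
        if np.all(diffs == 0):
            report["signed_rank_p"] = 1.0
        else:
            stat, p = stats.wilcoxon(corr, up, alternative="two-sided")
            report["signed_rank_p"] = float(p)
        report["median_site_minus_upstream"] = float(np.median(diffs))
    return report


def rank_correlation(x: list[float], y: list[float]) -> tuple[float, float]:
    """Spearman rank correlation with tie-corrected p-value."""
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
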