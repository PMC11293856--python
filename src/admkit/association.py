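"""Proportionality ρ, its per-sample α decomposition, and FDR thresholds.

For CLR vectors ``mj``, ``mk`` over n samples the proportionality metric is

    rho(mj, mk) = 1 - var(mj - mk) / (var(mj) + var(mk)),

with population variances (divisor n). It is a correlation analogue on
compositional data: +1 for perfectly proportional taxa, -1 for perfectly
anti-proportional ones. Writing ``d_i = m_ji - m_ki`` the deficit ``1 - rho``
splits exactly across samples,

    alpha_i = (d_i - dbar)^2 / (sum_i (m_ji - mbar_j)^2 + sum_i (m_ki - mbar_k)^2),
    rho = 1 - sum_i alpha_i,

so each ``alpha_i >= 0`` measures how much sample i weakens the association.
This per-sample decomposition is what the regression models downstream learn
as a function of the environment.

Because parametric p-values are unavailable for proportionality, significance
thresholds on rho come from a permutation bootstrap: each taxon's sample
labels are shuffled independently, preserving marginals while destroying
pairwise structure, and the threshold is the least extreme grid value whose
estimated false-discovery rate is below the requested level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compositional import ClrMatrix

__all__ = [
    "AlphaMatrix",
    "AssociationSet",
    "rho",
    "alpha_decompose",
    "reconstruct_rho",
    "all_pairs_rho",
    "bootstrap_fdr_thresholds",
]

DEFAULT_THRESHOLD_GRID = np.round(np.arange(-1.0, 1.0 + 1e-12, 0.05), 10)


class UndefinedAssociationError(ValueError):
    """Both vectors constant: var(mj) + var(mk) = 0, rho undefined."""


@dataclass
class AlphaMatrix:
    """Per-sample local contributions alpha for one taxon pair."""

    pair: tuple[str, str]
    alpha: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape[0] != len(self.sample_ids):
            raise ValueError("alpha and sample_ids length mismatch")

    @property
    def rho(self) -> float:
        return reconstruct_rho(self.alpha)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "alpha": self.alpha})


@dataclass
class AssociationSet:
    """All-pairs rho values with optional significance annotation.

    ``pairs[i] = (taxon_j, taxon_k)`` with j < k in the taxon ordering of the
    source CLR matrix. ``excluded`` lists constant pairs for which rho is
    undefined; they are flagged, never silently dropped.
    """

    pairs: list[tuple[str, str]]
    rho: np.ndarray
    thresholds: tuple[float, float] | None = None  # (t_neg, t_pos)
    fdr_level: float | None = None
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        if len(self.pairs) != self.rho.shape[0]:
            raise ValueError("pairs and rho length mismatch")
        if self.rho.size and np.nanmax(np.abs(self.rho)) > 1 + 1e-9:
            raise ValueError("|rho| > 1 encountered")

    @property
    def significant(self) -> np.ndarray:
        if self.thresholds is None:
            raise ValueError("thresholds unset; run bootstrap_fdr_thresholds first")
        t_neg, t_pos = self.thresholds
        return (self.rho >= t_pos) | (self.rho <= t_neg)

    @property
    def sign(self) -> np.ndarray:
        """'positive' / 'negative' per significant pair, '' otherwise."""
        out = np.full(len(self.pairs), "", dtype=object)
        if self.thresholds is not None:
            t_neg, t_pos = self.thresholds
            out[self.rho >= t_pos] = "positive"
            out[self.rho <= t_neg] = "negative"
        return out

    def with_thresholds(self, t_neg: float, t_pos: float, fdr_level: float) -> "AssociationSet":
        return AssociationSet(self.pairs, self.rho, (t_neg, t_pos), fdr_level, self.excluded)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "taxon_j": [p[0] for p in self.pairs],
                "taxon_k": [p[1] for p in self.pairs],
                "rho": self.rho,
            }
        )
        if self.thresholds is not None:
            df["significant"] = self.significant
            df["sign"] = self.sign
        return df


def _check_pair(mj: np.ndarray, mk: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mj = np.asarray(mj, dtype=float)
    mk = np.asarray(mk, dtype=float)
    if mj.shape != mk.shape or mj.ndim != 1:
        raise ValueError("mj and mk must be 1-D vectors of equal length")
    if mj.shape[0] < 2:
        raise ValueError("need at least two samples")
    return mj, mk


def rho(mj: np.ndarray, mk: np.ndarray) -> float:
    """Proportionality of two CLR vectors; population variances (divisor n)."""
    mj, mk = _check_pair(mj, mk)
    var_j = mj.var()
    var_k = mk.var()
    denom = var_j + var_k
    if denom == 0:
        raise UndefinedAssociationError(
            "rho undefined: both vectors are constant (zero variance)"
        )
    return float(1.0 - (mj - mk).var() / denom)


def alpha_decompose(
    mj: np.ndarray,
    mk: np.ndarray,
    pair: tuple[str, str] = ("j", "k"),
    sample_ids: list[str] | None = None,
) -> AlphaMatrix:
    """Split ``1 - rho`` into non-negative per-sample contributions.

    ``alpha_i = (d_i - dbar)^2 / D`` with ``d = mj - mk`` and ``D`` the sum of
    squared deviations of both vectors; ``1 - sum(alpha) = rho`` exactly.
    """
    mj, mk = _check_pair(mj, mk)
    denom = ((mj - mj.mean()) ** 2).sum() + ((mk - mk.mean()) ** 2).sum()
    if denom == 0:
        raise UndefinedAssociationError(
            "alpha undefined: both vectors are constant (zero variance)"
        )
    d = mj - mk
    alpha = (d - d.mean()) ** 2 / denom
    if sample_ids is None:
        sample_ids = [str(i) for i in range(mj.shape[0])]
    return AlphaMatrix(pair=tuple(pair), alpha=alpha, sample_ids=list(sample_ids))


def reconstruct_rho(alpha: np.ndarray) -> float:
    """rho = 1 - sum(alpha); inverse of the decomposition."""
    alpha = np.asarray(alpha, dtype=float)
    if alpha.size == 0:
        raise ValueError("empty alpha vector")
    if not np.all(np.isfinite(alpha)):
        raise ValueError("alpha contains non-finite entries")
    return float(1.0 - alpha.sum())


def _pairwise_rho_matrix(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised all-pairs rho.

    Returns (rho matrix, per-taxon variance). Entries where both variances
    vanish are NaN. Uses rho = 2 cov / (var_j + var_k), the algebraic
    rearrangement of 1 - var(mj - mk)/(var_j + var_k).
    """
    n = values.shape[0]
    centred = values - values.mean(axis=0, keepdims=True)
    var = (centred**2).sum(axis=0) / n
    cov = centred.T @ centred / n
    denom = var[:, None] + var[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = 2.0 * cov / denom
    r[denom == 0] = np.nan
    return r, var


def all_pairs_rho(clr: ClrMatrix) -> AssociationSet:
    """rho for every unordered taxon pair of a CLR matrix.

    Constant pairs (both variances zero) are excluded with a warning and
    listed in ``AssociationSet.excluded``.
    """
    if clr.n_taxa < 2:
        raise ValueError("need at least two taxa")
    r, _ = _pairwise_rho_matrix(clr.values)
    iu, ju = np.triu_indices(clr.n_taxa, k=1)
    vals = r[iu, ju]
    taxa = clr.taxon_ids
    bad = ~np.isfinite(vals)
    excluded = [(taxa[i], taxa[j]) for i, j in zip(iu[bad], ju[bad])]
    if excluded:
        warnings.warn(
            f"{len(excluded)} constant pair(s) excluded (rho undefined)",
            RuntimeWarning,
            stacklevel=2,
        )
    keep = ~bad
    pairs = [(taxa[i], taxa[j]) for i, j in zip(iu[keep], ju[keep])]
    return AssociationSet(pairs=pairs, rho=vals[keep], excluded=excluded)


def bootstrap_fdr_thresholds(
    clr: ClrMatrix,
    n_boot: int = 100,
    fdr_level: float = 0.01,
    seed: int = 0,
    threshold_grid: np.ndarray | None = None,
    observed: AssociationSet | None = None,
) -> tuple[float, float]:
    """Permutation-bootstrap FDR thresholds (t_neg, t_pos) on rho.

    For each candidate threshold t the FDR is the mean, over ``n_boot``
    null replicates (each taxon's samples permuted independently), of the
    number of null pairs at least as extreme as t divided by the number of
    observed pairs at least as extreme (floored at 1), clipped to 1.
    ``t_pos`` is the smallest positive t with FDR <= fdr_level, ``t_neg``
    the largest negative one.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not (0.0 < fdr_level <= 1.0):
        raise ValueError("fdr_level must lie in (0, 1]")
    grid = DEFAULT_THRESHOLD_GRID if threshold_grid is None else np.asarray(threshold_grid, float)
    if observed is None:
        observed = all_pairs_rho(clr)
    obs = observed.rho
    rng = np.random.default_rng(seed)

    pos_grid = np.sort(grid[grid > 0])
    neg_grid = np.sort(grid[grid < 0])[::-1]  # closest to zero first
    null_pos_counts = np.zeros((n_boot, pos_grid.size))
    null_neg_counts = np.zeros((n_boot, neg_grid.size))
    for b in range(n_boot):
        perm = np.empty_like(clr.values)
        for j in range(clr.n_taxa):
            perm[:, j] = rng.permutation(clr.values[:, j])
        r, _ = _pairwise_rho_matrix(perm)
        iu, ju = np.triu_indices(clr.n_taxa, k=1)
        null = r[iu, ju]
        null = null[np.isfinite(null)]
        null_pos_counts[b] = (null[:, None] >= pos_grid[None, :]).sum(axis=0)
        null_neg_counts[b] = (null[:, None] <= neg_grid[None, :]).sum(axis=0)

    def _first_passing(grid_side: np.ndarray, null_counts: np.ndarray, side: str):
        best_fdr = np.inf
        for idx, t in enumerate(grid_side):
            n_obs = int((obs >= t).sum()) if side == "pos" else int((obs <= t).sum())
            fdr = float(np.minimum(null_counts[:, idx] / max(1, n_obs), 1.0).mean())
            best_fdr = min(best_fdr, fdr)
            if fdr <= fdr_level:
                return float(t), best_fdr
        return None, best_fdr

    t_pos, best_pos = _first_passing(pos_grid, null_pos_counts, "pos")
    t_neg, best_neg = _first_passing(neg_grid, null_neg_counts, "neg")
    if t_pos is None or t_neg is None:
        raise ValueError(
            "no grid threshold attains the requested FDR level "
            f"{fdr_level}; minimum attainable FDR: positive side "
            f"{best_pos:.4f}, negative side {best_neg:.4f}"
        )
    return t_neg, t_pos
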