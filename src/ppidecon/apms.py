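"""From raw bait-prey peptide counts to a connectivity matrix.

Peptide counts are biased towards long proteins, so each count is divided
by the prey's sequence length, giving abundance ratios R(i, j).  Ratios are
symmetrized by averaging reciprocal observations and mapped through a
logistic function

    M(i, j) = 1 / (1 + exp(−(R(i, j) − α) / β))

whose parameters are fitted so that the distribution of transformed values
matches a reference connectivity distribution (χ² histogram distance).
The shipped defaults are α = 2.8921, β = −0.6318.  Note the negative β:
the fitted map *decreases* with the normalized count; the sign is exposed
so users can flip it.  Unobserved pairs carry no evidence of connectivity
and map to 0 (the logistic value at R = 0 would be ≈0.99 with the default
parameters, which would contradict the matrix semantics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, minimize

from .errors import DataError, FitError, InvalidArgumentError
from .graphs import ConnectivityMatrix

DEFAULT_ALPHA = 2.8921
DEFAULT_BETA = -0.6318


@dataclass
class LogisticParams:
    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA

    def __post_init__(self):
        if self.beta == 0:
            raise InvalidArgumentError("beta must be non-zero")


@dataclass
class PeptideCountTable:
    """Bait→prey peptide counts plus protein sequence lengths (residues)."""

    counts: Dict[Tuple[str, str], int] = field(default_factory=dict)
    protein_lengths: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for (b, p), c in self.counts.items():
            if c < 0:
                raise InvalidArgumentError(f"negative peptide count for ({b}, {p})")
        for prot, length in self.protein_lengths.items():
            if length <= 0:
                raise InvalidArgumentError(f"non-positive length for {prot}")

    @property
    def proteins(self) -> List[str]:
        ps = {b for b, _ in self.counts} | {p for _, p in self.counts}
        return sorted(ps)

    # ------------------------------------------------------------- I/O

    def to_tsv(self, counts_path, lengths_path) -> None:
        with open(counts_path, "w") as fh:
            fh.write("bait\tprey\tcount\n")
            for (b, p), c in sorted(self.counts.items()):
                fh.write(f"{b}\t{p}\t{c}\n")
        with open(lengths_path, "w") as fh:
            fh.write("protein\tlength\n")
            for prot, length in sorted(self.protein_lengths.items()):
                fh.write(f"{prot}\t{length}\n")

    @staticmethod
    def from_tsv(counts_path, lengths_path) -> "PeptideCountTable":
        cdf = pd.read_csv(counts_path, sep="\t", dtype={"bait": str, "prey": str})
        ldf = pd.read_csv(lengths_path, sep="\t", dtype={"protein": str})
        counts = {(r.bait, r.prey): int(r.count) for r in cdf.itertuples()}
        lengths = {r.protein: int(r.length) for r in ldf.itertuples()}
        return PeptideCountTable(counts, lengths)


def normalize_counts(table: PeptideCountTable) -> pd.DataFrame:
    """Abundance ratios R(i, j) = count(i→j) / length(j) as a DataFrame
    (NaN marks unobserved entries; reciprocal observations both kept)."""
    proteins = table.proteins
    missing = sorted({p for _, p in table.counts if p not in table.protein_lengths})
    if missing:
        raise DataError(f"missing protein length(s) for: {', '.join(missing)}")
    R = pd.DataFrame(np.nan, index=proteins, columns=proteins)
    for (b, p), c in table.counts.items():
        R.loc[b, p] = c / table.protein_lengths[p]
    return R


def symmetrize_ratios(R: pd.DataFrame) -> pd.DataFrame:
    """Average reciprocal entries where both were observed; keep the single
    observation otherwise."""
    A = R.to_numpy()
    B = A.T
    both = ~np.isnan(A) & ~np.isnan(B)
    out = np.where(both, (A + B) / 2.0, np.where(np.isnan(A), B, A))
    return pd.DataFrame(out, index=R.index, columns=R.columns)


def logistic_transform(R: pd.DataFrame,
                       params: LogisticParams = LogisticParams()) -> ConnectivityMatrix:
    """Map symmetrized ratios through the logistic; absent entries → 0,
    diagonal → 1, output clamped to [0, 1]."""
    S = symmetrize_ratios(R).to_numpy()
    with np.errstate(over="ignore"):
        M = 1.0 / (1.0 + np.exp(-(S - params.alpha) / params.beta))
    M = np.where(np.isnan(S), 0.0, M)
    M = np.clip(M, 0.0, 1.0)
    M = (M + M.T) / 2.0
    np.fill_diagonal(M, 1.0)
    return ConnectivityMatrix(list(R.index), M, p_hat=0.5, delta=0.0, n_samples=0)


def fit_logistic_params(R: pd.DataFrame, reference: np.ndarray,
                        bins: int = 20) -> LogisticParams:
    """Fit (α, β) so the histogram of transformed ratios matches a reference
    connectivity distribution under the χ² distance.

    The binned objective is piecewise constant, so a small quantile-matching
    term breaks plateau ties and the search runs seeded differential
    evolution (both β signs) with a Nelder-Mead polish.
    """
    ref = np.asarray(reference, dtype=float)
    edges = np.linspace(0.0, 1.0, bins + 1)
    ref_hist, _ = np.histogram(ref, bins=edges)
    if np.count_nonzero(ref_hist) < 2:
        raise FitError("reference distribution occupies fewer than 2 bins")
    ref_frac = ref_hist / ref_hist.sum()
    vals = symmetrize_ratios(R).to_numpy()
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise FitError("no observed ratios to fit")

    qs = np.linspace(0.02, 0.98, 49)
    ref_q = np.quantile(ref, qs)

    def chi2(theta):
        a, b = theta
        if b == 0:
            return np.inf
        m = 1.0 / (1.0 + np.exp(-(vals - a) / b))
        m = np.clip(m, 0, 1)
        h, _ = np.histogram(m, bins=edges)
        frac = h / h.sum()
        mask = ref_frac > 0
        c2 = float(np.sum((frac[mask] - ref_frac[mask]) ** 2 / ref_frac[mask])
                   + frac[~mask].sum())
        # the binned objective is piecewise constant; a small quantile-
        # matching term breaks ties within its flat basins
        qerr = float(np.mean((np.quantile(m, qs) - ref_q) ** 2))
        return c2 + 1e-3 * qerr

    lo, hi = np.min(vals), np.max(vals)
    span = max(hi - lo, 1e-6)
    bounds = [(lo - span, hi + span), (-4 * span, 4 * span)]
    best = None
    for sign in (-1, 1):  # the β sign flips the map's direction; try both basins
        b_bounds = [bounds[0], (span / 200, 4 * span) if sign > 0
                    else (-4 * span, -span / 200)]
        res = differential_evolution(chi2, b_bounds, seed=0, tol=1e-10,
                                     maxiter=200, polish=True)
        if best is None or res.fun < best.fun:
            best = res
    refine = minimize(chi2, best.x, method="Nelder-Mead",
                      options={"xatol": 1e-7, "fatol": 1e-12})
    a0, b0 = refine.x if refine.fun <= best.fun else best.x
    return LogisticParams(alpha=float(a0), beta=float(b0))
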