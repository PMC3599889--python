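"""Differential expression between two tag libraries.

The test statistic is the Audic-Claverie exact test for a single gene's
tag counts ``x`` and ``y`` in two libraries of sizes ``N1`` and ``N2``.
Conditional on ``x``, under the null hypothesis of equal relative
abundance the second count follows

    p(y | x) = (N2/N1)^y * (x + y)! / (x! * y! * (1 + N2/N1)^(x+y+1)),

which is the negative-binomial law NB(r = x + 1, p = N1/(N1+N2)).  The
pmf is evaluated in log space with log-gamma terms; the two-sided
p-value doubles the smaller of the two tails (capped at 1).  Tail sums
use the regularized incomplete beta function, the closed form of the
negative-binomial CDF, so whole count matrices are tested vectorially.

Genes are called up/down when the Benjamini-Hochberg FDR and an absolute
log2 fold-change on TPM both clear their thresholds; the tested set is
the union of genes detected in either library.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from statsmodels.stats.multitest import multipletests

from .quantify import ExpressionMatrix


def _validate_counts(x, y, n1: float, n2: float) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x)
    y = np.asarray(y)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("tag counts must be non-negative")
    if not np.all(np.equal(np.mod(x, 1), 0)) or not np.all(np.equal(np.mod(y, 1), 0)):
        raise ValueError("tag counts must be integers")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    return x.astype(np.float64), y.astype(np.float64)


def ac_pmf(y, x, n1: float, n2: float):
    """Audic-Claverie conditional probability p(y | x) for library sizes n1, n2.

    Computed in log space (log-gamma) so large counts do not overflow.
    Vectorized over ``x`` and ``y``.
    """
    x, y = _validate_counts(x, y, n1, n2)
    ratio = n2 / n1
    logp = (
        y * np.log(ratio)
        + special.gammaln(x + y + 1.0)
        - special.gammaln(x + 1.0)
        - special.gammaln(y + 1.0)
        - (x + y + 1.0) * np.log1p(ratio)
    )
    return np.exp(logp) if logp.shape else float(np.exp(logp))


# Below this combined count both tails are summed term by term from the
# log-space pmf, which keeps full *relative* precision even for p-values
# far below the incomplete-beta closed form's accuracy floor.
_SUMMATION_LIMIT = 2048


def _tails_summed(x: int, y: int, n1: float, n2: float) -> tuple[float, float]:
    r = n2 / n1
    k_max = int(max(8 * (x + 1) * max(r, 1.0) + 64, 2 * y + 64))
    while True:
        ks = np.arange(k_max + 1)
        pmf = ac_pmf(ks, np.full(k_max + 1, x), n1, n2)
        upper = float(pmf[y:].sum())
        if pmf[-1] < 1e-305 or pmf[-1] < 1e-25 * max(upper, 1e-300):
            break
        k_max *= 2
    lower = float(pmf[: y + 1].sum())
    return min(lower, 1.0), min(upper, 1.0)


def _tails(x, y, n1: float, n2: float) -> tuple[np.ndarray, np.ndarray]:
    """P(Y <= y | x) and P(Y >= y | x) under the AC conditional law.

    Y | x ~ NB(r = x + 1, p = n1/(n1+n2)); its CDF is the regularized
    incomplete beta I_p(r, y + 1), used for large counts; small-count
    entries (x + y <= 2048) are recomputed by exact pmf summation.
    """
    p = n1 / (n1 + n2)
    lower = special.betainc(x + 1.0, y + 1.0, p)
    # P(Y >= y) = 1 - P(Y <= y - 1); at y = 0 the upper tail is 1
    upper = np.where(y > 0, 1.0 - special.betainc(x + 1.0, np.maximum(y, 1.0), p), 1.0)
    xs, ys, lower, upper = (
        np.atleast_1d(a) for a in np.broadcast_arrays(x, y, lower, upper)
    )
    lower = lower.astype(np.float64).copy()
    upper = upper.astype(np.float64).copy()
    for i in np.flatnonzero(xs + ys <= _SUMMATION_LIMIT):
        lower[i], upper[i] = _tails_summed(int(xs[i]), int(ys[i]), n1, n2)
    shape = np.broadcast(x, y).shape
    return lower.reshape(shape), upper.reshape(shape)


def ac_test_two_sided(x, y, n1: float, n2: float):
    """Two-sided Audic-Claverie p-value: 2 x min(lower tail, upper tail), capped at 1.

    Symmetric under exchanging (x, n1) with (y, n2).  Vectorized.
    """
    x, y = _validate_counts(x, y, n1, n2)
    lower, upper = _tails(x, y, n1, n2)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return p if p.shape else float(p)


def fdr_adjust(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DeSummary:
    """Headline counts for one pairwise comparison."""

    comparison: str
    n_tested: int
    n_de: int
    n_up: int
    n_down: int

    @property
    def pct_de(self) -> int:
        """DE genes as an integer percentage of the tested (expressed) set."""
        return round(self.n_de / self.n_tested * 100) if self.n_tested else 0

    @property
    def pct_up(self) -> int:
        return round(self.n_up / self.n_de * 100) if self.n_de else 0

    @property
    def pct_down(self) -> int:
        return round(self.n_down / self.n_de * 100) if self.n_de else 0

    def as_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "n_tested": self.n_tested,
            "n_de": self.n_de,
            "n_up": self.n_up,
            "n_down": self.n_down,
            "pct_de": self.pct_de,
            "pct_up": self.pct_up,
            "pct_down": self.pct_down,
        }


def de_summary(comparison: str, n_tested: int, n_up: int, n_down: int) -> DeSummary:
    if n_up + n_down > n_tested:
        raise ValueError("more DE genes than tested genes")
    return DeSummary(
        comparison=comparison, n_tested=n_tested, n_de=n_up + n_down, n_up=n_up, n_down=n_down
    )


def call_de(
    matrix: ExpressionMatrix,
    library_a: str,
    library_b: str,
    fdr_threshold: float = 0.001,
    fc_threshold_log2: float = 1.0,
    tpm_floor: float = 0.001,
    detection_threshold: float = 1.0,
) -> tuple[pd.DataFrame, DeSummary]:
    """Call differential expression of B vs A with the AC exact test.

    The tested set is the union of genes detected in either library (TPM
    >= ``detection_threshold``).  log2 fold change is computed on TPM with
    zeros replaced by ``tpm_floor`` so it stays finite; the up/down call
    requires BH-FDR <= ``fdr_threshold`` and |log2FC| >= ``fc_threshold_log2``.

    Returns the per-gene result table and a DeSummary.
    """
    if library_a == library_b:
        raise ValueError("the two libraries of a comparison must differ")
    for lib in (library_a, library_b):
        if lib not in matrix.counts.columns:
            raise KeyError(f"library {lib!r} not in expression matrix")

    det = matrix.detection(detection_threshold)
    tested = matrix.counts.index[det[library_a] | det[library_b]]
    x = matrix.counts.loc[tested, library_a].to_numpy()
    y = matrix.counts.loc[tested, library_b].to_numpy()
    n1 = float(matrix.clean_totals[library_a])
    n2 = float(matrix.clean_totals[library_b])

    tpm = matrix.tpm
    tpm_a = tpm.loc[tested, library_a].to_numpy()
    tpm_b = tpm.loc[tested, library_b].to_numpy()
    log2fc = np.log2(np.where(tpm_b > 0, tpm_b, tpm_floor)) - np.log2(
        np.where(tpm_a > 0, tpm_a, tpm_floor)
    )

    pvals = ac_test_two_sided(x, y, n1, n2) if len(tested) else np.array([])
    fdr = fdr_adjust(pvals)
    significant = (fdr <= fdr_threshold) & (np.abs(log2fc) >= fc_threshold_log2)
    call = np.where(significant & (log2fc > 0), "up", np.where(significant, "down", "ns"))

    table = pd.DataFrame(
        {
            "gene_id": tested,
            "count_a": x.astype(int),
            "count_b": y.astype(int),
            "tpm_a": tpm_a,
            "tpm_b": tpm_b,
            "log2fc": log2fc,
            "p": pvals,
            "fdr": fdr,
            "call": call,
        }
    ).set_index("gene_id")
    summary = de_summary(
        comparison=f"{library_b}_vs_{library_a}",
        n_tested=len(tested),
        n_up=int((call == "up").sum()),
        n_down=int((call == "down").sum()),
    )
    return table, summary
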