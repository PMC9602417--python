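"""Per-gene multiple-regression comparator.

For every gene the expression vector over the 18 samples is modelled as

    v_l = a + b * t_l + c * s_l

with t_l the postnatal day of sample l (raw day scale) and s_l an
exposure indicator (1 = exposed, 0 = control).  The sample axis is laid
out exposed group first, then control; within each group replicate
blocks follow each other and the timepoints run in ascending PND order
inside a block, so t = (1, 21, 42, 1, 21, 42, ...) and s is nine ones
followed by nine zeros for the default 3-replicate, 3-timepoint design.

Both slope coefficients are tested with a Wald chi-square: the squared
standardized coefficient (b / SE)^2 is referred to the chi2(1) upper
tail (numerically identical to a two-sided normal z test).  A gene is
called significant when BOTH the PND coefficient and the exposure
coefficient reach p < alpha; no multiple-testing correction is applied
in this baseline.  A t-reference variant (exact under normal errors at
n = 18) is available via ``test="t"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_tensor import ExpressionTensor

__all__ = [
    "RegressionDesign",
    "RegressionResult",
    "build_design",
    "fit_genes",
    "fit_gene",
    "tensor_to_design_matrix",
    "select_genes_regression",
]


@dataclass
class RegressionDesign:
    """Covariate vectors t (PND) and s (exposure) plus the slot layout."""

    t: np.ndarray
    s: np.ndarray
    layout: list[tuple[int, int, int]]  # (replicate j, timepoint k, exposure l), 1-based

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.s = np.asarray(self.s, float)
        if not (len(self.t) == len(self.s) == len(self.layout)):
            raise ValueError("t, s and layout must have equal length")
        if not set(np.unique(self.s)) <= {0.0, 1.0}:
            raise ValueError("s must be a 0/1 indicator")

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def matrix(self) -> np.ndarray:
        """The n x 3 design matrix (intercept, t, s)."""
        return np.column_stack([np.ones(self.n), self.t, self.s])


def build_design(
    pnds: Sequence[int] = (1, 21, 42),
    replicates: int = 3,
) -> RegressionDesign:
    """Lay out the length M*K*2 design: exposed block first, PND fastest."""
    pnds = list(pnds)
    if list(pnds) != sorted(set(pnds)):
        raise ValueError("pnds must be strictly increasing")
    if replicates < 1:
        raise ValueError("replicates must be positive")
    t, s, layout = [], [], []
    for exposure in (1, 2):  # l=1 exposed, l=2 control
        for j in range(1, replicates + 1):
            for k, day in enumerate(pnds, start=1):
                t.append(day)
                s.append(1.0 if exposure == 1 else 0.0)
                layout.append((j, k, exposure))
    return RegressionDesign(t=np.array(t, float), s=np.array(s, float), layout=layout)


def tensor_to_design_matrix(tensor: ExpressionTensor, design: RegressionDesign) -> np.ndarray:
    """Flatten the tensor's sample axes into design order: genes x n."""
    x = tensor.values
    cols = [x[:, j - 1, k - 1, l - 1] for j, k, l in design.layout]
    return np.column_stack(cols)


@dataclass
class RegressionResult:
    """Per-gene OLS coefficients, standard errors and Wald p-values."""

    gene_ids: list[str]
    coef: np.ndarray  # genes x 3 (intercept a, PND slope b, exposure effect c)
    se: np.ndarray  # genes x 3
    p_t: np.ndarray  # p-value for the PND coefficient b
    p_s: np.ndarray  # p-value for the exposure coefficient c
    test: str
    degenerate: np.ndarray  # genes with ~zero residual variance

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "intercept": self.coef[:, 0],
                "pnd_slope": self.coef[:, 1],
                "exposure_effect": self.coef[:, 2],
                "se_intercept": self.se[:, 0],
                "se_pnd": self.se[:, 1],
                "se_exposure": self.se[:, 2],
                "p_pnd": self.p_t,
                "p_exposure": self.p_s,
                "degenerate": self.degenerate,
            }
        )

    def write_tsv(self, path: str | Path, alpha: float = 0.05) -> None:
        frame = self.to_frame()
        frame["selected"] = (self.p_t < alpha) & (self.p_s < alpha)
        frame.to_csv(path, sep="\t", index=False)


def fit_genes(
    values: np.ndarray,
    design: RegressionDesign,
    gene_ids: Sequence[str] | None = None,
    test: str = "chi2",
) -> RegressionResult:
    """Vectorized OLS of every gene on (1, t, s) with per-coefficient tests.

    The design is shared across genes, so the normal equations are solved
    once and applied to all expression vectors at once.  ``test`` selects
    the reference distribution for (coef/SE)^2: "chi2" (Wald, as the
    method states) or "t" (classical, df = n - 3).
    """
    if test not in ("chi2", "t"):
        raise ValueError(f"unknown test {test!r}")
    V = np.atleast_2d(np.asarray(values, float))
    if V.shape[1] != design.n:
        raise ValueError(f"expression rows of length {V.shape[1]} vs design length {design.n}")
    X = design.matrix
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix (1, t, s) is rank-deficient")
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = V @ X @ xtx_inv  # genes x 3
    resid = V - coef @ X.T
    ssr = np.sum(resid**2, axis=1)
    dof = n - k
    sigma2 = ssr / dof
    se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))
    degenerate = sigma2 <= np.finfo(float).eps * np.maximum(1.0, np.sum(V**2, axis=1))
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) have ~zero residual variance; "
            "their Wald p-values are degenerate"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, coef / se, np.inf * np.sign(coef))
    if test == "chi2":
        p = stats.chi2.sf(z**2, 1)
    else:
        p = 2 * stats.t.sf(np.abs(z), dof)
    # exact fit: coefficient exactly explains the data -> p = 0 (flagged);
    # a zero coefficient with zero SE stays non-significant
    p = np.where(np.isnan(p), np.where(coef == 0, 1.0, 0.0), p)
    ids = [str(g) for g in gene_ids] if gene_ids is not None else [
        f"gene{i}" for i in range(V.shape[0])
    ]
    return RegressionResult(
        gene_ids=ids,
        coef=coef,
        se=se,
        p_t=p[:, 1],
        p_s=p[:, 2],
        test=test,
        degenerate=degenerate,
    )


def fit_gene(
    v: np.ndarray, design: RegressionDesign, gene_id: str = "gene", test: str = "chi2"
) -> RegressionResult:
    """Single-gene convenience wrapper around :func:`fit_genes`."""
    return fit_genes(np.asarray(v, float)[None, :], design, [gene_id], test=test)


def select_genes_regression(result: RegressionResult, alpha: float = 0.05) -> list[str]:
    """Genes with p < alpha for BOTH the PND and the exposure coefficient."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    mask = (result.p_t < alpha) & (result.p_s < alpha)
    return [g for g, m in zip(result.gene_ids, mask) if m]
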