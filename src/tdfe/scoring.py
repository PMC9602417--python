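"""Chi-square gene scoring on the selected gene-mode components.

Each selected gene-mode singular vector u_{l1'} is assumed to follow an
independent normal distribution across genes.  Gene i's statistic is

    stat_i = sum over selected components l1' of (u_{l1',i} / sigma_{l1'})^2

where sigma_{l1'} is the standard deviation of component l1' over all
genes, computed about zero (no mean subtraction): singular vectors of
non-centred expression data do not have zero mean, and the normalization
divides by sigma only.  The upper-tail chi-square probability with
df = (number of selected components) gives a raw p per gene; after
multiple-testing adjustment (Benjamini-Hochberg by default), genes with
adjusted p strictly below alpha are selected as the ones carrying the
chosen interpretable pattern.

The whole stage is invariant to flipping the sign of any factor column
and to rescaling a column by any non-zero constant (sigma rescales with
it).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneScoreTable",
    "chi_square_statistic",
    "chi_square_p",
    "adjust_p",
    "score_genes",
    "select_genes",
]

_ADJUST_METHODS = {"bh": "fdr_bh", "holm": "holm", "bonferroni": "bonferroni"}


def chi_square_statistic(
    gene_factor: np.ndarray,
    components: Sequence[int],
    center: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene sum of squared sigma-normalized loadings, plus the sigmas.

    ``components`` are 1-based column indices into the gene factor.
    ``center`` subtracts the column mean before normalizing (off by
    default; the method's formula scales by sigma only).
    """
    u = np.asarray(gene_factor, float)
    comps = [int(c) for c in components]
    if not comps:
        raise ValueError("need at least one selected component")
    for c in comps:
        if not 1 <= c <= u.shape[1]:
            raise ValueError(f"component {c} outside 1..{u.shape[1]}")
    cols = u[:, [c - 1 for c in comps]]
    if center:
        cols = cols - cols.mean(axis=0)
    # sd about zero (second moment) unless the columns were just centred
    sigmas = np.sqrt(np.mean(cols**2, axis=0))
    if np.any(sigmas <= 0):
        bad = comps[int(np.argmin(sigmas))]
        raise ValueError(f"component {bad} has zero variance across genes")
    statistic = np.sum((cols / sigmas) ** 2, axis=1)
    return statistic, sigmas


def chi_square_p(statistic: np.ndarray, df: int) -> np.ndarray:
    """Upper-tail chi-square probability P[chi2_df > statistic]."""
    statistic = np.asarray(statistic, float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if np.any(statistic < 0):
        raise ValueError("chi-square statistic must be non-negative")
    return stats.chi2.sf(statistic, df)


def adjust_p(p_raw: np.ndarray, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment; 'bh' (step-up FDR) or 'holm'."""
    p_raw = np.asarray(p_raw, float)
    if np.any((p_raw < 0) | (p_raw > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in _ADJUST_METHODS:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p_raw, method=_ADJUST_METHODS[method])[1]


@dataclass
class GeneScoreTable:
    """Per-gene loadings, chi-square statistic, raw/adjusted p, selection flag."""

    gene_ids: list[str]
    components: list[int]
    loadings: np.ndarray  # genes x |components|
    sigmas: np.ndarray
    statistic: np.ndarray
    df: int
    p_raw: np.ndarray
    p_adj: np.ndarray
    alpha: float
    adjust_method: str

    @property
    def selected(self) -> np.ndarray:
        return self.p_adj < self.alpha

    def selected_genes(self) -> list[str]:
        """Selected gene ids in ascending adjusted-p order."""
        idx = np.flatnonzero(self.selected)
        order = idx[np.lexsort((idx, self.p_adj[idx]))]
        return [self.gene_ids[i] for i in order]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"gene_id": self.gene_ids})
        for pos, comp in enumerate(self.components):
            frame[f"u{comp}"] = self.loadings[:, pos]
        frame["statistic"] = self.statistic
        frame["p_raw"] = self.p_raw
        frame["p_adj"] = self.p_adj
        frame["selected"] = self.selected
        return frame

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_gene_list(self, path: str | Path) -> None:
        """Plain one-gene-per-line list, ready for enrichment-tool upload."""
        Path(path).write_text("\n".join(self.selected_genes()) + "\n")


def score_genes(
    gene_factor: np.ndarray,
    components: Sequence[int],
    gene_ids: Sequence[str],
    alpha: float = 0.05,
    adjust_method: str = "bh",
    center: bool = False,
    df_mode: str = "summed",
) -> GeneScoreTable:
    """Full scoring stage: statistic, p-values, adjustment, selection flags.

    ``df_mode`` picks between the single summed statistic with
    df = |components| ("summed", the default reading of the method's
    formula) and per-component df = 1 tests whose p-values are pooled
    into one adjustment, a gene keeping its smallest adjusted p
    ("per_component", the alternative reading in which each selected
    vector is tested separately).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if df_mode not in ("summed", "per_component"):
        raise ValueError(f"unknown df_mode {df_mode!r}")
    u = np.asarray(gene_factor, float)
    comps = [int(c) for c in components]
    statistic, sigmas = chi_square_statistic(u, comps, center=center)
    loadings = u[:, [c - 1 for c in comps]]
    if df_mode == "summed":
        df = len(comps)
        p_raw = chi_square_p(statistic, df)
        p_adj = adjust_p(p_raw, adjust_method)
    else:
        df = 1
        per = chi_square_p((loadings / sigmas) ** 2, 1)  # genes x comps
        adj = adjust_p(per.ravel(), adjust_method).reshape(per.shape)
        p_raw = per.min(axis=1)
        p_adj = adj.min(axis=1)
    return GeneScoreTable(
        gene_ids=[str(g) for g in gene_ids],
        components=comps,
        loadings=loadings,
        sigmas=sigmas,
        statistic=statistic,
        df=df,
        p_raw=p_raw,
        p_adj=p_adj,
        alpha=alpha,
        adjust_method=adjust_method,
    )


def select_genes(table: GeneScoreTable, alpha: float | None = None) -> list[str]:
    """Genes with adjusted p strictly below alpha, in ascending p order."""
    if alpha is not None:
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        table = GeneScoreTable(**{**table.__dict__, "alpha": alpha})
    return table.selected_genes()
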