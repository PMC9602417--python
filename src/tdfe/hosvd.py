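"""Tucker decomposition of the expression tensor by HOSVD.

Higher-order singular value decomposition factors a tensor ``x`` into a
core tensor ``G`` and one orthogonal matrix per mode::

    x[i, j, k, l] = sum_{l1 l2 l3 l4} G(l1, l2, l3, l4)
                    * U1[i, l1] * U2[j, l2] * U3[k, l3] * U4[l, l4]

Each factor ``U_n`` holds the left singular vectors of the mode-n
unfolding, ordered by descending singular value; the core is the tensor
mode-multiplied by every factor transpose.  Because the non-gene modes of
the expression tensor have extents (M, K, L) = (3, 3, 2), at most
M*K*L = 18 gene-mode core rows can be non-zero regardless of the number
of genes — the multilinear-rank fact that lets the core slice be
truncated at element 18.

Conventions (pinned so runs are bit-reproducible):

* ``mode`` arguments are 1-based (mode 1 = gene axis), matching the
  component indices l1..l4 used downstream.
* Mode-n unfolding: rows index the chosen axis; columns index the
  remaining axes in their original ascending order, flattened C-style
  (last remaining axis varies fastest).
* Sign fix: each factor column is flipped, if needed, so that its
  largest-magnitude entry is positive (ties resolved to the first such
  entry).  All downstream statistics are invariant to column signs; the
  fix only makes reports deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_tensor import ExpressionTensor

__all__ = ["TuckerFactors", "unfold", "refold", "mode_product", "hosvd", "reconstruct"]


def _check_mode(ndim: int, mode: int) -> int:
    if not 1 <= mode <= ndim:
        raise ValueError(f"mode must be in 1..{ndim}, got {mode}")
    return mode - 1


def unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n matricization: axis ``mode`` becomes the rows."""
    tensor = np.asarray(tensor)
    ax = _check_mode(tensor.ndim, mode)
    return np.moveaxis(tensor, ax, 0).reshape(tensor.shape[ax], -1)


def refold(matrix: np.ndarray, mode: int, shape: tuple[int, ...]) -> np.ndarray:
    """Inverse of :func:`unfold` for a tensor of the given shape."""
    ax = _check_mode(len(shape), mode)
    rest = [s for i, s in enumerate(shape) if i != ax]
    return np.moveaxis(np.asarray(matrix).reshape([shape[ax]] + rest), 0, ax)


def mode_product(tensor: np.ndarray, matrix: np.ndarray, mode: int) -> np.ndarray:
    """Contract the tensor's ``mode`` axis with the matrix's columns.

    The result's extent along ``mode`` equals the matrix row count.
    """
    tensor = np.asarray(tensor)
    matrix = np.asarray(matrix)
    ax = _check_mode(tensor.ndim, mode)
    if matrix.ndim != 2 or matrix.shape[1] != tensor.shape[ax]:
        raise ValueError(
            f"matrix of shape {matrix.shape} cannot contract mode {mode} "
            f"of extent {tensor.shape[ax]}"
        )
    return np.moveaxis(np.tensordot(matrix, tensor, axes=(1, ax)), 0, ax)


def _fix_signs(u: np.ndarray) -> np.ndarray:
    """Flip columns so each column's largest-|entry| is positive."""
    idx = np.argmax(np.abs(u), axis=0)
    signs = np.sign(u[idx, np.arange(u.shape[1])])
    signs[signs == 0] = 1.0
    return u * signs


@dataclass
class TuckerFactors:
    """Core tensor plus one orthonormal factor matrix per mode."""

    core: np.ndarray
    factors: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]
    singular_values: tuple[np.ndarray, ...] | None = None

    @property
    def gene_factor(self) -> np.ndarray:
        """u[l1, i] as an (genes x components) matrix U1."""
        return self.factors[0]

    @property
    def replicate_factor(self) -> np.ndarray:
        return self.factors[1]

    @property
    def time_factor(self) -> np.ndarray:
        return self.factors[2]

    @property
    def exposure_factor(self) -> np.ndarray:
        return self.factors[3]

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(
            directory / "tucker.npz",
            core=self.core,
            **{f"factor{n}": f for n, f in enumerate(self.factors, start=1)},
            **(
                {f"sv{n}": s for n, s in enumerate(self.singular_values, start=1)}
                if self.singular_values is not None
                else {}
            ),
        )
        meta = {
            "core_dims": list(self.core.shape),
            "unfolding": "rows = mode axis; columns = remaining axes, "
            "ascending order, C-contiguous flatten",
            "sign_convention": "largest-magnitude entry of each factor column positive",
        }
        (directory / "tucker_meta.json").write_text(json.dumps(meta, indent=2))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "TuckerFactors":
        with np.load(Path(directory) / "tucker.npz") as npz:
            factors = tuple(npz[f"factor{n}"] for n in range(1, 5))
            svs = tuple(npz[f"sv{n}"] for n in range(1, 5)) if "sv1" in npz else None
            return cls(core=npz["core"], factors=factors, singular_values=svs)


def hosvd(
    tensor: ExpressionTensor | np.ndarray, truncate_gene_factor: bool = False
) -> TuckerFactors:
    """Higher-order SVD of a 4-way tensor.

    Parameters
    ----------
    tensor
        The expression tensor (or a bare 4-way array).
    truncate_gene_factor
        If True, keep only the first M*K*L gene-mode components (the
        economy SVD).  The remaining columns span the null space of the
        gene unfolding and carry structurally zero core weight, so
        nothing downstream changes; the full square factor is the
        default for fidelity to the method's description.
    """
    x = tensor.values if isinstance(tensor, ExpressionTensor) else np.asarray(tensor, float)
    if x.ndim != 4:
        raise ValueError("hosvd expects a 4-way tensor")
    if not np.all(np.isfinite(x)):
        raise ValueError("hosvd requires finite tensor entries")
    factors: list[np.ndarray] = []
    svs: list[np.ndarray] = []
    for mode in range(1, 5):
        a = unfold(x, mode)
        full = not (mode == 1 and truncate_gene_factor)
        u, s, _ = np.linalg.svd(a, full_matrices=full)
        factors.append(_fix_signs(u))
        svs.append(s)
    core = x
    for mode, u in enumerate(factors, start=1):
        core = mode_product(core, u.T, mode)
    return TuckerFactors(core=core, factors=tuple(factors), singular_values=tuple(svs))


def reconstruct(factors: TuckerFactors) -> np.ndarray:
    """Multiply the core back through all four factors."""
    x = factors.core
    for mode, u in enumerate(factors.factors, start=1):
        x = mode_product(x, u, mode)
    return x
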