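"""Interpretability-driven selection of core-tensor components.

The method picks one component per non-gene mode by inspecting the factor
matrices, then ranks gene-mode components by the magnitude of the core
slice at the chosen triple:

* replicate mode — the component with the least variation across
  replicates (biological replicates under identical conditions should
  agree, so a near-constant column is the interpretable choice);
* time mode — a component that is strictly monotone over the postnatal
  days, so the loading reads directly as "expression rises (or falls)
  with age";
* exposure mode — a component whose two entries have opposite signs, i.e.
  a contrast between the exposed and control groups.

With the triple (l2', l3', l4') fixed, the vector ``G(l1, l2', l3', l4')``
over l1 weights each gene-mode component's contribution to that
interpretable pattern; the top components by absolute weight feed the
gene-scoring stage.

All component indices here are 1-based, matching the convention of the
R tooling this methodology family comes from.  Every score is invariant
to flipping the sign of any factor column: monotonicity is tested in both
orientations, the replicate score is a magnitude ratio, and the contrast
score uses the absolute entry difference.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hosvd import TuckerFactors

__all__ = [
    "ComponentChoice",
    "score_replicate_invariance",
    "score_monotonic_time",
    "score_condition_contrast",
    "rank_gene_components",
    "select_components",
]

#: Absolute tolerance on consecutive differences when testing strict
#: monotonicity; continuous-valued factors make exact ties measure-zero,
#: so this only guards against floating-point noise on constant columns.
MONOTONE_TOL = 1e-12


class SelectionError(ValueError):
    """Raised when no factor column satisfies an interpretability criterion."""


@dataclass
class ModeScore:
    """Per-column scores for one mode plus the chosen column (1-based)."""

    scores: list[float | None]
    best: int
    detail: dict = field(default_factory=dict)


def score_replicate_invariance(replicate_factor: np.ndarray) -> ModeScore:
    """Score replicate-factor columns by relative variation; lower is better.

    score(column) = std(entries) / max|entry|.  A constant column scores 0.
    All-zero columns are excluded with a warning (the ratio is undefined).
    Ties go to the smallest index.
    """
    u = np.asarray(replicate_factor, float)
    if u.ndim != 2 or u.shape[0] < 2:
        raise ValueError("replicate factor must be a matrix with >= 2 rows")
    scores: list[float | None] = []
    for col in u.T:
        peak = np.max(np.abs(col))
        if peak == 0.0:
            warnings.warn("all-zero replicate column excluded from scoring")
            scores.append(None)
        else:
            scores.append(float(np.std(col) / peak))
    valid = [(s, i) for i, s in enumerate(scores) if s is not None]
    if not valid:
        raise SelectionError("every replicate column is all-zero")
    best = min(valid)[1] + 1
    return ModeScore(scores=scores, best=best)


def _monotone(col: np.ndarray, direction: str) -> bool:
    d = np.diff(col)
    if direction == "decreasing":
        return bool(np.all(d < -MONOTONE_TOL))
    return bool(np.all(d > MONOTONE_TOL))


def score_monotonic_time(time_factor: np.ndarray, direction: str = "decreasing") -> ModeScore:
    """Flag strictly monotone time-factor columns and pick the best one.

    A column counts as monotone in a direction if either orientation
    (the column or its negation) is strictly monotone that way — singular
    vector signs are arbitrary, and the criterion is about shape.  Among
    the columns matching the requested direction the one with the largest
    first-to-last swing ``|u[0] - u[-1]|`` is chosen (the most pronounced
    trend), ties broken by the smaller index.  ``direction`` may be
    "decreasing", "increasing" or "either".
    """
    if direction not in ("decreasing", "increasing", "either"):
        raise ValueError(f"unknown direction {direction!r}")
    u = np.asarray(time_factor, float)
    if u.ndim != 2 or u.shape[0] < 2:
        raise ValueError("time factor must be a matrix with >= 2 rows")
    dec, inc, swing = [], [], []
    for col in u.T:
        dec.append(_monotone(col, "decreasing") or _monotone(-col, "decreasing"))
        inc.append(_monotone(col, "increasing") or _monotone(-col, "increasing"))
        swing.append(float(abs(col[0] - col[-1])))
    if direction == "decreasing":
        match = dec
    elif direction == "increasing":
        match = inc
    else:
        match = [d or i for d, i in zip(dec, inc)]
    candidates = [(swing[i], i) for i, ok in enumerate(match) if ok]
    if not candidates:
        raise SelectionError(
            f"no time-factor column is strictly monotone {direction}; "
            "inspect the factor and choose the time component manually"
        )
    best = max(candidates, key=lambda t: (t[0], -t[1]))[1] + 1
    return ModeScore(
        scores=swing,
        best=best,
        detail={"decreasing": dec, "increasing": inc},
    )


def score_condition_contrast(exposure_factor: np.ndarray) -> ModeScore:
    """Pick the exposure column contrasting the two groups.

    For L = 2 a column qualifies iff its entries have opposite signs;
    the score is the absolute entry difference and the qualifying column
    with the largest score wins.
    """
    u = np.asarray(exposure_factor, float)
    if u.ndim != 2 or u.shape[0] != 2:
        raise ValueError("exposure factor must have exactly two rows")
    qualifies = [bool(col[0] * col[1] < 0) for col in u.T]
    scores = [float(abs(col[0] - col[1])) for col in u.T]
    candidates = [(scores[i], i) for i, ok in enumerate(qualifies) if ok]
    if not candidates:
        raise SelectionError(
            "no exposure-factor column has opposite-sign entries; "
            "choose the exposure component manually"
        )
    best = max(candidates, key=lambda t: (t[0], -t[1]))[1] + 1
    return ModeScore(scores=scores, best=best, detail={"qualifies": qualifies})


@dataclass
class ComponentChoice:
    """The chosen component per mode and the ranked gene components."""

    replicate_component: int
    time_component: int
    exposure_component: int
    time_direction: str
    gene_components: list[int]
    core_slice: np.ndarray
    criteria_report: dict = field(default_factory=dict)

    def to_json(self) -> str:
        obj = {
            "replicate_component": self.replicate_component,
            "time_component": self.time_component,
            "exposure_component": self.exposure_component,
            "time_direction": self.time_direction,
            "gene_components": self.gene_components,
            "core_slice": np.asarray(self.core_slice).tolist(),
            "criteria_report": self.criteria_report,
        }
        return json.dumps(obj, indent=2)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def rank_gene_components(
    factors: TuckerFactors,
    replicate_component: int,
    time_component: int,
    exposure_component: int,
    top_t: int = 3,
    time_direction: str = "decreasing",
    criteria_report: dict | None = None,
) -> ComponentChoice:
    """Rank gene-mode components by |G(l1, l2', l3', l4')| and keep the top.

    Only the first M*K*L entries of the slice can be structurally
    non-zero (multilinear rank), so ``top_t`` may not exceed that count.
    Ties in magnitude break toward the smaller l1.
    """
    core = factors.core
    n_struct = int(np.prod(core.shape[1:]))
    if not 1 <= top_t <= n_struct:
        raise ValueError(
            f"top_t must be in 1..{n_struct} (the structurally non-zero count), got {top_t}"
        )
    for name, idx, axis in (
        ("replicate", replicate_component, 1),
        ("time", time_component, 2),
        ("exposure", exposure_component, 3),
    ):
        if not 1 <= idx <= core.shape[axis]:
            raise ValueError(f"{name} component {idx} outside 1..{core.shape[axis]}")
    core_slice = core[:, replicate_component - 1, time_component - 1, exposure_component - 1]
    order = np.lexsort((np.arange(core_slice.size), -np.abs(core_slice)))
    top = [int(i) + 1 for i in order[:top_t]]
    return ComponentChoice(
        replicate_component=replicate_component,
        time_component=time_component,
        exposure_component=exposure_component,
        time_direction=time_direction,
        gene_components=top,
        core_slice=core_slice.copy(),
        criteria_report=criteria_report or {},
    )


def select_components(
    factors: TuckerFactors,
    time_direction: str = "decreasing",
    top_t: int = 3,
    replicate_component: int | None = None,
    time_component: int | None = None,
    exposure_component: int | None = None,
) -> ComponentChoice:
    """Run the automatic per-mode criteria, honoring manual overrides.

    Any mode index given explicitly bypasses its criterion, mirroring the
    human-in-the-loop inspection the method describes; the per-column
    scores are still recorded in the report.
    """
    rep = score_replicate_invariance(factors.replicate_factor)
    report: dict = {"replicate_scores": rep.scores}
    l2 = replicate_component or rep.best
    if time_component is None:
        tim = score_monotonic_time(factors.time_factor, time_direction)
        report["time_swing"] = tim.scores
        report.update({f"time_{k}": v for k, v in tim.detail.items()})
        l3 = tim.best
    else:
        l3 = time_component
    if exposure_component is None:
        con = score_condition_contrast(factors.exposure_factor)
        report["exposure_scores"] = con.scores
        report["exposure_qualifies"] = con.detail["qualifies"]
        l4 = con.best
    else:
        l4 = exposure_component
    report["overridden"] = {
        "replicate": replicate_component is not None,
        "time": time_component is not None,
        "exposure": exposure_component is not None,
    }
    return rank_gene_components(
        factors, l2, l3, l4, top_t=top_t, time_direction=time_direction,
        criteria_report=report,
    )
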