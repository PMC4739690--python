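"""Felsenstein's phylogenetically independent contrasts under Brownian motion.

Tip trait values on a fully dichotomous time-tree are transformed into
n_tips - 1 standardized contrasts that are mutually independent when the
trait evolves by Brownian motion. The pruning recursion at an internal node
with children i, j (trait values X_i, X_j, branch durations v_i, v_j):

    contrast        C  = (X_i - X_j) / sqrt(v_i + v_j)
    ancestral value X_a = (X_i / v_i + X_j / v_j) / (1/v_i + 1/v_j)
    parent duration v_a' = v_a + v_i * v_j / (v_i + v_j)

Contrast-space regression is offered in two modes: the statistically standard
``positivized_origin`` (each contrast pair sign-flipped so the predictor
contrast is nonnegative, slope fit through the origin), and
``absolute_intercept`` (absolute values of both contrast sets, ordinary
regression with intercept), kept because some workers regress absolute
contrast magnitudes directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chronophylo import TimeTree
from .records import ValidationError
from .regression import RegressionResult, ols_fit

__all__ = ["Contrast", "ContrastSet", "felsenstein_contrasts", "contrast_regression"]

REGRESSION_MODES = ("positivized_origin", "absolute_intercept")


@dataclass(frozen=True)
class Contrast:
    node_id: str
    raw_difference: float
    contrast: float
    ancestral_value: float
    adjusted_duration: float


@dataclass(frozen=True)
class ContrastSet:
    """Standardized contrasts for one trait, in postorder node order."""

    contrasts: tuple[Contrast, ...]
    root_value: float

    def values(self) -> np.ndarray:
        return np.array([c.contrast for c in self.contrasts])

    def node_ids(self) -> tuple[str, ...]:
        return tuple(c.node_id for c in self.contrasts)

    def __len__(self) -> int:
        return len(self.contrasts)


def felsenstein_contrasts(tree: TimeTree, traits: dict[str, float]) -> ContrastSet:
    """Compute standardized independent contrasts of `traits` on `tree`.

    Requires every branch duration > 0 (run after 'equal' calibration) and a
    finite trait value for every tip.
    """
    dtree = tree.tree
    tips = tree.taxa()
    missing = [t for t in tips if t not in traits]
    if missing:
        raise ValidationError(f"traits missing for tips: {missing}")
    for nd in dtree.preorder_node_iter():
        if nd.parent_node is not None and nd.edge.length <= 0:
            raise ValidationError(
                "zero-duration branch encountered; time-calibrate with the "
                "'equal' method before computing contrasts"
            )
    contrasts: list[Contrast] = []
    counter = 0
    # pruning pass: (value, working duration) per node
    for nd in dtree.postorder_node_iter():
        if nd.is_leaf():
            value = float(traits[nd.taxon.label])
            if not np.isfinite(value):
                raise ValidationError(
                    f"non-finite trait value for {nd.taxon.label!r}"
                )
            nd._pic_value = value
            nd._pic_v = nd.edge.length
            continue
        children = nd.child_nodes()
        if len(children) != 2:
            raise ValidationError(
                "contrasts require a fully dichotomous tree"
            )
        i, j = children
        vi, vj = i._pic_v, j._pic_v
        diff = i._pic_value - j._pic_value
        counter += 1
        node_id = f"node{counter}"
        contrasts.append(
            Contrast(
                node_id=node_id,
                raw_difference=diff,
                contrast=diff / np.sqrt(vi + vj),
                ancestral_value=(i._pic_value / vi + j._pic_value / vj)
                / (1.0 / vi + 1.0 / vj),
                adjusted_duration=(nd.edge.length or 0.0) + vi * vj / (vi + vj),
            )
        )
        nd._pic_value = contrasts[-1].ancestral_value
        nd._pic_v = contrasts[-1].adjusted_duration
    return ContrastSet(
        contrasts=tuple(contrasts), root_value=float(dtree.seed_node._pic_value)
    )


def contrast_regression(
    cx: ContrastSet, cy: ContrastSet, mode: str = "positivized_origin"
) -> RegressionResult:
    """Regress y-contrasts on x-contrasts.

    ``positivized_origin``: each pair is sign-flipped so the x-contrast is
    >= 0 and the slope is fit through the origin (R-squared about zero).
    ``absolute_intercept``: both sets enter as absolute values and an ordinary
    intercept model is fit.
    """
    if mode not in REGRESSION_MODES:
        raise ValidationError(f"unknown mode {mode!r}; choose {REGRESSION_MODES}")
    if cx.node_ids() != cy.node_ids():
        raise ValidationError("contrast sets come from different trees")
    x = cx.values()
    y = cy.values()
    if len(x) < 3:
        raise ValidationError("need at least 3 contrasts")
    if np.all(x == 0):
        raise ValidationError("no variation in predictor contrasts")
    if mode == "positivized_origin":
        sign = np.where(x < 0, -1.0, 1.0)
        return ols_fit(sign * x, sign * y, with_intercept=False)
    return ols_fit(np.abs(x), np.abs(y), with_intercept=True)
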